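"""Collapse aligned sequences into distinct haplotypes.

Two individuals share a haplotype iff their sequences are identical under
the chosen ambiguity policy:

``strict`` (default)
    character-for-character identity; every column participates.
``ignore-ambiguous-sites``
    columns containing a gap, ``N`` or any IUPAC ambiguity code in *any*
    record are dropped before comparison (complete deletion), so ambiguity
    never splits haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AlignmentError
from .seqio import UNAMBIGUOUS, Alignment

POLICIES = ("strict", "ignore-ambiguous-sites")


@dataclass(frozen=True)
class Haplotype:
    """One distinct sequence with the individuals that carry it."""

    key: str
    members: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeTable:
    """Distinct haplotypes of an alignment, ordered by descending count
    (ties broken by first occurrence in the input)."""

    haplotypes: list[Haplotype]
    seq_length: int = field(default=0)

    @property
    def n(self) -> int:
        """Total number of individuals."""
        return sum(h.count for h in self.haplotypes)

    @property
    def nH(self) -> int:
        """Number of distinct haplotypes."""
        return len(self.haplotypes)

    @property
    def counts(self) -> list[int]:
        return [h.count for h in self.haplotypes]

    @property
    def frequencies(self) -> list[float]:
        """f_h = count / n per haplotype."""
        n = self.n
        return [h.count / n for h in self.haplotypes]

    def to_tsv(self) -> str:
        lines = ["haplotype\tcount\tmembers"]
        for i, h in enumerate(self.haplotypes):
            lines.append(f"{i}\t{h.count}\t{','.join(h.members)}")
        return "\n".join(lines) + "\n"


def _mask_ambiguous_columns(alignment: Alignment) -> list[str]:
    """Drop every column where any record carries a non-ACGT character."""
    seqs = [seq for _, seq in alignment.records]
    keep = [
        i
        for i in range(alignment.length)
        if all(s[i] in UNAMBIGUOUS for s in seqs)
    ]
    return ["".join(s[i] for i in keep) for s in seqs]


def collapse(alignment: Alignment, policy: str = "strict") -> HaplotypeTable:
    """Group individuals by identical sequence under *policy*.

    Returns a :class:`HaplotypeTable` whose keys are the sequences actually
    compared (full sequences under ``strict``; ambiguity-free columns under
    ``ignore-ambiguous-sites``), so downstream distances operate on the same
    site set that defined the haplotypes.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown ambiguity policy {policy!r}; choose from {POLICIES}")
    if policy == "strict":
        keys = [seq for _, seq in alignment.records]
    else:
        keys = _mask_ambiguous_columns(alignment)
        if keys and len(keys[0]) == 0:
            raise AlignmentError(
                "ignore-ambiguous-sites removed every column; no sites left "
                "to define haplotypes"
            )
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for (rid, _), key in zip(alignment.records, keys):
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rid)
    first_seen = {key: i for i, key in enumerate(order)}
    ordered = sorted(order, key=lambda k: (-len(groups[k]), first_seen[k]))
    table = HaplotypeTable(
        haplotypes=[Haplotype(key=k, members=tuple(groups[k])) for k in ordered],
        seq_length=len(keys[0]),
    )
    return table
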