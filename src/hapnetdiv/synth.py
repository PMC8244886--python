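"""Synthetic alignments realizing prescribed haplotype-network topologies.

Each edge of a specified haplotype tree consumes its own block of unique
sites, mutated once along that edge, so pairwise haplotype distances equal
tree path lengths exactly. Distances are then additive with no homoplasy,
the minimum spanning tree over them is unique and equals the specified
tree, and the full pipeline recovers the requested degree sequence. This
makes every pipeline stage testable without any external sequence files.

The shipped fixtures mirror the published model networks: 21-individual
panels with 6–21 haplotypes and 2–4 haplotype classes, and 48-individual
panels used for the class-count and evenness property demonstrations.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import SpecError
from .seqio import Alignment

_BASES = "ACGT"


def _mutate(base: str) -> str:
    # one mutational step: cycle A -> C -> G -> T -> A at the site
    return _BASES[(_BASES.index(base) + 1) % 4]


@dataclass
class NetworkSpec:
    """A haplotype tree plus per-haplotype individual counts.

    ``edges`` are ``(parent, child)`` or ``(parent, child, steps)`` tuples
    over haplotype indices 0..k-1 (steps >= 1, default 1). Haplotype 0 is
    the background (all-'A') sequence. ``seq_padding`` appends invariant
    sites so alignments have a realistic length beyond the mutated columns.
    """

    edges: list[tuple]
    individuals_per_haplotype: list[int]
    seed: int = 0
    seq_padding: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        k = len(self.individuals_per_haplotype)
        if k < 1:
            raise SpecError("at least one haplotype is required")
        if any(c < 1 for c in self.individuals_per_haplotype):
            raise SpecError("every haplotype needs >= 1 individual (zero counts)")
        norm: list[tuple[int, int, int]] = []
        for e in self.edges:
            if len(e) == 2:
                u, v, steps = e[0], e[1], 1
            elif len(e) == 3:
                u, v, steps = e
            else:
                raise SpecError(f"edge {e!r} must be (parent, child[, steps])")
            if steps < 1:
                raise SpecError(f"edge {e!r} has steps < 1")
            if not (0 <= u < k and 0 <= v < k) or u == v:
                raise SpecError(f"edge {e!r} out of range for {k} haplotypes")
            norm.append((int(u), int(v), int(steps)))
        self.edges = norm
        if len(norm) != k - 1:
            raise SpecError(f"a tree over {k} haplotypes needs {k - 1} edges")
        # connectivity over an undirected view => tree (right edge count + connected)
        adj: dict[int, list[int]] = {i: [] for i in range(k)}
        for u, v, _ in norm:
            adj[u].append(v)
            adj[v].append(u)
        seen = {0}
        stack = [0]
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(seen) != k:
            raise SpecError("edge list does not connect all haplotypes (not a tree)")

    @property
    def n_haplotypes(self) -> int:
        return len(self.individuals_per_haplotype)

    @property
    def n_individuals(self) -> int:
        return sum(self.individuals_per_haplotype)

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "edges": [list(e) for e in self.edges],
                "individuals_per_haplotype": list(self.individuals_per_haplotype),
                "seed": self.seed,
                "seq_padding": self.seq_padding,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        try:
            payload = json.loads(text)
            return cls(
                edges=[tuple(e) for e in payload["edges"]],
                individuals_per_haplotype=list(payload["individuals_per_haplotype"]),
                seed=int(payload.get("seed", 0)),
                seq_padding=int(payload.get("seq_padding", 0)),
                name=str(payload.get("name", "synthetic")),
            )
        except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
            raise SpecError(f"invalid network spec JSON: {exc}") from exc


def haplotype_sequences(spec: NetworkSpec) -> list[str]:
    """Per-haplotype sequences; pairwise distance equals tree path length."""
    total_steps = sum(steps for _, _, steps in spec.edges)
    length = total_steps + spec.seq_padding
    if length < 1:
        length = 1  # single-haplotype degenerate spec still needs a site
    seqs: dict[int, list[str]] = {0: ["A"] * length}
    site = 0
    site_of_edge: dict[tuple[int, int], tuple[int, int]] = {}
    for u, v, steps in spec.edges:
        site_of_edge[(u, v)] = (site, steps)
        site += steps
    # BFS from the background haplotype; each edge flips its own sites
    adj: dict[int, list[tuple[int, int, int]]] = {i: [] for i in range(spec.n_haplotypes)}
    for u, v, steps in spec.edges:
        start, _ = site_of_edge[(u, v)]
        adj[u].append((v, start, steps))
        adj[v].append((u, start, steps))
    pending = [0]
    while pending:
        node = pending.pop()
        for child, start, steps in adj[node]:
            if child in seqs:
                continue
            seq = list(seqs[node])
            for s in range(start, start + steps):
                seq[s] = _mutate(seq[s])
            seqs[child] = seq
            pending.append(child)
    return ["".join(seqs[i]) for i in range(spec.n_haplotypes)]


def realize(spec: NetworkSpec) -> Alignment:
    """Expand a spec into an alignment with deterministic individual ids.

    Individuals of haplotype ``h`` are named ``h<h>_<replicate>``; each is
    also assigned its own population label (every individual its own
    population, as in the published model panels).
    """
    seqs = haplotype_sequences(spec)
    records: list[tuple[str, str]] = []
    for h, count in enumerate(spec.individuals_per_haplotype):
        for rep in range(count):
            records.append((f"h{h}_{rep}", seqs[h]))
    population_of = {rid: f"pop_{rid}" for rid, _ in records}
    return Alignment(records=records, population_of=population_of)


def write_fixture(spec: NetworkSpec, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write the realized alignment as ``<prefix>.fasta`` and a population
    map as ``<prefix>_sites.csv``; returns both paths."""
    from .seqio import write_fasta

    alignment = realize(spec)
    prefix = Path(out_prefix)
    fasta_path = prefix.with_name(prefix.name + ".fasta")
    popmap_path = prefix.with_name(prefix.name + "_sites.csv")
    write_fasta(alignment, fasta_path)
    with open(popmap_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "population"])
        for rid in alignment.ids:
            writer.writerow([rid, alignment.population_of[rid]])
    return fasta_path, popmap_path


def star_spec(
    n_leaves: int,
    hub_count: int,
    leaf_counts: Sequence[int] | int,
    name: str = "star",
    seq_padding: int = 0,
) -> NetworkSpec:
    """Star topology: haplotype 0 is the hub; leaves sit one step away but
    >= 2 steps from each other, so the star is the unique MST."""
    if isinstance(leaf_counts, int):
        leaf_counts = [leaf_counts] * n_leaves
    if len(leaf_counts) != n_leaves:
        raise SpecError("leaf_counts length must equal n_leaves")
    edges = [(0, i + 1) for i in range(n_leaves)]
    return NetworkSpec(
        edges=edges,
        individuals_per_haplotype=[hub_count, *leaf_counts],
        name=name,
        seq_padding=seq_padding,
    )


def chain_spec(
    counts: Sequence[int], name: str = "chain", seq_padding: int = 0
) -> NetworkSpec:
    """Path topology h0 - h1 - ... - h(k-1), one step per edge."""
    k = len(counts)
    edges = [(i, i + 1) for i in range(k - 1)]
    return NetworkSpec(
        edges=edges,
        individuals_per_haplotype=list(counts),
        name=name,
        seq_padding=seq_padding,
    )


def panel_fixtures() -> dict[str, NetworkSpec]:
    """Named model-network specs used throughout the tests and examples.

    ``fig1A``
        21 individuals, 6 haplotypes in a star: a 5-branch hub holding 6
        individuals and five 1-branch tips holding 3 each — class breakdown
        (1:15, 5:6).
    ``fig1B``
        21 individuals, 6 haplotypes: a 4-branch hub (3 individuals), a
        2-branch internal haplotype (3), and four 1-branch tips (6,3,3,3) —
        classes (1:15, 2:3, 4:3), haplotype counts {6,3,3,3,3,3}.
    ``unique21_chain``
        21 individuals each with a private haplotype, arranged in a chain;
        Hd is exactly 1 regardless of topology.
    ``s1B_even2class``
        48 individuals in a 4-haplotype chain with 12 individuals each: a
        1-branch class and a 2-branch class with 24 individuals apiece —
        the maximally even two-class configuration.
    """
    fixtures = {
        "fig1A": star_spec(5, hub_count=6, leaf_counts=3, name="fig1A"),
        "fig1B": NetworkSpec(
            edges=[(0, 1), (0, 2), (0, 3), (0, 4), (4, 5)],
            individuals_per_haplotype=[3, 6, 3, 3, 3, 3],
            name="fig1B",
        ),
        "unique21_chain": chain_spec([1] * 21, name="unique21_chain"),
        "s1B_even2class": chain_spec([12, 12, 12, 12], name="s1B_even2class"),
    }
    return fixtures


def even_class_chain(
    n_internal_haplotypes: int, individuals_per_haplotype: int, name: str = "even_chain"
) -> NetworkSpec:
    """Chain with 2 end haplotypes (1-branch class) and a given number of
    internal haplotypes (2-branch class), all equally weighted — a family
    used for evenness sweeps at the network level."""
    k = n_internal_haplotypes + 2
    return chain_spec([individuals_per_haplotype] * k, name=name)
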