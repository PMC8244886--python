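"""Diversity and complexity metrics for haplotype networks.

Haplotypes are grouped into *classes* by their number of subtending
branches (node degree). For ``n`` individuals, ``nH`` haplotypes with
frequencies ``f_h`` and classes with individual frequencies ``f_Hc``:

``Hd = (1 - Σ f_h²) · n/(n-1)``
    haplotype diversity — the probability that two individuals drawn
    without replacement carry different haplotypes (Nei).
``Bd = (1 - Σ f_Hc²) · n/(n-1)``
    branch diversity — the same construction on haplotype-class
    frequencies: the probability that two individuals drawn without
    replacement fall in different classes.
``HBd = (1 - Σ f_h²) · (1 - Σ f_Hc²) · n/(n-1)``
    haplotype network branch diversity, the combined complexity metric.
    Note the single n/(n-1) correction: this literal form, not the product
    of the two individually corrected metrics, is what reproduces the
    published model-network values. ``both_corrected=True`` exposes the
    Hd·Bd product for sensitivity checks.
``Nd = (1 - Σ nhHc·(nbHc/nH)²) · nH/(nH-1)``
    node diversity, the earlier degree-based index. The inner terms are not
    frequencies (branch counts are divided by the number of haplotypes), so
    Nd — and HNd = Hd·Nd — has no probabilistic interpretation and can leave
    [0, 1] on degenerate inputs (e.g. Nd = 1 for any two-haplotype network).
    Values are reported as computed, never clamped.

π (nucleotide diversity), the mean per-site pairwise difference over all
C(n,2) individual pairs, is included for comparison only; it is the one
metric here that sees mutational distances rather than topology.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateNetworkError, NetworkValidationError, UndefinedMetricError
from .haplotypes import HaplotypeTable, collapse
from .netbuild import HaplotypeNetwork, build_msn, hamming_distances
from .seqio import Alignment


@dataclass(frozen=True)
class HaplotypeClass:
    """One haplotype class: all haplotypes with the same degree."""

    nbHc: int  #: subtending branches shared by the class's haplotypes
    nhHc: int  #: haplotypes in the class
    niHc: int  #: individuals in the class


@dataclass
class ClassDecomposition:
    """Degree-based partition of a network's haplotypes, sorted by nbHc."""

    classes: list[HaplotypeClass]
    nH: int
    n: int

    def __post_init__(self) -> None:
        degrees = [c.nbHc for c in self.classes]
        if len(set(degrees)) != len(degrees):
            raise NetworkValidationError("class branch counts must be unique")
        if sum(c.nhHc for c in self.classes) != self.nH:
            raise NetworkValidationError("class haplotype counts must sum to nH")
        if sum(c.niHc for c in self.classes) != self.n:
            raise NetworkValidationError("class individual counts must sum to n")
        if any(c.nhHc < 1 or c.niHc < 1 for c in self.classes):
            raise NetworkValidationError("every class needs >= 1 haplotype/individual")
        self.classes = sorted(self.classes, key=lambda c: c.nbHc)

    @property
    def nHc(self) -> int:
        return len(self.classes)

    @property
    def individual_counts(self) -> list[int]:
        return [c.niHc for c in self.classes]

    @property
    def class_frequencies(self) -> list[float]:
        """f_Hc = niHc / n per class."""
        return [c.niHc / self.n for c in self.classes]


def decompose_classes(
    network: HaplotypeNetwork,
    table: Optional[HaplotypeTable] = None,
    count_alternative: bool = True,
) -> ClassDecomposition:
    """Group a network's haplotypes by degree.

    If *table* is given, it must describe the same haplotypes (nodes are
    haplotype indices into the table); individual counts always come from
    the network's nodes.
    """
    if table is not None:
        if network.nH != table.nH:
            raise NetworkValidationError(
                f"network has {network.nH} nodes but table has {table.nH} haplotypes"
            )
        expected = {i: c for i, c in enumerate(table.counts)}
        if dict(network.counts) != expected:
            raise NetworkValidationError(
                "network node counts disagree with haplotype table"
            )
    degrees = network.degrees(count_alternative=count_alternative)
    by_degree: dict[int, list] = {}
    for node, deg in degrees.items():
        by_degree.setdefault(deg, []).append(node)
    classes = [
        HaplotypeClass(
            nbHc=deg,
            nhHc=len(nodes),
            niHc=sum(network.counts[node] for node in nodes),
        )
        for deg, nodes in sorted(by_degree.items())
    ]
    return ClassDecomposition(classes=classes, nH=network.nH, n=network.n)


def _corrected_heterozygosity(counts: Sequence[int], n: int) -> float:
    sum_sq = sum((c / n) ** 2 for c in counts)
    return (1.0 - sum_sq) * n / (n - 1)


def hd(counts: Sequence[int], n: Optional[int] = None, lenient: bool = False) -> float:
    """Haplotype diversity from per-haplotype individual counts.

    Equals the without-replacement pair probability
    ``1 - Σ c(c-1) / (n(n-1))``. Undefined for n < 2; with ``lenient=True``
    the single-individual case returns 0 instead of raising.
    """
    counts = list(counts)
    if any(c < 1 for c in counts):
        raise UndefinedMetricError("haplotype counts must be >= 1")
    total = sum(counts)
    if n is None:
        n = total
    elif n != total:
        raise UndefinedMetricError(f"counts sum to {total}, not n={n}")
    if n < 2:
        if lenient:
            return 0.0
        raise UndefinedMetricError("Hd undefined for n < 2")
    return _corrected_heterozygosity(counts, n)


def bd(decomp: ClassDecomposition, lenient: bool = False) -> float:
    """Branch diversity from a class decomposition.

    Applies the Hd construction to class individual frequencies; 0 whenever
    there is a single class (two-haplotype networks, pure cycles, ...).
    """
    if decomp.n < 2:
        if lenient:
            return 0.0
        raise UndefinedMetricError("Bd undefined for n < 2")
    return _corrected_heterozygosity(decomp.individual_counts, decomp.n)


def nd(decomp: ClassDecomposition, lenient: bool = False) -> float:
    """Node diversity: the adjusted degree-distribution index.

    ``(1 - Σ nhHc·(nbHc/nH)²) · nH/(nH-1)``. Not a probability; degenerate
    inputs can give values outside [0, 1] and are reported as computed.
    """
    if decomp.nH < 2:
        if lenient:
            return 0.0
        raise UndefinedMetricError("Nd undefined for nH < 2")
    nH = decomp.nH
    sum_term = sum(c.nhHc * (c.nbHc / nH) ** 2 for c in decomp.classes)
    return (1.0 - sum_term) * nH / (nH - 1)


def hnd(hd_value: float, nd_value: float) -> float:
    """Combined Hd·Nd index (combination formula assumed as a product, by
    symmetry with HBd = Hd·Bd; reported for comparison only)."""
    return hd_value * nd_value


def hbd(
    haplotype_counts: Sequence[int],
    class_counts: Sequence[int],
    n: Optional[int] = None,
    both_corrected: bool = False,
    lenient: bool = False,
) -> float:
    """Haplotype network branch diversity.

    ``(1 - Σ f_h²)(1 - Σ f_Hc²)·n/(n-1)`` — a single sample-size correction
    (see module docstring). With ``both_corrected=True`` returns the plain
    product Hd·Bd, which carries the correction twice.
    """
    haplotype_counts = list(haplotype_counts)
    class_counts = list(class_counts)
    total = sum(haplotype_counts)
    if sum(class_counts) != total:
        raise UndefinedMetricError("haplotype and class counts must sum to the same n")
    if n is None:
        n = total
    elif n != total:
        raise UndefinedMetricError(f"counts sum to {total}, not n={n}")
    if n < 2:
        if lenient:
            return 0.0
        raise UndefinedMetricError("HBd undefined for n < 2")
    gh = 1.0 - sum((c / n) ** 2 for c in haplotype_counts)
    gc = 1.0 - sum((c / n) ** 2 for c in class_counts)
    corr = n / (n - 1)
    if both_corrected:
        return gh * gc * corr * corr
    return gh * gc * corr


def nucleotide_diversity(
    table: HaplotypeTable,
    dist: np.ndarray,
    seq_length: Optional[int] = None,
) -> float:
    """Mean per-site pairwise difference over all C(n, 2) individual pairs.

    ``π = Σ_{i<j haplotypes} c_i c_j d_ij / (L · C(n, 2))``; within-haplotype
    pairs contribute zero. No sample-size correction is applied.
    """
    n = table.n
    if n < 2:
        raise UndefinedMetricError("pi undefined for n < 2")
    if seq_length is None:
        seq_length = table.seq_length
    if seq_length < 1:
        raise UndefinedMetricError("sequence length must be >= 1")
    counts = table.counts
    dist = np.asarray(dist)
    total = 0.0
    for i in range(table.nH):
        for j in range(i + 1, table.nH):
            total += counts[i] * counts[j] * dist[i, j]
    pairs = math.comb(n, 2)
    return float(total / (seq_length * pairs))


@dataclass
class ReportOptions:
    """Pipeline switches recorded alongside every report."""

    policy: str = "strict"  #: ambiguity policy for collapsing/distances
    epsilon: int = 0  #: extra slack for alternative links (mutational steps)
    count_alternative: bool = True  #: count alternative links as branches
    lenient: bool = False  #: degenerate inputs yield zeros instead of raising
    both_corrected: bool = False  #: HBd as Hd·Bd (double correction)


@dataclass
class MetricsReport:
    """All metrics for one dataset, with the settings that produced them."""

    dataset: str
    n: int
    nH: int
    nHc: int
    Hd: float
    Bd: float
    HBd: float
    Nd: float
    HNd: float
    pi: Optional[float]
    degenerate: bool = False
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "MetricsReport":
        return cls(**payload)


def report_from_network(
    network: HaplotypeNetwork,
    options: Optional[ReportOptions] = None,
    dataset: str = "network",
    pi: Optional[float] = None,
) -> MetricsReport:
    """Compute every network metric from an already-built network.

    π needs sequences, so it stays ``None`` unless supplied.
    """
    options = options or ReportOptions()
    decomp = decompose_classes(network, count_alternative=options.count_alternative)
    counts = [network.counts[node] for node in network.nodes]
    hd_val = hd(counts, lenient=options.lenient)
    bd_val = bd(decomp, lenient=options.lenient)
    nd_val = nd(decomp, lenient=options.lenient)
    return MetricsReport(
        dataset=dataset,
        n=network.n,
        nH=network.nH,
        nHc=decomp.nHc,
        Hd=hd_val,
        Bd=bd_val,
        HBd=hbd(
            counts,
            decomp.individual_counts,
            both_corrected=options.both_corrected,
            lenient=options.lenient,
        ),
        Nd=nd_val,
        HNd=hnd(hd_val, nd_val),
        pi=pi,
        settings=asdict(options),
    )


def compute_report(
    alignment: Alignment,
    options: Optional[ReportOptions] = None,
    dataset: str = "alignment",
) -> MetricsReport:
    """End-to-end pipeline: collapse -> distances -> MSN -> classes -> metrics.

    Degenerate inputs (a single haplotype, or a single individual) raise
    :class:`DegenerateNetworkError` unless ``options.lenient``, in which case
    an all-zero report flagged ``degenerate=True`` is returned.
    """
    options = options or ReportOptions()
    table = collapse(alignment, policy=options.policy)
    if table.nH < 2 or table.n < 2:
        if not options.lenient:
            raise DegenerateNetworkError(
                f"cannot build a network from {table.nH} haplotype(s) / "
                f"{table.n} individual(s); pass lenient=True for an all-zero report"
            )
        return MetricsReport(
            dataset=dataset,
            n=table.n,
            nH=table.nH,
            nHc=1 if table.nH else 0,
            Hd=0.0,
            Bd=0.0,
            HBd=0.0,
            Nd=0.0,
            HNd=0.0,
            pi=0.0,
            degenerate=True,
            settings=asdict(options),
        )
    dist = hamming_distances(table, policy=options.policy)
    network = build_msn(dist, counts=table.counts, epsilon=options.epsilon)
    report = report_from_network(
        network,
        options=options,
        dataset=dataset,
        pi=nucleotide_diversity(table, dist),
    )
    return report
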