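import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import pair_diversity
from hapnetdiv import (
    Alignment,
    ClassDecomposition,
    DegenerateNetworkError,
    HaplotypeClass,
    ReportOptions,
    UndefinedMetricError,
    bd,
    build_msn,
    collapse,
    compute_report,
    decompose_classes,
    hamming_distances,
    hbd,
    hd,
    hnd,
    nd,
    nucleotide_diversity,
)


def decomp(pairs, n):
    """pairs: iterable of (nbHc, nhHc, niHc)."""
    classes = [HaplotypeClass(*p) for p in pairs]
    return ClassDecomposition(classes=classes, nH=sum(p[1] for p in pairs), n=n)


PANEL_A = decomp([(1, 5, 15), (5, 1, 6)], n=21)
PANEL_B = decomp([(1, 4, 15), (2, 1, 3), (4, 1, 3)], n=21)


class TestDecompose:
    def test_fig1b_classes_match_published_breakdown(self, fig1b_alignment):
        table = collapse(fig1b_alignment)
        net = build_msn(hamming_distances(table), counts=table.counts)
        d = decompose_classes(net, table)
        assert [(c.nbHc, c.nhHc, c.niHc) for c in d.classes] == [
            (1, 4, 15),
            (2, 1, 3),
            (4, 1, 3),
        ]
        assert d.nHc == 3

    def test_two_haplotypes_form_single_class(self):
        aln = Alignment(records=[("a", "ACGT"), ("b", "ACGA"), ("c", "ACGA")])
        table = collapse(aln)
        net = build_msn(hamming_distances(table), counts=table.counts)
        d = decompose_classes(net, table)
        assert [(c.nbHc, c.nhHc, c.niHc) for c in d.classes] == [(1, 2, 3)]

    def test_cycle_network_is_one_two_branch_class(self):
        # 4-cycle: mutually-tied square; all degrees 2 once the equal-cost
        # alternative links are counted
        dist = np.array(
            [[0, 1, 2, 1], [1, 0, 1, 2], [2, 1, 0, 1], [1, 2, 1, 0]]
        )
        net = build_msn(dist)
        d = decompose_classes(net)
        assert d.nHc == 1
        assert d.classes[0].nbHc == 2


class TestHd:
    def test_monomorphic_sample_has_zero_diversity(self):
        assert hd([21]) == 0.0

    def test_all_unique_sample_has_diversity_one(self):
        assert hd([1] * 21) == pytest.approx(1.0)

    def test_worked_value_from_pair_enumeration(self):
        # brute-force over all 210 unordered pairs gives 180/210
        counts = [6, 3, 3, 3, 3, 3]
        assert pair_diversity(counts) == pytest.approx(180 / 210)
        assert hd(counts) == pytest.approx(0.857143, abs=1e-6)

    def test_undefined_below_two_individuals(self):
        with pytest.raises(UndefinedMetricError):
            hd([1])
        assert hd([1], lenient=True) == 0.0


class TestNd:
    def test_published_worked_example(self):
        assert nd(PANEL_B) == pytest.approx(0.4)

    def test_cycle_network_scores_zero(self):
        assert nd(decomp([(2, 4, 4)], n=4)) == pytest.approx(0.0)

    def test_two_haplotype_network_scores_one(self):
        # (1 - 2*(1/2)^2) * 2 = 1: a degenerate value with no probabilistic
        # reading, reported unclamped
        assert nd(decomp([(1, 2, 2)], n=2)) == pytest.approx(1.0)

    def test_undefined_for_single_haplotype(self):
        with pytest.raises(UndefinedMetricError):
            nd(decomp([(0, 1, 5)], n=5))


class TestBd:
    def test_worked_example_three_classes(self):
        assert bd(PANEL_B) == pytest.approx(0.471429, abs=1e-6)

    def test_panel_a_two_classes(self):
        assert bd(PANEL_A) == pytest.approx(0.428571, abs=1e-6)

    def test_single_class_scores_zero_regardless_of_frequency(self):
        for counts in ([(1, 2, 21)], [(2, 5, 7)]):
            assert bd(decomp(counts, n=counts[0][2])) == 0.0


class TestHnd:
    @pytest.mark.parametrize("h, n_, expected", [(0.0, 0.7, 0.0), (0.7, 0.0, 0.0)])
    def test_absorbing_zero(self, h, n_, expected):
        assert hnd(h, n_) == expected

    def test_panel_b_product(self):
        assert hnd(hd([6, 3, 3, 3, 3, 3]), nd(PANEL_B)) == pytest.approx(
            0.342857, abs=1e-6
        )


class TestHbd:
    def test_panel_a_single_correction(self):
        value = hbd([6, 3, 3, 3, 3, 3], [15, 6])
        assert value == pytest.approx(0.349854, abs=1e-6)
        # the double-corrected product is a different (non-published) number
        assert hbd([6, 3, 3, 3, 3, 3], [15, 6], both_corrected=True) == pytest.approx(
            hd([6, 3, 3, 3, 3, 3]) * bd(PANEL_A)
        )

    def test_panel_b_literal_form(self):
        assert hbd([6, 3, 3, 3, 3, 3], [15, 3, 3]) == pytest.approx(
            0.384840, abs=1e-6
        )

    def test_monomorphic_sample_scores_zero(self):
        assert hbd([21], [21]) == 0.0

    def test_mismatched_totals_rejected(self):
        with pytest.raises(UndefinedMetricError):
            hbd([3, 3], [5])


class TestNucleotideDiversity:
    def test_identical_sequences_give_zero(self):
        aln = Alignment(records=[("a", "ACGT"), ("b", "ACGT")])
        table = collapse(aln)
        assert nucleotide_diversity(table, np.zeros((1, 1))) == 0.0

    def test_single_pair_single_difference(self):
        aln = Alignment(records=[("a", "A" * 10), ("b", "C" + "A" * 9)])
        table = collapse(aln)
        dist = hamming_distances(table)
        assert nucleotide_diversity(table, dist) == pytest.approx(0.1)

    def test_three_individuals_by_pair_enumeration(self):
        # counts {2,1}, d=2, L=10: pairs (a1,a2)=0, (a1,b)=2, (a2,b)=2
        seq_a = "A" * 10
        seq_b = "CC" + "A" * 8
        aln = Alignment(records=[("a1", seq_a), ("a2", seq_a), ("b", seq_b)])
        table = collapse(aln)
        dist = hamming_distances(table)
        assert nucleotide_diversity(table, dist) == pytest.approx(4 / 30)


class TestComputeReport:
    def test_fig1b_end_to_end(self, fig1b_alignment):
        report = compute_report(fig1b_alignment, dataset="fig1B")
        assert (report.n, report.nH, report.nHc) == (21, 6, 3)
        assert round(report.Hd, 2) == 0.86
        assert round(report.Bd, 2) == 0.47
        assert report.Nd == pytest.approx(0.4)

    def test_monomorphic_alignment_degenerate_convention(self):
        aln = Alignment(records=[(f"s{i}", "ACGT") for i in range(5)])
        with pytest.raises(DegenerateNetworkError):
            compute_report(aln)
        report = compute_report(aln, ReportOptions(lenient=True))
        assert report.degenerate
        assert (report.Hd, report.Bd, report.HBd) == (0.0, 0.0, 0.0)

    def test_even_two_class_48_panel(self, panels):
        from hapnetdiv import realize

        report = compute_report(realize(panels["s1B_even2class"]))
        assert report.n == 48
        assert report.Bd == pytest.approx(0.510638, abs=1e-6)

    def test_settings_recorded(self, fig1a_alignment):
        opts = ReportOptions(policy="strict", epsilon=1, both_corrected=True)
        report = compute_report(fig1a_alignment, opts)
        assert report.settings["epsilon"] == 1
        assert report.settings["both_corrected"] is True


count_vectors = st.integers(2, 60).flatmap(
    lambda n: st.lists(st.integers(1, n), min_size=1).filter(
        lambda parts: sum(parts) <= n
    ).map(lambda parts: parts + [n - sum(parts)] if sum(parts) < n else parts)
)


@settings(deadline=None, max_examples=200)
@given(counts=count_vectors)
def test_hd_equals_pair_enumeration_oracle(counts):
    """Hd is exactly the fraction of unordered individual pairs with
    different haplotypes (identity 1 - sum c(c-1)/(n(n-1)))."""
    assert hd(counts) == pytest.approx(pair_diversity(counts), abs=1e-12)


@settings(deadline=None, max_examples=100)
@given(data=st.data())
def test_coarsening_inequality_bd_le_hd(data):
    """Merging haplotypes into classes can only lower diversity: Bd <= Hd,
    and HBd <= min(Hd, Bd), all within [0, 1]."""
    counts = data.draw(count_vectors)
    n = sum(counts)
    rng_seed = data.draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(rng_seed)
    k = len(counts)
    n_classes = int(rng.integers(1, k + 1))
    assignment = rng.integers(0, n_classes, size=k)
    class_counts = [
        int(sum(c for c, a in zip(counts, assignment) if a == cls))
        for cls in range(n_classes)
    ]
    class_counts = [c for c in class_counts if c > 0]
    h = hd(counts)
    b = hd(class_counts)  # same construction on the coarsened partition
    hb = hbd(counts, class_counts)
    assert b <= h + 1e-12
    assert hb <= min(h, b) + 1e-12
    assert -1e-12 <= hb and h <= 1.0 + 1e-12 and b <= 1.0 + 1e-12
    assert n == sum(class_counts)


class TestBdProperties:
    """Structural properties of branch diversity."""

    def test_monotone_in_class_count_with_even_classes(self):
        # n fixed, classes as even as integers allow: Bd non-decreasing in nHc
        n = 60
        values = []
        for n_classes in range(1, 13):
            base, extra = divmod(n, n_classes)
            counts = [base + 1] * extra + [base] * (n_classes - extra)
            values.append(hd(counts))
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        # and the even-count closed form approaches 1 from below
        assert values[-1] == pytest.approx((1 - 1 / 12) * n / (n - 1))

    def test_evenness_maximizes_bd(self):
        # any transfer from a smaller to a larger class strictly decreases Bd
        n = 48
        even = [16, 16, 16]
        assert hd(even) > hd([17, 16, 15])
        for skewed in ([20, 14, 14], [30, 9, 9], [46, 1, 1]):
            assert hd(even) > hd(skewed)
        # one-step transfers away from an uneven split keep decreasing it
        assert hd([17, 16, 15]) > hd([18, 16, 14])

    def test_bd_decreases_with_sample_size_at_fixed_proportions(self):
        # fixed class proportions {1/2, 1/4, 1/4}: the n/(n-1) factor decays
        values = [hd([2 * m, m, m]) for m in (2, 5, 20, 100, 1000)]
        assert all(b < a for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(1 - (0.5**2 + 0.25**2 + 0.25**2), rel=1e-3)


def test_metrics_invariant_under_record_permutation(fig1b_alignment):
    import random

    records = list(fig1b_alignment.records)
    random.Random(7).shuffle(records)
    shuffled = Alignment(records=records)
    r1 = compute_report(fig1b_alignment)
    r2 = compute_report(shuffled)
    for attr in ("Hd", "Bd", "HBd", "Nd", "HNd", "pi", "nH", "nHc"):
        assert getattr(r1, attr) == pytest.approx(getattr(r2, attr))
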