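"""Homopolymer indel filter: var/frmode statistics, calibration, decision."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampvar import (
    AlignedRead,
    HomopolymerThresholds,
    IndelLengthDistribution,
    ReferenceContext,
    TrainingIndel,
    VariantKey,
    calibrate,
    compute_frmode,
    compute_var,
    decide,
    extract_event_lengths,
)
from ampvar.homopolymer import homopolymer_run
from ampvar.model import ContractError, NoEventsError

DEL_SITE = VariantKey("chr1", 150, "AT", "A")


def dist(lengths, n_covering=None):
    return IndelLengthDistribution(
        site=DEL_SITE,
        aligner="bwa",
        lengths=list(lengths),
        n_covering=n_covering if n_covering is not None else len(lengths),
    )


# ---------------------------------------------------------------------------
# independent brute-force oracles

def oracle_var(lengths):
    mean = sum(lengths) / len(lengths)
    return sum((x - mean) ** 2 for x in lengths) / len(lengths)


def oracle_frmode(lengths):
    best = 0
    for value in set(lengths):
        best = max(best, sum(1 for x in lengths if x == value))
    return best / len(lengths)


def oracle_extract(reads, site):
    """Independent pileup walk: expand each CIGAR base by base."""
    lengths, n_covering = [], 0
    for read in reads:
        if read.chrom != site.chrom:
            continue
        ref = read.pos
        events = []
        covered = set()
        for op, length in read.cigar:
            if op == "M":
                for _ in range(length):
                    covered.add(ref)
                    ref += 1
            elif op == "D":
                events.append((ref - 1, -length))
                for _ in range(length):
                    covered.add(ref)
                    ref += 1
            elif op == "I":
                events.append((ref - 1, length))
        if site.pos not in covered:
            continue
        n_covering += 1
        for anchor, length in events:
            if anchor == site.pos:
                lengths.append(length)
                break
    return lengths, n_covering


class TestComputeVar:
    def test_identical_lengths_have_zero_variance(self):
        assert compute_var(dist([-1] * 10)) == 0.0

    def test_mixed_deletion_lengths(self):
        # frozen from the brute-force mean/variance oracle
        assert compute_var(dist([-1, -1, -1, -2])) == pytest.approx(0.1875)
        assert oracle_var([-1, -1, -1, -2]) == pytest.approx(0.1875)

    def test_signed_convention_makes_ins_del_mixture_disperse(self):
        assert compute_var(dist([1, -1])) == pytest.approx(1.0)

    def test_no_events_is_an_error(self):
        with pytest.raises(NoEventsError):
            compute_var(dist([], n_covering=5))


class TestComputeFrmode:
    def test_unanimous_reads_give_one(self):
        assert compute_frmode(dist([-1] * 10)) == 1.0

    def test_modal_fraction(self):
        assert compute_frmode(dist([-1, -1, -1, -2])) == pytest.approx(0.75)

    def test_tied_modes_share_the_count(self):
        assert compute_frmode(dist([-1, -1, -2, -2])) == pytest.approx(0.5)

    def test_event_free_covering_reads_not_in_denominator(self):
        assert compute_frmode(dist([-1, -1, -2], n_covering=100)) == pytest.approx(2 / 3)

    def test_no_events_is_an_error(self):
        with pytest.raises(NoEventsError):
            compute_frmode(dist([], n_covering=5))


@given(lengths=st.lists(st.integers(-4, 4).filter(bool), min_size=1, max_size=60))
@settings(derandomize=True, max_examples=300)
def test_var_frmode_match_oracles_and_link_at_degeneracy(lengths):
    d = dist(lengths)
    var, frmode = compute_var(d), compute_frmode(d)
    assert var == pytest.approx(oracle_var(lengths))
    assert frmode == pytest.approx(oracle_frmode(lengths))
    assert var >= 0 and 0 < frmode <= 1
    all_equal = len(set(lengths)) == 1
    assert (var == pytest.approx(0)) == all_equal
    assert (frmode == 1) == all_equal


class TestExtractEventLengths:
    def test_unanimous_deletion_pileup(self):
        reads = [
            AlignedRead(f"r{i}", "chr1", 101, (("M", 50), ("D", 1), ("M", 49)))
            for i in range(10)
        ]
        d = extract_event_lengths(reads, DEL_SITE)
        assert d.lengths == [-1] * 10
        assert d.n_covering == 10

    def test_read_ending_before_anchor_not_counted(self):
        reads = [AlignedRead("r", "chr1", 100, (("M", 40),))]  # ends at 139 < 150
        d = extract_event_lengths(reads, DEL_SITE)
        assert d.lengths == [] and d.n_covering == 0

    def test_covering_read_without_event_counts_coverage_only(self):
        reads = [AlignedRead("r", "chr1", 100, (("M", 100),))]
        d = extract_event_lengths(reads, DEL_SITE)
        assert d.lengths == [] and d.n_covering == 1

    def test_insertion_at_site_contributes_plus_one(self):
        reads = [AlignedRead("r", "chr1", 101, (("M", 50), ("I", 1), ("M", 49)))]
        d = extract_event_lengths(reads, VariantKey("chr1", 150, "A", "AT"))
        assert d.lengths == [1]

    def test_event_elsewhere_not_matched_in_exact_mode(self):
        reads = [AlignedRead("r", "chr1", 101, (("M", 60), ("D", 1), ("M", 39)))]
        d = extract_event_lengths(reads, DEL_SITE)  # event anchored at 160
        assert d.lengths == [] and d.n_covering == 1

    def test_homopolymer_run_mode_catches_shifted_events(self):
        # run TTTT at 1-based 151..154; events anchored anywhere in the run
        # (or on the anchor base before it) should count
        ref = ReferenceContext("chr1", 101, "A" * 50 + "TTTT" + "C" * 46)
        assert homopolymer_run(ref, 151) == (151, 154)
        reads = [
            AlignedRead("r1", "chr1", 101, (("M", 52), ("D", 1), ("M", 47))),  # anchor 152
            AlignedRead("r2", "chr1", 101, (("M", 54), ("D", 1), ("M", 45))),  # anchor 154
            AlignedRead("r3", "chr1", 101, (("M", 60), ("D", 1), ("M", 39))),  # anchor 160
        ]
        exact = extract_event_lengths(reads, DEL_SITE, mode="exact")
        assert exact.lengths == []
        run = extract_event_lengths(reads, DEL_SITE, reference=ref, mode="homopolymer_run")
        assert run.lengths == [-1, -1]

    def test_run_mode_requires_reference(self):
        with pytest.raises(ValueError):
            extract_event_lengths([], DEL_SITE, mode="homopolymer_run")

    def test_snp_site_is_contract_error(self):
        with pytest.raises(ContractError):
            extract_event_lengths([], VariantKey("chr1", 150, "A", "G"))

    @given(data=st.data())
    @settings(derandomize=True, max_examples=150)
    def test_agrees_with_independent_pileup_walk(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**20)))
        reads = []
        for i in range(int(rng.integers(1, 30))):
            start = int(rng.integers(100, 200))
            left = int(rng.integers(1, 60))
            cigar = [("M", left)]
            if rng.random() < 0.7:
                length = int(rng.integers(1, 4))
                cigar.append(("D" if rng.random() < 0.5 else "I", length))
            cigar.append(("M", int(rng.integers(1, 60))))
            reads.append(AlignedRead(f"r{i}", "chr1", start, tuple(cigar)))
        d = extract_event_lengths(reads, DEL_SITE)
        lengths, n_covering = oracle_extract(reads, DEL_SITE)
        assert sorted(d.lengths) == sorted(lengths)
        assert d.n_covering == n_covering


class TestCalibrate:
    def _tp(self, var, frmode, i=0):
        return TrainingIndel(VariantKey(f"c{i}", 10, "AT", "A"), "TP", var, frmode)

    def test_thresholds_are_tp_extremes(self):
        training = [
            self._tp(0.0, 1.0, 0),
            self._tp(0.031, 0.995, 1),
            self._tp(0.055, 0.9790, 2),
            TrainingIndel(VariantKey("c3", 10, "AT", "A"), "FP", 5.0, 0.2),
        ]
        thr = calibrate(training)
        assert thr.max_var == pytest.approx(0.055)
        assert thr.min_frmode == pytest.approx(0.9790)

    def test_single_tp(self):
        thr = calibrate([self._tp(0.02, 0.99)])
        assert (thr.max_var, thr.min_frmode) == (0.02, 0.99)

    def test_degenerate_perfectly_consistent_tps(self):
        thr = calibrate([self._tp(0.0, 1.0, i) for i in range(3)])
        assert (thr.max_var, thr.min_frmode) == (0.0, 1.0)

    def test_no_tp_is_an_error(self):
        fp = TrainingIndel(VariantKey("c", 10, "AT", "A"), "FP", 1.0, 0.5)
        with pytest.raises(ValueError):
            calibrate([fp])


class TestDecide:
    THR = HomopolymerThresholds()  # (0.055, 0.9790)

    def test_both_violations_filtered(self):
        assert not decide([(0.06, 0.97)], self.THR).passed

    def test_one_condition_alone_retains(self):
        assert decide([(0.06, 0.99)], self.THR).passed
        assert decide([(0.01, 0.50)], self.THR).passed

    def test_any_aligner_rule(self):
        # two aligners consistent, one (e.g. a different gap placement
        # strategy) dispersed: the conservative rule rejects
        stats = [(0.0, 1.0), (0.01, 0.99), (0.10, 0.90)]
        assert not decide(stats, self.THR).passed

    def test_boundary_values_retained_by_strict_inequalities(self):
        assert decide([(0.055, 0.9790)], self.THR).passed

    def test_empty_stats_is_an_error(self):
        with pytest.raises(ContractError):
            decide([], self.THR)

    @given(
        var=st.floats(0, 2, allow_nan=False),
        frmode=st.floats(0.01, 1.0, allow_nan=False),
        dv=st.floats(0, 1, allow_nan=False),
        df=st.floats(0, 0.5, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=200)
    def test_relaxing_thresholds_is_monotone(self, var, frmode, dv, df):
        strict = HomopolymerThresholds(max_var=0.05, min_frmode=0.98)
        relaxed = HomopolymerThresholds(
            max_var=0.05 + dv, min_frmode=max(0.98 - df, 1e-6)
        )
        if decide([(var, frmode)], strict).passed:
            assert decide([(var, frmode)], relaxed).passed


@given(
    tp_stats=st.lists(
        st.tuples(
            st.floats(0, 1, allow_nan=False), st.floats(0.01, 1.0, allow_nan=False)
        ),
        min_size=1,
        max_size=30,
    ),
    fp_stats=st.lists(
        st.tuples(
            st.floats(0, 5, allow_nan=False), st.floats(0.01, 1.0, allow_nan=False)
        ),
        max_size=30,
    ),
)
@settings(derandomize=True, max_examples=200)
def test_calibration_never_rejects_a_training_tp(tp_stats, fp_stats):
    """Threshold construction guarantees every TP training indel survives."""
    training = [
        TrainingIndel(VariantKey(f"tp{i}", 10, "AT", "A"), "TP", v, f)
        for i, (v, f) in enumerate(tp_stats)
    ] + [
        TrainingIndel(VariantKey(f"fp{i}", 10, "AT", "A"), "FP", v, f)
        for i, (v, f) in enumerate(fp_stats)
    ]
    thr = calibrate(training)
    for t in training:
        if t.label == "TP":
            assert decide([(t.var, t.frmode)], thr).passed
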