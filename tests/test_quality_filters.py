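"""Region filter, quality expression filters, union retention."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampvar import (
    CallSet,
    ComboId,
    DepthFilterConfig,
    GenomicInterval,
    IndelFilterConfig,
    QualityAnnotations,
    SnpFilterConfig,
    VariantCall,
    VariantKey,
    apply_union_retention,
    depth_filter,
    evaluate_indel_filters,
    evaluate_snp_filters,
    flag_snp_clusters,
    region_filter,
    retain_union,
)
from ampvar.model import ContractError

BWA_GATK = ComboId("bwa", "gatk")
BT2_GATK = ComboId("bowtie2", "gatk")
NGM_GATK = ComboId("nextgenmap", "gatk")


def snp(pos, combo=BWA_GATK, chrom="chr17", **ann):
    defaults = dict(qual=500.0, dp=200, qd=10.0, fs=1.0, mq0=0, read_pos_rank_sum=0.0)
    defaults.update(ann)
    defaults = {k: v for k, v in defaults.items() if v != "absent"}
    return VariantCall(VariantKey(chrom, pos, "A", "G"), QualityAnnotations(**defaults), combo)


def indel(pos, combo=BWA_GATK, **ann):
    defaults = dict(qual=500.0, dp=200, qd=10.0, fs=1.0, mq0=0, read_pos_rank_sum=0.0)
    defaults.update(ann)
    defaults = {k: v for k, v in defaults.items() if v != "absent"}
    return VariantCall(
        VariantKey("chr17", pos, "CA", "C"), QualityAnnotations(**defaults), combo
    )


class TestRegionFilter:
    REGION = [GenomicInterval("chr17", 7578000, 7578200, "AMP1")]

    def test_call_inside_region_retained(self):
        assert region_filter([snp(7578001)], self.REGION) == [snp(7578001)]

    def test_half_open_boundary(self):
        # 1-based 7578200 has 0-based anchor 7578199: the last covered base
        assert region_filter([snp(7578200)], self.REGION) == [snp(7578200)]
        # 1-based 7578201 (0-based 7578200) falls just outside
        assert region_filter([snp(7578201)], self.REGION) == []

    def test_no_regions_removes_everything(self):
        assert region_filter([snp(7578001)], []) == []

    def test_output_subset_with_order_preserved(self):
        calls = [snp(7578300), snp(7578150), snp(7578010)]
        kept = region_filter(calls, self.REGION)
        assert kept == [snp(7578150), snp(7578010)]


class TestSnpFilters:
    CFG = SnpFilterConfig()

    def test_healthy_call_passes(self):
        assert evaluate_snp_filters(snp(100), self.CFG).passed

    def test_mq0_ratio_rule(self):
        verdict = evaluate_snp_filters(snp(100, mq0=5, dp=40), self.CFG)
        assert "MQ0_RATIO" in verdict.reasons
        # high MQ0 count but low ratio passes the conjunction
        assert evaluate_snp_filters(snp(100, mq0=5, dp=200), self.CFG).passed

    @pytest.mark.parametrize(
        "field,value,reason",
        [
            ("dp", 4, "LOW_DP"),
            ("qual", 49.9, "LOW_QUAL"),
            ("qd", 0.69, "LOW_QD"),
            ("fs", 60.5, "HIGH_FS"),
        ],
    )
    def test_single_threshold_rules(self, field, value, reason):
        call = snp(100, combo=BT2_GATK, **{field: value})
        assert evaluate_snp_filters(call, self.CFG).reasons == {reason}

    def test_bwa_fs_override(self):
        # FS=100 passes on bwa (threshold 590) but fails elsewhere (60)
        assert evaluate_snp_filters(snp(100, combo=BWA_GATK, fs=100.0), self.CFG).passed
        verdict = evaluate_snp_filters(snp(100, combo=BT2_GATK, fs=100.0), self.CFG)
        assert verdict.reasons == {"HIGH_FS"}
        # and 600 fails even on bwa
        verdict = evaluate_snp_filters(snp(100, combo=BWA_GATK, fs=600.0), self.CFG)
        assert verdict.reasons == {"HIGH_FS"}

    @pytest.mark.parametrize(
        "field,reason",
        [
            ("qd", "MISSING_QD"),
            ("dp", "MISSING_DP"),
            ("qual", "MISSING_QUAL"),
            ("fs", "MISSING_FS"),
            ("mq0", "MISSING_MQ0"),
        ],
    )
    def test_missing_field_fails(self, field, reason):
        call = snp(100, **{field: "absent"})
        assert reason in evaluate_snp_filters(call, self.CFG).reasons

    def test_indel_input_is_contract_error(self):
        with pytest.raises(ContractError):
            evaluate_snp_filters(indel(100), self.CFG)

    @given(dp=st.integers(0, 20), relaxed_min=st.integers(0, 10))
    @settings(derandomize=True, max_examples=50)
    def test_relaxing_threshold_never_shrinks_passing_set(self, dp, relaxed_min):
        strict = SnpFilterConfig(min_dp=relaxed_min + 5)
        relaxed = SnpFilterConfig(min_dp=relaxed_min)
        call = snp(100, dp=dp)
        if evaluate_snp_filters(call, strict).passed:
            assert evaluate_snp_filters(call, relaxed).passed


def brute_force_clusters(positions, window, size):
    """Definitional scan: any i<=j with >= size SNPs spanning <= window flags all."""
    flagged = set()
    n = len(positions)
    for i in range(n):
        for j in range(i, n):
            if j - i + 1 >= size and positions[j] - positions[i] <= window:
                flagged.update(positions[i : j + 1])
    return flagged


class TestSnpClusters:
    CFG = SnpFilterConfig()

    def test_three_snps_spanning_nine_bases_all_flagged(self):
        calls = [snp(100), snp(104), snp(109)]
        verdicts = flag_snp_clusters(calls, self.CFG)
        assert all(v.reasons == {"SNP_CLUSTER"} for v in verdicts.values())

    def test_spread_snps_not_flagged(self):
        calls = [snp(100), snp(104), snp(120)]
        verdicts = flag_snp_clusters(calls, self.CFG)
        assert all(v.passed for v in verdicts.values())

    def test_single_snp_passes(self):
        verdicts = flag_snp_clusters([snp(100)], self.CFG)
        assert verdicts[snp(100).key].passed

    def test_indels_never_cluster_flagged(self):
        calls = sorted([snp(100), indel(101), snp(104), indel(105)], key=lambda c: c.key.pos)
        verdicts = flag_snp_clusters(calls, self.CFG)
        assert all(v.passed for v in verdicts.values())

    @given(
        positions=st.lists(st.integers(1, 300), min_size=0, max_size=50, unique=True)
    )
    @settings(derandomize=True, max_examples=200)
    def test_agrees_with_brute_force_scan(self, positions):
        positions = sorted(positions)
        calls = [snp(p) for p in positions]
        verdicts = flag_snp_clusters(calls, self.CFG)
        flagged = {k.pos for k, v in verdicts.items() if not v.passed}
        assert flagged == brute_force_clusters(
            positions, self.CFG.cluster_window, self.CFG.cluster_size
        )


class TestIndelFilters:
    CFG = IndelFilterConfig()

    def test_low_qd_fails(self):
        assert evaluate_indel_filters(indel(100, qd=2.4), self.CFG).reasons == {
            "INDEL_EXPR"
        }

    def test_healthy_indel_passes(self):
        call = indel(100, qd=10.0, read_pos_rank_sum=-1.0, fs=10.0)
        assert evaluate_indel_filters(call, self.CFG).passed

    def test_missing_rank_sum_fails(self):
        call = indel(100, read_pos_rank_sum="absent")
        assert evaluate_indel_filters(call, self.CFG).reasons == {
            "MISSING_READPOSRANKSUM"
        }

    @pytest.mark.parametrize(
        "ann", [dict(read_pos_rank_sum=-20.5), dict(fs=200.5)]
    )
    def test_other_disjuncts(self, ann):
        assert not evaluate_indel_filters(indel(100, **ann), self.CFG).passed

    def test_snp_input_is_contract_error(self):
        with pytest.raises(ContractError):
            evaluate_indel_filters(snp(100), self.CFG)


class TestDepthFilter:
    CFG = DepthFilterConfig()

    @pytest.mark.parametrize(
        "dp,ok", [(1, False), (2, True), (500, True), (4000, True), (4001, False)]
    )
    def test_inclusive_depth_boundaries(self, dp, ok):
        verdict = depth_filter(snp(100, dp=dp), self.CFG)
        assert verdict.passed == ok
        if not ok:
            assert verdict.reasons == {"DEPTH_RANGE"}

    def test_missing_dp_fails(self):
        verdict = depth_filter(snp(100, dp="absent"), self.CFG)
        assert verdict.reasons == {"MISSING_DP"}


class TestUnionRetention:
    def _labeled(self, combo, labeled_positions, all_positions):
        calls = [
            snp(p, combo=combo).with_labels({"LOW_DP"} if p in labeled_positions else set())
            for p in all_positions
        ]
        return CallSet(combo, calls)

    def test_key_unlabeled_in_one_combo_is_retained(self):
        positions = [100]
        callsets = [
            self._labeled(BWA_GATK, {100}, positions),
            self._labeled(BT2_GATK, {100}, positions),
            self._labeled(NGM_GATK, set(), positions),
        ]
        assert retain_union(callsets) == {snp(100).key}

    def test_key_labeled_everywhere_is_dropped(self):
        positions = [100]
        callsets = [
            self._labeled(c, {100}, positions) for c in (BWA_GATK, BT2_GATK, NGM_GATK)
        ]
        assert retain_union(callsets) == set()

    def test_empty_callsets_give_empty_set(self):
        assert retain_union([]) == set()

    def test_retention_applied_per_caller_group(self):
        gatk = self._labeled(BWA_GATK, {100}, [100, 110])
        samtools = CallSet(
            ComboId("bwa", "samtools"),
            [snp(100, combo=ComboId("bwa", "samtools"))],
        )
        survivors = apply_union_retention([gatk, samtools])
        by_combo = {cs.combo: cs.keys() for cs in survivors}
        # 100 labeled in the only GATK callset -> dropped from GATK side,
        # but the SAMtools group retained its own unlabeled copy
        assert by_combo[BWA_GATK] == {snp(110).key}
        assert by_combo[ComboId("bwa", "samtools")] == {snp(100).key}

    def test_duplicate_combo_rejected(self):
        cs = self._labeled(BWA_GATK, set(), [100])
        with pytest.raises(ContractError):
            apply_union_retention([cs, cs])
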