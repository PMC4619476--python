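"""The somatic filtering cascade and its individual stages."""

import statistics

import numpy as np
import pytest

from somaticmz import (
    FilterConfig,
    call_somatic,
    filter_by_quality,
    filter_consequence,
    filter_polymorphisms,
    load_blacklist,
    quality_threshold,
    run_cascade,
    variant_key,
)
from somaticmz.somatic_calling import (
    REJECT_COVERAGE,
    REJECT_DELTA,
    REJECT_NORMAL_VAF,
    REJECT_TUMOR_VAF,
)
from helpers import make_pair


class TestQualityThreshold:
    def test_zero_spread_threshold_equals_common_value(self):
        assert quality_threshold([30, 30, 30]) == 30.0

    def test_mean_minus_two_sample_sd(self):
        # mean 20, sample sd 10 -> 20 - 2*10 = 0
        assert quality_threshold([10, 20, 30]) == pytest.approx(0.0)

    def test_single_element_has_sd_zero(self):
        assert quality_threshold([23.5]) == 23.5

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            quality_threshold([])

    def test_discovery_qualities_all_survive_their_own_threshold(self, discovery_snvs):
        qualities = [o.quality for o in discovery_snvs]
        threshold = quality_threshold(qualities)
        assert all(q >= threshold for q in qualities)


class TestFilterByQuality:
    def test_equal_qualities_remove_nothing(self):
        pairs = [make_pair(quality=25.0) for _ in range(5)]
        kept, removed = filter_by_quality(pairs)
        assert kept == pairs and removed == []

    def test_low_outlier_removed(self):
        # mean 28, sd ~6.32, threshold ~15.35 -> the 10 falls below
        qualities = [10] + [30] * 9
        pairs = [make_pair(quality=q) for q in qualities]
        kept, removed = filter_by_quality(pairs)
        assert [p.tumor.quality for p, _ in removed] == [10]
        assert len(kept) == 9

    def test_threshold_is_per_case_not_global(self):
        # case A: tight high qualities; case B: one low outlier among high.
        # A global threshold would spare B's outlier; per-case removes it.
        case_a = [make_pair(quality=q, case_id="A") for q in [30, 30, 30, 30]]
        case_b = [make_pair(quality=q, case_id="B") for q in [10] + [30] * 9]
        kept, removed = filter_by_quality(case_a + case_b)
        assert len(removed) == 1 and removed[0][0].case_id == "B"
        assert len(kept) == 13

    def test_discovery_set_fully_retained(self, discovery_pairs):
        kept, removed = filter_by_quality(discovery_pairs)
        assert len(kept) == 25 and removed == []


class TestFilterConsequence:
    def test_splice_site_with_unchanged_codon_is_kept(self):
        pairs = [make_pair(consequence="splice_site")]
        kept, removed = filter_consequence(pairs)
        assert kept == pairs and removed == []

    @pytest.mark.parametrize("consequence", ["intronic", "utr", "synonymous"])
    def test_non_coding_consequences_removed(self, consequence):
        kept, removed = filter_consequence([make_pair(consequence=consequence)])
        assert kept == [] and len(removed) == 1

    def test_missense_kept(self):
        kept, _ = filter_consequence([make_pair(consequence="missense")])
        assert len(kept) == 1


class TestCallSomatic:
    def test_clonal_variant_with_clean_normal_is_somatic(self):
        decision = call_somatic(make_pair(tumor_depth=49, tumor_vaf=0.49, normal_vaf=0.0))
        assert decision.somatic and decision.reason is None

    def test_germline_heterozygote_rejected_on_normal_vaf(self):
        decision = call_somatic(make_pair(tumor_vaf=0.5, normal_vaf=0.5))
        assert not decision.somatic and decision.reason == REJECT_NORMAL_VAF

    def test_coverage_boundary_is_inclusive_at_20(self):
        assert not call_somatic(make_pair(tumor_depth=19, tumor_vaf=0.5)).somatic
        assert call_somatic(make_pair(tumor_depth=20, tumor_vaf=0.5)).somatic

    def test_tumor_vaf_floor_inclusive_normal_cap_strict(self):
        assert call_somatic(make_pair(tumor_vaf=0.1, normal_vaf=0.0)).somatic
        assert (
            call_somatic(make_pair(tumor_vaf=0.09, normal_vaf=0.0)).reason
            == REJECT_TUMOR_VAF
        )
        # normal vaf smaller than 0.2: exactly 0.2 fails
        assert (
            call_somatic(make_pair(tumor_vaf=0.5, normal_vaf=0.2)).reason
            == REJECT_NORMAL_VAF
        )
        assert call_somatic(make_pair(tumor_vaf=0.5, normal_vaf=0.19)).somatic

    def test_delta_rule_inclusive_at_point_one(self):
        assert call_somatic(make_pair(tumor_vaf=0.25, normal_vaf=0.15)).somatic
        assert (
            call_somatic(make_pair(tumor_vaf=0.24, normal_vaf=0.15)).reason
            == REJECT_DELTA
        )

    def test_rejection_reason_is_first_failing_rule(self):
        decision = call_somatic(make_pair(tumor_depth=10, tumor_vaf=0.05, normal_vaf=0.5))
        assert decision.reason == REJECT_COVERAGE

    def test_missing_normal_treated_as_zero_vaf(self, caplog):
        pair = make_pair(tumor_vaf=0.4)
        pair = type(pair)(tumor=pair.tumor, normal=None, case_id=pair.case_id)
        with caplog.at_level("WARNING", logger="somaticmz.somatic_calling"):
            decision = call_somatic(pair)
        assert decision.somatic
        assert any("assuming normal VAF" in m for m in caplog.messages)


class TestFilterPolymorphisms:
    def test_exact_match_removed_empty_blacklist_identity(self):
        pairs = [make_pair(pos=100), make_pair(pos=200)]
        kept, removed = filter_polymorphisms(pairs, {("1", 100, "A", "G")})
        assert [p.tumor.pos for p in kept] == [200]
        assert [p.tumor.pos for p, _ in removed] == [100]
        kept, removed = filter_polymorphisms(pairs, frozenset())
        assert kept == pairs and removed == []

    def test_blacklist_loader(self, tmp_path):
        path = tmp_path / "snps.tsv"
        path.write_text("chrom\tpos\tref\talt\n1\t100\ta\tg\nX\t5\tC\tT\n")
        assert load_blacklist(path) == {("1", 100, "A", "G"), ("X", 5, "C", "T")}


def _brute_force(pairs, cfg, blacklist):
    """Independent one-expression-per-variant re-statement of the cascade."""
    survivors = [p for p in pairs if p.tumor.consequence not in cfg.drop_consequences]
    thresholds = {}
    for case in {p.case_id for p in survivors}:
        quals = [p.tumor.quality for p in survivors if p.case_id == case]
        sd = statistics.stdev(quals) if len(quals) > 1 else 0.0
        thresholds[case] = statistics.fmean(quals) - cfg.quality_sd_multiplier * sd
    out = []
    for p in survivors:
        t = p.tumor
        n_vaf = p.normal.vaf if p.normal is not None else 0.0
        if (
            t.quality >= thresholds[p.case_id]
            and t.depth >= cfg.min_coverage
            and t.vaf >= cfg.min_tumor_vaf
            and n_vaf < cfg.max_normal_vaf
            and t.vaf - n_vaf >= cfg.min_delta
            and variant_key(p) not in blacklist
        ):
            out.append(p)
    return out


def _random_table(rng, n_rows):
    consequences = ["missense", "nonsense", "splice_site", "synonymous", "intronic", "utr"]
    pairs = []
    for i in range(n_rows):
        pairs.append(
            make_pair(
                chrom=str(rng.integers(1, 5)),
                pos=int(rng.integers(1, 10_000_000)),
                tumor_depth=int(rng.integers(1, 120)),
                tumor_vaf=float(rng.uniform(0, 1)),
                normal_depth=int(rng.integers(1, 120)),
                normal_vaf=float(rng.uniform(0, 0.6)),
                quality=float(rng.uniform(5, 40)),
                consequence=consequences[rng.integers(0, len(consequences))],
                case_id=f"case{rng.integers(1, 3)}",
            )
        )
    keys = [variant_key(p) for p in pairs]
    blacklist = {keys[i] for i in rng.choice(len(keys), size=max(1, n_rows // 10))}
    return pairs, blacklist


class TestRunCascade:
    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(20260921)
        cfg = FilterConfig()
        for _ in range(10):
            pairs, blacklist = _random_table(rng, int(rng.integers(5, 200)))
            called, report = run_cascade(pairs, cfg, blacklist)
            expected = _brute_force(pairs, cfg, blacklist)
            assert [variant_key(p) for p in called] == [variant_key(p) for p in expected]
            assert report.n_input == len(called) + report.total_removed

    def test_stage_counts_non_increasing_and_conserved(self):
        rng = np.random.default_rng(7)
        pairs, blacklist = _random_table(rng, 150)
        called, r = run_cascade(pairs, FilterConfig(), blacklist)
        assert (
            r.n_input
            >= r.n_after_consequence
            >= r.n_after_quality
            >= r.n_after_somatic_rules
            >= r.n_after_polymorphism
            == len(called)
        )

    def test_input_already_clean_passes_unchanged(self, discovery_pairs):
        called, report = run_cascade(discovery_pairs)
        assert called == discovery_pairs
        assert report.total_removed == 0

    def test_germline_only_cohort_yields_empty_callset(self):
        pairs = [
            make_pair(tumor_vaf=0.5, normal_vaf=0.5, consequence="missense")
            for _ in range(20)
        ]
        called, _ = run_cascade(pairs)
        assert called == []

    def test_tightening_thresholds_never_adds_variants(self):
        rng = np.random.default_rng(11)
        base = FilterConfig()
        pairs, blacklist = _random_table(rng, 200)
        base_keys = {variant_key(p) for p in run_cascade(pairs, base, blacklist)[0]}
        tightened = [
            FilterConfig(min_coverage=40),
            FilterConfig(min_tumor_vaf=0.25),
            FilterConfig(max_normal_vaf=0.05),
            FilterConfig(min_delta=0.3),
            FilterConfig(quality_sd_multiplier=1.0),
            FilterConfig(
                drop_consequences=frozenset({"synonymous", "intronic", "utr", "other"})
            ),
        ]
        for cfg in tightened:
            keys = {variant_key(p) for p in run_cascade(pairs, cfg, blacklist)[0]}
            assert keys <= base_keys, cfg

    def test_idempotent_on_study_like_callsets(self, discovery_pairs):
        from somaticmz import SimulationConfig, blacklist_from_truth, simulate_pair

        cfg = FilterConfig()
        for seed in (1, 2):
            sim = SimulationConfig(
                n_germline_het=500, n_somatic=50, n_artifacts=30, n_polymorphisms=20, seed=seed
            )
            pairs, truth = simulate_pair(sim)
            called, _ = run_cascade(pairs, cfg, blacklist_from_truth(pairs, truth))
            again, report = run_cascade(called, cfg)
            assert again == called and report.total_removed == 0
        again, _ = run_cascade(run_cascade(discovery_pairs, cfg)[0], cfg)
        assert again == discovery_pairs
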