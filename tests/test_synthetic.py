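"""Synthetic cohort generator: determinism, calibration, and truth closure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import noise_free_config, select_sample_mutations
from hgblkit.fish import classify_fish_table
from hgblkit.synthetic import (
    DEFAULT_GENOME,
    ConfigurationError,
    CohortConfig,
    calibrate_burden,
    default_gene_map,
    default_panel,
    default_templates,
    generate_cohort,
    sample_cna_profile,
    sample_fish,
    sample_clinical,
)


class TestCalibrateBurden:
    def test_uniform_closed_form(self):
        probs = {f"G{i}": 0.5 for i in range(115)}
        out = calibrate_burden(probs, 17.0)
        assert all(v == pytest.approx(17 / 115) for v in out.values())

    def test_conservation_around_clipped_entry(self):
        probs = {"HOT": 1.0, **{f"G{i}": 0.1 for i in range(50)}}
        out = calibrate_burden(probs, 17.0)
        assert out["HOT"] == 1.0
        assert sum(v for g, v in out.items() if g != "HOT") == pytest.approx(16.0)

    @given(
        target=st.floats(0.5, 20),
        probs=st.lists(st.floats(0.01, 1.0), min_size=25, max_size=60),
    )
    @settings(derandomize=True, max_examples=50)
    def test_sum_matches_target(self, target, probs):
        d = {f"G{i}": p for i, p in enumerate(probs)}
        out = calibrate_burden(d, target)
        assert sum(out.values()) == pytest.approx(target, abs=1e-9)
        assert all(0.0 <= v <= 1.0 for v in out.values())

    def test_infeasible_target_rejected(self):
        with pytest.raises(ConfigurationError):
            calibrate_burden({"A": 0.5, "B": 0.5}, 3.0)
        with pytest.raises(ConfigurationError):
            calibrate_burden({"A": 0.0}, 0.5)


class TestCnaProfile:
    def test_degenerate_frequency_one_always_present(self):
        template = default_templates()[2]  # MCAD: +8q24 at frequency 1.0
        rng = np.random.default_rng(0)
        for _ in range(20):
            rows, regions = sample_cna_profile(template, DEFAULT_GENOME, rng)
            assert any(
                r["chrom"] == "chr8" and r["direction"] == "gain" for r in regions
            )

    def test_segments_tile_each_chromosome_without_overlap(self):
        template = default_templates()[0]
        rng = np.random.default_rng(1)
        lengths = dict(DEFAULT_GENOME)
        for _ in range(100):
            rows, _ = sample_cna_profile(template, DEFAULT_GENOME, rng)
            df = pd.DataFrame(rows)
            for chrom, sub in df.groupby("chrom"):
                sub = sub.sort_values("start")
                assert sub.iloc[0]["start"] == 0
                assert sub.iloc[-1]["end"] == lengths[chrom]
                assert (
                    sub["start"].values[1:] == sub["end"].values[:-1]
                ).all()

    def test_binomial_concentration_of_region_frequency(self):
        """Observed presence of a 0.56-frequency region over 1000 draws stays
        within the exact binomial envelope."""
        template = default_templates()[0]
        target = ("chr1", 60_000_000, 75_000_000)  # gain at frequency 0.56
        rng = np.random.default_rng(42)
        hits = 0
        n = 1000
        for _ in range(n):
            _, regions = sample_cna_profile(template, DEFAULT_GENOME, rng)
            hits += any(
                (r["chrom"], r["start"], r["end"]) == target for r in regions
            )
        p = 0.56
        margin = 3 * np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < margin


class TestFishAndClinical:
    def test_rearranged_case_always_above_threshold(self):
        template = default_templates()[0]  # MYC-R probability 1
        rng = np.random.default_rng(0)
        for _ in range(20):
            flags, rows = sample_fish(template, rng)
            df = pd.DataFrame(rows)
            myc = df[df["probe"] == "MYC_BA"]
            assert flags["myc_r"]
            assert (myc["pattern"] == "split").mean() >= 0.10

    def test_mcad_signal_counts_exceed_ten_in_enough_cells(self):
        template = default_templates()[2]
        rng = np.random.default_rng(1)
        for _ in range(20):
            flags, rows = sample_fish(template, rng)
            df = pd.DataFrame(rows)
            myc = df[df["probe"] == "MYC_BA"]
            assert flags["myc_amp"]
            assert (myc["signal_count"] > 10).mean() >= 0.10

    def test_at_least_100_cells_per_probe(self):
        rng = np.random.default_rng(2)
        for template in default_templates():
            _, rows = sample_fish(template, rng)
            counts = pd.DataFrame(rows).groupby("probe").size()
            assert (counts >= 100).all()

    def test_dhl_thl_always_has_partner_rearrangement(self):
        template = default_templates()[0]
        rng = np.random.default_rng(3)
        for _ in range(50):
            flags, _ = sample_fish(template, rng)
            assert flags["bcl2_r"] or flags["bcl6_r"]

    def test_clinical_record_fields(self):
        rng = np.random.default_rng(4)
        for template in default_templates():
            for _ in range(20):
                rec = sample_clinical(template, rng)
                assert rec["first_course_response"] in ("CR", "PR", "other")
                assert rec["os_time"] > 0
                if rec["relapse"]:
                    assert rec["first_course_response"] == "CR"


class TestGenerateCohort:
    def test_seeded_determinism(self):
        cfg = noise_free_config({"DHL_THL": 2, "SHL": 2, "MCAD": 1}, seed=9)
        b1 = generate_cohort(cfg, default_templates())
        b2 = generate_cohort(cfg, default_templates())
        pd.testing.assert_frame_equal(b1.segments, b2.segments)
        pd.testing.assert_frame_equal(b1.fish, b2.fish)
        pd.testing.assert_frame_equal(b1.clinical, b2.clinical)
        assert b1.truth == b2.truth
        assert b1.caller_calls == b2.caller_calls

    def test_mcad_truth_has_8q24_gain_in_every_sample(self):
        cfg = noise_free_config({"MCAD": 3}, seed=5)
        b = generate_cohort(cfg, default_templates())
        for sid in b.samples:
            assert any(
                r["chrom"] == "chr8" and r["direction"] == "gain"
                and r["start"] <= 70_000_000
                for r in b.truth[sid]["cna_regions"]
            )

    def test_all_groups_zero_gives_empty_bundle(self):
        cfg = noise_free_config({"DHL_THL": 0, "SHL": 0, "MCAD": 0}, seed=1)
        b = generate_cohort(cfg, default_templates())
        assert b.samples == []
        assert len(b.segments) == 0 and len(b.fish) == 0

    def test_unknown_group_label_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(group_sizes={"NOS": 3}).validate()

    def test_template_gene_outside_panel_rejected(self):
        cfg = CohortConfig(group_sizes={"MCAD": 1}, panel=("TP53", "MYC"))
        with pytest.raises(ConfigurationError):
            generate_cohort(cfg, default_templates())

    def test_noise_free_all_callers_flag_every_true_variant(self):
        cfg = noise_free_config({"SHL": 3}, seed=11)
        b = generate_cohort(cfg, default_templates())
        for sample, per_caller in b.caller_calls.items():
            keys = [sorted((c.chrom, c.pos) for c in calls) for calls in per_caller]
            assert all(k == keys[0] for k in keys)

    def test_artifacts_constructed_with_at_most_two_callers(self):
        cfg = CohortConfig(
            group_sizes={"SHL": 5}, caller_sensitivity=(1.0,) * 5,
            artifact_rate=5.0, germline_rate=0.0, seed=13,
        )
        b = generate_cohort(cfg, default_templates())
        from hgblkit.variants import merge_caller_calls

        for sample in b.samples:
            merged = merge_caller_calls(b.caller_calls[sample], 5)
            true_genes = set(b.truth[sample]["mutated_genes"])
            for cand in merged:
                if cand.caller_count < 5:  # artifacts: true calls carry 5/5 here
                    assert cand.caller_count <= 2


class TestNoiseFreeClosure:
    """With perfect sensitivity and no injection, the downstream pipeline
    recovers the generator's truth exactly."""

    def test_burden_equals_truth_gene_count(self):
        cfg = noise_free_config({"DHL_THL": 5}, seed=21)
        b = generate_cohort(cfg, default_templates())
        from hgblkit.variants import mutation_burden

        for sample in b.samples:
            selected = select_sample_mutations(b, cfg, sample)
            rec = mutation_burden(selected, cfg.panel)
            assert sorted(rec.mutated_genes) == b.truth[sample]["mutated_genes"]

    def test_fish_classification_recovers_truth_subtype(self):
        cfg = noise_free_config({"DHL_THL": 5, "SHL": 5, "MCAD": 3}, seed=23)
        b = generate_cohort(cfg, default_templates())
        cases = classify_fish_table(b.fish).set_index("case_id")
        for sample in b.samples:
            assert cases.loc[sample, "subtype"] == b.truth[sample]["subtype"]


class TestGeneMap:
    def test_covers_panel_and_stays_on_genome(self):
        panel = default_panel()
        gm = default_gene_map(panel)
        lengths = dict(DEFAULT_GENOME)
        assert set(gm) == set(panel)
        for chrom, s, e in gm.values():
            assert 0 <= s < e <= lengths[chrom]

    def test_no_gene_straddles_a_template_region_boundary(self):
        gm = default_gene_map(default_panel())
        for template in default_templates():
            for chrom, rs, re_, *_ in template.cna_regions:
                for g, (gc, gs, ge) in gm.items():
                    if gc != chrom:
                        continue
                    # a gene is either fully inside or fully outside
                    assert not (gs < rs < ge) and not (gs < re_ < ge)
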