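import numpy as np
import pandas as pd
import pytest

from mirkit.enrichment import snea
from mirkit.expression_stats import one_way_anova
from mirkit.synthetic_data import (
    AssaySimConfig,
    FamilySimConfig,
    GenesetSimConfig,
    UtrSimConfig,
    simulate_assay,
    simulate_family,
    simulate_geneset_universe,
    simulate_utrs,
)

SITE = "CACTCC"


class TestUtrSimulator:
    def test_same_seed_is_byte_identical(self):
        cfg = UtrSimConfig(n_utrs=50, planted_target_fraction=0.1, seed=9)
        a, truth_a = simulate_utrs(cfg, SITE)
        b, truth_b = simulate_utrs(UtrSimConfig(n_utrs=50, planted_target_fraction=0.1, seed=9), SITE)
        assert [r.residues for r in a] == [r.residues for r in b]
        assert truth_a.payload == truth_b.payload
        assert truth_a.config_hash == truth_b.config_hash

    def test_fraction_zero_clean_pool_is_site_free(self):
        records, truth = simulate_utrs(
            UtrSimConfig(n_utrs=60, planted_target_fraction=0.0, seed=4), SITE
        )
        assert truth.payload["n_targets"] == 0
        assert all(SITE not in r.residues for r in records)

    def test_study_scale_fraction_gives_83_targets(self):
        cfg = UtrSimConfig(seed=12)  # defaults: n=1059, fraction 83/1059
        records, truth = simulate_utrs(cfg, SITE)
        assert len(records) == 1059
        assert truth.payload["n_targets"] == 83
        carrying = [r.id for r in records if SITE in r.residues]
        assert sorted(carrying) == truth.payload["target_ids"]

    def test_planted_positions_carry_the_site(self):
        records, truth = simulate_utrs(
            UtrSimConfig(n_utrs=40, planted_target_fraction=0.5, sites_per_target=2, seed=3), SITE
        )
        by_id = {r.id: r.residues for r in records}
        for utr_id, positions in truth.payload["planted_positions"].items():
            for pos in positions:
                assert by_id[utr_id][pos - 1 : pos - 1 + len(SITE)] == SITE

    def test_natural_background_leaves_chance_occurrences(self):
        cfg = UtrSimConfig(n_utrs=300, length_range=(1000, 1000),
                           planted_target_fraction=0.0, background="natural", seed=1)
        records, _ = simulate_utrs(cfg, SITE)
        # at ~0.24 expected sites per kb some UTRs must contain the hexamer
        assert any(SITE in r.residues for r in records)

    def test_site_longer_than_utr_rejected(self):
        with pytest.raises(ValueError):
            simulate_utrs(UtrSimConfig(length_range=(6, 10)), "ACGTACGTACGT")


class TestFamilySimulator:
    def test_zero_rates_give_identical_sequences(self):
        records, _, _ = simulate_family(
            FamilySimConfig(mu_mature=0.0, mu_star=0.0, mu_loop=0.0, seed=2)
        )
        assert len({r.residues for r in records}) == 1

    def test_mature_region_untouched_by_default(self):
        records, annot, truth = simulate_family(FamilySimConfig(seed=6))
        start, end = annot.regions["mature"]
        matures = {r.residues[start - 1 : end] for r in records}
        assert len(matures) == 1
        assert truth.payload["ancestor"][start - 1 : end] in matures

    def test_loop_less_conserved_than_star(self):
        from mirkit.conservation import conservation_profile, progressive_msa, region_conservation

        wins = 0
        for seed in range(5):
            records, annot, _ = simulate_family(FamilySimConfig(seed=seed))
            msa = progressive_msa(records)
            means, _ = region_conservation(msa, conservation_profile(msa), annot)
            wins += means["loop"] < means["star"]
        assert wins >= 4

    def test_determinism(self):
        a = simulate_family(FamilySimConfig(seed=5))[0]
        b = simulate_family(FamilySimConfig(seed=5))[0]
        assert [r.residues for r in a] == [r.residues for r in b]

    def test_regions_must_partition(self):
        with pytest.raises(ValueError, match="partition"):
            FamilySimConfig(mature=(1, 23), loop=(25, 57), star=(58, 80))


class TestGenesetSimulator:
    def test_strongly_planted_sets_occupy_top_ranks(self):
        universe, sets, truth = simulate_geneset_universe(
            GenesetSimConfig(n_genes=1000, n_sets=25, n_enriched=3, enrichment_factor=4.0, seed=10)
        )
        results, _ = snea(universe, sets)
        top = {r.set_id for r in results[:3]}
        assert top == set(truth.payload["enriched_set_ids"])

    def test_factor_one_plants_nothing(self):
        _, _, truth = simulate_geneset_universe(
            GenesetSimConfig(n_sets=10, n_enriched=5, enrichment_factor=1.0, seed=3)
        )
        assert truth.payload["enriched_set_ids"] == []

    def test_zero_sets_is_valid(self):
        universe, sets, _ = simulate_geneset_universe(
            GenesetSimConfig(n_sets=0, n_enriched=0, seed=1)
        )
        assert len(sets) == 0 and len(universe) == 2000

    def test_binary_scores_are_binary(self):
        universe, _, _ = simulate_geneset_universe(
            GenesetSimConfig(score_kind="binary", seed=2)
        )
        assert universe.is_binary

    def test_determinism(self):
        a = simulate_geneset_universe(GenesetSimConfig(seed=4))[0]
        b = simulate_geneset_universe(GenesetSimConfig(seed=4))[0]
        assert np.array_equal(a.scores, b.scores)


class TestAssaySimulator:
    def test_same_seed_gives_identical_tables(self):
        ct_a, met_a, _ = simulate_assay(AssaySimConfig(seed=7))
        ct_b, met_b, _ = simulate_assay(AssaySimConfig(seed=7))
        pd.testing.assert_frame_equal(ct_a, ct_b)
        pd.testing.assert_frame_equal(met_a, met_b)

    def test_design_shape(self):
        ct, met, _ = simulate_assay(AssaySimConfig(seed=1))
        assert set(ct["group"]) == {"saline", "low-dose", "high-dose"}
        assert ct.groupby(["gene", "group"])["sample_id"].nunique().eq(6).all()
        assert set(met["analyte"]) == {"glucose", "triglycerides", "free_fatty_acids",
                                       "cholesterol"}

    def test_reference_genes_are_effect_free(self):
        ct, _, _ = simulate_assay(AssaySimConfig(seed=8, n_per_group=200))
        u6 = ct[ct.gene == "u6"].groupby("group")["ct"].mean()
        assert u6.max() - u6.min() < 0.15  # only sampling noise

    def test_planted_fold_change_shifts_ct(self):
        ct, _, _ = simulate_assay(AssaySimConfig(seed=8, n_per_group=200))
        means = ct[ct.gene == "cyp2k5"].groupby("group")["ct"].mean()
        # fold 2 at E=2 is exactly one cycle earlier
        assert means["saline"] - means["high-dose"] == pytest.approx(1.0, abs=0.1)

    def test_metabolite_means_track_planted_percent_changes(self):
        _, met, truth = simulate_assay(AssaySimConfig(seed=42, n_per_group=2000))
        sub = met[met.analyte == "glucose"]
        means = sub.groupby("group")["value"].mean()
        for group, pct in truth.payload["analyte_percent_changes"]["glucose"].items():
            observed = 100 * (means[group] / means["saline"] - 1)
            assert observed == pytest.approx(pct, abs=1.5)

    def test_null_config_rejections_near_alpha(self):
        rejections = 0
        n = 0
        for seed in range(60):
            _, met, _ = simulate_assay(
                AssaySimConfig(seed=seed, gene_fold_changes={}, analyte_percent_changes={})
            )
            for _, sub in met.groupby("analyte"):
                groups = {g: v["value"].to_numpy() for g, v in sub.groupby("group")}
                rejections += one_way_anova(groups).p < 0.05
                n += 1
        assert rejections / n < 0.15  # coarse sanity; full calibration in acceptance
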