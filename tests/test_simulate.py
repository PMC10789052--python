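"""Generator contracts: determinism, conservation, planted ground truth."""

import numpy as np
import pandas as pd
import pytest

from pausekit import simulate, variants
from pausekit.regions import derive_regions
from pausekit.simulate import SimConfig


class TestConfig:
    def test_rejects_out_of_range_fractions(self):
        with pytest.raises(ValueError):
            SimConfig(lethality=1.5)
        with pytest.raises(ValueError):
            SimConfig(de_fraction=-0.1)

    def test_rejects_non_integer_counts(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=-3)


class TestAnnotation:
    def test_contract_gene_count_and_strands(self):
        genes = simulate.make_annotation(SimConfig(seed=1, n_genes=50))
        assert len(genes) == 50
        assert {g.strand for g in genes} == {"+", "-"}
        assert all(g.length >= 2_500 for g in genes)

    def test_genes_and_flanks_do_not_overlap(self, small_genes):
        for a, b in zip(small_genes, small_genes[1:]):
            assert b.start - a.end >= 20_000

    def test_determinism_same_config_identical_files(self, tmp_path):
        from pausekit.regions import write_bed12

        cfg = SimConfig(seed=9, n_genes=20)
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed12(simulate.make_annotation(cfg), p1)
        write_bed12(simulate.make_annotation(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_annotation(self):
        assert simulate.make_annotation(SimConfig(n_genes=0)) == []

    def test_infeasible_genome_raises_placement_error(self):
        with pytest.raises(simulate.PlacementError):
            simulate.make_annotation(SimConfig(n_genes=100, genome_length=50_000))


class TestChip:
    def test_fragment_count_conserves_library_size(self, small_config, small_genes):
        frags, _ = simulate.simulate_chip(small_genes, small_config)
        assert len(frags) == small_config.library_size

    def test_determinism(self, small_config, small_genes):
        f1, _ = simulate.simulate_chip(small_genes, small_config, "ko", 1)
        f2, _ = simulate.simulate_chip(small_genes, small_config, "ko", 1)
        pd.testing.assert_frame_equal(f1, f2)

    def test_zero_pausing_gives_unit_density_ratio(self):
        """pausing_level=0: promoter and body coverage densities agree."""
        from pausekit import occupancy

        cfg = SimConfig(seed=4, n_genes=80, library_size=400_000,
                        pausing_level=0.0, background_fraction=0.0)
        genes = simulate.make_annotation(cfg)
        derived = [derive_regions(g) for g in genes]
        frags, _ = simulate.simulate_chip(genes, cfg)
        cnt = occupancy.count_regions(frags, derived, ["promoter", "pi_body"])
        lens = occupancy.region_lengths(derived, ["promoter", "pi_body"])
        dens_p = (cnt["promoter"] / lens["promoter"]).to_numpy()
        dens_b = (cnt["pi_body"] / lens["pi_body"]).to_numpy()
        ratio = dens_p.sum() / dens_b.sum()  # aggregate: sampling-noise robust
        assert ratio == pytest.approx(1.0, rel=0.05)

    def test_unit_fold_means_equal_truth_densities(self, small_genes):
        cfg = SimConfig(seed=2, n_genes=60, occupancy_fold=1.0)
        _, t_wt = simulate.simulate_chip(small_genes, cfg, "wt")
        _, t_ko = simulate.simulate_chip(small_genes, cfg, "ko")
        assert np.allclose(t_wt["expected_count"], t_ko["expected_count"])

    def test_planted_fold_doubles_realized_counts(self):
        """occupancy_fold=2: planted genes' realized KO counts ≈ 2× WT over seeds."""
        ratios = []
        for seed in range(20):
            cfg = SimConfig(seed=seed, n_genes=40, library_size=100_000,
                            occupancy_fraction=0.2, occupancy_fold=2.0,
                            background_fraction=0.3)
            genes = simulate.make_annotation(cfg)
            truth = simulate.chip_truth(cfg, genes)
            fw, tw = simulate.simulate_chip(genes, cfg, "wt", 0, truth)
            fk, tk = simulate.simulate_chip(genes, cfg, "ko", 0, truth)
            planted = truth["planted"].to_numpy()
            assert np.allclose(
                tk["expected_count"], tw["expected_count"] * np.where(planted, 2, 1)
            )
            # realized fragments inside each planted gene's extended span,
            # minus the expected uniform-background contribution there
            genome_length = max(g.end for g in genes) + 10_000

            def realized(frags, truth_tab):
                mids = np.sort(
                    (frags["start"].to_numpy() + frags["end"].to_numpy()) // 2
                )
                bg_share = 1.0 - truth_tab["expected_count"].sum() / cfg.library_size
                total = 0.0
                for g, pl in zip(genes, planted):
                    if not pl:
                        continue
                    lo = g.start - 400 if g.strand == "+" else g.start - 2000
                    hi = g.end + 2000 if g.strand == "+" else g.end + 400
                    n = np.searchsorted(mids, hi) - np.searchsorted(mids, lo)
                    total += n - bg_share * cfg.library_size * (hi - lo) / genome_length
                return total
            ratios.append(realized(fk, tk) / realized(fw, tw))
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.03)


class TestCounts:
    def test_near_zero_dispersion_is_poisson_like(self):
        cfg = SimConfig(seed=6, n_transcripts=100, nb_dispersion=1e-8,
                        n_samples_per_group=50, de_fraction=0.0)
        counts, truth, _ = simulate.simulate_counts(cfg)
        mean = counts.mean(axis=1)
        var = counts.var(axis=1, ddof=1)
        big = mean > 20
        assert np.median((var[big] / mean[big])) == pytest.approx(1.0, abs=0.25)

    def test_no_de_when_fraction_zero(self):
        _, truth, _ = simulate.simulate_counts(SimConfig(seed=1, de_fraction=0.0))
        assert truth["is_de"].sum() == 0

    def test_anchor_means_equal_by_construction(self):
        _, truth, _ = simulate.simulate_counts(SimConfig(seed=3))
        row = truth.loc[simulate.ANCHOR_ID]
        assert row["mu_wt"] == row["mu_ko"]

    def test_determinism(self):
        c1, _, _ = simulate.simulate_counts(SimConfig(seed=8, n_transcripts=50))
        c2, _, _ = simulate.simulate_counts(SimConfig(seed=8, n_transcripts=50))
        pd.testing.assert_frame_equal(c1, c2)


class TestCohort:
    def test_no_causal_sites_when_af_zero(self):
        _, _, _, truth = simulate.simulate_cohort(
            SimConfig(seed=2, causal_af=0.0, cohort_n_cases=20, n_sites=10))
        assert truth["causal"].sum() == 0

    def test_all_passing_genotypes_give_full_an(self):
        cfg = SimConfig(seed=5, cohort_n_cases=30, n_sites=6, genotype_fail_rate=0.0)
        sites, pops, _, _ = simulate.simulate_cohort(cfg)
        for site in sites:
            an = sum(
                variants.recalc_stats(site, pops, p).an
                for p in ("EUR", "MEX")
            )
            assert an == 2 * cfg.cohort_n_cases

    def test_planted_variant_classified_novel(self):
        cfg = SimConfig(seed=7, cohort_n_cases=200, n_sites=10, causal_af=0.05,
                        genotype_fail_rate=0.0)
        sites, pops, controls, truth = simulate.simulate_cohort(cfg)
        causal_keys = set(truth.index[truth["causal"]])
        for site in sites:
            if site.key not in causal_keys:
                continue
            stats = variants.recalc_stats(site, pops, "EUR")
            if stats is None or stats.ac == 0:
                continue
            ctrl = controls[(site.key, "EUR")]
            assert ctrl.ac == 0 and ctrl.coverage >= 30
            assert variants.classify(stats, ctrl) == "novel"

    def test_vcf_round_trip(self, tmp_path):
        cfg = SimConfig(seed=3, cohort_n_cases=15, n_sites=8)
        sites, pops, _, _ = simulate.simulate_cohort(cfg)
        path = tmp_path / "c.vcf"
        simulate.write_vcf(sites, list(pops), path)
        back = variants.read_vcf(path)
        assert len(back) == len(sites)
        for a, b in zip(sites, back):
            assert a.key == b.key
            assert a.vqsr_pass == b.vqsr_pass
            assert a.calls == b.calls


class TestLitters:
    def test_no_lethality_keeps_mendelian_quarter(self):
        cfg = SimConfig(seed=1, litter_n=4000, lethality=0.0)
        lit, _ = simulate.simulate_litters(cfg)
        frac = lit["ko"].sum() / lit[["wt", "het", "ko"]].sum().sum()
        assert frac == pytest.approx(0.25, abs=0.02)

    def test_weaning_fraction_matches_closed_form(self):
        """lethality=0.6 renormalizes the weaning KO share to 0.1176…"""
        cfg = SimConfig(seed=2, litter_n=20_000, lethality=0.6)
        lit, truth = simulate.simulate_litters(cfg)
        frac = lit["ko"].sum() / lit[["wt", "het", "ko"]].sum().sum()
        expected = 0.25 * 0.4 / (0.75 + 0.25 * 0.4)
        assert truth["expected_ko_fraction"] == pytest.approx(expected)
        assert frac == pytest.approx(expected, abs=0.01)

    def test_zero_penetrance_zero_phenotypes(self):
        cfg = SimConfig(seed=3, litter_n=500, penetrance=0.0, wt_penetrance=0.0)
        lit, _ = simulate.simulate_litters(cfg)
        assert lit[["wt_pheno", "het_pheno", "ko_pheno"]].to_numpy().sum() == 0

    def test_genotype_counts_sum_to_survivors(self):
        lit, _ = simulate.simulate_litters(SimConfig(seed=4, litter_n=300))
        survivors = lit[["wt", "het", "ko"]].sum(axis=1)
        conceived = lit[["wt", "het"]].sum(axis=1) + lit["ko_conceived"]
        assert (survivors <= conceived).all()
        assert conceived.sum() == 300


class TestSpectral:
    def test_bait_row_present_and_positive(self):
        mat, labels, _ = simulate.simulate_spectral(SimConfig(seed=1))
        assert (mat.loc[simulate.BAIT_ID] > 0).all()
        assert set(labels) == {"wt", "mutant", "control"}

    def test_dropout_produces_zeros(self):
        mat, _, _ = simulate.simulate_spectral(SimConfig(seed=1))
        assert (mat.drop(index=simulate.BAIT_ID).to_numpy() == 0).any()
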