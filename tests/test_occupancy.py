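"""Region counting, FPKM/PI arithmetic, profiles, TMM and differential occupancy."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from pausekit import occupancy as oc
from pausekit import simulate
from pausekit.regions import GeneModel, derive_regions
from pausekit.simulate import SimConfig


def brute_force_counts(fragments, gene_regions, names):
    """Naive O(n·m) per-fragment oracle for midpoint-in-window counting."""
    out = pd.DataFrame(0, index=[r.gene_id for r in gene_regions], columns=names)
    for _, f in fragments.iterrows():
        mid = (f["start"] + f["end"]) // 2
        for r in gene_regions:
            if r.chrom != f["chrom"]:
                continue
            for name in names:
                s, e = r.intervals[name]
                if name not in r.empty and s <= mid < e:
                    out.at[r.gene_id, name] += 1
    return out


class TestCountRegions:
    def test_single_fragment_promoter_membership(self):
        g = GeneModel("g", "c", 10_000, 20_000, "+")
        r = derive_regions(g)
        frags = pd.DataFrame({"chrom": ["c"], "start": [9_850], "end": [10_050]})
        # midpoint 9,950 = TSS - 50: in promoter, not gene body
        cnt = oc.count_regions(frags, [r], ["promoter", "gene_body"])
        assert cnt.loc["g", "promoter"] == 1
        assert cnt.loc["g", "gene_body"] == 0

    def test_uniform_coverage_proportional_to_lengths(self):
        g = GeneModel("g", "c", 50_000, 58_000, "+")
        r = derive_regions(g)
        pos = np.arange(30_000, 80_000)
        frags = pd.DataFrame({"chrom": "c", "start": pos, "end": pos + 1})
        cnt = oc.count_regions(frags, [r], ["promoter", "gene_body", "tes_region"])
        assert cnt.loc["g", "promoter"] == r.length("promoter")
        assert cnt.loc["g", "gene_body"] == r.length("gene_body")
        assert cnt.loc["g", "tes_region"] == r.length("tes_region")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [
            GeneModel(f"g{i}", "c", s, s + int(rng.integers(2_500, 6_000)),
                      str(rng.choice(["+", "-"])))
            for i, s in enumerate(np.cumsum(rng.integers(25_000, 40_000, size=4)))
        ]
        regs = [derive_regions(g) for g in genes]
        starts = rng.integers(0, 200_000, size=300)
        frags = pd.DataFrame({"chrom": "c", "start": starts, "end": starts + 200})
        names = ["promoter", "gene_body", "pi_body", "upstream"]
        fast = oc.count_regions(frags, regs, names)
        slow = brute_force_counts(frags, regs, names)
        pd.testing.assert_frame_equal(fast, slow, check_dtype=False)

    def test_empty_region_list(self):
        frags = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10]})
        assert oc.count_regions(frags, [], []).empty


class TestFpkmAndPi:
    def test_fpkm_arithmetic(self):
        assert oc.fpkm(50, 500, 10_000_000) == pytest.approx(10.0)
        assert oc.fpkm(0, 500, 10_000_000) == 0.0

    def test_fpkm_ratio_invariance(self):
        assert oc.fpkm(100, 500, 2e7) == pytest.approx(oc.fpkm(50, 500, 1e7))

    def test_fpkm_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            oc.fpkm(1, 0, 1e6)
        with pytest.raises(ValueError):
            oc.fpkm(1, 100, 0)

    def test_pi_formula_as_printed(self):
        assert oc.pausing_index(40.0, 4.0, 2_000) == pytest.approx(40.0)

    def test_pi_scale_invariance(self):
        pi1 = oc.pausing_index(40.0, 4.0, 2_000)
        pi2 = oc.pausing_index(40.0 * 7, 4.0 * 7, 2_000)
        assert pi1 == pytest.approx(pi2)

    def test_pi_uniform_density_equals_length_ratio(self):
        """Equal promoter/body densities give equal FPKMs, so the printed
        formula returns L2/L1 while the density mode returns 1."""
        l2 = 4 * 500
        assert oc.pausing_index(10.0, 10.0, l2) == pytest.approx(l2 / 500)
        assert oc.pausing_index(10.0, 10.0, l2, mode="density") == pytest.approx(1.0)

    def test_pi_undefined_iff_zero_body(self):
        out = oc.pausing_index(np.array([1.0, 1.0]), np.array([0.0, 2.0]),
                               np.array([1_000, 1_000]))
        assert np.isnan(out[0]) and np.isfinite(out[1])

    def test_pi_rejects_negative(self):
        with pytest.raises(ValueError):
            oc.pausing_index(-1.0, 1.0, 1_000)


class TestComparePausing:
    def test_identical_tables_give_p_one(self):
        pi = pd.DataFrame(np.random.default_rng(0).uniform(1, 5, (20, 3)),
                          columns=["a", "b", "c"])
        res = oc.compare_pausing(pi, pi.copy(), [("a", "a"), ("b", "b"), ("c", "c")])
        assert (res["p"] == 1.0).all()

    def test_doubled_pi_with_zero_variance_is_significant(self):
        rng = np.random.default_rng(1)
        base = pd.DataFrame(rng.uniform(1, 5, (30, 3)), columns=list("abc"))
        base.iloc[0] = 2.0  # replicate-constant PI for the focal gene
        ko = base * 1.0
        ko.iloc[0] = base.iloc[0] * 2  # exact doubling, zero within-pair variance
        res = oc.compare_pausing(base, ko, list(zip("abc", "abc")))
        assert res["p"].iloc[0] == 0.0
        assert (res["p"].iloc[1:] == 1.0).all()

    def test_requires_two_pairs(self):
        pi = pd.DataFrame(np.ones((5, 1)), columns=["a"])
        with pytest.raises(ValueError):
            oc.compare_pausing(pi, pi, [("a", "a")])

    def test_null_type_i_error_calibrated(self):
        """occupancy_fold=1 simulation: ~5% of raw p fall below 0.05."""
        fractions = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mu = rng.uniform(20, 200, size=200)
            wt = pd.DataFrame(
                rng.poisson(mu[:, None], (200, 3)), columns=list("abc"))
            ko = pd.DataFrame(
                rng.poisson(mu[:, None], (200, 3)), columns=list("abc"))
            res = oc.compare_pausing(wt + 1.0, ko + 1.0, list(zip("abc", "abc")))
            fractions.append((res["p"] < 0.05).mean())
        assert np.mean(fractions) == pytest.approx(0.05, abs=0.02)


class TestProfiles:
    def test_metagene_uniform_coverage_is_flat_100_bins(self):
        g = GeneModel("g", "c", 50_000, 56_000, "+")
        pos = np.arange(40_000, 66_000)
        frags = pd.DataFrame({"chrom": "c", "start": pos - 100, "end": pos + 100})
        prof = oc.metagene([g], frags, total_mapped=len(frags))
        assert len(prof) == 100
        assert prof["mean"].max() / prof["mean"].min() < 1.1
        assert (prof["se"] == 0).all()

    def test_metagene_spike_lands_in_first_body_bin(self):
        g = GeneModel("g", "c", 50_000, 56_000, "-")
        # spike just inside the body at the TSS (right edge for '-')
        spike = np.full(500, g.end - 10)
        frags = pd.DataFrame({"chrom": "c", "start": spike - 50, "end": spike + 50})
        prof = oc.metagene([g], frags, total_mapped=len(frags))
        assert prof["mean"].idxmax() == 20  # first body bin after 20 flank bins

    def test_metagene_requires_eligible_genes(self):
        g = GeneModel("g", "c", 100, 150, "+")
        with pytest.raises(ValueError):
            oc.metagene([g], pd.DataFrame({"chrom": [], "start": [], "end": []}), 1)

    def test_tss_profile_empty_and_centered(self):
        genes = [GeneModel(f"g{i}", "c", 50_000 + 40_000 * i,
                           56_000 + 40_000 * i, "+") for i in range(4)]
        empty = oc.tss_profile(genes, pd.DataFrame({"chrom": [], "start": [], "end": []}))
        assert len(empty) == 51 and empty.sum() == 0
        peaks = pd.DataFrame(
            {"chrom": "c", "start": [g.tss - 50 for g in genes],
             "end": [g.tss + 50 for g in genes]})
        prof = oc.tss_profile(genes, peaks)
        assert prof[25] == len(genes)

    def test_tss_profile_uniform_peaks_flat(self):
        genes = [GeneModel("g", "c", 500_000, 520_000, "+")]
        rng = np.random.default_rng(0)
        starts = rng.integers(480_000, 520_000, size=20_000)
        peaks = pd.DataFrame({"chrom": "c", "start": starts, "end": starts + 1})
        prof = oc.tss_profile(genes, peaks)
        inner = prof[5:46]  # away from span edges
        assert inner.max() / inner.min() < 1.35


class TestTrack:
    def test_scaling_per_10m_reads(self):
        cov = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10], "value": [3.0]})
        assert oc.scale_track(cov, 10_000_000)["value"].iloc[0] == pytest.approx(3.0)
        assert oc.scale_track(cov, 20_000_000)["value"].iloc[0] == pytest.approx(1.5)

    def test_zero_library_rejected(self):
        cov = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1], "value": [1.0]})
        with pytest.raises(ValueError):
            oc.scale_track(cov, 0)

    def test_bedgraph_round_trip_six_decimals(self, tmp_path):
        rng = np.random.default_rng(0)
        cov = pd.DataFrame({
            "chrom": "c", "start": np.arange(10) * 10,
            "end": np.arange(1, 11) * 10, "value": rng.uniform(0, 5, 10)})
        path = tmp_path / "t.bedgraph"
        oc.write_bedgraph(cov, path)
        back = oc.read_bedgraph(path)
        assert np.allclose(back["value"], cov["value"], atol=5e-7)


class TestTmm:
    def test_identical_compositions_give_unit_factors(self):
        counts = pd.DataFrame(np.random.default_rng(0).poisson(50, (100, 4)),
                              columns=list("abcd"))
        same = pd.concat([counts["a"]] * 4, axis=1, keys=list("abcd"))
        assert np.allclose(oc.tmm_factors(same), 1.0)

    def test_matches_edger_reference(self, tmp_path):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.1, size=(400, 4)).astype(float),
            columns=list("ABCD"))
        counts.iloc[:40, 2] *= 4
        mine = oc.tmm_factors(counts)
        f = tmp_path / "c.tsv"
        counts.to_csv(f, sep="\t", index=False)
        r = subprocess.run(
            ["Rscript", "-e",
             f'suppressMessages(library(edgeR)); x <- as.matrix(read.delim("{f}"));'
             'cat(calcNormFactors(x, method="TMM"), sep=",")'],
            capture_output=True, text=True)
        if r.returncode != 0:
            pytest.skip("Rscript/edgeR unavailable")
        theirs = np.array([float(v) for v in r.stdout.strip().split(",")])
        assert np.allclose(mine.to_numpy(), theirs, rtol=1e-4)

    def test_factors_geometric_mean_one(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(40, (200, 5)) * [1, 2, 1, 3, 1],
                              columns=list("abcde"))
        f = oc.tmm_factors(counts)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)


class TestDifferentialOccupancy:
    def _paired(self, rng, n=300, planted=None, fold=1.0):
        mu = rng.uniform(20, 300, size=n)
        fold_vec = np.ones(n)
        if planted is not None:
            fold_vec[planted] = fold
        wt = pd.DataFrame({f"wt{i}": rng.poisson(mu) for i in range(3)})
        ko = pd.DataFrame({f"ko{i}": rng.poisson(mu * fold_vec) for i in range(3)})
        return wt, ko

    def test_identical_matrices_nothing_significant(self):
        rng = np.random.default_rng(0)
        wt, _ = self._paired(rng)
        res = oc.differential_occupancy(wt, wt.copy().set_axis(
            ["ko0", "ko1", "ko2"], axis=1))
        assert res["significant"].sum() == 0

    def test_ko_zero_genes_filtered(self):
        wt = pd.DataFrame(np.full((5, 3), 10), columns=["w0", "w1", "w2"])
        ko = wt.copy().set_axis(["k0", "k1", "k2"], axis=1)
        ko.iloc[0, 1] = 0
        res = oc.differential_occupancy(wt, ko)
        assert len(res) == 4 and 0 not in res.index

    def test_permuted_null_controls_fdr(self):
        """Label-permuted null data: average significant count ≤ nominal."""
        counts = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            wt, ko = self._paired(rng, n=400)
            res = oc.differential_occupancy(wt, ko, fdr=0.1)
            counts.append(res["significant"].sum())
        assert np.mean(counts) <= 0.1 * 400

    def test_planted_fold_recovered(self):
        rng = np.random.default_rng(7)
        planted = np.arange(15)
        wt, ko = self._paired(rng, n=300, planted=planted, fold=2.0)
        res = oc.differential_occupancy(wt, ko, fdr=0.1)
        called = res.index[res["significant"] & (res["direction"] == "up")]
        assert len(set(planted) & set(called)) >= 12


class TestBh:
    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        from pausekit.stats import bh_fdr

        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        mine = bh_fdr(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(mine, theirs)
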