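"""Simulator tests: frequency model, ancestry tracts, cohort structure."""

import numpy as np
import pytest
from scipy import stats

import admixstats as A
from admixstats.simulate import _drift


class TestPanel:
    def test_no_drift_frequencies_identical(self):
        spec = A.DemographicSpec(
            bottleneck_F={"AFR": 0.0, "EUR": 0.0, "NAM": 0.0}, sel_strength=0.0,
            seed=1,
        )
        panel = A.simulate_panel(20_000, spec)
        # with F=0 the bottleneck transform is the identity, site by site
        np.testing.assert_array_equal(
            panel.table["freq_AFR"], panel.table["freq_EUR"]
        )
        np.testing.assert_array_equal(
            panel.table["freq_AFR"], panel.table["freq_NAM"]
        )

    def test_bottleneck_excess_of_lost_and_fixed_sites(self, rng):
        spec = A.DemographicSpec(
            bottleneck_F={"AFR": 0.0, "EUR": 0.1, "NAM": 0.0}, sel_strength=0.0,
            seed=2,
        )
        panel = A.simulate_panel(100_000, spec)
        p_afr = panel.table["freq_AFR"].to_numpy()
        p_eur = panel.table["freq_EUR"].to_numpy()
        extreme = lambda p: np.mean((p == 0) | (p >= 0.99))
        assert extreme(p_eur) > extreme(p_afr)

        # independent Monte-Carlo re-draw of the same Beta-drift transform
        redraw = _drift(p_afr, 0.1, rng)
        redraw = np.where(redraw < 1e-3, 0.0, np.where(redraw > 0.999, 1.0, redraw))
        assert abs(extreme(redraw) - extreme(p_eur)) < 0.01
        # drift preserves the mean frequency
        assert abs(p_eur.mean() - p_afr.mean()) < 0.01

    def test_no_selection_decouples_conservation_and_frequency(self):
        spec = A.DemographicSpec(sel_strength=0.0, seed=3)
        panel = A.simulate_panel(100_000, spec)
        r = np.corrcoef(panel.table["conservation"], panel.table["freq_AFR"])[0, 1]
        assert abs(r) < 0.02

    def test_conservation_frequency_coupling_monotone_in_selection(self):
        rhos = []
        for s in (0.0, 0.3, 0.8):
            spec = A.DemographicSpec(sel_strength=s, seed=4)
            panel = A.simulate_panel(50_000, spec)
            rho, _ = stats.spearmanr(
                panel.table["conservation"], panel.table["freq_AFR"]
            )
            rhos.append(rho)
        assert rhos[0] > rhos[1] > rhos[2]

    def test_novelty_enriched_on_afr_only_sites(self):
        spec = A.DemographicSpec(seed=5)
        panel = A.simulate_panel(50_000, spec)
        t = panel.table
        afr_only = (t.freq_AFR > 0) & (t.freq_EUR == 0) & (t.freq_NAM == 0)
        seg_everywhere = (t.freq_AFR > 0) & (t.freq_EUR > 0)
        assert t.loc[afr_only, "known"].mean() < t.loc[seg_everywhere, "known"].mean()

    def test_coding_conservation_has_heavier_tail(self):
        spec = A.DemographicSpec(coding_fraction=0.3, seed=6)
        panel = A.simulate_panel(50_000, spec)
        t = panel.table
        q99 = np.quantile(t["conservation"], 0.99)
        assert (t.loc[t.coding, "conservation"] > q99).mean() > (
            t.loc[~t.coding, "conservation"] > q99
        ).mean()

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            A.DemographicSpec(bottleneck_F={"AFR": 0.0, "EUR": 1.2, "NAM": 0.0})
        with pytest.raises(ValueError):
            A.DemographicSpec(afr_sfs_alpha=-1.0)
        with pytest.raises(ValueError):
            A.DemographicSpec(s_f={"AFR": 0.7, "EUR": 0.2, "NAM": 0.2})
        with pytest.raises(ValueError):
            A.simulate_panel(0, A.DemographicSpec())


class TestLocalAncestry:
    def test_degenerate_simplex_gives_all_afr_codes(self):
        panel = A.differentiated_panel(500, seed=0)
        lac = A.simulate_local_ancestry(panel, [(1.0, 0.0, 0.0)] * 4, g=8, seed=0)
        assert np.all(lac.codes == 3)

    def test_large_g_matches_hardy_weinberg_code_frequencies(self):
        q = np.array([0.6, 0.3, 0.1])
        panel = A.differentiated_panel(100_000, seed=1)
        lac = A.simulate_local_ancestry(panel, q, g=1e7, seed=1)
        # closed-form expectation for unordered diplotype codes
        expected = {
            3: q[0] ** 2, 1: q[1] ** 2, 6: q[2] ** 2,
            2: 2 * q[0] * q[1], 5: 2 * q[0] * q[2], 4: 2 * q[1] * q[2],
        }
        counts = np.bincount(lac.codes.ravel(), minlength=7)[1:]
        n = lac.codes.size
        obs = {c: counts[c - 1] for c in expected}
        chi2 = sum((obs[c] - n * e) ** 2 / (n * e) for c, e in expected.items())
        assert stats.chi2.sf(chi2, df=5) > 0.01

    def test_mean_tract_length_matches_exponential_expectation(self):
        """Haplotype switch events arrive at g per Morgan and redraw from q, so
        the observable tract of ancestry k is Exponential with mean
        100/(g (1-q_k)) cM; at q_k=1/2 and g=8 that is 25 cM."""
        from admixstats.simulate import _haplotype_ancestry

        g, qk = 8.0, 0.5
        panel = A.differentiated_panel(40_000, seed=2, spacing_cm=0.05)
        pos = panel.table["pos_cm"].to_numpy()
        q = np.tile([qk, 1 - qk, 0.0], (30, 1))
        haps = _haplotype_ancestry(pos, q, g, np.random.default_rng(2))
        lengths = []
        for row in haps:
            change = np.flatnonzero(np.diff(row) != 0)
            bounds = pos[change + 1]
            if len(bounds) > 1:
                lengths.append(np.diff(bounds))  # interior (uncensored) tracts
        mean_len = np.concatenate(lengths).mean()
        expected = 100.0 / (g * (1 - qk))
        assert abs(mean_len - expected) / expected < 0.10

    def test_missing_genetic_map_raises(self):
        panel = A.differentiated_panel(100, seed=3)
        panel.table["pos_cm"] = np.nan
        with pytest.raises(ValueError, match="map"):
            A.simulate_local_ancestry(panel, [(0.5, 0.5, 0.0)], g=8, seed=0)

    def test_unknown_rate_injects_code_zero(self):
        panel = A.differentiated_panel(2000, seed=4)
        lac = A.simulate_local_ancestry(
            panel, [(0.5, 0.3, 0.2)] * 10, g=8, seed=0, unknown_rate=0.1
        )
        frac0 = (lac.codes == 0).mean()
        assert 0.05 < frac0 < 0.15


class TestCohort:
    def test_no_bias_means_x_equals_autosome(self):
        s = {"AFR": 0.6, "EUR": 0.3, "NAM": 0.1}
        spec = A.DemographicSpec(n_individuals=500, s_f=s, s_m=s, seed=8)
        cohort = A.simulate_cohort(spec, A.simulate_panel(300, spec))
        diff = cohort.true_global_auto["q_AFR"].mean() - cohort.true_global_x["q_AFR"].mean()
        assert abs(diff) < 0.01

    def test_sex_biased_contributions_shift_x_vs_autosome(self):
        spec = A.DemographicSpec(
            n_individuals=800,
            s_f={"AFR": 0.8, "EUR": 0.2, "NAM": 0.0},
            s_m={"AFR": 0.4, "EUR": 0.6, "NAM": 0.0},
            seed=9,
        )
        cohort = A.simulate_cohort(spec, A.simulate_panel(300, spec))
        assert cohort.true_global_auto["q_AFR"].mean() == pytest.approx(0.60, abs=0.01)
        assert cohort.true_global_x["q_AFR"].mean() == pytest.approx(2 / 3, abs=0.01)

    def test_genotypes_track_panel_frequencies_on_homozygous_background(self, small_cohort):
        """On AFR:AFR segments the per-site genotype mean is 2 x panel AFR frequency."""
        gm, lac, panel = (
            small_cohort.genotypes, small_cohort.true_local, small_cohort.panel
        )
        on3 = (lac.codes == 3) & ~gm.missing & ~gm.hemizygous
        f = panel.table["freq_AFR"].to_numpy()
        keep = (on3.sum(axis=0) >= 20) & (f > 0.05) & (f < 0.95)
        dos = np.where(on3, gm.dosages, 0).sum(axis=0)[keep] / on3.sum(axis=0)[keep]
        slope = np.polyfit(2 * f[keep], dos, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_male_x_is_hemizygous_0_or_2(self, small_cohort):
        gm = small_cohort.genotypes
        male_x = gm.hemizygous & ~gm.missing
        assert male_x.any()
        assert np.all(np.isin(gm.dosages[male_x], (0, 2)))

    def test_same_seed_bit_identical_different_seed_differs(self):
        spec = A.DemographicSpec(n_individuals=20, seed=42)
        c1 = A.simulate_cohort(spec, A.simulate_panel(1000, spec))
        c2 = A.simulate_cohort(spec, A.simulate_panel(1000, spec))
        np.testing.assert_array_equal(c1.genotypes.dosages, c2.genotypes.dosages)
        np.testing.assert_array_equal(c1.true_local.codes, c2.true_local.codes)
        spec3 = spec.with_(seed=43)
        c3 = A.simulate_cohort(spec3, A.simulate_panel(1000, spec3))
        assert not np.array_equal(c1.genotypes.dosages, c3.genotypes.dosages)
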