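"""Deleterious-site definition and mutation-load decomposition tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import admixstats as A
from admixstats.burden import robust_filter, MannWhitneyResult

from conftest import toy_annotations, toy_genotype_matrix


class TestThreshold:
    def test_nearest_rank_matches_sort_and_index(self, rng):
        scores = rng.normal(size=100_000)
        cutoff, flags = A.deleterious_threshold(scores, 99.9)
        # oracle: sort-and-index
        assert cutoff == np.sort(scores)[int(np.ceil(round(0.999 * 100_000, 9))) - 1]
        assert flags.sum() / len(scores) == pytest.approx(0.001, abs=2e-5)

    def test_score_at_cutoff_is_deleterious(self, rng):
        scores = np.concatenate([rng.normal(size=2000), [5.0]])
        cutoff, flags = A.deleterious_threshold(scores, 99.9)
        assert flags[np.flatnonzero(scores == cutoff)].all()

    def test_all_equal_scores_flag_everything_with_warning(self):
        with pytest.warns(UserWarning):
            cutoff, flags = A.deleterious_threshold(np.ones(2000), 99.9)
        assert flags.all()

    def test_too_few_sites_raise(self):
        with pytest.raises(ValueError):
            A.deleterious_threshold(np.ones(500), 99.9)


class TestRobustFilter:
    def test_cadd_conjunction_and_mode_nesting(self, rng):
        n = 5000
        flags = rng.random(n) < 0.1
        cadd = rng.uniform(0, 60, n)
        only, _ = robust_filter(flags, cadd, "phylop-only")
        c30, _ = robust_filter(flags, cadd, "phylop+cadd30")
        c20, _ = robust_filter(flags, cadd, "phylop+cadd20")
        # conserved but CADD 25 fails the cadd30 conjunction
        i = np.flatnonzero(flags & (cadd > 20) & (cadd < 30))
        assert not c30[i].any()
        assert c20[i].all()
        # cadd20 is a superset of cadd30; phylop-only a superset of both
        assert np.all(c30 <= c20)
        assert np.all(c20 <= only)

    def test_missing_cadd_dropped_and_counted(self):
        flags = np.array([True, True, False])
        cadd = np.array([35.0, np.nan, np.nan])
        out, dropped = robust_filter(flags, cadd, "phylop+cadd30")
        assert list(out) == [True, False, False]
        assert dropped == 1


class TestBurdenProfiles:
    def test_zygosity_identity_on_toy(self):
        gm = toy_genotype_matrix([[1, 1, 2]])
        ann = toy_annotations(3)
        prof = A.burden_profiles(gm, np.ones(3, bool), ann)
        assert prof["n_het"].iloc[0] == 2
        assert prof["n_homder"].iloc[0] == 1
        assert prof["n_derived"].iloc[0] == 4

    def test_matches_naive_loop_and_identity(self, rng):
        n, s = 50, 5000
        dos = rng.choice([-1, 0, 1, 2], size=(n, s), p=[0.02, 0.68, 0.2, 0.1])
        gm = toy_genotype_matrix(dos)
        coding = rng.random(s) < 0.3
        ann = toy_annotations(s, coding=coding)
        flags = rng.random(s) < 0.05
        prof = A.burden_profiles(gm, flags, ann)
        for i in rng.choice(n, 10, replace=False):
            het = hom = 0
            for site in np.flatnonzero(flags):
                if dos[i, site] == 1:
                    het += 1
                elif dos[i, site] == 2:
                    hom += 1
            assert prof["n_het"].iloc[i] == het
            assert prof["n_homder"].iloc[i] == hom
        assert (prof["n_derived"] == prof["n_het"] + 2 * prof["n_homder"]).all()
        for comp in ("n_het", "n_homder", "n_derived"):
            assert (prof[comp] == prof[f"coding_{comp}"] + prof[f"noncoding_{comp}"]).all()

    def test_total_burden_conserved_across_individuals(self, rng):
        dos = rng.choice([0, 1, 2], size=(30, 2000), p=[0.7, 0.2, 0.1])
        gm = toy_genotype_matrix(dos)
        flags = rng.random(2000) < 0.1
        prof = A.burden_profiles(gm, flags, toy_annotations(2000))
        assert prof["n_derived"].sum() == dos[:, flags].sum()

    def test_zero_flags_zero_profiles(self):
        gm = toy_genotype_matrix([[1, 2], [0, 1]])
        prof = A.burden_profiles(gm, np.zeros(2, bool), toy_annotations(2))
        assert (prof[["n_het", "n_homder", "n_derived"]] == 0).all().all()


class TestCorrelations:
    def test_perfectly_monotone_pairs_give_rho_one(self):
        prof = pd.DataFrame(
            {"n_derived": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
             "afr_ancestry": np.linspace(0.1, 0.9, 10)}
        )
        rho, _ = A.burden_ancestry_correlation(prof, "derived")
        assert rho == pytest.approx(1.0)

    def test_tied_toy_table_matches_hand_ranking(self):
        # 10 pairs with one tie in x: hand-computed average ranks
        x = np.array([3, 1, 4, 4, 2, 5, 6, 7, 8, 9])
        y = np.array([2, 1, 3, 4, 2, 6, 5, 8, 7, 9])
        prof = pd.DataFrame({"n_derived": x, "afr_ancestry": y})
        rho, p = A.burden_ancestry_correlation(prof, "derived")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        hand = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(hand, rel=1e-12)

    def test_constant_vector_raises(self):
        prof = pd.DataFrame({"n_derived": np.ones(12), "afr_ancestry": np.arange(12.0)})
        with pytest.raises(ValueError):
            A.burden_ancestry_correlation(prof, "derived")

    def test_bottleneck_cohort_shows_load_cancellation(self):
        """More African ancestry -> more deleterious heterozygotes; more
        European ancestry -> more deleterious derived homozygotes; totals
        nearly flat. A single replicate's realised drift is noisy, so the
        pattern is asserted on the mean over three panel draws."""
        rho = {"het": [], "homder": [], "derived": []}
        for seed in (22, 23, 24):
            spec = A.DemographicSpec(
                n_individuals=100,
                populations=("HI", "LO"),
                s_f={"HI": {"AFR": 0.8, "EUR": 0.15, "NAM": 0.05},
                     "LO": {"AFR": 0.2, "EUR": 0.7, "NAM": 0.1}},
                s_m={"HI": {"AFR": 0.8, "EUR": 0.15, "NAM": 0.05},
                     "LO": {"AFR": 0.2, "EUR": 0.7, "NAM": 0.1}},
                bottleneck_F={"AFR": 0.0, "EUR": 0.1, "NAM": 0.15},
                sel_strength=0.2,
                seed=seed,
            )
            panel = A.simulate_panel(50_000, spec)
            cohort = A.simulate_cohort(spec, panel)
            _, flags = A.deleterious_threshold(
                panel.table["conservation"].to_numpy(), 98.0
            )
            prof = A.burden_profiles(
                cohort.genotypes, flags, panel.table, cohort.true_global_auto["q_AFR"]
            )
            for comp in rho:
                rho[comp].append(A.burden_ancestry_correlation(prof, comp)[0])
        assert np.mean(rho["het"]) > 0.1
        assert np.mean(rho["homder"]) < -0.1
        assert abs(np.mean(rho["derived"])) < abs(np.mean(rho["homder"]))


class TestStratifiedProportions:
    def _toy(self, dos, codes, flags, coding=None):
        gm = toy_genotype_matrix(dos)
        ann = toy_annotations(dos.shape[1], coding=coding)
        lac = A.LocalAncestryCodes(
            np.asarray(codes, dtype=np.int8),
            gm.sites["site_id"].to_numpy(),
            gm.individuals.index.to_numpy(),
        )
        return gm, ann, lac

    def test_identical_proportions_give_null_u(self):
        dos = np.ones((8, 4), dtype=np.int8)
        flags = np.array([True, False, True, False])
        codes = np.tile(np.array([3, 3, 1, 1], np.int8), (8, 1))
        gm, ann, lac = self._toy(dos, codes, flags)
        df, res = A.stratified_proportions(gm, flags, lac, ann)
        # same proportion 0.5 on both backgrounds for everyone
        assert res.u == pytest.approx(8 * 8 / 2)
        assert res.pvalue > 0.9

    def test_u_statistic_matches_exhaustive_enumeration(self):
        a = np.array([0.10, 0.30, 0.50, 0.70])
        b = np.array([0.20, 0.40, 0.60, 0.80])
        u_impl = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        # exact U by enumeration of all cross pairs
        u_exact = sum(
            1.0 if x > y else (0.5 if x == y else 0.0)
            for x, y in itertools.product(a, b)
        )
        assert u_impl == pytest.approx(u_exact)

    def test_ambiguous_backgrounds_excluded(self):
        dos = np.ones((4, 4), dtype=np.int8)
        flags = np.array([True, False, True, False])
        # codes 2 (EUR:AFR) and 0 (unknown) must not contribute
        codes = np.tile(np.array([2, 0, 3, 1], np.int8), (4, 1))
        gm, ann, lac = self._toy(dos, codes, flags)
        df, _ = A.stratified_proportions(gm, flags, lac, ann)
        # only site 2 (code 3, flagged) on AFR; site 3 (code 1, unflagged) on EUR
        assert np.allclose(df["prop_afr_bg"], 1.0)
        assert np.allclose(df["prop_eur_bg"], 0.0)

    def test_african_specific_coding_selection_lowers_afr_proportion(self):
        spec = A.DemographicSpec(
            n_individuals=100,
            s_f={"AFR": 0.65, "EUR": 0.3, "NAM": 0.05},
            s_m={"AFR": 0.65, "EUR": 0.3, "NAM": 0.05},
            sel_strength=0.2,
            sel_coding_afr=0.3,
            coding_fraction=0.10,
            seed=31,
        )
        panel = A.simulate_panel(50_000, spec)
        cohort = A.simulate_cohort(spec, panel)
        _, flags = A.deleterious_threshold(panel.table["conservation"].to_numpy(), 98.0)
        df, res = A.stratified_proportions(
            cohort.genotypes, flags, cohort.true_local, panel.table, cls="coding"
        )
        assert np.nanmean(df["prop_afr_bg"]) < np.nanmean(df["prop_eur_bg"])
        assert res.pvalue < 0.05


class TestScoreCompare:
    def test_medians_match_sort_oracle_and_null_p(self, rng):
        n = 4000
        coding = rng.random(n) < 0.5
        scores = rng.normal(size=n)
        ann = toy_annotations(n, coding=coding, conservation=scores)
        flags = np.ones(n, bool)
        res = A.score_distribution_compare(flags, ann)
        assert res["median_coding"] == pytest.approx(
            np.sort(scores[coding])[len(scores[coding]) // 2]
            if len(scores[coding]) % 2
            else np.median(scores[coding])
        )
        assert res["pvalue"] > 0.01  # same distribution

    def test_detects_small_location_shift(self, rng):
        n = 10_000
        coding = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        scores = np.concatenate([rng.normal(0.03, 1, n), rng.normal(0, 1, n)])
        ann = toy_annotations(2 * n, coding=coding, conservation=scores)
        res = A.score_distribution_compare(np.ones(2 * n, bool), ann)
        assert res["pvalue"] < 0.05

    def test_empty_class_raises(self, rng):
        ann = toy_annotations(100, coding=np.zeros(100, bool))
        with pytest.raises(ValueError):
            A.score_distribution_compare(np.ones(100, bool), ann)
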