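"""Monte-Carlo verification studies for every pipeline stage.

Each study regenerates its own synthetic inputs, runs the corresponding
analysis through the public API and returns summary metrics. They serve two
audiences: the test suite asserts the documented tolerances on them, and the
reproduction script reports their values. Problem sizes are chosen so each
study carries the statistical power its check needs while staying desk-sized;
docs/methods.md discusses the choices.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from . import burden as burden_mod
from .catalog import SFS, allele_counts
from .containers import GenotypeMatrix
from .discovery import jackknife_project, neutral_sfs, rarefaction
from .doubletons import find_doubletons, sharing_matrix
from .sexbias import compare_x_autosome, estimate_q_supervised
from .simulate import (
    DemographicSpec,
    differentiated_panel,
    genotypes_given_ancestry,
    simulate_cohort,
    simulate_local_ancestry,
    simulate_panel,
)

__all__ = [
    "rarefaction_enumeration_study",
    "harmonic_series_study",
    "jackknife_recovery_study",
    "doubleton_oracle_study",
    "burden_pattern_study",
    "burden_null_study",
    "stratified_sign_study",
    "sexbias_calibration_study",
    "sexbias_power_study",
    "estimator_accuracy_study",
]


def _seeds(seed: int, n: int) -> np.ndarray:
    """n child seeds below 2**31, deterministically derived from one master."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


# ---------------------------------------------------------------------------
# discovery projection

def _enumeration_oracle(sfs: SFS, n: int) -> float:
    """Exhaustive average of polymorphic-site counts over all C(N,n) subsets."""
    N = sfs.n_chromosomes
    counts = [i for i, c in enumerate(sfs.xi, start=1) for _ in range(int(c))]
    total = 0.0
    n_subsets = 0
    for subset in itertools.combinations(range(N), n):
        mask = np.zeros(N, dtype=bool)
        mask[list(subset)] = True
        for i in counts:
            drawn = int(mask[:i].sum())
            total += 0 < drawn < n
        n_subsets += 1
    return total / n_subsets


def rarefaction_enumeration_study(seed: int, n_instances: int = 200) -> dict:
    """Hypergeometric rarefaction vs exhaustive subsample enumeration, N<=12."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_instances):
        N = int(rng.integers(4, 13))
        xi = rng.integers(0, 4, size=N - 1).astype(float)
        if xi.sum() == 0:
            xi[int(rng.integers(N - 1))] = 1
        sfs = SFS(N, xi)
        n = int(rng.integers(1, N + 1))
        err = abs(rarefaction(sfs, n) - _enumeration_oracle(sfs, n))
        max_err = max(max_err, err)
    return {"max_abs_error": max_err, "n_instances": n_instances}


def harmonic_series_study(theta: float = 10.0, N: int = 40) -> dict:
    """Neutral expected SFS: E[S(n)] must equal theta x partial harmonic series."""
    sfs = neutral_sfs(theta, N)
    max_err = 0.0
    for n in range(2, N + 1):
        target = theta * np.sum(1.0 / np.arange(1, n))
        max_err = max(max_err, abs(rarefaction(sfs, n) - target))
    return {"max_abs_error": max_err, "N": N}


def jackknife_recovery_study(
    seed: int, n_reps: int = 20, theta: float = 500.0,
    n_full: int = 2000, n_sub: int = 1000,
) -> dict:
    """Project S from a half-sample of unlinked neutral sites back to the truth."""
    rng = np.random.default_rng(seed)
    errs, orders = [], []
    for _ in range(n_reps):
        full = neutral_sfs(theta, n_full, rng=rng)
        xi_sub = np.zeros(n_sub - 1)
        for i in np.flatnonzero(full.xi) + 1:
            draws = rng.hypergeometric(i, n_full - i, n_sub, size=int(full.xi[i - 1]))
            draws = draws[(draws > 0) & (draws < n_sub)]
            xi_sub += np.bincount(draws, minlength=n_sub)[1:n_sub]
        res = jackknife_project(SFS(n_sub, xi_sub), n_full)
        errs.append(abs(res.value - full.segregating) / full.segregating)
        orders.append(res.order)
    return {
        "mean_rel_error": float(np.mean(errs)),
        "max_rel_error": float(np.max(errs)),
        "orders": orders,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# doubletons

def doubleton_oracle_study(
    seed: int, n_individuals: int = 20, n_sites: int = 5000
) -> dict:
    """Sharing matrix vs a naive per-site double loop, plus exact conservation."""
    spec = DemographicSpec(
        n_individuals=n_individuals, populations=("P1", "P2"),
        s_f={"P1": {"AFR": 0.8, "EUR": 0.15, "NAM": 0.05},
             "P2": {"AFR": 0.3, "EUR": 0.6, "NAM": 0.1}},
        s_m={"P1": {"AFR": 0.8, "EUR": 0.15, "NAM": 0.05},
             "P2": {"AFR": 0.3, "EUR": 0.6, "NAM": 0.1}},
        seed=int(seed),
    )
    panel = simulate_panel(n_sites, spec)
    cohort = simulate_cohort(spec, panel)
    gm = cohort.genotypes
    dbl = find_doubletons(gm, panel.table)
    share = sharing_matrix(gm, dbl)

    # brute force over raw dosages (derived copies; hemizygous males count 1)
    copies = gm.derived_copies
    copies = np.where(copies > 0, copies, 0)
    confident = panel.table["ancestral_confident"].to_numpy()
    counts = allele_counts(gm)
    n = gm.n_individuals
    brute = np.zeros((n, n))
    n_self = n_total = 0
    for s in range(gm.n_sites):
        if not confident[s] or counts["missingness"].iloc[s] > 0.05 + 1e-12:
            continue
        col = copies[:, s]
        if col.sum() != 2:
            continue
        n_total += 1
        carriers = np.flatnonzero(col)
        if len(carriers) == 1:
            n_self += 1
        else:
            brute[carriers[0], carriers[1]] += 1
            brute[carriers[1], carriers[0]] += 1
    pair_sum = int(share.individual_counts.to_numpy().sum() // 2)
    return {
        "matrix_max_abs_diff": float(
            np.abs(share.individual_counts.to_numpy() - brute).max()
        ),
        "conservation_gap": int(pair_sum + share.excluded_homozygous - n_total),
        "n_doubletons": n_total,
    }


# ---------------------------------------------------------------------------
# deleterious burden

_THREE_POPS = {
    "HI": {"AFR": 0.8, "EUR": 0.15, "NAM": 0.05},
    "MID": {"AFR": 0.5, "EUR": 0.4, "NAM": 0.1},
    "LO": {"AFR": 0.2, "EUR": 0.7, "NAM": 0.1},
}


def _cohort_spec(seed: int, n_per_pop: int, **kw) -> DemographicSpec:
    return DemographicSpec(
        n_individuals=n_per_pop,
        populations=tuple(_THREE_POPS),
        s_f=_THREE_POPS, s_m=_THREE_POPS,
        seed=int(seed), **kw,
    )


def _burden_rhos(spec: DemographicSpec, n_sites: int, percentile: float) -> dict:
    panel = simulate_panel(n_sites, spec)
    cohort = simulate_cohort(spec, panel)
    _, flags = burden_mod.deleterious_threshold(
        panel.table["conservation"].to_numpy(), percentile
    )
    prof = burden_mod.burden_profiles(
        cohort.genotypes, flags, panel.table, cohort.true_global_auto["q_AFR"]
    )
    out = {}
    for comp in ("het", "homder", "derived"):
        out[comp] = burden_mod.burden_ancestry_correlation(prof, comp)
    identity_ok = bool(
        (prof["n_derived"] == prof["n_het"] + 2 * prof["n_homder"]).all()
    )
    return {"rhos": out, "identity_ok": identity_ok}


def burden_pattern_study(
    seed: int, n_reps: int = 10, n_individuals: int = 200, n_sites: int = 50_000,
    percentile: float = 98.0,
) -> dict:
    """Out-of-Africa load cancellation under a European bottleneck + selection.

    Per replicate the drift realisation adds noise of the same order as the
    target correlations, so the pattern is summarised by the replicate mean
    and a Stouffer-combined p-value per component.
    """
    rows = {"het": [], "homder": [], "derived": []}
    identity_all = True
    for s in _seeds(seed, n_reps):
        spec = _cohort_spec(
            s, n_individuals // len(_THREE_POPS) + 1,
            bottleneck_F={"AFR": 0.0, "EUR": 0.1, "NAM": 0.15}, sel_strength=0.2,
        )
        res = _burden_rhos(spec, n_sites, percentile)
        identity_all &= res["identity_ok"]
        for comp in rows:
            rows[comp].append(res["rhos"][comp])
    out = {"identity_ok": identity_all, "n_reps": n_reps}
    for comp, vals in rows.items():
        rhos = np.array([v[0] for v in vals])
        ps = np.array([v[1] for v in vals])
        z = stats.norm.isf(np.clip(ps, 1e-300, 1) / 2) * np.sign(rhos)
        stouffer_z = float(z.sum() / np.sqrt(len(z)))
        out[comp] = {
            "mean_rho": float(rhos.mean()),
            "stouffer_z": stouffer_z,
            "stouffer_p": float(2 * stats.norm.sf(abs(stouffer_z))),
        }
    return out


def burden_null_study(
    seed: int, n_reps: int = 100, n_individuals: int = 402, n_sites: int = 8000,
    percentile: float = 98.0,
) -> dict:
    """No bottleneck, no selection: every ancestry correlation must be null."""
    frac_small = {c: 0 for c in ("het", "homder", "derived")}
    frac_ns = {c: 0 for c in ("het", "homder", "derived")}
    for s in _seeds(seed, n_reps):
        spec = _cohort_spec(
            s, n_individuals // len(_THREE_POPS),
            bottleneck_F={"AFR": 0.0, "EUR": 0.0, "NAM": 0.0}, sel_strength=0.0,
        )
        res = _burden_rhos(spec, n_sites, percentile)
        for comp, (rho, p) in res["rhos"].items():
            frac_small[comp] += abs(rho) < 0.1
            frac_ns[comp] += p > 0.05
    return {
        "frac_abs_rho_lt_0.1": {c: v / n_reps for c, v in frac_small.items()},
        "frac_p_gt_0.05": {c: v / n_reps for c, v in frac_ns.items()},
        "n_reps": n_reps,
    }


def stratified_sign_study(
    seed: int, n_reps: int = 50, n_individuals: int = 100, n_sites: int = 50_000,
    percentile: float = 98.0,
) -> dict:
    """Stronger coding selection on the African panel lowers the AFR:AFR
    coding deleterious proportion; count replicates with the right sign and
    Mann-Whitney p < 0.05."""
    hits = 0
    for s in _seeds(seed, n_reps):
        spec = DemographicSpec(
            n_individuals=n_individuals,
            s_f={"AFR": 0.65, "EUR": 0.3, "NAM": 0.05},
            s_m={"AFR": 0.65, "EUR": 0.3, "NAM": 0.05},
            sel_strength=0.2, sel_coding_afr=0.3, coding_fraction=0.10,
            seed=int(s),
        )
        panel = simulate_panel(n_sites, spec)
        cohort = simulate_cohort(spec, panel)
        _, flags = burden_mod.deleterious_threshold(
            panel.table["conservation"].to_numpy(), percentile
        )
        df, mw = burden_mod.stratified_proportions(
            cohort.genotypes, flags, cohort.true_local, panel.table, cls="coding"
        )
        sign = np.nanmean(df["prop_afr_bg"]) < np.nanmean(df["prop_eur_bg"])
        hits += bool(sign and mw.pvalue < 0.05)
    return {"success_rate": hits / n_reps, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# sex bias

def _truth_profiles(spec: DemographicSpec, panel):
    cohort = simulate_cohort(spec, panel)
    fem = cohort.sex == "female"
    return cohort.true_global_auto[fem], cohort.true_global_x[fem]


def sexbias_calibration_study(
    seed: int, n_reps: int = 1000, n_females: int = 100, alpha: float = 0.05
) -> dict:
    """Type-I error of the paired t-test under equal female/male contributions."""
    base = dict(n_individuals=n_females, female_fraction=1.0, missing_rate=0.0)
    spec0 = DemographicSpec(**base, seed=int(seed))
    panel = simulate_panel(60, spec0)
    rej = 0
    for s in _seeds(seed, n_reps):
        qa, qx = _truth_profiles(DemographicSpec(**base, seed=int(s)), panel)
        res = compare_x_autosome(qa, qx, m_tests=1).set_index("component")
        rej += int(res.loc["AFR", "pvalue"] < alpha)
    return {"type1_rate": rej / n_reps, "n_reps": n_reps, "alpha": alpha}


def sexbias_power_study(
    seed: int, n_reps: int = 100, n_females: int = 100
) -> dict:
    """Power to flag a female-biased African contribution (s_f=0.8, s_m=0.4)."""
    base = dict(
        n_individuals=n_females, female_fraction=1.0, missing_rate=0.0,
        s_f={"AFR": 0.8, "EUR": 0.2, "NAM": 0.0},
        s_m={"AFR": 0.4, "EUR": 0.6, "NAM": 0.0},
    )
    panel = simulate_panel(60, DemographicSpec(**base, seed=int(seed)))
    calls = 0
    mean_x, mean_auto = [], []
    for s in _seeds(seed, n_reps):
        qa, qx = _truth_profiles(DemographicSpec(**base, seed=int(s)), panel)
        res = compare_x_autosome(qa, qx).set_index("component")
        calls += int(res.loc["AFR", "direction"] == "female-biased")
        mean_x.append(qx["q_AFR"].mean())
        mean_auto.append(qa["q_AFR"].mean())
    return {
        "female_biased_call_rate": calls / n_reps,
        "mean_q_afr_x": float(np.mean(mean_x)),
        "mean_q_afr_auto": float(np.mean(mean_auto)),
        "expected_x": 2 / 3,
        "expected_auto": 0.6,
        "n_reps": n_reps,
    }


def estimator_accuracy_study(
    seed: int, n_individuals: int = 60, n_sites: int = 10_000
) -> dict:
    """EM accuracy, label equivariance and log-likelihood monotonicity."""
    rng = np.random.default_rng(seed)
    panel = differentiated_panel(n_sites, seed=rng)
    q_true = rng.dirichlet((2, 2, 1), size=n_individuals)
    lac = simulate_local_ancestry(panel, q_true, g=1e7, seed=rng)
    gm = genotypes_given_ancestry(lac, panel, seed=rng)
    q_hat, info = estimate_q_supervised(gm, panel.freqs)
    rmse = float(np.sqrt(((q_hat.to_numpy() - q_true) ** 2).mean()))

    swapped, _ = estimate_q_supervised(gm, panel.freqs[[1, 0, 2]])
    equiv = float(
        np.abs(
            q_hat[["q_AFR", "q_EUR", "q_NAM"]].to_numpy()
            - swapped[["q_EUR", "q_AFR", "q_NAM"]].to_numpy()
        ).max()
    )
    monotone = bool(np.all(np.diff(info.loglik_trace) >= -1e-9))
    simplex_dev = float(np.abs(q_hat.to_numpy().sum(axis=1) - 1).max())
    return {
        "rmse": rmse,
        "label_equivariance_max_diff": equiv,
        "loglik_monotone": monotone,
        "simplex_max_dev": simplex_dev,
        "n_sites": n_sites,
    }
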