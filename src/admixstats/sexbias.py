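"""Supervised admixture-proportion estimation and the X-vs-autosome contrast.

Ancestry proportions q are estimated per individual by maximum likelihood
under the binomial admixture model: each allele copy descends from ancestry k
with probability q_k and is then derived with probability f_ks, the fixed
reference-panel frequency. The EM update is the classical supervised-ADMIXTURE
recursion on the simplex; the log-likelihood is non-decreasing at every step.

Sex-biased gene flow leaves a footprint in the X-vs-autosome comparison:
because mothers transmit an X to all children and fathers only to daughters,
the equilibrium X expectation per ancestry is (2 s_f + s_m)/3 against the
autosomal (s_f + s_m)/2. A paired t-test on the per-female difference
(q_X - q_auto), Bonferroni-corrected, detects the bias; X > autosome flags a
female-biased contribution of that ancestry, X < autosome a male-biased one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ANCESTRIES, GenotypeMatrix

__all__ = [
    "estimate_q_supervised",
    "compare_x_autosome",
    "bias_report",
    "EMInfo",
]

_F_EPS = 1e-6


@dataclass
class EMInfo:
    n_iter: int
    loglik_trace: np.ndarray       # total log-likelihood per iteration
    converged: bool


def estimate_q_supervised(
    gm: GenotypeMatrix,
    panel_freqs: np.ndarray,
    site_mask: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    init: np.ndarray | None = None,
) -> tuple[pd.DataFrame, EMInfo]:
    """Maximum-likelihood ancestry proportions per individual, by EM.

    ``panel_freqs`` is (3, n_sites) in AFR/EUR/NAM order. All individuals are
    updated jointly (vectorised EM); convergence when the total log-likelihood
    improves by less than ``tol``. Initialisation is the simplex barycentre.
    Raises if the panel carries no frequency differentiation (non-identifiable).
    """
    F = np.asarray(panel_freqs, dtype=float)
    if F.shape != (3, gm.n_sites):
        raise ValueError(f"panel_freqs must be (3, {gm.n_sites})")
    if site_mask is not None:
        site_mask = np.asarray(site_mask, dtype=bool)
        gm = gm.subset_sites(site_mask)
        F = F[:, site_mask]
    if np.max(np.ptp(F, axis=0)) < 1e-9:
        raise ValueError(
            "reference frequencies are identical across ancestries at every "
            "site: ancestry proportions are not identifiable"
        )
    F = np.clip(F, _F_EPS, 1.0 - _F_EPS)

    d = gm.derived_copies.astype(float)          # derived copies (hemi -> 0/1)
    c = gm.ploidy.astype(float)                  # called copies per entry
    d[d < 0] = 0.0
    n, S = d.shape
    tot_copies = c.sum(axis=1)
    if np.any(tot_copies == 0):
        raise ValueError("individual with no called genotypes")

    Q = np.full((n, 3), 1.0 / 3.0) if init is None else np.array(init, dtype=float)
    ll_i = np.full(n, -np.inf)                    # per-individual log-likelihood
    active = np.arange(n)                         # individuals still iterating
    ll_trace = []
    for it in range(max_iter):
        Qa, da, ca = Q[active], d[active], c[active]
        P = np.clip(Qa @ F, 1e-12, 1.0 - 1e-12)   # (n_active, S)
        ll_new = np.sum(da * np.log(P) + (ca - da) * np.log1p(-P), axis=1)
        done = (ll_new - ll_i[active]) < tol
        ll_i[active] = ll_new
        ll_trace.append(float(ll_i.sum()))
        if it > 0 and done.any():
            if done.all():
                active = active[:0]
                break
            keep = ~done
            active, Qa, da, ca, P = active[keep], Qa[keep], da[keep], ca[keep], P[keep]
        # E-step responsibilities folded into the M-step update:
        # r_derived[k] = q_k f_k / P ; r_ancestral[k] = q_k (1-f_k) / (1-P)
        num = np.empty_like(Qa)
        for k in range(3):
            num[:, k] = Qa[:, k] * (
                (da / P) @ F[k] + ((ca - da) / (1.0 - P)) @ (1.0 - F[k])
            )
        Qa = np.clip(num / tot_copies[active, None], 0.0, None)
        Q[active] = Qa / Qa.sum(axis=1, keepdims=True)
    converged = active.size == 0

    profile = pd.DataFrame(Q, index=gm.individuals.index,
                           columns=[f"q_{k}" for k in ANCESTRIES])
    return profile, EMInfo(len(ll_trace), np.asarray(ll_trace), converged)


def compare_x_autosome(
    profiles_auto: pd.DataFrame,
    profiles_x: pd.DataFrame,
    m_tests: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t-test of X vs autosomal ancestry proportions, per component.

    Callers should pass female profiles only (diploid X against diploid
    autosomes). Returns one row per ancestry with the mean paired difference
    (X - autosome), t, df, raw and Bonferroni-adjusted p, and the direction
    label. ``m_tests`` defaults to the number of components tested here.
    """
    common = profiles_auto.index.intersection(profiles_x.index)
    if len(common) < 2:
        raise ValueError("need at least 2 individuals with both profiles")
    qa = profiles_auto.loc[common]
    qx = profiles_x.loc[common]
    m = m_tests if m_tests is not None else len(ANCESTRIES)

    rows = []
    for k in ANCESTRIES:
        diff = (qx[f"q_{k}"] - qa[f"q_{k}"]).to_numpy(dtype=float)
        mean_diff = float(diff.mean())
        if np.allclose(diff.std(ddof=1), 0.0):
            t = 0.0 if np.allclose(mean_diff, 0.0) else np.inf
            p_raw = 1.0 if t == 0.0 else 0.0
            degenerate = True
        else:
            t, p_raw = stats.ttest_rel(qx[f"q_{k}"], qa[f"q_{k}"])
            degenerate = False
        p_adj = min(1.0, m * float(p_raw))
        if degenerate and t == 0.0:
            direction = "none"
        elif p_adj < alpha:
            direction = "female-biased" if mean_diff > 0 else "male-biased"
        else:
            direction = "none"
        rows.append(
            {
                "component": k,
                "mean_diff": mean_diff,
                "t": float(t),
                "df": len(common) - 1,
                "pvalue": float(p_raw),
                "pvalue_bonferroni": p_adj,
                "direction": direction,
                "n": len(common),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def bias_report(results_by_population: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Long-format sex-bias table across populations."""
    frames = []
    for pop, res in results_by_population.items():
        r = res.copy()
        r.insert(0, "population", pop)
        frames.append(r)
    if not frames:
        return pd.DataFrame(
            columns=["population", "component", "mean_diff", "t", "df",
                     "pvalue", "pvalue_bonferroni", "direction", "n", "degenerate"]
        )
    return pd.concat(frames, ignore_index=True)
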