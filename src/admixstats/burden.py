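"""Deleterious-variant definition and per-individual mutation-load decomposition.

Deleterious sites are those whose conservation score reaches the 99.9th
percentile of the genome-wide empirical distribution (nearest-rank), optionally
intersected with a CADD cutoff of 30 (99.9th percentile) or 20 (99th) as a
robustness filter. Per-individual burden is decomposed into heterozygous and
derived-homozygous components — the decomposition behind the out-of-Africa
load cancellation: individuals with more African ancestry carry more
deleterious heterozygotes, those with more European ancestry more deleterious
derived homozygotes, while total derived deleterious alleles stay nearly flat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, LocalAncestryCodes

__all__ = [
    "deleterious_threshold",
    "robust_filter",
    "burden_profiles",
    "burden_ancestry_correlation",
    "stratified_proportions",
    "score_distribution_compare",
    "MannWhitneyResult",
]

ROBUST_MODES = ("phylop-only", "phylop+cadd30", "phylop+cadd20")
_CADD_CUTOFF = {"phylop+cadd30": 30.0, "phylop+cadd20": 20.0}


@dataclass
class MannWhitneyResult:
    u: float
    pvalue: float
    n1: int
    n2: int


def deleterious_threshold(
    scores: np.ndarray, percentile: float = 99.9, method: str = "nearest-rank"
) -> tuple[float, np.ndarray]:
    """Empirical-percentile cutoff and per-site deleterious flags (score >= cutoff).

    ``nearest-rank`` takes the ceil(q/100 * n)-th order statistic, which is
    deterministic and matches the cutoff-from-the-empirical-distribution
    convention; ``linear`` interpolates like ``np.percentile``.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 1000:
        raise ValueError(f"percentile unstable with {n} < 1000 scored sites")
    if not (0 < percentile < 100):
        raise ValueError("percentile must lie in (0, 100)")
    if method == "nearest-rank":
        # round guard: 99.9/100*n can land epsilon above the exact integer
        rank = int(np.ceil(np.round(percentile / 100.0 * n, 9)))
        cutoff = float(np.sort(scores)[rank - 1])
    elif method == "linear":
        cutoff = float(np.percentile(scores, percentile))
    else:
        raise ValueError(f"unknown percentile method {method!r}")
    flags = scores >= cutoff
    if np.all(scores == scores[0]):
        warnings.warn("all conservation scores identical; every site at the cutoff")
    return cutoff, flags


def robust_filter(
    flags: np.ndarray, cadd: np.ndarray, mode: str = "phylop-only"
) -> tuple[np.ndarray, int]:
    """Intersect conservation flags with a CADD cutoff; returns (flags, n_dropped).

    Sites flagged by conservation but missing a CADD score are dropped from
    the conjunction modes and counted.
    """
    if mode not in ROBUST_MODES:
        raise ValueError(f"mode must be one of {ROBUST_MODES}")
    flags = np.asarray(flags, dtype=bool)
    if mode == "phylop-only":
        return flags.copy(), 0
    cadd = np.asarray(cadd, dtype=float)
    missing = flags & ~np.isfinite(cadd)
    out = flags & np.isfinite(cadd) & (cadd >= _CADD_CUTOFF[mode])
    return out, int(missing.sum())


def burden_profiles(
    gm: GenotypeMatrix,
    flags: np.ndarray,
    annotations: pd.DataFrame,
    q_afr: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-individual deleterious burden, split by zygosity and coding class.

    Counts run over flagged sites with diploid calls (hemizygous male-X
    entries are excluded so n_derived = n_het + 2*n_homder holds exactly).
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != (gm.n_sites,):
        raise ValueError("flags must be one boolean per site")
    coding = annotations["coding"].to_numpy(dtype=bool)
    dos = gm.dosages
    diploid = ~gm.hemizygous & ~gm.missing

    out = {}
    for cls, cls_mask in (
        ("", np.ones(gm.n_sites, dtype=bool)),
        ("coding_", coding),
        ("noncoding_", ~coding),
    ):
        m = (flags & cls_mask)[None, :] & diploid
        het = ((dos == 1) & m).sum(axis=1)
        hom = ((dos == 2) & m).sum(axis=1)
        out[f"{cls}n_het"] = het
        out[f"{cls}n_homder"] = hom
        out[f"{cls}n_derived"] = het + 2 * hom
    prof = pd.DataFrame(out, index=gm.individuals.index)
    if q_afr is not None:
        prof["afr_ancestry"] = np.asarray(q_afr, dtype=float)
    return prof


_COMPONENT_COL = {"het": "n_het", "homder": "n_homder", "derived": "n_derived"}


def burden_ancestry_correlation(
    profiles: pd.DataFrame, component: str = "derived", cls: str = "all"
) -> tuple[float, float]:
    """Spearman correlation of a burden component with African ancestry.

    Average ranks for ties; two-sided p from the t approximation.
    """
    if component not in _COMPONENT_COL:
        raise ValueError(f"component must be one of {tuple(_COMPONENT_COL)}")
    prefix = {"all": "", "coding": "coding_", "noncoding": "noncoding_"}[cls]
    col = prefix + _COMPONENT_COL[component]
    x = profiles[col].to_numpy(dtype=float)
    y = profiles["afr_ancestry"].to_numpy(dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 individuals")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def stratified_proportions(
    gm: GenotypeMatrix,
    flags: np.ndarray,
    lac: LocalAncestryCodes,
    annotations: pd.DataFrame,
    cls: str = "all",
) -> tuple[pd.DataFrame, MannWhitneyResult]:
    """Per-individual deleterious-derived proportion on unambiguous backgrounds.

    Only diplotype codes 3 (AFR:AFR) and 1 (EUR:EUR) enter — the two
    backgrounds where both allele copies are unambiguously from one ancestral
    population. For each individual and background: deleterious derived-allele
    copies divided by all derived-allele copies on that background, optionally
    restricted to coding or non-coding sites. Backgrounds without derived
    alleles are undefined and excluded; the comparison is a two-sided
    Mann-Whitney U (normal approximation with continuity correction) between
    the per-individual AFR:AFR and EUR:EUR proportions.
    """
    lac.aligned_to(gm)
    flags = np.asarray(flags, dtype=bool)
    coding = annotations["coding"].to_numpy(dtype=bool)
    cls_mask = {"all": np.ones(gm.n_sites, dtype=bool),
                "coding": coding, "noncoding": ~coding}[cls]
    copies = np.where(gm.derived_copies > 0, gm.derived_copies, 0).astype(float)
    copies[:, ~cls_mask] = 0.0

    prop = {}
    for name, code in (("AFR", 3), ("EUR", 1)):
        on_bg = lac.codes == code
        tot = np.where(on_bg, copies, 0.0).sum(axis=1)
        dele = np.where(on_bg & flags[None, :], copies, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            prop[name] = np.where(tot > 0, dele / np.maximum(tot, 1), np.nan)

    df = pd.DataFrame(
        {"prop_afr_bg": prop["AFR"], "prop_eur_bg": prop["EUR"]},
        index=gm.individuals.index,
    )
    a = prop["AFR"][np.isfinite(prop["AFR"])]
    b = prop["EUR"][np.isfinite(prop["EUR"])]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("no individuals with derived alleles on a background")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", use_continuity=True,
                              method="asymptotic")
    return df, MannWhitneyResult(float(u), float(p), len(a), len(b))


def score_distribution_compare(
    flags: np.ndarray, annotations: pd.DataFrame
) -> dict:
    """Median conservation score of coding vs non-coding deleterious sites."""
    flags = np.asarray(flags, dtype=bool)
    coding = annotations["coding"].to_numpy(dtype=bool)
    scores = annotations["conservation"].to_numpy(dtype=float)
    a = scores[flags & coding]
    b = scores[flags & ~coding]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both coding and non-coding flagged sites are required")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return {
        "median_coding": float(np.median(a)),
        "median_noncoding": float(np.median(b)),
        "u": float(u),
        "pvalue": float(p),
        "n_coding": len(a),
        "n_noncoding": len(b),
    }
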