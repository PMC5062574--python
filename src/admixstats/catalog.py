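"""Allele counting, MAF classification, polarization, novelty accounting and
site-frequency-spectrum construction.

All derived-allele analyses (SFS, doubletons, burden) consume only sites whose
ancestral-state call is confident; low-confidence sites are retained for
MAF-only accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, LocalAncestryCodes

__all__ = [
    "FREQUENCY_CLASSES",
    "allele_counts",
    "classify_maf",
    "polarized_mask",
    "novelty_accounting",
    "novelty_by_background",
    "build_sfs",
    "SFS",
    "PairedTestResult",
]

#: MAF classes: singletons, MAF<1%, 1%<=MAF<=5%, MAF>5% (exhaustive for
#: segregating sites; boundaries inclusive at both ends of the middle class).
FREQUENCY_CLASSES = ("SINGLETON", "RARE_LT1", "LOW_1TO5", "COMMON_GT5")


@dataclass
class SFS:
    """Site-frequency spectrum: xi[i-1] sites with derived count i (i=1..N-1).

    Counts may be fractional (expected spectra, projected spectra).
    """

    n_chromosomes: int
    xi: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        if self.n_chromosomes < 2:
            raise ValueError("an SFS needs at least 2 chromosomes")
        if self.xi.shape != (self.n_chromosomes - 1,):
            raise ValueError(
                f"xi must have length N-1={self.n_chromosomes - 1}, got {self.xi.shape}"
            )
        if np.any(self.xi < 0):
            raise ValueError("SFS counts must be non-negative")

    @property
    def segregating(self) -> float:
        return float(self.xi.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"derived_count": np.arange(1, self.n_chromosomes), "xi": self.xi,
             "label": self.label}
        )


@dataclass
class PairedTestResult:
    statistic: float
    df: int
    pvalue: float
    n_used: int
    n_excluded: int


def allele_counts(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site derived count, called chromosomes, frequency, MAF, missingness.

    Missing calls are excluded from denominators; male-X entries contribute a
    single chromosome. ``missingness`` is the fraction of individuals without
    a call. Sites with zero called chromosomes are flagged non-segregating.
    """
    if gm.n_sites == 0 or gm.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    copies = gm.derived_copies
    called = gm.ploidy.sum(axis=0)
    derived = np.where(copies > 0, copies, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, derived / np.maximum(called, 1), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    missingness = gm.missing.mean(axis=0)
    out = gm.sites[["site_id", "chrom"]].copy()
    out["derived"] = derived
    out["called"] = called
    out["freq"] = freq
    out["maf"] = maf
    out["missingness"] = missingness
    out["segregating"] = (derived > 0) & (derived < called)
    return out


def classify_maf(derived, maf, singleton_mode: str = "allele", carriers=None):
    """Assign each segregating site to a MAF class.

    SINGLETON is derived-allele-count exactly 1 by default; with
    ``singleton_mode='carrier'`` a single carrier (possibly homozygous, count
    2) also qualifies. Otherwise RARE_LT1 if MAF<1%, LOW_1TO5 if
    1%<=MAF<=5% (both boundaries inclusive), COMMON_GT5 if MAF>5%.
    """
    derived = np.asarray(derived)
    maf = np.asarray(maf, dtype=float)
    if np.any((derived <= 0) | (maf <= 0) | ~np.isfinite(maf)):
        raise ValueError("classify_maf is defined for segregating sites only")
    if singleton_mode == "allele":
        singleton = derived == 1
    elif singleton_mode == "carrier":
        if carriers is None:
            raise ValueError("carrier mode needs per-site carrier counts")
        singleton = np.asarray(carriers) == 1
    else:
        raise ValueError(f"unknown singleton_mode {singleton_mode!r}")
    out = np.where(
        singleton,
        "SINGLETON",
        np.where(maf < 0.01, "RARE_LT1", np.where(maf <= 0.05, "LOW_1TO5", "COMMON_GT5")),
    )
    return pd.Categorical(out, categories=list(FREQUENCY_CLASSES))


def polarized_mask(annotations: pd.DataFrame) -> np.ndarray:
    """Sites usable for derived-allele analyses: confident ancestral call."""
    if "ancestral_confident" not in annotations.columns:
        raise ValueError("annotations need an 'ancestral_confident' column")
    return annotations["ancestral_confident"].to_numpy(dtype=bool)


def novelty_accounting(
    gm: GenotypeMatrix, annotations: pd.DataFrame, singleton_mode: str = "allele"
) -> pd.DataFrame:
    """Cross-tabulate novelty (known/novel) against MAF class.

    Returns a 4x2 table (rows = MAF classes, columns known/novel) over
    segregating sites; margins conserve the segregating-site total.
    """
    counts = allele_counts(gm)
    seg = counts["segregating"].to_numpy()
    carriers = (gm.derived_copies > 0).sum(axis=0)
    cls = classify_maf(
        counts.loc[seg, "derived"], counts.loc[seg, "maf"],
        singleton_mode=singleton_mode, carriers=carriers[seg],
    )
    known = annotations["known"].to_numpy(dtype=bool)[seg]
    tab = pd.crosstab(
        pd.Categorical(cls, categories=list(FREQUENCY_CLASSES)),
        pd.Categorical(np.where(known, "known", "novel"), categories=["known", "novel"]),
        dropna=False,
    )
    tab.index.name = "maf_class"
    return tab


def novelty_by_background(
    gm: GenotypeMatrix,
    annotations: pd.DataFrame,
    lac: LocalAncestryCodes,
    background_codes: tuple[int, int] = (3, 1),
) -> tuple[pd.DataFrame, PairedTestResult]:
    """Per-individual novel-variant rate on homozygous-ancestry backgrounds.

    For each individual, among derived-allele copies falling on code-3
    (AFR:AFR) versus code-1 (EUR:EUR) segments, the fraction that is novel;
    the two rates are compared across individuals with a paired t-test.
    Individuals lacking derived alleles on either background are excluded
    pairwise and counted.
    """
    lac.aligned_to(gm)
    confident = polarized_mask(annotations)
    novel = ~annotations["known"].to_numpy(dtype=bool)
    copies = np.where(gm.derived_copies > 0, gm.derived_copies, 0).astype(float)
    copies[:, ~confident] = 0.0

    rates = {}
    for code in background_codes:
        on_bg = (lac.codes == code) & (copies > 0)
        tot = np.where(on_bg, copies, 0.0).sum(axis=1)
        nov = np.where(on_bg & novel[None, :], copies, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            rates[code] = np.where(tot > 0, nov / np.maximum(tot, 1), np.nan)

    a, b = (rates[c] for c in background_codes)
    df = pd.DataFrame(
        {f"rate_code{background_codes[0]}": a, f"rate_code{background_codes[1]}": b},
        index=gm.individuals.index,
    )
    ok = np.isfinite(a) & np.isfinite(b)
    n_used, n_excl = int(ok.sum()), int((~ok).sum())
    if n_used < 2:
        raise ValueError("fewer than 2 individuals with both backgrounds")
    diff = a[ok] - b[ok]
    if np.allclose(diff.std(ddof=1), 0.0):
        t, p = (0.0, 1.0) if np.allclose(diff.mean(), 0.0) else (np.inf, 0.0)
    else:
        t, p = stats.ttest_rel(a[ok], b[ok])
    return df, PairedTestResult(float(t), n_used - 1, float(p), n_used, n_excl)


def build_sfs(
    gm: GenotypeMatrix,
    annotations: pd.DataFrame | None = None,
    site_mask: np.ndarray | None = None,
    chromosomes: str = "autosomes",
    label: str = "",
    n_project: int | None = None,
) -> SFS:
    """Tally the derived-allele SFS over polarized segregating sites.

    By default only autosomal sites enter (the X has a different chromosome
    count). Sites with missing calls are either restricted to complete-call
    sites (default) or hypergeometrically projected down to ``n_project``
    chromosomes, the standard treatment for missing data in spectra.
    """
    keep = np.ones(gm.n_sites, dtype=bool)
    if annotations is not None:
        keep &= polarized_mask(annotations)
    if site_mask is not None:
        keep &= np.asarray(site_mask, dtype=bool)
    if chromosomes == "autosomes":
        keep &= ~gm.is_x
    elif chromosomes != "all":
        keep &= gm.sites["chrom"].to_numpy() == chromosomes

    counts = allele_counts(gm)
    derived = counts["derived"].to_numpy()[keep]
    called = counts["called"].to_numpy()[keep]
    if len(called) == 0:
        raise ValueError("no sites left for the SFS after filtering")
    N = int(called.max())

    if n_project is None:
        full = called == N
        seg = full & (derived > 0) & (derived < N)
        xi = np.bincount(derived[seg], minlength=N)[1:N].astype(float)
        return SFS(N, xi, label=label)

    if n_project < 2 or n_project > N:
        raise ValueError("n_project must lie in [2, max called]")
    n = n_project
    xi = np.zeros(n - 1)
    seg = (derived > 0) & (called >= n)
    for c in np.unique(called[seg]):
        sel = seg & (called == c)
        for i in np.unique(derived[sel]):
            w = int((derived[sel] == i).sum())
            j = np.arange(1, n)
            pmf = stats.hypergeom.pmf(j, c, i, n)
            xi += w * pmf
    return SFS(n, xi, label=label)
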