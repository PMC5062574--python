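"""Core in-memory containers shared across the pipeline.

The pipeline models three-way admixed genomes (African, European, Native
American ancestry). Local ancestry at a site is summarised by an unordered
diplotype code in {0..6}: 0 marks unknown ancestry and 1..6 enumerate the six
unordered pairs of the three ancestries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical ancestry order used everywhere (arrays indexed AFR=0, EUR=1, NAM=2).
ANCESTRIES: tuple[str, ...] = ("AFR", "EUR", "NAM")

AFR, EUR, NAM = 0, 1, 2

#: Diplotype code convention for unordered ancestry pairs.
DIPLOTYPE_LABELS: dict[int, str] = {
    0: "unknown",
    1: "EUR:EUR",
    2: "EUR:AFR",
    3: "AFR:AFR",
    4: "EUR:NAM",
    5: "AFR:NAM",
    6: "NAM:NAM",
}

# 3x3 lookup: ancestry-index pair -> diplotype code (symmetric).
_CODE_TABLE = np.zeros((3, 3), dtype=np.int8)
for (_a, _b), _code in {
    (EUR, EUR): 1,
    (EUR, AFR): 2,
    (AFR, AFR): 3,
    (EUR, NAM): 4,
    (AFR, NAM): 5,
    (NAM, NAM): 6,
}.items():
    _CODE_TABLE[_a, _b] = _code
    _CODE_TABLE[_b, _a] = _code

#: code -> (ancestry index, ancestry index) for codes 1..6; code 0 has no pair.
CODE_TO_PAIR: dict[int, tuple[int, int]] = {
    1: (EUR, EUR),
    2: (EUR, AFR),
    3: (AFR, AFR),
    4: (EUR, NAM),
    5: (AFR, NAM),
    6: (NAM, NAM),
}

X_CHROM = "X"
MISSING = -1


def diplotype_code(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Combine two haplotype ancestry labels (indices 0..2) into codes 1..6."""
    return _CODE_TABLE[np.asarray(a), np.asarray(b)]


@dataclass
class AncestralPanel:
    """Per-site ancestry-specific derived-allele frequencies plus annotations.

    ``table`` columns: site_id, chrom, pos_cm, pos_bp, freq_AFR, freq_EUR,
    freq_NAM, conservation, cadd, coding, ancestral_confident, known.
    Within each chromosome ``pos_cm`` is strictly increasing.
    """

    table: pd.DataFrame

    REQUIRED = (
        "site_id", "chrom", "pos_cm", "pos_bp",
        "freq_AFR", "freq_EUR", "freq_NAM",
        "conservation", "cadd", "coding", "ancestral_confident", "known",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"panel table missing columns: {missing}")
        f = self.freqs
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("panel frequencies must lie in [0, 1]")
        for _, grp in self.table.groupby("chrom", sort=False):
            d = np.diff(grp["pos_cm"].to_numpy())
            if np.any(d <= 0):
                raise ValueError("pos_cm must be strictly increasing within a chromosome")

    @property
    def n_sites(self) -> int:
        return len(self.table)

    @property
    def freqs(self) -> np.ndarray:
        """(3, n_sites) derived-allele frequency array in ANCESTRIES order."""
        return self.table[[f"freq_{k}" for k in ANCESTRIES]].to_numpy().T

    @property
    def chroms(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def is_x(self) -> np.ndarray:
        return self.chroms == X_CHROM


@dataclass
class GenotypeMatrix:
    """Diploid derived-allele dosages for individuals x sites.

    ``dosages`` holds 0/1/2 derived copies (-1 = missing). Male X entries are
    hemizygous and encoded 0/2; :attr:`hemizygous` marks them and
    :attr:`derived_copies` converts back to 0/1 copies on a single chromosome.
    """

    dosages: np.ndarray                 # (n_individuals, n_sites) int8
    individuals: pd.DataFrame           # index: individual id; cols population, sex
    sites: pd.DataFrame                 # cols: site_id, chrom, pos_bp

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.individuals), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.individuals)} individuals x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.dosages, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {-1, 0, 1, 2}")
        if self.hemizygous.any():
            hemi_dos = self.dosages[self.hemizygous]
            if np.any(hemi_dos == 1):
                raise ValueError("hemizygous calls must be encoded 0/2, not 1")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def is_x(self) -> np.ndarray:
        return (self.sites["chrom"].to_numpy() == X_CHROM)

    @property
    def is_male(self) -> np.ndarray:
        return (self.individuals["sex"].to_numpy() == "male")

    @property
    def hemizygous(self) -> np.ndarray:
        """(n_individuals, n_sites) mask of male-X entries."""
        return self.is_male[:, None] & self.is_x[None, :]

    @property
    def missing(self) -> np.ndarray:
        return self.dosages == MISSING

    @property
    def ploidy(self) -> np.ndarray:
        """Called chromosome count per entry (0 where missing)."""
        p = np.where(self.hemizygous, 1, 2)
        return np.where(self.missing, 0, p)

    @property
    def derived_copies(self) -> np.ndarray:
        """Derived allele copies per entry (hemizygous 0/2 -> 0/1); -1 missing."""
        d = self.dosages.astype(np.int16)
        d = np.where(self.hemizygous & (d == 2), 1, d)
        return d

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.dosages[:, mask],
            self.individuals,
            self.sites.loc[mask].reset_index(drop=True),
        )

    def subset_individuals(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.dosages[mask, :],
            self.individuals.loc[mask],
            self.sites,
        )


@dataclass
class LocalAncestryCodes:
    """Per-(individual, site) unordered diplotype ancestry codes in {0..6}."""

    codes: np.ndarray                   # (n_individuals, n_sites) int8
    site_ids: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.site_ids = np.asarray(self.site_ids)
        self.individual_ids = np.asarray(self.individual_ids)
        if self.codes.shape != (len(self.individual_ids), len(self.site_ids)):
            raise ValueError("code matrix shape inconsistent with labels")
        if self.codes.min(initial=0) < 0 or self.codes.max(initial=0) > 6:
            raise ValueError("diplotype codes must lie in {0..6}")

    def aligned_to(self, gm: GenotypeMatrix) -> "LocalAncestryCodes":
        """Check site/individual alignment against a genotype matrix."""
        if not np.array_equal(self.site_ids, gm.sites["site_id"].to_numpy()):
            raise ValueError("local-ancestry sites do not match genotype sites")
        if not np.array_equal(self.individual_ids, gm.individuals.index.to_numpy()):
            raise ValueError("local-ancestry individuals do not match genotype individuals")
        return self


@dataclass
class SimulatedCohort:
    """A simulated admixed cohort with full ground truth."""

    genotypes: GenotypeMatrix
    true_local: LocalAncestryCodes
    true_global_auto: pd.DataFrame      # index individual; cols q_AFR, q_EUR, q_NAM
    true_global_x: pd.DataFrame
    sex: pd.Series
    panel: AncestralPanel
    populations: pd.Series = field(default=None)

    @property
    def females(self) -> np.ndarray:
        return (self.sex.to_numpy() == "female")
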