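"""Derived-doubleton identification and the pairwise sharing statistic.

A doubleton is a site carrying exactly two derived-allele copies in the
sample. Two heterozygous carriers make a pair-type doubleton (evidence of
recent shared ancestry between the two individuals); a single homozygous
carrier is self-type and enters no pair. Population-level sharing divides the
summed pair counts by the number of possible pairs — n(n-1)/2 within a
population, n1*n2 between populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import allele_counts, polarized_mask
from .containers import GenotypeMatrix

__all__ = ["find_doubletons", "sharing_matrix", "SharingMatrix"]


@dataclass
class SharingMatrix:
    individual_counts: pd.DataFrame     # symmetric, zero diagonal
    pop_normalized: pd.DataFrame        # population pair -> mean sharing per pair
    excluded_homozygous: int            # self-type doubletons (no pair defined)
    n_pair_doubletons: int

    @property
    def total_doubletons(self) -> int:
        return self.n_pair_doubletons + self.excluded_homozygous


def find_doubletons(
    gm: GenotypeMatrix,
    annotations: pd.DataFrame | None = None,
    missingness_max: float = 0.05,
) -> pd.DataFrame:
    """Sites with exactly two derived copies and missingness <= the threshold.

    The 5% missingness bound is inclusive. Returns one row per doubleton with
    its type ('pair' or 'self') and, for pair-type, the two carrier ids.
    """
    counts = allele_counts(gm)
    keep = (counts["derived"].to_numpy() == 2) & (
        counts["missingness"].to_numpy() <= missingness_max + 1e-12
    )
    if annotations is not None:
        keep &= polarized_mask(annotations)

    copies = gm.derived_copies
    idx = np.flatnonzero(keep)
    ids = gm.individuals.index.to_numpy()
    rows = []
    for s in idx:
        col = copies[:, s]
        hom = np.flatnonzero(col == 2)
        het = np.flatnonzero(col == 1)
        if len(hom) == 1:
            rows.append((gm.sites["site_id"].iloc[s], "self", ids[hom[0]], None))
        else:  # two single-copy carriers (het, or hemizygous on X)
            rows.append((gm.sites["site_id"].iloc[s], "pair", ids[het[0]], ids[het[1]]))
    return pd.DataFrame(rows, columns=["site_id", "type", "carrier1", "carrier2"])


def sharing_matrix(
    gm: GenotypeMatrix,
    doubletons: pd.DataFrame,
    populations: pd.Series | None = None,
) -> SharingMatrix:
    """Count doubletons shared by each individual pair and normalize by population.

    Within-population cells for populations of size 1 are undefined (NaN).
    """
    ids = gm.individuals.index.to_numpy()
    n = len(ids)
    pos = {v: i for i, v in enumerate(ids)}
    mat = np.zeros((n, n), dtype=np.int64)
    pair = doubletons[doubletons["type"] == "pair"]
    for c1, c2 in zip(pair["carrier1"], pair["carrier2"]):
        i, j = pos[c1], pos[c2]
        mat[i, j] += 1
        mat[j, i] += 1
    individual_counts = pd.DataFrame(mat, index=ids, columns=ids)

    if populations is None:
        populations = gm.individuals["population"]
    pops = pd.Series(populations).reindex(ids)
    labels = pops.unique()
    norm = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for a in labels:
        ia = np.flatnonzero((pops == a).to_numpy())
        for b in labels:
            ib = np.flatnonzero((pops == b).to_numpy())
            if a == b:
                n_pairs = len(ia) * (len(ia) - 1) / 2
                total = mat[np.ix_(ia, ia)].sum() / 2
            else:
                n_pairs = len(ia) * len(ib)
                total = mat[np.ix_(ia, ib)].sum()
            norm.loc[a, b] = total / n_pairs if n_pairs > 0 else np.nan

    n_self = int((doubletons["type"] == "self").sum())
    return SharingMatrix(individual_counts, norm, n_self, len(pair))
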