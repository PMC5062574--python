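"""Synthetic admixed-cohort simulator with known truth.

The generator emulates the population-genetic structure the downstream
analyses exploit:

* ancestry-specific allele-frequency spectra: the African panel draws derived
  frequencies from a rare-skewed Beta; European and Native American panels are
  derived from it through a Balding–Nichols drift transform (same mean,
  variance inflated by a per-ancestry drift coefficient F), so bottlenecked
  panels segregate fewer sites but fix more derived alleles;
* purifying selection as a frequency reduction that grows with a site's
  conservation score, with coding sites drawing conservation from a
  heavier-tailed mixture;
* known/novel status whose probability rises with global frequency and drops
  for sites segregating only on the African panel;
* Markov local-ancestry tracts along a genetic map (switch intensity g per
  Morgan after g generations of single-pulse admixture);
* sex-specific ancestral contributions, giving autosomal expectation
  (s_f + s_m)/2 and X expectation (2 s_f + s_m)/3 per ancestry.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    ANCESTRIES,
    AncestralPanel,
    GenotypeMatrix,
    LocalAncestryCodes,
    SimulatedCohort,
    X_CHROM,
    diplotype_code,
)

__all__ = [
    "DemographicSpec",
    "simulate_panel",
    "simulate_local_ancestry",
    "simulate_cohort",
    "differentiated_panel",
    "genotypes_given_ancestry",
]

# Frequencies this close to the boundary are clamped to lost/fixed, giving
# bottlenecked panels a genuine excess of p=0 and p=1 sites.
_LOSS_EPS = 1e-3
_FIX_EPS = 1e-3


def _as_simplex(x, name: str) -> np.ndarray:
    v = np.asarray(
        [x[k] for k in ANCESTRIES] if isinstance(x, dict) else x, dtype=float
    )
    if v.shape != (3,) or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-8:
        raise ValueError(f"{name} must be a simplex over {ANCESTRIES}, got {x}")
    return v


@dataclass
class DemographicSpec:
    """Parameters of the single-pulse admixture history and the genome model.

    ``s_f`` / ``s_m`` are the female and male ancestral contribution fractions
    (each a simplex over AFR/EUR/NAM); they may be a single simplex applied to
    every population or a ``{population: simplex}`` mapping. ``bottleneck_F``
    is the Balding–Nichols drift coefficient per ancestry, ``sel_strength``
    scales the conservation-linked frequency reduction and ``sel_coding_afr``
    adds African-panel-specific selection at coding sites (used to emulate
    ancestry-differential constraint).
    """

    n_individuals: int = 200
    populations: tuple[str, ...] = ("POP1",)
    g: int = 8
    s_f: object = field(default_factory=lambda: {"AFR": 0.8, "EUR": 0.15, "NAM": 0.05})
    s_m: object = field(default_factory=lambda: {"AFR": 0.8, "EUR": 0.15, "NAM": 0.05})
    bottleneck_F: dict = field(
        default_factory=lambda: {"AFR": 0.0, "EUR": 0.10, "NAM": 0.15}
    )
    sel_strength: float = 0.3
    sel_coding_afr: float = 0.0
    ancestry_dispersion: float = 30.0
    afr_sfs_alpha: float = 0.2
    afr_sfs_beta: float = 1.8
    coding_fraction: float = 0.02
    x_fraction: float = 0.10
    n_autosomes: int = 2
    spacing_cm: float = 0.05
    missing_rate: float = 0.005
    unknown_rate: float = 0.0
    female_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g < 1:
            raise ValueError("g must be a positive integer (generations since admixture)")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.afr_sfs_alpha <= 0 or self.afr_sfs_beta <= 0:
            raise ValueError("Beta parameters must be positive")
        for k in ANCESTRIES:
            F = self.bottleneck_F.get(k, 0.0)
            if not (0.0 <= F < 1.0):
                raise ValueError(f"bottleneck_F[{k}] must lie in [0, 1)")
        if self.sel_strength < 0 or self.sel_coding_afr < 0:
            raise ValueError("selection strengths must be non-negative")
        for r in ("coding_fraction", "x_fraction", "missing_rate",
                  "unknown_rate", "female_fraction"):
            v = getattr(self, r)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{r} must lie in [0, 1]")
        # normalise contribution fractions eagerly so errors surface here
        self._s_by_pop = {}
        for pop in self.populations:
            self._s_by_pop[pop] = (
                _as_simplex(self.s_f[pop] if isinstance(self.s_f, dict)
                            and pop in self.s_f else self.s_f, f"s_f[{pop}]"),
                _as_simplex(self.s_m[pop] if isinstance(self.s_m, dict)
                            and pop in self.s_m else self.s_m, f"s_m[{pop}]"),
            )

    def contributions(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        """(s_f, s_m) simplexes for one population."""
        return self._s_by_pop[population]

    def expected_q(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        """Expected (autosomal, X) ancestry proportions for one population."""
        s_f, s_m = self.contributions(population)
        return (s_f + s_m) / 2.0, (2.0 * s_f + s_m) / 3.0

    def with_(self, **kw) -> "DemographicSpec":
        return replace(self, **kw)


def _child_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one master seed."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode()) % (2**31)])
    return np.random.default_rng(ss)


def _drift(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols drift: Beta with mean p and variance F p(1-p)."""
    if F == 0.0:
        return p.copy()
    out = p.copy()
    inner = (p > 0) & (p < 1)
    c = (1.0 - F) / F
    out[inner] = rng.beta(p[inner] * c, (1.0 - p[inner]) * c)
    return out


def simulate_panel(
    n_sites: int, spec: DemographicSpec, rng: np.random.Generator | None = None
) -> AncestralPanel:
    """Simulate the ancestral reference panel: frequencies plus annotations.

    Sites are laid out on ``spec.n_autosomes`` autosomes plus an X chromosome
    (fraction ``spec.x_fraction``), evenly spaced at ``spec.spacing_cm`` on a
    uniform 1 cM/Mb map.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if rng is None:
        rng = _child_rng(spec.seed, "panel")

    # chromosome layout
    n_x = int(round(spec.x_fraction * n_sites))
    n_auto = n_sites - n_x
    per_auto = np.full(spec.n_autosomes, n_auto // spec.n_autosomes)
    per_auto[: n_auto % spec.n_autosomes] += 1
    chroms, pos_cm = [], []
    for c, k in enumerate(per_auto, start=1):
        chroms += [str(c)] * int(k)
        pos_cm.append(spec.spacing_cm * (np.arange(k) + 1))
    if n_x:
        chroms += [X_CHROM] * n_x
        pos_cm.append(spec.spacing_cm * (np.arange(n_x) + 1))
    pos_cm = np.concatenate(pos_cm) if pos_cm else np.empty(0)
    pos_bp = np.maximum(1, np.round(pos_cm * 1e6).astype(np.int64))  # 1 cM/Mb

    # annotations
    coding = rng.random(n_sites) < spec.coding_fraction
    conservation = rng.normal(0.0, 1.0, n_sites)
    heavy = coding & (rng.random(n_sites) < 0.25)
    conservation[coding] = rng.normal(0.3, 1.0, int(coding.sum()))
    conservation[heavy] = rng.normal(2.0, 1.5, int(heavy.sum()))
    cadd = np.clip(8.0 + 5.0 * conservation + rng.normal(0.0, 3.0, n_sites), 0.0, 60.0)
    ancestral_confident = rng.random(n_sites) < 0.9

    # African frequencies, with selection scaled by conservation
    p_afr = rng.beta(spec.afr_sfs_alpha, spec.afr_sfs_beta, n_sites)
    if spec.sel_strength > 0:
        p_afr = p_afr * np.exp(-spec.sel_strength * np.clip(conservation, 0.0, None))

    # bottleneck transforms (mean-preserving before clamping)
    p_eur = _drift(p_afr, spec.bottleneck_F.get("EUR", 0.0), rng)
    p_nam = _drift(p_afr, spec.bottleneck_F.get("NAM", 0.0), rng)

    # ancestry-differential purifying selection on coding sites (African panel)
    if spec.sel_coding_afr > 0:
        p_afr = np.where(
            coding,
            p_afr * np.exp(-spec.sel_coding_afr * np.clip(conservation, 0.0, None)),
            p_afr,
        )

    freqs = {}
    for name, p in (("AFR", p_afr), ("EUR", p_eur), ("NAM", p_nam)):
        p = np.where(p < _LOSS_EPS, 0.0, p)
        p = np.where(p > 1.0 - _FIX_EPS, 1.0, p)
        freqs[name] = p

    # known/novel: more likely known when globally common, less when AFR-only
    pbar = (freqs["AFR"] + freqs["EUR"] + freqs["NAM"]) / 3.0
    p_known = 0.05 + 0.93 * (1.0 - np.exp(-8.0 * pbar))
    afr_only = (freqs["AFR"] > 0) & (freqs["EUR"] == 0) & (freqs["NAM"] == 0)
    p_known = np.where(afr_only, 0.35 * p_known, p_known)
    known = rng.random(n_sites) < p_known

    table = pd.DataFrame(
        {
            "site_id": np.arange(n_sites),
            "chrom": chroms,
            "pos_cm": pos_cm,
            "pos_bp": pos_bp,
            "freq_AFR": freqs["AFR"],
            "freq_EUR": freqs["EUR"],
            "freq_NAM": freqs["NAM"],
            "conservation": conservation,
            "cadd": cadd,
            "coding": coding,
            "ancestral_confident": ancestral_confident,
            "known": known,
        }
    )
    return AncestralPanel(table)


def differentiated_panel(
    n_sites: int,
    seed: int | np.random.Generator = 0,
    freq_low: float = 0.05,
    freq_high: float = 0.95,
    spacing_cm: float = 0.05,
    chrom: str = "1",
) -> AncestralPanel:
    """Panel with independent uniform frequencies per ancestry.

    Every site is ancestry-informative (typical pairwise frequency difference
    ~0.2-0.3), which is the regime supervised ancestry estimation assumes.
    Annotations are neutral placeholders.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos_cm = spacing_cm * (np.arange(n_sites) + 1)
    table = pd.DataFrame(
        {
            "site_id": np.arange(n_sites),
            "chrom": chrom,
            "pos_cm": pos_cm,
            "pos_bp": np.maximum(1, np.round(pos_cm * 1e6).astype(np.int64)),
            "freq_AFR": rng.uniform(freq_low, freq_high, n_sites),
            "freq_EUR": rng.uniform(freq_low, freq_high, n_sites),
            "freq_NAM": rng.uniform(freq_low, freq_high, n_sites),
            "conservation": rng.normal(0.0, 1.0, n_sites),
            "cadd": rng.uniform(0.0, 40.0, n_sites),
            "coding": np.zeros(n_sites, dtype=bool),
            "ancestral_confident": np.ones(n_sites, dtype=bool),
            "known": np.ones(n_sites, dtype=bool),
        }
    )
    return AncestralPanel(table)


def _haplotype_ancestry(
    pos_cm: np.ndarray, q: np.ndarray, g: float, rng: np.random.Generator
) -> np.ndarray:
    """Markov ancestry along one chromosome for a batch of haplotypes.

    ``q`` is (n_hap, 3). Switch events arrive at intensity g per Morgan; at a
    switch (and at the chromosome start) ancestry is redrawn from q, so tract
    lengths are Exponential with mean 100/g cM and the chain is stationary.
    """
    n_hap = q.shape[0]
    n_sites = pos_cm.shape[0]
    if n_sites == 0:
        return np.empty((n_hap, 0), dtype=np.int8)
    d = np.diff(pos_cm)
    p_switch = 1.0 - np.exp(-g * d / 100.0)
    switch = np.empty((n_hap, n_sites), dtype=bool)
    switch[:, 0] = True
    switch[:, 1:] = rng.random((n_hap, n_sites - 1)) < p_switch[None, :]

    # fresh draw from q at every site; keep the one at the last switch point
    cumq = np.cumsum(q, axis=1)
    u = rng.random((n_hap, n_sites))
    draws = (u[:, :, None] >= cumq[:, None, :2]).sum(axis=2).astype(np.int8)

    idx = np.where(switch, np.arange(n_sites)[None, :], 0)
    np.maximum.accumulate(idx, axis=1, out=idx)
    return np.take_along_axis(draws, idx, axis=1)


def _q_matrix(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.ndim == 1:
        q = q[None, :]
    if q.shape[1] != 3 or np.any(q < 0) or np.any(np.abs(q.sum(axis=1) - 1) > 1e-6):
        raise ValueError("q must be one simplex over 3 ancestries per individual")
    return q


def simulate_local_ancestry(
    panel: AncestralPanel,
    q,
    g: float,
    seed: int | np.random.Generator = 0,
    unknown_rate: float = 0.0,
    individual_ids=None,
    chrom_mask: np.ndarray | None = None,
) -> LocalAncestryCodes:
    """Draw per-site unordered diplotype ancestry codes for each individual.

    Each of the two haplotypes follows an independent Markov chain along the
    genetic map with stationary distribution ``q`` (one simplex per
    individual) and switch intensity ``g`` per Morgan.
    """
    q = _q_matrix(q)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ind = q.shape[0]

    table = panel.table if chrom_mask is None else panel.table.loc[chrom_mask]
    if len(table) and table["pos_cm"].isna().any():
        raise ValueError("panel genetic map (pos_cm) required for local ancestry")

    codes = np.empty((n_ind, len(table)), dtype=np.int8)
    start = 0
    for _, grp in table.groupby("chrom", sort=False):
        pos = grp["pos_cm"].to_numpy()
        h1 = _haplotype_ancestry(pos, q, g, rng)
        h2 = _haplotype_ancestry(pos, q, g, rng)
        codes[:, start : start + len(pos)] = diplotype_code(h1, h2)
        start += len(pos)

    if unknown_rate > 0:
        codes[rng.random(codes.shape) < unknown_rate] = 0

    if individual_ids is None:
        individual_ids = np.array([f"ind{i:04d}" for i in range(n_ind)])
    return LocalAncestryCodes(codes, table["site_id"].to_numpy(), np.asarray(individual_ids))


def _dirichlet(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise Dirichlet tolerating exact zeros in the concentration."""
    gam = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-12)), 0.0)
    s = gam.sum(axis=-1, keepdims=True)
    s[s == 0] = 1.0
    return gam / s


def _genotypes_from_codes(
    codes: np.ndarray, freqs_site: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Diploid dosages: sum of one Bernoulli draw per haplotype ancestry."""
    pair = np.array(_CODE_PAIRS, dtype=np.int8)
    a = pair[codes, 0]
    b = pair[codes, 1]
    fa = freqs_site[a, np.arange(codes.shape[1])[None, :]]
    fb = freqs_site[b, np.arange(codes.shape[1])[None, :]]
    dos = (rng.random(codes.shape) < fa).astype(np.int8)
    dos += (rng.random(codes.shape) < fb).astype(np.int8)
    return dos


# code -> ancestry index pair; code 0 handled separately (drawn as AFR:AFR
# placeholder then masked missing by the caller)
_CODE_PAIRS = [(0, 0), (1, 1), (1, 0), (0, 0), (1, 2), (0, 2), (2, 2)]


def genotypes_given_ancestry(
    lac: LocalAncestryCodes,
    panel: AncestralPanel,
    seed: int | np.random.Generator = 0,
    populations=None,
    sex=None,
) -> GenotypeMatrix:
    """Draw diploid dosages conditional on known local-ancestry codes.

    Convenience for simulation studies that fix the ancestry mosaic and only
    resample genotypes. All individuals are treated as diploid at every site.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if lac.codes.shape[1] != panel.n_sites:
        raise ValueError("local-ancestry codes do not match panel sites")
    dosages = _genotypes_from_codes(lac.codes, panel.freqs, rng)
    individuals = pd.DataFrame(
        {
            "population": populations if populations is not None else "NA",
            "sex": sex if sex is not None else "female",
        },
        index=pd.Index(lac.individual_ids, name="individual"),
    )
    return GenotypeMatrix(
        dosages, individuals, panel.table[["site_id", "chrom", "pos_bp"]].reset_index(drop=True)
    )


def simulate_cohort(
    spec: DemographicSpec, panel: AncestralPanel | None = None
) -> SimulatedCohort:
    """Simulate a full cohort: global ancestry, local tracts and genotypes.

    Individual ancestry proportions are drawn from a Dirichlet centred on the
    population expectation — autosomes (s_f+s_m)/2, X (2 s_f+s_m)/3 — with
    concentration ``spec.ancestry_dispersion``. Genotypes at a site with
    diplotype (a, b) are the sum of Bernoulli(freq_a) and Bernoulli(freq_b);
    male X is a single draw encoded 0/2 with the hemizygote flag.
    """
    if panel is None:
        panel = simulate_panel(20_000, spec)
    n_pop = len(spec.populations)
    n = spec.n_individuals * n_pop

    rng_q = _child_rng(spec.seed, "global-q")
    rng_sex = _child_rng(spec.seed, "sex")
    rng_la = _child_rng(spec.seed, "local-ancestry")
    rng_geno = _child_rng(spec.seed, "genotypes")
    rng_miss = _child_rng(spec.seed, "missingness")

    pops = np.repeat(list(spec.populations), spec.n_individuals)
    ids = np.array([f"{p}_{i:04d}" for i, p in enumerate(pops)])
    sex = np.where(rng_sex.random(n) < spec.female_fraction, "female", "male")

    q_auto = np.empty((n, 3))
    q_x = np.empty((n, 3))
    for pop in spec.populations:
        m = pops == pop
        ea, ex = spec.expected_q(pop)
        q_auto[m] = _dirichlet(
            np.broadcast_to(spec.ancestry_dispersion * ea, (int(m.sum()), 3)), rng_q
        )
        q_x[m] = _dirichlet(
            np.broadcast_to(spec.ancestry_dispersion * ex, (int(m.sum()), 3)), rng_q
        )

    is_x_site = panel.is_x
    # autosomal codes for everyone; X codes with the X-scope proportions
    la_auto = simulate_local_ancestry(
        panel, q_auto, spec.g, rng_la, spec.unknown_rate, ids, chrom_mask=~is_x_site
    )
    codes = np.empty((n, panel.n_sites), dtype=np.int8)
    codes[:, ~is_x_site] = la_auto.codes
    if is_x_site.any():
        female = sex == "female"
        x_codes = np.empty((n, int(is_x_site.sum())), dtype=np.int8)
        if female.any():
            x_codes[female] = simulate_local_ancestry(
                panel, q_x[female], spec.g, rng_la, spec.unknown_rate,
                ids[female], chrom_mask=is_x_site,
            ).codes
        if (~female).any():
            # males: one X haplotype; record the homozygous-pair code
            pos = panel.table.loc[is_x_site, "pos_cm"].to_numpy()
            h = _haplotype_ancestry(pos, q_x[~female], spec.g, rng_la)
            mx = diplotype_code(h, h)
            if spec.unknown_rate > 0:
                mx[rng_la.random(mx.shape) < spec.unknown_rate] = 0
            x_codes[~female] = mx
        codes[:, is_x_site] = x_codes

    # genotypes conditional on local ancestry
    dosages = _genotypes_from_codes(codes, panel.freqs, rng_geno)
    unknown = codes == 0
    # male X: hemizygous, one draw, encoded 0/2
    male_x = (sex == "male")[:, None] & is_x_site[None, :]
    if male_x.any():
        pair0 = np.array(_CODE_PAIRS, dtype=np.int8)[codes, 0]
        site_idx = np.broadcast_to(np.arange(panel.n_sites)[None, :], codes.shape)
        f_single = panel.freqs[pair0, site_idx]
        single = (rng_geno.random(codes.shape) < f_single).astype(np.int8) * 2
        dosages = np.where(male_x, single, dosages)

    del unknown  # genotypes at unknown-ancestry sites are kept as drawn
    if spec.missing_rate > 0:
        dosages[rng_miss.random(dosages.shape) < spec.missing_rate] = -1

    individuals = pd.DataFrame({"population": pops, "sex": sex}, index=pd.Index(ids, name="individual"))
    gm = GenotypeMatrix(
        dosages,
        individuals,
        panel.table[["site_id", "chrom", "pos_bp"]].reset_index(drop=True),
    )
    qcols = [f"q_{k}" for k in ANCESTRIES]
    return SimulatedCohort(
        genotypes=gm,
        true_local=LocalAncestryCodes(codes, panel.table["site_id"].to_numpy(), ids),
        true_global_auto=pd.DataFrame(q_auto, index=individuals.index, columns=qcols),
        true_global_x=pd.DataFrame(q_x, index=individuals.index, columns=qcols),
        sex=pd.Series(sex, index=individuals.index, name="sex"),
        panel=panel,
        populations=pd.Series(pops, index=individuals.index, name="population"),
    )
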