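"""Variant-discovery rarefaction and jackknife projection.

Rarefaction computes the expected number of sites polymorphic within a
hypergeometric subsample of n of the N sampled chromosomes,

    E[S(n)] = sum_i xi_i * (1 - [C(N-i,n) + C(i,n)] / C(N, n)),

subtracting both the probability that no derived copy is drawn and the
probability the subsample is fixed derived (a monomorphic subsample discovers
no variant). Under the standard neutral spectrum xi_i = theta/i this is
exactly theta times the partial harmonic series. Combinatorics are in log
space so spectra with millions of sites and large N are safe.

Projection beyond N extrapolates the curve with an order-k Newton-forward
scheme whose backward differences at n=N have the exact closed form
grad^j E[S](N) = (-1)^(j+1) (xi_j + xi_{N-j}) / C(N, j), so the projection

    S(M) ~= S_obs + sum_{j=1..k} C(M-N+j-1, j) (-1)^(j+1) (xi_j + xi_{N-j}) / C(N, j)

depends only on the spectrum's edges — the part that carries the information
about undiscovered variation. Because true discovery is non-decreasing in
sample size, projections are floored at the observed count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .catalog import SFS

__all__ = [
    "rarefaction",
    "jackknife_project",
    "discovery_gain",
    "discovery_curve",
    "neutral_sfs",
    "ProjectionResult",
]


def rarefaction(sfs: SFS, n) -> float | np.ndarray:
    """Expected segregating sites discovered in a subsample of n chromosomes."""
    n_arr = np.atleast_1d(np.asarray(n, dtype=int))
    N = sfs.n_chromosomes
    if np.any(n_arr < 1) or np.any(n_arr > N):
        raise ValueError(f"subsample size must lie in [1, N={N}]; use "
                         "jackknife_project to extrapolate beyond N")
    i = np.arange(1, N)
    out = np.empty(n_arr.shape, dtype=float)
    for j, nn in enumerate(n_arr):
        # P(no derived drawn) = C(N-i, n)/C(N, n), for sites with N-i >= n
        p_mono = np.zeros(N - 1)
        keep = (N - i) >= nn
        p_mono[keep] = np.exp(
            gammaln(N - i[keep] + 1)
            - gammaln(N - i[keep] - nn + 1)
            + gammaln(N - nn + 1)
            - gammaln(N + 1)
        )
        # P(all drawn derived) = C(i, n)/C(N, n), for sites with i >= n
        keep = i >= nn
        p_mono[keep] += np.exp(
            gammaln(i[keep] + 1)
            - gammaln(i[keep] - nn + 1)
            + gammaln(N - nn + 1)
            - gammaln(N + 1)
        )
        out[j] = float(np.sum(sfs.xi * (1.0 - p_mono)))
    return out if np.ndim(n) else float(out[0])


@dataclass
class ProjectionResult:
    """Projection of the discovery curve to M chromosomes."""

    value: float
    order: int
    M: int
    projections: dict[int, float]   # order -> projection, all computed orders
    stability: dict[int, float]     # order -> |P_{k+1}-P_k|/|P_k|
    stable: bool                    # True if the 1% stability rule was met


def _order_term(sfs: SFS, M: int, j: int) -> float:
    """(-1)^(j+1) (xi_j + xi_{N-j}) C(m+j-1, j) / C(N, j) with m = M - N."""
    N, m = sfs.n_chromosomes, M - sfs.n_chromosomes
    if m == 0:
        return 0.0
    ratio = 1.0
    for t in range(j):
        ratio *= (m + t) / (N - t)
    edge = float(sfs.xi[j - 1]) + float(sfs.xi[N - j - 1])
    return (-1) ** (j + 1) * edge * ratio


def jackknife_project(
    sfs: SFS,
    M: int,
    order: int | None = None,
    max_order: int = 5,
    stability_tol: float = 0.01,
) -> ProjectionResult:
    """Project the number of segregating sites to M > N sampled chromosomes.

    With ``order`` given, returns that single projection. Otherwise orders
    1..max_order are computed and the smallest order whose successive
    projections differ by less than ``stability_tol`` (relatively) is chosen;
    if none stabilises, the order with the smallest successive change wins.
    """
    N = sfs.n_chromosomes
    if M < N:
        raise ValueError("M must be >= N; use rarefaction below the sample size")
    top = max_order if order is None else order
    if not (1 <= top <= min(N - 1, len(sfs.xi))):
        raise ValueError(f"order must lie in [1, {min(N - 1, len(sfs.xi))}]")

    S_obs = sfs.segregating
    proj, acc = {}, S_obs
    for j in range(1, top + 1):
        acc = acc + _order_term(sfs, M, j)
        proj[j] = max(acc, S_obs)  # discovery never decreases with sample size
    if order is not None:
        return ProjectionResult(proj[order], order, M, proj, {}, True)

    stab = {
        k: abs(proj[k + 1] - proj[k]) / max(abs(proj[k]), 1e-12)
        for k in range(1, top)
    }
    if M == N or not stab:
        return ProjectionResult(S_obs, 1, M, proj, stab, True)
    stable_orders = [k for k, d in stab.items() if d < stability_tol]
    if stable_orders:
        k = min(stable_orders)
        return ProjectionResult(proj[k], k, M, proj, stab, True)
    k = min(stab, key=stab.get)
    return ProjectionResult(proj[k], k, M, proj, stab, False)


def discovery_gain(sfs: SFS, factor: float = 2.0, **kwargs) -> float:
    """Percent additional segregating sites expected at factor x N chromosomes."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    M = int(round(factor * sfs.n_chromosomes))
    res = jackknife_project(sfs, M, **kwargs)
    S = sfs.segregating
    if S == 0:
        raise ValueError("empty SFS")
    return 100.0 * (res.value - S) / S


def discovery_curve(sfs: SFS, n_grid=None) -> pd.DataFrame:
    """Rarefaction curve over a grid of subsample sizes."""
    if n_grid is None:
        N = sfs.n_chromosomes
        n_grid = np.unique(np.linspace(2, N, min(50, N - 1)).astype(int))
    vals = rarefaction(sfs, np.asarray(n_grid))
    return pd.DataFrame({"n": np.asarray(n_grid), "expected_S": vals,
                         "label": sfs.label})


def neutral_sfs(
    theta: float,
    n_chromosomes: int,
    rng: np.random.Generator | None = None,
    label: str = "neutral",
) -> SFS:
    """Standard-neutral spectrum xi_i = theta / i, expected or Poisson-sampled."""
    i = np.arange(1, n_chromosomes)
    xi = theta / i
    if rng is not None:
        xi = rng.poisson(xi).astype(float)
    return SFS(n_chromosomes, xi, label=label)
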