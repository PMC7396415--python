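"""Adaptive mono-/biexponential T2 decay fitting with adjusted-R² model selection.

Each voxel's noise-corrected decay y(TE_k), k = 1..K, is fitted twice by bounded
non-linear least squares:

    N = 1:  y ~ A * exp(-TE/T2),                      T2 in [27, 2500] ms
    N = 2:  y ~ A1 * exp(-TE/T2_1) + A2 * exp(-TE/T2_2),
            T2_1 in [27, 120] ms, T2_2 in [120.1, 2500] ms

with amplitudes in [0, 2000] a.u.  The model kept per voxel is the one with the
higher adjusted R²,

    adj_R² = 1 - (1 - R²) (K - 1) / (K - m - 1),
    R²     = 1 - Σ(y_i - G_i)² / Σ(y_i - ȳ)²,

where G is the fitted curve and m the number of free parameters (2 for mono, 4
for bi).  The parameter-count penalty makes the comparison fair: the bi model
always attains a residual at least as small, but pays for its two extra degrees
of freedom.  Exact ties (within 1e-12) resolve to the monoexponential model by
parsimony.

The disjoint T2 intervals of the two-component model double as an
identifiability constraint: the short and long pools cannot swap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .preprocess import NoiseProfile, eligible_voxel_mask, subtract_noise
from .protocol import AcquisitionProtocol

__all__ = [
    "SearchSpace",
    "FitResult",
    "ParametricMaps",
    "goodness_of_fit",
    "fit_monoexponential",
    "fit_biexponential",
    "select_model",
    "fit_voxelwise",
]

#: adjusted-R² difference below which two fits are considered tied
TIE_TOLERANCE = 1e-12

#: optimizer settings (relative cost tolerance, iteration cap per start)
FTOL = 1e-10
MAX_NFEV = 400


@dataclass(frozen=True)
class SearchSpace:
    """Box constraints of the non-linear least-squares problems (a.u. / ms)."""

    amp_lo: float = 0.0
    amp_hi: float = 2000.0
    mono_T2_lo: float = 27.0
    mono_T2_hi: float = 2500.0
    bi_T2_1_lo: float = 27.0
    bi_T2_1_hi: float = 120.0
    bi_T2_2_lo: float = 120.1
    bi_T2_2_hi: float = 2500.0

    def __post_init__(self) -> None:
        if not self.amp_lo < self.amp_hi:
            raise ValueError("amplitude interval is empty")
        for lo, hi in [
            (self.mono_T2_lo, self.mono_T2_hi),
            (self.bi_T2_1_lo, self.bi_T2_1_hi),
            (self.bi_T2_2_lo, self.bi_T2_2_hi),
        ]:
            if not 0 < lo < hi:
                raise ValueError("T2 interval must be nonempty and positive")
        if not self.bi_T2_1_hi < self.bi_T2_2_lo:
            raise ValueError("short and long T2 intervals must be disjoint")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class FitResult:
    """Outcome of one bounded NLLS fit of a single decay curve."""

    model_order: int
    A: np.ndarray
    T2: np.ndarray
    r2: float
    adj_r2: float
    m: int
    fitted_curve: np.ndarray
    converged: bool
    n_points: int

    @property
    def rss(self) -> float:
        return float(np.sum((self.fitted_curve - self._y) ** 2)) if hasattr(self, "_y") else np.nan


def _decay(tes: np.ndarray, A: np.ndarray, T2: np.ndarray) -> np.ndarray:
    return np.exp(-tes[:, None] / T2[None, :]) @ A


def goodness_of_fit(y: np.ndarray, G: np.ndarray, m: int) -> tuple[float, float]:
    """Coefficient of determination and its small-sample adjustment.

    Parameters
    ----------
    y : array
        Measured decay samples.
    G : array
        Model curve evaluated at the same echo times.
    m : int
        Number of free model parameters (2 per exponential component).

    Returns
    -------
    (r2, adj_r2)

    Raises
    ------
    ValueError
        If K <= m + 1 (the adjustment is undefined) or y is constant
        (degenerate variance).
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    if y.shape != G.shape or y.ndim != 1:
        raise ValueError("y and G must be 1-D arrays of equal length")
    K = y.size
    if K <= m + 1:
        raise ValueError(f"adjusted R^2 undefined for K={K} <= m+1={m + 1}")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("constant signal: variance is degenerate")
    rss = float(np.sum((y - G) ** 2))
    r2 = 1.0 - rss / tss
    adj_r2 = 1.0 - (1.0 - r2) * (K - 1) / (K - m - 1)
    return r2, adj_r2


def _solve(resid, x0, jac, lo, hi):
    # scipy's trf emits harmless overflow warnings when a trust-region
    # subproblem degenerates near a bound; they do not affect the solution
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return least_squares(
            resid, x0, jac=jac, bounds=(lo, hi), method="trf",
            ftol=FTOL, xtol=1e-12, gtol=None, max_nfev=MAX_NFEV,
        )


def _converged(sol, y) -> bool:
    # status > 0 is a tolerance-based stop; an essentially-zero residual
    # (noiseless data) also counts even if the iteration cap was hit
    return bool(sol.status > 0) or 2 * sol.cost <= 1e-20 * float(y @ y)


def _amp_ls(y: np.ndarray, basis: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Linear least-squares amplitudes for fixed T2s, clipped into bounds."""
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return np.clip(coef, lo, hi)


def _finish(y, tes, A, T2, m, converged) -> FitResult:
    G = _decay(tes, A, T2)
    try:
        r2, adj = goodness_of_fit(y, G, m)
    except ValueError:
        r2, adj = np.nan, -np.inf
        converged = False
    res = FitResult(
        model_order=len(A), A=A, T2=T2, r2=r2, adj_r2=adj, m=m,
        fitted_curve=G, converged=converged, n_points=len(y),
    )
    res._y = y
    return res


def fit_monoexponential(
    signal: np.ndarray, tes: np.ndarray, space: SearchSpace = SearchSpace()
) -> FitResult:
    """Fit y ~ A exp(-TE/T2) by bounded trust-region least squares.

    Three multi-starts with T2 initial values log-spaced across the mono search
    interval; the amplitude at each start is initialised by linear least
    squares given the starting T2.  The best final residual wins.
    """
    y = np.asarray(signal, dtype=float)
    tes = np.asarray(tes, dtype=float)
    if y.size < 3:
        raise ValueError("monoexponential fit needs at least 3 echoes")
    if np.any(np.diff(tes) <= 0):
        raise ValueError("echo times must be strictly increasing")

    if not np.any(np.abs(y) > 0):
        A = np.array([max(space.amp_lo, 0.0)])
        T2 = np.array([space.mono_T2_lo])
        return _finish(y, tes, A, T2, m=2, converged=False)

    lo = np.array([space.amp_lo, space.mono_T2_lo])
    hi = np.array([space.amp_hi, space.mono_T2_hi])

    def resid(p):
        return p[0] * np.exp(-tes / p[1]) - y

    def jac(p):
        e = np.exp(-tes / p[1])
        return np.column_stack([e, p[0] * e * tes / p[1] ** 2])

    t2_starts = np.geomspace(space.mono_T2_lo, space.mono_T2_hi, 5)[1:4]
    best, best_cost = None, np.inf
    for t2_0 in t2_starts:
        b = np.exp(-tes / t2_0)
        a_0 = float(np.clip(y @ b / (b @ b), space.amp_lo, space.amp_hi))
        x0 = np.clip([a_0, t2_0], lo, hi)
        sol = _solve(resid, x0, jac, lo, hi)
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
    A = np.array([best.x[0]])
    T2 = np.array([best.x[1]])
    return _finish(y, tes, A, T2, m=2, converged=_converged(best, y))


def fit_biexponential(
    signal: np.ndarray, tes: np.ndarray, space: SearchSpace = SearchSpace()
) -> FitResult:
    """Fit the two-component decay by bounded trust-region least squares.

    Multi-start over a fixed 3x3 log-spaced grid of (T2_1, T2_2) initial
    values; amplitudes at each start are initialised by linear least squares on
    the exponential basis of the starting T2s.  T2s are reported ascending
    (guaranteed by the disjoint search intervals).
    """
    y = np.asarray(signal, dtype=float)
    tes = np.asarray(tes, dtype=float)
    if y.size < 5:
        raise ValueError("biexponential fit needs at least 5 echoes")
    if np.any(np.diff(tes) <= 0):
        raise ValueError("echo times must be strictly increasing")

    if not np.any(np.abs(y) > 0):
        A = np.zeros(2)
        T2 = np.array([space.bi_T2_1_lo, space.bi_T2_2_lo])
        return _finish(y, tes, A, T2, m=4, converged=False)

    lo = np.array([space.amp_lo, space.bi_T2_1_lo, space.amp_lo, space.bi_T2_2_lo])
    hi = np.array([space.amp_hi, space.bi_T2_1_hi, space.amp_hi, space.bi_T2_2_hi])

    def resid(p):
        return p[0] * np.exp(-tes / p[1]) + p[2] * np.exp(-tes / p[3]) - y

    def jac(p):
        e1 = np.exp(-tes / p[1])
        e2 = np.exp(-tes / p[3])
        return np.column_stack(
            [e1, p[0] * e1 * tes / p[1] ** 2, e2, p[2] * e2 * tes / p[3] ** 2]
        )

    s1 = np.geomspace(space.bi_T2_1_lo, space.bi_T2_1_hi, 5)[1:4]
    s2 = np.geomspace(space.bi_T2_2_lo, space.bi_T2_2_hi, 5)[1:4]
    best, best_cost = None, np.inf
    for t1_0 in s1:
        for t2_0 in s2:
            basis = np.column_stack([np.exp(-tes / t1_0), np.exp(-tes / t2_0)])
            a = _amp_ls(y, basis, space.amp_lo, space.amp_hi)
            x0 = np.clip([a[0], t1_0, a[1], t2_0], lo, hi)
            sol = _solve(resid, x0, jac, lo, hi)
            if sol.cost < best_cost:
                best, best_cost = sol, sol.cost
    A = np.array([best.x[0], best.x[2]])
    T2 = np.array([best.x[1], best.x[3]])
    return _finish(y, tes, A, T2, m=4, converged=_converged(best, y))


def select_model(mono: FitResult, bi: FitResult) -> FitResult | None:
    """Keep the fit with the higher adjusted R² ("R2 criterion").

    Ties within ``TIE_TOLERANCE`` resolve to the monoexponential model by
    parsimony; if only one fit converged that one is kept; if neither
    converged the voxel is unfitted (None).
    """
    if not mono.converged and not bi.converged:
        return None
    if not bi.converged:
        return mono
    if not mono.converged:
        return bi
    if bi.adj_r2 > mono.adj_r2 + TIE_TOLERANCE:
        return bi
    return mono


@dataclass
class ParametricMaps:
    """Per-voxel model selection and component parameter maps for one slice.

    ``model_map`` holds 0 (unfitted / outside mask), 1 (mono) or 2 (bi).
    Component maps are NaN wherever their model was not selected.
    """

    model_map: np.ndarray
    mono_t2: np.ndarray
    bi_t2_short: np.ndarray
    bi_t2_long: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    r2: np.ndarray
    adj_r2: np.ndarray

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "ParametricMaps":
        nan = lambda: np.full(shape, np.nan)
        return cls(
            model_map=np.zeros(shape, dtype=np.int16),
            mono_t2=nan(), bi_t2_short=nan(), bi_t2_long=nan(),
            a1=nan(), a2=nan(), r2=nan(), adj_r2=nan(),
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.model_map.shape

    def map_names(self) -> list[str]:
        return ["model_map", "mono_t2", "bi_t2_short", "bi_t2_long",
                "a1", "a2", "r2", "adj_r2"]

    def to_dataframe(self, mask: np.ndarray | None = None) -> pd.DataFrame:
        """Per-voxel fit table (one row per in-mask voxel)."""
        if mask is None:
            mask = np.ones(self.shape, dtype=bool)
        rows, cols = np.nonzero(mask)
        model = self.model_map[rows, cols]
        t2_1 = np.where(model == 1, self.mono_t2[rows, cols],
                        self.bi_t2_short[rows, cols])
        return pd.DataFrame({
            "row": rows, "col": cols, "model": model,
            "A1": self.a1[rows, cols], "T2_1": t2_1,
            "A2": self.a2[rows, cols], "T2_2": self.bi_t2_long[rows, cols],
            "r2": self.r2[rows, cols], "adj_r2": self.adj_r2[rows, cols],
            "converged": model > 0,
        })


def fit_voxelwise(
    stack: np.ndarray,
    tissue_mask: np.ndarray,
    profile: NoiseProfile,
    space: SearchSpace = SearchSpace(),
    protocol: AcquisitionProtocol | None = None,
    tes: np.ndarray | None = None,
    eligibility_factor: float = 2.0,
    clip_negative: bool = False,
) -> ParametricMaps:
    """Noise-subtract and model-fit every eligible voxel of a masked slice.

    Parameters
    ----------
    stack : (H, W, K) array
        Effective-echo image stack (first acquired echo already dropped).
    tissue_mask : (H, W) bool array
        Voxels to fit.
    profile : NoiseProfile
        Per-echo mean background noise, subtracted from each voxel.
    protocol, tes :
        Echo times of the stack; give one of the two.
    eligibility_factor : float
        Voxels whose mean corrected signal over the first 3 effective echoes
        falls below ``eligibility_factor * mean(profile.e)`` are flagged
        unfitted (model 0) instead of fitted.
    clip_negative : bool
        If True, clip noise-subtracted signals at 0 before fitting.
    """
    if tes is None:
        if protocol is None:
            raise ValueError("provide either protocol or tes")
        tes = protocol.effective_tes
    tes = np.asarray(tes, dtype=float)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if tissue_mask.shape != stack.shape[:2]:
        raise ValueError("mask and stack grids differ")
    if not tissue_mask.any():
        raise ValueError("tissue mask is empty")
    if stack.shape[2] != tes.size:
        raise ValueError("stack echo count does not match echo-time vector")

    eligible = eligible_voxel_mask(stack, profile, tissue_mask, factor=eligibility_factor)
    maps = ParametricMaps.empty(tissue_mask.shape)
    for r, c in zip(*np.nonzero(tissue_mask & eligible)):
        y = subtract_noise(stack[r, c, :], profile)
        if clip_negative:
            y = np.clip(y, 0.0, None)
        try:
            mono = fit_monoexponential(y, tes, space)
            bi = fit_biexponential(y, tes, space)
        except ValueError:
            continue
        sel = select_model(mono, bi)
        if sel is None:
            continue
        maps.model_map[r, c] = sel.model_order
        maps.r2[r, c] = sel.r2
        maps.adj_r2[r, c] = sel.adj_r2
        if sel.model_order == 1:
            maps.mono_t2[r, c] = sel.T2[0]
            maps.a1[r, c] = sel.A[0]
        else:
            maps.bi_t2_short[r, c] = sel.T2[0]
            maps.bi_t2_long[r, c] = sel.T2[1]
            maps.a1[r, c] = sel.A[0]
            maps.a2[r, c] = sel.A[1]
    return maps
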