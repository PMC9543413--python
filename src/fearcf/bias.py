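"""Bias grids, the adaptive flat-histogram update, WHAM, and spline gradients.

The adaptive scheme drives sampling along the reaction coordinates toward
flatness: at convergence the biasing potential cancels the free energy,
W(ξ) + U(ξ) = 0.  Each iteration estimates the unbiased density P from the
biased histogram,

    P(ξ) ∝ P'(ξ) exp(U(ξ)/k_B T),        (unbias)
    W(ξ) = −k_B T ln P(ξ),               (Boltzmann inversion)
    U_next(ξ) = −W(ξ),                   (bias update)

with the histograms of parallel replicas combined by the weighted histogram
analysis method (WHAM) before inversion.  The biasing force needs ∂U/∂ξ at
arbitrary RC values, supplied by a tensor-product cubic spline interpolant
of U over the grid (natural boundaries on bounded dimensions, periodic
closure on angular ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import NdBSpline, make_interp_spline
from scipy.special import logsumexp

from .constants import KB


@dataclass(frozen=True)
class DimSpec:
    """One grid dimension of RC space."""

    name: str
    min: float
    max: float
    n_bins: int
    periodic: bool = False

    def __post_init__(self):
        if not self.min < self.max:
            raise ValueError(f"dim {self.name!r}: min must be < max")
        if self.n_bins < 4:
            raise ValueError(f"dim {self.name!r}: need at least 4 bins")

    @property
    def width(self) -> float:
        return (self.max - self.min) / self.n_bins

    @property
    def centers(self) -> np.ndarray:
        return self.min + (np.arange(self.n_bins) + 0.5) * self.width

    @property
    def edges(self) -> np.ndarray:
        return self.min + np.arange(self.n_bins + 1) * self.width


@dataclass(frozen=True)
class GridSpec:
    """d-dimensional RC grid: a tuple of :class:`DimSpec`."""

    dims: tuple[DimSpec, ...]

    def __post_init__(self):
        object.__setattr__(self, "dims", tuple(
            d if isinstance(d, DimSpec) else DimSpec(**d) for d in self.dims))

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(d.n_bins for d in self.dims)

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.dims]

    def wrap(self, xi: np.ndarray) -> np.ndarray:
        """Map periodic coordinates into [min, max)."""
        xi = np.array(xi, float, copy=True)
        for k, d in enumerate(self.dims):
            if d.periodic:
                span = d.max - d.min
                xi[..., k] = d.min + np.mod(xi[..., k] - d.min, span)
        return xi

    def bin_index(self, xi) -> tuple[np.ndarray, np.ndarray]:
        """(flat bin indices, in-range mask) for RC values xi (..., d).

        Periodic coordinates are wrapped; out-of-range non-periodic samples
        are masked out (flat index clipped, mask False).
        """
        xi = self.wrap(np.atleast_2d(np.asarray(xi, float)))
        idx = np.empty(xi.shape[:-1] + (self.ndim,), dtype=np.intp)
        ok = np.ones(xi.shape[:-1], dtype=bool)
        for k, d in enumerate(self.dims):
            j = np.floor((xi[..., k] - d.min) / d.width).astype(np.intp)
            if d.periodic:
                j = np.clip(j, 0, d.n_bins - 1)   # guards the xi == max edge
            else:
                ok &= (j >= 0) & (j < d.n_bins)
                j = np.clip(j, 0, d.n_bins - 1)
            idx[..., k] = j
        flat = np.ravel_multi_index(
            tuple(idx[..., k] for k in range(self.ndim)), self.shape)
        return flat, ok


@dataclass
class BiasGrid:
    """Visit counts, unbiased density P, free energy W and bias U on a grid.

    All arrays share ``spec.shape``; W and U are in kcal/mol, P sums to 1
    over occupied bins.  ``U = -W`` wherever both are defined.
    """

    spec: GridSpec
    temperature: float = 300.0
    counts: np.ndarray = None
    P: np.ndarray = None
    W: np.ndarray = None
    U: np.ndarray = None

    def __post_init__(self):
        shape = self.spec.shape
        if self.counts is None:
            self.counts = np.zeros(shape)
        if self.U is None:
            self.U = np.zeros(shape)
        for name in ("counts", "P", "W", "U"):
            arr = getattr(self, name)
            if arr is not None and tuple(arr.shape) != shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {shape}")

    @property
    def kT(self) -> float:
        return KB * self.temperature

    def accumulate(self, xi) -> int:
        """Bin RC observations into ``counts``; returns the number binned."""
        return accumulate(self.counts, self.spec, xi)

    def interpolant(self, mode: str = "cubic") -> "SplineInterpolant":
        return SplineInterpolant(self.spec, self.U, mode=mode)


def accumulate(counts: np.ndarray, spec: GridSpec, xi) -> int:
    """Increment the containing bin count for each observation in ``xi``.

    Out-of-range samples along non-periodic dimensions are not binned.
    """
    flat, ok = spec.bin_index(xi)
    flat = flat.ravel()[ok.ravel()]
    np.add.at(counts.ravel(), flat, 1.0)
    return int(flat.size)


def unbias(biased_counts: np.ndarray, U: np.ndarray, temperature: float) -> np.ndarray:
    """Unbiased density P ∝ P' exp(U/k_B T), normalized; empty bins get 0."""
    c = np.asarray(biased_counts, float)
    occ = c > 0
    if not occ.any():
        raise ValueError("no occupied bins")
    if not np.all(np.isfinite(np.asarray(U)[occ])):
        raise ValueError("non-finite bias on an occupied bin")
    kT = KB * temperature
    logP = np.full(c.shape, -np.inf)
    logP[occ] = np.log(c[occ]) + np.asarray(U)[occ] / kT
    logP -= logsumexp(logP[occ])
    P = np.zeros_like(c)
    P[occ] = np.exp(logP[occ])
    return P


def potential_from_density(P: np.ndarray, temperature: float,
                           empty_bin_offset: float | None = None) -> np.ndarray:
    """Free energy W = −k_B T ln P, shifted so min W = 0.

    Never-visited bins are assigned max(W over visited) plus
    ``empty_bin_offset`` (default k_B T), keeping W finite everywhere.
    """
    P = np.asarray(P, float)
    if np.any(P < 0):
        raise ValueError("negative probability")
    occ = P > 0
    if not occ.any():
        raise ValueError("all-zero density")
    kT = KB * temperature
    W = np.empty_like(P)
    W[occ] = -kT * np.log(P[occ])
    W[occ] -= W[occ].min()
    if empty_bin_offset is None:
        empty_bin_offset = kT
    W[~occ] = W[occ].max() + empty_bin_offset
    return W


def update_bias(W: np.ndarray) -> np.ndarray:
    """Next bias U = −W (no damping by default; see ``mix_bias``)."""
    W = np.asarray(W, float)
    if not np.all(np.isfinite(W)):
        raise ValueError("non-finite free energy")
    return -W


def mix_bias(U_old: np.ndarray, W: np.ndarray, factor: float = 1.0) -> np.ndarray:
    """Damped update U_next = (1−f) U_old + f (−W); f = 1 is the plain rule."""
    return (1.0 - factor) * np.asarray(U_old) + factor * update_bias(W)


def flatness_ratio(counts: np.ndarray) -> float:
    """max/min visit-count ratio over occupied bins (>= 1; 1 = flat)."""
    c = np.asarray(counts, float)
    occ = c[c > 0]
    if occ.size == 0:
        raise ValueError("empty histogram")
    return float(occ.max() / occ.min())


def wham_combine(histograms, biases, temperature: float,
                 tol: float = 1e-7, max_iter: int = 10000) -> np.ndarray:
    """Self-consistent WHAM combination of K biased histograms.

    ``histograms`` and ``biases`` are sequences of same-shaped count and
    bias arrays (bias U_k in kcal/mol as applied during sampling of
    histogram k).  Returns the unbiased P normalized over occupied bins.
    When all biases are identical this reduces exactly to
    ``unbias(sum(histograms), U)``.
    """
    hs = [np.asarray(h, float) for h in histograms]
    if len(hs) == 0:
        raise ValueError("empty histogram set")
    Us = [np.asarray(u, float) for u in biases]
    if len(Us) != len(hs):
        raise ValueError("need one bias per histogram")
    shape = hs[0].shape
    kT = KB * temperature

    H = np.stack([h.ravel() for h in hs])          # (K, M)
    B = np.stack([u.ravel() for u in Us]) / kT     # (K, M) reduced bias
    N = H.sum(axis=1)                              # samples per replica
    keep = N > 0
    H, B, N = H[keep], B[keep], N[keep]
    pooled = H.sum(axis=0)
    occ = pooled > 0
    if not occ.any():
        raise ValueError("no occupied bins")

    # log P_m = log(Σ_k n_km) − log(Σ_k N_k exp(f_k − B_km)), with
    # f_k = −log Σ_m P_m exp(−B_km) the reduced free energy of window k.
    logN = np.log(N)
    f = np.zeros(len(N))
    log_pool = np.log(pooled[occ])
    Bo = -B[:, occ]                                # −U_k/kT on occupied bins
    for _ in range(max_iter):
        denom = logsumexp(logN[:, None] + f[:, None] + Bo, axis=0)
        logP = log_pool - denom
        logP -= logsumexp(logP)
        f_new = -logsumexp(logP[None, :] + Bo, axis=1)
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    denom = logsumexp(logN[:, None] + f[:, None] + Bo, axis=0)
    logP = log_pool - denom
    logP -= logsumexp(logP)
    P = np.zeros(pooled.shape)
    P[occ] = np.exp(logP)
    return P.reshape(shape)


class SplineInterpolant:
    """Tensor-product cubic interpolant of a grid array with gradients.

    ``mode='cubic'`` uses natural boundary conditions on bounded dimensions;
    ``mode='b_spline'`` uses not-a-knot.  Periodic dimensions always close
    periodically.  Node values at bin centers are reproduced exactly (up to
    the linear-solve round-off of the coefficient computation).
    """

    def __init__(self, spec: GridSpec, values: np.ndarray, mode: str = "cubic"):
        if mode not in ("cubic", "b_spline"):
            raise ValueError(f"unknown spline mode {mode!r}")
        self.spec = spec
        self.mode = mode
        values = np.asarray(values, float)
        if values.shape != spec.shape:
            raise ValueError("values shape does not match grid")
        self._values = values

        knots = []
        c = values
        for ax, d in enumerate(spec.dims):
            x = d.centers
            y = c
            if d.periodic:
                x = np.append(x, x[0] + (d.max - d.min))
                y = np.concatenate([y, np.take(y, [0], axis=ax)], axis=ax)
                bc = "periodic"
            else:
                bc = "natural" if mode == "cubic" else None
            spl = make_interp_spline(x, y, k=3, bc_type=bc, axis=ax)
            knots.append(spl.t)
            c = spl.c
            if ax != 0:
                c = np.moveaxis(c, 0, ax)
        self._nd = NdBSpline(tuple(knots), c, k=3)

    def _prep(self, xi) -> np.ndarray:
        xi = self.spec.wrap(np.atleast_2d(np.asarray(xi, float)))
        for k, d in enumerate(self.spec.dims):
            lo, hi = d.centers[0], d.centers[-1]
            if d.periodic:
                span = d.max - d.min
                xi[..., k] = lo + np.mod(xi[..., k] - lo, span)
            else:
                # clamp to the node range; outside the grid the driver
                # applies a restraining wall instead of extrapolating
                xi[..., k] = np.clip(xi[..., k], lo, hi)
        return xi

    def __call__(self, xi) -> np.ndarray:
        """Interpolated values at RC points ``xi`` (..., d)."""
        return self._nd(self._prep(xi))

    def gradient(self, xi) -> np.ndarray:
        """∂U/∂ξ at ``xi``: shape (..., d), kcal/mol per external RC unit."""
        pts = self._prep(xi)
        out = np.empty(pts.shape)
        nu = np.zeros(self.spec.ndim, dtype=int)
        for k in range(self.spec.ndim):
            nu[:] = 0
            nu[k] = 1
            out[..., k] = self._nd(pts, nu=nu)
        return out


def bias_gradient(interp: SplineInterpolant, xi) -> np.ndarray:
    """Convenience wrapper: per-dimension ∂U/∂ξ of an interpolated bias."""
    return interp.gradient(xi)
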