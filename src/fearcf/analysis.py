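"""Post-processing of free-energy volumes and trajectories.

Covers minima location on visited bins, Boltzmann-averaged low-dimensional
projections of a multidimensional free-energy volume (FEV), the
dipole–dipole autocorrelation Q(t) with single/double exponential relaxation
fits, projection of RC time series onto a FEV, and geometric classification
of water-dimer hydrogen-bond configurations (Chain / Cyclic / Bifurcated).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .bias import BiasGrid, DimSpec, GridSpec
from .constants import KB

__all__ = [
    "find_minima", "boltzmann_project", "dipole_autocorrelation",
    "AutocorrResult", "AutocorrFit", "fit_exponential",
    "ConfigurationLabel", "classify_configuration", "classify_timeseries",
    "project_trajectory",
]


# ---------------------------------------------------------------------------
# FEV geometry
# ---------------------------------------------------------------------------

def find_minima(fev: BiasGrid, visited_only: bool = True):
    """Local minima of W over the grid (full 3^d−1 neighborhood).

    Periodic dimensions wrap; never-visited bins are excluded when
    ``visited_only`` (and count as +inf neighbors).  Returns a list of
    ``(multi_index, bin_center_coordinates, W)`` sorted by W, ties broken
    by lexicographic bin index.
    """
    W = np.asarray(fev.W, float)
    if W.size == 0:
        raise ValueError("empty free-energy volume")
    mask = np.ones(W.shape, bool)
    if visited_only and fev.counts is not None and np.any(fev.counts > 0):
        mask = fev.counts > 0
    Wm = np.where(mask, W, np.inf)
    d = W.ndim
    periodic = [dim.periodic for dim in fev.spec.dims]
    neighbor_min = np.full(W.shape, np.inf)
    for shift in itertools.product((-1, 0, 1), repeat=d):
        if all(s == 0 for s in shift):
            continue
        sh = Wm
        for ax, s in enumerate(shift):
            if s == 0:
                continue
            if periodic[ax]:
                sh = np.roll(sh, s, axis=ax)
            else:
                sh = np.roll(sh, s, axis=ax)
                idx = [slice(None)] * d
                idx[ax] = 0 if s == 1 else -1
                sh = sh.copy()
                sh[tuple(idx)] = np.inf
        neighbor_min = np.minimum(neighbor_min, sh)
    is_min = mask & (Wm <= neighbor_min) & np.isfinite(Wm)
    out = []
    centers = [dim.centers for dim in fev.spec.dims]
    for mi in np.argwhere(is_min):
        mi = tuple(int(v) for v in mi)
        coord = tuple(float(centers[k][mi[k]]) for k in range(d))
        out.append((mi, coord, float(W[mi])))
    out.sort(key=lambda t: (t[2], t[0]))
    return out


def boltzmann_project(fev: BiasGrid, keep, temperature: float | None = None) -> BiasGrid:
    """Boltzmann-averaged projection of W onto the ``keep`` dimensions:

        W_proj(ξ_kept) = −k_B T ln Σ_dropped exp(−W/k_B T),  min-shifted to 0.

    ``keep`` is a sequence of dimension indices or names.  Counts and P are
    marginalized alongside.
    """
    spec = fev.spec
    names = spec.names
    keep_idx = tuple(names.index(k) if isinstance(k, str) else int(k) for k in keep)
    if len(set(keep_idx)) != len(keep_idx) or not keep_idx:
        raise ValueError("invalid projection dimensions")
    if any(k < 0 or k >= spec.ndim for k in keep_idx):
        raise ValueError("projection dimension out of range")
    drop = tuple(i for i in range(spec.ndim) if i not in keep_idx)
    T = fev.temperature if temperature is None else temperature
    kT = KB * T
    # move kept axes first, in the requested order
    Wp = np.transpose(fev.W, keep_idx + drop)
    flatter = Wp.reshape(Wp.shape[:len(keep_idx)] + (-1,))
    from scipy.special import logsumexp
    W2 = -kT * logsumexp(-flatter / kT, axis=-1)
    W2 -= W2.min()
    new_spec = GridSpec(tuple(spec.dims[k] for k in keep_idx))
    counts = None
    P = None
    if fev.counts is not None:
        counts = np.transpose(fev.counts, keep_idx + drop).reshape(flatter.shape).sum(-1)
    if fev.P is not None:
        P = np.transpose(fev.P, keep_idx + drop).reshape(flatter.shape).sum(-1)
    return BiasGrid(new_spec, temperature=T, counts=counts, P=P, W=W2, U=-W2)


def project_trajectory(rc_timeseries, fev: BiasGrid):
    """Per-frame (flat bin index, W) path of an RC time series on a FEV.

    Frames outside the grid get bin index −1, W = nan, and are flagged in
    the returned boolean mask.
    """
    xi = np.atleast_2d(np.asarray(rc_timeseries, float))
    flat, ok = fev.spec.bin_index(xi)
    W = np.where(ok, fev.W.ravel()[flat], np.nan)
    bins = np.where(ok, flat, -1)
    return bins, W, ok


# ---------------------------------------------------------------------------
# dipole autocorrelation
# ---------------------------------------------------------------------------

@dataclass
class AutocorrResult:
    lags_fs: np.ndarray
    Q: np.ndarray
    normalized: bool = False


def total_dipole(positions, charges) -> np.ndarray:
    """Total dipole D = Σ q_i x_i (e·Å) per frame, (..., 3)."""
    q = np.asarray(charges, float)
    return np.einsum("...ij,i->...j", np.asarray(positions, float), q)


def dipole_autocorrelation(trajectory=None, charges=None, max_lag: int = None,
                           dt_fs: float = 1.0, dipoles=None,
                           normalize: bool = False) -> AutocorrResult:
    """Time-origin-averaged autocorrelation Q(t) = <D(0)·D(t)>.

    Supply either ``trajectory`` (n_frames, n_atoms, 3) with per-atom
    ``charges``, or precomputed ``dipoles`` (n_frames, 3).  The raw
    (unnormalized) dot product is returned by default; ``normalize=True``
    divides by Q(0).
    """
    if dipoles is None:
        if trajectory is None or charges is None:
            raise ValueError("need trajectory+charges or dipoles")
        dipoles = total_dipole(trajectory, charges)
    D = np.asarray(dipoles, float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames")
    if max_lag is None:
        max_lag = n // 2
    if max_lag >= n:
        raise ValueError("max_lag must be below the trajectory length")
    # FFT-based correlation per component, summed
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fd = np.fft.rfft(D, n=nfft, axis=0)
    acf = np.fft.irfft((fd * fd.conj()).real, n=nfft, axis=0)[:max_lag + 1].sum(axis=1)
    acf /= (n - np.arange(max_lag + 1))          # per-origin average
    if normalize:
        acf = acf / acf[0]
    return AutocorrResult(lags_fs=np.arange(max_lag + 1) * dt_fs, Q=acf,
                          normalized=normalize)


@dataclass
class AutocorrFit:
    """Exponential relaxation fit of a Q(t) decay.

    single: Q ≈ exp(−(t+x)/τ); double: Q ≈ exp(−(t+x1)/τ1) + exp(−(t+x2)/τ2)
    with τ1 < τ2.  ``params``/``stderr`` are keyed by parameter name.
    """

    model: str
    params: dict
    stderr: dict
    lags_fs: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def tau(self):
        return self.params.get("tau")

    @property
    def tau1(self):
        return self.params.get("tau1")

    @property
    def tau2(self):
        return self.params.get("tau2")


def _single(t, tau, x):
    return np.exp(-(t + x) / tau)


def _double(t, tau1, x1, tau2, x2):
    return np.exp(-(t + x1) / tau1) + np.exp(-(t + x2) / tau2)


def fit_exponential(ac: AutocorrResult, model: str = "double",
                    fit_floor: float = 0.05, sigma=None) -> AutocorrFit:
    """Nonlinear least-squares fit of Q(t) by one or two exponentials.

    The fitted window runs from lag 0 to the first lag where Q drops below
    ``fit_floor``·Q(0).  Unweighted by default; pass per-point ``sigma``
    (e.g. ∝ Q for relative noise) for weighted least squares — with
    multiplicative noise the weighted fit gives honest standard errors for
    the fast component.  The double model relabels so τ1 < τ2.
    Non-convergence raises with the optimizer diagnostics.
    """
    t = np.asarray(ac.lags_fs, float)
    Q = np.asarray(ac.Q, float)
    if Q.size == 0 or Q[0] <= 0:
        raise ValueError("Q must be positive over the fitted range")
    below = np.nonzero(Q < fit_floor * Q[0])[0]
    end = int(below[0]) if below.size else len(Q)
    t, Q = t[:end], Q[:end]
    if Q[0] <= 0 or np.any(Q <= 0):
        raise ValueError("Q must be positive over the fitted range")
    scale = Q[0]
    Qs = Q / scale      # amplitudes folded into the x offsets
    sg = None if sigma is None else np.asarray(sigma, float)[:end] / scale
    span = t[-1] - t[0] if len(t) > 1 else 1.0
    try:
        if model == "single":
            p0 = (0.5 * span, 0.0)
            popt, pcov = curve_fit(_single, t, Qs, p0=p0, sigma=sg,
                                   maxfev=20000)
            names = ["tau", "x"]
        elif model == "double":
            p0 = (0.1 * span, 0.0, 0.7 * span, 0.0)
            popt, pcov = curve_fit(_double, t, Qs, p0=p0, sigma=sg,
                                   maxfev=40000)
            names = ["tau1", "x1", "tau2", "x2"]
        else:
            raise ValueError(f"unknown model {model!r}")
    except RuntimeError as exc:
        raise RuntimeError(f"exponential fit did not converge: {exc}") from exc
    err = np.sqrt(np.diag(pcov))
    if model == "double" and popt[0] > popt[2]:
        popt = np.r_[popt[2:], popt[:2]]
        err = np.r_[err[2:], err[:2]]
    fitted_scaled = popt.copy()
    # the fit ran on Q/Q(0); fold the amplitude back into the time offsets
    # so the reported parameters describe the raw decay: c·e^{−(t+x)/τ}
    # = e^{−(t + x − τ ln c)/τ}
    ln_c = math.log(scale)
    if model == "single":
        popt = popt.copy()
        popt[1] -= popt[0] * ln_c
    else:
        popt = popt.copy()
        popt[1] -= popt[0] * ln_c
        popt[3] -= popt[2] * ln_c
    params = dict(zip(names, popt))
    stderr = dict(zip(names, err))
    for nm in ("tau", "tau1", "tau2"):
        if nm in params and params[nm] <= 0:
            raise RuntimeError(f"fit produced nonpositive relaxation time {nm}")
    fitted = scale * (_single(t, *fitted_scaled) if model == "single"
                      else _double(t, *fitted_scaled))
    return AutocorrFit(model=model, params=params, stderr=stderr,
                       lags_fs=t, fitted=fitted)


# ---------------------------------------------------------------------------
# hydrogen-bond configuration classification
# ---------------------------------------------------------------------------

#: (θ1, θ2) templates (degrees) of the three dimer hydrogen-bond
#: configurations; Chain and Bifurcated also occur with molecules swapped.
TEMPLATES = {
    "C": (65.5, 118.3),
    "Cy": (81.9, 84.5),
    "B": (172.4, 7.9),
}


@dataclass
class ConfigurationLabel:
    label: str                  # C | Cy | B | unbound | other
    rc_values: tuple


def classify_configuration(rc_values, angular_window: float = 20.0,
                           unbound_cutoff: float = 5.0) -> ConfigurationLabel:
    """Nearest-template label for one 4D RC observation (r, θ1, θ2, φ).

    Distance r beyond ``unbound_cutoff`` (Å) → ``unbound``; otherwise the
    nearest (θ1, θ2) template (molecule exchange symmetric) within
    ``angular_window`` degrees per angle, else ``other``.
    """
    rc = tuple(float(v) for v in np.asarray(rc_values, float))
    if len(rc) != 4:
        raise ValueError("classification needs 4D RC values (r, θ1, θ2, φ)")
    r, t1, t2, _ = rc
    if r > unbound_cutoff:
        return ConfigurationLabel("unbound", rc)
    best, best_d = "other", np.inf
    for name, (a, b) in TEMPLATES.items():
        for ta, tb in ((a, b), (b, a)):        # molecule exchange
            d = max(abs(t1 - ta), abs(t2 - tb))
            if d < best_d:
                best_d, best = d, name
    if best_d > angular_window:
        best = "other"
    return ConfigurationLabel(best, rc)


def classify_timeseries(rc_timeseries, **kwargs):
    """Vector version: list of labels, one per frame."""
    return [classify_configuration(row, **kwargs).label
            for row in np.atleast_2d(np.asarray(rc_timeseries, float))]
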