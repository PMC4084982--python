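"""Multidimensional WHAM over umbrella-coordinate samples, and the projected
observables built on the self-consistent solution: the ratchet-progress
coordinate R1, the signed tRNA-travel coordinate R2, 1-D/2-D free-energy
profiles, and weighted averages with spreads.

The full (n_biased x 3)-dimensional WHAM is solved in its binless
sample-reweighting form: each sample receives an unbiased weight from the
self-consistent per-window free-energy shifts F_j, and any projected
histogram is then a weighted sum.  This is mathematically equivalent to
histogramming in the full space followed by projection, without ever
materializing the (n_biased x 3)-dimensional histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from . import units
from .structure import kabsch_rotation


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass
class UmbrellaWindow:
    """One window's samples and bias specification."""

    samples: np.ndarray      # (n_j, G, 3) umbrella coordinates, A
    centers: np.ndarray      # (G, 3) bias centers, A
    k: np.ndarray            # (G,) force constants, kcal/mol/A^2
    form: str = "k_dr2"      # "k_dr2": V = k|dr|^2 ; "half_k_dr2": V = k|dr|^2/2

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if self.samples.ndim == 2:
            self.samples = self.samples[:, :, None] * np.array([1.0, 0.0, 0.0])
        self.centers = np.asarray(self.centers, float).reshape(-1, 3)
        self.k = np.asarray(self.k, float).reshape(-1)
        if self.samples.shape[0] == 0:
            raise ValueError("window has no samples")
        if self.form not in ("k_dr2", "half_k_dr2"):
            raise ValueError(f"unknown bias form {self.form!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def bias_energy(self, R: np.ndarray) -> np.ndarray:
        """Total bias energy V_j(R) for coordinates R of shape (n, G, 3)."""
        R = np.asarray(R, float)
        d2 = ((R - self.centers[None]) ** 2).sum(axis=2)
        pref = 1.0 if self.form == "k_dr2" else 0.5
        return pref * (d2 * self.k[None, :]).sum(axis=1)


@dataclass
class UmbrellaDataset:
    windows: list
    temperature: float = 300.0    # K

    @classmethod
    def from_window_records(cls, records, temperature=300.0):
        """Build from sampling_engine WindowRecords."""
        wins = [UmbrellaWindow(r.samples, r.bias_centers, r.bias_k,
                               r.bias_form) for r in records]
        return cls(wins, temperature)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def all_samples(self) -> np.ndarray:
        return np.concatenate([w.samples for w in self.windows], axis=0)


@dataclass
class WhamSolution:
    free_energies: np.ndarray    # (N_win,) F_j in kcal/mol, F_1 = 0
    weights: np.ndarray          # (S,) unbiased per-sample weights, sum 1
    iterations: int
    max_delta: float             # last max |dF_j|, kcal/mol
    temperature: float

    @property
    def kT(self) -> float:
        return units.thermal_energy(self.temperature)


def _pairwise_overlap(data: UmbrellaDataset) -> np.ndarray:
    """Histogram overlap coefficient between neighboring windows, computed
    on the projection onto the line joining their bias centers."""
    n = data.n_windows
    ov = np.ones(max(n - 1, 0))
    for j in range(n - 1):
        a, b = data.windows[j], data.windows[j + 1]
        d = (b.centers - a.centers).ravel()
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        u = d / norm
        xa = a.samples.reshape(a.n_samples, -1) @ u
        xb = b.samples.reshape(b.n_samples, -1) @ u
        lo = min(xa.min(), xb.min())
        hi = max(xa.max(), xb.max())
        if hi <= lo:
            continue
        bins = np.linspace(lo, hi, 41)
        ha, _ = np.histogram(xa, bins=bins, density=False)
        hb, _ = np.histogram(xb, bins=bins, density=False)
        ov[j] = np.minimum(ha / a.n_samples, hb / b.n_samples).sum()
    return ov


def wham_solve(data: UmbrellaDataset, tol: float = 1e-4,
               max_iter: int = 50000,
               overlap_warn: float = 1e-3) -> WhamSolution:
    """Self-consistent WHAM solution.

    Iterates the coupled equations for the per-window shifts F_j and the
    unbiased sample weights until max |dF_j| < tol (kcal/mol, default 1e-4).
    F_1 is anchored at zero.  Neighboring windows with sampled-distribution
    overlap below `overlap_warn` trigger a warning.
    """
    kT = units.thermal_energy(data.temperature)
    overlaps = _pairwise_overlap(data)
    if overlaps.size and overlaps.min() < overlap_warn:
        worst = int(np.argmin(overlaps))
        warnings.warn(
            f"windows {worst} and {worst + 1} barely overlap "
            f"(coefficient {overlaps.min():.2e}); WHAM may be unreliable",
            RuntimeWarning, stacklevel=2)

    R = data.all_samples()
    S = R.shape[0]
    N = data.n_windows
    n_j = np.array([w.n_samples for w in data.windows], float)
    # B[j, s] = V_j(R_s) / kT
    B = np.empty((N, S))
    for j, w in enumerate(data.windows):
        B[j] = w.bias_energy(R) / kT
    log_n = np.log(n_j)

    f = np.zeros(N)  # F_j / kT
    for it in range(1, max_iter + 1):
        # log denominator per sample: logsumexp_j [ log n_j + f_j - B_js ]
        log_den = logsumexp(log_n[:, None] + f[:, None] - B, axis=0)
        # f_j <- -log sum_s exp(-B_js - log_den)
        f_new = -logsumexp(-B - log_den[None, :], axis=1)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f))) * kT
        f = f_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {delta:.3g} kcal/mol)")
    log_w = -log_den
    log_w -= logsumexp(log_w)
    weights = np.exp(log_w)
    return WhamSolution(free_energies=f * kT, weights=weights,
                        iterations=it, max_delta=delta,
                        temperature=data.temperature)


# ---------------------------------------------------------------------------
# Reaction-coordinate projections
# ---------------------------------------------------------------------------

@dataclass
class ProjectionFrame:
    """Reference geometry for the projected reaction coordinates.

    mask selects the ratchet-related umbrella groups (the reference analysis
    excludes the stalk proteins and the translocase from R1); R_initial /
    R_final are the masked umbrella-coordinate endpoints.  The tRNA anchors
    define the travel axis e_tRNA = unit(r_E^i - r_P^i), pointing in the
    P -> E translocation direction.
    """

    mask: np.ndarray                  # (G,) bool, ratchet subset
    R_initial: np.ndarray             # (Gm, 3)
    R_final: np.ndarray               # (Gm, 3)
    r_P_initial: np.ndarray = None    # (3,)
    r_E_initial: np.ndarray = None    # (3,)
    superpose: bool = True

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)
        self.R_initial = np.asarray(self.R_initial, float).reshape(-1, 3)
        self.R_final = np.asarray(self.R_final, float).reshape(-1, 3)
        if self.R_initial.shape != self.R_final.shape:
            raise ValueError("R_initial and R_final must have equal shapes")
        if self.r_P_initial is not None:
            self.r_P_initial = np.asarray(self.r_P_initial, float).reshape(3)
        if self.r_E_initial is not None:
            self.r_E_initial = np.asarray(self.r_E_initial, float).reshape(3)

    @classmethod
    def from_endpoints(cls, mask, R_initial, R_final,
                       r_P_initial=None, r_E_initial=None,
                       superpose: bool = True) -> "ProjectionFrame":
        """Build a frame from raw endpoint umbrella coordinates.

        When `superpose` is on, the final endpoint is first rigidly
        superposed onto the initial one (unit weights per group) so that
        u_final measures genuine internal progress, not a net rigid offset
        between the endpoint structures — the same treatment every sample
        receives during projection.
        """
        mask = np.asarray(mask, bool)
        Ri = np.asarray(R_initial, float).reshape(-1, 3)[mask[:len(R_initial)]] \
            if len(R_initial) == len(mask) else np.asarray(R_initial, float)
        Rf = np.asarray(R_final, float).reshape(-1, 3)[mask[:len(R_final)]] \
            if len(R_final) == len(mask) else np.asarray(R_final, float)
        if superpose:
            Rf = _superpose_onto(Rf, Ri)
        return cls(mask, Ri, Rf, r_P_initial, r_E_initial, superpose)

    @property
    def u_final(self) -> np.ndarray:
        """Unit vector of vec(R_final - R_initial), flattened."""
        d = (self.R_final - self.R_initial).ravel()
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("R_final coincides with R_initial")
        return d / norm

    @property
    def e_tRNA(self) -> np.ndarray:
        d = self.r_E_initial - self.r_P_initial
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("tRNA anchors coincide")
        return d / norm


def _superpose_onto(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rigid-fit point set X (G,3) onto ref with unit weights."""
    w = np.ones(X.shape[0])
    cx = X.mean(axis=0)
    cr = ref.mean(axis=0)
    Rm = kabsch_rotation(X - cx, ref - cr, w)
    return (X - cx) @ Rm.T + cr


def project_R1(samples: np.ndarray, frame: ProjectionFrame) -> np.ndarray:
    """Ratchet-progress coordinate per sample (A).

    The masked umbrella coordinates are rigidly superposed onto R_initial
    (unit weights per group), then projected:
    R1 = vec(R_ratchet - R_initial) . u_final.
    """
    samples = np.asarray(samples, float)
    single = samples.ndim == 2
    if single:
        samples = samples[None]
    u = frame.u_final
    out = np.empty(samples.shape[0])
    for s in range(samples.shape[0]):
        X = samples[s][frame.mask]
        if frame.superpose:
            X = _superpose_onto(X, frame.R_initial)
        out[s] = (X - frame.R_initial).ravel() @ u
    return out[0] if single else out


def project_R2(r_X, frame: ProjectionFrame) -> float | np.ndarray:
    """Signed travel coordinate of a group (A): the distance of r_X from the
    initial E-site anchor, signed positive when the displacement points in
    the P -> E translocation direction (along e_tRNA)."""
    r_X = np.asarray(r_X, float)
    single = r_X.ndim == 1
    d = r_X.reshape(-1, 3) - frame.r_E_initial[None, :]
    mag = np.linalg.norm(d, axis=1)
    sign = np.where(d @ frame.e_tRNA >= 0, 1.0, -1.0)
    out = sign * mag
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# Profiles and weighted observables
# ---------------------------------------------------------------------------

def profile_1d(solution: WhamSolution, values: np.ndarray, bins):
    """Unbiased free-energy profile F(X) = -kT ln P(X), minimum at zero.

    Returns (bin_centers, F, P) with empty interior bins marked NaN (gaps
    are reported, never interpolated).
    """
    values = np.asarray(values, float)
    edges = np.asarray(bins, float) if np.ndim(bins) else \
        np.linspace(values.min(), values.max(), int(bins) + 1)
    P, _ = np.histogram(values, bins=edges, weights=solution.weights)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        F = -solution.kT * np.log(P)
    F[P == 0] = np.nan
    finite = np.isfinite(F)
    if not finite.any():
        raise ValueError("no samples fall inside the requested bins")
    F -= np.nanmin(F)
    return centers, F, P


def weighted_average(solution: WhamSolution, values: np.ndarray,
                     observable: np.ndarray, bins):
    """Per-bin unbiased weighted mean and RMS deviation of an observable.

    Returns (bin_centers, mean_A, rmsd_A); empty bins are NaN.
    """
    values = np.asarray(values, float)
    A = np.asarray(observable, float)
    edges = np.asarray(bins, float) if np.ndim(bins) else \
        np.linspace(values.min(), values.max(), int(bins) + 1)
    which = np.digitize(values, edges) - 1
    nb = len(edges) - 1
    mean = np.full(nb, np.nan)
    spread = np.full(nb, np.nan)
    w = solution.weights
    for b in range(nb):
        m = which == b
        if not m.any():
            continue
        wb = w[m]
        tot = wb.sum()
        if tot <= 0:
            continue
        mu = float((wb * A[m]).sum() / tot)
        mean[b] = mu
        spread[b] = float(np.sqrt((wb * (A[m] - mu) ** 2).sum() / tot))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, mean, spread


def landscape_2d(solution: WhamSolution, x_values, y_values, x_bins, y_bins):
    """2-D free-energy landscape F(X, Y) = -kT ln P(X, Y), minimum at zero.

    Returns (x_centers, y_centers, F, P).
    """
    x = np.asarray(x_values, float)
    y = np.asarray(y_values, float)
    xe = np.asarray(x_bins, float) if np.ndim(x_bins) else \
        np.linspace(x.min(), x.max(), int(x_bins) + 1)
    ye = np.asarray(y_bins, float) if np.ndim(y_bins) else \
        np.linspace(y.min(), y.max(), int(y_bins) + 1)
    P, _, _ = np.histogram2d(x, y, bins=(xe, ye), weights=solution.weights)
    with np.errstate(divide="ignore"):
        F = -solution.kT * np.log(P)
    F[P == 0] = np.nan
    F -= np.nanmin(F)
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    return xc, yc, F, P
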