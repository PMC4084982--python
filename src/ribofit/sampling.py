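"""Desk-scale dynamics engine: toy structural potentials, the restraint zoo
(center-of-mass umbrellas, flat-bottom distances, RMSD caps, steering
harmonics), a BAOAB Langevin integrator, steepest-descent minimization, and
the windowed EM-fitting + umbrella-sampling protocol.

Conventions
-----------
Units are kcal/mol, Angstrom, picosecond, amu; k_B = 1.987204e-3 kcal/mol/K.
Umbrella / center-of-mass restraints use V = k |dr|^2 (so k = 1.0
kcal/mol/A^2 reproduces the reference umbrella stiffness); steering
restraints quoted in pN/A use V = (1/2) k |dr|^2 so that force = k * dr.
The functional form is recorded with every window and consumed verbatim by
the WHAM stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import units
from .density import DensityMap, EMFitParams, correlation_coefficient, \
    em_force, scale_weight, synthesize_map
from .structure import AtomicModel, kabsch_rotation

_FCONV = units.FORCE_TO_AMU_A_PS2


# ---------------------------------------------------------------------------
# Potentials
# ---------------------------------------------------------------------------

@dataclass
class HarmonicBond:
    """V = 1/2 k (r - r0)^2 between atoms i and j."""
    i: int
    j: int
    k: float
    r0: float


@dataclass
class SoftRepulsion:
    """Purely repulsive V = eps (sigma/r)^12 between atoms i and j."""
    i: int
    j: int
    eps: float
    sigma: float


class ExternalField:
    """Per-atom analytic external potential acting on an index set.

    `fn(coords_subset) -> (energy, forces_subset)` where forces are
    -dV/dr in kcal/mol/A.
    """

    def __init__(self, indices, fn):
        self.indices = np.asarray(indices, dtype=int)
        self.fn = fn

    def energy_forces(self, coords):
        e, f = self.fn(coords[self.indices])
        out = np.zeros_like(coords)
        out[self.indices] = f
        return e, out


class ToyPotential:
    """Stand-in structural potential: harmonic bonds, soft-core repulsions,
    and arbitrary external field terms."""

    def __init__(self, bonds=(), repulsions=(), fields=()):
        self.bonds = list(bonds)
        self.repulsions = list(repulsions)
        self.fields = list(fields)
        self._bond_ij = np.array([[b.i, b.j] for b in self.bonds], int).reshape(-1, 2)
        self._bond_k = np.array([b.k for b in self.bonds], float)
        self._bond_r0 = np.array([b.r0 for b in self.bonds], float)
        self._rep_ij = np.array([[r.i, r.j] for r in self.repulsions], int).reshape(-1, 2)
        self._rep_eps = np.array([r.eps for r in self.repulsions], float)
        self._rep_sig = np.array([r.sigma for r in self.repulsions], float)

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = np.asarray(coords, float)
        energy = 0.0
        forces = np.zeros_like(coords)
        if len(self.bonds):
            d = coords[self._bond_ij[:, 1]] - coords[self._bond_ij[:, 0]]
            r = np.linalg.norm(d, axis=1)
            dr = r - self._bond_r0
            energy += float(0.5 * (self._bond_k * dr * dr).sum())
            # force on j = -k (r - r0) * d/r
            fij = (-self._bond_k * dr / np.maximum(r, 1e-12))[:, None] * d
            np.add.at(forces, self._bond_ij[:, 1], fij)
            np.add.at(forces, self._bond_ij[:, 0], -fij)
        if len(self.repulsions):
            d = coords[self._rep_ij[:, 1]] - coords[self._rep_ij[:, 0]]
            r = np.linalg.norm(d, axis=1)
            sr = self._rep_sig / np.maximum(r, 1e-12)
            e12 = self._rep_eps * sr ** 12
            energy += float(e12.sum())
            fij = (12.0 * e12 / np.maximum(r, 1e-12) ** 2)[:, None] * d
            np.add.at(forces, self._rep_ij[:, 1], fij)
            np.add.at(forces, self._rep_ij[:, 0], -fij)
        for fld in self.fields:
            e, f = fld.energy_forces(coords)
            energy += e
            forces += f
        if not math.isfinite(energy):
            raise FloatingPointError("non-finite potential energy")
        return energy, forces


# ---------------------------------------------------------------------------
# Restraints
# ---------------------------------------------------------------------------

class Restraint:
    def energy_forces(self, coords):  # pragma: no cover - interface
        raise NotImplementedError


class COMHarmonic(Restraint):
    """Harmonic restraint on a group's center of mass.

    form="k_dr2": V = k |R - c|^2 (umbrella convention, k in kcal/mol/A^2).
    form="half_k_dr2": V = 1/2 k |R - c|^2 (steering convention).
    """

    def __init__(self, indices, masses, center, k, form="k_dr2"):
        if form not in ("k_dr2", "half_k_dr2"):
            raise ValueError(f"unknown form {form!r}")
        self.indices = np.asarray(indices, int)
        m = np.asarray(masses, float)[self.indices]
        self.weights = m / m.sum()
        self.center = np.asarray(center, float).reshape(3)
        self.k = float(k)
        self.form = form

    def com(self, coords):
        return (self.weights[:, None] * coords[self.indices]).sum(axis=0)

    def energy_forces(self, coords):
        d = self.com(coords) - self.center
        pref = 1.0 if self.form == "k_dr2" else 0.5
        e = pref * self.k * float(d @ d)
        # dV/dR = 2*pref*k*d ; chain through COM weights
        g = 2.0 * pref * self.k * d
        f = np.zeros_like(coords)
        f[self.indices] = -self.weights[:, None] * g[None, :]
        return e, f


class PositionalHarmonic(Restraint):
    """V = k sum_i |r_i - r_i^0|^2 over an atom set."""

    def __init__(self, indices, reference, k):
        self.indices = np.asarray(indices, int)
        self.reference = np.asarray(reference, float).reshape(-1, 3)
        self.k = float(k)

    def energy_forces(self, coords):
        d = coords[self.indices] - self.reference
        e = self.k * float((d * d).sum())
        f = np.zeros_like(coords)
        f[self.indices] = -2.0 * self.k * d
        return e, f


class FlatBottomDistance(Restraint):
    """Zero inside |d - d0| <= tol; V = k (|d - d0| - tol)^2 outside.

    The default 0.1 A tolerance matches the hydrogen-bond restraint width
    used during path-search fitting.
    """

    def __init__(self, i, j, d0, k, tol=0.1):
        self.i, self.j = int(i), int(j)
        self.d0, self.k, self.tol = float(d0), float(k), float(tol)

    def energy_forces(self, coords):
        d = coords[self.j] - coords[self.i]
        r = float(np.linalg.norm(d))
        dev = r - self.d0
        f = np.zeros_like(coords)
        if abs(dev) <= self.tol or r < 1e-12:
            return 0.0, f
        excess = dev - math.copysign(self.tol, dev)
        e = self.k * excess * excess
        g = 2.0 * self.k * excess * d / r
        f[self.j] = -g
        f[self.i] = g
        return e, f


class RMSDRestraint(Restraint):
    """Zero at RMSD <= limit; V = k (RMSD - limit)^2 beyond.

    RMSD is computed directly against the stored reference (no re-fitting;
    the reference lives in the simulation frame).  Default limit 1 A matches
    the cap applied to tRNAs and the EF-G lever domain between windows.
    """

    def __init__(self, indices, reference, k, limit=1.0):
        self.indices = np.asarray(indices, int)
        self.reference = np.asarray(reference, float).reshape(-1, 3)
        self.k = float(k)
        self.limit = float(limit)

    def energy_forces(self, coords):
        d = coords[self.indices] - self.reference
        n = d.shape[0]
        msd = float((d * d).sum()) / n
        r = math.sqrt(msd)
        f = np.zeros_like(coords)
        if r <= self.limit or r < 1e-12:
            return 0.0, f
        excess = r - self.limit
        e = self.k * excess * excess
        # dRMSD/dr_i = d_i / (n * RMSD)
        f[self.indices] = -2.0 * self.k * excess * d / (n * r)
        return e, f


def total_energy_forces(coords, potential, restraints):
    e, f = potential.energy_forces(coords)
    for r in restraints:
        er, fr = r.energy_forces(coords)
        e += er
        f += fr
    return e, f


# ---------------------------------------------------------------------------
# Integrator
# ---------------------------------------------------------------------------

@dataclass
class SimState:
    coords: np.ndarray
    velocities: np.ndarray   # A/ps
    time: float = 0.0

    def copy(self):
        return SimState(self.coords.copy(), self.velocities.copy(), self.time)


def thermal_velocities(masses, temperature, rng) -> np.ndarray:
    """Maxwell-Boltzmann velocities (A/ps)."""
    kT = units.thermal_energy(temperature) * _FCONV   # amu A^2/ps^2
    sig = np.sqrt(kT / np.asarray(masses, float))
    return rng.standard_normal((len(masses), 3)) * sig[:, None]


def remove_rigid_motion(coords, velocities, reference, masses):
    """Superpose `coords` onto `reference` (mass-weighted, all atoms) and
    rotate velocities accordingly: removes accumulated net translation and
    rotation of the whole system, the way production protocols null the
    complex's systematic rigid drift."""
    w = masses
    cx = (w[:, None] * coords).sum(0) / w.sum()
    cr = (w[:, None] * reference).sum(0) / w.sum()
    R = kabsch_rotation(coords - cx, reference - cr, w)
    new_coords = (coords - cx) @ R.T + cr
    new_vel = velocities @ R.T
    return new_coords, new_vel


def run_dynamics(state: SimState, masses, potential, restraints,
                 n_steps: int, dt: float, temperature: float,
                 friction: float, rng,
                 em_force_fn=None, em_stride: int = 4,
                 callback=None, rigid_reference=None,
                 rigid_stride: int = 20) -> SimState:
    """BAOAB Langevin dynamics.

    `em_force_fn(coords) -> forces` supplies the (already scaled) density
    force; it is treated as a slow force and recomputed every `em_stride`
    steps, mirroring the multiple-time-step treatment of density fitting.
    friction = 0 recovers velocity Verlet (the symplectic limit).
    When `rigid_reference` coordinates are given, the system's net rigid
    motion relative to them is removed every `rigid_stride` steps.
    """
    masses = np.asarray(masses, float)
    x = state.coords.copy()
    v = state.velocities.copy()
    inv_m = (1.0 / masses)[:, None]
    kT = units.thermal_energy(temperature) * _FCONV
    if friction > 0:
        c1 = math.exp(-friction * dt)
        c2 = math.sqrt(kT * (1.0 - c1 * c1))
    else:
        c1, c2 = 1.0, 0.0
    sig = c2 / np.sqrt(masses)[:, None]

    def forces_at(coords, em_cache):
        e, f = total_energy_forces(coords, potential, restraints)
        if em_cache is not None:
            f = f + em_cache
        if not np.all(np.isfinite(f)):
            bad = np.flatnonzero(~np.isfinite(f).all(axis=1))
            raise FloatingPointError(
                f"non-finite force on atoms {bad[:5].tolist()}")
        return f * _FCONV  # amu A / ps^2

    em_cache = em_force_fn(x) if em_force_fn is not None else None
    a = forces_at(x, em_cache) * inv_m
    for step in range(n_steps):
        v = v + 0.5 * dt * a
        x = x + 0.5 * dt * v
        if friction > 0:
            v = c1 * v + sig * rng.standard_normal(v.shape)
        x = x + 0.5 * dt * v
        if rigid_reference is not None and (step + 1) % rigid_stride == 0:
            x, v = remove_rigid_motion(x, v, rigid_reference, masses)
        if em_force_fn is not None and (step + 1) % em_stride == 0:
            em_cache = em_force_fn(x)
        a = forces_at(x, em_cache) * inv_m
        v = v + 0.5 * dt * a
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite coordinates during dynamics")
        if callback is not None:
            callback(step, x, v)
    return SimState(x, v, state.time + n_steps * dt)


def minimize(coords, potential, restraints=(), max_steps: int = 1000,
             step0: float = 0.05, gtol: float = 1e-6):
    """Steepest descent with backtracking line search.

    Returns ``(coords, energy, converged)``; energy never increases across
    accepted steps.
    """
    x = np.asarray(coords, float).copy()
    e, f = total_energy_forces(x, potential, restraints)
    step = step0
    for _ in range(max_steps):
        gnorm = float(np.abs(f).max())
        if gnorm < gtol:
            return x, e, True
        d = f / max(np.linalg.norm(f, axis=1).max(), 1e-12)
        accepted = False
        for _ in range(30):
            x_new = x + step * d
            try:
                e_new, f_new = total_energy_forces(x_new, potential, restraints)
            except FloatingPointError:
                step *= 0.5
                continue
            if e_new <= e:
                x, e, f = x_new, e_new, f_new
                step = min(step * 1.2, 1.0)
                accepted = True
                break
            step *= 0.5
        if not accepted:
            return x, e, False
    return x, e, False


# ---------------------------------------------------------------------------
# Window protocol
# ---------------------------------------------------------------------------

def adapt_w_em(prev_shift, w_em: float, cap: float = 0.60,
               bounds: tuple[float, float] = (1.0e-7, 1.0e-4)) -> float:
    """Multiplicative w_EM controller for the per-window displacement cap.

    Doubles w_EM when the largest umbrella-coordinate shift in the previous
    fitting phase was below cap/2, halves it when the shift exceeded the cap
    (0.60 A by default), and clips to the schedule bounds.
    """
    shift = float(np.max(prev_shift)) if np.ndim(prev_shift) else float(prev_shift)
    if shift > cap:
        w_em *= 0.5
    elif shift < cap / 2.0:
        w_em *= 2.0
    return float(np.clip(w_em, bounds[0], bounds[1]))


@dataclass
class WindowProtocol:
    """Schedule of one EM-fitting + umbrella-sampling window.

    Step counts are desk-scale stand-ins for the reference protocol's
    nanosecond phases; the restart_fraction generalizes "restart from the
    configuration midway through the previous sampling phase".
    """

    em_steps: int = 300
    equil_steps: int = 200
    sample_steps: int = 400
    dt: float = 0.01                 # ps
    temperature: float = 300.0       # K
    friction: float = 5.0            # 1/ps
    em_friction: float | None = None # fitting-phase friction (defaults to friction)
    sample_stride: int = 5
    restart_fraction: float = 0.5
    umbrella_k: float = 1.0          # kcal/mol/A^2, V = k |dr|^2
    umbrella_form: str = "k_dr2"
    displacement_cap: float = 0.60   # A per fitting phase
    w_em_bounds: tuple = (1.0e-7, 1.0e-4)
    em_stride: int = 4
    max_retries: int = 3
    remove_rigid_drift: bool = True   # null the complex's net rigid motion


@dataclass
class WindowRecord:
    index: int
    bias_centers: np.ndarray         # (G, 3)
    bias_k: np.ndarray               # (G,)
    bias_form: str
    samples: np.ndarray              # (n_samples, G, 3) umbrella coordinates
    w_em: float
    cc_start: float | None
    cc_fit: float | None             # CC right after the EM-fitting phase
    cc_end: float | None
    fitting_shift: np.ndarray        # (G,) per-group COM shift in fit phase
    restart_state: SimState = None
    final_state: SimState = None
    group_names: tuple = ()
    extra_samples: np.ndarray | None = None   # (n_samples, Gx, 3) observables
    extra_group_names: tuple = ()

    def bias_energies(self, samples=None, temperature=None) -> np.ndarray:
        """Recompute total bias energy for each stored sample (kcal/mol)."""
        R = self.samples if samples is None else samples
        d2 = ((R - self.bias_centers[None]) ** 2).sum(axis=2)
        pref = 1.0 if self.bias_form == "k_dr2" else 0.5
        return pref * (d2 * self.bias_k[None, :]).sum(axis=1)


def _group_coms(coords, groups, masses):
    out = np.empty((len(groups), 3))
    for g, idx in enumerate(groups):
        m = masses[idx]
        out[g] = (m[:, None] * coords[idx]).sum(0) / m.sum()
    return out


def run_window(model: AtomicModel, state: SimState, potential,
               umbrella_groups: dict[str, np.ndarray],
               exp_map: DensityMap | None, fit_params: EMFitParams | None,
               protocol: WindowProtocol, rng,
               index: int = 0,
               prev: WindowRecord | None = None,
               steering_restraints=(), extra_restraints=(),
               em_exclude: np.ndarray | None = None,
               observable_groups: dict | None = None) -> WindowRecord:
    """Execute one window: EM-fitting phase (density force on, steering
    optional), then umbrella centers are pinned at the current group centers
    of mass, the system is equilibrated (steering ramped off), and umbrella
    coordinates are sampled.

    The fitting phase is retried with halved w_EM if any umbrella coordinate
    moves more than the displacement cap; persistent violation aborts.
    """
    names = list(umbrella_groups)
    groups = [np.asarray(umbrella_groups[n], int) for n in names]
    obs_names = list(observable_groups) if observable_groups else []
    obs_groups = [np.asarray(observable_groups[n], int) for n in obs_names]
    masses = model.masses
    start_coms = _group_coms(state.coords, groups, masses)

    def cc_of(coords):
        if exp_map is None:
            return None
        m2 = model.copy()
        m2.coords = coords
        sim = synthesize_map(m2, exp_map.origin, exp_map.spacing, exp_map.dims,
                             fit_params.resolution, fit_params.n_neighbor)
        return correlation_coefficient(sim, exp_map)

    cc_start = cc_of(state.coords)
    w_em = fit_params.w_em if fit_params is not None else 0.0
    rigid_ref = state.coords.copy() if protocol.remove_rigid_drift else None

    # --- EM-fitting phase ------------------------------------------------
    fit_state = state
    shifts = np.zeros(len(groups))
    for attempt in range(protocol.max_retries + 1):
        if exp_map is not None and w_em > 0:
            _, f_str = total_energy_forces(state.coords, potential,
                                           tuple(extra_restraints))
            shim = model.copy()

            def em_fn(coords, _shim=shim):
                _shim.coords = coords
                f_em_unit = em_force(_shim, exp_map,
                                     EMFitParams(fit_params.resolution,
                                                 fit_params.n_neighbor,
                                                 w_em, 1.0))
                try:
                    k_em = scale_weight(f_em_unit, f_str, w_em)
                except ValueError:
                    return np.zeros_like(coords)
                f = k_em * f_em_unit
                if em_exclude is not None:
                    f[em_exclude] = 0.0
                return f
        else:
            em_fn = None
        fit_state = run_dynamics(
            state.copy(), masses, potential,
            tuple(extra_restraints) + tuple(steering_restraints),
            protocol.em_steps, protocol.dt, protocol.temperature,
            protocol.em_friction or protocol.friction,
            np.random.default_rng(rng.integers(2 ** 31)),
            em_force_fn=em_fn, em_stride=protocol.em_stride,
            rigid_reference=rigid_ref)
        shifts = np.linalg.norm(
            _group_coms(fit_state.coords, groups, masses) - start_coms, axis=1)
        if shifts.max() <= protocol.displacement_cap or em_fn is None:
            break
        if attempt == protocol.max_retries:
            raise RuntimeError(
                f"umbrella displacement cap {protocol.displacement_cap} A "
                f"violated after {protocol.max_retries} retries "
                f"(max shift {shifts.max():.3f} A)")
        w_em *= 0.5

    cc_fit = cc_of(fit_state.coords)

    # --- umbrella setup + equilibration (steering ramped off) ------------
    centers = _group_coms(fit_state.coords, groups, masses)
    k_arr = np.full(len(groups), protocol.umbrella_k)
    umbrellas = [COMHarmonic(g, masses, centers[i], protocol.umbrella_k,
                             protocol.umbrella_form)
                 for i, g in enumerate(groups)]

    eq_state = fit_state
    if steering_restraints and protocol.equil_steps > 0:
        # linear ramp-down of steering stiffness over the equilibration
        n_seg = 4
        seg = max(protocol.equil_steps // n_seg, 1)
        k0 = [s.k for s in steering_restraints]
        for s_i in range(n_seg):
            lam = 1.0 - (s_i + 1) / n_seg
            for s, k in zip(steering_restraints, k0):
                s.k = k * lam
            eq_state = run_dynamics(
                eq_state, masses, potential,
                tuple(extra_restraints) + tuple(umbrellas)
                + tuple(steering_restraints),
                seg, protocol.dt, protocol.temperature, protocol.friction,
                np.random.default_rng(rng.integers(2 ** 31)),
                rigid_reference=rigid_ref)
        for s, k in zip(steering_restraints, k0):
            s.k = k
    elif protocol.equil_steps > 0:
        eq_state = run_dynamics(
            eq_state, masses, potential,
            tuple(extra_restraints) + tuple(umbrellas),
            protocol.equil_steps, protocol.dt, protocol.temperature,
            protocol.friction, np.random.default_rng(rng.integers(2 ** 31)),
            rigid_reference=rigid_ref)

    # --- sampling ---------------------------------------------------------
    samples = []
    extra = []
    restart_idx = int(protocol.sample_steps * protocol.restart_fraction)
    restart_box = {}

    def record(step, x, v):
        if (step + 1) % protocol.sample_stride == 0:
            samples.append(_group_coms(x, groups, masses))
            if obs_groups:
                extra.append(_group_coms(x, obs_groups, masses))
        if step + 1 == restart_idx:
            restart_box["state"] = SimState(x.copy(), v.copy())

    final_state = run_dynamics(
        eq_state, masses, potential, tuple(extra_restraints) + tuple(umbrellas),
        protocol.sample_steps, protocol.dt, protocol.temperature,
        protocol.friction, np.random.default_rng(rng.integers(2 ** 31)),
        callback=record, rigid_reference=rigid_ref)
    cc_end = cc_of(final_state.coords)
    return WindowRecord(
        index=index, bias_centers=centers, bias_k=k_arr,
        bias_form=protocol.umbrella_form,
        samples=np.array(samples), w_em=w_em,
        cc_start=cc_start, cc_fit=cc_fit, cc_end=cc_end,
        fitting_shift=shifts,
        restart_state=restart_box.get("state", final_state),
        final_state=final_state, group_names=tuple(names),
        extra_samples=np.array(extra) if extra else None,
        extra_group_names=tuple(obs_names))
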