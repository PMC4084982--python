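"""Synthetic fixtures with known answers.

Three generators give every stage of the pipeline a desk-scale, statistically
controlled input:

- a two-body "ratchet" bead assembly whose small body rotates against a
  large body, whose head sub-group can swivel in the tRNA-travel plane, and
  whose two tRNA bead groups can translocate, with gate-analogue beads
  mirroring the A790 / G1338-A1339 construction;
- density maps of the assembly's conformational states at a stated
  resolution (optionally with noise, clamped non-negative);
- reference landscapes with closed-form free energies, and exact Monte-Carlo
  umbrella datasets drawn from their biased Boltzmann densities, so the
  WHAM stack is testable independently of the dynamics engine.

All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .density import clamp_negative, synthesize_map
from .sampling import ExternalField, HarmonicBond, ToyPotential
from .structure import AtomicModel
from .units import thermal_energy
from .wham import UmbrellaDataset, UmbrellaWindow


# ---------------------------------------------------------------------------
# Toy ribosome assembly
# ---------------------------------------------------------------------------

@dataclass
class ToyRibosomeSpec:
    """Geometry and stiffness of the toy ratchet assembly.

    Amplitudes mirror the scale of the real transition: an intersubunit
    rotation of a few degrees, a head swivel of ~10 degrees, and a tRNA
    travel of ~15 A between the classical and hybrid positions, with the
    gate opening by ~8 A between the closed (POST) and open (PRE) states.
    """

    n_large: int = 260
    n_small: int = 170
    n_head: int = 80
    n_trna: int = 16             # beads per tRNA group
    n_gate: int = 3              # beads per gate residue analogue
    k_intra: float = 15.0        # kcal/mol/A^2, bonds within a group
    k_inter: float = 0.3         # kcal/mol/A^2, springs between groups
    ratchet_amplitude: float = 7.0   # deg, measured intersubunit rotation
    head_amplitude: float = 10.0     # deg, measured clockwise head swivel
    trna_travel: float = 15.0        # A, tRNA displacement POST -> PRE
    gate_opening: float = 8.0        # A, extra gate width in the PRE state
    seed: int = 0


@dataclass
class ToyRibosome:
    spec: ToyRibosomeSpec
    model: AtomicModel                 # POST-state model with group tags
    potential: ToyPotential
    endpoints: dict                    # name -> AtomicModel (POST/INT/PRE)
    umbrella_groups: dict              # name -> atom index array
    e_ratchet: np.ndarray              # unit, small COM -> large COM
    e_tRNA: np.ndarray                 # unit, P site -> E site

    def ratchet_mask(self) -> np.ndarray:
        """Boolean mask over umbrella groups for the ratchet-progress
        projection: everything except the tRNA cargo groups (the analogue
        of excluding the factor/stalk groups from the ratchet subset)."""
        return np.array([not n.startswith("tRNA")
                         for n in self.umbrella_groups])


def _ellipsoid_cloud(rng, n, center, semi_axes):
    pts = []
    while len(pts) < n:
        p = rng.uniform(-1.0, 1.0, size=3)
        if (p ** 2).sum() <= 1.0:
            pts.append(center + p * semi_axes)
    return np.array(pts)


def _nearest_neighbor_bonds(coords, indices, k, n_neighbors=3):
    sub = coords[indices]
    n = len(indices)
    uniq = {}
    for a in range(n):
        d = np.linalg.norm(sub - sub[a], axis=1)
        for b in np.argsort(d)[1:n_neighbors + 1]:
            i, j = int(indices[a]), int(indices[int(b)])
            if i > j:
                i, j = j, i
            uniq[(i, j)] = float(d[b])
    return [HarmonicBond(i, j, k, r0) for (i, j), r0 in sorted(uniq.items())]


def _bridge_bonds(coords, idx_a, idx_b, k, n_pairs):
    d = np.linalg.norm(coords[idx_a][:, None, :] - coords[idx_b][None, :, :],
                       axis=2)
    flat = np.argsort(d, axis=None)[:n_pairs]
    out = []
    for f in flat:
        a, b = np.unravel_index(f, d.shape)
        out.append(HarmonicBond(int(idx_a[a]), int(idx_b[b]), k, float(d[a, b])))
    return out


def _rotate_about(coords, indices, axis, angle_deg, pivot):
    R = Rotation.from_rotvec(np.radians(angle_deg) * np.asarray(axis, float))
    out = coords.copy()
    out[indices] = R.apply(coords[indices] - pivot) + pivot
    return out


def make_toy_ribosome(spec: ToyRibosomeSpec | None = None) -> ToyRibosome:
    """Build the toy assembly, its structural potential, and the POST / INT /
    PRE endpoint conformations.

    Endpoint construction (POST is the base geometry):

    - INT: the head (plus its gate loop) swivels by `head_amplitude` in the
      (e_tRNA, e_ratchet) plane — a pure swivel, so the measured head angle
      reproduces the amplitude exactly;
    - PRE: the small subunit (body, head, gate beads) rotates about the
      intersubunit axis so the measured ratchet angle equals
      `ratchet_amplitude`; the tRNA groups travel `trna_travel` against the
      P->E direction (reverse translocation); the body-side gate analogue
      moves `gate_opening` further from the loop.
    """
    spec = spec or ToyRibosomeSpec()
    rng = np.random.default_rng(spec.seed)

    blocks = {}
    coords = []
    names, resnames, resnums, chains = [], [], [], []

    def add_block(name, pts, chain, resname, resnum0, per_atom_resnum=True):
        start = len(coords)
        for p in pts:
            coords.append(p)
            names.append("C")
            resnames.append(resname)
            resnums.append(resnum0 + (len(coords) - start - 1
                                      if per_atom_resnum else 0))
            chains.append(chain)
        blocks[name] = np.arange(start, len(coords))

    add_block("large_body",
              _ellipsoid_cloud(rng, spec.n_large, np.zeros(3),
                               np.array([16.0, 13.0, 11.0])),
              "L", "LBD", 1)
    add_block("small_body",
              _ellipsoid_cloud(rng, spec.n_small, np.array([0.0, 0.0, 26.0]),
                               np.array([13.0, 11.0, 8.0])),
              "S", "SBD", 1)
    # gate analogues: body-side nucleotide and the head-side loop; block
    # order keeps each chain identifier contiguous in the atom order
    add_block("gate_A790",
              np.array([-2.0, -4.5, 23.0]) + rng.normal(0, 0.8, (spec.n_gate, 3)),
              "S", "GBD", 790, per_atom_resnum=False)
    add_block("head",
              _ellipsoid_cloud(rng, spec.n_head, np.array([0.0, 9.0, 34.0]),
                               np.array([8.0, 5.0, 3.5])),
              "H", "HED", 1)
    add_block("gate_G1338",
              np.array([-2.0, 6.5, 29.0]) + rng.normal(0, 0.8, (spec.n_gate, 3)),
              "H", "GLP", 1338, per_atom_resnum=False)
    add_block("gate_A1339",
              np.array([0.0, 7.0, 29.5]) + rng.normal(0, 0.8, (spec.n_gate, 3)),
              "H", "GLP", 1339, per_atom_resnum=False)
    add_block("tRNA_P",
              _ellipsoid_cloud(rng, spec.n_trna, np.array([4.0, 2.0, 15.0]),
                               np.array([2.5, 2.5, 4.0])),
              "P", "TRN", 1)
    add_block("tRNA_E",
              _ellipsoid_cloud(rng, spec.n_trna, np.array([-5.0, 2.0, 15.0]),
                               np.array([2.5, 2.5, 4.0])),
              "E", "TRN", 1)

    # anticodon analogues: light sub-groups the path search can steer
    blocks["anticodon_P"] = blocks["tRNA_P"][:5]
    blocks["anticodon_E"] = blocks["tRNA_E"][:5]

    coords = np.array(coords)
    n = len(coords)
    masses = rng.uniform(12.0, 32.0, size=n)
    model = AtomicModel(
        names=np.array(names), elements=np.array(["C"] * n),
        resnames=np.array(resnames), resnums=np.array(resnums),
        chains=np.array(chains), coords=coords, masses=masses,
        groups=dict(blocks))

    def com(idx):
        m = masses[idx]
        return (m[:, None] * coords[idx]).sum(0) / m.sum()

    e_ratchet = com(blocks["large_body"]) - com(blocks["small_body"])
    e_ratchet /= np.linalg.norm(e_ratchet)
    e_tRNA = com(blocks["tRNA_E"]) - com(blocks["tRNA_P"])
    e_tRNA /= np.linalg.norm(e_tRNA)

    # --- endpoints -------------------------------------------------------
    plane_normal = np.cross(e_tRNA, e_ratchet)
    plane_normal /= np.linalg.norm(plane_normal)
    head_idx = np.concatenate([blocks["head"], blocks["gate_G1338"],
                               blocks["gate_A1339"]])
    small_all = np.concatenate([blocks["small_body"], head_idx,
                                blocks["gate_A790"]])

    # INT: pure head swivel (clockwise-positive convention -> rotate by
    # -amplitude about the plane normal)
    int_coords = _rotate_about(coords, head_idx, plane_normal,
                               -spec.head_amplitude, com(blocks["head"]))

    # PRE: intersubunit rotation + reverse tRNA travel + gate opening
    pre_coords = _rotate_about(coords, small_all, e_ratchet,
                               -spec.ratchet_amplitude,
                               com(blocks["small_body"]))
    for trna in ("tRNA_P", "tRNA_E"):
        pre_coords[blocks[trna]] = _rotate_about(
            coords, blocks[trna], e_ratchet, -spec.ratchet_amplitude,
            com(blocks["small_body"]))[blocks[trna]] \
            - spec.trna_travel * e_tRNA
    gate_dir = com(blocks["gate_A790"]) - 0.5 * (com(blocks["gate_G1338"])
                                                 + com(blocks["gate_A1339"]))
    gate_dir /= np.linalg.norm(gate_dir)
    pre_coords[blocks["gate_A790"]] += spec.gate_opening * gate_dir

    def as_model(c):
        out = model.copy()
        out.coords = c.copy()
        return out

    endpoints = {"POST": as_model(coords), "INT": as_model(int_coords),
                 "PRE": as_model(pre_coords)}

    # --- potential -------------------------------------------------------
    # intra-group bonds anchor each group's shape (rest length = POST
    # geometry, which the endpoint construction preserves rigidly);
    # inter-group bridges get rest lengths midway between the POST and PRE
    # distances so the structural potential favors neither endpoint.
    bonds = []
    for name in ("large_body", "small_body", "head", "tRNA_P", "tRNA_E",
                 "gate_A790", "gate_G1338", "gate_A1339"):
        bonds += _nearest_neighbor_bonds(coords, blocks[name], spec.k_intra)
    bridges = []
    bridges += _bridge_bonds(coords, blocks["large_body"],
                             blocks["small_body"], spec.k_inter, 12)
    bridges += _bridge_bonds(coords, blocks["small_body"], blocks["head"],
                             spec.k_inter, 8)
    bridges += _bridge_bonds(coords, blocks["small_body"],
                             blocks["gate_A790"], spec.k_inter, 3)
    bridges += _bridge_bonds(coords, blocks["head"], blocks["gate_G1338"],
                             spec.k_inter, 3)
    bridges += _bridge_bonds(coords, blocks["head"], blocks["gate_A1339"],
                             spec.k_inter, 3)
    for trna in ("tRNA_P", "tRNA_E"):
        bridges += _bridge_bonds(coords, blocks["small_body"], blocks[trna],
                                 0.2 * spec.k_inter, 2)
    for b in bridges:
        r_pre = float(np.linalg.norm(pre_coords[b.j] - pre_coords[b.i]))
        b.r0 = 0.5 * (b.r0 + r_pre)
    potential = ToyPotential(bonds=bonds + bridges)

    # umbrella groups: bodies split into sub-groups + head + tRNAs
    umb = {}
    for part, splits in (("large_body", 3), ("small_body", 2)):
        idx = blocks[part]
        for s, chunk in enumerate(np.array_split(idx, splits)):
            umb[f"{part}_{s}"] = chunk
    umb["head"] = blocks["head"]
    umb["tRNA_P"] = blocks["tRNA_P"]
    umb["tRNA_E"] = blocks["tRNA_E"]

    return ToyRibosome(spec=spec, model=endpoints["POST"], potential=potential,
                       endpoints=endpoints, umbrella_groups=umb,
                       e_ratchet=e_ratchet, e_tRNA=e_tRNA)


def make_transition_field(post_coords, pre_coords, indices,
                          barrier: float, min_displacement: float = 0.5,
                          k_perp: float = 0.05, weighting: str = "squared"):
    """Double-well external field along each moving atom's POST -> PRE
    displacement line, with minima at both endpoints and a total barrier
    (kcal/mol) summed over the affected atoms.

    Only atoms displaced more than `min_displacement` participate.  The
    per-atom well is quartic in the normalized line coordinate s in [-1, 1]:
    U = h_i (s^2 - 1)^2 with s = 2 (d - L/2)/L, plus a weak transverse
    tether k_perp |r_perp|^2 (kcal/mol/A^2) that keeps each atom near its
    displacement line so the transition path is well defined.

    weighting="squared" distributes the barrier over atoms proportionally to
    the squared displacement L_i^2 (the far-travelling cargo gets the deep
    wells, mimicking work done along the path); "uniform" splits it evenly.
    """
    post_coords = np.asarray(post_coords, float)
    pre_coords = np.asarray(pre_coords, float)
    indices = np.asarray(indices, int)
    disp = pre_coords[indices] - post_coords[indices]
    L = np.linalg.norm(disp, axis=1)
    active = L > min_displacement
    idx = indices[active]
    if idx.size == 0:
        raise ValueError("no atoms move enough for a transition field")
    u = disp[active] / L[active, None]
    L = L[active]
    anchors = post_coords[idx]
    if weighting == "squared":
        h = barrier * L ** 2 / (L ** 2).sum()
    elif weighting == "uniform":
        h = np.full(idx.size, barrier / idx.size)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    def fn(sub):
        rel = sub - anchors
        d = (rel * u).sum(axis=1)                     # progress along the line
        s = 2.0 * (d - 0.5 * L) / L                   # -1 at POST, +1 at PRE
        e = float((h * (s * s - 1.0) ** 2).sum())
        dE_dd = h * 4.0 * s * (s * s - 1.0) * (2.0 / L)
        f = -dE_dd[:, None] * u
        perp = rel - d[:, None] * u
        e += float(k_perp * (perp * perp).sum())
        f -= 2.0 * k_perp * perp
        return e, f

    return ExternalField(idx, fn)


# ---------------------------------------------------------------------------
# State maps
# ---------------------------------------------------------------------------

def make_state_maps(endpoints: dict, resolution: float = 11.0,
                    spacing: float = 2.5, margin: float = 14.0,
                    n_neighbor: int = 4, noise_sigma: float = 0.0,
                    seed: int = 0) -> dict:
    """One density map per endpoint conformation, on a common grid covering
    all endpoints.  Optional additive Gaussian noise (std as a fraction of
    the peak density) with negative values clamped, emulating experimental
    maps."""
    all_coords = np.concatenate([m.coords for m in endpoints.values()])
    lo = all_coords.min(axis=0) - margin
    hi = all_coords.max(axis=0) + margin
    sp = np.full(3, float(spacing))
    dims = tuple(int(np.ceil((hi[a] - lo[a]) / sp[a])) + 1 for a in range(3))
    rng = np.random.default_rng(seed)
    maps = {}
    for name, m in endpoints.items():
        d = synthesize_map(m, lo, sp, dims, resolution, n_neighbor)
        if noise_sigma > 0:
            d.values = d.values + rng.normal(
                0.0, noise_sigma * d.values.max(), size=d.values.shape)
            d = clamp_negative(d)
        maps[name] = d
    return maps


# ---------------------------------------------------------------------------
# Reference landscapes
# ---------------------------------------------------------------------------

class ReferenceLandscape:
    """Analytic potential with a closed-form free-energy profile.

    For a 1-D coordinate the unbiased density is p(x) ~ exp(-U(x)/kT), so
    F(x) = U(x) up to a constant; the evaluator returns U(x) - min U over
    the queried points.
    """

    def __init__(self, kind: str, params: dict, temperature: float = 300.0):
        self.kind = kind
        self.params = dict(params)
        self.temperature = float(temperature)
        if kind == "harmonic":
            self._a = float(params["k"])         # U = k x^2
            self.dim = 1
        elif kind == "double_well":
            self._a = float(params["a"])         # U = a (x^2 - b^2)^2
            self._b = float(params["b"])
            self.dim = 1
        elif kind == "separable_2d":
            self.part_x = ReferenceLandscape(params["x"]["kind"],
                                             params["x"], temperature)
            self.part_y = ReferenceLandscape(params["y"]["kind"],
                                             params["y"], temperature)
            self.dim = 2
        else:
            raise ValueError(f"unknown landscape kind {kind!r}")

    # -- potential ---------------------------------------------------------
    def potential(self, x, y=None):
        if self.dim == 2:
            return self.part_x.potential(x) + self.part_y.potential(y)
        x = np.asarray(x, float)
        if self.kind == "harmonic":
            return self._a * x ** 2
        return self._a * (x ** 2 - self._b ** 2) ** 2

    def force(self, x, y=None):
        if self.dim == 2:
            return np.stack([self.part_x.force(x), self.part_y.force(y)])
        x = np.asarray(x, float)
        if self.kind == "harmonic":
            return -2.0 * self._a * x
        return -4.0 * self._a * x * (x ** 2 - self._b ** 2)

    @property
    def barrier(self) -> float:
        """Barrier height between wells (kcal/mol; double-well only)."""
        if self.kind != "double_well":
            raise AttributeError("barrier defined for double_well only")
        return self._a * self._b ** 4

    @property
    def well_positions(self):
        if self.kind != "double_well":
            raise AttributeError("wells defined for double_well only")
        return (-self._b, self._b)

    def free_energy(self, x, y=None):
        """Closed-form F relative to its minimum over the queried points."""
        U = self.potential(x) if self.dim == 1 else self.potential(x, y)
        return U - np.min(U)

    def boltzmann_free_energy(self, x, half_width: float):
        """Numerical-quadrature oracle: -kT ln of the Boltzmann integral of
        exp(-U/kT) over bins centered at x (1-D), min-shifted."""
        from scipy.integrate import quad
        kT = thermal_energy(self.temperature)
        x = np.atleast_1d(np.asarray(x, float))
        out = np.empty_like(x)
        for i, xi in enumerate(x):
            val, _ = quad(lambda t: math.exp(-float(self.potential(t)) / kT),
                          xi - half_width, xi + half_width)
            out[i] = -kT * math.log(val / (2 * half_width))
        return out - out.min()


def make_reference_landscape(kind: str, params: dict,
                             temperature: float = 300.0) -> ReferenceLandscape:
    return ReferenceLandscape(kind, params, temperature)


# ---------------------------------------------------------------------------
# Exact Monte-Carlo umbrella datasets
# ---------------------------------------------------------------------------

def generate_umbrella_dataset(landscape: ReferenceLandscape, centers,
                              bias_k, n_per_window: int, seed: int,
                              burn_in: int = 500, step: float = 0.4,
                              form: str = "k_dr2") -> UmbrellaDataset:
    """Metropolis samples from each window's biased Boltzmann density
    exp(-(U + V_bias)/kT), V_bias = k (x - c)^2 (or k/2 with the steering
    form).  Deterministic given the seed; an acceptance rate below 1%
    raises (the proposal is too wide for the stiffest window).
    """
    if landscape.dim != 1:
        raise ValueError("umbrella generation is 1-D")
    kT = thermal_energy(landscape.temperature)
    centers = np.atleast_1d(np.asarray(centers, float))
    bias_k = np.broadcast_to(np.asarray(bias_k, float), centers.shape)
    pref = 1.0 if form == "k_dr2" else 0.5
    rng = np.random.default_rng(seed)
    windows = []
    for c, k in zip(centers, bias_k):
        def energy(x):
            return float(landscape.potential(x)) + pref * k * (x - c) ** 2
        x = float(c)
        e = energy(x)
        samples = np.empty(n_per_window)
        accepted = 0
        total = burn_in + n_per_window
        prop = rng.normal(0.0, step, size=total)
        unif = rng.random(total)
        for i in range(total):
            x_new = x + prop[i]
            e_new = energy(x_new)
            if e_new <= e or unif[i] < math.exp(-(e_new - e) / kT):
                x, e = x_new, e_new
                accepted += 1
            if i >= burn_in:
                samples[i - burn_in] = x
        if accepted / total < 0.01:
            raise RuntimeError(
                f"acceptance rate {accepted / total:.3%} in window at "
                f"{c:+.2f}; widen the proposal step")
        R = np.zeros((n_per_window, 1, 3))
        R[:, 0, 0] = samples
        windows.append(UmbrellaWindow(R, np.array([[c, 0.0, 0.0]]),
                                      np.array([k]), form))
    return UmbrellaDataset(windows, landscape.temperature)


def biased_harmonic_moments(landscape: ReferenceLandscape, center: float,
                            bias_k: float, form: str = "k_dr2"):
    """Closed-form mean and variance of a harmonic landscape under a
    harmonic bias (the Gaussian product): used as the sampling oracle."""
    if landscape.kind != "harmonic":
        raise ValueError("closed form requires a harmonic landscape")
    kT = thermal_energy(landscape.temperature)
    pref = 1.0 if form == "k_dr2" else 0.5
    a = landscape._a
    k = pref * bias_k
    mean = k * center / (a + k)
    var = kT / (2.0 * (a + k))
    return mean, var
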