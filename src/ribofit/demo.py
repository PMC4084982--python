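"""End-to-end transition demo: drive the toy assembly from its POST state
into the PRE-state density map through a series of EM-fitting + umbrella
windows with adaptive anticodon steering, then recover the free-energy
profile along the progress coordinate by WHAM.

This is the desk-scale analogue of the windowed fitting protocol: per
window, a short EM-fitting phase (density force balanced against the
structural force by the w_EM controller, steering harmonics on the
anticodon analogues), umbrella centers pinned at the current group centers
of mass, equilibration with the steering ramped off, and umbrella-coordinate
sampling.  The tRNA groups are not umbrella'd (their positions are recorded
as observables), so the 0.60 A displacement cap governs the ribosome-body
umbrella coordinates exactly as in the reference protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import pathsearch, sampling, synthetic, units, wham
from .density import EMFitParams
from .sampling import (COMHarmonic, RMSDRestraint, SimState, WindowProtocol,
                       run_window)
from .wham import ProjectionFrame, UmbrellaDataset


@dataclass
class DemoResult:
    records: list                     # WindowRecords
    dataset: UmbrellaDataset
    solution: wham.WhamSolution
    frame: ProjectionFrame
    r1_values: np.ndarray             # per retained sample
    profile: tuple                    # (bin centers, F, P)
    cc_trace: list                    # per-window CC against the target map
    r1_endpoint: float                # R1 of the PRE reference
    steering_log: list                # per-window dicts


def default_protocol() -> WindowProtocol:
    """Window schedule used by the demo: ~1 ps fitting, ~1 ps equilibration,
    ~3 ps sampling per window at 300 K.  The fitting phase runs at higher
    friction so the per-window drift of the umbrella coordinates stays
    within the 0.60 A cap."""
    return WindowProtocol(em_steps=100, equil_steps=120, sample_steps=320,
                          dt=0.01, temperature=300.0, friction=2.0,
                          em_friction=10.0, sample_stride=4,
                          umbrella_k=1.0, displacement_cap=0.60,
                          w_em_bounds=(0.02, 2.0), em_stride=4,
                          max_retries=6)


def run_transition_demo(seed: int = 42, n_windows: int = 72,
                        barrier: float = 6.0,
                        spec: synthetic.ToyRibosomeSpec | None = None,
                        protocol: WindowProtocol | None = None,
                        target: str = "PRE", resolution: float = 11.0,
                        map_spacing: float = 2.5,
                        n_bins: int = 24) -> DemoResult:
    """Run the full pipeline and return windows, WHAM solution and the
    free-energy profile along the progress coordinate R1.

    R1 is projected from the umbrella coordinates plus the recorded tRNA
    observables (the cargo dominates the POST -> PRE progress, exactly as
    the far-travelling head/body groups dominate it in the real system).
    """
    spec = spec or synthetic.ToyRibosomeSpec()
    protocol = protocol or default_protocol()
    toy = synthetic.make_toy_ribosome(spec)
    maps = synthetic.make_state_maps(toy.endpoints, resolution=resolution,
                                     spacing=map_spacing)
    target_map = maps[target]
    model = toy.model
    field = synthetic.make_transition_field(
        toy.endpoints["POST"].coords, toy.endpoints[target].coords,
        np.arange(model.n_atoms), barrier=barrier, weighting="squared")
    potential = sampling.ToyPotential(bonds=toy.potential.bonds,
                                      fields=[field])

    umbrella = {n: g for n, g in toy.umbrella_groups.items()
                if not n.startswith("tRNA")}
    observables = {n: g for n, g in toy.umbrella_groups.items()
                   if n.startswith("tRNA")}
    anticodons = {"anticodon_P": model.groups["anticodon_P"],
                  "anticodon_E": model.groups["anticodon_E"]}

    # the large subunit is the analysis frame: an RMSD cap keeps its
    # internal orientation from random-walking away over the window series
    # (its center-of-mass umbrellas alone cannot restrain rotation)
    anchor = RMSDRestraint(model.groups["large_body"],
                           model.coords[model.groups["large_body"]],
                           k=5.0, limit=1.0)

    rng = np.random.default_rng(seed)
    state = SimState(model.coords.copy(),
                     sampling.thermal_velocities(model.masses,
                                                 protocol.temperature, rng))

    def gcom(coords, idx):
        m = model.masses[idx]
        return (m[:, None] * coords[idx]).sum(0) / m.sum()

    steer_states = {}
    for name, idx in anticodons.items():
        steer_states[name] = pathsearch.SteeringState(
            prev_mean=gcom(state.coords, idx),
            targets=[gcom(toy.endpoints[target].coords, idx)],
            delta=0.6)

    records, cc_trace, steering_log = [], [], []
    w_em = 0.2
    for wi in range(n_windows):
        steers = []
        for name, ss in steer_states.items():
            if np.linalg.norm(ss.target - ss.prev_mean) > ss.delta / 2:
                steers.append(COMHarmonic(
                    anticodons[name], model.masses,
                    pathsearch.desired_position(ss),
                    pathsearch.convert_force_constant(ss.k), "half_k_dr2"))
        rec = run_window(model, state, potential, umbrella, target_map,
                         EMFitParams(resolution, 4, w_em), protocol, rng,
                         index=wi, steering_restraints=steers,
                         extra_restraints=(anchor,),
                         observable_groups=observables)
        state = rec.restart_state
        log = {"window": wi, "w_em": rec.w_em, "cc": rec.cc_end,
               "cc_fit": rec.cc_fit}
        for name, ss in steer_states.items():
            mean = gcom(rec.final_state.coords, anticodons[name])
            pathsearch.update_after_window(ss, mean)
            log[name] = {"k_pn": ss.k,
                         "dist": float(np.linalg.norm(ss.target - mean))}
        steering_log.append(log)
        w_em = sampling.adapt_w_em(rec.fitting_shift, rec.w_em,
                                   protocol.displacement_cap,
                                   protocol.w_em_bounds)
        records.append(rec)
        cc_trace.append(rec.cc_fit)

    dataset = UmbrellaDataset.from_window_records(
        records, temperature=protocol.temperature)
    solution = wham.wham_solve(dataset, tol=1e-4)

    # progress coordinate over umbrella groups + tRNA observables
    all_names = list(umbrella) + list(observables)
    all_groups = {**umbrella, **observables}

    def coms_of(mdl):
        return np.array([gcom(mdl.coords, all_groups[n]) for n in all_names])

    Ri = coms_of(toy.endpoints["POST"])
    Rf = coms_of(toy.endpoints[target])
    frame = ProjectionFrame.from_endpoints(np.ones(len(all_names), bool),
                                           Ri, Rf)
    joint = np.concatenate(
        [np.concatenate([r.samples, r.extra_samples], axis=1)
         for r in records], axis=0)
    r1 = wham.project_R1(joint, frame)
    r1_end = float(wham.project_R1(Rf, frame))
    edges = np.linspace(r1.min() - 1e-9, r1.max() + 1e-9, n_bins + 1)
    centers, F, P = wham.profile_1d(solution, r1, edges)
    return DemoResult(records=records, dataset=dataset, solution=solution,
                      frame=frame, r1_values=r1,
                      profile=(centers, F, P), cc_trace=cc_trace,
                      r1_endpoint=r1_end, steering_log=steering_log)


def run_steered_double_well(seed: int = 3, barrier_kt: float = 5.0,
                            b: float = 4.0, delta: float = 0.5,
                            temperature: float = 300.0,
                            k_perp: float = 0.5, max_windows: int = 200,
                            window_steps: int = 1600,
                            mean_from_step: int = 400):
    """Closed-loop validation of the adaptive steer: a single bead on a
    double well of height `barrier_kt` k_BT along x (harmonically confined
    in y and z) is driven from the left well to the right one under the
    windowed controller with the standard constants (k1 = 100 pN/A,
    +-25 pN/A adaptation, Delta = delta/2).

    Returns ``(windows used, final distance to target, progress list)``.
    """
    kT = units.thermal_energy(temperature)
    a = barrier_kt * kT / b ** 4

    def dw(sub):
        x, y, z = sub[:, 0], sub[:, 1], sub[:, 2]
        e = float((a * (x ** 2 - b ** 2) ** 2
                   + k_perp * (y ** 2 + z ** 2)).sum())
        f = np.empty_like(sub)
        f[:, 0] = -4 * a * x * (x ** 2 - b ** 2)
        f[:, 1] = -2 * k_perp * y
        f[:, 2] = -2 * k_perp * z
        return e, f

    potential = sampling.ToyPotential(
        fields=[sampling.ExternalField([0], dw)])
    masses = np.array([20.0])
    rng = np.random.default_rng(seed)
    state = SimState(np.array([[-b, 0.0, 0.0]]),
                     sampling.thermal_velocities(masses, temperature, rng))
    target = np.array([b, 0.0, 0.0])
    steer = pathsearch.SteeringState(prev_mean=state.coords[0],
                                     targets=[target], delta=delta)
    progress = []
    final = np.inf
    for win in range(1, max_windows + 1):
        restraint = COMHarmonic(
            [0], masses, pathsearch.desired_position(steer),
            pathsearch.convert_force_constant(steer.k), "half_k_dr2")
        means = []

        def record(step, x, v):
            if step >= mean_from_step:
                means.append(x[0].copy())

        state = sampling.run_dynamics(state, masses, potential,
                                      (restraint,), window_steps, 0.01,
                                      temperature, 5.0, rng,
                                      callback=record)
        mean = np.mean(means, axis=0)
        prev = steer.prev_mean.copy()
        pathsearch.update_after_window(steer, mean)
        denom = max(np.linalg.norm(target - prev), 1e-12)
        progress.append(float((mean - prev) @ (target - prev) / denom))
        final = float(np.linalg.norm(mean - target))
        if final <= 0.5:
            return win, final, progress
    return max_windows, final, progress


def endpoint_basins_are_minima(centers, F, edge_fraction: float = 0.25
                               ) -> bool:
    """True when the profile's first and last quarter each contain a local
    minimum that is lower than the interior maximum between them (the two
    endpoint basins are separated by a barrier)."""
    finite = np.isfinite(F)
    c, f = centers[finite], F[finite]
    if len(f) < 5:
        return False
    n_edge = max(int(len(f) * edge_fraction), 2)
    left = f[:n_edge].min()
    right = f[-n_edge:].min()
    middle = f[n_edge:-n_edge].max() if len(f) > 2 * n_edge else -np.inf
    return bool(middle > left and middle > right)
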