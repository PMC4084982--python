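"""Adaptive path-search steering.

Each steered group carries a moving harmonic target: every window the target
is placed a step delta ahead of the group's previous mean position along the
direction of the final target, and the force constant is raised or lowered
by a fixed increment (25 pN/A) depending on whether the realized progress
projection beat the threshold Delta = delta/2.  Way-point lists let the
final target switch mid-path (e.g. intermediate state -> final state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import pn_to_kcal_mol_angstrom

#: paper-scale defaults: k_1 = 100 pN/A, +-25 pN/A steps, delta in [0.3, 0.6] A
K_INITIAL_PN = 100.0
K_STEP_PN = 25.0
DELTA_RANGE = (0.3, 0.6)


def convert_force_constant(value_pn_per_angstrom: float) -> float:
    """pN/A -> kcal/mol/A^2 (1 pN = 1.439e-2 kcal/mol/A)."""
    return pn_to_kcal_mol_angstrom(value_pn_per_angstrom)


@dataclass
class SteeringState:
    """Per-group state of the adaptive steer."""

    prev_mean: np.ndarray                  # (3,) previous-window mean, A
    targets: list = field(default_factory=list)  # way-point positions, (3,) each
    delta: float = 0.5                     # step length, A
    k: float = K_INITIAL_PN                # force constant, pN/A
    stage: int = 0                         # current way-point index

    def __post_init__(self):
        self.prev_mean = np.asarray(self.prev_mean, float).reshape(3)
        self.targets = [np.asarray(t, float).reshape(3) for t in self.targets]
        if not (DELTA_RANGE[0] <= self.delta <= DELTA_RANGE[1]):
            raise ValueError(
                f"delta must lie in {DELTA_RANGE}, got {self.delta}")
        if self.k < 0:
            raise ValueError("force constant must be non-negative")

    @property
    def target(self) -> np.ndarray:
        return self.targets[self.stage]

    @property
    def threshold(self) -> float:
        """Progress threshold Delta = delta / 2."""
        return self.delta / 2.0


def desired_position(state: SteeringState) -> np.ndarray:
    """Center of the steering harmonic for the next window.

    r* = <r>_{n-1} + delta * u, with u the unit vector toward the current
    way-point; clamped to the way-point when the remaining distance is
    shorter than delta (the unclamped rule would overshoot).
    """
    diff = state.target - state.prev_mean
    dist = float(np.linalg.norm(diff))
    if dist <= state.delta or dist == 0.0:
        return state.target.copy()
    return state.prev_mean + state.delta * diff / dist


def progress_projection(mean_n, mean_prev, target) -> float:
    """Realized progress: (<r>_n - <r>_{n-1}) . u toward the target (A)."""
    mean_n = np.asarray(mean_n, float)
    mean_prev = np.asarray(mean_prev, float)
    diff = np.asarray(target, float) - mean_prev
    dist = float(np.linalg.norm(diff))
    if dist == 0.0:
        raise ValueError("target coincides with previous mean")
    return float((mean_n - mean_prev) @ (diff / dist))


def adapt_force_constant(k: float, projection: float, threshold: float,
                         step: float = K_STEP_PN) -> float:
    """Raise k by `step` (pN/A) when progress fell short of the threshold,
    lower it otherwise; floored at zero."""
    if k < 0:
        raise ValueError("force constant must be non-negative")
    k_new = k + step if projection < threshold else k - step
    return max(k_new, 0.0)


def advance_stage(states: dict, current_means: dict,
                  switch_radius: float = 2.0) -> bool:
    """Switch every group to its next way-point once all steered groups are
    within `switch_radius` of their current way-point.  Returns True when a
    switch happened."""
    if not states:
        return False
    at_waypoint = all(
        np.linalg.norm(np.asarray(current_means[name], float) - st.target)
        <= switch_radius
        for name, st in states.items())
    can_advance = all(st.stage + 1 < len(st.targets) for st in states.values())
    if at_waypoint and can_advance:
        for st in states.values():
            st.stage += 1
        return True
    return False


def update_after_window(state: SteeringState, mean_n) -> SteeringState:
    """Apply the per-window adaptation: measure the progress projection,
    adapt k, and roll the mean forward."""
    mean_n = np.asarray(mean_n, float).reshape(3)
    if np.linalg.norm(state.target - state.prev_mean) > 0:
        proj = progress_projection(mean_n, state.prev_mean, state.target)
        state.k = adapt_force_constant(state.k, proj, state.threshold)
    state.prev_mean = mean_n
    return state
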