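"""Structure-pair descriptors for the ribosome's large-scale motions.

- ratchet angle: rotation of the small subunit against the large subunit,
  projected on the intersubunit axis;
- head angle: signed in-plane swivel of the small-subunit head, measured
  from the third principal axis of the head selection;
- P/E-gate width: COM-COM distance between the body-side nucleotide (A790)
  and the head-side loop (G1338 + A1339);
- screw-axis (Chasles) decomposition of a rigid displacement, and the
  internal/external split of a conformational change.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import (AtomicModel, center_of_mass, kabsch_rotation,
                        principal_axes, superpose)


def _unit(v):
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


# ---------------------------------------------------------------------------
# Angles
# ---------------------------------------------------------------------------

def ratchet_axis(reference: AtomicModel, large_sel, small_sel) -> np.ndarray:
    """Unit vector from the small-subunit COM to the large-subunit COM."""
    return _unit(center_of_mass(reference, large_sel)
                 - center_of_mass(reference, small_sel))


def ratchet_angle(model: AtomicModel, reference: AtomicModel,
                  large_sel, small_sel) -> float:
    """Signed intersubunit rotation angle (degrees).

    The model is best-fit onto the reference over the large subunit; the
    rotation best-fitting the small subunit onto the reference small subunit
    is then extracted, and its rotation vector is projected on the
    intersubunit axis e_ratchet.  Rotation about an axis perpendicular to
    e_ratchet therefore reports ~0.
    """
    fit = superpose(model, reference, large_sel)
    posed = model.transformed(fit)
    idx_m = posed.select(small_sel)
    idx_r = reference.select(small_sel)
    if idx_m.size != idx_r.size:
        raise ValueError("small-subunit selections differ in atom count")
    w = posed.masses[idx_m]
    X = posed.coords[idx_m]
    Y = reference.coords[idx_r]
    cx = (w[:, None] * X).sum(0) / w.sum()
    cy = (w[:, None] * Y).sum(0) / w.sum()
    # rotation taking the posed small subunit onto the reference one
    R = kabsch_rotation(X - cx, Y - cy, w)
    rotvec = Rotation.from_matrix(R).as_rotvec(degrees=True)
    e = ratchet_axis(reference, large_sel, small_sel)
    return float(rotvec @ e)


def head_angle(model: AtomicModel, reference: AtomicModel, head_sel,
               e_tRNA, e_ratchet, fit_sel=None) -> float:
    """Signed head-swivel angle of `model` relative to `reference` (degrees).

    The head axis is the principal axis of the head selection most parallel
    to the tRNA-travel direction e_tRNA; it is projected onto the
    (e_tRNA, e_ratchet) plane and the in-plane angle to e_tRNA is measured
    for both structures.  Positive = clockwise when viewed from the plane
    normal e_tRNA x e_ratchet (fixed here as the package's sign convention;
    out-of-plane rotation reports ~0).
    """
    e1 = _unit(e_tRNA)
    e2 = _unit(np.asarray(e_ratchet, float)
               - (np.asarray(e_ratchet, float) @ e1) * e1)

    def in_plane_angle(structure):
        axes, moments, degenerate = principal_axes(structure, head_sel)
        if degenerate:
            warnings.warn("near-degenerate head principal moments",
                          RuntimeWarning, stacklevel=3)
        k = int(np.argmax(np.abs(axes @ e1)))
        ax = axes[k]
        if ax @ e1 < 0:
            ax = -ax
        p1, p2 = float(ax @ e1), float(ax @ e2)
        if p1 == 0.0 and p2 == 0.0:
            raise ValueError("head axis is perpendicular to the plane")
        # anticlockwise about n = e1 x e2 would be +atan2; clockwise positive
        return -math.degrees(math.atan2(p2, p1))

    if fit_sel is not None:
        model = model.transformed(superpose(model, reference, fit_sel))
    return in_plane_angle(model) - in_plane_angle(reference)


def gate_width(model: AtomicModel, body_sel, loop_sel) -> float:
    """P/E-gate width (A): |COM(body nucleotide) - COM(head loop)|.

    For the ribosome, body_sel selects A790 and loop_sel selects
    G1338 + A1339 of the 16S rRNA.
    """
    for sel, label in ((body_sel, "body (A790)"), (loop_sel, "loop (G1338/A1339)")):
        if model.select(sel).size == 0:
            raise ValueError(f"gate selection {label} resolves to no atoms")
    return float(np.linalg.norm(center_of_mass(model, body_sel)
                                - center_of_mass(model, loop_sel)))


# ---------------------------------------------------------------------------
# Screw (Chasles) decomposition
# ---------------------------------------------------------------------------

@dataclass
class ScrewMotion:
    """A rigid displacement as rotation about a line plus translation along it."""

    point: np.ndarray        # (3,) a point on the axis, A
    axis: np.ndarray         # (3,) unit direction
    angle: float             # degrees
    translation: float       # A along the axis
    residual_rmsd: float = 0.0

    def __post_init__(self):
        self.point = np.asarray(self.point, float).reshape(3)
        self.axis = np.asarray(self.axis, float).reshape(3)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the screw to coordinates: rotate about the axis line, then
        translate along the axis."""
        coords = np.asarray(coords, float)
        R = Rotation.from_rotvec(np.radians(self.angle) * self.axis).as_matrix()
        return (coords - self.point) @ R.T + self.point \
            + self.translation * self.axis


#: below this rotation angle the displacement is treated as a pure translation
PURE_TRANSLATION_ANGLE = 0.1  # degrees


def screw_decompose(reference: np.ndarray, displaced: np.ndarray,
                    weights: np.ndarray | None = None) -> ScrewMotion:
    """Best-fit screw parameters taking `reference` onto `displaced`.

    Extracts the least-squares rotation R and translation t, converts them
    to Chasles form: axis from the rotation vector, translation along the
    axis t.u, and the axis point from the perpendicular component of t.
    The reported axis point is the point on the axis closest to the
    reference centroid (axis points form a line; a canonical representative
    is needed).  Angles below 0.1 degrees take the pure-translation branch.
    """
    X = np.asarray(reference, float).reshape(-1, 3)
    Y = np.asarray(displaced, float).reshape(-1, 3)
    if X.shape != Y.shape:
        raise ValueError("coordinate sets must match in shape")
    w = np.ones(X.shape[0]) if weights is None else np.asarray(weights, float)
    cx = (w[:, None] * X).sum(0) / w.sum()
    cy = (w[:, None] * Y).sum(0) / w.sum()
    R = kabsch_rotation(X - cx, Y - cy, w)
    t = cy - R @ cx
    fitted = X @ R.T + t
    residual = float(np.sqrt((w * ((fitted - Y) ** 2).sum(1)).sum() / w.sum()))

    rotvec = Rotation.from_matrix(R).as_rotvec()
    angle = math.degrees(np.linalg.norm(rotvec))
    if angle < PURE_TRANSLATION_ANGLE:
        tn = np.linalg.norm(t)
        axis = t / tn if tn > 0 else np.array([0.0, 0.0, 1.0])
        return ScrewMotion(point=cx.copy(), axis=axis, angle=0.0,
                           translation=float(tn), residual_rmsd=residual)
    u = rotvec / np.linalg.norm(rotvec)
    d = float(t @ u)
    t_perp = t - d * u
    # axis point p solves (I - R) p = t_perp; singular along u -> pseudo-inverse
    p = np.linalg.pinv(np.eye(3) - R) @ t_perp
    # canonical representative: closest point on the axis to the reference COM
    p = p + ((cx - p) @ u) * u
    return ScrewMotion(point=p, axis=u, angle=angle, translation=d,
                       residual_rmsd=residual)


# ---------------------------------------------------------------------------
# Internal / external motion split
# ---------------------------------------------------------------------------

@dataclass
class MotionSplit:
    internal: np.ndarray     # (N, 3) per-atom deformation displacement
    external: np.ndarray     # (N, 3) per-atom rigid-carry displacement
    total: np.ndarray        # (N, 3) = internal + external
    report: dict             # per-sub-selection mean |d_int|, |d_ext|, |d_tot|


def split_internal_external(model_a: AtomicModel, model_b: AtomicModel,
                            whole_sel=None,
                            sub_selections: dict | None = None) -> MotionSplit:
    """Split the displacement A -> B over `whole_sel` into internal
    (deformation remaining after the best rigid fit of A onto B) and
    external (the rigid part, total - internal) fields.

    `sub_selections` maps labels to selections; the report carries mean
    displacement magnitudes and the internal:external ratio for each.
    """
    idx_a = model_a.select(whole_sel)
    idx_b = model_b.select(whole_sel)
    if idx_a.size != idx_b.size:
        raise ValueError("selections resolve to different atom counts")
    fit = superpose(model_a, model_b, whole_sel)
    A = model_a.coords[idx_a]
    B = model_b.coords[idx_b]
    A_fit = fit.apply(A)
    internal = B - A_fit
    total = B - A
    external = total - internal

    def stats(mask_idx):
        sel = np.searchsorted(idx_a, mask_idx)
        di = float(np.linalg.norm(internal[sel], axis=1).mean())
        de = float(np.linalg.norm(external[sel], axis=1).mean())
        dt = float(np.linalg.norm(total[sel], axis=1).mean())
        return {"mean_internal": di, "mean_external": de, "mean_total": dt,
                "ratio_internal_external": (di / de if de > 0 else math.inf)}

    report = {"whole": stats(idx_a)}
    for label, sel in (sub_selections or {}).items():
        sub_idx = model_a.select(sel)
        sub_idx = sub_idx[np.isin(sub_idx, idx_a)]
        if sub_idx.size == 0:
            raise ValueError(f"sub-selection {label!r} is empty inside whole_sel")
        report[label] = stats(sub_idx)
    return MotionSplit(internal=internal, external=external, total=total,
                       report=report)
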