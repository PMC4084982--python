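"""Rigid alignment of experimental density maps onto an atomic model:
volume thresholding, moment-of-inertia fitting, deterministic CC-ascent
refinement, and re-orientation of the map into the model frame.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .density import (DensityMap, cic_regrid, clamp_negative,
                      correlation_coefficient, grid_for_model, synthesize_map)
from .structure import AtomicModel, RigidTransform, inertia_tensor


@dataclass
class VoxelPointSet:
    """Voxels above an adaptive threshold: positions (A), values, threshold."""

    positions: np.ndarray    # (M, 3)
    values: np.ndarray       # (M,)
    threshold: float
    voxel_volume: float

    @property
    def occupied_volume(self) -> float:
        return self.values.size * self.voxel_volume


def molecular_volume(model: AtomicModel, packing_factor: float = 1.2) -> float:
    """Estimate of the molecular volume (A^3): sum of atomic van der Waals
    sphere volumes times a packing factor."""
    vol = 0.0
    for el in model.elements:
        r = gemmi.Element(str(el)).vdw_r
        if r <= 0:
            r = 1.7
        vol += 4.0 / 3.0 * math.pi * r ** 3
    return vol * packing_factor


def threshold_to_volume(map_: DensityMap, target_volume: float) -> VoxelPointSet:
    """Select the highest-valued positive voxels whose cumulative volume best
    matches `target_volume` (ties broken by voxel order)."""
    vv = map_.voxel_volume
    if target_volume <= 0:
        return VoxelPointSet(np.empty((0, 3)), np.empty(0), math.inf, vv)
    vals = map_.values.ravel()
    pos_mask = vals > 0
    available = pos_mask.sum() * vv
    if target_volume > available + 0.5 * vv:
        raise ValueError(
            f"target volume {target_volume:.1f} A^3 exceeds positive-voxel "
            f"volume {available:.1f} A^3")
    count = int(np.clip(round(target_volume / vv), 1, pos_mask.sum()))
    order = np.argsort(-vals, kind="stable")[:count]
    threshold = float(vals[order[-1]])
    positions = map_.voxel_positions()[order]
    return VoxelPointSet(positions, vals[order], threshold, vv)


def _principal_frame(coords: np.ndarray, weights: np.ndarray):
    com = (weights[:, None] * coords).sum(0) / weights.sum()
    I = inertia_tensor(coords, weights)
    moments, vecs = np.linalg.eigh(I)
    axes = vecs.T  # rows, ascending moment
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return com, axes, moments


def moment_fit(model: AtomicModel, voxels: VoxelPointSet,
               target_map: DensityMap | None = None,
               resolution: float = 10.0, n_neighbor: int = 4) -> RigidTransform:
    """Rigid transform posing the model into the map frame by matching
    centers of mass and principal inertia axes (density-weighted voxel
    "masses").  Principal axes are sign-ambiguous; among the four proper
    sign assignments the one maximizing CC of the posed model's synthetic
    map against `target_map` is returned (the first candidate if no map is
    given).  Degenerate inertia tensors fall back to COM alignment.
    """
    com_m, axes_m, mom_m = _principal_frame(model.coords, model.masses)
    if voxels.values.size < 4:
        raise ValueError("too few voxels for a moment fit")
    com_v, axes_v, mom_v = _principal_frame(voxels.positions, voxels.values)
    scale = max(abs(mom_m[-1]), abs(mom_v[-1]), 1.0)
    if (np.min(np.diff(mom_m)) < 1e-9 * scale
            or np.min(np.diff(mom_v)) < 1e-9 * scale):
        warnings.warn("degenerate inertia tensor; falling back to COM "
                      "alignment", RuntimeWarning, stacklevel=2)
        return RigidTransform(np.eye(3), com_v - com_m)

    candidates = []
    for s0, s1 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        S = np.diag([s0, s1, s0 * s1])  # det +1 sign assignments
        R = axes_v.T @ S @ axes_m
        candidates.append(RigidTransform(R, com_v - R @ com_m))
    if target_map is None:
        return candidates[0]
    best, best_cc = None, -np.inf
    for cand in candidates:
        posed = model.transformed(cand)
        try:
            sim = synthesize_map(posed, target_map.origin, target_map.spacing,
                                 target_map.dims, resolution, n_neighbor)
            cc = correlation_coefficient(sim, target_map)
        except ValueError:
            continue
        if cc > best_cc:
            best, best_cc = cand, cc
    if best is None:
        raise ValueError("no sign assignment keeps the model on the grid")
    return best


def refine_rigid_cc(model: AtomicModel, map_: DensityMap,
                    start: RigidTransform,
                    resolution: float = 10.0, n_neighbor: int = 4,
                    translation_steps=(1.0, 0.5, 0.25, 0.1, 0.05),
                    rotation_steps=(2.0, 1.0, 0.5, 0.2, 0.1)):
    """Deterministic coordinate-wise CC ascent over the 6 rigid degrees of
    freedom with shrinking steps.  Returns ``(transform, cc_trace)``; the
    trace is non-decreasing and the final CC >= the starting CC.
    """
    def cc_of(transform):
        posed = model.transformed(transform)
        try:
            sim = synthesize_map(posed, map_.origin, map_.spacing, map_.dims,
                                 resolution, n_neighbor)
            cc = correlation_coefficient(sim, map_)
        except ValueError:
            return -np.inf
        if not np.isfinite(cc):
            raise FloatingPointError("non-finite CC during rigid refinement")
        return cc

    current = start
    cc = cc_of(current)
    if not np.isfinite(cc):
        raise ValueError("start pose is outside the map support")
    trace = [cc]
    axes = np.eye(3)
    for t_step, r_step in zip(translation_steps, rotation_steps):
        improved = True
        while improved:
            improved = False
            pivot = current.apply(model.coords).mean(axis=0)
            moves = []
            for a in range(3):
                for sgn in (1.0, -1.0):
                    moves.append(RigidTransform(np.eye(3),
                                                sgn * t_step * axes[a]))
                    R = Rotation.from_rotvec(
                        np.radians(sgn * r_step) * axes[a]).as_matrix()
                    moves.append(RigidTransform(R, pivot - R @ pivot))
            for mv in moves:
                cand = mv.compose(current)
                c = cc_of(cand)
                if c > cc:
                    current, cc = cand, c
                    trace.append(cc)
                    improved = True
    return current, trace


def align_map_to_model(map_: DensityMap, model: AtomicModel,
                       resolution: float | None = None,
                       n_neighbor: int = 4,
                       target_volume: float | None = None,
                       grid_margin: float = 14.0,
                       clip_tolerance: float = 1e-3):
    """Full alignment pipeline: threshold the map to the molecular volume,
    moment-fit the model into the map, refine by CC ascent, then apply the
    inverse transform to the map and regrid (cloud-in-cell) onto a
    model-frame grid.

    Returns ``(aligned_map, report)`` where the report carries the
    threshold, the model->map transform, and the CC trace.
    """
    resolution = map_.resolution if resolution is None else resolution
    if resolution <= 0:
        raise ValueError("a positive map resolution is required")
    clamped = clamp_negative(map_)
    vol = molecular_volume(model) if target_volume is None else target_volume
    voxels = threshold_to_volume(clamped, vol)
    start = moment_fit(model, voxels, target_map=clamped,
                       resolution=resolution, n_neighbor=n_neighbor)
    transform, trace = refine_rigid_cc(model, clamped, start,
                                       resolution=resolution,
                                       n_neighbor=n_neighbor)
    origin, spacing, dims = grid_for_model(
        model, spacing=float(np.mean(map_.spacing)), margin=grid_margin)
    aligned = cic_regrid(clamped, transform.inverse(), origin, spacing, dims,
                         clip_tolerance=clip_tolerance)
    aligned.resolution = resolution
    report = {
        "threshold": voxels.threshold,
        "target_volume": vol,
        "model_to_map": transform,
        "cc_trace": trace,
        "cc_final": trace[-1],
    }
    return aligned, report
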