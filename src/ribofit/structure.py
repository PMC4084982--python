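"""Atomic models, selections, and rigid-body superposition.

The :class:`AtomicModel` is the substrate for every other module: a flat
array-of-atoms container with per-atom masses and named group tags (umbrella
groups, domains, subunit selections).  Superposition is mass-weighted
least-squares (Kabsch); principal axes come from the mass-weighted inertia
tensor.  PDB I/O goes through gemmi.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np


class DegenerateGeometryError(ValueError):
    """Raised when a geometric operation receives degenerate input
    (e.g. fewer than 3 non-collinear atoms for a superposition)."""


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body motion x -> R @ x + t (rotation in SO(3), t in A)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper orthogonal (det = +1)")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthogonal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` first, then self."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

class SelectionSpec:
    """Composable atom-selection predicate.

    Built from chain / residue-range / atom-name / group predicates and
    combined with ``|`` (union) and ``&`` (intersection).  Resolution against
    a model is deterministic: the result is always a sorted unique index
    array, independent of composition order.
    """

    def __init__(self, predicate):
        self._predicate = predicate

    @classmethod
    def all(cls) -> "SelectionSpec":
        return cls(lambda m: np.ones(m.n_atoms, dtype=bool))

    @classmethod
    def chain(cls, chain_id: str) -> "SelectionSpec":
        return cls(lambda m: m.chains == chain_id)

    @classmethod
    def residues(cls, first: int, last: int | None = None) -> "SelectionSpec":
        last = first if last is None else last
        return cls(lambda m: (m.resnums >= first) & (m.resnums <= last))

    @classmethod
    def resname(cls, name: str) -> "SelectionSpec":
        return cls(lambda m: m.resnames == name)

    @classmethod
    def atom_name(cls, name: str) -> "SelectionSpec":
        return cls(lambda m: m.names == name)

    @classmethod
    def group(cls, group_name: str) -> "SelectionSpec":
        def pred(m):
            mask = np.zeros(m.n_atoms, dtype=bool)
            mask[m.groups[group_name]] = True
            return mask
        return cls(pred)

    @classmethod
    def indices(cls, idx) -> "SelectionSpec":
        idx = np.asarray(idx, dtype=int)

        def pred(m):
            mask = np.zeros(m.n_atoms, dtype=bool)
            mask[idx] = True
            return mask
        return cls(pred)

    def __or__(self, other: "SelectionSpec") -> "SelectionSpec":
        return SelectionSpec(lambda m: self._predicate(m) | other._predicate(m))

    def __and__(self, other: "SelectionSpec") -> "SelectionSpec":
        return SelectionSpec(lambda m: self._predicate(m) & other._predicate(m))

    def resolve(self, model: "AtomicModel") -> np.ndarray:
        mask = self._predicate(model)
        return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Atomic model
# ---------------------------------------------------------------------------

@dataclass
class AtomicModel:
    """Named atoms with coordinates (A), masses (amu) and group tags."""

    names: np.ndarray          # (N,) str
    elements: np.ndarray       # (N,) str
    resnames: np.ndarray       # (N,) str
    resnums: np.ndarray        # (N,) int
    chains: np.ndarray         # (N,) str
    coords: np.ndarray         # (N, 3) float, A
    masses: np.ndarray         # (N,) float, amu
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        self.masses = np.asarray(self.masses, dtype=float).reshape(n)
        for arr_name in ("names", "elements", "resnames", "chains"):
            setattr(self, arr_name, np.asarray(getattr(self, arr_name)).reshape(n))
        self.resnums = np.asarray(self.resnums, dtype=int).reshape(n)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        for gname, idx in self.groups.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"group {gname!r} references invalid atom indices")
            self.groups[gname] = idx

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "AtomicModel":
        return replace(
            self,
            coords=self.coords.copy(),
            masses=self.masses.copy(),
            groups={k: v.copy() for k, v in self.groups.items()},
        )

    def transformed(self, transform: RigidTransform) -> "AtomicModel":
        out = self.copy()
        out.coords = transform.apply(self.coords)
        return out

    def select(self, sel: SelectionSpec | None) -> np.ndarray:
        if sel is None:
            return np.arange(self.n_atoms)
        return sel.resolve(self)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def center_of_mass(model: AtomicModel, sel: SelectionSpec | None = None) -> np.ndarray:
    """Mass-weighted mean position of the selected atoms (A)."""
    idx = model.select(sel)
    if idx.size == 0:
        raise ValueError("empty selection has no center of mass")
    m = model.masses[idx]
    return (m[:, None] * model.coords[idx]).sum(axis=0) / m.sum()


def _check_noncollinear(coords: np.ndarray, weights: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 atoms")
    c = (weights[:, None] * coords).sum(0) / weights.sum()
    d = coords - c
    s = np.linalg.svd(d * np.sqrt(weights[:, None]), compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("atoms are (near-)collinear")


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray,
                    weights: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centered `mobile` onto centered
    `reference` under weights (Kabsch/SVD with reflection correction)."""
    H = (weights[:, None] * mobile).T @ reference
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(mobile: AtomicModel, reference: AtomicModel,
              sel: SelectionSpec | None = None,
              ref_sel: SelectionSpec | None = None) -> RigidTransform:
    """Mass-weighted least-squares rigid fit of `mobile` onto `reference`.

    Returns the transform that, applied to `mobile`'s coordinates, minimizes
    the mass-weighted RMSD over the selection.  Selections must resolve to
    equal atom counts in both models (pairing is by order).
    """
    idx_m = mobile.select(sel)
    idx_r = reference.select(sel if ref_sel is None else ref_sel)
    if idx_m.size != idx_r.size:
        raise ValueError("selections resolve to different atom counts")
    if idx_m.size < 3:
        raise DegenerateGeometryError("need >= 3 atoms to superpose")
    w = mobile.masses[idx_m]
    X = mobile.coords[idx_m]
    Y = reference.coords[idx_r]
    _check_noncollinear(X, w)
    cx = (w[:, None] * X).sum(0) / w.sum()
    cy = (w[:, None] * Y).sum(0) / w.sum()
    R = kabsch_rotation(X - cx, Y - cy, w)
    t = cy - R @ cx
    return RigidTransform(R, t)


def rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    """(Weighted) root-mean-square deviation between coordinate sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d2 = ((a - b) ** 2).sum(axis=1)
    if weights is None:
        return float(np.sqrt(d2.mean()))
    w = np.asarray(weights, float)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def inertia_tensor(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted inertia tensor about the center of mass."""
    c = (masses[:, None] * coords).sum(0) / masses.sum()
    d = coords - c
    r2 = (d ** 2).sum(axis=1)
    I = np.einsum("i,ij,ik->jk", masses, d, d)
    return np.diag([(masses * r2).sum()] * 3) - I


def principal_axes(model: AtomicModel, sel: SelectionSpec | None = None,
                   reference_directions: np.ndarray | None = None,
                   degeneracy_tol: float = 1e-9):
    """Principal axes of the mass-weighted inertia tensor of a selection.

    Returns ``(axes, moments, degenerate)`` with axes as rows sorted by
    increasing moment of inertia.  Each axis is sign-oriented to a positive
    dot product with the matching row of `reference_directions` (identity by
    default; principal axes are otherwise sign-ambiguous).  `degenerate` is
    True when two moments coincide within `degeneracy_tol` (relative).
    """
    idx = model.select(sel)
    if idx.size < 3:
        raise DegenerateGeometryError("need >= 3 atoms for principal axes")
    m = model.masses[idx]
    X = model.coords[idx]
    _check_noncollinear(X, m)
    I = inertia_tensor(X, m)
    moments, vecs = np.linalg.eigh(I)
    axes = vecs.T  # rows, ascending moment
    if reference_directions is None:
        reference_directions = np.eye(3)
    refs = np.asarray(reference_directions, float).reshape(3, 3)
    for k in range(3):
        if axes[k] @ refs[k] < 0:
            axes[k] = -axes[k]
    # re-impose right-handedness after sign fixing
    if np.linalg.det(axes) < 0:
        # flip the axis least constrained by its reference
        dots = np.abs([axes[k] @ refs[k] for k in range(3)])
        axes[int(np.argmin(dots))] *= -1
    scale = max(abs(moments[-1]), 1.0)
    degenerate = bool(np.any(np.diff(moments) < degeneracy_tol * scale)
                      or np.any(np.diff(moments) / scale < 1e-6))
    return axes, moments, degenerate


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _element_mass(element: str, name: str,
                  mass_overrides: dict[str, float] | None) -> float:
    if mass_overrides and name in mass_overrides:
        return mass_overrides[name]
    if mass_overrides and element in mass_overrides:
        return mass_overrides[element]
    el = gemmi.Element(element)
    w = el.weight
    if el.is_hydrogen:
        return w
    if el.name == "X" or w <= 0:
        raise ValueError(
            f"unknown element {element!r} for atom {name!r}; "
            "provide a mass override")
    return w


def read_pdb(path, mass_overrides: dict[str, float] | None = None) -> AtomicModel:
    """Read a PDB file into an :class:`AtomicModel`.

    One atom per ATOM/HETATM record; the first MODEL of multi-model files;
    altloc '' or 'A' only.  Masses come from the element table unless
    overridden by atom or element name.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    names, elements, resnames, resnums, chains, coords, masses = \
        [], [], [], [], [], [], []
    for chain in model:
        for res in chain:
            for atom in res:
                if atom.altloc not in ("\0", "", "A"):
                    continue
                names.append(atom.name)
                el = atom.element.name
                elements.append(el)
                resnames.append(res.name)
                resnums.append(res.seqid.num)
                chains.append(chain.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                masses.append(_element_mass(el, atom.name, mass_overrides))
    if not names:
        raise ValueError(f"no atoms read from {path}")
    return AtomicModel(
        names=np.array(names), elements=np.array(elements),
        resnames=np.array(resnames), resnums=np.array(resnums),
        chains=np.array(chains), coords=np.array(coords),
        masses=np.array(masses))


def write_pdb(model: AtomicModel, path) -> None:
    """Write an :class:`AtomicModel` as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = "ribofit"
    gm = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for i in range(model.n_atoms):
        cid = str(model.chains[i])
        if cid not in chain_map:
            chain_map[cid] = gemmi.Chain(cid)
        chain = chain_map[cid]
        resnum = int(model.resnums[i])
        resname = str(model.resnames[i])
        if (len(chain) == 0 or chain[-1].seqid.num != resnum
                or chain[-1].name != resname):
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            chain.add_residue(res)
        res = chain[-1]
        atom = gemmi.Atom()
        atom.name = str(model.names[i])
        atom.element = gemmi.Element(str(model.elements[i]))
        atom.pos = gemmi.Position(*model.coords[i])
        res.add_atom(atom)
    for chain in chain_map.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
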