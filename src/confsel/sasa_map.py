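"""Solvent-accessible surface areas and deletion-difference interface maps.

SASA is computed with the Shrake-Rupley rolling-probe quadrature: each atom
sphere is inflated by the probe radius, covered with a deterministic
golden-spiral point set, and the fraction of points not buried inside any
neighbouring inflated sphere gives the exposed area.

Interface mapping follows the deletion-difference logic: remove a residue
range (or a chain) from the structure, recompute the SASA of what remains,
and the per-residue gain in exposed area marks the residues that were in
contact with the deleted part.  The same machinery selects
conformational-reporter residues — residues far from every functional
interface, whose shifts track only the intra-domain equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "StructureModel",
    "SasaResult",
    "DeletionDiff",
    "SasaError",
    "VDW_RADII",
    "sasa",
    "deletion_diff",
    "reporter_select",
    "expand_ranges",
]


class SasaError(ValueError):
    pass


#: Bondi-type van der Waals radii (A).  Heavy atoms only by default; when
#: hydrogens are stripped their volume is considered absorbed into the heavy
#: atoms (a united-atom convention).  Unknown elements fall back to carbon.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
DEFAULT_RADIUS = 1.70


@dataclass
class StructureModel:
    """Atoms with coordinates and radii, indexed by residue.

    Arrays are parallel over atoms: ``element`` (upper-case symbols),
    ``atom_name`` (PDB atom names, e.g. "CA"), ``residue_id``, ``chain``,
    ``xyz`` (n, 3) in A, ``radius`` in A.
    """

    element: np.ndarray
    atom_name: np.ndarray
    residue_id: np.ndarray
    chain: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.element)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.residue_id = np.asarray(self.residue_id, dtype=int)
        if self.xyz.shape != (n, 3):
            raise SasaError("xyz must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise SasaError("non-finite coordinates")
        if np.any(self.radius <= 0):
            raise SasaError("all radii must be positive")
        if n == 0:
            raise SasaError("structure has no atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.element)

    @property
    def residues(self) -> list[int]:
        return sorted(set(self.residue_id.tolist()))

    # -- construction ------------------------------------------------------

    @classmethod
    def from_arrays(cls, element, residue_id, xyz, chain=None, atom_name=None,
                    radius=None) -> "StructureModel":
        element = np.asarray([str(e).upper() for e in element], dtype=object)
        n = len(element)
        if chain is None:
            chain = np.asarray(["A"] * n, dtype=object)
        if atom_name is None:
            atom_name = element.copy()
        if radius is None:
            radius = np.array([VDW_RADII.get(e, DEFAULT_RADIUS) for e in element])
        return cls(element, np.asarray(atom_name, dtype=object),
                   np.asarray(residue_id), np.asarray(chain, dtype=object),
                   np.asarray(xyz, dtype=float), np.asarray(radius, dtype=float))

    @classmethod
    def from_pdb(
        cls,
        path: str | Path,
        heavy_only: bool = True,
        chain: str | Iterable[str] | None = None,
        include_hetero: bool = False,
    ) -> "StructureModel":
        """Read the first model of a PDB file (via biotite)."""
        import biotite.structure.io.pdb as pdb

        arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
        mask = np.ones(arr.array_length(), dtype=bool)
        if not include_hetero:
            mask &= ~arr.hetero
        if heavy_only:
            mask &= np.char.upper(arr.element.astype(str)) != "H"
        if chain is not None:
            chains = {chain} if isinstance(chain, str) else set(chain)
            mask &= np.isin(arr.chain_id, list(chains))
        arr = arr[mask]
        if arr.array_length() == 0:
            raise SasaError(f"no atoms selected from {path}")
        return cls.from_arrays(
            element=arr.element,
            residue_id=arr.res_id,
            xyz=arr.coord,
            chain=arr.chain_id,
            atom_name=arr.atom_name,
        )

    def to_pdb(self, path: str | Path) -> None:
        """Write the model as a PDB file (via biotite)."""
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        arr = struc.AtomArray(self.n_atoms)
        arr.coord = self.xyz.astype(np.float32)
        arr.chain_id = self.chain.astype("U4")
        arr.res_id = self.residue_id
        arr.res_name = np.asarray(["GLY"] * self.n_atoms, dtype="U5")
        arr.atom_name = self.atom_name.astype("U6")
        arr.element = self.element.astype("U2")
        arr.hetero = np.zeros(self.n_atoms, dtype=bool)
        f = pdb.PDBFile()
        f.set_structure(arr)
        f.write(str(path))

    # -- selection ---------------------------------------------------------

    def subset(self, mask: np.ndarray) -> "StructureModel":
        if not np.any(mask):
            raise SasaError("selection removes every atom")
        return StructureModel(
            self.element[mask], self.atom_name[mask], self.residue_id[mask],
            self.chain[mask], self.xyz[mask], self.radius[mask],
        )

    def select_residues(self, residues: Iterable[int], invert: bool = False
                        ) -> "StructureModel":
        wanted = np.isin(self.residue_id, list(residues))
        return self.subset(~wanted if invert else wanted)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureModel":
        """Rigidly moved copy (rotation applied first)."""
        out = StructureModel(
            self.element, self.atom_name, self.residue_id, self.chain,
            self.xyz @ np.asarray(rotation).T + np.asarray(translation),
            self.radius,
        )
        return out


# ---------------------------------------------------------------------------
# Shrake-Rupley


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))


@dataclass
class SasaResult:
    per_atom: np.ndarray  # A^2, parallel to structure atoms
    per_residue: dict[int, float]
    probe: float
    n_points: int

    def total(self) -> float:
        return float(self.per_atom.sum())


def sasa(
    structure: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom contributes ``exposed_fraction * 4 pi (r + probe)^2`` where the
    exposed fraction is estimated on ``n_points`` golden-spiral points.
    Exactly coincident atom pairs are computed as-is with a warning (their
    shared surface is double-counted by construction).
    """
    if probe < 0:
        raise SasaError("probe radius must be >= 0")
    if n_points < 100:
        raise SasaError("n_points must be >= 100")
    xyz = structure.xyz
    ext = structure.radius + probe
    n = structure.n_atoms

    tree = cKDTree(xyz)
    dirs = _sphere_points(n_points)
    rmax = float(ext.max())

    dup = tree.query_pairs(1e-9)
    if dup:
        import warnings

        warnings.warn(f"{len(dup)} coincident atom pair(s); computed as-is",
                      stacklevel=2)

    per_atom = np.empty(n)
    for i in range(n):
        neigh = tree.query_ball_point(xyz[i], ext[i] + rmax)
        neigh = [j for j in neigh if j != i
                 and np.linalg.norm(xyz[j] - xyz[i]) < ext[i] + ext[j]]
        area_full = 4.0 * np.pi * ext[i] ** 2
        if not neigh:
            per_atom[i] = area_full
            continue
        pts = xyz[i] + ext[i] * dirs  # (m, 3)
        buried = np.zeros(n_points, dtype=bool)
        for j in neigh:
            d2 = np.einsum("ij,ij->i", pts - xyz[j], pts - xyz[j])
            buried |= d2 < ext[j] ** 2
            if buried.all():
                break
        per_atom[i] = area_full * (1.0 - buried.mean())

    per_res: dict[int, float] = {}
    for res in structure.residues:
        per_res[res] = float(per_atom[structure.residue_id == res].sum())
    return SasaResult(per_atom, per_res, probe, n_points)


# ---------------------------------------------------------------------------
# Deletion-difference interface mapping


def expand_ranges(ranges: str | Sequence) -> set[int]:
    """Expand '226-379' / '100-110,120' / [(1, 5), 9] style range specs."""
    if isinstance(ranges, str):
        parts = [p.strip() for p in ranges.split(",") if p.strip()]
    else:
        parts = list(ranges)
    out: set[int] = set()
    for part in parts:
        if isinstance(part, str):
            if "-" in part:
                lo, hi = part.split("-")
                out.update(range(int(lo), int(hi) + 1))
            else:
                out.add(int(part))
        elif isinstance(part, (tuple, list)):
            out.update(range(int(part[0]), int(part[1]) + 1))
        else:
            out.add(int(part))
    return out


@dataclass
class DeletionDiff:
    """Per-residue SASA gain of the remainder upon deleting a region."""

    deleted: set[int]
    delta: dict[int, float]  # residue -> SASA(remainder) - SASA(full), A^2
    threshold: float
    flagged: list[int] = field(init=False)

    def __post_init__(self) -> None:
        self.flagged = [r for r, v in sorted(self.delta.items())
                        if v > self.threshold]

    def above_mean_plus_sd(self) -> list[int]:
        vals = np.array(list(self.delta.values()))
        cut = vals.mean() + (vals.std(ddof=1) if len(vals) > 1 else 0.0)
        return [r for r, v in sorted(self.delta.items()) if v > cut]


def deletion_diff(
    structure: StructureModel,
    deleted: str | Sequence | set[int],
    threshold: float = 5.0,
    probe: float = 1.4,
    n_points: int = 960,
    delete_chain: str | None = None,
) -> DeletionDiff:
    """SASA change of the remaining residues upon deleting a residue range.

    Delta-SASA per remaining residue is SASA of the remainder computed alone
    minus its SASA within the full structure; deletion can only expose
    surface, so values are >= 0 up to quadrature noise.  Residues above
    ``threshold`` (A^2) are the contact (interface) residues.

    ``delete_chain`` removes a whole chain instead of / in addition to the
    residue ranges (used for subunit-deletion maps of a complex).
    """
    del_set = expand_ranges(deleted) if deleted else set()
    del_mask = np.isin(structure.residue_id, list(del_set)) if del_set else \
        np.zeros(structure.n_atoms, dtype=bool)
    if delete_chain is not None:
        del_mask |= structure.chain == delete_chain
        del_set |= set(structure.residue_id[structure.chain == delete_chain].tolist())
    if del_mask.all():
        raise SasaError("deletion removes the entire structure")

    full = sasa(structure, probe, n_points)
    if not del_mask.any():
        remaining = structure.residues
        return DeletionDiff(set(), {r: 0.0 for r in remaining}, threshold)

    remainder = structure.subset(~del_mask)
    alone = sasa(remainder, probe, n_points)

    # SASA of remainder residues inside the full structure
    delta: dict[int, float] = {}
    for res in remainder.residues:
        in_full = float(full.per_atom[(structure.residue_id == res) & ~del_mask].sum())
        delta[res] = alone.per_residue[res] - in_full
    return DeletionDiff(del_set, delta, threshold)


def reporter_select(
    structure: StructureModel,
    interface_sets: Mapping[str, Iterable[int]] | Sequence[Iterable[int]],
    min_dist: float = 8.0,
) -> list[int]:
    """Residues distant from every listed functional interface.

    A residue is a conformational reporter when its minimum heavy-atom
    distance to every residue of every interface set (cAMP sites, R:C
    interface, CBD-A/B interface, ...) exceeds ``min_dist`` (A).  An empty
    result is an error suggesting a smaller cutoff.
    """
    if min_dist <= 0:
        raise SasaError("min_dist must be positive")
    if isinstance(interface_sets, Mapping):
        sets = list(interface_sets.values())
    else:
        sets = list(interface_sets)
    interface = set()
    for s in sets:
        interface.update(int(r) for r in s)
    if not interface:
        return structure.residues

    if_mask = np.isin(structure.residue_id, list(interface))
    if not if_mask.any():
        return [r for r in structure.residues if r not in interface]
    tree = cKDTree(structure.xyz[if_mask])
    dmin, _ = tree.query(structure.xyz)

    selected = []
    for res in structure.residues:
        if res in interface:
            continue
        if dmin[structure.residue_id == res].min() > min_dist:
            selected.append(res)
    if not selected:
        raise SasaError(
            f"no residue is further than {min_dist} A from all interfaces; "
            "reduce min_dist"
        )
    return selected
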