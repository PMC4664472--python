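"""Rigid-body spectral-density prediction from rotational diffusion.

Predicts the per-residue spectral densities expected for a rigidly tumbling
molecule — no internal motions — so that the observed reduced densities can
be compared against them and the excess attributed to real dynamics.

For an N-H bond vector at angle alpha to the unique axis of an axially
symmetric rotational diffusion tensor (D_par about the unique axis, D_perp
about the two others), the spectral density is the Woessner three-Lorentzian
form::

    J(w) = (2/5) * sum_k A_k * tau_k / (1 + (w tau_k)^2)

    A1 = (3 cos^2 a - 1)^2 / 4      1/tau1 = 6 D_perp
    A2 = 3 sin^2 a cos^2 a          1/tau2 = 5 D_perp + D_par
    A3 = (3/4) sin^4 a              1/tau3 = 2 D_perp + 4 D_par

The weights sum to one for every alpha, and the isotropic limit
(D_par = D_perp = D) collapses to the single Lorentzian with
tau_c = 1/(6D).

The diffusion tensor can be supplied externally (e.g. from a bead-model
hydrodynamics program) or estimated from the structure's equivalent inertia
ellipsoid via Perrin's spheroid relations, with the overall time scale fixed
by a user-supplied isotropic correlation time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate

from .relaxometry import SpectralDensities
from .sasa_map import StructureModel

__all__ = [
    "DiffusionTensor",
    "NHVector",
    "RigidBodyError",
    "predict_J",
    "estimate_tensor_ellipsoid",
    "perrin_axial_ratio",
    "nh_vectors_from_structure",
    "compare_profiles",
    "ProfileComparison",
    "read_predicted_j_tsv",
]


class RigidBodyError(ValueError):
    pass


@dataclass
class DiffusionTensor:
    """Rotational diffusion tensor: principal values and orientation.

    ``values`` are the principal diffusion rates in ascending order
    (Dx <= Dy <= Dz, s^-1); ``axes`` is a (3, 3) matrix whose row i is the
    unit principal direction of ``values[i]`` in the molecule frame.
    """

    values: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))
        self.axes = np.asarray(self.axes, dtype=float)
        if np.any(self.values <= 0):
            raise RigidBodyError("all principal diffusion rates must be positive")
        if self.axes.shape != (3, 3):
            raise RigidBodyError("axes must be a 3x3 rotation matrix")

    @classmethod
    def axial(
        cls, d_par: float, d_perp: float, axis: Sequence[float] = (0.0, 0.0, 1.0)
    ) -> "DiffusionTensor":
        """Axially symmetric tensor with the unique axis along ``axis``."""
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        # complete an orthonormal frame around the unique axis
        helper = np.array([1.0, 0.0, 0.0])
        if abs(axis @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        perp1 = np.cross(axis, helper)
        perp1 /= np.linalg.norm(perp1)
        perp2 = np.cross(axis, perp1)
        vals = np.array([d_perp, d_perp, d_par])
        rows = np.vstack([perp1, perp2, axis])
        order = np.argsort(vals)
        return cls(vals[order], rows[order])

    @property
    def tau_iso(self) -> float:
        """Isotropic rotational correlation time 1 / (2 (Dx + Dy + Dz)), s."""
        return 1.0 / (2.0 * self.values.sum())

    @property
    def is_axial(self) -> bool:
        v = self.values
        return bool(
            np.isclose(v[0], v[1], rtol=1e-6) or np.isclose(v[1], v[2], rtol=1e-6)
        )

    def axial_components(self) -> tuple[float, float, np.ndarray]:
        """(D_par, D_perp, unique_axis) for an axially symmetric tensor."""
        v = self.values
        if np.isclose(v[0], v[1], rtol=1e-6):
            return float(v[2]), float((v[0] + v[1]) / 2), self.axes[2]
        if np.isclose(v[1], v[2], rtol=1e-6):
            return float(v[0]), float((v[1] + v[2]) / 2), self.axes[0]
        raise RigidBodyError(
            "tensor is fully anisotropic (Dx != Dy != Dz); the fully "
            "anisotropic extension is not implemented — supply an axially "
            "symmetric tensor or external per-residue J predictions"
        )


@dataclass
class NHVector:
    """Unit N->H bond vector of one residue in the molecule frame."""

    residue_id: int
    vector: np.ndarray
    approximate: bool = False  # True when H was placed by convention

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        norm = np.linalg.norm(self.vector)
        if norm == 0:
            raise RigidBodyError(f"residue {self.residue_id}: zero NH vector")
        if abs(norm - 1.0) > 1e-6:
            self.vector = self.vector / norm


def predict_J(
    tensor: DiffusionTensor,
    nh: NHVector,
    omegas: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Woessner spectral density J(omega) for one NH vector, s/rad.

    Requires an axially symmetric tensor.  ``omegas`` are angular
    frequencies in rad/s; the result is positive everywhere.
    """
    d_par, d_perp, axis = tensor.axial_components()
    cos_a = float(np.clip(nh.vector @ axis, -1.0, 1.0))
    c2 = cos_a**2
    s2 = 1.0 - c2
    weights = np.array(
        [(3.0 * c2 - 1.0) ** 2 / 4.0, 3.0 * s2 * c2, 0.75 * s2**2]
    )
    taus = np.array(
        [
            1.0 / (6.0 * d_perp),
            1.0 / (5.0 * d_perp + d_par),
            1.0 / (2.0 * d_perp + 4.0 * d_par),
        ]
    )
    omegas = np.asarray(omegas, dtype=float)
    lorentz = taus / (1.0 + np.outer(omegas, taus) ** 2)  # (n_omega, 3)
    return 0.4 * lorentz @ weights


def woessner_weights(alpha: float) -> np.ndarray:
    """The three Woessner amplitude weights for angle ``alpha`` (radians)."""
    c2 = np.cos(alpha) ** 2
    s2 = 1.0 - c2
    return np.array([(3 * c2 - 1) ** 2 / 4.0, 3 * s2 * c2, 0.75 * s2**2])


# ---------------------------------------------------------------------------
# Ellipsoid surrogate for hydrodynamic predictions


def _perrin_alpha(ai: float, semi: np.ndarray) -> float:
    """Perrin integral alpha_i = int_0^inf ds / ((ai^2+s) Delta(s))."""

    def integrand(s: float) -> float:
        delta = np.sqrt(np.prod(semi**2 + s))
        return 1.0 / ((ai**2 + s) * delta)

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return val


def perrin_axial_ratio(axial_ratio: float) -> float:
    """D_par / D_perp of a spheroid with unique-to-equatorial axis ratio.

    ``axial_ratio`` = a/b with a the unique semi-axis (>1 prolate,
    <1 oblate).  Derived from Perrin's rotational friction factors; the
    viscosity and temperature cancel in the ratio.
    """
    if axial_ratio <= 0:
        raise RigidBodyError("axial ratio must be positive")
    a, b = float(axial_ratio), 1.0
    semi = np.array([a, b, b])
    alpha_a = _perrin_alpha(a, semi)
    alpha_b = _perrin_alpha(b, semi)
    d_par = alpha_b  # rotation about the unique axis
    d_perp = (a**2 * alpha_a + b**2 * alpha_b) / (a**2 + b**2)
    return float(d_par / d_perp)


def estimate_tensor_ellipsoid(
    structure: StructureModel, tau_iso: float
) -> DiffusionTensor:
    """Estimate an axially symmetric diffusion tensor from the structure shape.

    The coordinate second-moment (gyration) tensor gives the principal axes
    and, under a uniform-solid-ellipsoid model (semi-axis a_i = sqrt(5
    lambda_i)), the equivalent ellipsoid.  The spheroid axial ratio sets
    D_par/D_perp through Perrin's relations; the absolute scale comes from
    the user-supplied isotropic correlation time ``tau_iso`` (s).  This is a
    shape-only surrogate for bead-model hydrodynamics: it captures the
    anisotropy direction and magnitude trend, not hydration detail.
    """
    if structure.n_atoms < 10:
        raise RigidBodyError("need at least 10 atoms to estimate a tensor")
    if tau_iso <= 0:
        raise RigidBodyError("tau_iso must be positive")
    xyz = structure.xyz - structure.xyz.mean(axis=0)
    cov = xyz.T @ xyz / len(xyz)
    lam, vec = np.linalg.eigh(cov)  # ascending
    if lam[1] <= 1e-12 * max(lam[2], 1.0):
        raise RigidBodyError("degenerate (collinear) coordinates")
    # pick the most distinct eigenvalue as the unique (symmetry) axis
    if lam[2] - lam[1] >= lam[1] - lam[0]:
        unique_axis = vec[:, 2]  # prolate-like: long axis unique
        a = np.sqrt(5 * lam[2])
        b = np.sqrt(5 * (lam[0] + lam[1]) / 2)
    else:
        unique_axis = vec[:, 0]  # oblate-like: short axis unique
        a = np.sqrt(5 * lam[0])
        b = np.sqrt(5 * (lam[1] + lam[2]) / 2)
    ratio = perrin_axial_ratio(a / b)
    d_iso = 1.0 / (6.0 * tau_iso)
    d_perp = 3.0 * d_iso / (2.0 + ratio)
    d_par = ratio * d_perp
    return DiffusionTensor.axial(d_par, d_perp, unique_axis)


# ---------------------------------------------------------------------------
# NH vectors from structures


def nh_vectors_from_structure(structure: StructureModel) -> list[NHVector]:
    """Backbone N->H unit vectors, one per residue where derivable.

    Uses the H position when present.  When hydrogens are absent, H is
    placed along the bisector convention — opposite the bisector of the
    N-CA and N-C(i-1) bond directions — and the vector is flagged
    approximate.  Residues lacking the needed atoms are skipped.
    """
    out: list[NHVector] = []
    by_res: dict[int, dict[str, np.ndarray]] = {}
    for i in range(structure.n_atoms):
        by_res.setdefault(int(structure.residue_id[i]), {})[
            str(structure.atom_name[i])
        ] = structure.xyz[i]
    for res in sorted(by_res):
        atoms = by_res[res]
        if "N" not in atoms:
            continue
        n = atoms["N"]
        if "H" in atoms:
            out.append(NHVector(res, atoms["H"] - n, approximate=False))
            continue
        prev = by_res.get(res - 1, {})
        if "CA" in atoms and "C" in prev:
            u = atoms["CA"] - n
            v = prev["C"] - n
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            bisector = u + v
            norm = np.linalg.norm(bisector)
            if norm < 1e-9:
                continue
            out.append(NHVector(res, -bisector / norm, approximate=True))
    return out


# ---------------------------------------------------------------------------
# Observed vs predicted comparison


@dataclass
class ProfileComparison:
    """Per-residue excess of observed over rigid-body-predicted J(0)."""

    residues: list[int]
    delta_j0: dict[int, float]
    delta_err: dict[int, float]
    flagged: list[int]
    k: float


def compare_profiles(
    observed: Sequence[SpectralDensities],
    predicted: Mapping[int, float] | Mapping[int, tuple[float, float]],
    k: float = 2.0,
) -> ProfileComparison:
    """Excess J(0) of observed over predicted, flagging candidate dynamics.

    ``predicted`` maps residue -> J0 or (J0, err) in s/rad.  A residue is
    flagged as a candidate for ms-us dynamics when its excess exceeds ``k``
    times the combined error (observed and predicted errors in quadrature);
    with zero stated errors any positive excess flags.
    """
    shared = [s for s in observed if s.residue_id in predicted]
    if not shared:
        raise RigidBodyError("observed and predicted profiles share no residues")
    delta: dict[int, float] = {}
    derr: dict[int, float] = {}
    flagged: list[int] = []
    for s in shared:
        pred = predicted[s.residue_id]
        if isinstance(pred, (tuple, list)):
            pj0, perr = float(pred[0]), float(pred[1])
        else:
            pj0, perr = float(pred), 0.0
        d = s.j0 - pj0
        e = float(np.hypot(s.j0_err, perr))
        delta[s.residue_id] = d
        derr[s.residue_id] = e
        if d > k * e:
            flagged.append(s.residue_id)
    return ProfileComparison(
        [s.residue_id for s in shared], delta, derr, sorted(flagged), k
    )


def read_predicted_j_tsv(source: str | Path) -> dict[int, tuple[float, float]]:
    """Read externally computed per-residue J(0) predictions.

    Expects columns ``residue`` and ``J0`` (s/rad) and optionally ``J0_err``;
    this is the ingestion path for bead-model hydrodynamics output.
    """
    df = pd.read_csv(source, sep="\t")
    if "residue" not in df.columns or "J0" not in df.columns:
        raise RigidBodyError("predicted-J TSV needs columns 'residue' and 'J0'")
    err = df["J0_err"] if "J0_err" in df.columns else pd.Series(0.0, index=df.index)
    return {
        int(r): (float(j), float(e))
        for r, j, e in zip(df["residue"], df["J0"], err)
    }
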