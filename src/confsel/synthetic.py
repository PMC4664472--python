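"""Synthetic ground-truth data for every pipeline stage.

Three generators, all driven by explicit seeded :class:`numpy.random.Generator`
state (never global):

* two-state fast-exchange shift tables — an apo table built as the
  population-weighted average of active and inactive endpoint tables plus
  Gaussian shift noise, with the inactive fraction p known per residue;
* model-free (Lipari-Szabo) 15N relaxation tables — R1/R2/NOE computed from
  the full five-frequency dipolar + CSA expressions for a two-time-scale
  spectral density, with optional exchange broadening Rex added to R2, and
  the ground-truth J values emitted alongside;
* toy structures — ideal helices, two-lobe contact clusters with a designed
  interface, and isotropic sphere clouds, for the SASA and diffusion-tensor
  stages.

Defaults emulate the tandem CBD study conditions: inactive fractions 0.5
(CBD-A) and 0.7 (CBD-B), shift noise 0.005 / 0.025 ppm (1H / 15N), endpoint
separations 0.02-0.3 ppm (1H) and 0.1-1.5 ppm (15N), relaxation at 700.13 MHz
with tau_c = 18 ns and S^2 = 0.85, and Rex = 3 s^-1 confined to the CBD-A
hinge when requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .relaxometry import PhysicalConstants, RelaxationRecord
from .sasa_map import StructureModel
from .shift_tables import ShiftTable

__all__ = [
    "TwoStateConfig",
    "TwoStateTables",
    "ModelFreeConfig",
    "RelaxationFixture",
    "gen_two_state_tables",
    "gen_relaxation",
    "gen_toy_structure",
    "default_two_state_config",
    "default_relaxation_config",
    "model_free_j",
]


# ---------------------------------------------------------------------------
# Two-state fast-exchange shift tables


@dataclass
class TwoStateConfig:
    """Ground truth for a fast-exchange two-state shift fixture.

    ``endpoints`` maps residue -> ((H_active, N_active), (H_inactive,
    N_inactive)) in ppm; ``p`` is the inactive molar fraction, scalar or per
    residue; ``noise_h`` / ``noise_n`` are the Gaussian shift noise SDs
    applied to the apo table; ``endpoint_noise`` optionally adds independent
    noise to the endpoint tables as well (0 keeps them exact).
    """

    endpoints: dict[int, tuple[tuple[float, float], tuple[float, float]]]
    p: float | Mapping[int, float] = 0.5
    noise_h: float = 0.005
    noise_n: float = 0.025
    endpoint_noise: float = 0.0
    seed: int | None = None

    def p_of(self, res: int) -> float:
        p = self.p[res] if isinstance(self.p, Mapping) else float(self.p)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"inactive fraction p={p} outside [0, 1]")
        return p

    def __post_init__(self) -> None:
        if min(self.noise_h, self.noise_n, self.endpoint_noise) < 0:
            raise ValueError("noise SDs must be >= 0")
        for res in self.endpoints:
            self.p_of(res)


@dataclass
class TwoStateTables:
    apo: ShiftTable
    active: ShiftTable
    inactive: ShiftTable
    config: TwoStateConfig


def gen_two_state_tables(cfg: TwoStateConfig) -> TwoStateTables:
    """Generate {apo, active-endpoint, inactive-endpoint} shift tables.

    The apo shift of each nucleus is ``p * inactive + (1 - p) * active`` plus
    Gaussian noise.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(cfg.seed)
    apo: dict[int, tuple[float, float]] = {}
    act: dict[int, tuple[float, float]] = {}
    inact: dict[int, tuple[float, float]] = {}
    for res in sorted(cfg.endpoints):
        (ha, na), (hi, ni) = cfg.endpoints[res]
        p = cfg.p_of(res)
        h = p * hi + (1 - p) * ha + cfg.noise_h * rng.standard_normal()
        n = p * ni + (1 - p) * na + cfg.noise_n * rng.standard_normal()
        apo[res] = (h, n)
        if cfg.endpoint_noise > 0:
            e = cfg.endpoint_noise
            act[res] = (ha + e * rng.standard_normal(), na + 5 * e * rng.standard_normal())
            inact[res] = (hi + e * rng.standard_normal(), ni + 5 * e * rng.standard_normal())
        else:
            act[res] = (ha, na)
            inact[res] = (hi, ni)
    return TwoStateTables(
        ShiftTable("apo", apo),
        ShiftTable("cAMP2", act),
        ShiftTable("C-bound", inact),
        cfg,
    )


def default_two_state_config(
    n_per_domain: int = 30,
    p_a: float = 0.5,
    p_b: float = 0.7,
    seed: int | None = 0,
    noise_h: float = 0.005,
    noise_n: float = 0.025,
) -> TwoStateConfig:
    """Study-condition fixture: two domains with known inactive fractions.

    Reporter residues are placed in the non-overlapping parts of the two
    tandem domains (CBD-A 119-243, CBD-B 269-379) so their domain membership
    is unambiguous.  Endpoint peak positions sit in the amide region and the
    active-to-inactive separations are drawn once per residue from
    0.02-0.3 ppm (1H) and 0.1-1.5 ppm (15N) with random signs.
    """
    rng = np.random.default_rng(seed)
    res_a = sorted(rng.choice(np.arange(119, 244), size=n_per_domain, replace=False))
    res_b = sorted(rng.choice(np.arange(269, 380), size=n_per_domain, replace=False))
    endpoints: dict[int, tuple[tuple[float, float], tuple[float, float]]] = {}
    p_map: dict[int, float] = {}
    for residues, p in ((res_a, p_a), (res_b, p_b)):
        for res in residues:
            h0 = rng.uniform(7.2, 9.3)
            n0 = rng.uniform(105.0, 130.0)
            dh = rng.uniform(0.02, 0.30) * rng.choice([-1.0, 1.0])
            dn = rng.uniform(0.10, 1.50) * rng.choice([-1.0, 1.0])
            endpoints[int(res)] = ((h0, n0), (h0 + dh, n0 + dn))
            p_map[int(res)] = p
    return TwoStateConfig(
        endpoints,
        p_map,
        noise_h=noise_h,
        noise_n=noise_n,
        seed=None if seed is None else seed + 1,
    )


# ---------------------------------------------------------------------------
# Model-free relaxation data


def model_free_j(
    omega: np.ndarray | float, s2: float, tau_c: float, tau_e: float
) -> np.ndarray:
    """Two-time-scale Lipari-Szabo spectral density, s/rad.

    ``J(w) = (2/5) [S^2 tau_c / (1 + (w tau_c)^2)
    + (1 - S^2) tau' / (1 + (w tau')^2)]`` with
    ``1/tau' = 1/tau_c + 1/tau_e``.  Times in seconds, omega in rad/s.
    """
    omega = np.asarray(omega, dtype=float)
    tau_p = 1.0 / (1.0 / tau_c + 1.0 / tau_e)
    return 0.4 * (
        s2 * tau_c / (1.0 + (omega * tau_c) ** 2)
        + (1.0 - s2) * tau_p / (1.0 + (omega * tau_p) ** 2)
    )


@dataclass
class ModelFreeConfig:
    """Ground truth for a model-free relaxation fixture.

    ``s2`` (order parameter) and ``rex`` (exchange broadening, s^-1) may be
    scalars or per-residue maps; ``tau_c`` is the overall tumbling time (ns),
    ``tau_e`` the internal correlation time (ps).  Noise is fractional for
    R1/R2 and absolute for the NOE, applied last.
    """

    residues: Sequence[int]
    s2: float | Mapping[int, float] = 0.85
    tau_c_ns: float = 18.0
    tau_e_ps: float = 50.0
    rex: float | Mapping[int, float] = 0.0
    field_MHz: float = 700.13
    noise_frac_r1: float = 0.02
    noise_frac_r2: float = 0.02
    noise_abs_noe: float = 0.03
    seed: int | None = None

    def s2_of(self, res: int) -> float:
        v = self.s2[res] if isinstance(self.s2, Mapping) else float(self.s2)
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"S2={v} outside [0, 1]")
        return v

    def rex_of(self, res: int) -> float:
        v = self.rex.get(res, 0.0) if isinstance(self.rex, Mapping) else float(self.rex)
        if v < 0:
            raise ValueError("Rex must be >= 0")
        return v

    def __post_init__(self) -> None:
        if self.tau_c_ns <= 0 or self.tau_e_ps <= 0:
            raise ValueError("tau_c and tau_e must be positive")


@dataclass
class RelaxationFixture:
    records: list[RelaxationRecord]
    truth_j: dict[int, tuple[float, float, float]]  # res -> (J0, JwN, JwH)
    rex: dict[int, float]
    config: ModelFreeConfig


def gen_relaxation(
    cfg: ModelFreeConfig, k: PhysicalConstants | None = None
) -> RelaxationFixture:
    """Forward-simulate (R1, R2, NOE) from model-free dynamics parameters.

    Rates use the full five-frequency dipolar + CSA expressions (no
    high-frequency approximation), so mapping them back through the reduced
    scheme probes the documented approximation error.  The ground-truth J
    values are evaluated at the frequencies the reduced mapping reports
    (0, omegaN, and the effective high frequency).  Rex adds to R2 only.
    """
    k = k or PhysicalConstants()
    rng = np.random.default_rng(cfg.seed)
    wh = k.omega_h(cfg.field_MHz)
    wn = k.omega_n(cfg.field_MHz)
    d2 = k.d**2
    c2 = k.c(cfg.field_MHz) ** 2
    tau_c = cfg.tau_c_ns * 1e-9
    tau_e = cfg.tau_e_ps * 1e-12

    records: list[RelaxationRecord] = []
    truth: dict[int, tuple[float, float, float]] = {}
    rex_map: dict[int, float] = {}
    freqs = np.array([0.0, wn, wh - wn, wh, wh + wn])
    for res in cfg.residues:
        s2 = cfg.s2_of(res)
        rex = cfg.rex_of(res)
        j = model_free_j(freqs, s2, tau_c, tau_e)
        j0, jn, jhmn, jh, jhpn = j
        r1 = (d2 / 4.0) * (jhmn + 3 * jn + 6 * jhpn) + c2 * jn
        r2 = (
            (d2 / 8.0) * (4 * j0 + jhmn + 3 * jn + 6 * jh + 6 * jhpn)
            + (c2 / 6.0) * (4 * j0 + 3 * jn)
            + rex
        )
        sigma = (d2 / 4.0) * (6 * jhpn - jhmn)
        noe = 1.0 + sigma / (r1 * k.gamma_ratio)

        r1_err = cfg.noise_frac_r1 * r1
        r2_err = cfg.noise_frac_r2 * r2
        noe_err = cfg.noise_abs_noe
        r1_obs = r1 + r1_err * rng.standard_normal()
        r2_obs = r2 + r2_err * rng.standard_normal()
        noe_obs = noe + noe_err * rng.standard_normal()
        records.append(
            RelaxationRecord(
                int(res), r1_obs, r2_obs, noe_obs,
                r1_err, r2_err, noe_err, cfg.field_MHz,
            )
        )
        jwh_truth = float(model_free_j(k.omega_high(cfg.field_MHz), s2, tau_c, tau_e))
        truth[int(res)] = (float(j0), float(jn), jwh_truth)
        rex_map[int(res)] = rex
    return RelaxationFixture(records, truth, rex_map, cfg)


def default_relaxation_config(
    residues: Sequence[int] | None = None,
    tau_c_ns: float = 18.0,
    hinge_rex: float = 3.0,
    hinge_range: tuple[int, int] = (226, 251),
    seed: int | None = 0,
    **kwargs,
) -> ModelFreeConfig:
    """Study-condition relaxation fixture over the full construct.

    Residues 119-379 with uniform S^2 = 0.85 and an Rex contribution
    confined to the CBD-A hinge helices — the ms-us dynamics signature the
    J(0) profile is expected to flag.  ``tau_c_ns=18`` emulates the compact
    cAMP2-bound tandem construct; use ~15 ns for the de-correlated
    (interface-disrupted) condition.
    """
    if residues is None:
        residues = list(range(119, 380))
    rex = {r: hinge_rex for r in range(hinge_range[0], hinge_range[1] + 1)}
    return ModelFreeConfig(
        list(residues), tau_c_ns=tau_c_ns, rex=rex, seed=seed, **kwargs
    )


# ---------------------------------------------------------------------------
# Toy structures


def gen_toy_structure(
    kind: str,
    n_residues: int = 20,
    seed: int | None = 0,
    gap: float = 3.0,
) -> tuple[StructureModel, dict]:
    """Generate a toy structure with a known geometry.

    ``kind`` is one of:

    * ``"helix"`` — an ideal alpha-helix with N, H, CA and C atoms per
      residue (NH vectors well defined);
    * ``"two_lobe"`` — two 3x3x3 residue grids (5 A spacing, one atom per
      residue) whose facing layers are ``gap`` A apart; the designed contact
      residues are returned in the info dict (``n_residues`` is ignored);
    * ``"sphere_cloud"`` — ``n_residues`` single-atom residues uniform in a
      solid sphere (isotropic by construction).

    Returns ``(structure, info)`` where info carries the ground truth
    (contact sets, lobe memberships, designed geometry).
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(seed)

    if kind == "helix":
        element, name, resid, xyz = [], [], [], []
        rise, twist = 1.5, np.deg2rad(100.0)
        for i in range(n_residues):
            res = i + 1
            ang = i * twist
            ca = np.array([2.3 * np.cos(ang), 2.3 * np.sin(ang), i * rise])
            n_pos = np.array(
                [1.6 * np.cos(ang - 0.49), 1.6 * np.sin(ang - 0.49), i * rise - 0.9]
            )
            h_pos = n_pos + 1.02 * np.array([0.28 * np.cos(ang - 0.49),
                                             0.28 * np.sin(ang - 0.49), -0.96])
            h_pos = n_pos + 1.02 * (h_pos - n_pos) / np.linalg.norm(h_pos - n_pos)
            c_pos = np.array(
                [2.0 * np.cos(ang + 0.47), 2.0 * np.sin(ang + 0.47), i * rise + 0.7]
            )
            for el, nm, p in (("N", "N", n_pos), ("H", "H", h_pos),
                              ("C", "CA", ca), ("C", "C", c_pos)):
                element.append(el)
                name.append(nm)
                resid.append(res)
                xyz.append(p)
        structure = StructureModel.from_arrays(element, resid, np.array(xyz),
                                               atom_name=name)
        return structure, {"kind": "helix", "axis": np.array([0.0, 0.0, 1.0])}

    if kind == "two_lobe":
        spacing = 5.0
        coords, resid = [], []
        res = 0
        lobe_a, lobe_b, face_a, face_b = [], [], [], []
        for ix in range(3):  # lobe A: x = -10, -5, 0
            for iy in range(3):
                for iz in range(3):
                    res += 1
                    coords.append([-10.0 + ix * spacing, iy * spacing, iz * spacing])
                    resid.append(res)
                    lobe_a.append(res)
                    if ix == 2:
                        face_a.append(res)
        for ix in range(3):  # lobe B: x = gap, gap+5, gap+10
            for iy in range(3):
                for iz in range(3):
                    res += 1
                    coords.append([gap + ix * spacing, iy * spacing, iz * spacing])
                    resid.append(res)
                    lobe_b.append(res)
                    if ix == 0:
                        face_b.append(res)
        structure = StructureModel.from_arrays(
            ["C"] * len(resid), resid, np.array(coords)
        )
        # contacts exist only when the inflated spheres can occlude each other
        touching = gap < 2 * (1.7 + 1.4)
        return structure, {
            "kind": "two_lobe",
            "gap": gap,
            "lobe_a": lobe_a,
            "lobe_b": lobe_b,
            "contacts_a": face_a if touching else [],
            "contacts_b": face_b if touching else [],
        }

    if kind == "sphere_cloud":
        # uniform in a solid sphere via rejection-free radial inversion
        u = rng.standard_normal((n_residues, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = 15.0 * rng.uniform(0, 1, n_residues) ** (1 / 3)
        xyz = u * r[:, None]
        structure = StructureModel.from_arrays(
            ["C"] * n_residues, np.arange(1, n_residues + 1), xyz
        )
        return structure, {"kind": "sphere_cloud", "radius": 15.0}

    raise ValueError(f"unknown toy-structure kind '{kind}'")
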