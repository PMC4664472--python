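"""Reduced spectral density mapping of backbone 15N relaxation.

Per-residue longitudinal (R1) and transverse (R2) 15N relaxation rates plus
the {1H}-15N heteronuclear NOE are mapped algebraically into the spectral
density of the N-H bond reorientation at three frequencies: J(0), J(omegaN)
and J(0.87*omegaH).  The mapping uses the standard high-frequency
approximation J(omegaH - omegaN) ~ J(omegaH) ~ J(omegaH + omegaN) ~
J(0.87*omegaH), which collapses the five-frequency relaxation equations into
three linear relations:

    sigma_NH = R1 * (NOE - 1) * gammaN / gammaH
    J(0.87wH) = 4 * sigma_NH / (5 d^2)
    J(wN)     = (R1 - 7 (d^2/4) J(0.87wH)) / (3 d^2 / 4 + c^2)
    J(0)      = (R2 - (d^2/8)(3 J(wN) + 13 J(0.87wH)) - (c^2/6) 3 J(wN))
                / (d^2/2 + 2 c^2/3)

with d the dipolar coupling constant for the amide N-H pair and
c = omegaN * delta_sigma / sqrt(3) the 15N CSA constant.  No exchange term is
subtracted from R2, so any ms-us conformational exchange inflates J(0) by
exactly Rex / (d^2/2 + 2 c^2/3) — this deliberate convention is what makes
elevated J(0) a diagnostic for slow residual dynamics.

Uncertainties are propagated by Monte-Carlo resampling of (R1, R2, NOE).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import constants as spc

from .shift_tables import DomainDefinition

__all__ = [
    "PhysicalConstants",
    "RelaxationRecord",
    "SpectralDensities",
    "RelaxometryError",
    "reduce_map",
    "mc_propagate",
    "region_average",
    "rates_from_spectral_densities",
    "read_relaxation_tsv",
    "write_relaxation_tsv",
    "spectral_densities_to_frame",
]

GAMMA_H = 2.6752218744e8  # rad s^-1 T^-1, 1H gyromagnetic ratio


class RelaxometryError(ValueError):
    pass


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants of the amide 15N relaxation model.

    rNH is the effective N-H bond length (1.02 A default), delta_sigma the
    15N chemical-shift anisotropy (-160 ppm default), gamma_ratio the
    gammaN/gammaH ratio.  The dipolar constant d and CSA constant c are
    always derived from these fields, never stored.  ``high_freq_scale``
    sets the effective frequency reported for the high-frequency density
    (0.87*omegaH by default; set to ``None`` to report omegaH + omegaN).
    """

    rNH_angstrom: float = 1.02
    delta_sigma_ppm: float = -160.0
    gamma_ratio: float = -0.10136
    high_freq_scale: float | None = 0.87

    def __post_init__(self) -> None:
        if not (self.rNH_angstrom > 0 and np.isfinite(self.delta_sigma_ppm)):
            raise RelaxometryError("invalid physical constants")

    @property
    def gamma_n(self) -> float:
        return GAMMA_H * self.gamma_ratio

    @property
    def d(self) -> float:
        """Dipolar constant mu0*hbar*gammaH*gammaN/(4 pi rNH^3), rad/s (signed)."""
        r = self.rNH_angstrom * 1e-10
        return spc.mu_0 * spc.hbar * GAMMA_H * self.gamma_n / (4 * np.pi * r**3)

    def omega_h(self, field_MHz: float) -> float:
        """1H Larmor frequency magnitude, rad/s."""
        return 2 * np.pi * field_MHz * 1e6

    def omega_n(self, field_MHz: float) -> float:
        """15N Larmor frequency magnitude, rad/s."""
        return self.omega_h(field_MHz) * abs(self.gamma_ratio)

    def c(self, field_MHz: float) -> float:
        """CSA constant omegaN * delta_sigma / sqrt(3), rad/s."""
        return self.omega_n(field_MHz) * self.delta_sigma_ppm * 1e-6 / np.sqrt(3)

    def omega_high(self, field_MHz: float) -> float:
        """Effective frequency assigned to the high-frequency density."""
        if self.high_freq_scale is not None:
            return self.high_freq_scale * self.omega_h(field_MHz)
        return self.omega_h(field_MHz) + self.omega_n(field_MHz)


@dataclass
class RelaxationRecord:
    """Measured 15N relaxation of one residue at a stated 1H field."""

    residue_id: int
    r1: float  # s^-1
    r2: float  # s^-1
    noe: float  # dimensionless {1H}-15N NOE
    r1_err: float = 0.0
    r2_err: float = 0.0
    noe_err: float = 0.0
    field_MHz: float = 700.13

    def __post_init__(self) -> None:
        if not (self.r1 > 0 and self.r2 > 0):
            raise RelaxometryError(
                f"residue {self.residue_id}: R1 and R2 must be positive"
            )
        if min(self.r1_err, self.r2_err, self.noe_err) < 0:
            raise RelaxometryError(f"residue {self.residue_id}: negative error")
        if self.field_MHz <= 0:
            raise RelaxometryError("field_MHz must be positive")


@dataclass
class SpectralDensities:
    """Reduced spectral densities (s/rad) for one residue with errors.

    ``omega_n`` / ``omega_high`` record the frequencies (rad/s) at which JwN
    and JwH are reported.  ``noe_flag`` marks records whose NOE exceeded the
    physical bound; ``jwh_negative`` marks a JwH below zero by more than its
    error (both are reported, never silently fixed).
    """

    residue_id: int
    j0: float
    jwn: float
    jwh: float
    j0_err: float = 0.0
    jwn_err: float = 0.0
    jwh_err: float = 0.0
    omega_n: float = 0.0
    omega_high: float = 0.0
    noe_flag: bool = False

    @property
    def jwh_negative(self) -> bool:
        return self.jwh < -self.jwh_err


def _reduce(r1, r2, noe, k: PhysicalConstants, field_MHz: float):
    """Vector-friendly core of the reduced mapping."""
    d2 = k.d**2
    c2 = k.c(field_MHz) ** 2
    sigma = r1 * (noe - 1.0) * k.gamma_ratio
    jwh = 4.0 * sigma / (5.0 * d2)
    jwn = (r1 - 7.0 * (d2 / 4.0) * jwh) / (3.0 * d2 / 4.0 + c2)
    j0 = (r2 - (d2 / 8.0) * (3.0 * jwn + 13.0 * jwh) - (c2 / 6.0) * 3.0 * jwn) / (
        d2 / 2.0 + 2.0 * c2 / 3.0
    )
    return j0, jwn, jwh


def reduce_map(
    rec: RelaxationRecord,
    k: PhysicalConstants | None = None,
    noe_upper: float = 1.05,
) -> SpectralDensities:
    """Map one (R1, R2, NOE) record into J(0), J(wN), J(0.87wH).

    A NOE above ``noe_upper`` (default 1.05) is physically impossible for an
    amide 15N and flags the record; the mapping is still computed so the
    offending value is visible downstream.
    """
    k = k or PhysicalConstants()
    j0, jwn, jwh = _reduce(rec.r1, rec.r2, rec.noe, k, rec.field_MHz)
    return SpectralDensities(
        rec.residue_id,
        float(j0),
        float(jwn),
        float(jwh),
        omega_n=k.omega_n(rec.field_MHz),
        omega_high=k.omega_high(rec.field_MHz),
        noe_flag=bool(rec.noe > noe_upper),
    )


def mc_propagate(
    rec: RelaxationRecord,
    k: PhysicalConstants | None = None,
    n_mc: int = 1000,
    seed: int | None = None,
) -> SpectralDensities:
    """Reduced mapping with Monte-Carlo error propagation.

    (R1, R2, NOE) are resampled ``n_mc`` times from independent Gaussians at
    their stated errors; the output errors are the SDs of the resulting J
    values.  Deterministic for a given seed.
    """
    if n_mc < 100:
        raise RelaxometryError("n_mc must be >= 100")
    k = k or PhysicalConstants()
    out = reduce_map(rec, k)
    if rec.r1_err == rec.r2_err == rec.noe_err == 0.0:
        return out  # degenerate resampling: every draw reproduces the input
    rng = np.random.default_rng(seed)
    r1 = rec.r1 + rec.r1_err * rng.standard_normal(n_mc)
    r2 = rec.r2 + rec.r2_err * rng.standard_normal(n_mc)
    noe = rec.noe + rec.noe_err * rng.standard_normal(n_mc)
    j0, jwn, jwh = _reduce(r1, r2, noe, k, rec.field_MHz)
    out.j0_err = float(np.std(j0, ddof=1))
    out.jwn_err = float(np.std(jwn, ddof=1))
    out.jwh_err = float(np.std(jwh, ddof=1))
    return out


def rates_from_spectral_densities(
    j0: float,
    jwn: float,
    jwh: float,
    k: PhysicalConstants | None = None,
    field_MHz: float = 700.13,
    rex: float = 0.0,
    noe_from: str = "reduced",
) -> tuple[float, float, float]:
    """Forward-simulate (R1, R2, NOE) from a spectral-density triple.

    With ``noe_from="reduced"`` the same three linear relations used by
    :func:`reduce_map` are applied in the forward direction, so the mapping
    inverts this function exactly (an algebraic round trip).  ``rex`` adds a
    pure exchange contribution to R2 only.
    """
    if noe_from != "reduced":
        raise RelaxometryError("only the reduced forward convention is supported")
    k = k or PhysicalConstants()
    d2 = k.d**2
    c2 = k.c(field_MHz) ** 2
    r1 = (3.0 * d2 / 4.0 + c2) * jwn + 7.0 * (d2 / 4.0) * jwh
    r2 = (
        (d2 / 2.0 + 2.0 * c2 / 3.0) * j0
        + (d2 / 8.0) * (3.0 * jwn + 13.0 * jwh)
        + (c2 / 6.0) * 3.0 * jwn
        + rex
    )
    sigma = 5.0 * d2 * jwh / 4.0
    noe = 1.0 + sigma / (r1 * k.gamma_ratio)
    return float(r1), float(r2), float(noe)


@dataclass
class RegionAverage:
    """Mean +/- SD of each reduced spectral density over a residue region."""

    domain: str
    region: str
    j0_mean: float
    j0_sd: float
    jwn_mean: float
    jwn_sd: float
    jwh_mean: float
    jwh_sd: float
    n: int


def region_average(
    densities: Iterable[SpectralDensities],
    domain: DomainDefinition,
    region: str = "Total",
) -> RegionAverage:
    """Average J(0), J(wN), J(wH) over the residues of a named region.

    Residues without data are skipped; ``n`` reports how many contributed.
    Fewer than two residues with data is an error.
    """
    residues = set(domain.region_residues(region))
    rows = [s for s in densities if s.residue_id in residues]
    if len(rows) < 2:
        raise RelaxometryError(
            f"region '{region}' of '{domain.name}': need >= 2 residues with "
            f"data, found {len(rows)}"
        )
    j0 = np.array([s.j0 for s in rows])
    jwn = np.array([s.jwn for s in rows])
    jwh = np.array([s.jwh for s in rows])
    return RegionAverage(
        domain.name,
        region,
        float(j0.mean()),
        float(j0.std(ddof=1)),
        float(jwn.mean()),
        float(jwn.std(ddof=1)),
        float(jwh.mean()),
        float(jwh.std(ddof=1)),
        len(rows),
    )


# ---------------------------------------------------------------------------
# TSV I/O

_COLUMNS = ["residue", "R1", "R1_err", "R2", "R2_err", "NOE", "NOE_err"]


def read_relaxation_tsv(
    source: str | Path | io.TextIOBase, field_MHz: float = 700.13
) -> list[RelaxationRecord]:
    """Read a relaxation table (columns residue R1 R1_err R2 R2_err NOE NOE_err)."""
    df = pd.read_csv(source, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise RelaxometryError(f"relaxation TSV missing column(s): {missing}")
    return [
        RelaxationRecord(
            int(row.residue),
            float(row.R1),
            float(row.R2),
            float(row.NOE),
            float(row.R1_err),
            float(row.R2_err),
            float(row.NOE_err),
            field_MHz,
        )
        for row in df.itertuples()
    ]


def write_relaxation_tsv(
    records: Sequence[RelaxationRecord], target: str | Path | io.TextIOBase
) -> None:
    df = pd.DataFrame(
        {
            "residue": [r.residue_id for r in records],
            "R1": [r.r1 for r in records],
            "R1_err": [r.r1_err for r in records],
            "R2": [r.r2 for r in records],
            "R2_err": [r.r2_err for r in records],
            "NOE": [r.noe for r in records],
            "NOE_err": [r.noe_err for r in records],
        }
    )
    df.to_csv(target, sep="\t", index=False, float_format="%.6g")


def spectral_densities_to_frame(densities: Sequence[SpectralDensities]) -> pd.DataFrame:
    """Per-residue J table as a DataFrame (for TSV export and plotting)."""
    return pd.DataFrame(
        {
            "residue": [s.residue_id for s in densities],
            "J0": [s.j0 for s in densities],
            "J0_err": [s.j0_err for s in densities],
            "JwN": [s.jwn for s in densities],
            "JwN_err": [s.jwn_err for s in densities],
            "JwH": [s.jwh for s in densities],
            "JwH_err": [s.jwh_err for s in densities],
            "noe_flag": [s.noe_flag for s in densities],
        }
    )
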