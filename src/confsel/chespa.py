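"""Chemical Shift Projection Analysis (CHESPA).

For every residue assigned in three states — a perturbed state and two
reference states that bracket a conformational equilibrium — CHESPA builds two
vectors in compounded (1H, alpha*15N) shift space:

* ``vecA`` = perturbed - reference1
* ``vecB`` = reference2 - reference1  (the full inter-state "activation" vector)

and reports

* ``cos_theta`` — the angle cosine between the two vectors, a per-residue
  linearity statistic (|cos_theta| near 1 means the perturbed peak lies on the
  line joining the two reference peaks, as expected for fast two-state
  exchange between the reference conformations), and
* ``X = (vecA . vecB) / |vecB|**2`` — the fractional shift of the perturbed
  peak along the reference1 -> reference2 direction.

In the canonical orientation for PKA RIalpha, reference1 is the cAMP2-bound
(active) state, reference2 the C-subunit-bound (inactive) state and the
perturbed state is apo, so X is the apo fractional *inhibition*; the
fractional activation is 1 - X.  Under fast exchange with populations
p (inactive) and 1-p (active), X estimates p residue by residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .shift_tables import DEFAULT_ALPHA, DomainDefinition, ShiftTable

__all__ = [
    "ChespaRecord",
    "ChespaError",
    "chespa_analyze",
    "filter_linear",
    "domain_fractional_activation",
    "records_to_rows",
]

#: Default minimum |vecB| (ppm, compounded space) for a residue to count as a
#: reporter: residues whose shifts barely distinguish the two reference
#: states carry no information about the equilibrium.
DEFAULT_MIN_MAGB = 0.02


class ChespaError(ValueError):
    pass


@dataclass
class ChespaRecord:
    """Per-residue CHESPA output.

    ``cos_theta`` is ``None`` (and ``defined`` False) when the perturbation
    vector has zero length — the perturbed peak coincides with reference1 —
    because the angle is then geometrically undefined.  X is still 0 in that
    case and remains usable.
    """

    residue_id: int
    vecA: tuple[float, float]
    vecB: tuple[float, float]
    magA: float
    magB: float
    cos_theta: float | None
    X: float

    @property
    def defined(self) -> bool:
        return self.cos_theta is not None


def chespa_analyze(
    perturbed: ShiftTable,
    ref1: ShiftTable,
    ref2: ShiftTable,
    alpha: float = DEFAULT_ALPHA,
    min_magB: float = DEFAULT_MIN_MAGB,
) -> list[ChespaRecord]:
    """Run CHESPA over the residues shared by all three tables.

    Vectors are formed as ``(delta_dH, alpha * delta_dN)``.  Residues with
    ``|vecB| < min_magB`` are dropped as non-reporters; fewer than three
    survivors is an error (the cutoff is then too aggressive for the data).
    """
    if min_magB < 0:
        raise ChespaError("min_magB must be >= 0")
    shared = perturbed.shared_residues(ref1, ref2)
    if not shared:
        raise ChespaError("the three tables share no residues")

    dA = perturbed.deltas(ref1, shared)
    dB = ref2.deltas(ref1, shared)
    dA[:, 1] *= alpha
    dB[:, 1] *= alpha

    records: list[ChespaRecord] = []
    for i, res in enumerate(shared):
        magB = float(np.hypot(*dB[i]))
        if magB < min_magB or magB == 0.0:
            continue
        magA = float(np.hypot(*dA[i]))
        dot = float(dA[i] @ dB[i])
        x = dot / magB**2
        cos = dot / (magA * magB) if magA > 0 else None
        if cos is not None:
            cos = float(np.clip(cos, -1.0, 1.0))
        records.append(
            ChespaRecord(res, tuple(dA[i]), tuple(dB[i]), magA, magB, cos, x)
        )
    if len(records) < 3:
        raise ChespaError(
            f"only {len(records)} residues exceed min_magB={min_magB} ppm; "
            "lower the cutoff"
        )
    return records


def filter_linear(
    records: Iterable[ChespaRecord], cos_cut: float = 0.95
) -> list[ChespaRecord]:
    """Keep records whose peaks form a linear three-state pattern.

    Retains records with a defined cos_theta and ``|cos_theta| > cos_cut``
    (default 0.95).  May return an empty list.
    """
    if not 0 < cos_cut <= 1:
        raise ChespaError("cos_cut must lie in (0, 1]")
    return [r for r in records if r.defined and abs(r.cos_theta) > cos_cut]


def domain_fractional_activation(
    records: Iterable[ChespaRecord], domain: DomainDefinition
) -> tuple[float, float, int]:
    """Mean and sample SD of X over the records inside a domain.

    Returns ``(mean_X, sd_X, n)``.  In the canonical orientation X is the
    fractional inhibition; report ``1 - mean_X`` for fractional activation
    when the references are ordered active -> inactive.
    """
    xs = np.array([r.X for r in records if domain.contains(r.residue_id)])
    if xs.size < 2:
        raise ChespaError(
            f"need >= 2 records inside '{domain.name}', found {xs.size}"
        )
    return float(xs.mean()), float(xs.std(ddof=1)), int(xs.size)


def records_to_rows(records: Sequence[ChespaRecord], cos_cut: float = 0.95) -> list[dict]:
    """Flatten records for TSV/JSON export, with a retained flag at *cos_cut*."""
    rows = []
    for r in records:
        rows.append(
            {
                "residue": r.residue_id,
                "magA": r.magA,
                "magB": r.magB,
                "cos_theta": r.cos_theta if r.defined else float("nan"),
                "X": r.X,
                "retained": bool(r.defined and abs(r.cos_theta) > cos_cut),
            }
        )
    return rows
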