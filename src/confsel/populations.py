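"""Two-state populations from chemical-shift correlation slopes.

Under fast exchange between an active and an inactive conformation, the
observed apo shift of every nucleus is the population-weighted average of the
two endpoint shifts:

    delta_apo = p * delta_inactive + (1 - p) * delta_active

so for each reporter nucleus,

    (delta_apo - delta_cAMP) = p * (delta_C - delta_cAMP)

when the cAMP2-bound state stands in for the active endpoint and the C-bound
state for the inactive one.  Plotting y = delta_apo - delta_cAMP against
x = delta_C - delta_cAMP over a set of reporter residues (one point per
nucleus, 1H and 15N in native ppm) therefore gives a line through the origin
whose slope is the inactive-state molar fraction p.

The same machinery, fed a mutant-vs-WT shift difference on the y axis, acts
as a null check: if the mutation does not shift the active/inactive
equilibrium, the correlation disappears.

Caveat surfaced in every report: when the inactive reference is a weak,
transient complex (as for CBD-B binding the C-subunit), its peaks are pulled
toward apo and the measured slope overestimates p; the fitted value is an
upper bound in that case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .shift_tables import ShiftTable

__all__ = [
    "CorrelationPoint",
    "CorrelationFit",
    "NullCheckResult",
    "PopulationsError",
    "build_correlation",
    "fit_population",
    "null_correlation_check",
]

#: Per-nucleus shift reproducibility floors (ppm) used to detect reporter
#: sets whose x spread is indistinguishable from noise.
NOISE_FLOOR = {"H": 0.005, "N": 0.025}


class PopulationsError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationPoint:
    residue_id: int
    nucleus: str  # "H" or "N"
    x: float  # ppm, inactive-ref minus active-ref
    y: float  # ppm, perturbed minus active-ref


@dataclass
class CorrelationFit:
    """Through-origin fit of a shift-difference correlation.

    ``slope`` is interpreted as the inactive-state molar fraction p;
    ``slope_err`` is a bootstrap SD over points; ``r`` is the plain Pearson
    correlation so a non-correlation is detectable independently of the
    slope.
    """

    points: list[CorrelationPoint]
    slope: float
    slope_err: float
    r: float
    n: int
    method: str


def build_correlation(
    apo: ShiftTable,
    camp: ShiftTable,
    cbound: ShiftTable,
    reporters: Iterable[int],
) -> list[CorrelationPoint]:
    """Build (x, y) shift-difference points over a reporter residue set.

    Two points per reporter (one per nucleus), each in native ppm — no 15N
    scaling, since each point's y/x ratio is internal to one nucleus.
    """
    reporters = sorted(set(reporters))
    if not reporters:
        raise PopulationsError("reporter set is empty")
    missing = [
        r
        for r in reporters
        if r not in apo.entries or r not in camp.entries or r not in cbound.entries
    ]
    if missing:
        raise PopulationsError(
            f"reporters missing from at least one table: {missing}"
        )
    points: list[CorrelationPoint] = []
    for res in reporters:
        ah, an = apo.entries[res]
        ch, cn = camp.entries[res]
        bh, bn = cbound.entries[res]
        points.append(CorrelationPoint(res, "H", bh - ch, ah - ch))
        points.append(CorrelationPoint(res, "N", bn - cn, an - cn))
    return points


def _slope_tls(x: np.ndarray, y: np.ndarray) -> float:
    """Through-origin orthogonal (total least squares) slope.

    Minimises the summed squared perpendicular distances to the line
    y = s*x; both axes carry comparable shift noise so the symmetric loss is
    the right default.  Closed form from the 2x2 second-moment matrix.
    """
    sxx = float(x @ x)
    syy = float(y @ y)
    sxy = float(x @ y)
    if sxy == 0.0:
        return 0.0
    disc = np.hypot(syy - sxx, 2 * sxy)
    return (syy - sxx + disc) / (2 * sxy)


def _slope_ols(x: np.ndarray, y: np.ndarray) -> float:
    sxx = float(x @ x)
    if sxx == 0.0:
        raise PopulationsError("degenerate x values (all zero)")
    return float(x @ y) / sxx


def fit_population(
    points: Sequence[CorrelationPoint],
    method: str = "tls",
    n_boot: int = 1000,
    seed: int | None = None,
) -> CorrelationFit:
    """Fit the through-origin slope and interpret it as the inactive fraction.

    ``method`` is ``"tls"`` (orthogonal through-origin regression, default)
    or ``"ols"`` (ordinary least squares through the origin).  ``slope_err``
    is the SD of the slope over ``n_boot`` bootstrap resamples of the points
    (0 disables the bootstrap).  Degenerate x spreads — every |x| under three
    times the per-nucleus noise floor — raise "reporters insensitive".
    """
    n = len(points)
    if n < 4:
        raise PopulationsError(f"need >= 4 points, got {n}")
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    floors = np.array([NOISE_FLOOR[p.nucleus] for p in points])
    if np.all(np.abs(x) < 3 * floors):
        raise PopulationsError(
            "reporters insensitive: all reference shift differences are "
            "below 3x the noise floor"
        )
    slope_fn = {"tls": _slope_tls, "ols": _slope_ols}.get(method)
    if slope_fn is None:
        raise PopulationsError(f"unknown method '{method}'")
    slope = slope_fn(x, y)
    r = float(stats.pearsonr(x, y).statistic) if np.std(x) > 0 and np.std(y) > 0 else 0.0

    slope_err = 0.0
    if n_boot:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = slope_fn(x[idx[b]], y[idx[b]])
        slope_err = float(np.std(boots, ddof=1))
    return CorrelationFit(list(points), float(slope), slope_err, r, n, method)


@dataclass
class NullCheckResult:
    correlated: bool
    r: float
    p_value: float
    r_threshold: float
    n: int

    @property
    def verdict(self) -> str:
        return "correlated" if self.correlated else "uncorrelated"


def null_correlation_check(
    points: Sequence[CorrelationPoint],
    r_threshold: float = 0.5,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> NullCheckResult:
    """Classify a shift-difference correlation as real or absent.

    Computes Pearson |r| and a permutation p-value (y shuffled against x,
    ``n_perm`` draws, seeded).  The verdict is "correlated" only when both
    the effect size (|r| >= r_threshold) and the significance (p <= 0.05)
    conditions hold; either one alone is not evidence of a shifted
    equilibrium.  Sign-insensitive: anti-correlation counts as correlation.
    """
    n = len(points)
    if n < 4:
        raise PopulationsError(f"need >= 4 points, got {n}")
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    if np.std(x) == 0 or np.std(y) == 0:
        return NullCheckResult(False, 0.0, 1.0, r_threshold, n)
    r_obs = float(stats.pearsonr(x, y).statistic)

    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    perm = np.empty(n_perm)
    for i in range(n_perm):
        perm[i] = xc @ rng.permutation(yc)
    r_perm = perm / denom
    # one extra count for the observed statistic itself (exact test convention)
    p = (1 + np.sum(np.abs(r_perm) >= abs(r_obs))) / (n_perm + 1)
    correlated = abs(r_obs) >= r_threshold and p <= 0.05
    return NullCheckResult(bool(correlated), r_obs, float(p), r_threshold, n)
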