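"""Backbone amide chemical-shift tables for named ligation states.

A :class:`ShiftTable` holds per-residue (deltaH, deltaN) chemical shifts in ppm
for one state of the protein (apo, cAMP2-bound, C-subunit-bound, a mutant, ...).
Tables are read from Sparky-style assignment lists or plain TSV, aligned across
states on the intersection of assigned residues, and combined into weighted
Euclidean shift magnitudes (combined chemical shifts, CCS).

Residue numbering follows the construct's author numbering throughout; prolines
and unassigned residues are simply absent from a table and therefore drop out
of any cross-state comparison.
"""

from __future__ import annotations

import io
import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "ShiftTable",
    "DomainDefinition",
    "ShiftTableError",
    "read_shift_table",
    "write_shift_table",
    "ccs",
    "ccs_difference_profile",
    "CcsProfile",
    "default_domains",
    "load_domains",
    "DEFAULT_ALPHA",
]

#: Default 15N scaling used in combined-shift space.  This is the common
#: one-fifth convention (gamma-ratio-like weighting); it is a community
#: convention, not a measured quantity, and every entry point exposes it.
DEFAULT_ALPHA = 0.2

# Plausibility windows for backbone amides; violations warn but never fail,
# because unusual shifts (e.g. strongly ring-current-shifted amides) are real.
H_RANGE = (-2.0, 13.0)
N_RANGE = (95.0, 140.0)

_SPARKY_RE = re.compile(r"^([A-Z])(\d+)N-H$")


class ShiftTableError(ValueError):
    """Raised for malformed or inconsistent shift-table input."""


@dataclass
class ShiftTable:
    """Per-residue (1H, 15N) shifts, in ppm, for one named ligation state.

    Parameters
    ----------
    state_label:
        Free-text state name, e.g. ``"apo"``, ``"cAMP2"``, ``"C-bound"``,
        ``"W260A:cAMP2"``.
    entries:
        Mapping residue id -> ``(deltaH, deltaN)`` in ppm.
    construct_range:
        Inclusive residue interval of the construct in author numbering.
        Inferred from the data when omitted.
    """

    state_label: str
    entries: dict[int, tuple[float, float]]
    construct_range: tuple[int, int] | None = None
    skipped_lines: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ShiftTableError(f"shift table '{self.state_label}' is empty")
        for res, (dh, dn) in self.entries.items():
            if not (np.isfinite(dh) and np.isfinite(dn)):
                raise ShiftTableError(
                    f"non-finite shift for residue {res} in '{self.state_label}'"
                )
        if self.construct_range is None:
            self.construct_range = (min(self.entries), max(self.entries))
        lo, hi = self.construct_range
        bad = [r for r in self.entries if not lo <= r <= hi]
        if bad:
            raise ShiftTableError(
                f"residues {bad} outside construct range {lo}-{hi} "
                f"in '{self.state_label}'"
            )
        self._sanity_warn()

    def _sanity_warn(self) -> None:
        dh = np.array([v[0] for v in self.entries.values()])
        dn = np.array([v[1] for v in self.entries.values()])
        odd_h = int(np.sum((dh < H_RANGE[0]) | (dh > H_RANGE[1])))
        odd_n = int(np.sum((dn < N_RANGE[0]) | (dn > N_RANGE[1])))
        if odd_h or odd_n:
            warnings.warn(
                f"'{self.state_label}': {odd_h} 1H shifts outside {H_RANGE} ppm, "
                f"{odd_n} 15N shifts outside {N_RANGE} ppm",
                stacklevel=3,
            )

    @property
    def residues(self) -> list[int]:
        return sorted(self.entries)

    def shared_residues(self, *others: "ShiftTable") -> list[int]:
        """Residues assigned in this table and in every table of *others*."""
        common = set(self.entries)
        for other in others:
            common &= set(other.entries)
        return sorted(common)

    def deltas(self, other: "ShiftTable", residues: Iterable[int]) -> np.ndarray:
        """(n, 2) array of (dH_self - dH_other, dN_self - dN_other)."""
        res = list(residues)
        out = np.empty((len(res), 2))
        for i, r in enumerate(res):
            a, b = self.entries[r], other.entries[r]
            out[i] = (a[0] - b[0], a[1] - b[1])
        return out


def read_shift_table(
    source: str | Path | io.TextIOBase,
    dialect: str = "sparky_list",
    state_label: str | None = None,
    construct_range: tuple[int, int] | None = None,
) -> ShiftTable:
    """Parse a chemical-shift table from a Sparky-style list or a TSV file.

    The ``sparky_list`` dialect expects lines of the form
    ``G223N-H  105.1  8.21`` (assignment, w1 = 15N ppm, w2 = 1H ppm); extra
    columns are ignored and header/comment lines are collected in the
    resulting table's ``skipped_lines`` with a single summarising warning.
    The ``tsv`` dialect expects a header ``residue  deltaN  deltaH``.

    Duplicate residue assignments and empty tables are hard errors.
    """
    if dialect not in ("sparky_list", "tsv"):
        raise ShiftTableError(f"unknown dialect '{dialect}'")
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text()
        label = state_label or path.stem
    else:
        text = source.read()
        label = state_label or "unnamed"

    entries: dict[int, tuple[float, float]] = {}
    skipped: list[str] = []

    lines = text.splitlines()
    if dialect == "tsv":
        header_seen = False
        for line in lines:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            cols = stripped.split()
            if not header_seen:
                low = [c.lower() for c in cols[:3]]
                if low == ["residue", "deltan", "deltah"]:
                    header_seen = True
                    continue
                raise ShiftTableError(
                    "TSV dialect requires header 'residue  deltaN  deltaH'"
                )
            try:
                res = int(cols[0])
                dn, dh = float(cols[1]), float(cols[2])
            except (ValueError, IndexError):
                skipped.append(line)
                continue
            _insert(entries, res, dh, dn, label)
    else:
        for line in lines:
            stripped = line.strip()
            if not stripped:
                continue
            cols = stripped.split()
            m = _SPARKY_RE.match(cols[0])
            if m is None or len(cols) < 3:
                skipped.append(line)
                continue
            try:
                dn, dh = float(cols[1]), float(cols[2])
            except ValueError:
                skipped.append(line)
                continue
            _insert(entries, int(m.group(2)), dh, dn, label)

    if skipped:
        warnings.warn(
            f"'{label}': {len(skipped)} unparseable line(s) skipped "
            f"(first: {skipped[0]!r})",
            stacklevel=2,
        )
    if not entries:
        raise ShiftTableError(f"no shift entries parsed for '{label}'")
    table = ShiftTable(label, entries, construct_range)
    table.skipped_lines = skipped
    return table


def _insert(entries, res, dh, dn, label) -> None:
    if res in entries:
        raise ShiftTableError(f"duplicate assignment for residue {res} in '{label}'")
    entries[res] = (float(dh), float(dn))


def write_shift_table(
    table: ShiftTable,
    target: str | Path | io.TextIOBase,
    dialect: str = "sparky_list",
) -> None:
    """Write a table in either supported dialect (round-trips with the reader)."""
    lines: list[str] = []
    if dialect == "tsv":
        lines.append("residue\tdeltaN\tdeltaH")
        for res in table.residues:
            dh, dn = table.entries[res]
            lines.append(f"{res}\t{dn:.4f}\t{dh:.4f}")
    elif dialect == "sparky_list":
        for res in table.residues:
            dh, dn = table.entries[res]
            lines.append(f"X{res}N-H\t{dn:.4f}\t{dh:.4f}")
    else:
        raise ShiftTableError(f"unknown dialect '{dialect}'")
    text = "\n".join(lines) + "\n"
    if isinstance(target, (str, Path)):
        Path(target).write_text(text)
    else:
        target.write(text)


def ccs(dh: float, dn: float, alpha: float = DEFAULT_ALPHA) -> float:
    """Combined chemical shift ``sqrt(dH**2 + (alpha*dN)**2)`` in ppm.

    ``alpha`` down-weights the 15N dimension so that 1H and 15N perturbations
    contribute on a comparable scale; the default 0.2 is a convention.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    dh = float(dh)
    dn = float(dn)
    if not (np.isfinite(dh) and np.isfinite(dn)):
        raise ValueError("non-finite shift difference")
    return float(np.hypot(dh, alpha * dn))


@dataclass
class CcsProfile:
    """Per-residue CCS difference profile between two states.

    ``values`` maps residue -> CCS of the (a - b) shift difference; ``mean``
    and ``sd`` summarise the profile so "above-average" residues (mean + SD)
    can be flagged the way interface maps are built.
    """

    state_a: str
    state_b: str
    values: dict[int, float]
    mean: float
    sd: float

    def above_mean_plus_sd(self) -> list[int]:
        cut = self.mean + self.sd
        return [r for r, v in sorted(self.values.items()) if v > cut]


def ccs_difference_profile(
    a: ShiftTable, b: ShiftTable, alpha: float = DEFAULT_ALPHA
) -> CcsProfile:
    """CCS of the per-residue shift difference between two states.

    Restricted to residues assigned in both tables; symmetric in its
    arguments because CCS is a norm of the difference vector.
    """
    shared = a.shared_residues(b)
    if not shared:
        raise ShiftTableError(
            f"no shared residues between '{a.state_label}' and '{b.state_label}'"
        )
    deltas = a.deltas(b, shared)
    vals = np.hypot(deltas[:, 0], alpha * deltas[:, 1])
    values = {r: float(v) for r, v in zip(shared, vals)}
    return CcsProfile(
        a.state_label,
        b.state_label,
        values,
        float(np.mean(vals)),
        float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# Domain / region definitions


@dataclass(frozen=True)
class DomainDefinition:
    """A CBD and its conserved sub-regions as inclusive residue intervals.

    Sub-regions are the conserved structural elements used as averaging
    regions: N3A motif, beta2-3 loop, base-binding region (BBR),
    phosphate-binding cassette (PBC) and the hinge helices.  The tandem
    domains of RIalpha overlap at 244-268 (the N3A of CBD-B doubles as part
    of CBD-A); that overlap is legal.
    """

    name: str
    domain_range: tuple[int, int]
    subregions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.domain_range
        if lo > hi:
            raise ValueError(f"empty domain range for '{self.name}'")
        for sub, (slo, shi) in self.subregions.items():
            if slo > shi:
                raise ValueError(f"empty subregion '{sub}' in '{self.name}'")

    def contains(self, residue: int) -> bool:
        lo, hi = self.domain_range
        return lo <= residue <= hi

    def region_residues(self, region: str) -> range:
        """Residues of a named subregion, or of the whole domain for 'Total'."""
        if region in ("Total", "total", self.name):
            lo, hi = self.domain_range
        else:
            try:
                lo, hi = self.subregions[region]
            except KeyError:
                raise KeyError(
                    f"unknown region '{region}' for domain '{self.name}'; "
                    f"have {sorted(self.subregions)}"
                ) from None
        return range(lo, hi + 1)


def default_domains() -> dict[str, DomainDefinition]:
    """The tandem CBD-A / CBD-B definitions shipped with the package."""
    with resources.files("confsel.data").joinpath("domains.yaml").open() as fh:
        return load_domains(fh)


def load_domains(source: str | Path | io.TextIOBase) -> dict[str, DomainDefinition]:
    """Load domain definitions from YAML or JSON.

    Expected structure::

        CBD-A:
          range: [119, 268]
          subregions: {N3A: [119, 150], ...}
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    try:
        raw: Mapping = json.loads(text)
    except json.JSONDecodeError:
        raw = yaml.safe_load(text)
    domains: dict[str, DomainDefinition] = {}
    for name, spec in raw.items():
        subs = {k: (int(v[0]), int(v[1])) for k, v in spec.get("subregions", {}).items()}
        domains[name] = DomainDefinition(
            name, (int(spec["range"][0]), int(spec["range"][1])), subs
        )
    return domains
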