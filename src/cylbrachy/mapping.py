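"""Surface <-> 5 mm-depth dose mapping.

For each cylinder size there is a nine-row dose table pairing a 5 mm-depth
prescription dose with the surface dose the optimized plan delivers, and a
pair of fifth-order polynomial mapping functions

    y = a x^5 + b x^4 + c x^3 + d x^2 + e x + f

fitted to that table (one per direction).  The polynomials let an arbitrary
prescription at one site be translated to the other within the tabulated
dose range.

Unit convention (important): the polynomial variable x and value y are doses
in **Gy**.  Evaluating the published coefficients with doses in cGy produces
astronomically wrong values; in Gy they reproduce the dose table, which is
how the unit was pinned down (see ``consistency_report``).  The public API
takes and returns cGy and converts internally.

Because a high-order polynomial oscillates outside its fitted support, the
mappings are valid for interpolation only: evaluation outside the tabulated
dose range raises :class:`MappingRangeError`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_DATA_DIR = Path(__file__).parent / "data"
DOSE_TABLE_CSV = _DATA_DIR / "dose_table.csv"
COEFFICIENTS_CSV = _DATA_DIR / "mapping_coefficients.csv"

Direction = Literal["to_surface", "to_5mm"]


class MappingRangeError(ValueError):
    """Dose outside the fitted range: the mapping is interpolation-only,
    never extrapolation."""


class InsufficientDataError(ValueError):
    """Too few table rows to determine the six quintic coefficients."""


def round_to_10(dose_cgy: float) -> float:
    """Round to the nearest 10 cGy, the granularity of prescription doses."""
    return float(round(dose_cgy / 10.0) * 10.0)


@dataclass(frozen=True)
class DoseTable:
    """Correspondence between 5 mm-depth and surface doses for one cylinder.

    ``rows`` is an (n, 2) array of (dose_5mm, dose_surface) in cGy, both
    columns strictly increasing and surface > 5 mm in every row (the surface
    is closer to the source, so it always receives more dose).
    """

    cylinder_diameter: float
    rows: np.ndarray
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float).reshape(-1, 2)
        if np.any(np.diff(rows[:, 0]) <= 0) or np.any(np.diff(rows[:, 1]) <= 0):
            raise ValueError("dose table columns must be strictly increasing")
        if np.any(rows[:, 1] <= rows[:, 0]):
            raise ValueError("surface dose must exceed the 5 mm-depth dose in every row")
        object.__setattr__(self, "rows", rows)

    @property
    def dose_5mm(self) -> np.ndarray:
        return self.rows[:, 0]

    @property
    def dose_surface(self) -> np.ndarray:
        return self.rows[:, 1]

    def source_column(self, direction: Direction) -> np.ndarray:
        return self.dose_5mm if direction == "to_surface" else self.dose_surface

    def target_column(self, direction: Direction) -> np.ndarray:
        return self.dose_surface if direction == "to_surface" else self.dose_5mm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "diameter_cm": self.cylinder_diameter,
                "dose_5mm_cGy": self.dose_5mm,
                "dose_surface_cGy": self.dose_surface,
            }
        )


@dataclass(frozen=True)
class MappingPolynomial:
    """One quintic mapping function with its validity domain.

    ``coefficients`` are (a, b, c, d, e, f) for doses expressed in Gy;
    ``valid_domain`` is the [min, max] of the source column in Gy.  Calling
    the object takes and returns cGy.
    """

    cylinder_diameter: float
    direction: Direction
    coefficients: tuple[float, ...]
    valid_domain: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.coefficients) != 6:
            raise ValueError("a quintic needs exactly six coefficients")
        if self.direction not in ("to_surface", "to_5mm"):
            raise ValueError("direction must be 'to_surface' or 'to_5mm'")

    def evaluate_gy(self, x_gy: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(x_gy, dtype=float))

    def __call__(self, dose_cgy: float) -> float:
        x = dose_cgy / 100.0
        lo, hi = self.valid_domain
        if not (lo - 1e-9 <= x <= hi + 1e-9):
            raise MappingRangeError(
                f"{dose_cgy:g} cGy outside the fitted range "
                f"[{lo * 100:g}, {hi * 100:g}] cGy: the mapping functions are "
                "only for interpolation, not for extrapolation"
            )
        return float(self.evaluate_gy(x) * 100.0)

    def is_monotone(self, samples: int = 1000) -> bool:
        """Strict monotonicity on the valid domain, by dense sampling."""
        x = np.linspace(*self.valid_domain, samples)
        return bool(np.all(np.diff(self.evaluate_gy(x)) > 0))


def evaluate_mapping(poly: MappingPolynomial, dose_cgy: float) -> float:
    """Evaluate the mapping at ``dose_cgy``; returns cGy (unrounded).

    Use :func:`round_to_10` on the result for prescription display.
    """
    return poly(dose_cgy)


@dataclass(frozen=True)
class DiameterMapping:
    """Both mapping directions for one cylinder size (the ``mapping_ctx``
    expected by :func:`cylbrachy.optimizer.make_plan`).

    When the underlying dose table is attached, a dose that exactly matches a
    tabulated entry returns its printed correspondent (the tabulated pairs
    are the authoritative prescriptions); the quintic handles doses between
    the rows.
    """

    cylinder_diameter: float
    forward: MappingPolynomial | None  # to_surface
    backward: MappingPolynomial | None  # to_5mm
    table: "DoseTable | None" = None

    def _lookup(self, dose_cgy: float, src: np.ndarray, tgt: np.ndarray) -> float | None:
        if self.table is None:
            return None
        hit = np.isclose(src, dose_cgy, rtol=0, atol=1e-6)
        return float(tgt[hit][0]) if hit.any() else None

    def to_surface(self, dose_cgy: float) -> float:
        if self.table is not None:
            exact = self._lookup(dose_cgy, self.table.dose_5mm, self.table.dose_surface)
            if exact is not None:
                return exact
        if self.forward is None:
            raise MappingRangeError(
                f"{dose_cgy:g} cGy is not a tabulated 5 mm dose and this "
                "table-only mapping has no fitted polynomial"
            )
        return self.forward(dose_cgy)

    def to_5mm(self, dose_cgy: float) -> float:
        if self.table is not None:
            exact = self._lookup(dose_cgy, self.table.dose_surface, self.table.dose_5mm)
            if exact is not None:
                return exact
        if self.backward is None:
            raise MappingRangeError(
                f"{dose_cgy:g} cGy is not a tabulated surface dose and this "
                "table-only mapping has no fitted polynomial"
            )
        return self.backward(dose_cgy)


# ---------------------------------------------------------------------------
# reference data (the published nine-row tables and quintic coefficients)
# ---------------------------------------------------------------------------

def load_reference_tables() -> dict[float, DoseTable]:
    """The bundled dose tables for the 2.5/3.0/3.5 cm cylinders."""
    df = pd.read_csv(DOSE_TABLE_CSV)
    out = {}
    for diam, grp in df.groupby("diameter_cm"):
        out[float(diam)] = DoseTable(
            cylinder_diameter=float(diam),
            rows=grp[["dose_5mm_cGy", "dose_surface_cGy"]].to_numpy(float),
        )
    return out


def load_reference_polynomials() -> dict[tuple[float, Direction], MappingPolynomial]:
    """The bundled quintic coefficients, domains taken from the dose tables."""
    tables = load_reference_tables()
    df = pd.read_csv(COEFFICIENTS_CSV)
    out = {}
    for _, row in df.iterrows():
        diam = float(row["diameter_cm"])
        direction = row["direction"]
        src = tables[diam].source_column(direction) / 100.0
        out[(diam, direction)] = MappingPolynomial(
            cylinder_diameter=diam,
            direction=direction,
            coefficients=tuple(float(row[c]) for c in "abcdef"),
            valid_domain=(float(src.min()), float(src.max())),
        )
    return out


def reference_mapping(diameter: float) -> DiameterMapping:
    """Bundled :class:`DiameterMapping` for one of the standard sizes."""
    polys = load_reference_polynomials()
    try:
        return DiameterMapping(
            cylinder_diameter=diameter,
            forward=polys[(diameter, "to_surface")],
            backward=polys[(diameter, "to_5mm")],
            table=load_reference_tables()[diameter],
        )
    except KeyError:
        raise KeyError(
            f"no bundled mapping for diameter {diameter} cm (have 2.5/3.0/3.5)"
        ) from None


def consistency_report(table: DoseTable, poly: MappingPolynomial) -> pd.DataFrame:
    """Residuals of the polynomial against its dose table, row by row.

    Columns: source/target dose (cGy), predicted (cGy), residual_pct, and the
    nearest-10 rounded prediction.  This check (run in both directions, all
    rows) is what pins the polynomial dose unit to Gy: in Gy the worst row
    across the three bundled tables deviates 2.2%, in cGy predictions are off
    by orders of magnitude.
    """
    src = table.source_column(poly.direction)
    tgt = table.target_column(poly.direction)
    pred = poly.evaluate_gy(src / 100.0) * 100.0
    return pd.DataFrame(
        {
            "source_cGy": src,
            "target_cGy": tgt,
            "predicted_cGy": pred,
            "residual_pct": 100.0 * (pred - tgt) / tgt,
            "predicted_rounded_cGy": [round_to_10(p) for p in pred],
        }
    )


# ---------------------------------------------------------------------------
# fitting and regeneration
# ---------------------------------------------------------------------------

def fit_mapping(table: DoseTable, direction: Direction) -> MappingPolynomial:
    """Ordinary least-squares quintic fit of one table direction.

    Doses are scaled to Gy before fitting to keep the Vandermonde matrix
    conditioned (cGy-scale powers up to x^5 span ~15 orders of magnitude).
    Needs at least 7 rows (6 coefficients + 1).
    """
    if table.rows.shape[0] < 7:
        raise InsufficientDataError("quintic fit requires at least 7 table rows")
    x = table.source_column(direction) / 100.0
    y = table.target_column(direction) / 100.0
    V = np.vander(x, 6)
    coeffs, *_ = np.linalg.lstsq(V, y, rcond=None)
    cond = np.linalg.cond(V)
    resid = V @ coeffs - y
    logger.info(
        "quintic fit %.1f cm %s: cond(V)=%.3g, max residual %.3g%%",
        table.cylinder_diameter, direction, cond, 100 * np.max(np.abs(resid / y)),
    )
    return MappingPolynomial(
        cylinder_diameter=table.cylinder_diameter,
        direction=direction,
        coefficients=tuple(coeffs),
        valid_domain=(float(x.min()), float(x.max())),
    )


def fit_diameter_mapping(table: DoseTable) -> DiameterMapping:
    """Fit both directions of one dose table."""
    return DiameterMapping(
        cylinder_diameter=table.cylinder_diameter,
        forward=fit_mapping(table, "to_surface"),
        backward=fit_mapping(table, "to_5mm"),
        table=table,
    )


@dataclass(frozen=True)
class PlannerContext:
    """Everything :func:`build_dose_table` needs to run single-site plans:
    the source model, line sampling, and the smoothing dial."""

    source: object
    spacing: float = 0.25
    apex_samples: int = 9
    smoothing: float = 300.0


def build_dose_table(planner_ctx: PlannerContext, cylinder,
                     dose_levels: Sequence[float],
                     anchor_site: str = "depth5mm") -> DoseTable:
    """Regenerate a dose table by planning at each level.

    For every dose level a single-site plan is optimized at ``anchor_site``
    and the mean dose over the other site's lines, rounded to the nearest
    10 cGy, is recorded as its correspondent.  Because dose is linear in
    dwell time, the correspondents scale exactly with the anchor dose (up to
    rounding).  A level whose optimization does not converge is flagged in
    ``DoseTable.flags``, never silently dropped.
    """
    from .applicator import generate_dwell_positions, generate_reference_lines
    from .optimizer import PrescriptionSpec, optimize_dwell_times

    other = "surface" if anchor_site == "depth5mm" else "depth5mm"
    dwells = generate_dwell_positions(cylinder)
    refs = generate_reference_lines(cylinder, spacing=planner_ctx.spacing,
                                    apex_samples=planner_ctx.apex_samples)
    rows, flags = [], []
    for level in dose_levels:
        rx = PrescriptionSpec(primary_site=anchor_site, primary_dose=float(level),
                              smoothing=planner_ctx.smoothing)
        sol = optimize_dwell_times(planner_ctx.source, dwells, refs, rx)
        if not sol.converged:
            flags.append(f"level {level:g} cGy: optimizer did not converge")
        mean_other = float(np.mean(sol.doses(other)))
        pair = (float(level), round_to_10(mean_other))
        rows.append(pair if anchor_site == "depth5mm" else pair[::-1])
    rows.sort(key=lambda r: r[0])
    return DoseTable(cylinder_diameter=cylinder.diameter, rows=np.asarray(rows),
                     flags=tuple(flags))
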