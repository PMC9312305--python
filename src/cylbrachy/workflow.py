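"""Reproducible planning workflows.

Ties the dose engine, geometry, optimizer, mapping and metrics together:
run one plan from a config mapping, or enumerate and solve the full
four-method comparison matrix (dose levels x methods x cylinder sizes x
geometries) and aggregate the per-site DMax/DMin/DMean statistics.

Everything here is deterministic: there is no randomness anywhere in the
pipeline, so re-running the same configuration reproduces byte-identical
reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .applicator import CylinderApplicator, generate_dwell_positions, generate_reference_lines
from .mapping import (DiameterMapping, PlannerContext, build_dose_table,
                      fit_diameter_mapping, load_reference_tables,
                      reference_mapping, round_to_10)
from .metrics import PlanMetrics, aggregate_plans, sorted_profile
from .optimizer import PLAN_METHODS, DwellSolution, make_plan, optimize_dwell_times
from .source_model import SourceSpec

#: the two treatment lengths standing in for per-patient geometry variation
DEFAULT_TREATMENT_LENGTHS = (3.5, 4.5)
#: canonical length used when regenerating a dose table for a cylinder size
TABLE_BUILD_LENGTH = 4.0


def _default_levels() -> dict[float, tuple[float, ...]]:
    return {
        d: tuple(t.dose_5mm) for d, t in load_reference_tables().items()
    }


@dataclass(frozen=True)
class ComparisonMatrixSpec:
    """The plan-comparison matrix: which cells to enumerate.

    Defaults reproduce the full study matrix: nine 5 mm-depth dose levels per
    cylinder size, four prescription methods, three sizes, two geometries per
    size (treatment lengths standing in for patient variation) = 216 plans.
    """

    dose_levels: Mapping[float, Sequence[float]] = field(default_factory=_default_levels)
    diameters: tuple[float, ...] = (2.5, 3.0, 3.5)
    methods: tuple[str, ...] = PLAN_METHODS
    treatment_lengths: tuple[float, ...] = DEFAULT_TREATMENT_LENGTHS

    @property
    def geometries_per_size(self) -> int:
        return len(self.treatment_lengths)

    @property
    def total_plans(self) -> int:
        return sum(
            len(self.dose_levels[d]) * len(self.methods) * self.geometries_per_size
            for d in self.diameters
        )

    def plan_cells(self) -> list[dict]:
        """Enumerate every plan cell of the matrix, in deterministic order."""
        cells = []
        for diameter in self.diameters:
            for length in self.treatment_lengths:
                for level in self.dose_levels[diameter]:
                    for method in self.methods:
                        cells.append(
                            {
                                "diameter_cm": diameter,
                                "treatment_length_cm": length,
                                "dose_5mm_cGy": float(level),
                                "method": method,
                            }
                        )
        return cells


@dataclass
class ComparisonReport:
    """Outputs of :func:`run_comparison`."""

    cells: pd.DataFrame                 # one row per plan x site
    aggregate: pd.DataFrame             # mean ± sigma per (method, site, statistic)
    profiles: dict                      # (method, site) -> sorted % profile
    tables: dict                        # diameter -> regenerated DoseTable
    errors: list
    resolved_config: dict

    def write(self, outdir: str | Path) -> None:
        """Write the report bundle (CSV + JSON) to a directory."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "plan_metrics.csv", index=False)
        self.aggregate.to_csv(out / "aggregate.csv", index=False)
        prof = pd.DataFrame(
            [
                {"method": m, "site": s, "rank": i, "pct": v}
                for (m, s), arr in sorted(self.profiles.items())
                for i, v in enumerate(arr)
            ]
        )
        prof.to_csv(out / "sorted_profiles.csv", index=False)
        pd.concat([t.to_frame() for t in self.tables.values()]).to_csv(
            out / "dose_table_regenerated.csv", index=False
        )
        (out / "resolved_config.json").write_text(
            json.dumps(self.resolved_config, indent=2, sort_keys=True) + "\n"
        )
        if self.errors:
            (out / "errors.json").write_text(json.dumps(self.errors, indent=2) + "\n")


def _self_mapping(table) -> DiameterMapping:
    """Mapping from a regenerated table: fitted quintics when the table has
    enough rows, exact row lookup alone otherwise."""
    from .mapping import InsufficientDataError
    try:
        return fit_diameter_mapping(table)
    except InsufficientDataError:
        return DiameterMapping(cylinder_diameter=table.cylinder_diameter,
                               forward=None, backward=None, table=table)


def run_comparison(spec: ComparisonMatrixSpec | None = None,
                   source: SourceSpec | None = None,
                   spacing: float = 0.25, apex_samples: int = 9,
                   smoothing: float = 300.0,
                   mapping_source: str = "reference",
                   profile_cell: tuple[float, float] | None = None,
                   outdir: str | Path | None = None) -> ComparisonReport:
    """Solve the comparison matrix and aggregate plan-quality statistics.

    Each cell's surface prescription is the mapped correspondent of its
    5 mm-depth dose level.  With ``mapping_source="reference"`` (default) the
    bundled published dose tables supply the correspondents for the standard
    cylinder sizes — the tabulated prescription pairs are the point of the
    double-prescription method.  With ``mapping_source="self"`` a dose table
    is instead regenerated on a canonical geometry of this source model
    (single-site plans at the matrix's levels) and its fitted quintic used;
    either way a regenerated table ships in the report bundle for audit.  All
    sites are normalized to their own (possibly mapped) prescription.  Any
    cell failure is recorded in ``errors`` and the run completes.

    ``profile_cell`` = (diameter, dose_5mm level) selects the cell whose
    sorted per-site dose profiles are exported (default: 2.5 cm at 600 cGy).
    """
    if mapping_source not in ("reference", "self"):
        raise ValueError("mapping_source must be 'reference' or 'self'")
    spec = spec or ComparisonMatrixSpec()
    source = source or SourceSpec.generic_ir192()
    profile_cell = profile_cell or (2.5, 600.0)
    ctx = PlannerContext(source=source, spacing=spacing,
                         apex_samples=apex_samples, smoothing=smoothing)

    mappings: dict[float, DiameterMapping] = {}
    tables = {}
    for diameter in spec.diameters:
        cyl = CylinderApplicator(diameter=diameter, treatment_length=TABLE_BUILD_LENGTH)
        table = build_dose_table(ctx, cyl, spec.dose_levels[diameter],
                                 anchor_site="depth5mm")
        tables[diameter] = table
        if mapping_source == "self":
            mappings[diameter] = _self_mapping(table)
        else:
            try:
                mappings[diameter] = reference_mapping(diameter)
            except KeyError:  # non-standard size: fall back to the self table
                mappings[diameter] = _self_mapping(table)

    geometry_cache: dict[tuple[float, float], tuple] = {}
    metrics_list, rows, errors = [], [], []
    profiles: dict = {}

    for cell in spec.plan_cells():
        diameter = cell["diameter_cm"]
        length = cell["treatment_length_cm"]
        level = cell["dose_5mm_cGy"]
        method = cell["method"]
        try:
            key = (diameter, length)
            if key not in geometry_cache:
                cyl = CylinderApplicator(diameter=diameter, treatment_length=length)
                dwells = generate_dwell_positions(cyl)
                refs = generate_reference_lines(cyl, spacing=spacing,
                                                apex_samples=apex_samples)
                geometry_cache[key] = (cyl, dwells, refs)
            cyl, dwells, refs = geometry_cache[key]

            dose_surface = round_to_10(mappings[diameter].to_surface(level))
            rx = make_plan(method, dose_5mm=level, dose_surface=dose_surface,
                           smoothing=smoothing)
            sol = optimize_dwell_times(source, dwells, refs, rx)
            rx_by_site = {"surface": dose_surface, "depth5mm": level}
            pm = PlanMetrics.from_solution(sol, rx_by_site, plan_method=method)
            metrics_list.append(pm)
            for r in pm.to_rows():
                rows.append({**cell, "dose_surface_cGy": dose_surface, **r,
                             "converged": sol.converged})
            if (diameter, level) == profile_cell and length == spec.treatment_lengths[0]:
                for site in ("surface", "depth5mm"):
                    profiles[(method, site)] = sorted_profile(
                        sol.doses(site), rx_by_site[site]
                    )
        except Exception as exc:  # record and continue: the run must complete
            errors.append({**cell, "error": f"{type(exc).__name__}: {exc}"})

    report = ComparisonReport(
        cells=pd.DataFrame(rows),
        aggregate=aggregate_plans(metrics_list),
        profiles=profiles,
        tables=tables,
        errors=errors,
        resolved_config={
            "diameters": list(spec.diameters),
            "dose_levels": {str(k): list(map(float, v))
                            for k, v in spec.dose_levels.items()},
            "methods": list(spec.methods),
            "treatment_lengths": list(spec.treatment_lengths),
            "spacing_cm": spacing,
            "apex_samples": apex_samples,
            "smoothing": smoothing,
            "mapping_source": mapping_source,
            "source": source.name,
            "total_plans": spec.total_plans,
        },
    )
    if outdir is not None:
        report.write(outdir)
    return report


# ---------------------------------------------------------------------------
# single-plan config runner (used by the CLI `plan` command)
# ---------------------------------------------------------------------------

def plan_from_config(config: Mapping) -> DwellSolution:
    """Run one plan from a config mapping (parsed YAML/JSON).

    Schema::

        cylinder:      {diameter_cm, treatment_length_cm, tip_offset_cm}
        prescription:  {method, dose_5mm_cGy, dose_surface_cGy}
        smoothing:     0-300 (default 300)
        spacing_cm:    reference-line point spacing (default 0.25)
        apex_samples:  per arc half (default 9)
        source_file:   path to a source parameter JSON (default: bundled
                       illustrative Ir-192-type model)

    A missing dose for a dual-site method is derived through the bundled
    mapping for that cylinder size.
    """
    cyl_cfg = dict(config.get("cylinder", {}))
    rx_cfg = dict(config.get("prescription", {}))
    cyl = CylinderApplicator(
        diameter=float(cyl_cfg.get("diameter_cm", 3.0)),
        treatment_length=float(cyl_cfg.get("treatment_length_cm", 4.0)),
        tip_offset=float(cyl_cfg.get("tip_offset_cm", 0.6)),
    )
    source = (SourceSpec.from_file(config["source_file"])
              if "source_file" in config else SourceSpec.generic_ir192())
    from .mapping import reference_mapping
    try:
        mapping_ctx = reference_mapping(cyl.diameter)
    except KeyError:
        mapping_ctx = None
    rx = make_plan(
        rx_cfg.get("method", "P4_Sur&5mm"),
        dose_5mm=rx_cfg.get("dose_5mm_cGy"),
        dose_surface=rx_cfg.get("dose_surface_cGy"),
        mapping_ctx=mapping_ctx,
        smoothing=float(config.get("smoothing", 300.0)),
    )
    dwells = generate_dwell_positions(cyl)
    refs = generate_reference_lines(
        cyl, spacing=float(config.get("spacing_cm", 0.25)),
        apex_samples=int(config.get("apex_samples", 9)),
    )
    return optimize_dwell_times(source, dwells, refs, rx)
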