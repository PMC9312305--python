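"""Inverse dwell-time optimization for single- and double-site prescriptions.

The planning problem: given the dose-rate design matrix A (cGy per second of
dwell time, one row per prescribed reference point) and a prescription dose
Rx per site, find non-negative dwell times t minimizing

    J(t) = sum_p w_p (d_p(t) - Rx_site(p))**2  +  lambda_s sum_i (t_{i+1} - t_i)**2

where w_p = priority(p)/100 encodes the planner's priority dial and the
second term is a first-difference smoothing penalty on the dwell profile.
The problem is solved exactly (active-set non-negative least squares on the
stacked design), so the solver is deterministic with no random
initialization.

Priorities follow the double-prescription convention: points of the primary
site carry priority > 100, points of the secondary site < 80, and within
each site group the apex line is weighted 10-50 higher than the straight
lines because the dome is where hot/cold spots concentrate.  The smoothing
dial runs 0-300 (300 = strongest smoothing); its internal scale
``lambda_s = (smoothing/300) * lambda_ref`` uses a per-problem reference
``lambda_ref = trace(A^T W A)/n_dwells`` so the two terms of J are
commensurate at full dial.

The ±50 cGy prescription window is a planning goal, not a hard constraint:
each solution reports the fraction of points within the window per site
(target: >= 0.98).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .applicator import ReferencePointSet
from .source_model import DwellPosition, SourceSpec, dose_rate_matrix

PLAN_METHODS = ("P1_5mm", "P2_5mm&Sur", "P3_Sur", "P4_Sur&5mm")

#: default priorities: primary site > 100, secondary < 80, apex 10-50 above
#: the straight lines within each group
DEFAULT_PRIMARY_STRAIGHT = 110.0
DEFAULT_PRIMARY_APEX = 140.0
DEFAULT_SECONDARY_STRAIGHT = 60.0
DEFAULT_SECONDARY_APEX = 79.0


class ConfigurationError(ValueError):
    """Prescription/geometry combination that cannot be optimized."""


def default_priority_map(primary_site: str, secondary_site: str | None) -> dict:
    pm = {}
    for line in ("left", "right"):
        pm[(primary_site, line)] = DEFAULT_PRIMARY_STRAIGHT
    pm[(primary_site, "apex")] = DEFAULT_PRIMARY_APEX
    if secondary_site is not None:
        for line in ("left", "right"):
            pm[(secondary_site, line)] = DEFAULT_SECONDARY_STRAIGHT
        pm[(secondary_site, "apex")] = DEFAULT_SECONDARY_APEX
    return pm


@dataclass(frozen=True)
class PrescriptionSpec:
    """One of the four prescription strategies.

    ``primary_site``/``primary_dose`` carry the high-priority objective;
    ``secondary_site`` is None for single-site plans.  ``priority_map`` maps
    (site_tag, line_tag) to the Eclipse-style priority number; weights in the
    objective are priority/100.
    """

    primary_site: str
    primary_dose: float
    secondary_site: str | None = None
    secondary_dose: float | None = None
    priority_map: Mapping = None
    dose_window: float = 50.0
    smoothing: float = 300.0
    method: str | None = None

    def __post_init__(self) -> None:
        if self.primary_site not in ("surface", "depth5mm"):
            raise ValueError("primary_site must be 'surface' or 'depth5mm'")
        if self.secondary_site is not None:
            if self.secondary_site not in ("surface", "depth5mm"):
                raise ValueError("secondary_site must be 'surface' or 'depth5mm'")
            if self.secondary_site == self.primary_site:
                raise ValueError("secondary_site must differ from primary_site")
            if self.secondary_dose is None:
                raise ConfigurationError("secondary_site set but secondary_dose missing")
        if self.primary_dose <= 0:
            raise ValueError("primary_dose must be positive")
        if not (0.0 <= self.smoothing <= 300.0):
            raise ValueError("smoothing must lie in [0, 300]")
        if self.priority_map is None:
            object.__setattr__(
                self, "priority_map",
                default_priority_map(self.primary_site, self.secondary_site),
            )
        self._validate_priorities()

    def _validate_priorities(self) -> None:
        pm = dict(self.priority_map)
        for line in ("left", "right", "apex"):
            if pm[(self.primary_site, line)] <= 100:
                raise ValueError("primary-site priorities must exceed 100")
        apex_gap = pm[(self.primary_site, "apex")] - max(
            pm[(self.primary_site, "left")], pm[(self.primary_site, "right")]
        )
        if not (10.0 <= apex_gap <= 50.0):
            raise ValueError("primary apex priority must be 10-50 above the straight lines")
        if self.secondary_site is not None:
            for line in ("left", "right", "apex"):
                if pm[(self.secondary_site, line)] >= 80:
                    raise ValueError("secondary-site priorities must be below 80")
            gap = pm[(self.secondary_site, "apex")] - max(
                pm[(self.secondary_site, "left")], pm[(self.secondary_site, "right")]
            )
            if not (10.0 <= gap <= 50.0):
                raise ValueError("secondary apex priority must be 10-50 above the straight lines")

    @property
    def prescribed_sites(self) -> tuple[str, ...]:
        if self.secondary_site is None:
            return (self.primary_site,)
        return (self.primary_site, self.secondary_site)

    def rx_for(self, site: str) -> float | None:
        if site == self.primary_site:
            return self.primary_dose
        if site == self.secondary_site:
            return self.secondary_dose
        return None


def make_plan(method: str, dose_5mm: float | None = None,
              dose_surface: float | None = None, mapping_ctx=None,
              smoothing: float = 300.0, dose_window: float = 50.0,
              priority_map: Mapping | None = None) -> PrescriptionSpec:
    """Factory for the four standard plans.

    P1_5mm: 5 mm-depth prescription only.  P2_5mm&Sur: 5 mm primary + surface
    secondary.  P3_Sur: surface only.  P4_Sur&5mm: surface primary + 5 mm
    secondary.  A missing dose for a dual plan is derived from the other site
    through ``mapping_ctx`` (an object with ``to_surface``/``to_5mm`` methods
    taking and returning cGy, e.g. :class:`cylbrachy.mapping.DiameterMapping`),
    rounded to the nearest 10 cGy as prescriptions are.
    """
    if method not in PLAN_METHODS:
        raise ValueError(f"unknown plan method {method!r}; choose one of {PLAN_METHODS}")

    def _derive(need: str) -> float:
        if mapping_ctx is None:
            raise ConfigurationError(
                f"{method} needs a {need} dose: pass it or provide a mapping context"
            )
        from .mapping import round_to_10
        if need == "surface":
            return round_to_10(mapping_ctx.to_surface(dose_5mm))
        return round_to_10(mapping_ctx.to_5mm(dose_surface))

    if method == "P1_5mm":
        if dose_5mm is None:
            raise ConfigurationError("P1_5mm requires dose_5mm")
        primary, secondary = ("depth5mm", dose_5mm), (None, None)
    elif method == "P3_Sur":
        if dose_surface is None:
            raise ConfigurationError("P3_Sur requires dose_surface")
        primary, secondary = ("surface", dose_surface), (None, None)
    elif method == "P2_5mm&Sur":
        if dose_5mm is None:
            raise ConfigurationError("P2_5mm&Sur requires dose_5mm")
        if dose_surface is None:
            dose_surface = _derive("surface")
        primary, secondary = ("depth5mm", dose_5mm), ("surface", dose_surface)
    else:  # P4_Sur&5mm
        if dose_surface is None:
            raise ConfigurationError("P4_Sur&5mm requires dose_surface")
        if dose_5mm is None:
            dose_5mm = _derive("depth5mm")
        primary, secondary = ("surface", dose_surface), ("depth5mm", dose_5mm)

    return PrescriptionSpec(
        primary_site=primary[0], primary_dose=primary[1],
        secondary_site=secondary[0], secondary_dose=secondary[1],
        priority_map=priority_map, dose_window=dose_window,
        smoothing=smoothing, method=method,
    )


@dataclass
class DwellSolution:
    """Results of one dwell-time optimization.

    Carries the optimized times (seconds), the objective value and its
    fidelity/smoothing breakdown, the per-site coverage fraction against the
    ±dose_window goal, and a back-reference to the model for dose queries.
    """

    times: np.ndarray
    objective_value: float
    term_breakdown: tuple[float, float]  # (fidelity, smoothing)
    converged: bool
    coverage_fraction: dict
    model: "DwellTimeModel"

    # -- dose queries ---------------------------------------------------

    def doses(self, site_tag: str | None = None, line_tag: str | None = None) -> np.ndarray:
        """Delivered dose (cGy) at the reference points of the given site/line
        selection (all six lines by default), prescribed or not."""
        pts = self.model.refs.select(site_tag, line_tag)
        A = dose_rate_matrix(self.model.source, self.model.dwells, pts)
        return A @ self.times

    def site_metrics(self, site_tag: str, rx: float) -> tuple[float, float, float]:
        """(DMax%, DMin%, DMean%) of the site, normalized to ``rx``."""
        from .metrics import compute_site_metrics
        return compute_site_metrics(self.doses(site_tag), rx)

    def point_table(self) -> pd.DataFrame:
        """Per-point dose table over all six lines."""
        df = self.model.refs.to_frame()
        df["dose_cGy"] = self.doses()
        rx = [self.model.prescription.rx_for(s) for s in df["site_tag"]]
        df["normalized_pct"] = [
            100.0 * d / r if r else np.nan for d, r in zip(df["dose_cGy"], rx)
        ]
        return df

    def summary(self) -> str:
        rx = self.model.prescription
        lines = [
            "Dwell-time optimization results",
            "=" * 34,
            f"method:            {rx.method or 'custom'}",
            f"primary:           {rx.primary_dose:.0f} cGy at {rx.primary_site}",
        ]
        if rx.secondary_site:
            lines.append(
                f"secondary:         {rx.secondary_dose:.0f} cGy at {rx.secondary_site}"
            )
        lines += [
            f"dwells:            {self.times.size}",
            f"total time:        {self.times.sum():.1f} s",
            f"objective:         {self.objective_value:.4g} "
            f"(fidelity {self.term_breakdown[0]:.4g}, smoothing {self.term_breakdown[1]:.4g})",
            f"converged:         {self.converged}",
        ]
        for site, frac in self.coverage_fraction.items():
            lines.append(
                f"coverage ±{rx.dose_window:.0f} cGy at {site}: {100 * frac:.1f}% of points"
            )
        for site in ("surface", "depth5mm"):
            r = rx.rx_for(site)
            if r:
                mx, mn, me = self.site_metrics(site, r)
                lines.append(
                    f"{site:9s} DMax/DMin/DMean: {mx:6.1f} / {mn:6.1f} / {me:6.1f} % of Rx"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "times_s": self.times.tolist(),
            "objective_value": self.objective_value,
            "fidelity_term": self.term_breakdown[0],
            "smoothing_term": self.term_breakdown[1],
            "converged": self.converged,
            "coverage_fraction": dict(self.coverage_fraction),
        }


class DwellTimeModel:
    """Planning model: source + dwell positions + reference lines + prescription.

    ``fit()`` solves the non-negative least-squares problem and returns a
    :class:`DwellSolution`.  The model owns the design matrix over the
    prescribed points, the priority weights and the smoothing scale, so
    repeated fits (e.g. along a smoothing path) reuse the geometry.
    """

    def __init__(self, source: SourceSpec, dwells: Sequence[DwellPosition],
                 refs: ReferencePointSet, prescription: PrescriptionSpec,
                 smoothing_scale: float | None = None) -> None:
        if len(dwells) < 1:
            raise ConfigurationError("at least one dwell position is required")
        self.source = source
        self.dwells = list(dwells)
        self.refs = refs
        self.prescription = prescription

        pts, weights, targets = [], [], []
        for site in prescription.prescribed_sites:
            site_pts = refs.select(site)
            if not site_pts:
                raise ConfigurationError(f"site {site!r} is prescribed but has no points")
            rx = prescription.rx_for(site)
            for p in site_pts:
                pts.append(p)
                weights.append(prescription.priority_map[(site, p.line_tag)] / 100.0)
                targets.append(rx)
        self.points = pts
        self.weights = np.asarray(weights)
        self.targets = np.asarray(targets)
        self.design = dose_rate_matrix(source, self.dwells, pts)  # cGy per s

        n = len(self.dwells)
        self.diff = np.diff(np.eye(n), axis=0)  # first-difference operator
        if smoothing_scale is None:
            WA = self.design * np.sqrt(self.weights)[:, None]
            self.smoothing_scale = float(np.trace(WA.T @ WA)) / n
        else:
            self.smoothing_scale = float(smoothing_scale)

    @property
    def lambda_s(self) -> float:
        return (self.prescription.smoothing / 300.0) * self.smoothing_scale

    def objective(self, times: np.ndarray) -> tuple[float, float]:
        """(fidelity, smoothing) terms of J at the given dwell times."""
        t = np.asarray(times, dtype=float)
        resid = self.design @ t - self.targets
        fid = float(np.sum(self.weights * resid**2))
        smo = float(self.lambda_s * np.sum((self.diff @ t) ** 2))
        return fid, smo

    def fit(self) -> DwellSolution:
        """Solve min_t>=0 J(t) by active-set NNLS on the stacked design."""
        sw = np.sqrt(self.weights)
        B = self.design * sw[:, None]
        y = self.targets * sw
        lam = self.lambda_s
        if lam > 0:
            B = np.vstack([B, np.sqrt(lam) * self.diff])
            y = np.concatenate([y, np.zeros(self.diff.shape[0])])

        converged = True
        if np.linalg.matrix_rank(B) < B.shape[1]:
            converged = False  # rank-deficient design: solution not unique
        try:
            t, _ = nnls(B, y)
        except RuntimeError:  # pragma: no cover - iteration limit
            t = np.zeros(B.shape[1])
            converged = False

        fid, smo = self.objective(t)
        coverage = {}
        window = self.prescription.dose_window
        doses = self.design @ t
        for site in self.prescription.prescribed_sites:
            mask = np.array([p.site_tag == site for p in self.points])
            rx = self.prescription.rx_for(site)
            coverage[site] = float(np.mean(np.abs(doses[mask] - rx) <= window))
        return DwellSolution(
            times=t, objective_value=fid + smo, term_breakdown=(fid, smo),
            converged=converged, coverage_fraction=coverage, model=self,
        )


def optimize_dwell_times(source: SourceSpec, dwells: Sequence[DwellPosition],
                         refs: ReferencePointSet, rx: PrescriptionSpec,
                         smoothing_scale: float | None = None) -> DwellSolution:
    """Functional wrapper: build a :class:`DwellTimeModel` and fit it."""
    return DwellTimeModel(source, dwells, refs, rx, smoothing_scale=smoothing_scale).fit()
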