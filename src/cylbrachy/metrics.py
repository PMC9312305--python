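"""Plan-quality dosimetry metrics.

Per-site DMax/DMin/DMean over the pooled reference points (left + right +
apex lines), expressed as percentages of that site's own prescription dose,
plus cross-plan aggregation (mean ± sample standard deviation) and sorted
dose profiles for hot/cold-spot display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STATISTICS = ("d_max_pct", "d_min_pct", "d_mean_pct")


def compute_site_metrics(doses_cgy: Sequence[float], rx_cgy: float) -> tuple[float, float, float]:
    """(DMax%, DMin%, DMean%) of one site, normalized to its prescription."""
    d = np.asarray(doses_cgy, dtype=float)
    if d.size == 0:
        raise ValueError("dose vector is empty")
    if rx_cgy <= 0:
        raise ValueError("prescription dose must be positive")
    return (
        float(100.0 * d.max() / rx_cgy),
        float(100.0 * d.min() / rx_cgy),
        float(100.0 * d.mean() / rx_cgy),
    )


@dataclass(frozen=True)
class PlanMetrics:
    """Per-site normalized dose statistics of one plan.

    ``records`` maps site_tag -> dict with d_max_pct/d_min_pct/d_mean_pct.
    Doses at each site are normalized to that site's own prescription; for
    single-site plans the unprescribed site is normalized to its mapped
    prescription so the four methods remain comparable.
    """

    plan_method: str
    records: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for site, rec in self.records.items():
            if not rec["d_min_pct"] <= rec["d_mean_pct"] <= rec["d_max_pct"]:
                raise ValueError(f"inconsistent metrics for site {site!r}")

    @classmethod
    def from_solution(cls, solution, rx_by_site: Mapping[str, float],
                      plan_method: str | None = None) -> "PlanMetrics":
        """Measure a :class:`cylbrachy.optimizer.DwellSolution` at both sites.

        ``rx_by_site`` supplies the normalization dose per site, including the
        mapped dose of an unprescribed site.
        """
        records = {}
        for site, rx in rx_by_site.items():
            mx, mn, me = compute_site_metrics(solution.doses(site), rx)
            records[site] = {"d_max_pct": mx, "d_min_pct": mn, "d_mean_pct": me}
        return cls(
            plan_method=plan_method or (solution.model.prescription.method or "custom"),
            records=records,
        )

    def to_rows(self) -> list[dict]:
        return [
            {"plan_method": self.plan_method, "site": site, **rec}
            for site, rec in self.records.items()
        ]


def aggregate_plans(metrics: Sequence[PlanMetrics]) -> pd.DataFrame:
    """Mean ± sample standard deviation per (method, site, statistic).

    The sigma column uses the n-1 sample convention; a singleton group
    reports sigma as NaN (undefined), never as zero.
    """
    rows = [r for m in metrics for r in m.to_rows()]
    if not rows:
        raise ValueError("no plan metrics to aggregate")
    df = pd.DataFrame(rows)
    long = df.melt(id_vars=["plan_method", "site"], value_vars=list(STATISTICS),
                   var_name="statistic", value_name="pct")
    agg = (
        long.groupby(["plan_method", "site", "statistic"], sort=True)["pct"]
        .agg(mean="mean", sigma=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    return agg


def sorted_profile(doses_cgy: Sequence[float], rx_cgy: float) -> np.ndarray:
    """Normalized doses (% of prescription) sorted from highest to lowest."""
    if rx_cgy <= 0:
        raise ValueError("prescription dose must be positive")
    d = 100.0 * np.asarray(doses_cgy, dtype=float) / rx_cgy
    return np.sort(d)[::-1]
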