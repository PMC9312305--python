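"""TG-43 dose engine for a stepping HDR source.

Implements the AAPM TG-43 dose-rate factorization

    D'(r, theta) = S_k * Lambda * G(r, theta)/G(r0, theta0) * g(r) * F(r, theta)

with the reference geometry r0 = 1 cm, theta0 = 90 deg.  Two geometry-factor
formalisms are supported: the point source (``G = 1/r**2``, anisotropy reduced
to a 1D factor ``phi_an(r)``) and the line source (``G = beta / (L r sin
theta)`` with ``beta`` the angle subtended by the active length at the
calculation point).

Units follow brachytherapy convention throughout: distances in cm, air-kerma
strength in U (uGy m^2 / h), dose-rate constant in cGy/(h U), dose rates in
cGy/h, dwell times in seconds (the 3600 s/h conversion lives in
:func:`accumulate_dose`), accumulated dose in cGy.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_DATA_DIR = Path(__file__).parent / "data"

SiteTag = Literal["surface", "depth5mm"]
LineTag = Literal["left", "right", "apex"]

#: reference geometry of the TG-43 formalism
R0_CM = 1.0
THETA0_DEG = 90.0


class DegenerateGeometryError(ValueError):
    """Calculation point coincides with (or sits inside) the source."""


class TableRangeError(ValueError):
    """Radius outside the tabulated range with clamping disabled."""


@dataclass(frozen=True)
class AnisotropyTable2D:
    """F(r, theta) on a rectangular (r, theta) grid; bilinear interpolation."""

    r_cm: np.ndarray
    theta_deg: np.ndarray
    values: np.ndarray  # shape (len(r_cm), len(theta_deg))

    def __post_init__(self) -> None:
        r = np.asarray(self.r_cm, dtype=float)
        th = np.asarray(self.theta_deg, dtype=float)
        F = np.asarray(self.values, dtype=float)
        if F.shape != (r.size, th.size):
            raise ValueError("anisotropy matrix shape does not match axes")
        if np.any(np.diff(r) <= 0) or np.any(np.diff(th) <= 0):
            raise ValueError("anisotropy axes must be strictly increasing")
        # F at theta = 90 deg must be unity by TG-43 normalization
        i90 = int(np.argmin(np.abs(th - 90.0)))
        if abs(th[i90] - 90.0) < 1e-6 and np.any(np.abs(F[:, i90] - 1.0) > 5e-3):
            raise ValueError("F(r, 90 deg) must equal 1 within table tolerance")
        object.__setattr__(self, "r_cm", r)
        object.__setattr__(self, "theta_deg", th)
        object.__setattr__(self, "values", F)

    def __call__(self, r: np.ndarray, theta_deg: np.ndarray) -> np.ndarray:
        r = np.clip(np.asarray(r, dtype=float), self.r_cm[0], self.r_cm[-1])
        t = np.clip(np.asarray(theta_deg, dtype=float), self.theta_deg[0], self.theta_deg[-1])
        ir = np.clip(np.searchsorted(self.r_cm, r) - 1, 0, self.r_cm.size - 2)
        it = np.clip(np.searchsorted(self.theta_deg, t) - 1, 0, self.theta_deg.size - 2)
        fr = (r - self.r_cm[ir]) / (self.r_cm[ir + 1] - self.r_cm[ir])
        ft = (t - self.theta_deg[it]) / (self.theta_deg[it + 1] - self.theta_deg[it])
        v00 = self.values[ir, it]
        v01 = self.values[ir, it + 1]
        v10 = self.values[ir + 1, it]
        v11 = self.values[ir + 1, it + 1]
        return (v00 * (1 - fr) * (1 - ft) + v01 * (1 - fr) * ft
                + v10 * fr * (1 - ft) + v11 * fr * ft)


@dataclass(frozen=True)
class SourceSpec:
    """TG-43 parameter set for one HDR source model.

    Parameters
    ----------
    air_kerma_strength : float
        S_k in U.
    dose_rate_constant : float
        Lambda in cGy/(h U).
    active_length : float
        Active source length L in cm (used by the line formalism).
    radial_r, radial_g : arrays
        Radial dose function table g(r); r strictly increasing, g > 0.
    anisotropy : AnisotropyTable2D | (r, phi) tuple of arrays | None
        2D F(r, theta), 1D phi_an(r), or None for an isotropic kernel.
    formalism : {"point", "line"}
    clamp : bool
        Clamp r to the table edges outside the tabulated range (with a logged
        warning); if False, out-of-range radii raise :class:`TableRangeError`.
    """

    air_kerma_strength: float
    dose_rate_constant: float
    active_length: float
    radial_r: np.ndarray
    radial_g: np.ndarray
    anisotropy: object = None
    formalism: Literal["point", "line"] = "line"
    clamp: bool = True
    name: str = "unnamed"

    def __post_init__(self) -> None:
        r = np.atleast_1d(np.asarray(self.radial_r, dtype=float))
        g = np.atleast_1d(np.asarray(self.radial_g, dtype=float))
        if r.size != g.size or r.size < 1:
            raise ValueError("radial dose table r/g size mismatch")
        if np.any(np.diff(r) <= 0):
            raise ValueError("radial dose table r must be strictly increasing")
        if np.any(g <= 0):
            raise ValueError("g(r) must be positive")
        if self.formalism not in ("point", "line"):
            raise ValueError(f"unknown formalism {self.formalism!r}")
        if self.formalism == "line" and self.active_length <= 0:
            raise ValueError("active_length must be > 0 for the line formalism")
        object.__setattr__(self, "radial_r", r)
        object.__setattr__(self, "radial_g", g)

    # -- factories -----------------------------------------------------

    @classmethod
    def unit_kernel(cls, formalism: str = "point", active_length: float = 0.35) -> "SourceSpec":
        """S_k = 1 U, Lambda = 1, g = 1, F = 1: the bare geometry factor.

        Used by tests and oracles; at (r0, theta0) the dose rate is exactly
        1 cGy/h by construction.
        """
        return cls(
            air_kerma_strength=1.0,
            dose_rate_constant=1.0,
            active_length=active_length,
            radial_r=np.array([0.05, 50.0]),
            radial_g=np.array([1.0, 1.0]),
            anisotropy=None,
            formalism=formalism,
            name="unit-kernel",
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "SourceSpec":
        """Load a source parameter file (JSON; see bundled example)."""
        path = Path(path)
        payload = json.loads(path.read_text())
        rdt = np.asarray(payload["radial_dose_table"], dtype=float)
        aniso_cfg = payload.get("anisotropy")
        aniso: object = None
        if aniso_cfg is not None:
            if aniso_cfg.get("type") == "2d":
                aniso = AnisotropyTable2D(
                    r_cm=np.asarray(aniso_cfg["r_cm"], dtype=float),
                    theta_deg=np.asarray(aniso_cfg["theta_deg"], dtype=float),
                    values=np.asarray(aniso_cfg["F"], dtype=float),
                )
            elif aniso_cfg.get("type") == "1d":
                tab = np.asarray(aniso_cfg["table"], dtype=float)
                aniso = (tab[:, 0], tab[:, 1])
            else:
                raise ValueError("anisotropy type must be '1d' or '2d'")
        return cls(
            air_kerma_strength=float(payload["air_kerma_strength"]),
            dose_rate_constant=float(payload["dose_rate_constant"]),
            active_length=float(payload.get("active_length", 0.0)),
            radial_r=rdt[:, 0],
            radial_g=rdt[:, 1],
            anisotropy=aniso,
            formalism=payload.get("formalism", "line"),
            name=payload.get("name", path.stem),
        )

    @classmethod
    def generic_ir192(cls) -> "SourceSpec":
        """Bundled illustrative Ir-192-type parameter set (synthetic tables)."""
        return cls.from_file(_DATA_DIR / "ir192_generic_source.json")

    # -- table lookups -------------------------------------------------

    def _check_range(self, r: np.ndarray) -> None:
        out = (r < self.radial_r[0]) | (r > self.radial_r[-1])
        if np.any(out):
            if not self.clamp:
                raise TableRangeError(
                    f"radius outside radial dose table "
                    f"[{self.radial_r[0]}, {self.radial_r[-1]}] cm"
                )
            logger.warning(
                "clamping %d radii to the radial dose table edge", int(np.sum(out))
            )

    def g(self, r: np.ndarray) -> np.ndarray:
        """Radial dose function, linear interpolation, edge-clamped."""
        r = np.asarray(r, dtype=float)
        self._check_range(r)
        return np.interp(r, self.radial_r, self.radial_g)

    def F(self, r: np.ndarray, theta_deg: np.ndarray) -> np.ndarray:
        """Anisotropy factor: 2D F(r,theta), 1D phi_an(r), or 1."""
        if self.anisotropy is None:
            return np.ones(np.broadcast(np.asarray(r), np.asarray(theta_deg)).shape)
        if isinstance(self.anisotropy, AnisotropyTable2D):
            return self.anisotropy(r, theta_deg)
        ar, aphi = self.anisotropy
        return np.interp(np.asarray(r, dtype=float), np.asarray(ar), np.asarray(aphi))


@dataclass(frozen=True)
class DwellPosition:
    """One stopping point of the stepping source on the applicator channel."""

    index: int
    position: np.ndarray  # cm, source center
    orientation: np.ndarray  # unit vector, source long axis

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        ori = np.asarray(self.orientation, dtype=float).reshape(3)
        if self.index < 0:
            raise ValueError("dwell index must be >= 0")
        if abs(np.linalg.norm(ori) - 1.0) > 1e-9:
            raise ValueError("orientation must have unit norm")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "orientation", ori)


@dataclass(frozen=True)
class DosePoint:
    """A reference dose point tagged by site (surface/depth5mm) and line."""

    position: np.ndarray
    site_tag: SiteTag
    line_tag: LineTag

    def __post_init__(self) -> None:
        if self.site_tag not in ("surface", "depth5mm"):
            raise ValueError(f"unknown site_tag {self.site_tag!r}")
        if self.line_tag not in ("left", "right", "apex"):
            raise ValueError(f"unknown line_tag {self.line_tag!r}")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float).reshape(3))


def _positions(points: Sequence) -> np.ndarray:
    """Accept DosePoints or bare 3-vectors; return an (n, 3) array."""
    return np.asarray(
        [p.position if isinstance(p, DosePoint) else np.asarray(p, dtype=float) for p in points]
    ).reshape(-1, 3)


def _geometry_factor(source: SourceSpec, r: np.ndarray, sin_t: np.ndarray,
                     cos_t: np.ndarray) -> np.ndarray:
    """G(r, theta) for the configured formalism (vectorized)."""
    if source.formalism == "point":
        return 1.0 / r**2
    L = source.active_length
    half = L / 2.0
    z = r * cos_t  # along source axis
    y = r * sin_t  # perpendicular distance
    on_axis = y < 1e-9 * np.maximum(r, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.arctan2(y, z - half) - np.arctan2(y, z + half)
        G = beta / (L * y)
        G_axis = 1.0 / (r**2 - half**2)
    G = np.where(on_axis, G_axis, G)
    if np.any(on_axis & (r <= half)):
        raise DegenerateGeometryError("point on the source axis inside the active length")
    return G


def _g_ref(source: SourceSpec) -> float:
    """G(r0, theta0) at the 1 cm / 90 deg reference geometry."""
    if source.formalism == "point":
        return 1.0
    L = source.active_length
    return 2.0 * math.atan(L / (2.0 * R0_CM)) / (L * R0_CM)


def _phi_an(source: SourceSpec, r: np.ndarray) -> np.ndarray:
    """1D anisotropy factor phi_an(r) for the point formalism.

    A 1D table is interpolated directly; a 2D F(r, theta) table is reduced to
    its solid-angle average over theta; no table means isotropic.
    """
    if source.anisotropy is None:
        return np.ones_like(r)
    if isinstance(source.anisotropy, AnisotropyTable2D):
        theta = np.linspace(0.0, 180.0, 181)
        w = np.sin(np.radians(theta))
        F = source.anisotropy(r[:, None], theta[None, :])
        return np.trapezoid(F * w, theta, axis=1) / np.trapezoid(w, theta)
    ar, aphi = source.anisotropy
    return np.interp(r, np.asarray(ar), np.asarray(aphi))


def dose_rate_vector(source: SourceSpec, dwell: DwellPosition,
                     points: np.ndarray) -> np.ndarray:
    """TG-43 dose rate (cGy/h) from one dwell at an (n, 3) array of points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    d = pts - dwell.position
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-12):
        raise DegenerateGeometryError("calculation point coincides with the source center")
    cos_t = np.clip(d @ dwell.orientation / r, -1.0, 1.0)
    sin_t = np.sqrt(1.0 - cos_t**2)
    theta = np.degrees(np.arccos(cos_t))
    G = _geometry_factor(source, r, sin_t, cos_t)
    rate = (source.air_kerma_strength * source.dose_rate_constant
            * G / _g_ref(source) * source.g(r))
    if source.formalism == "point":
        return rate * _phi_an(source, r)
    return rate * source.F(r, theta)


def dose_rate_at(source: SourceSpec, dwell: DwellPosition, point) -> float:
    """TG-43 dose rate (cGy/h) at a single point from one dwell position."""
    pt = point.position if isinstance(point, DosePoint) else np.asarray(point, dtype=float)
    return float(dose_rate_vector(source, dwell, pt.reshape(1, 3))[0])


def dose_rate_matrix(source: SourceSpec, dwells: Sequence[DwellPosition],
                     points: Sequence) -> np.ndarray:
    """Rate matrix in cGy/s: entry (p, i) is point p's dose rate per second of
    dwell time at position i.  This is the design matrix of the optimizer."""
    pts = _positions(points)
    A = np.empty((pts.shape[0], len(dwells)))
    for i, dw in enumerate(dwells):
        A[:, i] = dose_rate_vector(source, dw, pts)
    return A / 3600.0


def accumulate_dose(source: SourceSpec, dwells: Sequence[DwellPosition],
                    times: Sequence[float], points: Sequence) -> np.ndarray:
    """Total dose (cGy) at each point: sum_i t_i * rate_i, times in seconds.

    Linear and permutation-invariant in the dwell list by construction.
    """
    t = np.asarray(times, dtype=float)
    if t.size != len(dwells):
        raise ValueError("times and dwells must have equal length")
    if np.any(t < 0):
        raise ValueError("dwell times must be non-negative")
    return dose_rate_matrix(source, dwells, points) @ t
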