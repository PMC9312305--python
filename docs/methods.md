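# Methods

This note records the model, the numerical choices, and the limits of what
the bundled tests demonstrate. It is the package's own account; the API
reference lives in the module docstrings.

## Dose model

Dose rate from a single source dwell follows the TG-43 factorization

    D'(r, θ) = S_k · Λ · G(r, θ)/G(r₀, θ₀) · g(r) · F(r, θ),   r₀ = 1 cm, θ₀ = 90°

with two geometry factors: point (`G = 1/r²`, anisotropy collapsed to a 1D
factor φ_an(r); a 2D anisotropy table is reduced to its solid-angle average
when used this way) and line (`G = β/(L·r·sinθ)` with β the angle subtended
by the active length L at the calculation point, and the `1/(r² − L²/4)`
limit on the source axis). Radial dose and anisotropy tables are interpolated
linearly in r and θ and clamped to the nearest table edge beyond their range
(with a logged warning; clamping can be disabled, turning out-of-range radii
into errors). Units are fixed throughout: cm, U for air-kerma strength,
cGy·h⁻¹·U⁻¹ for the dose-rate constant, seconds for dwell times, with the
3600 s/h conversion applied once in dose accumulation.

Two source parameter sets ship with the package. The *unit kernel*
(S_k = 1 U, Λ = 1, g ≡ 1, F ≡ 1) isolates the geometry factor and is what
the oracles and closed-form tests use. The *generic Ir-192-type* file is an
illustrative, synthetic parameter set (smoothed round-number tables with the
familiar Ir-192 features: g(r) within ~1% of unity out to 4 cm, polar
anisotropy shadow down to ~0.64 along the axis). It is the default for the
comparison workflow and deliberately not a commissioned model of any
commercial source; any real source can be supplied as JSON.

## Applicator geometry

Axis = z, dome center at the origin, apex pole at +dome_radius
(hemispherical dome, dome_radius = diameter/2 by default). Dwell centers sit
on the axis at a fixed 0.5 cm step, the first one `tip_offset` (default
0.6 cm, representative of commercial cylinders) below the apex surface;
`floor(treatment_length/step) + 1` dwells in total. Default treatment length
4.0 cm, within the 3–5 cm coverage commonly recommended for the upper
vagina.

The six reference lines live in the sagittal plane (cylindrical symmetry
makes one plane sufficient): left/right straight lines at radial distance
diameter/2, an apex arc over the dome, and the same three lines 0.5 cm
farther along the outward normal (radial for the straight lines,
spherical-radial for the arc). Straight lines run from the dome junction
down to the z of the most distal dwell — reference points beyond the last
dwell would sit in the unavoidable longitudinal falloff and poison the
optimization targets, so they are not generated. Default sampling: 0.25 cm
along straight lines, 9 angular samples per apex half-arc; both
configurable. Surface and depth points are generated in matched order, so
every surface point has a 5 mm partner, which the geometry tests exploit.

## Optimization

The planning objective is priority-weighted least squares with a
first-difference smoothing penalty:

    J(t) = Σ_p w_p (d_p(t) − Rx_site(p))² + λ_s Σ_i (t_{i+1} − t_i)²,  t ≥ 0

- d_p(t) is linear in t (row p of the dose-rate design matrix times t).
- w_p = priority/100. Default priorities: primary straight lines 110,
  primary apex 140, secondary straight 60, secondary apex 79 — the apex runs
  hotter/colder than the straight lines, so it gets 10–50 extra priority
  within each group, and the primary/secondary split (> 100 / < 80) is what
  makes the double prescription a *prioritized* trade rather than an
  average.
- λ_s = (smoothing/300) · λ_ref maps the 0–300 smoothing dial onto a
  per-problem scale λ_ref = trace(AᵀWA)/n_dwells, chosen so that at dial 300
  the smoothing curvature is commensurate with the fidelity curvature. The
  dial's internal scale in commercial systems is not public; only the
  ordering semantics (0 = off, 300 = strongest) are preserved, and the scale
  can be overridden for studies of the λ → ∞ limit.
- The stacked problem min ‖[√W A; √λ_s D] t − [√W Rx; 0]‖² over t ≥ 0 is
  solved by scipy's active-set NNLS: deterministic, no initialization, exact
  at convergence. The objective is strictly convex when the stacked design
  has full column rank; rank deficiency is reported on the solution
  (`converged = False`), never resolved silently.
- The ±50 cGy prescription window is reported as a per-site coverage
  fraction (planning goal ≥ 98% of points), not enforced as a constraint —
  treating it as hard would make many single-site geometries infeasible and
  it is phrased as a goal in clinical practice.

The four standard plans: P1_5mm (depth only), P2_5mm&Sur (depth primary,
surface secondary), P3_Sur (surface only), P4_Sur&5mm (surface primary,
depth secondary). A missing dose for a dual plan is derived through the dose
mapping and rounded to the nearest 10 cGy, the granularity prescriptions are
written in.

## Dose mapping

Each cylinder size carries a nine-row table pairing 5 mm-depth and surface
prescription doses, and two fifth-order polynomials (one per direction)
fitted to it. **The polynomial variable is dose in Gy**: the published
coefficients produce wildly wrong values if evaluated in cGy, and reproduce
their tables in Gy — the package pins this down with a row-by-row
consistency check (`consistency_report`). Measured residuals of the bundled
coefficients against the bundled tables: every row within 1.6% except the
3.0 cm 500 ↔ 730 cGy row at 2.24%; a fresh least-squares refit shows the
same outlier (1.62% residual, optimal in the least-squares sense), with both
the published and refitted quintics placing that correspondent near
745 cGy. The discrepancy is in the printed data, which is kept verbatim.

Mapping functions are valid for interpolation only: a quintic oscillates
outside its support, so evaluation outside the source column's range raises
an error rather than extrapolating. Exactly tabulated doses return their
printed correspondents directly (the table is authoritative); the quintic
serves between rows. Fits are always performed in Gy to keep the Vandermonde
matrix conditioned (condition number is logged), and require ≥ 7 rows.

`build_dose_table` regenerates a table on any source/geometry: one
single-site plan per anchor dose level, recording the mean dose over the
other site's lines, rounded to the nearest 10 cGy. Mean (rather than median
or a percentile) is the documented convention; since dose is linear in dwell
time and the optimizer is positively homogeneous, correspondents scale
exactly with the anchor level before rounding.

## Metrics and the comparison matrix

DMax/DMin/DMean pool all points of a site's three lines and are expressed as
% of that site's own prescription; for single-site plans the unprescribed
site is normalized to its mapped prescription so all four methods stay
comparable. Aggregation over plans reports the arithmetic mean and the
sample (n−1) standard deviation; a singleton group's σ is undefined (NaN),
never zero.

The default comparison matrix is 9 dose levels × 4 methods × 3 cylinder
sizes × 2 geometries = 216 plans; the two geometries are treatment lengths
of 3.5 and 4.5 cm, standing in for per-patient variation (anatomy plays no
role in the optimization model, which has no organ-at-risk terms — mirroring
routine cylinder practice). Cell prescriptions come from the bundled
published tables by default (`mapping_source="reference"`): the tabulated
pairs are the point of the method, and the directional findings — the
secondary surface prescription cutting the surface DMax, the secondary depth
prescription lifting DMin/DMean at both sites, surface-primary plans having
the tighter surface spread — emerge under those pairs. With
`mapping_source="self"` the prescriptions instead come from a table
regenerated on the run's own source/geometry; that variant is self-
consistent by construction, which leaves the secondary depth objective
almost exactly at the dose a surface-only plan already delivers, so the
P4-over-P3 improvement largely vanishes there. Every report bundle includes
the regenerated table for audit, and re-running a configuration reproduces
byte-identical CSVs (there is no randomness anywhere).

## What the bundled tests do and do not show

The synthetic ingredients (unit kernel, illustrative Ir-192-type source,
idealized cylinder with perfectly known geometry) emulate the *structure* of
clinical planning — steep inverse-square gradients, polar anisotropy at the
apex, the 5 mm dwell lattice — but none of its uncertainties: no applicator
reconstruction error, no source calibration uncertainty, no tissue
heterogeneity (TG-43 assumes water), no organ-at-risk anatomy. Passing tests
therefore demonstrate the correctness of the formalism, the optimizer and
the mapping algebra, and the qualitative plan-quality ordering of the four
prescription methods on this geometry; absolute percentages (e.g. a surface
DMax of 128.9% for the dual depth-primary plan) depend on the source model,
the line sampling and the proprietary objective of any clinical optimizer,
and transfer only directionally. Problem sizes used by the test suite and
acceptance checks — the full 216-plan matrix, 200-per-dimension brute-force
grids on ≤ 3-dwell instances, adaptive quadrature line-source oracles — were
chosen so every check runs in seconds on one CPU.

## Known limitations

- Single-channel cylinders only; no ovoids, tandems or multichannel
  applicators, and no image-based applicator reconstruction.
- TG-43 water-kernel dosimetry: no heterogeneity or shielding corrections,
  no Monte-Carlo benchmark.
- The Eclipse-style priority dial is mapped linearly to weights
  (w = priority/100); only the published ordering semantics are guaranteed.
- Mapping functions are size-specific to 2.5/3.0/3.5 cm; no interpolation
  across diameters.
- No DICOM-RT import/export and no afterloader transfer files.
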