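# Methods

## The measurement model

The pipeline treats a muscle as a 3D binary label on an anisotropic voxel
grid (typical MRI spacing 1.1 × 1.1 mm in-plane, 3–5 mm between slices).
Physical coordinates follow the voxel-centre convention: voxel (i, j, k)
sits at (i·sx, j·sy, k·sz) mm with the origin at the first voxel centre, so
all derived quantities are translation-equivariant by construction.

**Volume.** V_M = foreground voxel count × voxel volume, reported in cm³.
No partial-volume modelling is attempted; accuracy is set by how finely the
grid samples the shape (phantom tests bound the error at ≤ 5% for tube
radii ≥ 8 mm on a (1, 1, 3) mm grid).

**Centreline and anatomical length.** Cross-sections are taken
perpendicular to the acquisition slice axis — the axis along which the limb
was scanned — never re-sliced along the muscle's own principal axis. Each
occupied slice contributes one representative point; the ordered points are
smoothed with a centred moving average and l_M is the arc length of the
smoothed polyline, in cm.

The representative point is derived from the 2D medial-axis skeleton of the
cross-section: the centroid of the skeleton pixels weighted by the *square*
of their inscribed-disk radius, i.e. by the area of mask each skeleton
point accounts for. A plain unweighted centroid of the skeleton pixel set
is unusable in practice: the digitised skeleton of a near-round section
degenerates to a sparse, off-centre ridge whose centroid jumps by 2–3
pixels between adjacent slices, and those jumps accumulate into a 10–20%
arc-length inflation on curved phantoms. The area weighting restores a
stable sub-pixel estimate while remaining a pure function of the skeleton:
for a convex section it approximates the maximal-inscribed-disk centre, and
for a looped skeleton of uniform depth (an annular section) it reduces to
the ring centroid, which may fall outside the mask and is flagged in the
output rather than suppressed.

Cross-sections that split into several connected components use the largest
component (flagged); empty slices interior to the span are filled by linear
interpolation between neighbours (flagged); masks occupying fewer than
three slices are rejected.

**Smoothing.** The moving-average span must be odd; windows shrink
symmetrically at the ends so endpoints are fixed, and span 1 is the
identity. The default span is the odd integer nearest 10% of the occupied
slice count, clamped to [3, 15]; it is overridable per muscle, because the
appropriate span genuinely depends on a muscle's slice count and shape
(thin, smooth structures need little smoothing; noisy, broad ones need
more).

**End correction.** Each per-slice point represents a slab of thickness
equal to the slice spacing, so the full-chain length in `muscle_geometry`
extends the smoothed polyline by half a slab along the tangent at either
end. Without this the polyline spans first-to-last slice *centres* and
systematically underestimates length by one slice spacing. The primitive
`centreline_length` remains a pure polyline arc length.

**Forces.** PCSA = V_M / (k · l_M) with k the literature optimal-fibre-
length-to-muscle-length ratio (k = 1 for the Tensor fasciae latae, whose
ratio is not available in the cadaveric source). F_max(VLS) = σ · PCSA with
σ = 61 N/cm² by default, a specific tension proposed for older adults.
F_max(LLMS) = (m_LL / m_LLGen) · F_maxGen scales each generic-model
actuator by the subject's lower-limb mass, m_LL = segmented lower-limb
volume × tissue density (1.056 g/cm³ default). The generic model's
bilateral lower-limb mass defaults to 29.15 kg; whether m_LL means both
limbs or one limb doubled is a config switch (`limb_mass_convention`),
since conventions differ between modelling groups. The k table, generic
force table, σ, density and m_LLGen all ship as editable CSV/scalar config:
the shipped values are representative defaults from the cadaveric and
generic-model literature, not authoritative reproductions, and any study
should substitute its preferred sources.

## Statistics

- CoV = 100 · sample SD (n−1 denominator) / mean.
- Repeatability gate: inter-operator CoV ≤ 5% → accepted without further
  testing; > 5% demands an intra-operator repeat, accepted iff its CoV
  ≤ 10%, otherwise the muscle is discarded. Applied to the published
  25-muscle operator table this retains exactly 23 muscles.
- Paired comparisons (right vs left; VLS vs LLMS) test the per-subject
  differences for normality with a one-sample Kolmogorov–Smirnov test
  against a normal with sample-estimated mean and SD (α = 0.05); normal
  data take a paired t test, otherwise the Wilcoxon signed-rank test
  (exact method for small n; verified in tests against exhaustive
  enumeration of all 2^n sign assignments for n ≤ 12). The plain KS test
  with estimated parameters is anti-conservative; a Lilliefors-corrected
  variant is available (`lilliefors=True`) but off by default.
- Percentage differences are signed, positive when the right limb (or the
  VLS estimate) is larger. The denominator is a convention, not a fact:
  default (right − left)/right and (VLS − LLMS)/LLMS, both switchable,
  because asymmetric reported ranges depend on the choice.
- Between-subject CoV is computed and reported per side (a pooled option
  exists).
- Regressions of total muscle volume (sum over retained muscles, both
  limbs) on anthropometric predictors are ordinary least squares with the
  two-sided slope p-value; R² equals the squared sample correlation for
  these simple regressions (asserted to 1e−12).
- No multiple-testing correction is applied across muscles by default;
  Holm adjustment is available (`holm_adjust`).

## Synthetic data

**Phantoms** are tube solids — straight, circular-arc ("quarter-torus"),
or linearly tapered — rasterised by the centre-inside rule: a voxel belongs
to the mask iff its centre lies inside the analytic solid. The solid is
placed at a sub-voxel offset drawn from the seed; grid-aligned placement is
a degenerate configuration (analytic faces containing whole planes of voxel
centres) that biases volume by a full slice. Curved tubes are oriented
symmetrically about the slice axis, end tangents at ±(arc/2) from it, and
are cut flat at the arc endpoints' axial planes: a per-slice method is
simply undefined where a muscle's axis turns into the slice plane, and
lower-limb muscles run roughly along the scan axis. Ground truth is
analytic: Pappus' theorem for straight/tapered tubes, dense quadrature of
exact cross-section areas (relative error ~1e−4) for the clipped arc tube,
and the exact arc length for every centreline.

**Cohorts** draw one record per subject × side × muscle for volume and
length. Right-limb volumes are mean_m · (1 + CoV_m · (a·g_i + b·e_im)) with
a shared subject size factor g_i (a² = 0.6 of the variance shared,
b² = 0.4 idiosyncratic, resampled if non-positive); the left limb applies a
signed percentage difference d_im ~ N(μ_d, σ_d) as left = right·(1 −
d/100), so d equals the (right − left)/right difference exactly. Default
per-muscle volume means and CoVs are the study population's published
per-muscle mean (SD) values for the 23 analysed muscles; default asymmetry
is μ_d = 0, σ_d = 15%. Lengths are not published for this population, so
mean lengths are anatomically plausible values fixed once, with CoV 8% and
a small (σ = 3%) independent length asymmetry. Body mass ~ N(66.9, 7.7) kg
and height ~ N(159, 3) cm match the study cohort; the size factor
correlates with body mass at 0.75, giving a large-sample total-volume R²
against body mass of ≈ 0.5 while height stays uncorrelated. Lower-limb
mass is 0.32 × body mass with 3% noise.

What the generator does *not* emulate: MRI intensities, noise or bias
fields; segmentation error; muscle-shaped (non-tubular) geometry; tapering
to tendinous tips; correlations between a muscle's volume and its length;
dominance-related asymmetry patterns. Passing phantom and recovery tests
therefore demonstrates that the measurement and statistics chains are
correct on known ground truth — not that real segmentations are this
well-behaved.

## Problem sizes and numerics

Tests and the acceptance script run phantoms of ~10–70 slices at 1–5 mm
slice spacing, 11-subject cohorts of 23 muscles for the study-scale
statistics, and n = 200 single-muscle cohorts for parameter recovery
(Monte-Carlo tolerance ±3% absolute on a 20% CoV; asymmetry within 3
standard errors). The spacing-refinement convergence suite uses an axis
length of 57.5 mm, deliberately incommensurate with the 5/3/1 mm slice
spacings: a length that is an exact multiple of every spacing has zero
axial quantisation error and makes the refinement sequence degenerate.
Wilcoxon p-values use the exact distribution whenever scipy's criteria
allow; ties and zeros fall back to the normal approximation. Degenerate
paired data (all differences zero) are reported as "no difference", p = 1,
rather than passed to the signed-rank test. All randomness flows through
one seeded generator per call and seeds are recorded in outputs.

## Known limitations

- The centreline length is only meaningful for muscles whose principal
  axis stays within roughly ±45° of the slice axis; no re-slicing is
  attempted.
- k ratios and generic-model forces are shipped as representative
  defaults; force magnitudes (and the sign of VLS-vs-LLMS differences per
  muscle) depend directly on them.
- The LLMS path estimates lower-limb mass from whatever labels are
  segmented; if only muscles (not whole-limb tissue) are labelled, m_LL is
  underestimated and should instead be supplied via the anthropometrics
  table (`limb_mass_kg`).
- Tendon slack length, pennation angle and per-subject specific tension
  are out of scope: they are not measurable from the supported imaging.
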