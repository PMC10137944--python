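# Methods

## Model and assumptions

Hepatocyte polyploidy has two layers. Cellular ploidy — nuclei per cell —
is reconstructed geometrically: two nuclei are assumed to share a cell
exactly when the gap between their equivalent circles (the *relative
distance* d − r₁ − r₂) is small, an assumption that holds when nuclei of
one cell sit closer together than nuclei of neighbouring cells. Nuclear
ploidy — DNA content class per nucleus — is assumed to be expressed in
cross-sectional area: nuclei are treated as spheres whose radius grows
with ploidy, cut by the section plane at a uniformly random offset.
Neither assumption is exact on real tissue (nuclei are ellipsoidal,
sections have thickness, cells deform under fixation); both are exact in
the synthetic regime the test suite constructs.

## Pipeline

1. **Ingestion** (`pipeline.load_instances`): an integer instance-label
   image plus a label→class table (six classes: hepatocyte, stroma,
   lymphocyte, macrophage, red blood cell, karyorrhexis). Centroid, area
   and equivalent radius are measured from the mask; only hepatocyte-class
   nuclei go forward. Producing such masks from H&E colour images is an
   upstream instance-segmentation problem and out of scope here.
2. **Grouping** (`grouping.RelativeDistanceGrouping`): all-pairs relative
   distances, links where the distance is strictly below the threshold,
   cells = connected components. Components are the only partition
   consistent with pairwise link decisions; components of ≥3 nuclei are
   possible under a miscalibrated threshold and are flagged in summaries
   rather than split.
3. **Central-region filter** (`segmentation.filter_central`): cells whose
   centroid (arithmetic mean of member nucleus centroids) falls within
   `padding` of the patch edge are dropped after grouping, so truncated
   cells cannot bias counts. The test is half-open:
   `padding ≤ coordinate < size − padding`.
4. **Nuclear ploidy** (`gmm.NuclearPloidyGMM`): maximum-posterior call
   under the fitted three-component mixture; total ploidy per cell is the
   sum of member nuclear copy numbers.

## Threshold calibration

On membrane-resolved two-channel images, nuclei and cell regions are
segmented by watershed: Gaussian smoothing (σ = 1 px), Otsu foreground,
seeds from distance-transform maxima with ≥5 px separation, flooding on
the inverted distance transform (nuclei) or on the membrane ridge
landscape seeded by inter-ridge components (cells). An Otsu split is only
trusted when the foreground/background contrast exceeds 0.15 on the [0,1]
scale; otherwise the image is treated as signal-free. These parameters are
exposed and tuned for the synthetic regime; on real fluorescence they
would need re-tuning.

Per nucleus, one RDNDC sample (nearest different-cell nucleus) and — in
polynuclear cells — one RDNSC sample (nearest same-cell nucleus) are
collected. "Nearest" is by *relative* distance, keeping the sampling
metric identical to the classifier's; nearest-by-absolute-distance is the
plausible alternative and the spatial layouts used for calibration make
the two coincide in practice. Because sampling is per nucleus, an
unordered pair may appear twice; it is retained both times.

Threshold selection sweeps the midpoints between consecutive distinct
relative distances plus sentinels beyond the range (ties are therefore
measure-zero), predicts same-cell by strict `<`, and returns the smallest
candidate maximising F1 — deterministic by construction. AUC is the
trapezoidal area under the swept ROC and equals the Mann–Whitney
statistic on the same samples (asserted in tests). Conversion between
pixel scales multiplies by the resolution ratio; the converted value is
kept at full precision and rounded to two decimals only for reporting.

## Sphere-slicing simulation

Defaults are the normal-liver study conditions: diploid mean radius
μ = 9 with σ = a·μ/3 and a = 0.3 (so σ_di = 0.9); radius multiplier 1.18
per ploidy step (theory: 2^(1/3) ≈ 1.26 for volume doubling); 600/350/250
sphere radii per class with as many cuts each, giving 360,000 / 122,500 /
62,500 cross-sections (66.05% / 22.48% / 11.47%); detection floor 200
area units. Units are pixels at the H&E scale; the model is
unit-agnostic. A cut at offset h ~ U(0, R) exposes area π(R² − h²), so
for fixed R, E[area] = (2/3)πR² — the closed form the tests check.
Censoring defaults to deterministically dropping every area below the
floor (the same rule applied proportionately across classes); a
`random-proportional` strategy that removes the same per-class counts at
random is available as a sensitivity check.

**Multiplier search.** `search_merge_multiplier` walks candidates down
from 1.26 and returns the largest whose pooled censored histogram is
unimodal under a deterministic criterion: 256-bin histogram, Gaussian
smoothing at Silverman's bandwidth, local maxima (boundary maxima
included) above 1% relative prominence. A limitation worth stating
plainly: under the default parameters the pooled censored area density is
unimodal for *every* candidate in [1.10, 1.26] — verified against the
exact density computed by quadrature — because the radius spread
(σ/μ = 0.1) smears the per-class slicing peaks into shoulders well below
any reasonable prominence. The search therefore returns 1.26, and the
working multiplier 1.18 is treated as a fixed input of the simulation,
not as a reproducible output of the search. The mode counter itself
behaves as expected on genuinely separated data (three separated
components → three modes).

## Two-stage mixture

Stage one fits a single Gaussian (sample mean and variance), giving the
dominant-peak location k. Stage two runs one-dimensional EM for three
components initialised at means (k, 1.4k, 1.96k), uniform weights, and
the stage-one variance for every component; with the initialisation fully
specified there are no random restarts and the fit is deterministic.
Convergence: improvement of the mean log-likelihood below 1e-4; iteration
cap 500 (exceeding it raises an error carrying the full likelihood
trace); variance floor 1e-8 × the stage-one variance. The trace is
non-decreasing (an EM guarantee, asserted in tests) and the fit is
cross-checked against scikit-learn's `GaussianMixture` started from the
identical initialisation. Components sorted by ascending mean map to
2n/4n/8n; minimum 30 observations to fit (≈10 per component). A frozen
model stores its training resolution (μm/px); areas supplied at another
resolution are rescaled by the squared resolution ratio before scoring,
since a physical area covers (res_new/res_train)² more training pixels.

On the simulation dataset itself the three fitted means do not coincide
with the per-class empirical mean areas: the sliced-sphere class densities
are skewed and censored, not Gaussian, so EM places the lower two means
toward the censoring floor (~9% below the class means) while the top
component tracks the octoploid class within 5%. Tests assert the
properties the fit actually guarantees (mixture mean equals data mean,
ordered non-degenerate components) rather than a per-class identity that
does not hold.

## Synthetic data

The generator emulates the two data regimes the pipeline consumes:
360×360 fluorescence-like patches (nuclear + membrane channel) and
labelled instance masks standing in for an H&E segmenter's output.
Defaults, chosen once as study conditions: nucleus equivalent-radius mean
9 px (matching the simulation's μ_di), sd 0.9 px, binuclear fraction 0.25
(within the human polynuclear range), ploidy class fractions
(0.6605, 0.2248, 0.1147) matching the simulation proportions, radius
multiplier 1.18 per ploidy step, sibling relative distance ≤3 px,
cross-cell relative distance ≥12 px. Binuclear cells and ploidy classes
are allocated by deterministic quota (largest remainder), so tests can
assert exact counts. Nuclei are ellipses with axis ratio in [0.8, 1.0]
(exercising the equivalent-radius definition); sibling ellipses are
oriented with their major axes perpendicular to the separation axis and
additionally checked for pixel-level disjointness, so footprints never
overlap. Placement is rejection sampling with a hard cap of 10,000
attempts per cell and an explicit error naming the violated constraint.
Intensities: foreground 0.8, background 0.1, Gaussian noise sd 0.05 —
comfortably above any Otsu split, which is what makes the segmentation
tests stable. Membrane ridges are the boundaries of the Voronoi partition
of the true cell centroids.

What the synthetic regime does *not* model: H&E colour and texture,
irregular nuclear shapes, touching or overlapping nuclei, karyorrhexis
morphology, section thickness. Passing tests therefore demonstrate the
correctness of the geometry, calibration, grouping and classification
machinery on data satisfying the model assumptions — not segmentation
robustness on real stains.

## Numerical choices and degenerate inputs

* Coordinates are 0-based (row, col) with pixel centres at integers; a
  centroid exactly on the padding line is kept (half-open rule); a
  centroid on a region-boundary pixel takes that pixel's label.
* Nearest-neighbour and F1 ties break toward the smaller nucleus id /
  smaller threshold, making every stage deterministic.
* Blank or contrast-free images segment to nothing (nuclei) or one region
  (membranes) rather than erroring; a single-cell calibration input yields
  no RDNDC samples and a logged warning; calibration with only one class
  of pairs raises an error naming the missing class.
* `min_area` = 30 px² at nucleus segmentation suppresses noise specks and
  sits far below any simulated nucleus.
* Problem sizes in the test suite (patches of 10–50 cells, 2,000
  calibration pairs, the full 545,000-sample simulation) keep the whole
  suite under half a minute while leaving every statistical check several
  standard errors of headroom.

## Known limitations

* The pipeline consumes instance masks; it does not segment H&E colour
  images, and the quality of upstream segmentation bounds everything
  downstream.
* The relative-distance rule cannot distinguish a binuclear cell from two
  adjacent mononuclear cells whose nuclei happen to sit closer than the
  threshold; the calibration data's separability is what gives the
  threshold its meaning.
* The mixture model fixes three components; higher ploidy classes (≥16n)
  would be absorbed into the 8n component.
* The multiplier search criterion cannot recover a non-trivial merge
  point under the default simulation parameters (see above).
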