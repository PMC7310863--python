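# Methods

This note documents the models, numerical choices and known limitations of
the package. All empirical statements below are recomputed by the test
suite or by `scripts/acceptance.py`.

## The analysis chain

**Maxima detection.** Confocal foci are reduced to single-pixel points by a
prominence criterion: a candidate maximum is suppressed when it connects to
a higher maximum through intensity levels within the noise tolerance
(90 for DMC1, 100 for RAD51 by default). This is implemented with the
h-maxima transform; surviving plateaus contribute the centroid of their
highest pixels, and a region must additionally stand above the global
image minimum by more than the tolerance (a constant image therefore
yields no maxima). On plateaus the centroid convention may differ from
scan-order-based implementations by a pixel; the behaviour is verified
against a brute-force flood oracle in the tests.

**Density estimation and segmentation.** Localisations are binned on a
5 nm grid and smoothed with an isotropic Gaussian of 20 nm standard
deviation (the approximate average localisation precision), truncated at
four bandwidths (relative kernel error < 1e-4). The surface is scaled to
absolute density so that it integrates to the localisation count;
the test suite checks mass conservation to within 1% for centred data.
Nanofoci are 8-connected components of the super-threshold set
(0.2 events/nm² = 5 events/pixel) with at least 50 pixels; connectivity
and every constant are configurable. Density-weighted centres of mass are
computed per component; coincident input collapses to a pixel centre, so
positions are meaningful to half a pixel (2.5 nm).

**ROI rules.** ROIs are closed 300 nm-radius discs. A pair of ROIs sharing
more than 25% of their localisations (fraction relative to the smaller
ROI) is excluded entirely — the rule does not specify a survivor, so both
members are removed — and ROIs with fewer than 50 localisations (total
over both channels by default; a per-channel variant is available) are
excluded.

**Distances and roles.** The minimum focus distance is taken over
DMC1–RAD51 centre pairs; the maximum over *all* nanofocus pairs including
same-channel pairs, so a D2R1's DMC1–DMC1 separation sets its maximum.
In D2R1/D1R2 the duplicated-channel nanofocus realising the inter-channel
minimum is *close*, the other *far*; ties break toward the larger area,
then the lower index.

**Morphology.** The published classification was visual; here it is an
explicit decision rule on the mask-overlap graph (overlap = ≥1 shared
5 nm pixel): bridges (one nanofocus overlapping two of the other channel)
take precedence, then paired (two disjoint overlapping twin pairs), then
simple/complex for a single overlapping major pair — *simple* requires
both majors roundish (mask eccentricity ≤ 0.85) and all other nanofoci to
be satellites (< 50% of the largest same-channel area) — and *separate*
when no inter-channel overlap exists. The eccentricity and major-fraction
thresholds are proxies for the visual calls and are configurable; exact
agreement with manual labels is not claimed.

**Rotational alignment.** Foci are aligned by a proper rigid motion
(determinant +1, no reflection or scaling) taking the anchor centre to the
origin and the goal centre onto the positive y axis. Quadrants are the
four 90° wedges bounded by y = ±x, with boundary events assigned to the
vertical wedges; the "top half" feature counts events with y > 0. The
RAD51 length is the σ of a single Gaussian with offset least-squares
fitted to the 5 nm-binned y-marginal of the pooled localisations (fitting
pooled events rather than image rows is a package choice; the two differ
only through rendering weights). FWHM is reported as 2√(2 ln 2)σ ≈ 2.355σ.

## The generative D2R1 model

One simulated focus consists of three Gaussian 3D clusters and uniform
background:

| component   | count | shape                                    |
|-------------|-------|------------------------------------------|
| close DMC1  | 564   | isotropic, σ = 30 nm                     |
| far DMC1    | 51    | isotropic, σ = 15 nm                     |
| RAD51       | 267   | ellipsoid, σ_major free, σ_minor = 15 nm |
| background  | 50    | uniform in a 600 nm cube                 |

The far DMC1 centre sits 400 nm from the close centre in a uniformly
random 3D direction. The RAD51 major axis makes an angle drawn uniformly
in [0, α] with the close→far axis (uniform azimuth), and its centre is
offset one major-axis σ along that direction, so the filament emanates
from the close cluster. The counts are the mean localisations per
nanofocus in the source data; the cluster widths are not stated there, so
the defaults were chosen to place segmented areas in the observed
large/small regime (the far nanofocus roughly an order of magnitude
smaller in area than the close one) and are configurable. Background
points are assigned a channel uniformly at random. Everything draws from
per-focus substreams of one seeded generator, so outputs are reproducible
bit-for-bit.

Grid fitting simulates 200 foci per (σ, α) cell — the default grid covers
FWHM ∈ {80, 96, 112, 128, 144, 160} nm and α ∈ {90, 105, 120, 132, 150,
180}° — discards z, runs each projected focus through the standard
segmentation/classification/alignment chain, and summarises each cell by
three features (σ-RAD51, %DMC1 top half, %RAD51 top quadrant). Because σ
in nm and two percentages are incommensurate, each feature is divided by
its range over the grid before the mean-squared-error comparison
(raw-unit comparison available); ties break toward smaller σ, then
smaller α. Self-fits return error exactly 0, and the test suite shows a
known interior (σ, α) is recovered within one grid step in ≥ 90% of 20
seeded replicates at 200 foci per dataset.

### The density threshold in the simulation study

The segmentation threshold is quoted as 5 localisations per 5 nm pixel,
i.e. 0.2 events/nm². A hard bound shows this cannot segment the model's
own cluster counts: a component of area A of a density surface that
integrates to N events satisfies A ≤ N / threshold, so at 0.2 events/nm²
the 50-pixel (1250 nm²) minimum area requires ≥ 250 in-mask events — and
for Gaussian clusters under a 20 nm-bandwidth KDE the practical floor is
about 830 events, above all three cluster counts (267/564/51). The only
unit reading under which those counts are segmentable is 0.2 events *per
pixel* (0.008 events/nm²), which the simulation study therefore uses
(`nanofoci.d2r1_fit.STUDY_THRESHOLD`); the segmentation module itself
keeps 0.2 events/nm² as its default, and both are configurable.

Under this configuration about 4–5% of 3D D2R1 foci re-classify as D1R1
after 2D projection (the far DMC1 merges into the close cluster when the
projected separation, 400·sin θ, falls below the ~100 nm merge radius).
Larger loss rates are only reachable by making far-DMC1 detection itself
marginal (e.g. σ_far ≥ 18 nm), at which point the in-plane control — a
far cluster displaced purely in the imaging plane, which should virtually
always be recovered — starts failing; the package keeps the robust
regime. The reported loss percentage should therefore be read as the pure
projection-geometry component.

## CSR testing and statistics

The mask-constrained randomisation places the observed number of foci
uniformly on distinct mask pixels, renders them with a 110 nm Gaussian
blur at 99 nm pixels (the pixel size and impulse amplitude, 1000 by
default, are configurable — the amplitude is chosen so blurred peaks clear
the detection tolerances), adds the constant offset of 5 and per-pixel
uniform noise in ±√intensity, and re-detects maxima through the same
chain as observed images, so detector artefacts affect both distributions
alike. Fifty simulations per nucleus are pooled and compared with a
two-sample Kolmogorov–Smirnov test (asymptotic p, matching `ks.test`).

Within-set nearest-neighbour samples contain duplicated distances from
mutual nearest-neighbour pairs (~60% of points in random patterns), which
violates the independence assumption of the KS test and inflates its
type-I error roughly three-fold (measured). The KS comparison therefore
counts each mutual pair once (`unique_pairs`), restoring calibration
(measured tail frequencies 4%/9%/45% at nominal 5%/10%/50% over 200 null
repeats); histograms keep the full per-focus convention. Cross-channel
comparisons simulate both channels so observed and null distributions
match. Group comparisons use two-sided two-sample t, paired t (pairing on
the nucleus) and Mann–Whitney U tests with the conventional p < 0.05
threshold and no multiple-testing correction — a deliberate caveat
mirroring standard practice in this literature.

## What the synthetic data does and does not emulate

The generators reproduce the statistical structure the chain assumes:
Gaussian localisation clusters with realistic counts, uniform background,
foci placed on curvilinear axes, and diffraction-blurred confocal foci
with shot noise. They do not emulate fluorophore photophysics (blinking,
multi-frame grouping), localisation-precision heterogeneity, drift or
channel misalignment, antibody linkage error, or non-Gaussian filament
shapes. Passing tests therefore validate the pipeline's correctness and
calibration on data obeying its assumptions, not robustness to every
artefact of real dSTORM acquisitions.

## Problem sizes

Defaults used by the shipped analyses: 200 foci per simulated dataset and
per grid cell (6×6 grid); 2000-localisation clusters for whole-nucleus
synthetic fixtures; 200 repeats for the CSR calibration check; 20
replicates for parameter recovery. All are arguments with these values as
defaults.

## Known limitations

* Morphology thresholds are calibrated proxies for visual classification.
* The far-DMC1 detectability knife-edge (above) means projection-loss
  percentages depend strongly on the assumed far-cluster width.
* The KDE is binned; positions inherit half-pixel quantisation.
* dSTORM analysis is strictly 2D; z is used only by the generative model.
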