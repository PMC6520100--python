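# Methods

This document records the analytical conventions implemented in
`boldfractal`, in pipeline order.

## Wavelet Hurst estimation (`boldfractal.fractal`)

Each voxel/series is decomposed with a **maximal-overlap discrete wavelet
transform (MODWT)** using the 8-tap Daubechies extremal-phase filter
(`db4` in PyWavelets naming — the "D(8)" of the wavelet-variance
literature) over 5 scales by default. The MODWT is computed by circular
convolution in the FFT domain: the level-j filters are the base filters
upsampled by 2^(j-1), so their DFT is a polynomial in
exp(-2 pi i k 2^(j-1) / n) evaluated at the filter taps.

The wavelet variance at scale j is the mean square of the **boundary-free**
detail coefficients (the first (2^j - 1)(L - 1) coefficients are affected by
circularity and are excluded), rescaled by 2^j so that white noise has a
flat variance-versus-scale profile. The requested depth is automatically
reduced (with a logged warning) when the series is too short to leave any
boundary-free coefficient at the deepest scale.

H is the ordinary-least-squares slope gamma of log2 wavelet variance on
scale index, mapped as **H = (gamma + 1) / 2**; the fractal dimension is
D = 2 - H. A flat spectrum (gamma = 0) is therefore exactly H = 0.5, the
white-noise reference. Voxels with H below 0.5 are flagged invalid in
`HurstMap.validity` (raw estimates are retained so thresholding can be
audited) and excluded from downstream means.

At realistic BOLD lengths the estimator's per-voxel standard deviation is
about 0.18 at 269 timepoints and scales as n^(-1/2) (about 0.13 at 512 and
0.09 at 1024).

## Synthetic data (`boldfractal.synthetic`)

**Fractional Gaussian noise** is generated exactly by Davies–Harte
circulant embedding: the closed-form fGn autocovariance out to lag n is
embedded in a circulant of size 2n whose FFT eigenvalues must be
non-negative (they are for all H in (0, 1); negativity beyond round-off
raises rather than silently truncating).

The **phantom** is a two-hemisphere grey-matter slab with white-matter
cores and a midline CSF gap; a spherical tumor is carved out of the right
hemisphere. Every brain voxel's BOLD series is exact fGn at its
ground-truth H. Ipsilateral grey matter follows an implanted
suppression-then-overshoot quadratic profile of the Euclidean distance to
the tumor margin; the contralateral hemisphere is uniformly at baseline.
Two design choices matter for validation studies:

- The implanted quadratic is evaluated at the **centre of the 2-mm annulus
  band** containing each voxel (piecewise-constant per band) rather than
  continuously. Band-averaging a continuous radial field yields band means
  that are systematically non-quadratic in band-centre distance, so profile
  recovery would otherwise test that averaging distortion rather than the
  pipeline; with the banded implant the ground truth in annulus-profile
  space is exactly the quadratic evaluated at band centres.
- The default profile stays at least 3 estimator standard deviations above
  the H = 0.5 validity threshold at the default series length, so threshold
  truncation cannot materially bias band means; lesion geometry is jittered
  per subject (centre +/- 2 mm, radius +/- 10%) to emulate anatomical
  variability.

## Peritumoral annuli (`boldfractal.lesion`)

Distances are measured with an **exact Euclidean distance transform in
world millimetres** (anisotropic voxels handled via the affine), the
standard operationalization of "distance beyond the tumor margin". The
peritumoral tissue is partitioned into disjoint 2-mm shells out to 30 mm
with the half-open convention (k-1)*step < d <= k*step, restricted to grey
matter. For each annulus the profile reports the ipsilateral mean H, the
mean over the **mirror-image (contralateral homologous) annulus** (voxels
reflected across the mid-sagittal plane), and their ratio; bands whose
voxels are all invalid yield NaN.

## Parcellation and connectomes (`boldfractal.parcellate`, `.connectome`)

Grey matter (plus tumor: an atlas does not know about the lesion, so
tumor-infiltrated parcels exist) is partitioned into parcels; parcels
overlapping the tumor by at least one voxel are removed, and each remaining
parcel is paired with its contralateral homologue by mutual-nearest
mirrored centroids. Node-to-tumor distance is centroid-to-tumor-centroid in
millimetres.

Connectivity between parcel mean time series supports Pearson correlation,
partial correlation via Ledoit–Wolf shrinkage covariance (stable when
parcels outnumber timepoints), and wavelet correlation (Pearson on MODWT
detail coefficients at a chosen scale, default scale 2). Negative weights
are clipped to zero so the matrices are non-negative, symmetric, and
zero-diagonal.

## Graph measures (`boldfractal.graph`)

Edges are converted to lengths as 1/weight for path-based measures.
Implemented measures: strength, nodal and global efficiency (mean inverse
shortest-path length), betweenness (unnormalized, Dijkstra), eigenvector
centrality (Perron vector of the weight matrix), participation coefficient
and within-module degree z-score against a seeded Louvain partition, and
**delta efficiency**: the percentage change in global efficiency after
synthetically lesioning a node. Two lesioning conventions are supported —
`reduced` (remove the node, recompute on the (n-1)-node graph; the default)
and `isolate` (zero the node's edges, keep it in the denominator).
Homologue ratios divide each node's measure by its paired contralateral
node's value. Per-node measures are correlated with parcel mean H with
Bonferroni correction over measures.

## Gradient statistics (`boldfractal.gradstats`)

Five families of value-on-distance models are fitted: linear, quadratic,
cubic, exponential b*exp(c*d), and exponential-with-intercept
a + b*exp(c*d). Polynomials use least squares; the exponentials use
variable projection (the model is linear in the amplitude/intercept for a
fixed rate, so those are profiled out in closed form and only the rate is
searched over a bounded grid with a 1-D polish), which is deterministic and
robust.

Model comparison uses **AIC = n ln(RSS/n) + 2(k+1)** (Gaussian
log-likelihood form, k coefficients plus the noise variance). The selected
family is the most parsimonious one within 2 AIC of the minimum: models
within ~2 AIC are conventionally regarded as equivalently supported, so an
extra parameter must buy a real improvement (a pure min-AIC rule would
prefer an overfitted nested model with asymptotic probability
P(chi2_1 > 2) = 0.157 even when the smaller model is true).

Cohort-level gradient fits operate on the **cohort-mean profile** (per-band
means over subjects, one observation per 2-mm band), so the AIC sample size
is the number of bands.

Group comparisons are implemented from the design-matrix / sums-of-squares
decompositions directly: one-way ANOVA for tissue-class H, and an ANCOVA
with a cohort-by-distance interaction term on log mean H, with pairwise
post-hoc slope contrasts Bonferroni-corrected over pairs. SciPy is used
only for F- and t-distribution tails.

## Pipeline (`boldfractal.pipeline`, CLI `boldfractal`)

`run_subject` chains the stages above for one subject (annulus stages are
skipped with a warning when no tumor mask is supplied); `run_cohort` runs
every subject, fits the per-cohort and combined cohort-mean profiles,
and produces the ANCOVA/ANOVA/correlation report. Every stage is
deterministic under the supplied seed, and results carry a 12-character
configuration hash for provenance. The `boldfractal` CLI exposes each stage
(`simulate`, `hurst`, `annuli`, `parcellate`, `connectome`, `metrics`,
`gradient`, `run-subject`, `run-cohort`) over NIfTI volumes and TSV tables.
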