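"""Synthetic inputs: exact fractional Gaussian noise, phantom BOLD cohorts
with an implanted distance-dependent Hurst gradient, and modular weighted
networks.

The phantom emulates the study situation the pipeline targets: a lateralized
tumor in otherwise bilaterally symmetric anatomy, with grey-matter signal
complexity (H) varying as a quadratic function of distance from the tumor
margin on the lesioned side — suppressed at the margin, overshooting the
contralateral baseline at intermediate distance — and constant at baseline
contralaterally.  Every voxel's time series is exact fGn at that voxel's H,
so the ground-truth H volume is a distribution-exact oracle for the
estimator and for the annulus/parcel gradient analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# tissue label codes used throughout the package
BACKGROUND, CSF, GREY_MATTER, WHITE_MATTER, TUMOR = 0, 1, 2, 3, 4

TISSUE_NAMES = {
    BACKGROUND: "background",
    CSF: "csf",
    GREY_MATTER: "grey_matter",
    WHITE_MATTER: "white_matter",
    TUMOR: "tumor",
}

# fixed H assigned to non-gradient tissue in the phantom
H_WHITE_MATTER = 0.65
H_CSF = 0.55
H_TUMOR = 0.30


@dataclass(frozen=True)
class FgnSpec:
    """Specification of a fractional Gaussian noise sequence."""

    hurst: float
    n_samples: int
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.hurst < 1.0:
            raise ValueError("hurst must lie in (0, 1)")
        if self.n_samples < 16:
            raise ValueError("n_samples must be >= 16")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def fgn_autocovariance(hurst: float, sigma: float, lags: np.ndarray) -> np.ndarray:
    """Closed-form fGn autocovariance
    ``rho(k) = sigma^2/2 (|k+1|^2H - 2|k|^2H + |k-1|^2H)``."""
    k = np.abs(np.asarray(lags, dtype=float))
    two_h = 2.0 * hurst
    return 0.5 * sigma**2 * ((k + 1) ** two_h - 2 * k**two_h + np.abs(k - 1) ** two_h)


def _fgn_batch(
    hurst: np.ndarray, n: int, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact fGn via circulant embedding (Davies-Harte), vectorized over a
    batch of per-series Hurst exponents.

    Embeds the autocovariance out to lag n in a circulant of size 2n whose
    eigenvalues (the FFT of the first row) must be non-negative; for the fGn
    autocovariance they are for all H in (0, 1).  A negativity beyond
    round-off raises rather than silently truncating.
    """
    hurst = np.atleast_1d(np.asarray(hurst, dtype=float))
    m = 2 * n
    lags = np.arange(n + 1)
    r = fgn_autocovariance(hurst[:, None], sigma, lags[None, :])  # (b, n+1)
    # circulant first row: r_0 .. r_n, r_{n-1} .. r_1
    row = np.concatenate([r, r[:, -2:0:-1]], axis=1)  # (b, 2n)
    lam = np.fft.fft(row, axis=1).real
    if np.any(lam < -1e-8 * sigma**2):
        raise ValueError(
            "circulant embedding produced negative eigenvalues; "
            "cannot synthesize exactly for this spec"
        )
    lam = np.clip(lam, 0.0, None)
    z = rng.standard_normal((hurst.size, m)) + 1j * rng.standard_normal((hurst.size, m))
    # Var(Re sum) halves the complex variance, hence lam/m (not lam/2m)
    seq = np.fft.fft(np.sqrt(lam / m) * z, axis=1)
    return seq.real[:, :n]


def simulate_fgn(spec: FgnSpec) -> np.ndarray:
    """Exact stationary fGn sequence with the closed-form autocovariance;
    bit-reproducible under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    return _fgn_batch(np.array([spec.hurst]), spec.n_samples, spec.sigma, rng)[0]


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of the phantom cohort.

    The H field on the tumor side is ``H(d) = a + b*d + c*d**2`` of the
    distance d (mm) from the tumor margin, clipped to (0.05, 0.95), reverting
    to ``h_baseline`` beyond ``gradient_extent_mm``; the contralateral
    hemisphere is uniformly at baseline.  Defaults implant a
    suppression-then-overshoot profile: H below baseline inside ~13 mm,
    above it from ~13 mm out to ~27 mm, crossing back toward baseline —
    the "functional penumbra" shape, at an amplitude chosen so annulus means
    separate cleanly from estimator noise at the default series length.
    The default tumor sits deep in the right hemisphere so that the whole
    30-mm annulus band stays ipsilateral: mirrored annuli then sample pure
    baseline tissue and the measured ratio profile is uncontaminated.

    ``n_timepoints`` and ``tr_s`` default to a 269-volume acquisition at
    TR = 2.42 s.
    """

    grid_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size_mm: float = 2.0
    n_timepoints: int = 269
    tr_s: float = 2.42
    tumor_center_mm: tuple[float, float, float] = (30.0, 14.0, 0.0)
    tumor_radius_mm: float = 4.5
    h_baseline: float = 0.88
    # quadratic with baseline crossings at 13 and 27 mm; the whole profile
    # stays >= 0.80, i.e. >= 3 estimator SDs above the 0.5 white-noise
    # threshold at the default series length, so threshold selection cannot
    # distort the band means
    h_quad_coeffs: tuple[float, float, float] = (0.7993, 0.0092, -0.00023)
    gradient_extent_mm: float = 30.0
    # the quadratic is evaluated at the centre of the annulus band containing
    # each voxel (piecewise-constant implant): the ground truth in annulus
    # band-mean space is then exactly the quadratic evaluated at the band
    # centres, so profile recovery tests the pipeline rather than the
    # band-averaging distortion of a continuous radial field.  Set to 0 for a
    # continuous (unquantized) implant.
    profile_step_mm: float = 2.0
    n_subjects: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.h_baseline < 1.0:
            raise ValueError("h_baseline must lie in (0, 1)")
        if self.tumor_radius_mm <= 0 or self.voxel_size_mm <= 0:
            raise ValueError("sizes must be positive")
        if self.n_subjects < 1 or self.n_timepoints < 32:
            raise ValueError("need >= 1 subject and >= 32 timepoints")

    def gradient_h(self, d: np.ndarray) -> np.ndarray:
        """Ground-truth H at distance d (mm) from the tumor margin,
        ipsilateral grey matter.

        With ``profile_step_mm`` > 0 the quadratic is evaluated at the
        centre of the band ``(k*step, (k+1)*step]`` containing d (matching
        the annulus convention of :func:`boldfractal.lesion.dilate_annuli`).
        """
        d = np.asarray(d, dtype=float)
        dq = d
        if self.profile_step_mm > 0:
            s = self.profile_step_mm
            dq = s * (np.ceil(d / s) - 0.5)
            dq = np.where(d <= 0, 0.0, dq)
        a, b, c = self.h_quad_coeffs
        h = np.where(
            d <= self.gradient_extent_mm,
            a + b * dq + c * dq**2,
            self.h_baseline,
        )
        return np.clip(h, 0.05, 0.95)


def phantom_affine(spec: PhantomSpec) -> np.ndarray:
    """RAS affine placing the mid-sagittal plane at world x = 0."""
    v = spec.voxel_size_mm
    aff = np.diag([v, v, v, 1.0])
    aff[:3, 3] = -v * (np.array(spec.grid_shape) - 1) / 2.0
    return aff


@dataclass
class PhantomSubject:
    """One phantom subject: BOLD data plus the generative ground truth."""

    bold: np.ndarray  # (x, y, z, t)
    tissue: np.ndarray  # integer labels (see module constants)
    tumor_mask: np.ndarray  # bool
    truth_h: np.ndarray  # per-voxel generative H (nan outside brain)
    affine: np.ndarray
    tr_s: float
    subject_id: str = "sub-00"


def _phantom_geometry(spec: PhantomSpec, subject_index: int = 0):
    """Tissue labels, tumor mask and world coordinate grids.

    Lesion geometry is jittered per subject (centre +/- 2 mm in y/z, radius
    +/- 10%) to emulate the anatomical variability of a real cohort; the
    implanted H profile itself is identical across subjects.
    """
    from scipy.ndimage import distance_transform_edt

    nx, ny, nz = spec.grid_shape
    aff = phantom_affine(spec)
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    xw = aff[0, 0] * ii + aff[0, 3]
    yw = aff[1, 1] * jj + aff[1, 3]
    zw = aff[2, 2] * kk + aff[2, 3]

    v = spec.voxel_size_mm
    half_extent = v * (nx - 1) / 2.0
    gap = max(v, 2.0)  # mid-sagittal CSF gap
    outer = min(half_extent - v, 18.0 * v)
    yz_half = min(v * (ny - 1) / 2.0 - 2 * v, v * (nz - 1) / 2.0 - 2 * v)

    slab = (np.abs(xw) >= gap) & (np.abs(xw) <= outer)
    slab &= (np.abs(yw) <= yz_half) & (np.abs(zw) <= yz_half)

    # small deep white-matter core per hemisphere; thick GM all round it
    core_x = (gap + outer) / 2.0
    wm = (
        (np.abs(np.abs(xw) - core_x) <= 2 * v)
        & (np.abs(yw) <= 3 * v)
        & (np.abs(zw) <= 3 * v)
    )

    tissue = np.full(spec.grid_shape, BACKGROUND, dtype=np.int16)
    tissue[np.abs(xw) < gap] = CSF
    tissue[slab] = GREY_MATTER
    tissue[slab & wm] = WHITE_MATTER

    jitter_rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, subject_index, 1])
    )
    cx, cy, cz = spec.tumor_center_mm
    cy += jitter_rng.uniform(-2.0, 2.0)
    cz += jitter_rng.uniform(-2.0, 2.0)
    radius = spec.tumor_radius_mm * jitter_rng.uniform(0.9, 1.1)
    if cx <= 0:
        raise ValueError("tumor_center_mm must lie in the right hemisphere (x > 0)")
    dist2 = (xw - cx) ** 2 + (yw - cy) ** 2 + (zw - cz) ** 2
    tumor = dist2 <= radius**2
    if not tumor.any():
        raise ValueError("tumor sphere contains no voxels at this resolution")
    if np.any(tumor & (xw <= 0)):
        raise ValueError("tumor sphere crosses the midline")
    if np.any(tumor & (tissue != GREY_MATTER)):
        raise ValueError("tumor sphere not fully inside right-hemisphere grey matter")
    tissue[tumor] = TUMOR

    # distance (mm) from the tumor margin, exact EDT in world units
    dist_mm = distance_transform_edt(~tumor, sampling=(v, v, v))
    return tissue, tumor, dist_mm, xw, aff


def _phantom_truth(spec: PhantomSpec, subject_index: int = 0):
    tissue, tumor, dist_mm, xw, aff = _phantom_geometry(spec, subject_index)
    truth = np.full(spec.grid_shape, np.nan)
    gm = tissue == GREY_MATTER
    ipsi = gm & (xw > 0)
    contra = gm & (xw < 0)
    truth[ipsi] = spec.gradient_h(dist_mm[ipsi])
    truth[contra] = spec.h_baseline
    truth[tissue == WHITE_MATTER] = H_WHITE_MATTER
    truth[tissue == CSF] = H_CSF
    truth[tumor] = H_TUMOR
    return tissue, tumor, truth, aff


def simulate_phantom_subject(spec: PhantomSpec, subject_index: int = 0) -> PhantomSubject:
    """Generate one phantom subject; the time series of every brain voxel is
    exact fGn at that voxel's ground-truth H."""
    tissue, tumor, truth, aff = _phantom_truth(spec, subject_index)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_index]))
    brain = np.isfinite(truth)
    bold = np.zeros(spec.grid_shape + (spec.n_timepoints,))
    h_vox = truth[brain]
    # batch the circulant synthesis in chunks to bound memory
    series = np.empty((h_vox.size, spec.n_timepoints))
    chunk = 4096
    for start in range(0, h_vox.size, chunk):
        series[start : start + chunk] = _fgn_batch(
            h_vox[start : start + chunk], spec.n_timepoints, 1.0, rng
        )
    bold[brain] = series
    return PhantomSubject(
        bold=bold,
        tissue=tissue,
        tumor_mask=tumor,
        truth_h=truth,
        affine=aff,
        tr_s=spec.tr_s,
        subject_id=f"sub-{subject_index:02d}",
    )


def simulate_phantom_cohort(spec: PhantomSpec) -> list[PhantomSubject]:
    """Generate ``spec.n_subjects`` phantom subjects sharing the implanted
    gradient law, with per-subject lesion-geometry jitter and independent
    noise realizations."""
    return [simulate_phantom_subject(spec, i) for i in range(spec.n_subjects)]


@dataclass(frozen=True)
class ModularNetSpec:
    """Specification of a weighted modular random network."""

    n_nodes: int = 40
    n_modules: int = 4
    p_within_weight: float = 1.0
    p_between_weight: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 2 or self.n_modules < 1:
            raise ValueError("need >= 2 nodes and >= 1 module")
        if self.p_within_weight < 0 or self.p_between_weight < 0:
            raise ValueError("weights must be non-negative")
        if self.p_within_weight <= self.p_between_weight:
            raise ValueError("within-module mean weight must exceed between-module")


def simulate_modular_network(spec: ModularNetSpec) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric non-negative weighted adjacency with a known module
    partition; returns (weights, module_labels)."""
    rng = np.random.default_rng(spec.seed)
    labels = np.arange(spec.n_nodes) % spec.n_modules
    rng.shuffle(labels)
    same = labels[:, None] == labels[None, :]
    mean_w = np.where(same, spec.p_within_weight, spec.p_between_weight)
    w = rng.exponential(1.0, size=(spec.n_nodes, spec.n_nodes)) * mean_w
    w = np.triu(w, 1)
    w = w + w.T
    return w, labels
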