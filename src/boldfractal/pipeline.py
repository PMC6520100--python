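"""Per-subject and per-cohort orchestration of the full analysis.

A subject contributes a voxelwise Hurst map, a peritumoral annulus ratio
profile, parcel mean-H values, one or more weighted connectomes, and node
metric tables with homologue ratios and tumor distances.  A cohort report
pools annulus (and optionally parcel) observations per cohort and fits the
five distance-gradient families with AIC selection, tests cohort-by-distance
interaction on log H (ANCOVA), compares tissue-class H (ANOVA), and
correlates node H with every network measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import connectome as cn
from . import fractal, gradstats, graph, lesion, parcellate
from .io import config_hash
from .synthetic import CSF, GREY_MATTER, PhantomSubject, TUMOR, WHITE_MATTER

logger = logging.getLogger(__name__)


@dataclass
class SubjectInput:
    """Co-registered single-subject inputs on one voxel grid.

    Preprocessing (denoising, registration, segmentation) is upstream: the
    pipeline consumes a 4-D BOLD array, an integer tissue segmentation
    (codes as in :mod:`boldfractal.synthetic`), an optional binary tumor
    mask, and the shared affine.
    """

    bold: np.ndarray
    tissue: np.ndarray
    affine: np.ndarray
    tr_s: float
    tumor_mask: np.ndarray | None = None
    subject_id: str = "sub-00"

    @classmethod
    def from_phantom(cls, subject: PhantomSubject) -> "SubjectInput":
        return cls(
            bold=subject.bold,
            tissue=subject.tissue,
            affine=subject.affine,
            tr_s=subject.tr_s,
            tumor_mask=subject.tumor_mask,
            subject_id=subject.subject_id,
        )


@dataclass
class SubjectResult:
    subject_id: str
    config_hash: str
    hurst: fractal.HurstMap
    tissue_means: dict[str, float]
    profile: pd.DataFrame | None = None
    parcellation: parcellate.Parcellation | None = None
    parcel_values: pd.DataFrame | None = None
    connectomes: dict[str, cn.ConnectomeMatrix] = field(default_factory=dict)
    metrics: dict[str, pd.DataFrame] = field(default_factory=dict)


_TISSUE_CLASSES = {
    "grey_matter": GREY_MATTER,
    "white_matter": WHITE_MATTER,
    "csf": CSF,
    "tumor": TUMOR,
}


def run_subject(
    subject: SubjectInput,
    wavelet: str = fractal.DEFAULT_WAVELET,
    n_levels: int = fractal.DEFAULT_N_LEVELS,
    threshold: float = fractal.DEFAULT_THRESHOLD,
    step_mm: float = 2.0,
    max_mm: float = 30.0,
    network: bool = True,
    n_parcels: int = 256,
    connectivity_methods: tuple[str, ...] = ("pearson",),
    lesion_convention: str = "reduced",
    seed: int = 0,
) -> SubjectResult:
    """Run every analysis stage for one subject.

    Without a tumor mask the annulus and tumor-distance stages are skipped
    with a logged warning; fractal and network stages still run.  All stages
    are deterministic under the supplied seed.
    """
    settings = {
        "wavelet": wavelet, "n_levels": n_levels, "threshold": threshold,
        "step_mm": step_mm, "max_mm": max_mm, "network": network,
        "n_parcels": n_parcels, "connectivity_methods": connectivity_methods,
        "lesion_convention": lesion_convention, "seed": seed,
    }
    chash = config_hash(settings)
    brain = subject.tissue > 0
    logger.info("[%s] %d brain voxels", subject.subject_id, int(brain.sum()))

    hmap = fractal.hurst_map(
        subject.bold, brain, wavelet=wavelet, n_levels=n_levels, threshold=threshold
    )
    logger.info(
        "[%s] %d voxels survive the H >= %.2f threshold",
        subject.subject_id, int(hmap.validity.sum()), threshold,
    )

    tissue_means = {}
    for name, code in _TISSUE_CLASSES.items():
        sel = (subject.tissue == code) & hmap.validity
        tissue_means[name] = float(hmap.values[sel].mean()) if sel.any() else np.nan

    result = SubjectResult(
        subject_id=subject.subject_id,
        config_hash=chash,
        hurst=hmap,
        tissue_means=tissue_means,
    )

    gm = subject.tissue == GREY_MATTER
    if subject.tumor_mask is not None and np.asarray(subject.tumor_mask).any():
        annuli = lesion.dilate_annuli(subject.tumor_mask, subject.affine, step_mm, max_mm)
        annuli = lesion.restrict_to_gm(annuli, gm)
        result.profile = lesion.gradient_profile(
            hmap, annuli, subject.affine, tumor=subject.tumor_mask
        )
    else:
        logger.warning(
            "[%s] no tumor mask: annulus and tumor-distance stages skipped",
            subject.subject_id,
        )

    if network:
        # parcellate grey matter plus tumor: an atlas does not know about the
        # lesion, so tumor-infiltrated parcels exist and are then removed
        parcel_mask = gm | (subject.tissue == TUMOR)
        parc = parcellate.random_parcellation(
            parcel_mask, n_parcels, seed=seed, affine=subject.affine
        )
        parc = parcellate.pair_homologues(parc, subject.affine)
        if subject.tumor_mask is not None and np.asarray(subject.tumor_mask).any():
            parc = parcellate.remove_tumor_parcels(parc, subject.tumor_mask)
            parc = parcellate.node_tumor_distance(parc, subject.tumor_mask)
            logger.info(
                "[%s] %d/%d parcels kept after tumor-overlap removal",
                subject.subject_id, parc.table["kept"].sum(), len(parc.table),
            )
        result.parcellation = parc
        result.parcel_values = parcellate.parcel_means(hmap, parc)

        ts = cn.extract_timeseries(subject.bold, parc, tr_s=subject.tr_s)
        for method in connectivity_methods:
            W = cn.connectivity(ts, method=method)
            result.connectomes[method] = W
            metrics = graph.node_centralities(
                W.weights,
                parcel_ids=W.parcel_ids,
                lesion_convention=lesion_convention,
                partition_seed=seed,
            )
            metrics = graph.homologue_ratio(metrics, parc)
            metrics.attrs["config_hash"] = chash
            result.metrics[method] = metrics
    return result


@dataclass
class CohortReport:
    config_hash: str
    gradient_fits: dict[str, pd.DataFrame]
    best_family: dict[str, str]
    ancova: gradstats.AncovaResult | None
    tissue_anova: tuple[float, float] | None
    correlations: pd.DataFrame | None
    subject_results: list[SubjectResult] = field(default_factory=list)


def run_cohort(
    subjects: list[SubjectInput],
    cohort_labels: list[str],
    seed: int = 0,
    **subject_kwargs,
) -> CohortReport:
    """Run every subject, then fit the per-cohort (and combined) mean
    annulus-ratio profile — per-subject band values averaged at each
    distance, one observation per 2-mm band — with the five gradient
    families, plus ANCOVA across cohorts on log mean H, tissue ANOVA, and
    metric-H correlations.

    With a single cohort the ANCOVA is skipped with a warning.
    """
    if len(subjects) != len(cohort_labels):
        raise ValueError("one cohort label per subject required")
    results = [
        run_subject(s, seed=seed + i, **subject_kwargs)
        for i, s in enumerate(subjects)
    ]
    chash = config_hash({"seed": seed, **{k: str(v) for k, v in subject_kwargs.items()}})

    labels = np.asarray(cohort_labels)
    pooled: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    dist_all, ratio_all, meanh_all, cohort_all = [], [], [], []
    for res, lab in zip(results, labels):
        if res.profile is None:
            continue
        prof = res.profile.dropna(subset=["ratio"])
        dist_all.append(prof["distance_mm"].to_numpy())
        ratio_all.append(prof["ratio"].to_numpy())
        meanh_all.append(prof["mean_h_ipsi"].to_numpy())
        cohort_all.append(np.repeat(lab, len(prof)))

    gradient_fits: dict[str, pd.DataFrame] = {}
    best_family: dict[str, str] = {}
    if dist_all:
        dist = np.concatenate(dist_all)
        ratio = np.concatenate(ratio_all)
        meanh = np.concatenate(meanh_all)
        cohort = np.concatenate(cohort_all)
        for name in list(np.unique(labels)) + ["complete"]:
            sel = np.ones(dist.size, bool) if name == "complete" else cohort == name
            # fit the cohort-mean profile: average the per-subject band values
            # at each distance, one observation per 2-mm band
            banded = (
                pd.DataFrame({"distance_mm": dist[sel], "ratio": ratio[sel]})
                .groupby("distance_mm", as_index=False)["ratio"]
                .mean()
            )
            if len(banded) < 6:
                logger.warning("cohort %s: too few annulus bands to fit", name)
                continue
            fits = gradstats.fit_gradient_models(
                banded["distance_mm"].to_numpy(), banded["ratio"].to_numpy(), seed=seed
            )
            gradient_fits[name] = gradstats.fits_table(fits)
            best_family[name] = gradstats.select_best(fits).family

        ancova = None
        if np.unique(cohort).size >= 2:
            ok = meanh > 0
            ancova = gradstats.cohort_ancova(np.log(meanh[ok]), dist[ok], cohort[ok])
        else:
            logger.warning("single cohort: ANCOVA skipped")
    else:
        ancova = None
        logger.warning("no annulus profiles available: gradient stage empty")

    tissue_groups: dict[str, list[float]] = {"grey_matter": [], "white_matter": []}
    for res in results:
        for name in tissue_groups:
            v = res.tissue_means.get(name, np.nan)
            if np.isfinite(v):
                tissue_groups[name].append(v)
    anova = None
    if all(len(v) >= 2 for v in tissue_groups.values()):
        anova = gradstats.tissue_anova({k: np.asarray(v) for k, v in tissue_groups.items()})

    correlations = None
    method = subject_kwargs.get("connectivity_methods", ("pearson",))[0]
    per_node_h, per_node_metrics = [], []
    for res in results:
        if res.parcel_values is None or method not in res.metrics:
            continue
        merged = res.metrics[method].merge(
            res.parcel_values.rename(columns={"value": "h"}), on="id"
        )
        per_node_h.append(merged["h"].to_numpy())
        per_node_metrics.append(merged)
    if per_node_h:
        merged_all = pd.concat(per_node_metrics, ignore_index=True)
        h_all = np.concatenate(per_node_h)
        correlations = gradstats.metric_hurst_correlations(
            h_all, merged_all, columns=graph.BASE_METRICS
        )

    return CohortReport(
        config_hash=chash,
        gradient_fits=gradient_fits,
        best_family=best_family,
        ancova=ancova,
        tissue_anova=anova,
        correlations=correlations,
        subject_results=results,
    )
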