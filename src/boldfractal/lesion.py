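"""Peritumoral annulus construction, mid-sagittal mirroring, and the
homologous-H gradient profile.

The tumor mask is dilated outward in fixed metric increments (default 2 mm,
to 30 mm) and each dilation minus its predecessor yields a 2-mm-thick
annulus.  Annuli are restricted to cortical grey matter, reflected across
the interhemispheric fissure (world x = 0), and the mean valid Hurst
exponent in each annulus is expressed as a ratio over its mirror — the
distance profile in which a peritumoral "penumbra" of suppressed complexity
appears as ratios below 1 near the margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .fractal import HurstMap


def _voxel_sizes(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


@dataclass
class AnnulusSeries:
    """Ordered disjoint distance shells around a tumor mask.

    ``annuli[k]`` holds the voxels whose Euclidean distance (mm) to the
    nearest tumor voxel lies in ``(inner_edges_mm[k], inner_edges_mm[k] + step_mm]``.
    """

    annuli: list[np.ndarray]
    inner_edges_mm: np.ndarray
    step_mm: float
    max_mm: float

    def __len__(self) -> int:
        return len(self.annuli)

    @property
    def midpoints_mm(self) -> np.ndarray:
        return self.inner_edges_mm + self.step_mm / 2.0


def dilate_annuli(
    tumor: np.ndarray,
    affine: np.ndarray,
    step_mm: float = 2.0,
    max_mm: float = 30.0,
) -> AnnulusSeries:
    """Partition the <= ``max_mm`` band around the tumor into metric shells.

    Distances are computed with an exact Euclidean distance transform in
    world millimetres (``sampling`` = voxel sizes), so anisotropic voxels are
    handled; band membership uses the half-open convention
    ``(k-1)*step < d <= k*step``.
    """
    tumor = np.asarray(tumor, dtype=bool)
    if not tumor.any():
        raise ValueError("empty tumor mask")
    if step_mm <= 0 or max_mm <= 0 or max_mm < step_mm:
        raise ValueError("need 0 < step_mm <= max_mm")
    dist = distance_transform_edt(~tumor, sampling=tuple(_voxel_sizes(affine)))
    n_bands = int(np.ceil(max_mm / step_mm))
    edges = np.arange(n_bands) * step_mm
    annuli = [
        (dist > lo) & (dist <= min(lo + step_mm, max_mm)) for lo in edges
    ]
    return AnnulusSeries(annuli=annuli, inner_edges_mm=edges, step_mm=step_mm, max_mm=max_mm)


def restrict_to_gm(annuli: AnnulusSeries, gm: np.ndarray) -> AnnulusSeries:
    """Intersect every annulus with the grey-matter mask (empty annuli are
    retained so band indexing is stable)."""
    gm = np.asarray(gm, dtype=bool)
    return AnnulusSeries(
        annuli=[a & gm for a in annuli.annuli],
        inner_edges_mm=annuli.inner_edges_mm,
        step_mm=annuli.step_mm,
        max_mm=annuli.max_mm,
    )


def mirror_mask(mask: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Reflect a binary mask across the mid-sagittal plane (world x = 0).

    Each set voxel maps to the voxel nearest world coordinate (-x, y, z); on
    a grid symmetric about x = 0 the operation is an exact involution.
    """
    if affine is None:
        raise ValueError("affine required for mirroring")
    mask = np.asarray(mask, dtype=bool)
    inv = np.linalg.inv(affine)
    idx = np.argwhere(mask)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    world[:, 0] *= -1.0
    mirrored_idx = np.rint((world - affine[:3, 3]) @ inv[:3, :3].T).astype(int)
    out = np.zeros_like(mask)
    inside = np.all((mirrored_idx >= 0) & (mirrored_idx < mask.shape), axis=1)
    mi = mirrored_idx[inside]
    out[mi[:, 0], mi[:, 1], mi[:, 2]] = True
    return out


def gradient_profile(
    hmap: HurstMap,
    annuli: AnnulusSeries,
    affine: np.ndarray,
    tumor: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean valid H per annulus and per mirrored annulus, and their ratio.

    Returns a table with one row per band: ``distance_mm`` (band midpoint),
    ``mean_h_ipsi``, ``mean_h_contra``, ``ratio``, ``n_voxels`` (valid
    ipsilateral voxels).  Bands empty on either side yield NaN, never an
    exception.  A tumor mask overlapping its own mirror (midline lesion)
    raises, since homologue ratios are then ill-defined.
    """
    if tumor is not None:
        tumor = np.asarray(tumor, dtype=bool)
        if (tumor & mirror_mask(tumor, affine)).any():
            raise ValueError("tumor mask overlaps its own mirror; midline tumors unsupported")
    rows = []
    valid = hmap.validity
    for mid, annulus in zip(annuli.midpoints_mm, annuli.annuli):
        ipsi_sel = annulus & valid
        contra_sel = mirror_mask(annulus, affine) & valid
        mean_ipsi = float(hmap.values[ipsi_sel].mean()) if ipsi_sel.any() else np.nan
        mean_contra = float(hmap.values[contra_sel].mean()) if contra_sel.any() else np.nan
        ratio = (
            mean_ipsi / mean_contra
            if np.isfinite(mean_ipsi) and np.isfinite(mean_contra) and mean_contra != 0
            else np.nan
        )
        rows.append(
            {
                "distance_mm": float(mid),
                "mean_h_ipsi": mean_ipsi,
                "mean_h_contra": mean_contra,
                "ratio": ratio,
                "n_voxels": int(ipsi_sel.sum()),
            }
        )
    return pd.DataFrame(rows)
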