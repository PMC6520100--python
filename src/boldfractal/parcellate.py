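"""Grey-matter parcellations: randomized equal-size templates, per-parcel
value extraction, tumor-overlap removal, homologue pairing and node-tumor
distances.

Randomized templates are built by seeded region growing: seeds are placed by
farthest-point sampling over the grey-matter voxels and parcels grow one
voxel at a time, always extending the currently smallest parcel, which keeps
sizes near-equal and every parcel face-connected.  A bilateral
"anatomical-like" template is obtained by growing one hemisphere and
mirroring the labels, giving exact homologue pairs on symmetric grids.
User-supplied integer-label volumes are accepted anywhere a generated
template is.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fractal import HurstMap
from .lesion import _voxel_sizes

_NEIGHBORS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


@dataclass
class Parcellation:
    """Integer-labelled volume (0 = background) plus the per-parcel table.

    Table columns: ``id, x_mm, y_mm, z_mm, size, hemisphere, homologue_id,
    kept, tumor_distance_mm``.  Removal (e.g. tumor overlap) flips ``kept``
    rather than renumbering, so ids are stable across pipeline stages.
    """

    labels: np.ndarray
    affine: np.ndarray
    table: pd.DataFrame

    def kept_ids(self) -> np.ndarray:
        return self.table.loc[self.table["kept"], "id"].to_numpy()


def _centroids_mm(labels: np.ndarray, ids: np.ndarray, affine: np.ndarray) -> np.ndarray:
    cents = np.empty((ids.size, 3))
    for row, pid in enumerate(ids):
        idx = np.argwhere(labels == pid)
        cents[row] = idx.mean(axis=0) @ affine[:3, :3].T + affine[:3, 3]
    return cents


def _build_table(labels: np.ndarray, affine: np.ndarray) -> pd.DataFrame:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    cents = _centroids_mm(labels, ids, affine)
    sizes = np.array([(labels == pid).sum() for pid in ids])
    hemi = np.where(cents[:, 0] < 0, "L", np.where(cents[:, 0] > 0, "R", "M"))
    return pd.DataFrame(
        {
            "id": ids,
            "x_mm": cents[:, 0],
            "y_mm": cents[:, 1],
            "z_mm": cents[:, 2],
            "size": sizes,
            "hemisphere": hemi,
            "homologue_id": -1,
            "kept": True,
            "tumor_distance_mm": np.nan,
        }
    )


def from_labels(labels: np.ndarray, affine: np.ndarray) -> Parcellation:
    """Wrap a user-supplied integer-label volume (0 = background)."""
    labels = np.asarray(labels)
    return Parcellation(labels=labels, affine=affine, table=_build_table(labels, affine))


def _farthest_point_seeds(
    coords: np.ndarray, n_seeds: int, rng: np.random.Generator
) -> np.ndarray:
    """Greedy farthest-point sampling (first seed random)."""
    chosen = np.empty(n_seeds, dtype=int)
    chosen[0] = rng.integers(coords.shape[0])
    mind = np.sum((coords - coords[chosen[0]]) ** 2, axis=1)
    for s in range(1, n_seeds):
        chosen[s] = int(np.argmax(mind))
        mind = np.minimum(mind, np.sum((coords - coords[chosen[s]]) ** 2, axis=1))
    return chosen


def _grow_labels(
    gm: np.ndarray, seed_idx: np.ndarray, seed_ids: np.ndarray
) -> np.ndarray:
    """Balanced region growing: repeatedly extend the smallest live parcel
    by one face-adjacent grey-matter voxel (breadth-first within a parcel,
    which keeps parcels compact)."""
    labels = np.zeros(gm.shape, dtype=np.int32)
    nx, ny, nz = gm.shape
    offsets = [tuple(o) for o in _NEIGHBORS]
    frontiers: dict[int, list[tuple[int, int, int]]] = {}
    heads: dict[int, int] = {}
    sizes: dict[int, int] = {}
    counter = 0
    heap: list[tuple[int, int, int]] = []

    def push(pid):
        nonlocal counter
        heapq.heappush(heap, (sizes[pid], counter, pid))
        counter += 1

    for vox, pid in zip(seed_idx, seed_ids):
        pid = int(pid)
        labels[tuple(vox)] = pid
        frontiers[pid] = [tuple(int(v) for v in vox)]
        heads[pid] = 0
        sizes[pid] = 1
        push(pid)

    while heap:
        _, _, pid = heapq.heappop(heap)
        frontier = frontiers[pid]
        head = heads[pid]
        grew = False
        while head < len(frontier) and not grew:
            bx, by, bz = frontier[head]
            for dx, dy, dz in offsets:
                cx, cy, cz = bx + dx, by + dy, bz + dz
                if 0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz:
                    if gm[cx, cy, cz] and labels[cx, cy, cz] == 0:
                        labels[cx, cy, cz] = pid
                        frontier.append((cx, cy, cz))
                        sizes[pid] += 1
                        grew = True
                        break
            else:
                head += 1  # this frontier voxel is saturated
        heads[pid] = head
        if grew:
            push(pid)
    return labels


def random_parcellation(
    gm: np.ndarray,
    n_parcels: int,
    seed: int = 0,
    affine: np.ndarray | None = None,
) -> Parcellation:
    """Space-filling partition of grey matter into ``n_parcels`` connected,
    near-equal-size parcels; deterministic under a fixed seed.

    Raises when the target is unreachable (seeds cannot cover disconnected
    grey matter), naming the achievable count.
    """
    gm = np.asarray(gm, dtype=bool)
    if affine is None:
        affine = np.eye(4)
    n_gm = int(gm.sum())
    if n_gm == 0:
        raise ValueError("empty grey-matter mask")
    if n_parcels > n_gm:
        raise ValueError(f"cannot form {n_parcels} parcels from {n_gm} voxels")
    rng = np.random.default_rng(seed)
    coords = np.argwhere(gm)
    seeds = coords[_farthest_point_seeds(coords.astype(float), n_parcels, rng)]
    labels = _grow_labels(gm, seeds, np.arange(1, n_parcels + 1))
    uncovered = gm & (labels == 0)
    if uncovered.any():
        # voxels in components containing no seed
        from scipy.ndimage import label as cc_label

        n_comp = cc_label(gm)[1]
        raise ValueError(
            f"grey matter has {n_comp} disconnected components unreachable from "
            f"the {n_parcels} seeds; achievable parcel count may be as low as "
            f"{n_parcels - int(uncovered.sum())}"
        )
    return from_labels(labels, affine)


def bilateral_parcellation(
    gm: np.ndarray,
    affine: np.ndarray,
    n_parcels: int,
    seed: int = 0,
) -> Parcellation:
    """Bilateral template: grow ``n_parcels // 2`` parcels on the left
    hemisphere and mirror the labels to the right (ids offset by
    ``n_parcels // 2``), giving exact mirror homologues on symmetric grids.
    """
    if n_parcels % 2:
        raise ValueError("bilateral template needs an even parcel count")
    gm = np.asarray(gm, dtype=bool)
    half = n_parcels // 2
    nx = gm.shape[0]
    ii = np.arange(nx)
    xw = affine[0, 0] * ii + affine[0, 3]
    left_cols = xw < 0
    left_gm = gm & left_cols[:, None, None]
    left = random_parcellation(left_gm, half, seed=seed, affine=affine)
    labels = left.labels.copy()
    # mirror: voxel i <-> voxel with world -x
    mirror_i = np.rint((-xw - affine[0, 3]) / affine[0, 0]).astype(int)
    valid = (mirror_i >= 0) & (mirror_i < nx)
    right = np.zeros_like(labels)
    right[mirror_i[valid]] = labels[ii[valid]]
    right[~gm] = 0
    labels = np.where(labels > 0, labels, np.where(right > 0, right + half, 0))
    parc = from_labels(labels, affine)
    return pair_homologues(parc, affine)


def parcel_means(hmap: HurstMap, parc: Parcellation) -> pd.DataFrame:
    """Mean valid H per kept parcel; parcels with zero valid voxels yield
    NaN with ``n_valid_voxels = 0``."""
    if hmap.values.shape != parc.labels.shape:
        raise ValueError("grids do not match")
    rows = []
    for pid in parc.kept_ids():
        sel = (parc.labels == pid) & hmap.validity
        n = int(sel.sum())
        rows.append(
            {
                "id": int(pid),
                "value": float(hmap.values[sel].mean()) if n else np.nan,
                "n_valid_voxels": n,
            }
        )
    return pd.DataFrame(rows)


def remove_tumor_parcels(parc: Parcellation, tumor: np.ndarray) -> Parcellation:
    """Mark parcels overlapping the tumor mask (>= 1 voxel) as removed;
    homologues of removed parcels remain kept."""
    tumor = np.asarray(tumor, dtype=bool)
    if tumor.shape != parc.labels.shape:
        raise ValueError("grids do not match")
    overlapping = set(np.unique(parc.labels[tumor])) - {0}
    table = parc.table.copy()
    table.loc[table["id"].isin(overlapping), "kept"] = False
    return Parcellation(labels=parc.labels, affine=parc.affine, table=table)


def pair_homologues(parc: Parcellation, affine: np.ndarray | None = None) -> Parcellation:
    """Pair each parcel with the contralateral parcel whose centroid is
    nearest its mirrored centroid, keeping only mutual-nearest pairs;
    unpaired parcels get ``homologue_id = -1``."""
    table = parc.table.copy()
    cents = table[["x_mm", "y_mm", "z_mm"]].to_numpy()
    ids = table["id"].to_numpy()
    left = cents[:, 0] < 0
    right = cents[:, 0] > 0
    mirrored = cents * np.array([-1.0, 1.0, 1.0])

    nearest = np.full(ids.size, -1, dtype=int)
    for side, other in ((left, right), (right, left)):
        if not side.any() or not other.any():
            continue
        d = np.linalg.norm(mirrored[side][:, None, :] - cents[other][None, :, :], axis=2)
        nearest[np.flatnonzero(side)] = np.flatnonzero(other)[np.argmin(d, axis=1)]

    homologue = np.full(ids.size, -1, dtype=int)
    for i, j in enumerate(nearest):
        if j >= 0 and nearest[j] == i:
            homologue[i] = ids[j]
    table["homologue_id"] = homologue
    return Parcellation(labels=parc.labels, affine=parc.affine, table=table)


def node_tumor_distance(parc: Parcellation, tumor: np.ndarray) -> Parcellation:
    """Euclidean distance (mm) from each parcel centroid to the tumor
    centroid (centre-of-node to centre-of-tumor convention)."""
    tumor = np.asarray(tumor, dtype=bool)
    if not tumor.any():
        raise ValueError("empty tumor mask")
    aff = parc.affine
    tumor_cent = np.argwhere(tumor).mean(axis=0) @ aff[:3, :3].T + aff[:3, 3]
    table = parc.table.copy()
    cents = table[["x_mm", "y_mm", "z_mm"]].to_numpy()
    table["tumor_distance_mm"] = np.linalg.norm(cents - tumor_cent, axis=1)
    return Parcellation(labels=parc.labels, affine=parc.affine, table=table)
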