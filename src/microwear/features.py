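"""Watershed motif segmentation and the six ISO feature parameters.

A surface is segmented into *hills* (watershed catchments of the inverted
surface, one per significant local maximum) and *dales* (catchments of the
surface itself, one per significant local minimum), with 8-connectivity.
Insignificant motifs are removed by Wolf pruning: a peak (pit) whose height
difference to its connecting saddle is below ``prune_fraction`` of the
surface's total height range does not seed its own motif. Pruning is
realised through h-extrema reconstruction, which suppresses exactly the
maxima/minima whose dynamic (peak-to-saddle height) falls below the
threshold.

The six feature parameters:

* Spd — density of surviving peaks (1/µm²)
* Spc — arithmetic mean peak curvature (1/µm)
* Sha / Sda — mean area of closed hills / dales (µm²)
* Shv / Sdv — mean hill volume above the bounding saddle / dale volume
  below it (µm³)

A motif counts as *closed* when its catchment does not touch the window
border; a motif spanning the entire evaluation area is closed by
convention, since it has no neighbour to pour into.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology
from skimage.measure import label as sk_label
from skimage.segmentation import watershed

from microwear.io import HeightMap
from microwear.iso25178 import AnalysisConfig

__all__ = [
    "MotifSegmentation",
    "segment_motifs",
    "spd",
    "spc",
    "motif_area_volume",
    "feature_params",
]


@dataclass
class MotifSegmentation:
    """Hills and dales of one surface with their summits and saddles.

    Labels are 1-based; 0 marks unassigned (invalid) pixels. ``peaks`` and
    ``pits`` map motif label → (row, col, height). ``hill_saddles`` /
    ``dale_saddles`` give each motif's bounding (pour-over) saddle height.
    """

    hill_labels: np.ndarray
    dale_labels: np.ndarray
    peaks: dict[int, tuple[int, int, float]]
    pits: dict[int, tuple[int, int, float]]
    hill_saddles: dict[int, float]
    dale_saddles: dict[int, float]
    closed_hill_flags: dict[int, bool]
    closed_dale_flags: dict[int, bool]
    prune_threshold_um: float
    dx: float = 1.0
    dy: float = 1.0

    @property
    def n_hills(self) -> int:
        return len(self.peaks)

    @property
    def n_dales(self) -> int:
        return len(self.pits)


_OFFSETS = [(0, 1), (1, 0), (1, 1), (1, -1)]  # 8-connectivity pair directions


def _saddle_heights(labels: np.ndarray, z: np.ndarray, invert: bool) -> dict[int, float]:
    """Bounding saddle per motif: the best pour-over height to a neighbour.

    For hills (``invert=False``) the saddle between two catchments is the
    highest of the pairwise minima along their shared boundary, and a
    motif's bounding saddle is the highest such saddle over its neighbours.
    For dales the surface is negated so the same logic applies.
    """
    zz = -z if invert else z
    best: dict[int, float] = {}
    nrow, ncol = labels.shape
    for dj, di in _OFFSETS:
        j0a, j1a = max(0, -dj), nrow - max(0, dj)
        i0a, i1a = max(0, -di), ncol - max(0, di)
        a_lab = labels[j0a:j1a, i0a:i1a]
        b_lab = labels[j0a + dj : j1a + dj, i0a + di : i1a + di]
        a_z = zz[j0a:j1a, i0a:i1a]
        b_z = zz[j0a + dj : j1a + dj, i0a + di : i1a + di]
        diff = (a_lab != b_lab) & (a_lab > 0) & (b_lab > 0)
        if not diff.any():
            continue
        pair_min = np.minimum(a_z[diff], b_z[diff])
        for lab, h in zip(np.concatenate([a_lab[diff], b_lab[diff]]), np.concatenate([pair_min, pair_min])):
            lab = int(lab)
            if h > best.get(lab, -np.inf):
                best[lab] = float(h)
    out: dict[int, float] = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        lab = int(lab)
        if lab in best:
            h = best[lab]
        else:
            # single motif: pour-over leaves through the lowest border point
            border = np.zeros(labels.shape, dtype=bool)
            border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
            sel = border & (labels == lab)
            h = float(zz[sel].min()) if sel.any() else float(zz[labels == lab].min())
        out[lab] = -h if invert else h
    return out


def _extrema(labels: np.ndarray, z: np.ndarray, maximum: bool) -> dict[int, tuple[int, int, float]]:
    out: dict[int, tuple[int, int, float]] = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        jj, ii = np.nonzero(labels == lab)
        vals = z[jj, ii]
        k = int(np.argmax(vals) if maximum else np.argmin(vals))
        out[int(lab)] = (int(jj[k]), int(ii[k]), float(vals[k]))
    return out


def _closed_flags(labels: np.ndarray, saddles: dict[int, float]) -> dict[int, bool]:
    border = np.zeros(labels.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    n_motifs = len(saddles)
    out: dict[int, bool] = {}
    for lab in saddles:
        if n_motifs == 1:
            # a motif spanning the whole evaluation area has no neighbour
            # to pour into; border contact is vacuous
            out[lab] = True
        else:
            out[lab] = not bool(((labels == lab) & border).any())
    return out


def segment_motifs(hmap: HeightMap, config: AnalysisConfig | None = None) -> MotifSegmentation:
    """Segment a surface into Wolf-pruned hills and dales.

    Watershed with 8-connectivity, seeded from the h-extrema of the surface
    with ``h = prune_fraction * (max - min)``, so motifs whose summit lies
    less than ``h`` above (below) their connecting saddle are merged into
    their neighbours. A constant surface yields an empty segmentation.
    """
    config = config or AnalysisConfig()
    mask = hmap.valid_mask
    z = hmap.heights
    zv = z[mask]
    if zv.size == 0 or np.ptp(zv) == 0.0:
        empty = np.zeros(z.shape, dtype=int)
        return MotifSegmentation(
            hill_labels=empty,
            dale_labels=empty.copy(),
            peaks={},
            pits={},
            hill_saddles={},
            dale_saddles={},
            closed_hill_flags={},
            closed_dale_flags={},
            prune_threshold_um=0.0,
            dx=hmap.dx,
            dy=hmap.dy,
        )
    h = config.prune_fraction * float(np.ptp(zv))
    zf = np.where(mask, z, zv.min())  # invalid points sink to the minimum

    def _segment(surface: np.ndarray) -> np.ndarray:
        if h > 0:
            seeds = morphology.h_maxima(surface, h, footprint=np.ones((3, 3)))
        else:
            seeds = morphology.local_maxima(surface, connectivity=2)
        markers = sk_label(seeds, connectivity=2)
        if markers.max() == 0:
            return np.zeros(surface.shape, dtype=int)
        return watershed(-surface, markers=markers, mask=mask, connectivity=2)

    hill_labels = _segment(zf)
    dale_labels = _segment(-zf)
    peaks = _extrema(hill_labels, z, maximum=True)
    pits = _extrema(dale_labels, z, maximum=False)
    hill_saddles = _saddle_heights(hill_labels, zf, invert=False)
    dale_saddles = _saddle_heights(dale_labels, zf, invert=True)
    return MotifSegmentation(
        hill_labels=hill_labels,
        dale_labels=dale_labels,
        peaks=peaks,
        pits=pits,
        hill_saddles=hill_saddles,
        dale_saddles=dale_saddles,
        closed_hill_flags=_closed_flags(hill_labels, hill_saddles),
        closed_dale_flags=_closed_flags(dale_labels, dale_saddles),
        prune_threshold_um=h,
        dx=hmap.dx,
        dy=hmap.dy,
    )


def spd(seg: MotifSegmentation, area_um2: float) -> float:
    """Density of peaks: surviving peak count per unit area (1/µm²)."""
    if area_um2 <= 0:
        raise ValueError("definition area must be positive")
    return seg.n_hills / area_um2


def _peak_curvature(hmap: HeightMap, j: int, i: int) -> float | None:
    """Mean curvature −(z_xx + z_yy)/2 at a summit from a 3x3 quadratic fit."""
    j = int(np.clip(j, 1, hmap.ny - 2))
    i = int(np.clip(i, 1, hmap.nx - 2))
    patch = hmap.heights[j - 1 : j + 2, i - 1 : i + 2]
    if not hmap.valid_mask[j - 1 : j + 2, i - 1 : i + 2].all():
        return None
    xs = np.array([-hmap.dx, 0.0, hmap.dx])
    ys = np.array([-hmap.dy, 0.0, hmap.dy])
    X, Y = np.meshgrid(xs, ys)
    design = np.column_stack(
        [np.ones(9), X.ravel(), Y.ravel(), X.ravel() ** 2, X.ravel() * Y.ravel(), Y.ravel() ** 2]
    )
    coef, *_ = np.linalg.lstsq(design, patch.ravel(), rcond=None)
    zxx, zyy = 2.0 * coef[3], 2.0 * coef[5]
    return float(-0.5 * (zxx + zyy))


def spc(seg: MotifSegmentation, hmap: HeightMap) -> float:
    """Arithmetic mean peak curvature (1/µm) over surviving peaks; NaN if none."""
    curvatures = [
        c
        for (j, i, _h) in seg.peaks.values()
        if (c := _peak_curvature(hmap, j, i)) is not None
    ]
    if not curvatures:
        return float("nan")
    return float(np.mean(curvatures))


def motif_area_volume(
    seg: MotifSegmentation,
    hmap: HeightMap,
    kind: str = "hill",
    closed_only: bool = True,
) -> tuple[float, float]:
    """Mean motif area (µm²) and mean motif volume (µm³).

    Hill volume is integrated above the motif's bounding saddle height;
    dale volume below it. ``closed_only`` restricts to closed motifs
    (the convention for the area parameters Sha/Sda). Returns NaN for a
    measure with no qualifying motifs.
    """
    if kind not in ("hill", "dale"):
        raise ValueError("kind must be 'hill' or 'dale'")
    labels = seg.hill_labels if kind == "hill" else seg.dale_labels
    saddles = seg.hill_saddles if kind == "hill" else seg.dale_saddles
    closed = seg.closed_hill_flags if kind == "hill" else seg.closed_dale_flags
    cell = seg.dx * seg.dy
    areas: list[float] = []
    volumes: list[float] = []
    for lab, sad in saddles.items():
        if closed_only and not closed.get(lab, False):
            continue
        motif = labels == lab
        areas.append(float(motif.sum()) * cell)
        dz = hmap.heights - sad if kind == "hill" else sad - hmap.heights
        volumes.append(float(np.clip(dz[motif], 0.0, None).sum()) * cell)
    if not areas:
        return float("nan"), float("nan")
    return float(np.mean(areas)), float(np.mean(volumes))


def feature_params(
    seg: MotifSegmentation, hmap: HeightMap, which: set[str] | None = None
) -> dict[str, float]:
    """The six feature parameters (or the requested subset) for one surface."""
    which = which or {"Spd", "Spc", "Sha", "Sda", "Shv", "Sdv"}
    area = hmap.nx * hmap.dx * hmap.ny * hmap.dy
    out: dict[str, float] = {}
    if "Spd" in which:
        out["Spd"] = spd(seg, area)
    if "Spc" in which:
        out["Spc"] = spc(seg, hmap)
    if {"Sha", "Shv"} & which:
        sha, _ = motif_area_volume(seg, hmap, "hill", closed_only=True)
        _, shv = motif_area_volume(seg, hmap, "hill", closed_only=False)
        if "Sha" in which:
            out["Sha"] = sha
        if "Shv" in which:
            out["Shv"] = shv
    if {"Sda", "Sdv"} & which:
        sda, _ = motif_area_volume(seg, hmap, "dale", closed_only=True)
        _, sdv = motif_area_volume(seg, hmap, "dale", closed_only=False)
        if "Sda" in which:
            out["Sda"] = sda
        if "Sdv" in which:
            out["Sdv"] = sdv
    return out
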