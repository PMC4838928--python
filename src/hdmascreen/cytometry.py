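"""Image cytometry: chamber tiles -> per-cell feature records.

Converts 3-channel fluorescence tiles (DNA / cTnT / Ki67) into one feature
row per cell: nuclei are segmented on the smoothed DNA channel (global Otsu
threshold with a per-tile local fallback, distance-transform watershed
declumping of touching nuclei), cytoplasm is assigned by seeded propagation
from the nuclei into the above-background cTnT signal, and size, shape and
background-subtracted integrated intensities are measured over both masks.
Chambers are QC-flagged (empty / failed) so downstream statistics can apply
the zero-replacement rule of array-wide heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import expand_labels, watershed

__all__ = [
    "ArrayLayout",
    "NucleiParams",
    "CytoplasmParams",
    "QCParams",
    "ChamberQC",
    "LayoutError",
    "slice_montage",
    "assemble_montage",
    "segment_nuclei",
    "propagate_cytoplasm",
    "measure_features",
    "flag_chamber",
    "normalize_column_fluorescence",
    "process_chamber",
]

CHANNEL_NAMES = ("dna", "ctnt", "ki67")


class LayoutError(ValueError):
    """Raised when an array layout does not fit the supplied montage."""


@dataclass(frozen=True)
class ArrayLayout:
    """Grid placement of chamber tiles in a whole-array montage.

    Columns run left to right (0-based, matching the design column index),
    rows top to bottom (1-based, matching the serial-chamber index); each
    chamber occupies a ``tile_px`` x ``tile_px`` crop.
    """

    n_columns: int
    n_rows: int
    tile_px: int
    um_per_px: float = 2.0

    def __post_init__(self) -> None:
        if min(self.n_columns, self.n_rows, self.tile_px) < 1:
            raise LayoutError("layout dimensions must be positive")


def assemble_montage(tiles: dict[tuple[int, int], np.ndarray], layout: ArrayLayout) -> np.ndarray:
    """Inverse of :func:`slice_montage`: paste (column, row) tiles onto a grid."""
    t = layout.tile_px
    sample = next(iter(tiles.values()))
    montage = np.zeros(
        (sample.shape[0], layout.n_rows * t, layout.n_columns * t), dtype=sample.dtype
    )
    for (col, row), tile in tiles.items():
        montage[:, (row - 1) * t : row * t, col * t : (col + 1) * t] = tile
    return montage


def slice_montage(montage: np.ndarray, layout: ArrayLayout):
    """Slice a channel-first montage into per-chamber tiles.

    Yields ``(column, row, tile)`` in row-major order (all columns of row 1,
    then row 2, ...), rows 1-based to match the design addressing.
    """
    if montage.ndim == 2:
        montage = montage[None]
    t = layout.tile_px
    need_h, need_w = layout.n_rows * t, layout.n_columns * t
    if montage.shape[-2] < need_h or montage.shape[-1] < need_w:
        raise LayoutError(
            f"montage {montage.shape[-2:]} smaller than layout "
            f"({need_h}, {need_w})"
        )
    out = []
    for row in range(1, layout.n_rows + 1):
        for col in range(layout.n_columns):
            tile = montage[:, (row - 1) * t : row * t, col * t : (col + 1) * t]
            out.append((col, row, tile))
    return out


@dataclass(frozen=True)
class NucleiParams:
    """Nuclei segmentation parameters (pixel units unless noted)."""

    smooth_sigma: float = 0.8
    min_area: int = 4
    max_area: int = 30  # ~2x the default nuclear footprint: larger blobs get declumped
    declump_min_distance: int = 3
    threshold_method: str = "otsu"  # or "local"
    min_contrast_snr: float = 4.0  # fg-bg separation below this => empty tile


@dataclass(frozen=True)
class CytoplasmParams:
    smooth_sigma: float = 1.0
    annulus_px: int = 2  # fallback ring for cells without cytoplasm signal
    min_contrast_snr: float = 4.0  # below this the channel is treated as signal-free


@dataclass(frozen=True)
class QCParams:
    min_cells: int = 1
    max_saturated_fraction: float = 0.05
    saturation_level: int = 65535


@dataclass(frozen=True)
class ChamberQC:
    chamber: int
    flag: str  # ok | empty | failed
    reason: str = ""

    def __post_init__(self) -> None:
        if self.flag not in ("ok", "empty", "failed"):
            raise ValueError(f"unknown QC flag {self.flag!r}")
        if self.flag != "ok" and not self.reason:
            raise ValueError("flagged chambers must carry a reason")


def segment_nuclei(dna: np.ndarray, params: NucleiParams = NucleiParams()) -> np.ndarray:
    """Label nuclei in a single-channel DNA image.

    Gaussian smoothing, Otsu global threshold (an empty tile — foreground
    below ``min_foreground_fraction`` — yields zero labels rather than an
    error), size filtering, and distance-transform watershed to split
    touching nuclei.
    """
    if dna.ndim != 2:
        raise ValueError("segment_nuclei expects a single-channel image")
    img = dna.astype(float)
    if params.smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, params.smooth_sigma)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros(dna.shape, dtype=np.int32)
    thr = threshold_otsu(img)
    mask = img > thr
    # an empty tile is noise: Otsu then splits the noise distribution and the
    # two halves sit within a few noise SDs of each other
    bg = img[~mask]
    if not mask.any() or not bg.size:
        return np.zeros(dna.shape, dtype=np.int32)
    sd = float(bg.std())
    if sd > 0 and (img[mask].mean() - bg.mean()) < params.min_contrast_snr * sd:
        return np.zeros(dna.shape, dtype=np.int32)
    if params.threshold_method == "local":
        from skimage.filters import threshold_local

        block = 2 * (min(img.shape) // 8) + 1
        mask = img > threshold_local(img, block_size=max(block, 3))
    lbl, _ = ndimage.label(mask)
    sizes = np.bincount(lbl.ravel())
    # remove specks, then declump only blobs large enough to hold >1 nucleus
    small = sizes < params.min_area
    small[0] = True
    mask &= ~small[lbl]
    lbl, n = ndimage.label(mask)
    if n == 0:
        return np.zeros(dna.shape, dtype=np.int32)
    sizes = np.bincount(lbl.ravel())
    big = np.flatnonzero(sizes > params.max_area)
    big = big[big > 0]  # never declump the background
    if big.size:
        clump = np.isin(lbl, big)
        dist = ndimage.distance_transform_edt(clump)
        from skimage.feature import peak_local_max

        peaks = peak_local_max(
            dist,
            min_distance=params.declump_min_distance,
            labels=clump,
            exclude_border=False,
        )
        markers = np.zeros_like(lbl)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        split = watershed(-dist, markers, mask=clump)
        lbl = _relabel_sequential(np.where(clump, 0, lbl))
        # keep watershed labels distinct even where split fronts touch
        lbl = np.where(split > 0, split + lbl.max(), lbl)
    return _relabel_sequential(lbl)


def _relabel_sequential(lbl: np.ndarray) -> np.ndarray:
    ids = np.unique(lbl)
    ids = ids[ids > 0]
    lut = np.zeros(lbl.max() + 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    return lut[lbl]


def propagate_cytoplasm(
    nuclei: np.ndarray,
    cyto_channel: np.ndarray,
    params: CytoplasmParams = CytoplasmParams(),
) -> np.ndarray:
    """Grow each nucleus label into the surrounding above-background
    cytoplasm signal; competing fronts meet along intensity-guided midlines.

    Cells without cytoplasm signal keep the nucleus plus a fixed-radius
    annulus.  The result maps 1:1 onto the nuclear labels (same label ids).
    """
    if nuclei.shape != cyto_channel.shape:
        raise ValueError("nuclei mask and cytoplasm channel shapes differ")
    img = cyto_channel.astype(float)
    if params.smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, params.smooth_sigma)
    base = expand_labels(nuclei, distance=params.annulus_px)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return base.astype(np.int32)
    thr = threshold_otsu(img)
    cyto_mask = img > thr
    if not cyto_mask.any() or cyto_mask.all():
        return base.astype(np.int32)
    bg = img[~cyto_mask]
    sd = float(bg.std())
    if sd > 0 and (img[cyto_mask].mean() - bg.mean()) < params.min_contrast_snr * sd:
        return base.astype(np.int32)
    region = cyto_mask | (base > 0)
    cells = watershed(-img, markers=nuclei, mask=region)
    # fallback annulus where propagation found nothing beyond the nucleus
    cells = np.where(cells > 0, cells, base)
    cells[nuclei > 0] = nuclei[nuclei > 0]
    return cells.astype(np.int32)


def measure_features(
    nuclei: np.ndarray,
    cells: np.ndarray,
    channels: dict[str, np.ndarray],
    um_per_px: float = 2.0,
    background: str | float = "median",
    solidity: bool = True,
) -> pd.DataFrame:
    """One CellRecord row per label: areas, shape, and integrated intensities.

    Integrated intensity is the sum of background-subtracted pixel values
    over the nuclear or cellular mask, floored at zero.  The background per
    channel is the median of non-cell pixels (or a given constant).
    Eccentricity comes from per-label central moments (vectorized); solidity
    needs a convex hull per object and can be switched off on large batch
    runs where it is not consumed.
    """
    labels = np.unique(nuclei)
    labels = labels[labels > 0]
    if len(labels) == 0:
        cols = ["cell", "y", "x", "nuclear_area_px", "nuclear_area_um2",
                "cell_area_px", "cell_area_um2", "eccentricity", "solidity"]
        for ch in channels:
            cols += [f"nuclear_intensity_{ch}", f"cell_intensity_{ch}"]
        return pd.DataFrame(columns=cols)
    idx = labels  # labels are sequential 1..K by construction
    nuc_area = ndimage.sum_labels(np.ones_like(nuclei), nuclei, idx)
    cell_area = ndimage.sum_labels(np.ones_like(cells), cells, idx)
    cy, cx = np.array(ndimage.center_of_mass(np.ones_like(nuclei), nuclei, idx)).T
    data = {
        "cell": idx,
        "y": cy,
        "x": cx,
        "nuclear_area_px": nuc_area,
        "nuclear_area_um2": nuc_area * um_per_px**2,
        "cell_area_px": cell_area,
        "cell_area_um2": cell_area * um_per_px**2,
    }
    yy, xx = np.indices(nuclei.shape)
    s_y2 = ndimage.sum_labels(yy.astype(float) ** 2, nuclei, idx)
    s_x2 = ndimage.sum_labels(xx.astype(float) ** 2, nuclei, idx)
    s_xy = ndimage.sum_labels((yy * xx).astype(float), nuclei, idx)
    mu20 = s_y2 - nuc_area * cy**2
    mu02 = s_x2 - nuc_area * cx**2
    mu11 = s_xy - nuc_area * cy * cx
    common = np.sqrt(((mu20 - mu02) / 2.0) ** 2 + mu11**2)
    l1 = (mu20 + mu02) / 2.0 + common
    l2 = (mu20 + mu02) / 2.0 - common
    with np.errstate(invalid="ignore", divide="ignore"):
        ecc = np.sqrt(np.clip(1.0 - l2 / l1, 0.0, 1.0))
    data["eccentricity"] = np.where(l1 > 0, ecc, 0.0)
    if solidity:
        sol = np.full(len(idx), np.nan)
        for prop in regionprops(nuclei):
            sol[prop.label - 1] = prop.solidity
        data["solidity"] = sol
    bg_mask = cells == 0
    for name, img in channels.items():
        img = img.astype(float)
        if background == "median":
            bg = float(np.median(img[bg_mask])) if bg_mask.any() else 0.0
        else:
            bg = float(background)
        sub = img - bg
        data[f"nuclear_intensity_{name}"] = np.maximum(
            ndimage.sum_labels(sub, nuclei, idx), 0.0
        )
        data[f"cell_intensity_{name}"] = np.maximum(
            ndimage.sum_labels(sub, cells, idx), 0.0
        )
    return pd.DataFrame(data)


def flag_chamber(
    records: pd.DataFrame,
    tile: np.ndarray,
    qc: QCParams = QCParams(),
    chamber: int = 0,
    error: str | None = None,
) -> ChamberQC:
    """QC verdict for one chamber: ok, empty (too few cells) or failed
    (processing error or saturated staining)."""
    if error:
        return ChamberQC(chamber, "failed", f"processing error: {error}")
    sat = float((tile >= qc.saturation_level).mean())
    if sat > qc.max_saturated_fraction:
        return ChamberQC(chamber, "failed", f"saturated fraction {sat:.3f}")
    if len(records) < qc.min_cells:
        return ChamberQC(chamber, "empty", f"{len(records)} cells detected")
    return ChamberQC(chamber, "ok")


def normalize_column_fluorescence(raw, blank: float):
    """Blank-subtracted min/max normalization of per-column intensities.

    ``raw`` is one intensity per column, or a (columns, replicates) array
    whose replicate chambers are averaged first.  Returns
    ``(mean - blank) / (max - blank)`` so a blank column reads 0 and the
    brightest column reads 1.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim == 2:
        arr = arr.mean(axis=1)
    top = float(arr.max())
    if top <= blank:
        raise ValueError("channel maximum does not exceed the blank; cannot normalize")
    return (arr - blank) / (top - blank)


def process_chamber(
    tile: np.ndarray,
    chamber: int = 0,
    nuclei_params: NucleiParams = NucleiParams(),
    cyto_params: CytoplasmParams = CytoplasmParams(),
    qc_params: QCParams = QCParams(),
    um_per_px: float = 2.0,
    solidity: bool = False,
) -> tuple[pd.DataFrame, ChamberQC]:
    """Full per-chamber pipeline: segment, propagate, measure, flag.

    ``tile`` is channel-first (3, H, W) in the order DNA, cTnT, Ki67.
    """
    try:
        nuclei = segment_nuclei(tile[0], nuclei_params)
        if nuclei.max() == 0:
            records = measure_features(nuclei, nuclei, {})
        else:
            cells = propagate_cytoplasm(nuclei, tile[1], cyto_params)
            records = measure_features(
                nuclei,
                cells,
                dict(zip(CHANNEL_NAMES, tile)),
                um_per_px=um_per_px,
                solidity=solidity,
            )
    except Exception as exc:  # pragma: no cover - defensive QC path
        empty = measure_features(np.zeros((1, 1), np.int32), np.zeros((1, 1), np.int32), {})
        return empty, flag_chamber(empty, tile, qc_params, chamber, error=str(exc))
    qc = flag_chamber(records, tile, qc_params, chamber)
    records = records.copy()
    records.insert(0, "chamber", chamber)
    return records, qc
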