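"""Image quantification: segmentation, RCP detection and classification.

Re-implements the CellProfiler-style analysis used for dual-tag
rolling-circle assays: nuclei from the nuclear channel (Otsu threshold,
diameter gating, declumping by intensity-seeded watershed); cells by
expanding nuclei a fixed distance with nearest-nucleus assignment; per
detection channel, background removal with a white top-hat ("enhance
speckles"), spot detection within a diameter range, shrink-to-point /
re-expand consolidation merging the two channels into unified RCP objects;
masking of objects outside cells; per-object dual-channel mean intensities;
classification into free-A / free-B / complex by angled thresholds in the
background-subtracted intensity plane; per-cell counts and normalized
fractions. A single-channel in situ PLA variant is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, filters, morphology, segmentation
from skimage.measure import regionprops

__all__ = [
    "SegmentationParams",
    "ClassificationThresholds",
    "segment_nuclei",
    "delineate_cells",
    "enhance_speckles",
    "detect_spots",
    "consolidate_spots",
    "mask_and_assign",
    "measure_and_classify",
    "per_cell_counts",
    "pooled_fractions",
    "quantify_field",
    "quantify_pla",
]

RCP_CLASSES = ("freeA", "freeB", "complex")

SPOT_COLUMNS = [
    "object_id",
    "y",
    "x",
    "area",
    "from_a",
    "from_b",
    "cell_id",
    "intensity_a",
    "intensity_b",
    "rcp_class",
]

CELL_COLUMNS = [
    "cell_id",
    "n_free_a",
    "n_free_b",
    "n_complex",
    "n_total",
    "f_free_a",
    "f_free_b",
    "f_complex",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Segmentation and spot-detection parameters (pixel units).

    ``nucleus_threshold`` is two- or three-class Otsu (three-class takes the
    middle and high classes as foreground); ``spot_threshold`` is two-class
    Otsu, ``("manual", level)`` or ``"robust_background"`` (trimmed
    mean + 3 sd of the background pixels). ``cell_expand_n`` is the
    nucleus-to-cell expansion distance N; ``spot_expand_b`` the
    shrink-to-point re-expansion distance B used to consolidate the two
    detection channels into unified RCP objects.
    """

    nucleus_diameter_range: tuple[float, float] = (40.0, 110.0)
    nucleus_threshold: str = "otsu2"
    nucleus_smooth_px: float = 3.0
    cell_expand_n: float = 90.0
    spot_diameter_range: tuple[float, float] = (1.5, 10.0)
    speckle_feature_size: int = 5
    spot_threshold: "str | tuple[str, float]" = "robust_background"
    spot_expand_b: float = 1.0
    robust_background_k: float = 4.0

    def __post_init__(self) -> None:
        for name in ("cell_expand_n", "spot_expand_b", "speckle_feature_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("nucleus_diameter_range", "spot_diameter_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} must be an increasing positive range")


@dataclass(frozen=True)
class ClassificationThresholds:
    """Angled-threshold classification in the (I_A, I_B) intensity plane.

    Intensities are first background-subtracted (cutoffs ``t_a``/``t_b``;
    ``None`` means the per-channel Otsu level over non-spot pixels) and
    clipped at zero. The polar angle from the I_A axis then bins each object:
    below ``theta_low`` degrees -> free A; above ``theta_high`` -> free B;
    between them -> complex. Objects at the origin are discarded as
    background.
    """

    t_a: "float | None" = None
    t_b: "float | None" = None
    theta_low: float = 30.0
    theta_high: float = 60.0

    def __post_init__(self) -> None:
        if not 0 <= self.theta_low < self.theta_high <= 90:
            raise ValueError("require 0 <= theta_low < theta_high <= 90")
        for t in (self.t_a, self.t_b):
            if t is not None and t < 0:
                raise ValueError("background cutoffs must be >= 0")


def _diameter_filter(labels: np.ndarray, diameter_range: tuple[float, float]) -> np.ndarray:
    """Keep objects within the equivalent-diameter range; relabel the
    survivors compactly in raster order of their centroids (deterministic)."""
    lo, hi = diameter_range
    props = regionprops(labels)
    keep = [p for p in props if lo <= p.equivalent_diameter_area <= hi]
    keep.sort(key=lambda p: p.centroid)
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    for new_id, p in enumerate(keep, start=1):
        lut[p.label] = new_id
    return lut[labels]


def segment_nuclei(nuclear: np.ndarray, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Label nuclei in the nuclear channel.

    Smooth, Otsu-threshold (two- or three-class), fill holes, then declump
    touching nuclei by watershed seeded at intensity maxima separated by at
    least the minimum nucleus diameter; finally discard objects outside the
    diameter range. A blank image yields zero labels.
    """
    img = np.asarray(nuclear, dtype=float)
    smoothed = ndimage.gaussian_filter(img, params.nucleus_smooth_px)
    if smoothed.max() <= smoothed.min():
        return np.zeros(img.shape, dtype=np.int32)
    if params.nucleus_threshold == "otsu2":
        level = filters.threshold_otsu(smoothed)
    elif params.nucleus_threshold == "otsu3":
        # three-class Otsu: middle + high classes are foreground
        level = filters.threshold_multiotsu(smoothed, classes=3)[0]
    else:
        raise ValueError(f"unknown nucleus_threshold {params.nucleus_threshold!r}")
    mask = smoothed > level
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)
    min_dist = max(1, int(params.nucleus_diameter_range[0]))
    peaks = feature.peak_local_max(
        smoothed, min_distance=min_dist, labels=mask, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        labels, _ = ndimage.label(mask)
    else:
        labels = segmentation.watershed(-smoothed, markers, mask=mask)
    return _diameter_filter(labels, params.nucleus_diameter_range).astype(np.int32)


def delineate_cells(nuclei_labels: np.ndarray, expand_n: float) -> np.ndarray:
    """Expand each nucleus by at most ``expand_n`` px into a cell region.

    Contested pixels go to the Euclidean-nearest nucleus; exact ties resolve
    deterministically (scan order, favouring the earlier-labeled nucleus).
    Each cell contains its nucleus.
    """
    if expand_n <= 0:
        raise ValueError("expansion distance must be > 0")
    return segmentation.expand_labels(nuclei_labels, distance=expand_n)


def enhance_speckles(channel: np.ndarray, feature_size: int) -> np.ndarray:
    """White top-hat: the image minus its opening with a disk of radius
    ``feature_size`` — keeps bright features smaller than the disk, removes
    slowly varying background. Output is non-negative."""
    if feature_size <= 0:
        raise ValueError("feature_size must be > 0")
    img = np.asarray(channel, dtype=float)
    return morphology.white_tophat(img, footprint=morphology.disk(feature_size))


def _spot_level(enhanced: np.ndarray, params: SegmentationParams) -> float:
    spec = params.spot_threshold
    if spec == "otsu2":
        return float(filters.threshold_otsu(enhanced))
    if spec == "robust_background":
        # background statistics after trimming the brightest 5 % of pixels
        flat = np.sort(enhanced.ravel())
        trimmed = flat[: int(0.95 * len(flat))]
        return float(trimmed.mean() + params.robust_background_k * trimmed.std())
    if isinstance(spec, (tuple, list)) and spec[0] == "manual":
        return float(spec[1])
    raise ValueError(f"unknown spot_threshold {spec!r}")


def detect_spots(enhanced: np.ndarray, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Label spots in the speckle-enhanced image.

    Pixels above the spot threshold are segmented and touching spots are
    declumped by watershed seeded at intensity maxima separated by at least
    the minimum spot diameter; objects outside the diameter range are
    discarded.
    """
    img = np.asarray(enhanced, dtype=float)
    if img.max() <= img.min():
        return np.zeros(img.shape, dtype=np.int32)
    level = _spot_level(img, params)
    mask = img > level
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)
    min_dist = max(1, int(round(params.spot_diameter_range[0])))
    peaks = feature.peak_local_max(
        img, min_distance=min_dist, labels=mask, exclude_border=False
    )
    if len(peaks) == 0:
        labels, _ = ndimage.label(mask)
    else:
        markers = np.zeros(img.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = segmentation.watershed(-img, markers, mask=mask)
    return _diameter_filter(labels, params.spot_diameter_range).astype(np.int32)


def consolidate_spots(
    spots_a: np.ndarray, spots_b: np.ndarray, expand_b: float
) -> tuple[np.ndarray, pd.DataFrame]:
    """Merge the two detection channels into unified RCP objects.

    Each spot is reduced to its centroid and re-grown to a disk of radius
    ``expand_b``; disks overlapping across (or within) channels merge into
    one object. Returns the object label image and a table with centroid,
    area and channel provenance (``from_a``/``from_b``) per object.
    """
    if expand_b <= 0:
        raise ValueError("expansion distance must be > 0")
    if spots_a.shape != spots_b.shape:
        raise ValueError("spot images must share one grid")
    shape = spots_a.shape
    cents: list[tuple[float, float, str]] = []
    for chan, labels in (("A", spots_a), ("B", spots_b)):
        for prop in regionprops(np.asarray(labels)):
            cents.append((prop.centroid[0], prop.centroid[1], chan))
    canvas = np.zeros(shape, dtype=bool)
    r = int(np.ceil(expand_b))
    disk = morphology.disk(r).astype(bool)
    for y, x, _ in cents:
        yi, xi = int(round(y)), int(round(x))
        y0, x0 = yi - r, xi - r
        ys = slice(max(0, y0), min(shape[0], yi + r + 1))
        xs = slice(max(0, x0), min(shape[1], xi + r + 1))
        canvas[ys, xs] |= disk[
            ys.start - y0 : ys.stop - y0, xs.start - x0 : xs.stop - x0
        ]
    objects, _ = ndimage.label(canvas)
    rows = []
    by_label: dict[int, dict] = {}
    for y, x, chan in cents:
        lab = int(objects[int(round(y)), int(round(x))])
        if lab == 0:
            continue
        rec = by_label.setdefault(
            lab, {"object_id": lab, "ys": [], "xs": [], "from_a": False, "from_b": False}
        )
        rec["ys"].append(y)
        rec["xs"].append(x)
        rec["from_a"] |= chan == "A"
        rec["from_b"] |= chan == "B"
    areas = ndimage.sum_labels(canvas, objects, index=np.arange(1, objects.max() + 1))
    for lab in sorted(by_label):
        rec = by_label[lab]
        rows.append(
            {
                "object_id": lab,
                "y": float(np.mean(rec["ys"])),
                "x": float(np.mean(rec["xs"])),
                "area": float(areas[lab - 1]),
                "from_a": rec["from_a"],
                "from_b": rec["from_b"],
            }
        )
    table = pd.DataFrame(rows, columns=["object_id", "y", "x", "area", "from_a", "from_b"])
    return objects.astype(np.int32), table


def mask_and_assign(objects: pd.DataFrame, cell_labels: np.ndarray) -> pd.DataFrame:
    """Drop objects whose centroid lies outside every cell; assign the rest
    the cell label under their centroid."""
    if objects.empty:
        return objects.assign(cell_id=pd.Series(dtype=int))
    ys = objects["y"].round().astype(int).clip(0, cell_labels.shape[0] - 1)
    xs = objects["x"].round().astype(int).clip(0, cell_labels.shape[1] - 1)
    cell_ids = cell_labels[ys, xs]
    out = objects.assign(cell_id=cell_ids)
    return out[out["cell_id"] > 0].reset_index(drop=True)


def _auto_cutoff(channel: np.ndarray, spot_mask: np.ndarray) -> float:
    """Background cutoff: Otsu level over the channel's non-spot pixels."""
    bg = channel[~spot_mask]
    if bg.size == 0 or bg.max() <= bg.min():
        return float(bg.mean()) if bg.size else 0.0
    return float(filters.threshold_otsu(bg))


def measure_and_classify(
    objects_img: np.ndarray,
    objects: pd.DataFrame,
    chan_a: np.ndarray,
    chan_b: np.ndarray,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.DataFrame:
    """Measure per-object mean intensities and classify by angled thresholds.

    Mean intensities are taken over the object mask in each raw detection
    channel. In the background-subtracted plane (clipped at zero) the polar
    angle ``phi = atan2(I_B', I_A')`` bins objects into free A
    (``phi < theta_low``), free B (``phi > theta_high``) and complex
    (in between); objects with both subtracted intensities zero are discarded
    as background.
    """
    if objects.empty:
        return objects.assign(
            intensity_a=pd.Series(dtype=float),
            intensity_b=pd.Series(dtype=float),
            rcp_class=pd.Series(dtype=object),
        )
    chan_a = np.asarray(chan_a, dtype=float)
    chan_b = np.asarray(chan_b, dtype=float)
    spot_mask = objects_img > 0
    t_a = thresholds.t_a if thresholds.t_a is not None else _auto_cutoff(chan_a, spot_mask)
    t_b = thresholds.t_b if thresholds.t_b is not None else _auto_cutoff(chan_b, spot_mask)
    ids = objects["object_id"].to_numpy()
    mean_a = ndimage.mean(chan_a, labels=objects_img, index=ids)
    mean_b = ndimage.mean(chan_b, labels=objects_img, index=ids)
    ia = np.clip(mean_a - t_a, 0, None)
    ib = np.clip(mean_b - t_b, 0, None)
    phi = np.degrees(np.arctan2(ib, ia))
    rcp_class = np.where(
        phi < thresholds.theta_low,
        "freeA",
        np.where(phi > thresholds.theta_high, "freeB", "complex"),
    )
    out = objects.assign(intensity_a=mean_a, intensity_b=mean_b, rcp_class=rcp_class)
    keep = (ia > 0) | (ib > 0)
    return out[keep].reset_index(drop=True)


def per_cell_counts(
    spot_table: pd.DataFrame, cell_ids: "np.ndarray | list | None" = None
) -> pd.DataFrame:
    """Per-cell counts and normalized fractions of the three signal classes.

    Fractions are each class count over the total detected signal in the
    cell; cells with zero spots are reported with ``n_total = 0`` and NaN
    fractions. ``cell_ids`` lists the cells to report (defaults to the cells
    present in the spot table).
    """
    if cell_ids is None:
        cell_ids = sorted(spot_table["cell_id"].unique()) if not spot_table.empty else []
    rows = []
    for cid in cell_ids:
        sub = spot_table[spot_table["cell_id"] == cid] if not spot_table.empty else spot_table
        counts = {c: int((sub["rcp_class"] == c).sum()) if not sub.empty else 0 for c in RCP_CLASSES}
        total = sum(counts.values())
        rows.append(
            {
                "cell_id": int(cid),
                "n_free_a": counts["freeA"],
                "n_free_b": counts["freeB"],
                "n_complex": counts["complex"],
                "n_total": total,
                "f_free_a": counts["freeA"] / total if total else np.nan,
                "f_free_b": counts["freeB"] / total if total else np.nan,
                "f_complex": counts["complex"] / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def pooled_fractions(spot_table: pd.DataFrame) -> dict[str, float]:
    """Frame-level percentages: each class's share of all in-cell RCPs."""
    total = len(spot_table)
    return {
        c: (100.0 * (spot_table["rcp_class"] == c).sum() / total if total else np.nan)
        for c in RCP_CLASSES
    }


def quantify_field(
    stack: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> dict:
    """Run the full dual-channel pipeline on a (nuclear, det A, det B) stack.

    Returns a dict with the spot table, per-cell summary, label images and
    the pooled frame-level fractions.
    """
    nuclear, chan_a, chan_b = (np.asarray(c, dtype=float) for c in stack)
    nuclei = segment_nuclei(nuclear, params)
    cells = delineate_cells(nuclei, params.cell_expand_n)
    enh_a = enhance_speckles(chan_a, params.speckle_feature_size)
    enh_b = enhance_speckles(chan_b, params.speckle_feature_size)
    spots_a = detect_spots(enh_a, params)
    spots_b = detect_spots(enh_b, params)
    objects_img, objects = consolidate_spots(spots_a, spots_b, params.spot_expand_b)
    objects = mask_and_assign(objects, cells)
    spot_table = measure_and_classify(objects_img, objects, chan_a, chan_b, thresholds)
    cell_ids = [int(c) for c in np.unique(cells) if c > 0]
    cell_table = per_cell_counts(spot_table, cell_ids)
    return {
        "spot_table": spot_table[
            [c for c in SPOT_COLUMNS if c in spot_table.columns]
        ],
        "cell_table": cell_table,
        "nuclei_labels": nuclei,
        "cell_labels": cells,
        "objects_img": objects_img,
        "pooled_fractions": pooled_fractions(spot_table),
    }


def quantify_pla(
    nuclear: np.ndarray,
    signal: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> dict:
    """Single-channel in situ PLA quantification: per-cell RCP counts.

    Nuclei use three-class Otsu; the signal channel is speckle-enhanced, spots
    detected, masked to cells and counted — a single signal category.
    """
    params = replace(params, nucleus_threshold="otsu3")
    nuclei = segment_nuclei(np.asarray(nuclear, dtype=float), params)
    cells = delineate_cells(nuclei, params.cell_expand_n)
    enhanced = enhance_speckles(np.asarray(signal, dtype=float), params.speckle_feature_size)
    spots = detect_spots(enhanced, params)
    rows = []
    for prop in regionprops(spots):
        y, x = prop.centroid
        rows.append({"object_id": prop.label, "y": y, "x": x, "area": prop.area})
    objects = pd.DataFrame(rows, columns=["object_id", "y", "x", "area"])
    objects = mask_and_assign(objects, cells)
    cell_ids = [int(c) for c in np.unique(cells) if c > 0]
    counts = (
        objects.groupby("cell_id").size() if not objects.empty else pd.Series(dtype=int)
    )
    cell_table = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "n_rcp": [int(counts.get(c, 0)) for c in cell_ids],
        }
    )
    return {
        "spot_table": objects,
        "cell_table": cell_table,
        "nuclei_labels": nuclei,
        "cell_labels": cells,
    }
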