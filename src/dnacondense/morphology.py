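"""Condensate segmentation, shape statistics, and fluidity classification.

The shape statistic is the aspect ratio ``(Rmax - Rmin)/(Rmax + Rmin)``
where ``Rmax`` and ``Rmin`` are the maximum and minimum radius of the
segmented structure, measured from its centroid to a sub-pixel boundary
contour.  The statistic vanishes for a circle and approaches unity for an
elongated rod, which makes it a convenient scalar for separating
round-shaped (liquid-like) from irregular (solid-like) condensates.

Conditions -- one (DNA length, DNA concentration) cell of a phase diagram,
summarized by mean aspect ratio and mean FRAP mobile fraction -- are
grouped by agglomerative hierarchical clustering (Euclidean distance,
complete linkage) into three classes and mapped onto the phase-diagram
regions:

- region I, liquid-like: dynamic round-shaped assemblies,
- region II, intermediate: static but round-shaped assemblies,
- region III, solid-like: static irregular assemblies.

The cluster-to-region mapping orders clusters by decreasing mean mobile
fraction (ties broken by increasing mean aspect ratio), since region I is
defined by its dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy import ndimage as ndi
from skimage import filters, measure, segmentation, feature

__all__ = [
    "CondensateShape",
    "ConditionRecord",
    "segment_condensates",
    "aspect_ratio",
    "measure_condensates",
    "classify_conditions",
    "annotate_phase_diagram",
    "REGION_GLYPHS",
]

#: plotting glyphs conventionally used for the three condensate classes
REGION_GLYPHS = {"I": "circle", "II": "triangle", "III": "square"}


@dataclass(frozen=True)
class CondensateShape:
    """Shape descriptors of one segmented condensate."""

    label: int
    area_px: float
    centroid: tuple[float, float]
    r_max: float
    r_min: float
    aspect_ratio: float
    degenerate: bool = False


@dataclass(frozen=True)
class ConditionRecord:
    """Per-condition summary entering the fluidity classification."""

    dna_length_bp: float
    dna_concentration: float  # g/mL
    mean_aspect_ratio: float
    mean_mobile_fraction: float
    detected: bool = True
    cluster: Optional[str] = None


def segment_condensates(
    image: np.ndarray,
    min_area: int = 20,
    threshold_method: str = "otsu",
    smooth_sigma: float = 1.0,
    watershed: bool = False,
    watershed_min_distance: int = 5,
) -> list[np.ndarray]:
    """Segment bright condensates in a grayscale image.

    The image is Gaussian-smoothed, thresholded (Otsu by default), and
    connected components smaller than ``min_area`` pixels are dropped.
    With ``watershed=True`` touching objects are split by a
    distance-transform watershed seeded at local maxima.

    Returns
    -------
    list of ndarray
        One boolean mask per condensate (possibly empty; a blank image is
        not an error).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if img.max() == img.min():
        return []
    smooth = filters.gaussian(img, sigma=smooth_sigma, preserve_range=True)
    if threshold_method == "otsu":
        thr = filters.threshold_otsu(smooth)
    elif threshold_method == "mean":
        thr = smooth.mean()
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    binary = smooth > thr
    if watershed:
        distance = ndi.distance_transform_edt(binary)
        coords = feature.peak_local_max(
            distance, min_distance=watershed_min_distance, labels=binary
        )
        markers = np.zeros_like(binary, dtype=int)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        labels = segmentation.watershed(-distance, markers, mask=binary)
    else:
        labels, _ = ndi.label(binary)
    masks = []
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        if mask.sum() >= min_area:
            masks.append(mask)
    return masks


def aspect_ratio(
    mask: np.ndarray, intensity: Optional[np.ndarray] = None, label: int = 0
) -> CondensateShape:
    """Aspect ratio ``(Rmax - Rmin)/(Rmax + Rmin)`` of one mask.

    ``Rmax``/``Rmin`` are the maximum/minimum Euclidean distances from the
    centroid (intensity-weighted if an intensity image is given) to the
    object boundary, where the boundary is the sub-pixel 0.5-level contour
    of the mask (marching squares).  A mask too small to carry a contour
    (single pixel) is returned with aspect ratio 0 and the ``degenerate``
    flag set.

    Raises
    ------
    ValueError
        For an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask is empty")
    area = float(mask.sum())
    if intensity is not None:
        w = np.where(mask, np.asarray(intensity, dtype=float), 0.0)
        total = w.sum()
        ys, xs = np.nonzero(mask)
        cy = float((ys * w[ys, xs]).sum() / total)
        cx = float((xs * w[ys, xs]).sum() / total)
    else:
        ys, xs = np.nonzero(mask)
        cy, cx = float(ys.mean()), float(xs.mean())
    if area < 2:
        return CondensateShape(label, area, (cy, cx), 0.0, 0.0, 0.0, degenerate=True)
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return CondensateShape(label, area, (cy, cx), 0.0, 0.0, 0.0, degenerate=True)
    boundary = max(contours, key=len) - 1.0  # undo padding offset
    d = np.hypot(boundary[:, 0] - cy, boundary[:, 1] - cx)
    r_max, r_min = float(d.max()), float(d.min())
    ar = (r_max - r_min) / (r_max + r_min) if r_max + r_min > 0 else 0.0
    return CondensateShape(label, area, (cy, cx), r_max, r_min, ar)


def measure_condensates(
    image: np.ndarray,
    min_area: int = 20,
    threshold_method: str = "otsu",
    smooth_sigma: float = 1.0,
    watershed: bool = False,
) -> pd.DataFrame:
    """Segment an image and tabulate per-condensate shape descriptors."""
    masks = segment_condensates(
        image,
        min_area=min_area,
        threshold_method=threshold_method,
        smooth_sigma=smooth_sigma,
        watershed=watershed,
    )
    rows = []
    for i, mask in enumerate(masks, start=1):
        s = aspect_ratio(mask, intensity=image, label=i)
        rows.append(
            {
                "label": s.label,
                "area_px": s.area_px,
                "centroid_y": s.centroid[0],
                "centroid_x": s.centroid[1],
                "r_max": s.r_max,
                "r_min": s.r_min,
                "aspect_ratio": s.aspect_ratio,
                "degenerate": s.degenerate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "area_px",
            "centroid_y",
            "centroid_x",
            "r_max",
            "r_min",
            "aspect_ratio",
            "degenerate",
        ],
    )


def _scale_features(x: np.ndarray, scaling: str) -> np.ndarray:
    if scaling == "minmax":
        span = x.max(axis=0) - x.min(axis=0)
        span[span == 0] = 1.0
        return (x - x.min(axis=0)) / span
    if scaling == "zscore":
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        return (x - x.mean(axis=0)) / sd
    raise ValueError(f"unknown scaling {scaling!r}")


def classify_conditions(
    records: pd.DataFrame, k: int = 3, scaling: str = "minmax"
) -> pd.DataFrame:
    """Cluster conditions into fluidity classes (regions I/II/III).

    ``records`` needs columns ``mean_aspect_ratio`` and
    ``mean_mobile_fraction``; rows with a ``detected`` column set to False
    are passed through with cluster ``"no condensates"``.  Features are
    min-max scaled to [0, 1] (``scaling="zscore"`` available), clustered
    by complete-linkage on Euclidean distances, and the tree cut at ``k``
    clusters.  Clusters are mapped to regions I..k in order of decreasing
    mean mobile fraction, ties broken by increasing mean aspect ratio.
    Degenerate inputs (all rows identical) collapse to a single cluster,
    which maps to region I.

    Returns a copy of ``records`` with a ``cluster`` column.

    Raises
    ------
    ValueError
        If fewer than ``k`` detected records are available.
    """
    out = records.copy()
    out["cluster"] = "no condensates"
    detected = (
        out["detected"].to_numpy(dtype=bool)
        if "detected" in out.columns
        else np.ones(len(out), dtype=bool)
    )
    sub = out.loc[detected]
    if len(sub) < k:
        raise ValueError(f"need >= {k} detected records, got {len(sub)}")
    feats = sub[["mean_aspect_ratio", "mean_mobile_fraction"]].to_numpy(dtype=float)
    scaled = _scale_features(feats, scaling)
    if np.allclose(scaled, scaled[0]):
        labels = np.ones(len(sub), dtype=int)
    else:
        z = linkage(scaled, method="complete", metric="euclidean")
        labels = fcluster(z, t=k, criterion="maxclust")
    # order clusters: decreasing mean mobile fraction, then increasing AR
    order = sorted(
        np.unique(labels),
        key=lambda lab: (
            -feats[labels == lab, 1].mean(),
            feats[labels == lab, 0].mean(),
        ),
    )
    roman = ["I", "II", "III", "IV", "V", "VI"]
    mapping = {lab: roman[i] for i, lab in enumerate(order)}
    out.loc[detected, "cluster"] = [mapping[lab] for lab in labels]
    return out


def annotate_phase_diagram(records: pd.DataFrame) -> pd.DataFrame:
    """Tidy phase-diagram table with one row per condition.

    Adds the plotting glyph for each cluster (circle/triangle/square for
    regions I/II/III, diamond for cells without visible condensates) so
    the table can be rendered directly as a phase-diagram figure.  An
    empty input yields an empty table.
    """
    cols = [
        "dna_length_bp",
        "dna_concentration",
        "detected",
        "cluster",
        "mean_aspect_ratio",
        "mean_mobile_fraction",
        "glyph",
    ]
    if len(records) == 0:
        return pd.DataFrame(columns=cols)
    out = records.copy()
    if "cluster" not in out.columns:
        out = classify_conditions(out)
    if "detected" not in out.columns:
        out["detected"] = True
    out["glyph"] = [
        REGION_GLYPHS.get(c, "diamond") for c in out["cluster"]
    ]
    keep = [c for c in cols if c in out.columns]
    if "truth_region" in out.columns:  # pass generator truth through untouched
        keep.append("truth_region")
    return out[keep].sort_values(
        ["dna_length_bp", "dna_concentration"], kind="mergesort"
    ).reset_index(drop=True)
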