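"""Histogram thresholding and SAN mask extraction.

Multi-Otsu thresholding maximizes the between-class variance of a binned
intensity histogram over all ordered threshold tuples; with N = 3 thresholds
it divides a trichrome blue-channel image into background, myocardium, SAN
and epicardial fibrotic layer. On relaxation-time maps the signal-free
background is pre-masked (invalid pixels) and the SAN threshold can also be
set by the relative-elevation rule (about 20% above the mean myocardium
T_RAFF2, 15% for T1rho).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import block_reduce

from .errors import DegenerateInputError
from .phantom import LabelMap
from .relaxometry import ParameterMap
from .tissues import Tissue

__all__ = [
    "ThresholdSet",
    "SanThresholdRule",
    "Segmentation3D",
    "multi_otsu",
    "classify",
    "blue_channel_fibrosis",
    "derive_san_threshold",
    "segment_3d",
    "region_area",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Ascending thresholds plus the maximized between-class variance."""

    thresholds: tuple[float, ...]
    objective: float
    n_bins: int
    hist_range: tuple[float, float]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly ascending")


@dataclass(frozen=True)
class SanThresholdRule:
    """SAN threshold as a relative elevation over the myocardium mean."""

    fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.fraction < 0:
            raise ValueError("fraction must be >= 0")

    def threshold(self, myocardium_mean: float) -> float:
        return myocardium_mean * (1.0 + self.fraction)


def _segment_scores(counts: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """A[a, b] = m^2 / w of the bin range [a, b) for all cut pairs, where w is
    the probability mass and m the first moment; empty ranges score 0.
    Between-class variance of a partition is the sum of its segment scores
    minus the squared global mean."""
    w = np.concatenate([[0.0], np.cumsum(counts)])
    m = np.concatenate([[0.0], np.cumsum(counts * centers)])
    W = w[None, :] - w[:, None]
    M = m[None, :] - m[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(W > 0, M**2 / np.where(W > 0, W, 1.0), 0.0)
    return A


def multi_otsu(
    values: np.ndarray,
    n_thresholds: int = 3,
    n_bins: int = 256,
    hist_range: tuple[float, float] | None = None,
) -> ThresholdSet:
    """Thresholds maximizing between-class variance, by exhaustive search.

    The histogram uses ``n_bins`` over ``hist_range`` (valid-value min-max by
    default). Every ordered tuple of interior bin edges is scored; ties are
    broken by the lexicographically smallest tuple, so the result is
    deterministic and exactly equal to brute-force enumeration.
    """
    v = np.asarray(values, float).ravel()
    v = v[np.isfinite(v)]
    if n_thresholds not in (1, 2, 3):
        raise ValueError("n_thresholds must be 1, 2 or 3")
    if np.unique(v).size < n_thresholds + 1:
        raise DegenerateInputError(
            f"need more than {n_thresholds} distinct values to place "
            f"{n_thresholds} thresholds"
        )
    rng = (float(v.min()), float(v.max())) if hist_range is None else hist_range
    if rng[1] <= rng[0]:
        raise DegenerateInputError("histogram range is empty")
    counts, edges = np.histogram(v, bins=n_bins, range=rng)
    p = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    A = _segment_scores(p, centers)

    B = n_bins
    cuts = np.arange(1, B)  # interior edge indices
    k = n_thresholds

    def _lex_argmax(T: np.ndarray) -> tuple:
        """First (row-major, hence lexicographically smallest) index whose
        objective ties the maximum; exact ties arise whenever a cut slides
        across empty bins, so equality is tested with a small tolerance."""
        tmax = float(T.max())
        tol = 1e-9 * max(1.0, abs(tmax))
        flat = int(np.argmax(T.ravel() >= tmax - tol))
        return np.unravel_index(flat, T.shape), tmax

    if k == 1:
        T = A[0, cuts] + A[cuts, B]
        (a,), obj = _lex_argmax(T)
        best = (cuts[a],)
        obj = float(T[a])
    elif k == 2:
        T = A[0, cuts][:, None] + A[np.ix_(cuts, cuts)] + A[cuts, B][None, :]
        T = np.where(cuts[:, None] < cuts[None, :], T, -np.inf)
        (a, b), _ = _lex_argmax(T)
        best = (cuts[a], cuts[b])
        obj = float(T[a, b])
    else:
        T = (
            A[0, cuts][:, None, None]
            + A[np.ix_(cuts, cuts)][:, :, None]
            + A[np.ix_(cuts, cuts)][None, :, :]
            + A[cuts, B][None, None, :]
        )
        i = cuts[:, None, None]
        j = cuts[None, :, None]
        kk = cuts[None, None, :]
        T = np.where((i < j) & (j < kk), T, -np.inf)
        (a, b, c), _ = _lex_argmax(T)
        best = (cuts[a], cuts[b], cuts[c])
        obj = float(T[a, b, c])

    mu = float((p * centers).sum())
    return ThresholdSet(
        thresholds=tuple(float(edges[c]) for c in best),
        objective=obj - mu**2,
        n_bins=n_bins,
        hist_range=rng,
    )


def classify(
    values: np.ndarray | ParameterMap,
    thresholds: ThresholdSet | tuple[float, ...],
    class_order: tuple[Tissue, ...],
    spacing_mm: float | None = None,
) -> LabelMap:
    """Bin pixels into ordered intervals and name them.

    A value equal to a threshold joins the upper interval. ``class_order``
    maps intervals (ascending value) to semantic classes — ascending
    relaxation time for maps (myocardium < SAN <= epicardial layer),
    ascending blue intensity for histology. Invalid pixels of a ParameterMap
    become background.
    """
    thr = thresholds.thresholds if isinstance(thresholds, ThresholdSet) else tuple(thresholds)
    if len(class_order) != len(thr) + 1:
        raise ValueError("class_order must have one entry per interval")
    if len(set(int(c) for c in class_order)) != len(class_order):
        raise ValueError("class_order entries must be distinct classes")
    if isinstance(values, ParameterMap):
        arr = values.values
        valid = values.valid
        spacing_mm = spacing_mm or values.spacing_mm
    else:
        arr = np.asarray(values, float)
        valid = np.ones(arr.shape, bool)
    idx = np.digitize(arr, thr)  # right-open bins: value == t -> upper interval
    lut = np.array([int(c) for c in class_order], dtype=np.int16)
    labels = lut[idx]
    labels[~valid] = int(Tissue.BACKGROUND)
    return LabelMap(labels, spacing_mm if spacing_mm is not None else 1.0)


def blue_channel_fibrosis(
    rgb: np.ndarray, spacing_um: float, target_um: float = 200.0
) -> tuple[np.ndarray, float]:
    """Blue channel of an RGB section, block-averaged to ~200 um resolution.

    The block size is the largest integer factor keeping the output pitch at
    or below ``target_um``; returns (image, output spacing in um). Input at
    the target pitch passes through unchanged.
    """
    img = np.asarray(rgb)
    if img.ndim != 3 or img.shape[-1] < 3:
        raise ValueError("expected an RGB image (rows, cols, 3)")
    if spacing_um > target_um:
        raise ValueError("input spacing is coarser than the target resolution")
    blue = img[..., 2].astype(float)
    f = int(target_um // spacing_um)
    if f <= 1:
        return blue, spacing_um
    r, c = (blue.shape[0] // f) * f, (blue.shape[1] // f) * f
    out = block_reduce(blue[:r, :c], (f, f), np.mean)
    return out, spacing_um * f


def derive_san_threshold(
    pmap: ParameterMap,
    myocardium_mask: np.ndarray,
    rule: SanThresholdRule = SanThresholdRule(0.20),
) -> float:
    """SAN threshold = mean of valid myocardium pixels x (1 + fraction)."""
    m = np.asarray(myocardium_mask, bool)
    if not (m & pmap.valid).any():
        raise DegenerateInputError("myocardium mask has no valid pixels")
    return rule.threshold(pmap.region_mean(m))


@dataclass
class Segmentation3D:
    """Thresholded 3D SAN mask plus per-structure relaxation-time histograms."""

    san_mask: np.ndarray  # (rows, cols, slices) bool
    threshold: float
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (counts, edges)


def segment_3d(
    maps: list[ParameterMap],
    threshold: float,
    structure_masks: dict[str, np.ndarray] | None = None,
    n_bins: int = 64,
) -> Segmentation3D:
    """Stack 2D maps into a volume and extract the supra-threshold SAN mask.

    Valid pixels at or above the threshold form the candidate mask; only the
    largest 26-connected component is kept (emulating the manual cropping of
    the region of interest). Optional structure masks yield per-structure
    histograms of the map values.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 slices")
    shape = maps[0].values.shape
    if any(m.values.shape != shape for m in maps):
        raise ValueError("slices have inconsistent shapes")
    vol = np.stack([m.values for m in maps], axis=-1)
    valid = np.stack([m.valid for m in maps], axis=-1)
    cand = valid & (vol >= threshold)
    if cand.any():
        lab, n = ndimage.label(cand, structure=np.ones((3, 3, 3), int))
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        keep = 1 + int(np.argmax(sizes))
        san = lab == keep
    else:
        san = cand
    hists: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if structure_masks:
        for name, m in structure_masks.items():
            vals = vol[np.asarray(m, bool) & valid]
            counts, edges = np.histogram(vals, bins=n_bins)
            hists[name] = (counts, edges)
    return Segmentation3D(san_mask=san, threshold=threshold, histograms=hists)


def region_area(
    labels: LabelMap | np.ndarray, cls: Tissue | int, pixel_area_mm2: float | None = None
) -> float:
    """Area of a labeled class in mm^2 (pixel count x pixel area)."""
    if isinstance(labels, LabelMap):
        arr = labels.labels
        if pixel_area_mm2 is None:
            pixel_area_mm2 = labels.pixel_area_mm2
    else:
        arr = np.asarray(labels)
        if pixel_area_mm2 is None:
            raise ValueError("pixel_area_mm2 required for a bare label array")
    return float(np.count_nonzero(arr == int(cls)) * pixel_area_mm2)
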