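"""Digital phantom: geometry, acquisition protocols, weighted-image simulation
and matched synthetic histology.

The phantom emulates an ex vivo right-atrial tissue block immersed in
perfluoropolyether (signal-free background): a rectangular slab of myocardium
with an epicardial fibrotic band along one edge and an ellipsoidal SAN just
beneath it. Weighted-image series follow the mono-exponential signal models
used in the analysis (S(t) = S0 exp(-t/T) for RAFF2 / T1rho / T2, magnitude
inversion recovery or saturation recovery for T1, a two-frame
saturated/reference pair for magnetization transfer), with Rician noise as
appropriate for magnitude MRI data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .errors import GeometryError, ProtocolError
from .tissues import (
    FIBROSIS_FRACTIONS,
    Tissue,
    TissueParams,
    tissue_table,
)

__all__ = [
    "Contrast",
    "AcquisitionProtocol",
    "PhantomGeometry",
    "LabelMap",
    "WeightedSeries",
    "HistologySynth",
    "raff2_pulse_duration",
    "default_protocols",
    "build_phantom",
    "simulate_series",
    "add_rician_noise",
    "render_histology",
    "jitter_geometry",
]


class Contrast(str, Enum):
    RAFF2 = "RAFF2"
    T1RHO = "T1RHO"
    T2 = "T2"
    T1_IR = "T1_IR"  # magnitude inversion recovery
    T1_SR = "T1_SR"  # saturation recovery
    MT = "MT"

    @property
    def is_exponential(self) -> bool:
        return self in (Contrast.RAFF2, Contrast.T1RHO, Contrast.T2)


#: tissue-table attribute holding the governing time constant per contrast
CONTRAST_PARAM = {
    Contrast.RAFF2: "t_raff2",
    Contrast.T1RHO: "t1rho",
    Contrast.T2: "t2",
    Contrast.T1_IR: "t1",
    Contrast.T1_SR: "t1",
    Contrast.MT: "mtr",
}


@dataclass(frozen=True)
class AcquisitionProtocol:
    """One contrast-weighting scheme.

    ``times_ms`` are the per-frame weighting times (pulse-train duration,
    spin-lock time, echo time or inversion/saturation time). For MT the two
    entries are instead the off-resonance offsets in Hz, stored ascending:
    the smaller offset is the saturated frame, the larger the reference.
    """

    contrast: Contrast
    times_ms: tuple[float, ...]
    rf_amplitude_hz: float | None = None
    pulse_duration_ms: float | None = None  # RAFF2 only
    pulse_counts: tuple[int, ...] | None = None  # RAFF2 only

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ProtocolError("protocol needs at least 2 weighting times")
        if np.any(t < 0):
            raise ProtocolError("weighting times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ProtocolError("weighting times must be strictly increasing")
        if self.contrast is Contrast.MT and t.size != 2:
            raise ProtocolError("MT protocol must have exactly 2 frames")
        if self.contrast is Contrast.RAFF2 and self.pulse_counts is not None:
            if self.pulse_duration_ms is None:
                raise ProtocolError("RAFF2 pulse counts given without pulse duration")
            expect = np.asarray(self.pulse_counts, float) * self.pulse_duration_ms
            if not np.allclose(expect, t, rtol=1e-9, atol=1e-9):
                raise ProtocolError(
                    "RAFF2 weighting times must equal pulse_count x pulse duration"
                )

    @property
    def n_frames(self) -> int:
        return len(self.times_ms)


def raff2_pulse_duration(rf_amplitude_hz: float, elements: int = 2) -> float:
    """Duration in ms of a RAFF2 pulse unit at a given nominal RF amplitude.

    Each sine/cosine-modulated RAFF2 element lasts sqrt(2)/gamma_B1; the
    published timings quote either a single element or a back-to-back pair,
    so ``elements`` selects the convention (2.26 ms = 2*sqrt(2)/1250 Hz,
    2.83 ms = sqrt(2)/500 Hz).
    """
    if rf_amplitude_hz <= 0:
        raise ProtocolError("RF amplitude must be positive")
    if elements not in (1, 2):
        raise ProtocolError("elements must be 1 or 2")
    return 1000.0 * elements * math.sqrt(2.0) / rf_amplitude_hz


def _times_from_counts(counts: tuple[int, ...], dur_ms: float) -> tuple[float, ...]:
    return tuple(round(c * dur_ms, 10) for c in counts)


def default_protocols(field: str = "7T") -> dict[Contrast, AcquisitionProtocol]:
    """Acquisition protocols replicating the published 7 T / 3 T sessions.

    7 T: RAFF2 pulse trains of 0/8/16/32 pulses of 2.26 ms at 1250 Hz; four
    spin-lock times 0-60 ms; TE 11/22/33/44 ms; five inversion times
    log-spaced in 100-1200 ms; MT offsets 1500 (saturated) / 20000 Hz
    (reference) at 425 Hz.

    3 T: pulse trains of 0/8/16/24/32 pulses of 2.82 ms at 500 Hz; five
    spin-lock times 0-60 ms; TE 10-50 ms in steps of 10; six saturation times
    spanning 200-3900 ms; MT offsets 1000 / 50000 Hz at 500 Hz.
    """
    field = field.upper()
    if field == "7T":
        counts = (0, 8, 16, 32)
        dur = 2.26
        return {
            Contrast.RAFF2: AcquisitionProtocol(
                Contrast.RAFF2, _times_from_counts(counts, dur), 1250.0, dur, counts
            ),
            Contrast.T1RHO: AcquisitionProtocol(
                Contrast.T1RHO, (0.0, 20.0, 40.0, 60.0), 1250.0
            ),
            Contrast.T2: AcquisitionProtocol(Contrast.T2, (11.0, 22.0, 33.0, 44.0)),
            Contrast.T1_IR: AcquisitionProtocol(
                Contrast.T1_IR,
                tuple(np.round(np.geomspace(100.0, 1200.0, 5), 3)),
            ),
            Contrast.MT: AcquisitionProtocol(Contrast.MT, (1500.0, 20000.0), 425.0),
        }
    if field == "3T":
        counts = (0, 8, 16, 24, 32)
        dur = 2.82
        return {
            Contrast.RAFF2: AcquisitionProtocol(
                Contrast.RAFF2, _times_from_counts(counts, dur), 500.0, dur, counts
            ),
            Contrast.T1RHO: AcquisitionProtocol(
                Contrast.T1RHO, (0.0, 15.0, 30.0, 45.0, 60.0), 500.0
            ),
            Contrast.T2: AcquisitionProtocol(
                Contrast.T2, (10.0, 20.0, 30.0, 40.0, 50.0)
            ),
            Contrast.T1_SR: AcquisitionProtocol(
                Contrast.T1_SR, tuple(np.round(np.linspace(200.0, 3900.0, 6), 3))
            ),
            Contrast.MT: AcquisitionProtocol(Contrast.MT, (1000.0, 50000.0), 500.0),
        }
    raise ValueError(f"unknown field strength {field!r}; expected '7T' or '3T'")


@dataclass(frozen=True)
class PhantomGeometry:
    """Geometry of the tissue-block phantom.

    All lengths in mm. ``shape`` is (rows, cols) or (rows, cols, slices);
    pixel centers sit at (i + 0.5) * spacing. The SAN is an ellipse
    (ellipsoid in 3D) with full minor axis ``san_thickness_mm`` (rows), full
    major axis ``san_length_mm`` (cols) and, in 3D, full depth
    ``san_depth_mm`` across slices, optionally tilted in-plane.
    """

    shape: tuple[int, ...] = (64, 64)
    spacing_mm: float = 15.0 / 64.0  # 234 um, 15 mm FOV over a 64 matrix
    slice_thickness_mm: float = 2.0
    margin_mm: float = 1.2  # background (Fomblin) border around the block
    epi_thickness_mm: float = 0.7  # epicardial fibrotic band along the top edge
    san_center_mm: tuple[float, float] = (3.8, 7.5)  # (row, col)
    san_thickness_mm: float = 2.5
    san_length_mm: float = 12.0
    san_depth_mm: float = 8.0
    san_tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if len(self.shape) not in (2, 3) or any(n <= 0 for n in self.shape):
            raise GeometryError("shape must be a positive (rows, cols[, slices])")
        if self.spacing_mm <= 0 or self.slice_thickness_mm <= 0:
            raise GeometryError("spacings must be positive")
        if self.san_thickness_mm < 0 or self.san_length_mm < 0:
            raise GeometryError("SAN axes must be non-negative")

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_mm**2

    @property
    def is_3d(self) -> bool:
        return len(self.shape) == 3


@dataclass
class LabelMap:
    """Per-pixel tissue class on the phantom grid."""

    labels: np.ndarray  # integer array, values from Tissue
    spacing_mm: float
    slice_thickness_mm: float | None = None

    def mask(self, cls: Tissue) -> np.ndarray:
        return self.labels == int(cls)

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_mm**2


@dataclass
class WeightedSeries:
    """A stack of co-registered magnitude images, one frame per weighting time."""

    images: np.ndarray  # (n_frames, *grid), magnitudes >= 0
    protocol: AcquisitionProtocol
    sigma: float = 0.0
    seed: int | None = None
    spacing_mm: float = 15.0 / 64.0

    def __post_init__(self) -> None:
        if self.images.shape[0] != self.protocol.n_frames:
            raise ProtocolError(
                f"series has {self.images.shape[0]} frames but protocol lists "
                f"{self.protocol.n_frames} weighting times"
            )
        if np.any(self.images < 0):
            raise ValueError("magnitude images must be non-negative")

    @property
    def times_ms(self) -> np.ndarray:
        return np.asarray(self.protocol.times_ms, float)


@dataclass
class HistologySynth:
    """Synthetic trichrome-stained section matched to a LabelMap.

    Collagen-rich tissue renders blue, myocytes red; the blue-channel mean of
    each class increases with its fibrosis fraction.
    """

    rgb: np.ndarray  # (rows, cols, 3) uint8
    spacing_um: float
    fractions: dict[Tissue, float]
    seed: int | None = None


def _pixel_centers(n: int, spacing: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * spacing


def build_phantom(geometry: PhantomGeometry | None = None, seed: int = 0) -> LabelMap:
    """Rasterize the four-class phantom onto the pixel grid.

    The grid is tiled by background, myocardium, SAN and epicardial layer
    (disjoint, exhaustive). A SAN ellipse that would leave the tissue block
    raises :class:`GeometryError`. Deterministic; ``seed`` is accepted for
    interface symmetry with the stochastic stages.
    """
    geom = geometry or PhantomGeometry()
    rows, cols = geom.shape[:2]
    sp = geom.spacing_mm
    y = _pixel_centers(rows, sp)[:, None]
    x = _pixel_centers(cols, sp)[None, :]
    h, w = rows * sp, cols * sp

    tissue = (
        (y >= geom.margin_mm)
        & (y <= h - geom.margin_mm)
        & (x >= geom.margin_mm)
        & (x <= w - geom.margin_mm)
    )
    if not tissue.any():
        raise GeometryError("margins leave no tissue on the grid")

    epi_rows = max(1, int(round(geom.epi_thickness_mm / sp)))
    tissue_rows = np.where(tissue.any(axis=1))[0]
    epi = np.zeros_like(tissue)
    epi[tissue_rows[:epi_rows], :] = True
    epi &= tissue

    a = geom.san_thickness_mm / 2.0  # row semi-axis
    b = geom.san_length_mm / 2.0  # col semi-axis
    cy, cx = geom.san_center_mm
    if a > 0 and b > 0:
        th = math.radians(geom.san_tilt_deg)
        dy, dx = y - cy, x - cx
        u = math.cos(th) * dy + math.sin(th) * dx
        v = -math.sin(th) * dy + math.cos(th) * dx
        san2d = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        # the analytic ellipse must fit inside the tissue block
        ext = max(a * abs(math.cos(th)) + b * abs(math.sin(th)), a)
        extx = max(b * abs(math.cos(th)) + a * abs(math.sin(th)), b)
        if (
            cy - ext < geom.margin_mm
            or cy + ext > h - geom.margin_mm
            or cx - extx < geom.margin_mm
            or cx + extx > w - geom.margin_mm
        ):
            raise GeometryError("SAN ellipse exceeds the tissue extent")
    else:
        san2d = np.zeros_like(tissue)
    san2d &= tissue & ~epi

    if geom.is_3d:
        nsl = geom.shape[2]
        z = _pixel_centers(nsl, geom.slice_thickness_mm)
        cz = nsl * geom.slice_thickness_mm / 2.0
        c = geom.san_depth_mm / 2.0
        labels = np.full(geom.shape, int(Tissue.BACKGROUND), dtype=np.int16)
        for k in range(nsl):
            labels_k = np.full((rows, cols), int(Tissue.BACKGROUND), np.int16)
            labels_k[tissue] = int(Tissue.MYOCARDIUM)
            labels_k[epi] = int(Tissue.EPICARDIUM)
            if c > 0 and a > 0 and b > 0:
                f = 1.0 - ((z[k] - cz) / c) ** 2
                if f > 0:
                    s = math.sqrt(f)  # in-plane axes shrink away from the equator
                    dy, dx = y - cy, x - cx
                    th = math.radians(geom.san_tilt_deg)
                    u = math.cos(th) * dy + math.sin(th) * dx
                    v = -math.sin(th) * dy + math.cos(th) * dx
                    sk = (u / (a * s)) ** 2 + (v / (b * s)) ** 2 <= 1.0
                    labels_k[sk & tissue & ~epi] = int(Tissue.SAN)
            labels[:, :, k] = labels_k
        return LabelMap(labels, sp, geom.slice_thickness_mm)

    labels = np.full((rows, cols), int(Tissue.BACKGROUND), dtype=np.int16)
    labels[tissue] = int(Tissue.MYOCARDIUM)
    labels[epi] = int(Tissue.EPICARDIUM)
    labels[san2d] = int(Tissue.SAN)
    return LabelMap(labels, sp)


def add_rician_noise(
    image: np.ndarray, sigma: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Magnitude-MRI (Rician) noise: sqrt((x + n1)^2 + n2^2) with n1, n2
    independent zero-mean Gaussians of scale ``sigma``."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    x = np.asarray(image, float)
    if sigma == 0:
        return x.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, x.shape)
    n2 = rng.normal(0.0, sigma, x.shape)
    return np.hypot(x + n1, n2)


def _noiseless_frames(
    labels: LabelMap,
    params: dict[Tissue, TissueParams],
    protocol: AcquisitionProtocol,
) -> np.ndarray:
    present = np.unique(labels.labels)
    for cls in present:
        if Tissue(int(cls)) not in params:
            raise ValueError(f"no tissue parameters for class {Tissue(int(cls)).name}")
    t = np.asarray(protocol.times_ms, float)
    frames = np.zeros((t.size,) + labels.labels.shape, float)
    for cls in present:
        p = params[Tissue(int(cls))]
        m = labels.labels == cls
        if protocol.contrast is Contrast.MT:
            vals = np.array([p.s0 * (1.0 - p.mtr / 100.0), p.s0])  # saturated, reference
        else:
            T = getattr(p, CONTRAST_PARAM[protocol.contrast])
            if protocol.contrast is Contrast.T1_IR:
                vals = p.s0 * np.abs(1.0 - 2.0 * np.exp(-t / T))
            elif protocol.contrast is Contrast.T1_SR:
                vals = p.s0 * (1.0 - np.exp(-t / T))
            else:
                vals = p.s0 * np.exp(-t / T)
        frames[:, m] = vals[:, None]
    return frames


def simulate_series(
    labels: LabelMap,
    params: dict[Tissue, TissueParams],
    protocol: AcquisitionProtocol,
    sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> WeightedSeries:
    """Simulate one weighted-image series on a label grid.

    Noiseless pixel values follow the per-contrast signal model evaluated at
    the class parameters; Rician noise of scale ``sigma`` is then applied
    frame-wise (``sigma = 0`` reproduces the model exactly).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    frames = _noiseless_frames(labels, params, protocol)
    if sigma > 0:
        frames = add_rician_noise(frames, sigma, seed)
    return WeightedSeries(
        frames,
        protocol,
        sigma=sigma,
        seed=seed if isinstance(seed, int) else None,
        spacing_mm=labels.spacing_mm,
    )


def render_histology(
    labels: LabelMap,
    fractions: dict[Tissue, float] | None = None,
    spacing_um: float = 46.875,
    seed: int | np.random.Generator = 0,
    texture_sd: float = 8.0,
) -> HistologySynth:
    """Render a synthetic trichrome RGB section from a 2D LabelMap.

    The label grid is upsampled by an integer factor to ``spacing_um``
    (which must divide the MRI pixel pitch and be <= 200 um); the blue
    channel encodes each class's fibrosis fraction (0.74 for the swine SAN by
    default), the red channel the myocyte content, with seeded Gaussian
    texture noise.
    """
    if labels.labels.ndim != 2:
        raise ValueError("histology rendering expects a 2D LabelMap")
    fr = dict(FIBROSIS_FRACTIONS if fractions is None else fractions)
    for cls, f in fr.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fibrosis fraction for {Tissue(cls).name} outside [0, 1]")
    if spacing_um > 200.0:
        raise ValueError("histology spacing must be <= 200 um")
    mri_um = labels.spacing_mm * 1000.0
    factor = mri_um / spacing_um
    if abs(factor - round(factor)) > 1e-6 or round(factor) < 1:
        raise ValueError(
            f"spacing_um must integer-divide the MRI pitch ({mri_um:.3f} um)"
        )
    factor = int(round(factor))
    up = np.kron(labels.labels, np.ones((factor, factor), dtype=np.int16))

    blue = np.zeros(up.shape, float)
    red = np.zeros(up.shape, float)
    tissue = up != int(Tissue.BACKGROUND)
    for cls, f in fr.items():
        m = up == int(cls)
        blue[m] = 255.0 * f
        red[m] = 255.0 * (1.0 - f)
    red[~tissue] = 0.0  # slide background stays dark

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if texture_sd > 0:
        blue = blue + rng.normal(0.0, texture_sd, blue.shape) * tissue
        red = red + rng.normal(0.0, texture_sd, red.shape) * tissue
    green = np.full(up.shape, 10.0) * tissue

    rgb = np.stack(
        [np.clip(red, 0, 255), np.clip(green, 0, 255), np.clip(blue, 0, 255)], axis=-1
    ).astype(np.uint8)
    return HistologySynth(
        rgb, spacing_um, fr, seed=seed if isinstance(seed, int) else None
    )


def jitter_geometry(
    geom: PhantomGeometry, rng: np.random.Generator
) -> PhantomGeometry:
    """Draw one heart's SAN geometry: thickness uniform in the anatomical
    2-3 mm range, length uniform in 10-12.2 mm (the anatomical 10-20 mm range
    truncated to what the 15 mm field of view can hold)."""
    return replace(
        geom,
        san_thickness_mm=float(rng.uniform(2.0, 3.0)),
        san_length_mm=float(rng.uniform(10.0, 12.2)),
    )
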