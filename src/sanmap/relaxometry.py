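"""Pixel-wise relaxometry: mono-exponential, T1 and MTR map estimation plus
B0/B1 field-map quality control.

The relaxation fits use a two-parameter model per pixel — S(t) = S0 f(t; T)
with f = exp(-t/T) (RAFF2, T1rho, T2), |1 - 2 exp(-TI/T1)| (magnitude
inversion recovery) or 1 - exp(-TI/T1) (saturation recovery) — initialized
from a log-linear regression (exponential decay) or a multi-start grid (T1
models, whose magnitude form has a sign ambiguity) and refined with a
bounded Levenberg-Marquardt iteration vectorized over pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ProtocolError
from .phantom import Contrast, WeightedSeries

__all__ = [
    "ParameterMap",
    "FitConfig",
    "QCReport",
    "fit_monoexp",
    "fit_t1",
    "compute_mtr",
    "fit_b1_cosine",
    "b0_from_phase",
    "qc_field_maps",
    "wrap_phase",
]


@dataclass
class ParameterMap:
    """Per-pixel fitted quantity with diagnostics.

    ``values`` holds the relaxation time (ms), MTR (percent), off-resonance
    (Hz) or relative B1 amplitude; invalid pixels carry NaN-safe placeholder
    values and must be excluded via ``valid`` in all downstream statistics.
    """

    values: np.ndarray
    valid: np.ndarray  # boolean mask
    s0: np.ndarray | None = None
    r_squared: np.ndarray | None = None
    units: str = "ms"
    name: str = ""
    spacing_mm: float | None = None

    def masked(self) -> np.ndarray:
        """Values with invalid pixels set to NaN."""
        out = np.where(self.valid, self.values, np.nan)
        return out

    def region_mean(self, mask: np.ndarray) -> float:
        m = mask & self.valid
        if not m.any():
            raise DegenerateInputError("no valid pixels in region")
        return float(self.values[m].mean())


@dataclass
class FitConfig:
    """Controls for the pixel-wise fits."""

    t_bounds: tuple[float, float] = (1.0, 10000.0)  # ms
    tol: float = 1e-8
    max_iter: int = 200
    min_signal_rel: float = 1e-6  # x max signal, absolute floor
    snr_floor: float = 3.0  # x sigma, noise floor for validity
    min_r_squared: float = 0.5
    t1_grid_size: int = 64  # multi-start grid for T1 models

    def __post_init__(self) -> None:
        if self.t_bounds[0] >= self.t_bounds[1]:
            raise ValueError("t_bounds must be ordered")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


def _model(kind: str, t: np.ndarray, s0: np.ndarray, T: np.ndarray):
    """Model values and Jacobian columns, broadcast over pixels.

    t: (nf,), s0/T: (np,), returns f: (np, nf), d/ds0: (np, nf), d/dT: (np, nf).
    """
    e = np.exp(-t[None, :] / T[:, None])
    tt2 = t[None, :] / T[:, None] ** 2
    if kind == "monoexp":
        g = e
        dT = s0[:, None] * tt2 * e
    elif kind == "saturation":
        g = 1.0 - e
        dT = -s0[:, None] * tt2 * e
    elif kind == "ir_magnitude":
        m = 1.0 - 2.0 * e
        g = np.abs(m)
        dT = s0[:, None] * np.sign(m) * (-2.0 * tt2 * e)
    else:  # pragma: no cover
        raise ValueError(kind)
    return s0[:, None] * g, g, dT


def _lm_refine(kind, t, S, s0, T, cfg: FitConfig):
    """Bounded Levenberg-Marquardt on (s0, T), vectorized over pixels."""
    lo, hi = cfg.t_bounds
    lam = np.full(T.shape, 1e-3)
    f, ds0, dT = _model(kind, t, s0, T)
    r = S - f
    cost = (r**2).sum(axis=1)
    converged = np.zeros(T.shape, bool)
    for _ in range(cfg.max_iter):
        # normal equations, 2x2 per pixel
        a = (ds0 * ds0).sum(axis=1)
        b = (ds0 * dT).sum(axis=1)
        c = (dT * dT).sum(axis=1)
        g0 = (ds0 * r).sum(axis=1)
        g1 = (dT * r).sum(axis=1)
        A = a * (1.0 + lam)
        C = c * (1.0 + lam)
        det = A * C - b * b
        ok = det > 1e-300
        d_s0 = np.where(ok, (C * g0 - b * g1) / np.where(ok, det, 1.0), 0.0)
        d_T = np.where(ok, (A * g1 - b * g0) / np.where(ok, det, 1.0), 0.0)
        s0_new = np.maximum(s0 + d_s0, 0.0)
        T_new = np.clip(T + d_T, lo, hi)
        f_new, ds0_new, dT_new = _model(kind, t, s0_new, T_new)
        r_new = S - f_new
        cost_new = (r_new**2).sum(axis=1)
        accept = cost_new <= cost
        rel = np.abs(T_new - T) / np.maximum(np.abs(T), 1e-12) + np.abs(
            s0_new - s0
        ) / np.maximum(np.abs(s0), 1e-12)
        s0 = np.where(accept, s0_new, s0)
        T = np.where(accept, T_new, T)
        lam = np.where(accept, lam / 3.0, lam * 10.0)
        lam = np.clip(lam, 1e-12, 1e12)
        upd = accept[:, None]
        f = np.where(upd, f_new, f)
        ds0 = np.where(upd, ds0_new, ds0)
        dT = np.where(upd, dT_new, dT)
        r = np.where(upd, r_new, r)
        cost = np.where(accept, cost_new, cost)
        converged |= (accept & (rel < cfg.tol)) | (lam >= 1e10)
        if converged.all():
            break
    return s0, T, cost


def _grid_init(kind, t, S, cfg: FitConfig):
    """Variable-projection grid over T: closed-form s0 per candidate, pick the
    best; used as multi-start initialization for the T1 models."""
    lo, hi = cfg.t_bounds
    Tg = np.geomspace(lo, hi, cfg.t1_grid_size)
    best_T = np.full(S.shape[0], (lo * hi) ** 0.5)
    best_s0 = np.zeros(S.shape[0])
    best_cost = np.full(S.shape[0], np.inf)
    for T in Tg:
        _, g, _ = _model(kind, t, np.ones(1), np.array([T]))
        g = g[0]
        denom = (g * g).sum()
        if denom <= 0:
            continue
        s0 = np.maximum((S * g[None, :]).sum(axis=1) / denom, 0.0)
        cost = ((S - s0[:, None] * g[None, :]) ** 2).sum(axis=1)
        better = cost < best_cost
        best_T = np.where(better, T, best_T)
        best_s0 = np.where(better, s0, best_s0)
        best_cost = np.where(better, cost, best_cost)
    return best_s0, best_T


def _loglinear_init(t, S, cfg: FitConfig):
    """Log-linear regression ln S = ln s0 - t/T on frames above a small floor."""
    floor = cfg.min_signal_rel * max(S.max(), 1e-300)
    W = (S > floor).astype(float)
    n = W.sum(axis=1)
    logS = np.log(np.maximum(S, floor))
    sw = W.sum(axis=1)
    mt = (W * t[None, :]).sum(axis=1) / np.maximum(sw, 1)
    my = (W * logS).sum(axis=1) / np.maximum(sw, 1)
    cov = (W * (t[None, :] - mt[:, None]) * (logS - my[:, None])).sum(axis=1)
    var = (W * (t[None, :] - mt[:, None]) ** 2).sum(axis=1)
    slope = np.where((n >= 2) & (var > 0), cov / np.maximum(var, 1e-300), -1.0 / 100.0)
    slope = np.minimum(slope, -1.0 / cfg.t_bounds[1])
    T0 = np.clip(-1.0 / slope, *cfg.t_bounds)
    s0 = np.exp(my - slope * mt)
    return s0, T0


def _finalize(series, s0, T, cost, S, valid, name, cfg):
    grid = series.images.shape[1:]
    ss_tot = ((S - S.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - cost / np.where(ss_tot > 0, ss_tot, np.nan)
    r2 = np.where(np.isfinite(r2), r2, 0.0)
    valid = valid & (r2 >= cfg.min_r_squared)
    vmap = np.zeros(grid)
    smap = np.zeros(grid)
    rmap = np.zeros(grid)
    mmap = np.zeros(grid, bool)
    vmap.reshape(-1)[:] = T
    smap.reshape(-1)[:] = s0
    rmap.reshape(-1)[:] = np.clip(r2, 0.0, 1.0)
    mmap.reshape(-1)[:] = valid
    return ParameterMap(
        vmap, mmap, s0=smap, r_squared=rmap, units="ms", name=name,
        spacing_mm=series.spacing_mm,
    )


def _validity_floor(series: WeightedSeries, S: np.ndarray, cfg: FitConfig):
    """A pixel is valid only if every frame clears both the relative floor and
    the noise floor (suppresses the signal-free Fomblin background)."""
    floor = max(cfg.snr_floor * series.sigma, cfg.min_signal_rel * S.max())
    return (S > floor).all(axis=1)


def fit_monoexp(series: WeightedSeries, config: FitConfig | None = None) -> ParameterMap:
    """Fit S(t) = S0 exp(-t/T) pixel-by-pixel (RAFF2, T1rho, T2 series)."""
    cfg = config or FitConfig()
    t = series.times_ms
    if len(np.unique(t)) < 2:
        raise ProtocolError("need at least 2 distinct weighting times")
    S = series.images.reshape(series.images.shape[0], -1).T.astype(float)
    valid = _validity_floor(series, S, cfg)
    s0, T0 = _loglinear_init(t, S, cfg)
    s0, T, cost = _lm_refine("monoexp", t, S, s0, np.clip(T0, *cfg.t_bounds), cfg)
    name = series.protocol.contrast.value if series.protocol else "T"
    return _finalize(series, s0, T, cost, S, valid, name, cfg)


def fit_t1(
    series: WeightedSeries,
    model: str = "ir_magnitude",
    config: FitConfig | None = None,
) -> ParameterMap:
    """Fit a T1 map from inversion-recovery magnitude or saturation-recovery data.

    ``ir_magnitude`` fits S0 |1 - 2 exp(-TI/T1)| (>= 3 frames); ``saturation``
    fits S0 (1 - exp(-TI/T1)) (>= 2 frames). Initialization is a multi-start
    grid over T1 to step over the magnitude model's sign ambiguity.
    """
    if model not in ("ir_magnitude", "saturation"):
        raise ValueError(f"unknown T1 model {model!r}")
    cfg = config or FitConfig()
    t = series.times_ms
    min_frames = 3 if model == "ir_magnitude" else 2
    if len(np.unique(t)) < min_frames:
        raise ProtocolError(f"{model} fit needs >= {min_frames} distinct times")
    S = series.images.reshape(series.images.shape[0], -1).T.astype(float)
    # IR/SR data legitimately pass near zero at the null, so validity is gated
    # on the strongest frame only; doubling the noise floor compensates for
    # the weaker test (a max over Rayleigh draws clears 3 sigma far more
    # often than every frame of a decay does).
    floor = max(2.0 * cfg.snr_floor * series.sigma, cfg.min_signal_rel * S.max())
    valid = S.max(axis=1) > floor
    s0, T0 = _grid_init(model, t, S, cfg)
    s0, T, cost = _lm_refine(model, t, S, s0, T0, cfg)
    return _finalize(series, s0, T, cost, S, valid, "T1", cfg)


def compute_mtr(
    reference_frame: np.ndarray,
    saturated_frame: np.ndarray,
    mask: np.ndarray | None = None,
    min_reference: float | None = None,
    spacing_mm: float | None = None,
) -> ParameterMap:
    """Magnetization transfer ratio map, MTR = 100 (S0 - S_MT) / S0 in percent.

    Pixels whose reference signal falls at or below the signal threshold are
    invalid; negative MTR values (S_MT > S0, possible under noise) are kept in
    the value map but flagged invalid.
    """
    ref = np.asarray(reference_frame, float)
    sat = np.asarray(saturated_frame, float)
    if ref.shape != sat.shape:
        raise ValueError("reference and saturated frames differ in shape")
    if mask is not None and mask.shape != ref.shape:
        raise ValueError("mask shape does not match the frames")
    thr = 1e-6 * ref.max() if min_reference is None else min_reference
    ok = ref > thr
    with np.errstate(invalid="ignore", divide="ignore"):
        mtr = 100.0 * (ref - sat) / np.where(ok, ref, np.nan)
    mtr = np.where(ok, mtr, 0.0)
    valid = ok & (mtr >= 0)
    if mask is not None:
        valid &= mask.astype(bool)
    return ParameterMap(mtr, valid, units="%", name="MTR", spacing_mm=spacing_mm)


def fit_b1_cosine(
    images: np.ndarray,
    pulse_lengths_ms: np.ndarray,
    nominal_amplitude_hz: float,
) -> ParameterMap:
    """Relative B1 map from a hard-pulse nutation experiment.

    Fits S(tau) = A cos(2 pi f1 tau) per pixel over the pulse-length series
    (variable projection over an f1 grid with golden-section refinement) and
    reports f1 / nominal as the relative B1 amplitude.
    """
    tau = np.asarray(pulse_lengths_ms, float) * 1e-3  # -> s
    if tau.size < 4:
        raise ProtocolError("B1 cosine fit needs >= 4 pulse lengths")
    if nominal_amplitude_hz <= 0:
        raise ValueError("nominal amplitude must be positive")
    imgs = np.asarray(images, float)
    grid = imgs.shape[1:]
    S = imgs.reshape(imgs.shape[0], -1).T
    const = np.ptp(S, axis=1) <= 1e-12 * np.maximum(np.abs(S).max(), 1.0)

    def cost_for(f1):
        c = np.cos(2 * np.pi * f1[:, None] * tau[None, :])  # (np, nf)
        denom = (c * c).sum(axis=1)
        A = (S * c).sum(axis=1) / np.maximum(denom, 1e-300)
        return ((S - A[:, None] * c) ** 2).sum(axis=1), A

    fgrid = np.linspace(0.05, 2.0, 160) * nominal_amplitude_hz
    best_f = np.full(S.shape[0], nominal_amplitude_hz)
    best_cost = np.full(S.shape[0], np.inf)
    for f in fgrid:
        cst, _ = cost_for(np.full(S.shape[0], f))
        better = cst < best_cost
        best_f = np.where(better, f, best_f)
        best_cost = np.where(better, cst, best_cost)
    # golden-section refinement around the best grid point
    step = fgrid[1] - fgrid[0]
    lo, hi = best_f - step, best_f + step
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - gr * (hi - lo)
    x2 = lo + gr * (hi - lo)
    f1_, _ = cost_for(x1)
    f2_, _ = cost_for(x2)
    for _ in range(60):
        take_left = f1_ < f2_
        hi = np.where(take_left, x2, hi)
        lo = np.where(take_left, lo, x1)
        x1 = hi - gr * (hi - lo)
        x2 = lo + gr * (hi - lo)
        f1_, _ = cost_for(x1)
        f2_, _ = cost_for(x2)
    fhat = (lo + hi) / 2.0
    _, A = cost_for(fhat)
    rel = fhat / nominal_amplitude_hz
    vmap = rel.reshape(grid)
    return ParameterMap(
        vmap, (~const).reshape(grid), s0=A.reshape(grid), units="relative", name="B1"
    )


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase to the interval (-pi, pi]."""
    return -(np.mod(-np.asarray(phi, float) + np.pi, 2.0 * np.pi) - np.pi)


def b0_from_phase(
    phase1: np.ndarray, phase2: np.ndarray, te1_ms: float, te2_ms: float
) -> ParameterMap:
    """Off-resonance (Hz) from the phase difference of two gradient echoes:
    wrapped(phase2 - phase1) / (2 pi (TE2 - TE1))."""
    if te2_ms <= te1_ms:
        raise ProtocolError("te2 must exceed te1")
    dphi = wrap_phase(np.asarray(phase2, float) - np.asarray(phase1, float))
    dte = (te2_ms - te1_ms) * 1e-3
    hz = dphi / (2.0 * np.pi * dte)
    return ParameterMap(hz, np.ones(hz.shape, bool), units="Hz", name="B0")


@dataclass
class QCReport:
    """Field-map homogeneity check over a tissue mask."""

    b1_min: float
    b1_max: float
    b0_min_hz: float
    b0_max_hz: float
    b1_pass: bool
    b0_pass: bool
    worst_b1_pixel: tuple[int, ...] | None = None
    worst_b0_pixel: tuple[int, ...] | None = None

    @property
    def passed(self) -> bool:
        return self.b1_pass and self.b0_pass


def qc_field_maps(
    b1_map: ParameterMap,
    b0_map: ParameterMap,
    tissue_mask: np.ndarray,
    b1_tolerance: float = 0.10,
    b0_limit_hz: float = 100.0,
) -> QCReport:
    """Verify B1 within +/-10% of nominal and B0 within +/-100 Hz on the mask."""
    m = np.asarray(tissue_mask, bool)
    if not m.any():
        raise DegenerateInputError("empty QC mask")
    b1 = b1_map.values[m & b1_map.valid]
    b0 = b0_map.values[m & b0_map.valid]
    if b1.size == 0 or b0.size == 0:
        raise DegenerateInputError("no valid field-map pixels in mask")
    b1_dev = np.abs(b1_map.values - 1.0)
    b1_dev[~(m & b1_map.valid)] = -np.inf
    b0_dev = np.abs(b0_map.values.astype(float))
    b0_dev[~(m & b0_map.valid)] = -np.inf
    b1_pass = bool(np.all(np.abs(b1 - 1.0) <= b1_tolerance))
    b0_pass = bool(np.all(np.abs(b0) <= b0_limit_hz))
    return QCReport(
        b1_min=float(b1.min()),
        b1_max=float(b1.max()),
        b0_min_hz=float(b0.min()),
        b0_max_hz=float(b0.max()),
        b1_pass=b1_pass,
        b0_pass=b0_pass,
        worst_b1_pixel=tuple(np.unravel_index(np.argmax(b1_dev), b1_dev.shape))
        if not b1_pass
        else None,
        worst_b0_pixel=tuple(np.unravel_index(np.argmax(b0_dev), b0_dev.shape))
        if not b0_pass
        else None,
    )
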