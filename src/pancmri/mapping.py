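"""Voxel-wise parametric mapping: ADC, B1-corrected VFA T1, and MTR.

Models
------
Two-point diffusion decay::

    SI(b_high) = SI(b_low) * exp(-ADC * (b_high - b_low))

so ``ADC = ln(SI(b_low)/SI(b_high)) / (b_high - b_low)`` — exact for two
b-values.  The standardized protocol uses the (200, 800) s/mm² pair; the
non-standardized variant uses (0, 800), which is perfusion-contaminated.

Spoiled gradient echo (SPGR) steady state at flip angle alpha, with transmit
correction factor f (actual/prescribed flip angle)::

    S = S0 * sin(f*alpha) * (1 - E) / (1 - E * cos(f*alpha)),  E = exp(-TR/T1)

fitted per voxel for (S0, T1).  Echo-time decay is neglected (TE << T2*).
S0 enters linearly, so it is profiled out exactly and the fit reduces to a
1-D bounded search over T1 (coarse log-grid bracket, then golden-section to
relative tolerance 1e-8), initialized and cross-checked by the linearized
DESPOT1 regression of S/sin(f*alpha) on S/tan(f*alpha).

Magnetization transfer ratio::

    MTR = (SI_off - SI_on) / SI_off
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import INVALID, FrameError, ImageVolume

__all__ = [
    "DWISeries",
    "VFASeries",
    "B1Map",
    "MTPair",
    "ParametricMap",
    "fit_adc",
    "fit_t1_vfa",
    "compute_mtr",
    "T1_BOUNDS_MS",
]

T1_BOUNDS_MS = (1.0, 10000.0)
_T1_REL_TOL = 1e-8
_T1_COARSE_GRID = 64  # log-spaced bracket points before golden-section


def _check_shared_grid(volumes, what: str) -> None:
    g0 = volumes[0].grid
    for v in volumes[1:]:
        if v.grid != g0:
            raise FrameError(f"{what}: frames are not on a shared grid")


@dataclass
class DWISeries:
    """Diffusion-weighted frames (b_value s/mm², volume) on one grid."""

    frames: list[tuple[float, ImageVolume]]

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("DWI series needs >= 2 b-values")
        self.frames = sorted(self.frames, key=lambda f: f[0])
        bs = [b for b, _ in self.frames]
        if len(set(bs)) != len(bs) or any(b < 0 for b in bs):
            raise ValueError(f"b-values must be unique and >= 0, got {bs}")
        _check_shared_grid([v for _, v in self.frames], "DWI series")

    @property
    def b_values(self) -> list[float]:
        return [b for b, _ in self.frames]

    def frame(self, b: float) -> ImageVolume:
        for bv, vol in self.frames:
            if bv == b:
                return vol
        raise ValueError(f"b-value {b} not in series; available: {self.b_values}")


@dataclass
class VFASeries:
    """Spoiled-GRE frames at several prescribed flip angles, shared TR."""

    frames: list[tuple[float, ImageVolume]]  # (flip angle deg, volume)
    tr_ms: float

    def __post_init__(self) -> None:
        angles = [a for a, _ in self.frames]
        if len(set(angles)) < 2:
            raise ValueError("VFA series needs >= 2 distinct flip angles")
        if any(not 0 < a < 90 for a in angles):
            raise ValueError(f"flip angles must lie in (0, 90) degrees, got {angles}")
        if self.tr_ms <= 0:
            raise ValueError("TR must be positive")
        _check_shared_grid([v for _, v in self.frames], "VFA series")

    @property
    def angles_deg(self) -> list[float]:
        return [a for a, _ in self.frames]


@dataclass
class B1Map:
    """Voxel-wise flip-angle correction factor f (actual/prescribed)."""

    volume: ImageVolume

    def __post_init__(self) -> None:
        d = self.volume.data
        if np.any(d[np.isfinite(d)] <= 0):
            raise ValueError("B1 correction factor must be > 0 where valid")


@dataclass
class MTPair:
    """Gradient-echo magnitudes without / with the MT saturation pre-pulse."""

    mt_off: ImageVolume
    mt_on: ImageVolume

    def __post_init__(self) -> None:
        if self.mt_off.grid != self.mt_on.grid:
            raise FrameError("MT on/off images are not on a shared grid")


MAP_KINDS = {
    "adc": "mm^2/s",
    "t1": "ms",
    "mtr": "dimensionless",
    "fat_fraction": "fraction",
}


@dataclass
class ParametricMap:
    """An ImageVolume tagged with its parameter kind, units and diagnostics."""

    volume: ImageVolume
    kind: str
    aux: ImageVolume | None = None  # S0 companion for T1 fits
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}; expected one of {sorted(MAP_KINDS)}")

    @property
    def units(self) -> str:
        return MAP_KINDS[self.kind]

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


def fit_adc(series: DWISeries, b_low: float = 200.0, b_high: float = 800.0) -> ParametricMap:
    """Two-point monoexponential ADC map from the (b_low, b_high) pair.

    Voxels with non-positive signal at either b-value, or with a negative
    ADC estimate, are flagged invalid; negative estimates are counted in
    ``diagnostics`` rather than clamped into the map.
    """
    if b_high <= b_low:
        raise ValueError(f"b_high ({b_high}) must exceed b_low ({b_low})")
    s_low = series.frame(b_low).data
    s_high = series.frame(b_high).data
    ok = np.isfinite(s_low) & np.isfinite(s_high) & (s_low > 0) & (s_high > 0)
    adc = np.full(s_low.shape, INVALID)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[ok] = np.log(s_low[ok] / s_high[ok]) / (b_high - b_low)
    negative = ok & (adc < 0)
    adc[negative] = INVALID
    diagnostics = {
        "b_pair": (b_low, b_high),
        "n_voxels": int(adc.size),
        "n_nonpositive_signal": int(adc.size - ok.sum()),
        "n_negative_adc": int(negative.sum()),
    }
    vol = series.frame(b_low).with_data(adc, description="ADC map")
    return ParametricMap(vol, "adc", diagnostics=diagnostics)


def _spgr_shape(e1: np.ndarray, sin_fa: np.ndarray, cos_fa: np.ndarray) -> np.ndarray:
    """SPGR signal per unit S0: sin(fa)(1-E)/(1-E cos(fa)).

    e1 has shape (..., 1) broadcasting against per-frame sin/cos (n_frames,).
    """
    return sin_fa * (1.0 - e1) / (1.0 - e1 * cos_fa)


def _profiled_sse(t1: np.ndarray, signals: np.ndarray, sin_fa: np.ndarray,
                  cos_fa: np.ndarray, tr: float) -> tuple[np.ndarray, np.ndarray]:
    """Residual sum of squares over frames with S0 profiled out, plus S0*.

    ``t1``: (n_vox,), ``signals``: (n_vox, n_frames), ``sin_fa``/``cos_fa``:
    (n_vox, n_frames).
    """
    e1 = np.exp(-tr / t1)[:, None]
    g = _spgr_shape(e1, sin_fa, cos_fa)
    gg = np.sum(g * g, axis=1)
    sg = np.sum(signals * g, axis=1)
    s0 = np.where(gg > 0, sg / np.where(gg > 0, gg, 1.0), 0.0)
    sse = np.sum(signals * signals, axis=1) - s0 * sg
    return sse, s0


def fit_t1_vfa(series: VFASeries, b1: B1Map | None = None) -> ParametricMap:
    """Voxel-wise (S0, T1) fit of the SPGR equation over a VFA series.

    ``b1=None`` selects the non-standardized variant: the correction factor
    is taken as f = 1 everywhere.  A supplied B1 map must already be on the
    series grid (regrid first).  Returns a T1 map (ms) with an S0 companion;
    voxels with invalid input, non-positive signal, an invalid/non-positive
    f, or a boundary-pinned T1 are flagged invalid with counted reasons.
    """
    vol0 = series.frames[0][1]
    shape = vol0.data.shape
    n_vox = int(np.prod(shape))
    signals = np.stack([v.data.reshape(n_vox) for _, v in series.frames], axis=1)
    angles = np.deg2rad(np.asarray(series.angles_deg))

    if b1 is None:
        f = np.ones(n_vox)
    else:
        if b1.volume.grid != vol0.grid:
            raise FrameError("B1 map grid differs from VFA grid; regrid it first")
        f = b1.volume.data.reshape(n_vox)

    ok = np.all(np.isfinite(signals), axis=1) & np.all(signals > 0, axis=1)
    f_ok = np.isfinite(f) & (f > 0)
    valid = ok & f_ok
    n_bad_signal = int((~ok).sum())
    n_bad_b1 = int((ok & ~f_ok).sum())
    if not valid.any():
        raise ValueError("T1 fit: no voxel has >= 2 valid positive frames")

    s = signals[valid]
    fa = f[valid][:, None] * angles[None, :]
    sin_fa, cos_fa = np.sin(fa), np.cos(fa)
    tr = series.tr_ms

    # DESPOT1 linearization: S/sin = E * S/tan + S0(1-E); slope -> T1 start
    y = s / sin_fa
    x = s * cos_fa / sin_fa
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    sxx = np.sum((x - xm) ** 2, axis=1)
    sxy = np.sum((x - xm) * (y - ym), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        t1_lin = -tr / np.log(slope)
    t1_lin = np.where(np.isfinite(t1_lin), t1_lin, np.sqrt(T1_BOUNDS_MS[0] * T1_BOUNDS_MS[1]))
    t1_lin = np.clip(t1_lin, *T1_BOUNDS_MS)

    # coarse log-grid bracket of the profiled SSE (global), then refine
    lo, hi = np.log(T1_BOUNDS_MS[0]), np.log(T1_BOUNDS_MS[1])
    grid = np.linspace(lo, hi, _T1_COARSE_GRID)
    sse_grid = np.empty((s.shape[0], grid.size))
    for i, lg in enumerate(grid):
        sse_grid[:, i], _ = _profiled_sse(np.full(s.shape[0], np.exp(lg)), s, sin_fa, cos_fa, tr)
    # include the DESPOT1 start in the bracket choice
    sse_lin, _ = _profiled_sse(t1_lin, s, sin_fa, cos_fa, tr)
    best = np.argmin(sse_grid, axis=1)
    use_lin = sse_lin < sse_grid[np.arange(s.shape[0]), best]
    centers = np.where(use_lin, np.log(t1_lin), grid[best])
    half = (hi - lo) / (_T1_COARSE_GRID - 1)
    a = np.maximum(centers - half, lo)
    b = np.minimum(centers + half, hi)

    # golden-section on log T1 (interval shrinks by 1/phi per iteration)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, _ = _profiled_sse(np.exp(c), s, sin_fa, cos_fa, tr)
    fd, _ = _profiled_sse(np.exp(d), s, sin_fa, cos_fa, tr)
    n_iter = int(np.ceil(np.log(_T1_REL_TOL / (2 * half)) / np.log(invphi)))
    for _ in range(max(n_iter, 1)):
        take_c = fc < fd
        b = np.where(take_c, d, b)
        a = np.where(take_c, a, c)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, _ = _profiled_sse(np.exp(c), s, sin_fa, cos_fa, tr)
        fd, _ = _profiled_sse(np.exp(d), s, sin_fa, cos_fa, tr)
    t1_hat = np.exp((a + b) / 2.0)
    _, s0_hat = _profiled_sse(t1_hat, s, sin_fa, cos_fa, tr)

    pinned = (t1_hat <= T1_BOUNDS_MS[0] * (1 + 1e-6)) | (t1_hat >= T1_BOUNDS_MS[1] * (1 - 1e-6))
    t1_hat[pinned] = INVALID
    s0_hat[pinned] = INVALID

    t1_full = np.full(n_vox, INVALID)
    s0_full = np.full(n_vox, INVALID)
    t1_full[valid] = t1_hat
    s0_full[valid] = s0_hat

    diagnostics = {
        "variant": "standardized" if b1 is not None else "non_standardized_no_b1",
        "n_voxels": n_vox,
        "n_invalid_signal": n_bad_signal,
        "n_invalid_b1": n_bad_b1,
        "n_boundary_pinned": int(pinned.sum()),
    }
    t1_vol = vol0.with_data(t1_full.reshape(shape), description="T1 map (VFA)")
    s0_vol = vol0.with_data(s0_full.reshape(shape), description="S0 map (VFA)")
    return ParametricMap(t1_vol, "t1", aux=s0_vol, diagnostics=diagnostics)


def compute_mtr(pair: MTPair) -> ParametricMap:
    """MTR = (SI_off - SI_on)/SI_off per voxel; SI_off <= 0 -> invalid.

    Noisy voxels may land outside [0, 1]; they are kept but counted in
    diagnostics.
    """
    off = pair.mt_off.data
    on = pair.mt_on.data
    ok = np.isfinite(off) & np.isfinite(on) & (off > 0)
    mtr = np.full(off.shape, INVALID)
    mtr[ok] = (off[ok] - on[ok]) / off[ok]
    out_of_range = ok & ((mtr < 0) | (mtr > 1))
    diagnostics = {
        "n_voxels": int(off.size),
        "n_invalid": int(off.size - ok.sum()),
        "n_outside_unit_interval": int(out_of_range.sum()),
    }
    vol = pair.mt_off.with_data(mtr, description="MTR map")
    return ParametricMap(vol, "mtr", diagnostics=diagnostics)
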