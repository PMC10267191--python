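"""Dual-gradient-echo SPGR signal synthesis and ΔR1 / tip-angle estimation.

Forward model (spoiled gradient echo, echo time TEi, repetition time TR,
flip angle θ, equilibrium magnetization M0)::

    signal_i(t) = M0 sinθ (1 − E(t)) e^{−TEi / T2*(t)} / (1 − cosθ E(t)),
    E(t) = e^{−TR / T1(t)}.

With two echoes at TE2 = μ·TE1 the per-frame combination

    h(t) = F(t)^{μ/(μ−1)} / S(t)^{1/(μ−1)}

is independent of T2*(t) for *any* μ > 1 (the echo-time exponents cancel the
transverse decay exactly), leaving ``h(t) = M0 sinθ (1 − E(t)) / (1 − cosθ E(t))``.
The pre-injection and late-saturation window sums of the two echoes, together
with the externally measured pre/post T1 factors ``E^pre = e^{−TR/T1(pre)}``
and ``E^post = e^{−TR/T1(post)}``, then determine the local tip angle:

    W    = (H_pre / H_sat) · (1 − E^post) / (1 − E^pre),
    cosθ = (1 − W) / (E^post − E^pre · W),

with ``H = (Σ F)^{μ/(μ−1)} / (Σ S)^{1/(μ−1)}`` over each window (the window
lengths cancel because the two windows have equal length, p − o = n − m).
Per frame, with x(t) = h(t)/h_pre,

    E(t)   = [(1 − cosθ·E^pre) − x(t)(1 − E^pre)] /
             [(1 − cosθ·E^pre) − cosθ·x(t)(1 − E^pre)],
    ΔR1(t) = −(1/TR)·ln(E(t)/E^pre),

which uses only ``E^pre`` — the post-contrast T1 factor enters the tip-angle
estimate alone. M0 and any common T2* dynamics cancel identically, so the
estimate is invariant under global rescaling of both echoes and under
arbitrary shared ΔR2*(t).

Frame indices in :class:`BaselineWindows` are 1-based inclusive, matching the
acquisition-protocol convention used throughout the user-facing API.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Tuple

import numpy as np

from .pk_models import ConcentrationCurve

__all__ = [
    "AcquisitionParams",
    "RelaxationState",
    "BaselineWindows",
    "DGEVoxelSeries",
    "DGEStudy",
    "WindowMeans",
    "spgr_echo",
    "window_means",
    "estimate_tip_angle",
    "estimate_delta_r1",
    "estimate_study_delta_r1",
    "DegenerateVoxelError",
]


class DegenerateVoxelError(ValueError):
    """Raised when a voxel carries no usable angle/ΔR1 information."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class AcquisitionParams:
    """Sequence and timing constants of the dual-echo DCE protocol.

    Defaults reflect a small-animal protocol: TR/TE1/TE2 = 24/2/4 ms, 18°
    nominal flip angle, 400 frames at 1.55 s, contrast bolus at frame 15.
    """

    tr: float = 0.024
    te1: float = 0.002
    te2: float = 0.004
    theta_nominal: float = math.radians(18.0)
    frame_interval: float = 1.55
    n_frames: int = 400
    injection_frame: int = 15  # 1-based

    def __post_init__(self) -> None:
        if not (0 < self.te1 < self.te2):
            raise ValueError("need te2 > te1 > 0")
        if self.tr <= self.te2:
            raise ValueError("need tr > te2")
        if not (0 < self.theta_nominal <= math.pi / 2):
            raise ValueError("theta_nominal must be in (0, pi/2]")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if not (1 <= self.injection_frame < self.n_frames):
            raise ValueError("injection_frame must lie inside the frame range")

    @property
    def mu(self) -> float:
        """Echo-time ratio TE2/TE1 (must exceed 1)."""
        return self.te2 / self.te1

    def times(self) -> np.ndarray:
        """Frame mid-times in seconds from experiment start."""
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def injection_time(self) -> float:
        return (self.injection_frame - 1) * self.frame_interval


@dataclass(frozen=True)
class RelaxationState:
    """Voxel relaxation state: M0 (a.u.), T1 (s), T2* (s); all positive."""

    m0: float
    t1: float
    t2star: float

    def __post_init__(self) -> None:
        for name in ("m0", "t1", "t2star"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite")


@dataclass(frozen=True)
class BaselineWindows:
    """Pre-injection window m..n and saturation window o..p (1-based, inclusive).

    The two windows must have equal length (p − o = n − m) so that the frame
    counts cancel in the tip-angle window sums, and the saturation window must
    end at the last frame.
    """

    m: int
    n: int
    o: int
    p: int

    def validate(self, acq: AcquisitionParams) -> None:
        if not (1 <= self.m <= self.n < acq.injection_frame):
            raise ValueError("pre-injection window must satisfy 1 <= m <= n < injection_frame")
        if not (self.n < self.o <= self.p):
            raise ValueError("saturation window must follow the pre-injection window")
        if self.p != acq.n_frames:
            raise ValueError("saturation window must end at the last frame")
        if (self.p - self.o) != (self.n - self.m):
            raise ValueError("windows must have equal length (p - o = n - m)")

    @classmethod
    def default_for(cls, acq: AcquisitionParams, length: int = 10) -> "BaselineWindows":
        """Ten-frame windows: m..n ends one frame before injection; o..p is the tail."""
        n = acq.injection_frame - 1
        m = max(1, n - length + 1)
        p = acq.n_frames
        o = p - (n - m)
        w = cls(m=m, n=n, o=o, p=p)
        w.validate(acq)
        return w

    @property
    def n_pre(self) -> int:
        return self.n - self.m + 1


@dataclass(frozen=True)
class DGEVoxelSeries:
    """Paired echo time courses of one voxel plus its T1-map factors."""

    f: np.ndarray
    s: np.ndarray
    e_pre: float
    e_post: float
    windows: BaselineWindows

    def __post_init__(self) -> None:
        f = np.asarray(self.f, float)
        s = np.asarray(self.s, float)
        if f.shape != s.shape or f.ndim != 1:
            raise ValueError("f and s must be 1-D arrays of equal length")
        for name, v in (("e_pre", self.e_pre), ("e_post", self.e_post)):
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "s", s)


class WindowMeans(NamedTuple):
    f_pre: float
    s_pre: float
    f_sat: float
    s_sat: float
    f_pre_sum: float
    s_pre_sum: float
    f_sat_sum: float
    s_sat_sum: float


def spgr_echo(state: RelaxationState, acq: AcquisitionParams, echo: int, theta: float):
    """Steady-state SPGR signal of one echo.

    ``theta`` in radians; ``echo`` selects TE1 or TE2. Accepts scalar or array
    relaxation values broadcast through :class:`RelaxationState` fields.
    """
    if echo not in (1, 2):
        raise ValueError("echo must be 1 or 2")
    te = acq.te1 if echo == 1 else acq.te2
    e1 = np.exp(-acq.tr / np.asarray(state.t1, float))
    return (
        state.m0
        * np.sin(theta)
        * (1.0 - e1)
        * np.exp(-te / np.asarray(state.t2star, float))
        / (1.0 - np.cos(theta) * e1)
    )


def window_means(series: DGEVoxelSeries) -> WindowMeans:
    """Arithmetic means and sums of both echoes over the two baseline windows."""
    w = series.windows
    sl_pre = slice(w.m - 1, w.n)
    sl_sat = slice(w.o - 1, w.p)
    fp, sp = series.f[sl_pre], series.s[sl_pre]
    fs, ss = series.f[sl_sat], series.s[sl_sat]
    if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(sp))
            and np.all(np.isfinite(fs)) and np.all(np.isfinite(ss))):
        raise DegenerateVoxelError("non-finite samples inside a baseline window")
    return WindowMeans(
        fp.mean(), sp.mean(), fs.mean(), ss.mean(),
        fp.sum(), sp.sum(), fs.sum(), ss.sum(),
    )


def _h_exponents(mu: float) -> Tuple[float, float]:
    if mu <= 1:
        raise ValueError("echo-time ratio mu must exceed 1")
    return mu / (mu - 1.0), 1.0 / (mu - 1.0)


def estimate_tip_angle(
    series: DGEVoxelSeries,
    acq: AcquisitionParams,
    clamp: bool = False,
) -> float:
    """Estimate the local tip angle (rad) from the baseline-window sums.

    Raises :class:`DegenerateVoxelError` for voxels whose arccos argument is
    undefined or out of range (no enhancement, noise); with ``clamp=True`` the
    argument is clamped into [−1, 1] instead.
    """
    wm = window_means(series)
    b_exp, a_exp = _h_exponents(acq.mu)
    if min(wm.f_pre_sum, wm.s_pre_sum, wm.f_sat_sum, wm.s_sat_sum) <= 0:
        raise DegenerateVoxelError("non-positive window sum")
    h_pre = wm.f_pre_sum ** b_exp / wm.s_pre_sum ** a_exp
    h_sat = wm.f_sat_sum ** b_exp / wm.s_sat_sum ** a_exp
    w = (h_pre / h_sat) * (1.0 - series.e_post) / (1.0 - series.e_pre)
    den = series.e_post - series.e_pre * w
    if abs(den) < 1e-12:
        raise DegenerateVoxelError("no enhancement: tip angle indeterminate (0/0)")
    cos_theta = (1.0 - w) / den
    if not np.isfinite(cos_theta) or abs(cos_theta) > 1.0:
        if clamp and np.isfinite(cos_theta):
            cos_theta = float(np.clip(cos_theta, -1.0, 1.0))
        else:
            raise DegenerateVoxelError(
                f"arccos argument {cos_theta:.6g} outside [-1, 1]"
            )
    return float(np.arccos(cos_theta))


def estimate_delta_r1(
    series: DGEVoxelSeries,
    theta_est: float,
    acq: AcquisitionParams,
) -> ConcentrationCurve:
    """Per-frame ΔR1(t) (s⁻¹) given the estimated tip angle.

    Invalid frames (non-positive signals or a non-positive log argument) are
    returned as NaN sentinels; callers count and propagate them. Only
    ``e_pre`` enters — the post-contrast T1 factor is not required.
    """
    if not (0 < theta_est < math.pi / 2):
        raise ValueError("theta_est must be in (0, pi/2)")
    wm = window_means(series)
    b_exp, a_exp = _h_exponents(acq.mu)
    if min(wm.f_pre_sum, wm.s_pre_sum) <= 0:
        raise DegenerateVoxelError("non-positive pre-injection window sum")
    c = math.cos(theta_est)
    e_pre = series.e_pre
    n_pre = series.windows.n_pre

    with np.errstate(invalid="ignore", divide="ignore"):
        h_t = np.where(
            (series.f > 0) & (series.s > 0),
            series.f ** b_exp / series.s ** a_exp,
            np.nan,
        )
        # x(t) = h(t) / h_pre written with the window *sums* and the
        # (n − m + 1) factor, as in the acquisition-window formulation.
        x = n_pre * (wm.s_pre_sum ** a_exp / wm.f_pre_sum ** b_exp) * h_t
        a0 = 1.0 - c * e_pre
        b0 = 1.0 - e_pre
        e_t = (a0 - x * b0) / (a0 - c * x * b0)
        ratio = e_t / e_pre
        dr1 = np.where(ratio > 0, -np.log(np.where(ratio > 0, ratio, 1.0)) / acq.tr, np.nan)
    return ConcentrationCurve(acq.times()[: series.f.size], dr1)


@dataclass
class DGEStudy:
    """One dual-echo DCE-MRI study: paired 4D echo volumes plus metadata.

    ``f`` and ``s`` have shape (nx, ny, nz, n_frames); ``mask`` is a boolean
    brain mask; ``e_pre``/``e_post`` are per-voxel T1 factors (maps or scalars
    broadcastable to the spatial grid).
    """

    f: np.ndarray
    s: np.ndarray
    mask: np.ndarray
    acq: AcquisitionParams
    e_pre: np.ndarray
    e_post: np.ndarray
    windows: Optional[BaselineWindows] = None

    def __post_init__(self) -> None:
        f = np.asarray(self.f)
        s = np.asarray(self.s)
        if f.shape != s.shape or f.ndim != 4:
            raise ValueError("f and s must be 4-D arrays of identical shape")
        if f.shape[-1] != self.acq.n_frames:
            raise ValueError(
                f"frame axis {f.shape[-1]} does not match acq.n_frames {self.acq.n_frames}"
            )
        mask = np.asarray(self.mask, bool)
        if mask.shape != f.shape[:3]:
            raise ValueError("mask grid does not match the echo volumes")
        self.f, self.s, self.mask = f, s, mask
        self.e_pre = np.broadcast_to(np.asarray(self.e_pre, float), f.shape[:3]).copy()
        self.e_post = np.broadcast_to(np.asarray(self.e_post, float), f.shape[:3]).copy()
        if self.windows is None:
            self.windows = BaselineWindows.default_for(self.acq)
        self.windows.validate(self.acq)

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.f.shape[:3]

    def voxel_series(self, idx: Tuple[int, int, int]) -> DGEVoxelSeries:
        return DGEVoxelSeries(
            f=self.f[idx].astype(float),
            s=self.s[idx].astype(float),
            e_pre=float(self.e_pre[idx]),
            e_post=float(self.e_post[idx]),
            windows=self.windows,
        )


# Voxel flag codes written to the validity map by the study driver.
FLAG_OK = 0
FLAG_OUTSIDE_MASK = 1
FLAG_DEGENERATE_ANGLE = 2
FLAG_BAD_WINDOW = 3
FLAG_TOO_MANY_INVALID_FRAMES = 4


def estimate_study_delta_r1(
    study: DGEStudy,
    clamp: bool = False,
    max_invalid_frame_frac: float = 0.2,
    roi_pooled_theta: bool = False,
):
    """Vectorized tip-angle + ΔR1 estimation over all masked voxels.

    Returns ``(dr1, theta, flags, invalid_frames)`` where ``dr1`` is a 4-D
    float array (NaN at invalid frames and outside the mask), ``theta`` a 3-D
    map in radians, ``flags`` an int code map and ``invalid_frames`` the
    per-voxel count of flagged frames. Voxels whose invalid-frame fraction
    exceeds ``max_invalid_frame_frac`` are flagged and excluded downstream.

    With ``roi_pooled_theta=True`` a single tip angle is estimated from the
    mask-summed signals (noise robustness) and applied to every voxel.
    """
    acq, w = study.acq, study.windows
    nx, ny, nz, nt = study.f.shape
    flat_mask = study.mask.reshape(-1)
    f = study.f.reshape(-1, nt)[flat_mask].astype(float)
    s = study.s.reshape(-1, nt)[flat_mask].astype(float)
    e_pre = study.e_pre.reshape(-1)[flat_mask]
    e_post = study.e_post.reshape(-1)[flat_mask]
    nvox = f.shape[0]

    b_exp, a_exp = _h_exponents(acq.mu)
    sl_pre, sl_sat = slice(w.m - 1, w.n), slice(w.o - 1, w.p)
    fpre, spre = f[:, sl_pre].sum(axis=1), s[:, sl_pre].sum(axis=1)
    fsat, ssat = f[:, sl_sat].sum(axis=1), s[:, sl_sat].sum(axis=1)

    flags = np.full(nvox, FLAG_OK, dtype=np.int16)
    bad_win = (
        ~np.isfinite(fpre) | ~np.isfinite(spre) | ~np.isfinite(fsat) | ~np.isfinite(ssat)
        | (fpre <= 0) | (spre <= 0) | (fsat <= 0) | (ssat <= 0)
    )
    flags[bad_win] = FLAG_BAD_WINDOW

    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        h_pre = fpre ** b_exp / spre ** a_exp
        h_sat = fsat ** b_exp / ssat ** a_exp
        big_w = (h_pre / h_sat) * (1.0 - e_post) / (1.0 - e_pre)
        den = e_post - e_pre * big_w
        cos_theta = np.where(np.abs(den) > 1e-12, (1.0 - big_w) / den, np.nan)
    strict_valid = np.isfinite(cos_theta) & (np.abs(cos_theta) <= 1.0)
    degenerate = ~strict_valid
    if clamp:
        still_bad = ~np.isfinite(cos_theta)
        cos_theta = np.clip(cos_theta, -1.0, 1.0)
        degenerate = still_bad
    flags[degenerate & (flags == FLAG_OK)] = FLAG_DEGENERATE_ANGLE
    theta = np.where(flags == FLAG_OK, np.arccos(np.clip(cos_theta, -1.0, 1.0)), np.nan)

    if roi_pooled_theta:
        # Robust ROI pooling: median of the per-voxel estimates over strongly
        # enhancing voxels (weak enhancers carry almost no angle information
        # and dominate the noise), applied to every voxel of the mask.
        ok = (flags == FLAG_OK) & strict_valid
        with np.errstate(invalid="ignore", divide="ignore"):
            rel_change = np.abs(fsat - fpre) / np.abs(fpre)
        reliable = ok & (rel_change > 0.05)
        if reliable.sum() < 10:
            reliable = ok
        if not reliable.any():
            raise DegenerateVoxelError("no voxel yields a usable tip angle")
        theta_val = float(np.median(theta[reliable]))
        good_windows = flags != FLAG_BAD_WINDOW
        theta = np.where(good_windows, theta_val, np.nan)
        flags[good_windows & (flags == FLAG_DEGENERATE_ANGLE)] = FLAG_OK

    cos_t = np.cos(theta)[:, None]
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        h_t = np.where((f > 0) & (s > 0), f ** b_exp / s ** a_exp, np.nan)
        x = w.n_pre * (spre ** a_exp / fpre ** b_exp)[:, None] * h_t
        a0 = 1.0 - cos_t * e_pre[:, None]
        b0 = (1.0 - e_pre)[:, None]
        e_t = (a0 - x * b0) / (a0 - cos_t * x * b0)
        ratio = e_t / e_pre[:, None]
        dr1 = np.where(ratio > 0, -np.log(np.where(ratio > 0, ratio, 1.0)) / acq.tr, np.nan)
    dr1[flags != FLAG_OK] = np.nan

    invalid = np.sum(~np.isfinite(dr1), axis=1)
    too_many = (flags == FLAG_OK) & (invalid > max_invalid_frame_frac * nt)
    flags[too_many] = FLAG_TOO_MANY_INVALID_FRAMES
    dr1[flags != FLAG_OK] = np.nan

    dr1_full = np.full((nx * ny * nz, nt), np.nan)
    dr1_full[flat_mask] = dr1
    theta_full = np.full(nx * ny * nz, np.nan)
    theta_full[flat_mask] = theta
    flags_full = np.full(nx * ny * nz, FLAG_OUTSIDE_MASK, dtype=np.int16)
    flags_full[flat_mask] = flags
    inval_full = np.zeros(nx * ny * nz, dtype=np.int32)
    inval_full[flat_mask] = invalid
    return (
        dr1_full.reshape(nx, ny, nz, nt),
        theta_full.reshape(nx, ny, nz),
        flags_full.reshape(nx, ny, nz),
        inval_full.reshape(nx, ny, nz),
    )
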