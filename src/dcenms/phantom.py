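"""Digital dual-echo DCE-MRI phantoms with full ground truth.

Each phantom study emulates a rat-brain acquisition: an elliptical brain of
normal vasculature (model-1 region, no leakage) containing a circular tumor
whose rim leaks without measurable back-flux (model 2) and whose core leaks
with back-flux (model 3), plus a small caudate-putamen-like reference ROI of
known plasma volume inside the normal region. Per-voxel pharmacokinetic
parameters are drawn inside region-specific ranges, tissue ΔR1(t) follows
the nested models driven by a shared population AIF, a vascular-weighted
ΔR2*(t) = factor · vp · C_AIF(t) couples the bolus into the transverse
rate, and both gradient echoes are synthesized with the SPGR signal model
at a per-voxel tip angle. Optional Gaussian (or Rician) noise is added on
the signals — the pipeline's first stage is signal-domain, so that is where
measurement noise lives.

Every intermediate quantity any downstream consumer may need (labels,
parameters, ΔR1(t), tip angles, T1/T2*/M0 maps, E^pre/E^post, the AIF) is
stored as truth; nothing is recomputed from noisy data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .aif import AIFShapeParams, make_population_aif, apply_dispersion
from .dge_signal import AcquisitionParams, BaselineWindows, DGEStudy, DGEVoxelSeries
from .pk_models import AIFTrace, PKParams, _exp_conv_values, ctissue, DEFAULT_HCT

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomStudy",
    "make_phantom_study",
    "make_cohort",
    "make_roundtrip_voxels",
]

_SPM = 60.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, parameter ranges and noise model of a phantom study.

    Defaults mirror the emulated protocol (128×64 in-plane matrix, 3 slices,
    400 frames at 1.55 s, bolus at frame 15); :meth:`small` returns a
    desk-scale variant used throughout the tests.
    """

    shape: Tuple[int, int, int] = (128, 64, 3)
    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    # region geometry (fractions of the in-plane grid)
    tumor_center: Tuple[float, float] = (0.68, 0.5)
    tumor_radius_frac: float = 0.14
    core_radius_frac: float = 0.07
    ref_center: Tuple[float, float] = (0.3, 0.5)
    ref_halfwidth: int = 1
    # parameter ranges
    vp_range: Tuple[float, float] = (0.005, 0.05)
    ktrans_range: Tuple[float, float] = (0.005, 0.05)   # min^-1, labels >= 2
    kep_range: Tuple[float, float] = (0.05, 0.5)        # min^-1, label 3
    vp_ref: float = 0.01
    # baseline relaxation / magnetization ranges
    t1_range: Tuple[float, float] = (1.3, 1.9)          # s
    t2star_range: Tuple[float, float] = (0.03, 0.05)    # s
    m0_range: Tuple[float, float] = (800.0, 1200.0)
    b1_jitter_frac: float = 0.05   # per-voxel tip-angle spread around nominal
    # contrast dynamics
    # Whole-blood ΔR1 surrogate at the bolus peak. 0.25 mmol/kg Magnevist by
    # hand push gives a first-pass blood [Gd] of roughly 3-4 mM; at
    # r1 ≈ 3.3 s⁻¹ mM⁻¹ that is a blood ΔR1 peak of order 10-13 s⁻¹.
    aif_peak: float = 12.0
    hct: float = DEFAULT_HCT
    r2star_factor: float = 20.0    # ΔR2* = factor · vp · C_AIF; 0 disables T2* dynamics
    # noise
    snr: Optional[float] = 20.0    # None or inf disables noise; sigma = mean baseline F / snr
    rician: bool = False

    def __post_init__(self) -> None:
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive (or None for noise-free)")
        for name in ("vp_range", "ktrans_range", "kep_range",
                     "t1_range", "t2star_range", "m0_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered")
        if not (0 < self.vp_ref < 1):
            raise ValueError("vp_ref must be a fraction in (0, 1)")

    @classmethod
    def small(cls, **overrides) -> "PhantomSpec":
        """Desk-scale phantom: 32×16 single slice, same protocol timing."""
        defaults = dict(shape=(32, 16, 1), tumor_radius_frac=0.2, core_radius_frac=0.1)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class PhantomTruth:
    """Ground truth of one phantom study (maps on the study grid)."""

    label_map: np.ndarray
    vp: np.ndarray
    ktrans: np.ndarray
    kep: np.ndarray
    ve: np.ndarray
    theta: np.ndarray
    t1: np.ndarray
    t2star: np.ndarray
    m0: np.ndarray
    e_pre: np.ndarray
    e_post: np.ndarray
    dr1: np.ndarray      # 4-D programmed ΔR1(t)
    ref_mask: np.ndarray
    aif: AIFTrace


@dataclass
class PhantomStudy:
    study_id: str
    study: DGEStudy
    truth: PhantomTruth
    seed: int


def _region_maps(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    nx, ny, nz = spec.shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = nx / 2.0 - 0.5, ny / 2.0 - 0.5
    brain2d = ((ii - cx) / (0.47 * nx)) ** 2 + ((jj - cy) / (0.45 * ny)) ** 2 <= 1.0
    tx, ty = spec.tumor_center[0] * nx, spec.tumor_center[1] * ny
    r_t = spec.tumor_radius_frac * nx
    r_c = spec.core_radius_frac * nx
    d2 = (ii - tx) ** 2 + (jj - ty) ** 2
    label2d = np.zeros((nx, ny), dtype=np.int16)
    label2d[brain2d] = 1
    label2d[brain2d & (d2 <= r_t**2)] = 2
    label2d[brain2d & (d2 <= r_c**2)] = 3
    rx, ry = int(spec.ref_center[0] * nx), int(spec.ref_center[1] * ny)
    hw = spec.ref_halfwidth
    ref2d = np.zeros((nx, ny), dtype=bool)
    ref2d[rx - hw : rx + hw + 1, ry - hw : ry + hw + 1] = True
    ref2d &= label2d == 1
    if not ref2d.any():
        raise ValueError("reference ROI does not intersect the model-1 region")
    label = np.repeat(label2d[:, :, None], nz, axis=2)
    ref = np.repeat(ref2d[:, :, None], nz, axis=2)
    return label, ref


def _study_aif(spec: PhantomSpec, times: np.ndarray,
               delay: float = 0.0, dispersion_tau: float = 0.0) -> AIFTrace:
    shape = make_population_aif(
        times,
        AIFShapeParams(arrival_time=spec.acq.injection_time + delay),
    )
    aif = AIFTrace(times=times, c_aif=spec.aif_peak * shape.values, hct=spec.hct,
                   normalization=f"phantom truth, peak={spec.aif_peak:g}/s")
    if dispersion_tau > 0:
        aif = apply_dispersion(aif, dispersion_tau)
    return aif


def make_phantom_study(
    spec: PhantomSpec,
    seed: int = 0,
    study_id: Optional[str] = None,
    aif_delay: float = 0.0,
    dispersion_tau: float = 0.0,
) -> PhantomStudy:
    """Forward-simulate one dual-echo phantom study with full truth."""
    rng = np.random.default_rng(seed)
    acq = spec.acq
    nx, ny, nz = spec.shape
    times = acq.times()
    nt = acq.n_frames
    windows = BaselineWindows.default_for(acq)

    label, ref = _region_maps(spec)
    brain = label > 0
    v = int(brain.sum())
    lab_f = label[brain]

    vp = rng.uniform(*spec.vp_range, size=v)
    vp[ref[brain]] = spec.vp_ref
    ktrans = np.where(lab_f >= 2, rng.uniform(*spec.ktrans_range, size=v), 0.0)
    kep = np.where(lab_f == 3, rng.uniform(*spec.kep_range, size=v), 0.0)

    aif = _study_aif(spec, times, delay=aif_delay, dispersion_tau=dispersion_tau)
    cp = aif.cp
    cum = _exp_conv_values(times, cp, 0.0)

    dr1 = vp[:, None] * cp[None, :]
    m2 = lab_f == 2
    dr1[m2] += (ktrans[m2, None] / _SPM) * cum[None, :]
    for i in np.flatnonzero(lab_f == 3):
        conv = _exp_conv_values(times, cp, kep[i] / _SPM)
        dr1[i] += (ktrans[i] / _SPM) * conv

    t1 = rng.uniform(*spec.t1_range, size=v)
    t2s = rng.uniform(*spec.t2star_range, size=v)
    m0 = rng.uniform(*spec.m0_range, size=v)
    theta = acq.theta_nominal * (
        1.0 + spec.b1_jitter_frac * rng.uniform(-1.0, 1.0, size=v)
    )

    dr2s = spec.r2star_factor * vp[:, None] * aif.c_aif[None, :]
    r1 = 1.0 / t1[:, None] + dr1
    r2s = 1.0 / t2s[:, None] + dr2s
    e = np.exp(-acq.tr * r1)
    sin_t, cos_t = np.sin(theta)[:, None], np.cos(theta)[:, None]
    base = m0[:, None] * sin_t * (1.0 - e) / (1.0 - cos_t * e)
    f = base * np.exp(-acq.te1 * r2s)
    s = base * np.exp(-acq.te2 * r2s)

    if spec.snr is not None and np.isfinite(spec.snr):
        sl_pre = slice(windows.m - 1, windows.n)
        sigma = float(f[:, sl_pre].mean()) / spec.snr
        if spec.rician:
            f = np.sqrt((f + rng.normal(0, sigma, f.shape)) ** 2
                        + rng.normal(0, sigma, f.shape) ** 2)
            s = np.sqrt((s + rng.normal(0, sigma, s.shape)) ** 2
                        + rng.normal(0, sigma, s.shape) ** 2)
        else:
            f = f + rng.normal(0, sigma, f.shape)
            s = s + rng.normal(0, sigma, s.shape)

    e_pre = np.exp(-acq.tr / t1)
    sl_sat = slice(windows.o - 1, windows.p)
    e_post = np.exp(-acq.tr * (1.0 / t1 + dr1[:, sl_sat].mean(axis=1)))

    def to_map(vals, fill=np.nan):
        m = np.full((nx, ny, nz), fill, dtype=float)
        m[brain] = vals
        return m

    f4 = np.zeros((nx, ny, nz, nt))
    s4 = np.zeros((nx, ny, nz, nt))
    f4[brain] = f
    s4[brain] = s
    dr1_4 = np.full((nx, ny, nz, nt), np.nan)
    dr1_4[brain] = dr1

    with np.errstate(invalid="ignore", divide="ignore"):
        ve = np.where(kep > 0, ktrans / kep, np.nan)

    study = DGEStudy(
        f=f4, s=s4, mask=brain, acq=acq,
        e_pre=to_map(e_pre, fill=0.5), e_post=to_map(e_post, fill=0.5),
        windows=windows,
    )
    truth = PhantomTruth(
        label_map=label, vp=to_map(vp), ktrans=to_map(np.where(lab_f >= 2, ktrans, np.nan)),
        kep=to_map(np.where(lab_f == 3, kep, np.nan)), ve=to_map(ve),
        theta=to_map(theta), t1=to_map(t1), t2star=to_map(t2s), m0=to_map(m0),
        e_pre=to_map(e_pre), e_post=to_map(e_post),
        dr1=dr1_4, ref_mask=ref, aif=aif,
    )
    return PhantomStudy(
        study_id=study_id or f"phantom-{seed}", study=study, truth=truth, seed=seed
    )


def make_cohort(
    spec: PhantomSpec,
    n_studies: int,
    seed: int = 0,
    delay_jitter: Tuple[float, float] = (0.0, 0.0),
    dispersion_jitter: Tuple[float, float] = (0.0, 0.0),
) -> Tuple[List[PhantomStudy], List[dict]]:
    """Simulate a cohort with independent per-study seeds and optional
    per-study AIF delay/dispersion jitter; returns (studies, manifest)."""
    if n_studies < 1:
        raise ValueError("need at least one study")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_studies)]
    jrng = np.random.default_rng(seed + 777)
    studies: List[PhantomStudy] = []
    manifest: List[dict] = []
    for i, s in enumerate(child_seeds):
        delay = float(jrng.uniform(*delay_jitter)) if delay_jitter[1] > 0 else 0.0
        tau = float(jrng.uniform(*dispersion_jitter)) if dispersion_jitter[1] > 0 else 0.0
        st = make_phantom_study(spec, seed=s, study_id=f"study-{i:03d}",
                                aif_delay=delay, dispersion_tau=tau)
        studies.append(st)
        manifest.append({"study_id": st.study_id, "seed": s,
                         "aif_delay_s": delay, "dispersion_tau_s": tau})
    assert len({m["seed"] for m in manifest}) == n_studies
    return studies, manifest


def make_roundtrip_voxels(
    n: int,
    seed: int = 0,
    acq: Optional[AcquisitionParams] = None,
    with_r2star: bool = True,
) -> List[dict]:
    """Noise-free single voxels with programmed ΔR1(t) and ΔR2*(t) dynamics.

    The programmed ΔR1 is a saturating uptake curve that reaches an exact
    plateau over the saturation window (the steady state the estimator's
    post-contrast T1 factor refers to); ΔR2*(t) is a nonzero bolus-shaped
    transient. Returns dicts with the voxel series and every truth value.
    """
    acq = acq or AcquisitionParams()
    rng = np.random.default_rng(seed)
    windows = BaselineWindows.default_for(acq)
    t = acq.times()
    t0 = acq.injection_time
    out: List[dict] = []
    for _ in range(n):
        t1 = rng.uniform(1.2, 2.0)
        t2s = rng.uniform(0.03, 0.05)
        m0 = rng.uniform(500.0, 1500.0)
        theta = math.radians(rng.uniform(12.0, 25.0))
        amp = rng.uniform(0.2, 2.5)
        rise = rng.uniform(30.0, 120.0)
        tau = np.clip(t - t0, 0.0, None)
        dr1 = amp * (1.0 - np.exp(-tau / rise))
        dr1[windows.o - 1 :] = dr1[windows.o - 1]  # exact saturation plateau
        dr2s = np.zeros_like(t)
        if with_r2star:
            a2 = rng.uniform(1.0, 10.0)
            dr2s = a2 * (tau / 20.0) * np.exp(1 - tau / 20.0)
            dr2s[windows.o - 1 :] = dr2s[windows.o - 1]
        r1 = 1.0 / t1 + dr1
        r2s = 1.0 / t2s + dr2s
        e = np.exp(-acq.tr * r1)
        base = m0 * math.sin(theta) * (1 - e) / (1 - math.cos(theta) * e)
        f = base * np.exp(-acq.te1 * r2s)
        s = base * np.exp(-acq.te2 * r2s)
        e_pre = math.exp(-acq.tr / t1)
        e_post = math.exp(-acq.tr * (1.0 / t1 + dr1[windows.o - 1 :].mean()))
        series = DGEVoxelSeries(f=f, s=s, e_pre=e_pre, e_post=e_post, windows=windows)
        out.append({
            "series": series, "dr1": dr1, "dr2star": dr2s, "theta": theta,
            "t1": t1, "t2star": t2s, "m0": m0,
        })
    return out
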