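"""Conventional pharmacokinetic arm: voxel-wise model fitting and
F-statistic nested model selection.

Each voxel's ΔR1(t) curve is fitted with the three nested models
(no-leakage / Patlak / extended Patlak) and the deepest model whose extra
parameter survives a sequential F-test at the chosen confidence level is
selected. Parametric maps are masked by the selected label: ``ktrans`` is
reported only where the label is ≥ 2 and ``ve`` only where it is 3 —
non-estimable parameters carry no value.

Fitting notes
-------------
Models 1 and 2 are linear in their parameters and are solved exactly by
least squares; model 3 is linear given ``kep``, so it is fitted by profiling
``kep`` over a log grid (including 0, which guarantees rss1 ≥ rss2 ≥ rss3)
followed by a bounded scalar refinement. A Nelder–Mead (simplex) path over
all free parameters is available (``method="simplex"``) and is used as a
cross-check of the linear algebra.

The selection-stage fits are *unconstrained*: the classical nested-F null
distribution requires it (a positivity constraint on ktrans would halve the
test size). Estimates outside the physical ranges are flagged, never
clipped; box-constrained refitting of the reported parameters is available
via ``bounds``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pk_models import AIFTrace, ConcentrationCurve, PKParams, _exp_conv_values

__all__ = [
    "PKResult",
    "NMSMaps",
    "fit_model",
    "f_test_select",
    "run_nms_maps",
    "KEP_PROFILE_GRID",
]

_SECONDS_PER_MINUTE = 60.0

#: Default kep profile grid (min^-1). Includes 0 so model 3 always nests model 2.
KEP_PROFILE_GRID: np.ndarray = np.concatenate(
    [[0.0], np.geomspace(5e-3, 3.0, 24)]
)


@dataclass(frozen=True)
class PKResult:
    """Per-voxel nested-model-selection outcome."""

    model_label: int
    params: PKParams
    rss1: float
    rss2: float
    rss3: float
    n_points: int
    fit_flags: Tuple[str, ...] = ()


@dataclass
class NMSMaps:
    """Study-level maps produced by :func:`run_nms_maps`.

    ``model_map`` is 0 outside the mask / for flagged voxels; parameter maps
    hold NaN wherever the parameter is not estimable under the selected label.
    """

    model_map: np.ndarray
    vp: np.ndarray
    ktrans: np.ndarray
    kep: np.ndarray
    ve: np.ndarray
    table: pd.DataFrame


def _design_columns(aif: AIFTrace, kep_minutes: float) -> np.ndarray:
    """Columns [C_p, conv(C_p; kep)/60] so coefficients are (vp, ktrans[min^-1])."""
    cp = aif.cp
    col2 = _exp_conv_values(aif.times, cp, kep_minutes / _SECONDS_PER_MINUTE) / _SECONDS_PER_MINUTE
    return np.column_stack([cp, col2])


def _lin_fit(y: np.ndarray, x: np.ndarray) -> Tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return coef, float(resid @ resid)


def _range_flags(params: PKParams) -> Tuple[str, ...]:
    flags: List[str] = []
    if not (0.0 <= params.vp <= 1.0):
        flags.append("vp_out_of_range")
    if params.ktrans is not None and params.ktrans < 0:
        flags.append("ktrans_negative")
    ve = params.ve
    if ve is not None and not (0.0 <= ve <= 1.0):
        flags.append("ve_out_of_range")
    return tuple(flags)


def fit_model(
    curve: ConcentrationCurve,
    aif: AIFTrace,
    model: int,
    init: Optional[Sequence[float]] = None,
    bounds: Optional[Sequence[Tuple[float, float]]] = None,
    method: str = "auto",
    kep_grid: Optional[np.ndarray] = None,
    seed: int = 0,
    restarts: int = 3,
) -> Tuple[PKParams, float, Tuple[str, ...]]:
    """Fit one nested model to one ΔR1 curve; returns (params, rss, flags).

    ``method="auto"`` uses exact linear algebra (models 1–2) and profiled
    ``kep`` + scalar refinement (model 3); ``method="simplex"`` runs seeded
    multi-start Nelder–Mead from the same initialization. NaN frames are
    excluded from the fit.
    """
    if model not in (1, 2, 3):
        raise ValueError("model must be 1, 2 or 3")
    y_all = np.asarray(curve.values, float)
    valid = np.isfinite(y_all)
    y = y_all[valid]
    if y.size <= model + 1:
        return PKParams(vp=np.nan), np.nan, ("too_few_points",)

    x2 = _design_columns(aif, 0.0)[valid]
    b1 = x2[:, 0]
    flags: List[str] = []

    if model == 1:
        denom = float(b1 @ b1)
        vp = float(b1 @ y) / denom if denom > 0 else 0.0
        params = PKParams(vp=vp)
        rss = float(np.sum((y - vp * b1) ** 2))
    elif model == 2:
        coef, rss = _lin_fit(y, x2)
        params = PKParams(vp=float(coef[0]), ktrans=float(coef[1]))
    else:
        grid = KEP_PROFILE_GRID if kep_grid is None else np.asarray(kep_grid, float)
        times = aif.times

        def rss_at(kep: float) -> Tuple[float, np.ndarray]:
            x3 = _design_columns(aif, kep)[valid]
            coef, rss_k = _lin_fit(y, x3)
            return rss_k, coef

        profile = np.array([rss_at(k)[0] for k in grid])
        i0 = int(np.argmin(profile))
        lo = grid[max(i0 - 1, 0)]
        hi = grid[min(i0 + 1, grid.size - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda k: rss_at(k)[0], bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-6},
            )
            kep_best = float(res.x) if res.fun <= profile[i0] else float(grid[i0])
        else:
            kep_best = float(grid[i0])
        rss, coef = rss_at(kep_best)
        params = PKParams(vp=float(coef[0]), ktrans=float(coef[1]), kep=kep_best)

    if method == "simplex":
        params, rss, nm_flags = _simplex_polish(
            y, aif, valid, model, params, bounds, seed=seed, restarts=restarts
        )
        flags.extend(nm_flags)

    flags.extend(_range_flags(params))
    return params, rss, tuple(flags)


def _simplex_polish(
    y: np.ndarray,
    aif: AIFTrace,
    valid: np.ndarray,
    model: int,
    init_params: PKParams,
    bounds: Optional[Sequence[Tuple[float, float]]],
    seed: int,
    restarts: int,
) -> Tuple[PKParams, float, List[str]]:
    """Multi-start Nelder–Mead refinement from the linear-algebra seed."""
    rng = np.random.default_rng(seed)

    def unpack(v: np.ndarray) -> PKParams:
        if model == 1:
            return PKParams(vp=v[0])
        if model == 2:
            return PKParams(vp=v[0], ktrans=v[1])
        return PKParams(vp=v[0], ktrans=v[1], kep=abs(v[2]))

    def cost(v: np.ndarray) -> float:
        p = unpack(v)
        if bounds is not None:
            vals = [p.vp, p.ktrans, p.kep][: len(bounds)]
            for val, (lo, hi) in zip(vals, bounds):
                if val is not None and not (lo <= val <= hi):
                    return 1e30
        x = _design_columns(aif, p.kep or 0.0)[valid]
        coefs = np.array([p.vp] + ([p.ktrans] if model >= 2 else []))
        r = y - x[:, : coefs.size] @ coefs
        return float(r @ r)

    x0 = np.array(
        [init_params.vp]
        + ([init_params.ktrans] if model >= 2 else [])
        + ([init_params.kep if init_params.kep is not None else 0.1] if model == 3 else [])
    )
    best_v, best_f = x0, cost(x0)
    flags: List[str] = []
    for i in range(restarts):
        start = x0 if i == 0 else x0 * (1.0 + 0.2 * rng.standard_normal(x0.size))
        res = optimize.minimize(cost, start, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
        if res.fun < best_f:
            best_v, best_f = res.x, res.fun
        if not res.success:
            flags.append("simplex_nonconvergence")
    return unpack(best_v), best_f, flags


def f_test_select(
    rss1,
    rss2,
    rss3,
    n_points,
    alpha: float = 0.05,
    rss_floor=0.0,
):
    """Sequential nested F-tests; returns the deepest accepted model label.

    Accept model 2 over 1 iff F = (rss1 − rss2) / (rss2 / (n − 2)) exceeds the
    upper-``alpha`` quantile of F(1, n − 2); if accepted, test model 3 over 2
    with F(1, n − 3) analogously. Negative rss differences (optimizer noise)
    are clipped to zero; a perfect nested fit (both rss zero) yields the
    simpler model. ``rss_floor`` declares rss values and improvements at
    machine-round-off scale effectively zero, so noise-free voxels whose
    nested fits are all perfect stay at the simpler model instead of
    escalating on round-off ratios. Accepts scalars or arrays.
    """
    rss1 = np.asarray(rss1, float)
    rss2 = np.asarray(rss2, float)
    rss3 = np.asarray(rss3, float)
    floor = np.asarray(rss_floor, float)
    n = np.asarray(n_points)
    if np.any(n <= 3):
        raise ValueError("need more than 3 fitted points")

    with np.errstate(divide="ignore", invalid="ignore"):
        num21 = np.clip(rss1 - rss2, 0.0, None)
        num21 = np.where(num21 <= floor, 0.0, num21)
        f21 = np.where(rss2 > floor, num21 / (rss2 / (n - 2)),
                       np.where(num21 > 0, np.inf, 0.0))
        crit21 = stats.f.ppf(1 - alpha, 1, n - 2)
        accept2 = f21 > crit21

        num32 = np.clip(rss2 - rss3, 0.0, None)
        num32 = np.where(num32 <= floor, 0.0, num32)
        f32 = np.where(rss3 > floor, num32 / (rss3 / (n - 3)),
                       np.where(num32 > 0, np.inf, 0.0))
        crit32 = stats.f.ppf(1 - alpha, 1, n - 3)
        accept3 = accept2 & (f32 > crit32)

    label = 1 + accept2.astype(int) + accept3.astype(int)
    return label if label.ndim else int(label)


def run_nms_maps(
    dr1: np.ndarray,
    aif: AIFTrace,
    mask: np.ndarray,
    alpha: float = 0.05,
    max_invalid_frame_frac: float = 0.2,
    kep_grid: Optional[np.ndarray] = None,
    refine_kep: bool = True,
) -> NMSMaps:
    """Voxel-wise nested model selection over a 4-D ΔR1 volume.

    Models 1 and 2 are solved for every voxel at once by exact linear algebra;
    the model-3 kep profile shares its design matrices across voxels. Voxels
    flagged upstream (all-NaN or too many invalid frames) receive label 0 and
    are excluded from the maps and the result table. Deterministic.
    """
    dr1 = np.asarray(dr1, float)
    mask = np.asarray(mask, bool)
    nx, ny, nz, nt = dr1.shape
    flat = dr1.reshape(-1, nt)
    midx = np.flatnonzero(mask.reshape(-1))
    y = flat[midx]

    finite = np.isfinite(y)
    n_valid = finite.sum(axis=1)
    usable = n_valid >= (1.0 - max_invalid_frame_frac) * nt
    usable &= n_valid > 4

    grid = KEP_PROFILE_GRID if kep_grid is None else np.asarray(kep_grid, float)
    designs = [_design_columns(aif, k) for k in grid]

    labels = np.zeros(midx.size, dtype=np.int16)
    out_vp = np.full(midx.size, np.nan)
    out_kt = np.full(midx.size, np.nan)
    out_kep = np.full(midx.size, np.nan)
    rss_all = np.full((midx.size, 3), np.nan)
    records: List[dict] = []

    clean = usable & finite.all(axis=1)
    dirty = usable & ~finite.all(axis=1)

    if clean.any():
        yc = y[clean]
        x2 = designs[0]
        b1 = x2[:, 0]
        vp1 = (yc @ b1) / (b1 @ b1)
        rss1 = np.sum((yc - vp1[:, None] * b1) ** 2, axis=1)
        coef2, *_ = np.linalg.lstsq(x2, yc.T, rcond=None)
        rss2 = np.sum((yc - (x2 @ coef2).T) ** 2, axis=1)
        # kep profile: shared pseudo-inverses across voxels
        nv = yc.shape[0]
        rss3 = np.full(nv, np.inf)
        best_k = np.zeros(nv, dtype=int)
        coef3 = np.zeros((nv, 2))
        for ki, x3 in enumerate(designs):
            ck, *_ = np.linalg.lstsq(x3, yc.T, rcond=None)
            rk = np.sum((yc - (x3 @ ck).T) ** 2, axis=1)
            better = rk < rss3
            rss3[better] = rk[better]
            best_k[better] = ki
            coef3[better] = ck.T[better]
        kep3 = grid[best_k].astype(float)
        if refine_kep:
            for i in np.flatnonzero(best_k > 0):
                ki = best_k[i]
                lo, hi = grid[max(ki - 1, 0)], grid[min(ki + 1, grid.size - 1)]
                if hi <= lo:
                    continue
                yi = yc[i]

                def rss_at(kv: float, yi=yi) -> float:
                    x3 = _design_columns(aif, kv)
                    c, r = _lin_fit(yi, x3)
                    return r

                res = optimize.minimize_scalar(rss_at, bounds=(lo, hi), method="bounded",
                                               options={"xatol": 1e-5})
                if res.fun < rss3[i]:
                    rss3[i] = res.fun
                    kep3[i] = float(res.x)
                    c, _ = _lin_fit(yi, _design_columns(aif, kep3[i]))
                    coef3[i] = c
        rss3 = np.minimum(rss3, rss2)  # guard against refinement round-off
        floor = 1e-24 * np.sum(yc * yc, axis=1)
        lab = f_test_select(rss1, rss2, rss3, n_valid[clean], alpha=alpha,
                            rss_floor=floor)
        ci = np.flatnonzero(clean)
        labels[ci] = lab
        rss_all[ci, 0], rss_all[ci, 1], rss_all[ci, 2] = rss1, rss2, rss3
        out_vp[ci] = np.where(lab == 1, vp1, np.where(lab == 2, coef2[0], coef3[:, 0]))
        out_kt[ci] = np.where(lab >= 2, np.where(lab == 2, coef2[1], coef3[:, 1]), np.nan)
        out_kep[ci] = np.where(lab == 3, kep3, np.nan)

    for i in np.flatnonzero(dirty):
        curve = ConcentrationCurve(aif.times, y[i])
        p1, r1, _ = fit_model(curve, aif, 1)
        p2, r2, _ = fit_model(curve, aif, 2)
        p3, r3, _ = fit_model(curve, aif, 3, kep_grid=grid)
        r3 = min(r3, r2)
        floor_i = 1e-24 * float(np.nansum(y[i] * y[i]))
        lab = f_test_select(r1, r2, r3, int(n_valid[i]), alpha=alpha,
                            rss_floor=floor_i)
        labels[i] = lab
        rss_all[i] = (r1, r2, r3)
        chosen = {1: p1, 2: p2, 3: p3}[lab]
        out_vp[i] = chosen.vp
        out_kt[i] = chosen.ktrans if lab >= 2 else np.nan
        out_kep[i] = chosen.kep if lab == 3 else np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        out_ve = np.where((labels == 3) & (out_kep > 0), out_kt / out_kep, np.nan)

    def to_map(vals: np.ndarray, fill=np.nan, dtype=float) -> np.ndarray:
        m = np.full(nx * ny * nz, fill, dtype=dtype)
        m[midx] = vals
        return m.reshape(nx, ny, nz)

    ii, jj, kk = np.unravel_index(midx, (nx, ny, nz))
    table = pd.DataFrame(
        {
            "i": ii, "j": jj, "k": kk,
            "label": labels,
            "vp": out_vp, "ktrans": out_kt, "kep": out_kep,
            "ve": np.where(labels == 3, out_ve, np.nan),
            "rss1": rss_all[:, 0], "rss2": rss_all[:, 1], "rss3": rss_all[:, 2],
            "n_points": n_valid,
        }
    )
    return NMSMaps(
        model_map=to_map(labels, fill=0, dtype=np.int16),
        vp=to_map(out_vp),
        ktrans=to_map(out_kt),
        kep=to_map(out_kep),
        ve=to_map(out_ve),
        table=table,
    )
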