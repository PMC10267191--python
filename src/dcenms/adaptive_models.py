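"""Knowledge-based adaptive models: four shallow feed-forward networks.

One network regresses the nested-model label (1/2/3) from the 190-element
raw-signal feature vector and doubles as a classifier through knowledge-based
response thresholds; three further networks regress the pharmacokinetic
parameters (vp, ktrans, ve), each trained only on the voxel stratum where its
parameter is estimable. All four are single-hidden-layer perceptrons (tanh
hidden units, linear output) trained by Levenberg–Marquardt: damped
Gauss–Newton steps on the full batch Jacobian with multiplicative damping
adaptation, so accepted steps never increase the batch MSE.

Model selection (hidden size, stopping epoch) and generalization error are
estimated by study-level tenfold nested cross-validation: an outer loop of
disjoint held-out study folds and an inner random-permutation-sampled k-fold
loop on the remaining studies for tuning. Performance metrics are the
non-parametric (rank-based) ROC AUC for class separation, the Pearson
correlation and adjusted R² for the parameter regressions, and the correct
classification fraction (CCF).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MLPWeights",
    "TrainHistory",
    "train_mlp_lm",
    "ccf_stopping_epoch",
    "ThresholdResult",
    "optimize_thresholds",
    "classify_nms",
    "AMBundle",
    "train_adaptive_bundle",
    "StudySamples",
    "NCVReport",
    "nested_cv",
    "pearson_r",
    "adjusted_r2",
    "auc_nonparametric",
    "ccf",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; raises on zero variance (undefined)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need at least 3 paired values")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def adjusted_r2(y_true: np.ndarray, y_pred: np.ndarray, p: int = 1) -> float:
    """Adjusted R² = 1 − (1 − r²)(n − 1)/(n − p − 1).

    R² is the squared Pearson correlation of prediction against truth — the
    single-predictor (p = 1) relation between the two.
    """
    n = np.asarray(y_true).size
    r = pearson_r(y_true, y_pred)
    return float(1.0 - (1.0 - r * r) * (n - 1) / (n - p - 1))


def auc_nonparametric(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ROC AUC (Mann–Whitney statistic; ties mid-ranked).

    ``labels`` is boolean (True = positive class).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for AUC")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def ccf(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Correct classification fraction, (TP + TN) / total."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    return float(np.mean(y_true == y_pred))


# ---------------------------------------------------------------------------
# shallow MLP + Levenberg–Marquardt
# ---------------------------------------------------------------------------

@dataclass
class MLPWeights:
    """Single-hidden-layer perceptron: tanh hidden units, linear output."""

    w1: np.ndarray  # (h, d)
    b1: np.ndarray  # (h,)
    w2: np.ndarray  # (h,)
    b2: float

    @property
    def hidden_size(self) -> int:
        return self.w1.shape[0]

    @property
    def n_params(self) -> int:
        h, d = self.w1.shape
        return h * d + h + h + 1

    def predict(self, x: np.ndarray) -> np.ndarray:
        z = np.tanh(x @ self.w1.T + self.b1)
        return z @ self.w2 + self.b2

    def pack(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.b1, self.w2, [self.b2]])

    @classmethod
    def unpack(cls, p: np.ndarray, h: int, d: int) -> "MLPWeights":
        i = h * d
        return cls(
            w1=p[:i].reshape(h, d).copy(),
            b1=p[i : i + h].copy(),
            w2=p[i + h : i + 2 * h].copy(),
            b2=float(p[-1]),
        )

    @classmethod
    def init(cls, h: int, d: int, rng: np.random.Generator, y_mean: float = 0.0) -> "MLPWeights":
        return cls(
            w1=rng.normal(0.0, 1.0 / np.sqrt(d + 1), size=(h, d)),
            b1=rng.normal(0.0, 0.1, size=h),
            w2=rng.normal(0.0, 1.0 / np.sqrt(h), size=h),
            b2=float(y_mean),
        )

    def to_dict(self) -> dict:
        return {
            "w1": self.w1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPWeights":
        return cls(
            w1=np.asarray(d["w1"], float), b1=np.asarray(d["b1"], float),
            w2=np.asarray(d["w2"], float), b2=float(d["b2"]),
        )


@dataclass
class TrainHistory:
    """Per-epoch record of one Levenberg–Marquardt training run."""

    mse: List[float] = field(default_factory=list)
    val_metric: List[float] = field(default_factory=list)
    stop_reason: str = ""
    aborted: bool = False


def _jacobian(net: MLPWeights, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Full batch Jacobian of predictions w.r.t. the packed parameters."""
    z = np.tanh(x @ net.w1.T + net.b1)  # (n, h)
    g = (1.0 - z * z) * net.w2  # (n, h)
    n = x.shape[0]
    jw1 = (g[:, :, None] * x[:, None, :]).reshape(n, -1)  # (n, h*d)
    j = np.concatenate([jw1, g, z, np.ones((n, 1))], axis=1)
    yhat = z @ net.w2 + net.b2
    return j, yhat


def train_mlp_lm(
    x: np.ndarray,
    y: np.ndarray,
    h: int,
    seed: int = 0,
    max_epochs: int = 100,
    mu0: float = 1e-3,
    mu_up: float = 10.0,
    mu_down: float = 0.1,
    mu_max: float = 1e10,
    rel_tol: float = 1e-9,
    patience: int = 3,
    val: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    val_metric: Optional[Callable[[np.ndarray, np.ndarray], float]] = None,
    sample_cap: Optional[int] = None,
) -> Tuple[MLPWeights, TrainHistory]:
    """Batch Levenberg–Marquardt training of a 1-hidden-layer MLP.

    Minimizes the mean squared error with damped Gauss–Newton steps:
    ``δ = (JᵀJ + μI)⁻¹ Jᵀ r``; on acceptance (MSE decreased) μ is relaxed, on
    rejection μ is escalated until a decreasing step is found or μ exceeds
    ``mu_max`` (aborted, flagged). When samples < parameters the algebraically
    identical dual step ``δ = Jᵀ (JJᵀ + μI)⁻¹ r`` is solved in sample space.
    Deterministic given ``seed``. Training stops early once the relative MSE
    improvement stays below ``rel_tol`` for ``patience`` epochs.

    If a training set exceeds ``sample_cap`` it is subsampled (seeded) to keep
    the Jacobian in memory; the history records it.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float).ravel()
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("x must be (n, d) aligned with y")
    if h < 1:
        raise ValueError("hidden size must be >= 1")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite training data")
    rng = np.random.default_rng(seed)
    hist = TrainHistory()
    if sample_cap is not None and x.shape[0] > sample_cap:
        keep = rng.choice(x.shape[0], size=sample_cap, replace=False)
        x, y = x[keep], y[keep]
        hist.stop_reason = f"subsampled to {sample_cap}; "

    d = x.shape[1]
    net = MLPWeights.init(h, d, rng, y_mean=float(y.mean()))
    p = net.pack()
    n = x.shape[0]
    n_params = p.size
    mu = mu0

    def mse_of(pvec: np.ndarray) -> float:
        w = MLPWeights.unpack(pvec, h, d)
        r = y - w.predict(x)
        return float(np.mean(r * r))

    current = mse_of(p)
    stall = 0
    for _ in range(max_epochs):
        net = MLPWeights.unpack(p, h, d)
        j, yhat = _jacobian(net, x)
        r = y - yhat
        accepted = False
        while mu <= mu_max:
            try:
                if n >= n_params:
                    a = j.T @ j
                    a[np.diag_indices_from(a)] += mu
                    delta = np.linalg.solve(a, j.T @ r)
                else:
                    a = j @ j.T
                    a[np.diag_indices_from(a)] += mu
                    delta = j.T @ np.linalg.solve(a, r)
            except np.linalg.LinAlgError:
                mu *= mu_up
                continue
            trial = p + delta
            trial_mse = mse_of(trial)
            if np.isfinite(trial_mse) and trial_mse < current:
                rel = (current - trial_mse) / max(current, 1e-300)
                p, current = trial, trial_mse
                mu = max(mu * mu_down, 1e-12)
                accepted = True
                break
            mu *= mu_up
        hist.mse.append(current)
        if val is not None and val_metric is not None:
            w = MLPWeights.unpack(p, h, d)
            try:
                hist.val_metric.append(float(val_metric(val[1], w.predict(val[0]))))
            except ValueError:
                hist.val_metric.append(np.nan)
        if not accepted:
            hist.stop_reason += "damping exhausted (singular/ascent everywhere)"
            hist.aborted = True
            break
        if rel < rel_tol:
            stall += 1
            if stall >= patience:
                hist.stop_reason += "converged (relative MSE tolerance)"
                break
        else:
            stall = 0
    else:
        hist.stop_reason += "max epochs"
    return MLPWeights.unpack(p, h, d), hist


def ccf_stopping_epoch(
    curve: Sequence[float],
    level: float = 0.9,
    plateau_frac: float = 0.1,
    smooth_window: int = 1,
) -> int:
    """First (1-based) epoch whose smoothed metric reaches ``level`` of its plateau.

    The plateau is the mean of the final ``plateau_frac`` of epochs of the
    smoothed curve; noisy curves are smoothed with a centered moving average.
    ``level = 0.9`` implements the within-10%-of-plateau reading of the
    stopping rule; the alternative reading (10% of the plateau value) is
    ``level = 0.1``.
    """
    c = np.asarray(curve, float)
    if c.size < 5:
        raise ValueError("need at least 5 epochs")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        c = np.convolve(c, kernel, mode="same")
    tail = max(1, int(np.ceil(plateau_frac * c.size)))
    plateau = c[-tail:].mean()
    hits = np.flatnonzero(c >= level * plateau)
    return int(hits[0]) + 1 if hits.size else c.size


# ---------------------------------------------------------------------------
# knowledge-based thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdResult:
    cut: float
    err_low: float   # misclassification rate of the lower class
    err_high: float  # misclassification rate of the upper class
    feasible: bool   # both per-class errors within tolerance


_PAIRS = {"t12": (1, 2), "t13": (1, 3), "t23": (2, 3)}


def optimize_thresholds(
    responses: np.ndarray,
    labels: np.ndarray,
    tolerance: float = 0.05,
) -> Dict[str, ThresholdResult]:
    """Best class-separation cut points on the NMS-net response distribution.

    For each nested class pair, candidate cuts are the midpoints of
    consecutive sorted unique responses of the pooled pair. Among cuts whose
    per-class misclassification rates are both within ``tolerance``, the one
    maximizing balanced correct classification is chosen (first maximum on
    the sorted candidate list); if none is feasible the cut minimizing the
    larger per-class error is returned, flagged infeasible.
    """
    responses = np.asarray(responses, float)
    labels = np.asarray(labels)
    present = [c for c in (1, 2, 3) if np.any(labels == c)]
    if len(present) < 2:
        raise ValueError("need at least two classes to optimize thresholds")
    out: Dict[str, ThresholdResult] = {}
    for key, (lo, hi) in _PAIRS.items():
        r_lo = responses[labels == lo]
        r_hi = responses[labels == hi]
        if r_lo.size == 0 or r_hi.size == 0:
            continue  # pair not represented; its cut is not defined
        pooled = np.unique(np.concatenate([r_lo, r_hi]))
        if pooled.size < 2:
            raise ValueError("degenerate responses: single unique value")
        cuts = 0.5 * (pooled[:-1] + pooled[1:])
        err_lo = np.array([np.mean(r_lo >= c) for c in cuts])
        err_hi = np.array([np.mean(r_hi < c) for c in cuts])
        balanced = 1.0 - 0.5 * (err_lo + err_hi)
        feas = (err_lo <= tolerance) & (err_hi <= tolerance)
        if feas.any():
            idx_f = np.flatnonzero(feas)
            best = idx_f[int(np.argmax(balanced[idx_f]))]
            out[key] = ThresholdResult(float(cuts[best]), float(err_lo[best]),
                                       float(err_hi[best]), True)
        else:
            worst = np.maximum(err_lo, err_hi)
            order = np.lexsort((-balanced, worst))
            best = order[0]
            out[key] = ThresholdResult(float(cuts[best]), float(err_lo[best]),
                                       float(err_hi[best]), False)
    return out


def classify_nms(response, thresholds: Dict[str, ThresholdResult]):
    """Map continuous NMS-net responses to labels 1/2/3.

    Right-closed convention: label 1 iff response < θ12; label 3 iff
    response ≥ θ23; label 2 otherwise (θ13 serves the optional pairwise
    scheme and does not enter the default rule).
    """
    r = np.asarray(response, float)
    t12 = thresholds["t12"].cut if "t12" in thresholds else -np.inf
    t23 = thresholds["t23"].cut if "t23" in thresholds else np.inf
    lab = np.where(r < t12, 1, np.where(r >= t23, 3, 2)).astype(np.int16)
    return lab if lab.ndim else int(lab)


# ---------------------------------------------------------------------------
# bundle training
# ---------------------------------------------------------------------------

_PK_NAMES = ("vp", "ktrans", "ve")


@dataclass
class AMBundle:
    """Trained adaptive-model bundle: NMS net, PK nets, thresholds, provenance."""

    nms_net: MLPWeights
    pk_nets: Dict[str, Optional[MLPWeights]]
    thresholds: Dict[str, ThresholdResult]
    scaling: Optional[Dict[str, np.ndarray]]  # feature z-scoring constants or None
    provenance: Dict[str, object] = field(default_factory=dict)

    def _scale(self, x: np.ndarray) -> np.ndarray:
        if self.scaling is None:
            return x
        return (x - self.scaling["mean"]) / self.scaling["std"]

    def nms_response(self, x: np.ndarray) -> np.ndarray:
        return self.nms_net.predict(self._scale(x))

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        return classify_nms(self.nms_response(x), self.thresholds)

    def predict_params(self, x: np.ndarray, labels: Optional[np.ndarray] = None) -> Dict[str, np.ndarray]:
        """PK parameter predictions masked by (predicted) label estimability."""
        xs = self._scale(x)
        if labels is None:
            labels = self.predict_labels(x)
        out: Dict[str, np.ndarray] = {}
        for name, min_label in (("vp", 1), ("ktrans", 2), ("ve", 3)):
            net = self.pk_nets.get(name)
            vals = np.full(x.shape[0], np.nan)
            if net is not None:
                sel = labels >= min_label
                if sel.any():
                    vals[sel] = net.predict(xs[sel])
            out[name] = vals
        return out

    def to_json(self) -> str:
        doc = {
            "format": "dcenms-ambundle-1",
            "nms_net": self.nms_net.to_dict(),
            "pk_nets": {k: (v.to_dict() if v is not None else None)
                        for k, v in self.pk_nets.items()},
            "thresholds": {k: vars(v) for k, v in self.thresholds.items()},
            "scaling": None if self.scaling is None else
                       {k: np.asarray(v).tolist() for k, v in self.scaling.items()},
            "provenance": self.provenance,
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AMBundle":
        doc = json.loads(text)
        if doc.get("format") != "dcenms-ambundle-1":
            raise ValueError("unrecognized bundle format")
        return cls(
            nms_net=MLPWeights.from_dict(doc["nms_net"]),
            pk_nets={k: (MLPWeights.from_dict(v) if v is not None else None)
                     for k, v in doc["pk_nets"].items()},
            thresholds={k: ThresholdResult(**v) for k, v in doc["thresholds"].items()},
            scaling=None if doc["scaling"] is None else
                    {k: np.asarray(v, float) for k, v in doc["scaling"].items()},
            provenance=doc["provenance"],
        )


def train_adaptive_bundle(
    x: np.ndarray,
    nms_truth: np.ndarray,
    pk_truth: Dict[str, np.ndarray],
    seed: int = 0,
    h_nms: int = 10,
    h_pk: int = 7,
    tolerance: float = 0.05,
    max_epochs: int = 60,
    zscore: bool = False,
    mask_source: str = "predicted",
    sample_cap: Optional[int] = None,
) -> AMBundle:
    """Train the four networks and the class-separation thresholds.

    The NMS net regresses the truth labels {1,2,3} on all voxels; thresholds
    are optimized on its training responses. The vp net trains on all voxels;
    the ktrans net on voxels of label ≥ 2 and the ve net on label = 3 voxels,
    where the stratifying label is the NMS net's own prediction
    (``mask_source="predicted"``, the default) or the truth labels
    (``mask_source="truth"``). An empty stratum leaves that net absent,
    flagged in the provenance.
    """
    x = np.asarray(x, float)
    nms_truth = np.asarray(nms_truth)
    scaling = None
    if zscore:
        std = x.std(axis=0)
        std[std == 0] = 1.0
        scaling = {"mean": x.mean(axis=0), "std": std}
        xs = (x - scaling["mean"]) / scaling["std"]
    else:
        xs = x

    nms_net, nms_hist = train_mlp_lm(
        xs, nms_truth.astype(float), h_nms, seed=seed,
        max_epochs=max_epochs, sample_cap=sample_cap,
    )
    thresholds = optimize_thresholds(nms_net.predict(xs), nms_truth, tolerance=tolerance)
    if mask_source == "predicted":
        strat_labels = classify_nms(nms_net.predict(xs), thresholds)
    elif mask_source == "truth":
        strat_labels = nms_truth
    else:
        raise ValueError("mask_source must be 'predicted' or 'truth'")

    pk_nets: Dict[str, Optional[MLPWeights]] = {}
    missing: List[str] = []
    for i, (name, min_label) in enumerate((("vp", 1), ("ktrans", 2), ("ve", 3))):
        target = np.asarray(pk_truth[name], float)
        sel = (strat_labels >= min_label) & np.isfinite(target)
        if sel.sum() < 10:
            pk_nets[name] = None
            missing.append(name)
            continue
        net, _ = train_mlp_lm(
            xs[sel], target[sel], h_pk, seed=seed + 1 + i,
            max_epochs=max_epochs, sample_cap=sample_cap,
        )
        pk_nets[name] = net

    return AMBundle(
        nms_net=nms_net,
        pk_nets=pk_nets,
        thresholds=thresholds,
        scaling=scaling,
        provenance={
            "seed": seed, "h_nms": h_nms, "h_pk": h_pk,
            "epochs_nms": len(nms_hist.mse), "tolerance": tolerance,
            "mask_source": mask_source, "n_train": int(x.shape[0]),
            "missing_nets": missing,
        },
    )


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class StudySamples:
    """Per-study voxel samples for cross-validation.

    ``nms_labels``/``pk`` are the *training truth* (conventional-pipeline
    results); ``truth_labels``/``truth_pk`` the evaluation reference (e.g.
    phantom ground truth). When the two coincide, pass the same arrays.
    """

    study_id: str
    x: np.ndarray
    nms_labels: np.ndarray
    pk: Dict[str, np.ndarray]
    truth_labels: Optional[np.ndarray] = None
    truth_pk: Optional[Dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.truth_labels is None:
            self.truth_labels = self.nms_labels
        if self.truth_pk is None:
            self.truth_pk = self.pk


@dataclass
class NCVReport:
    """Outcome of the nested cross-validation: per-fold rows + aggregates."""

    folds: pd.DataFrame
    aggregate: Dict[str, float]
    fold_assignment: Dict[str, int]

    def summary(self) -> str:
        lines = [f"{k}: {v:.4g}" for k, v in sorted(self.aggregate.items())]
        return "\n".join(lines)


def _concat_studies(studies: Sequence[StudySamples], cap_per_study: Optional[int],
                    rng: np.random.Generator):
    xs, labs, pk, tl, tpk = [], [], {k: [] for k in _PK_NAMES}, [], {k: [] for k in _PK_NAMES}
    for st in studies:
        n = st.x.shape[0]
        idx = np.arange(n)
        if cap_per_study is not None and n > cap_per_study:
            idx = rng.choice(n, size=cap_per_study, replace=False)
        xs.append(st.x[idx])
        labs.append(st.nms_labels[idx])
        tl.append(st.truth_labels[idx])
        for k in _PK_NAMES:
            pk[k].append(st.pk[k][idx])
            tpk[k].append(st.truth_pk[k][idx])
    return (
        np.concatenate(xs),
        np.concatenate(labs),
        {k: np.concatenate(v) for k, v in pk.items()},
        np.concatenate(tl),
        {k: np.concatenate(v) for k, v in tpk.items()},
    )


def _inner_tune(
    studies: Sequence[StudySamples],
    target: str,  # "nms" or a PK name
    hidden_grid: Sequence[int],
    inner_k: int,
    inner_repeats: int,
    rng: np.random.Generator,
    max_epochs: int,
    cap_per_study: Optional[int],
    zscore: bool = False,
) -> Tuple[int, int]:
    """Random-permutation-sampled inner CV; returns (best hidden size, stop epoch)."""
    scores = {h: [] for h in hidden_grid}
    curves = {h: [] for h in hidden_grid}
    ids = np.arange(len(studies))
    k = min(inner_k, len(studies))
    for _ in range(inner_repeats):
        perm = rng.permutation(ids)
        folds = np.array_split(perm, k)
        for fi in range(k):
            val_ids = folds[fi]
            tr_ids = np.concatenate([folds[j] for j in range(k) if j != fi])
            if val_ids.size == 0 or tr_ids.size == 0:
                continue
            xt, lt, pkt, _, _ = _concat_studies([studies[i] for i in tr_ids], cap_per_study, rng)
            xv, lv, pkv, _, _ = _concat_studies([studies[i] for i in val_ids], cap_per_study, rng)
            if target == "nms":
                yt, yv = lt.astype(float), lv.astype(float)
                sel_t = np.ones(yt.size, bool)
                sel_v = np.ones(yv.size, bool)
            else:
                min_label = {"vp": 1, "ktrans": 2, "ve": 3}[target]
                sel_t = (lt >= min_label) & np.isfinite(pkt[target])
                sel_v = (lv >= min_label) & np.isfinite(pkv[target])
                yt, yv = pkt[target], pkv[target]
            if sel_t.sum() < 20 or sel_v.sum() < 5:
                continue
            xt_s, xv_s = xt, xv
            if zscore:
                mu = xt[sel_t].mean(axis=0)
                sd = xt[sel_t].std(axis=0)
                sd[sd == 0] = 1.0
                xt_s = (xt - mu) / sd
                xv_s = (xv - mu) / sd
            for h in hidden_grid:
                net, hist = train_mlp_lm(
                    xt_s[sel_t], yt[sel_t], h,
                    seed=int(rng.integers(2**31 - 1)),
                    max_epochs=max_epochs,
                    val=(xv_s[sel_v], yv[sel_v]),
                    val_metric=lambda a, b: pearson_r(a, b),
                )
                try:
                    scores[h].append(pearson_r(yv[sel_v], net.predict(xv_s[sel_v])))
                except ValueError:
                    scores[h].append(0.0)
                curves[h].append(hist.val_metric)
    means = {h: (np.mean(s) if s else -np.inf) for h, s in scores.items()}
    best_h = max(hidden_grid, key=lambda h: means[h])
    stop_epoch = max_epochs
    if curves[best_h]:
        max_len = max(len(c) for c in curves[best_h])
        if max_len >= 5:
            padded = np.full((len(curves[best_h]), max_len), np.nan)
            for i, c in enumerate(curves[best_h]):
                padded[i, : len(c)] = c
                padded[i, len(c):] = c[-1] if c else np.nan
            mean_curve = np.nanmean(padded, axis=0)
            if np.all(np.isfinite(mean_curve)):
                stop_epoch = ccf_stopping_epoch(mean_curve)
    return best_h, stop_epoch


def nested_cv(
    studies: Sequence[StudySamples],
    k_outer: int = 10,
    seed: int = 0,
    hidden_grid: Sequence[int] = (5, 7, 10, 15),
    inner_k: int = 5,
    inner_repeats: int = 3,
    max_epochs: int = 60,
    cap_per_study: Optional[int] = None,
    tolerance: float = 0.05,
    zscore: bool = False,
    _inject_leak: bool = False,
) -> NCVReport:
    """Study-level tenfold nested cross-validation of the adaptive models.

    Outer folds are disjoint study sets covering the cohort; the inner loop
    tunes the hidden size (one for the NMS net, one shared by the PK nets,
    proxied by the ktrans regression) and the stopping epoch on the
    train+validation studies only. The tuned bundle is retrained on those
    studies and evaluated once on the held-out fold: Pearson r and adjusted
    R² per regression (against the evaluation truth), rank AUC for the
    model-1-vs-2&3 and 2-vs-3 separations, and the thresholded CCF.

    ``_inject_leak=True`` deliberately adds the held-out studies to training
    (a leakage detector for tests); never use it for reported numbers.
    """
    if len(studies) < k_outer:
        raise ValueError(
            f"{len(studies)} studies < k_outer={k_outer}: reduce k_outer or add studies"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(studies))
    folds = np.array_split(order, k_outer)
    assignment = {studies[i].study_id: fi for fi, fold in enumerate(folds) for i in fold}

    # structural no-leakage assertion: disjoint cover
    all_ids = np.concatenate(folds)
    assert np.array_equal(np.sort(all_ids), np.arange(len(studies)))

    rows: List[dict] = []
    for fi, test_ids in enumerate(folds):
        trainval_ids = np.array([i for i in order if i not in set(test_ids)])
        assert set(test_ids).isdisjoint(trainval_ids)
        trainval = [studies[i] for i in trainval_ids]
        if _inject_leak:
            trainval = trainval + [studies[i] for i in test_ids]
        test = [studies[i] for i in test_ids]

        fold_rng = np.random.default_rng(seed * 1000 + fi + 1)
        h_nms, ep_nms = _inner_tune(trainval, "nms", hidden_grid, inner_k,
                                    inner_repeats, fold_rng, max_epochs, cap_per_study,
                                    zscore=zscore)
        h_pk, ep_pk = _inner_tune(trainval, "ktrans", hidden_grid, inner_k,
                                  inner_repeats, fold_rng, max_epochs, cap_per_study,
                                  zscore=zscore)

        xt, lt, pkt, _, _ = _concat_studies(trainval, cap_per_study, fold_rng)
        bundle = train_adaptive_bundle(
            xt, lt, pkt, seed=seed * 100 + fi, h_nms=h_nms, h_pk=h_pk,
            tolerance=tolerance, max_epochs=max(ep_nms, ep_pk), zscore=zscore,
        )

        xv, _, _, tl, tpk = _concat_studies(test, None, fold_rng)
        resp = bundle.nms_response(xv)
        pred_lab = classify_nms(resp, bundle.thresholds)
        row = {"fold": fi, "h_nms": h_nms, "h_pk": h_pk,
               "stop_epoch_nms": ep_nms, "stop_epoch_pk": ep_pk,
               "n_test": int(xv.shape[0])}
        try:
            row["r_nms"] = pearson_r(tl.astype(float), resp)
            row["adj_r2_nms"] = adjusted_r2(tl.astype(float), resp)
        except ValueError:
            row["r_nms"] = np.nan
            row["adj_r2_nms"] = np.nan
        row["ccf_nms"] = ccf(tl, pred_lab)
        try:
            row["auc_1_vs_23"] = auc_nonparametric(resp, tl >= 2)
        except ValueError:
            row["auc_1_vs_23"] = np.nan
        try:
            sel23 = tl >= 2
            row["auc_2_vs_3"] = auc_nonparametric(resp[sel23], tl[sel23] == 3)
        except ValueError:
            row["auc_2_vs_3"] = np.nan

        preds = bundle.predict_params(xv, labels=tl)  # evaluate on truth-estimable strata
        for name, min_label in (("vp", 1), ("ktrans", 2), ("ve", 3)):
            truth = np.asarray(tpk[name], float)
            sel = (tl >= min_label) & np.isfinite(truth) & np.isfinite(preds[name])
            if sel.sum() >= 3 and np.std(truth[sel]) > 0:
                row[f"r_{name}"] = pearson_r(truth[sel], preds[name][sel])
                row[f"adj_r2_{name}"] = adjusted_r2(truth[sel], preds[name][sel])
                # constant mean predictor has zero covariance with the truth
                row[f"r_{name}_baseline"] = 0.0
                row[f"rmse_{name}"] = float(np.sqrt(np.mean((truth[sel] - preds[name][sel]) ** 2)))
                row[f"rmse_{name}_baseline"] = float(np.std(truth[sel]))
            else:
                row[f"r_{name}"] = np.nan
                row[f"adj_r2_{name}"] = np.nan
        rows.append(row)

    df = pd.DataFrame(rows)
    aggregate: Dict[str, float] = {}
    for col in df.columns:
        if col in ("fold",):
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.notna().any():
            aggregate[f"mean_{col}"] = float(vals.mean())
    return NCVReport(folds=df, aggregate=aggregate, fold_assignment=assignment)
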