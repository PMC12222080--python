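"""Sliding-window pairwise Granger causality with AIC order selection.

The statistic for an ordered channel pair (Y -> X) is

    F_{Y->X} = ln( var(eps_univariate) / var(eps_bivariate) )

where the univariate model regresses X on its own p lags and the bivariate
model adds the p lags of Y.  Both models are fit by ordinary least squares
with no intercept on mean-subtracted windows.  Residual sums of squares come
from a single QR factorization with the target's own lags ordered first, so
the univariate RSS equals the bivariate RSS plus the squared projections on
the added columns: nestedness (and hence F >= 0) holds exactly in floating
point, not merely to tolerance.

Model order is chosen by minimizing AIC = n ln(RSS/n) + 2k of the bivariate
fits, averaged over channel pairs, selected trials and sliding windows, with
n the effective observation count after lag truncation and k the number of
estimated coefficients (2p per bivariate target equation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EpochSet

__all__ = [
    "SlidingWindowSpec",
    "ARFit",
    "GCMatrix",
    "OrderSelection",
    "make_windows",
    "lag_matrix",
    "fit_ar",
    "gc_pair",
    "gc_matrix",
    "aic",
    "select_order",
    "gc_cells",
]

#: Relative tolerance below which an R-diagonal flags a rank-deficient design.
#: Exact collinearity lands near machine epsilon (~1e-16 relative); legitimate
#: narrowband-filtered series can reach ~1e-10, so the guard sits between.
_RANK_RTOL = 1e-13
#: Residual variance below this (relative to series power) is degenerate.
#: A deterministic pair leaves rss/power ~ (n*eps)^2 ~ 1e-27; narrowband
#: signals are legitimately predictable down to ~1e-21.
_DEGENERATE_RTOL = 1e-24


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the lagged design is rank deficient for a channel pair."""


class DegenerateSeriesError(ValueError):
    """Raised when a bivariate fit leaves (numerically) zero residual variance."""


@dataclass(frozen=True)
class SlidingWindowSpec:
    """Overlapping sliding windows tiling the epoch.

    Defaults give five 1-s windows at 50% overlap over the [-2, +1] s epoch:
    [-2,-1], [-1.5,-0.5], [-1,0], [-0.5,0.5], [0,1].
    """

    window_length: float = 1.0
    overlap: float = 0.5
    epoch_span: tuple = (-2.0, 1.0)

    def __post_init__(self):
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if self.window_length > self.epoch_span[1] - self.epoch_span[0]:
            raise ValueError("window longer than the epoch")


def make_windows(spec: SlidingWindowSpec, rate: float) -> list:
    """Half-open (start, end) sample intervals of the sliding windows."""
    step_s = spec.window_length * (1.0 - spec.overlap)
    if step_s <= 0:
        raise ValueError("window step is zero (overlap too high)")
    wlen = int(round(spec.window_length * rate))
    step = int(round(step_s * rate))
    if step < 1:
        raise ValueError("window step rounds to zero samples")
    total = int(round((spec.epoch_span[1] - spec.epoch_span[0]) * rate))
    windows = []
    start = 0
    while start + wlen <= total:
        windows.append((start, start + wlen))
        start += step
    return windows


def lag_matrix(x: np.ndarray, p: int) -> np.ndarray:
    """Lagged design of a single series: row t holds (x_{t-1}, ..., x_{t-p})."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n <= p:
        raise ValueError(f"series length {n} too short for order {p}")
    cols = [x[p - k : n - k] for k in range(1, p + 1)]
    return np.column_stack(cols)


@dataclass
class ARFit:
    """OLS fit of a (uni- or bivariate) autoregressive model without intercept."""

    order: int
    coeffs: np.ndarray  # (n_predictor_series, order)
    rss: float
    n_obs: int

    @property
    def residual_variance(self) -> float:
        return self.rss / self.n_obs


def _qr_checked(design: np.ndarray, label: str):
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    if diag.min() <= _RANK_RTOL * max(diag.max(), 1e-300):
        raise SingularDesignError(f"rank-deficient lagged design for {label}")
    return q, r


def fit_ar(target: np.ndarray, predictors, p: int) -> ARFit:
    """Fit an AR model of ``target`` on the p lags of each predictor series.

    ``predictors`` is a sequence of series (the target's own history first for
    a standard AR fit).  Raises :class:`SingularDesignError` on collinear
    designs (e.g. duplicated or constant series).
    """
    target = np.asarray(target, dtype=float)
    if not np.all(np.isfinite(target)):
        raise ValueError("non-finite values in target series")
    design = np.hstack([lag_matrix(np.asarray(s, float), p) for s in predictors])
    y = target[p:]
    q, r = _qr_checked(design, f"{len(predictors)}-series AR({p}) fit")
    qty = q.T @ y
    coeffs = np.linalg.solve(r, qty)
    resid = y - q @ qty
    return ARFit(
        order=p,
        coeffs=coeffs.reshape(len(predictors), p),
        rss=float(resid @ resid),
        n_obs=y.shape[0],
    )


def _pair_rss(own_lags, other_lags, y, label):
    """(rss_uni, rss_biv, n_obs) with exact nesting via own-first QR."""
    p = own_lags.shape[1]
    q, r = _qr_checked(np.hstack([own_lags, other_lags]), label)
    qty = q.T @ y
    resid = y - q @ qty
    rss_biv = float(resid @ resid)
    rss_uni = rss_biv + float(qty[p:] @ qty[p:])
    return rss_uni, rss_biv, y.shape[0]


def _check_degenerate(rss_biv, y, label):
    power = float(y @ y)
    if rss_biv <= _DEGENERATE_RTOL * max(power, 1e-300):
        raise DegenerateSeriesError(
            f"zero bivariate residual variance for {label} (deterministic pair)"
        )


def gc_pair(x: np.ndarray, y: np.ndarray, p: int) -> tuple:
    """Granger causality for one channel pair: returns (F_{y->x}, F_{x->y}).

    Both series are mean-subtracted before fitting (the AR models carry no
    intercept).  Raises on rank-deficient designs and on deterministic pairs
    with zero bivariate residual variance.
    """
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    lx, ly = lag_matrix(x, p), lag_matrix(y, p)
    out = []
    for own, other, tgt, label in ((lx, ly, x, "x"), (ly, lx, y, "y")):
        rss_u, rss_b, _ = _pair_rss(own, other, tgt[p:], f"target {label}")
        _check_degenerate(rss_b, tgt[p:], f"target {label}")
        out.append(float(np.log(rss_u / rss_b)))
    return out[0], out[1]


@dataclass
class GCMatrix:
    """Directed connectivity of one (subject, band, condition, window) cell.

    ``weights[i, j]`` is F_{i->j}; the diagonal is zero by convention.
    ``symmetric_max[i, j] = max(F_{i->j}, F_{j->i})`` is kept as the
    undirected interaction-strength variant.
    """

    weights: np.ndarray
    order: int
    window: tuple | None = None
    window_id: str | None = None
    band: str | None = None
    condition: str | None = None
    subject: str | None = None
    group: str | None = None
    symmetric_max: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.symmetric_max is None:
            self.symmetric_max = np.maximum(self.weights, self.weights.T)


def _gc_single(window: np.ndarray, p: int) -> np.ndarray:
    """F matrix of one demeaned (n_channels, n_samples) window.

    Block orthogonalization: each channel's own-lag block is QR-factored
    once; for a given target, every source-lag block is projected against
    the target's own-lag basis in a single matrix product, the residual
    blocks are QR-factored batched, and the bivariate RSS is the squared
    norm of the univariate residual after projection onto that basis.
    Because the projection is onto an orthonormal basis, the bivariate RSS
    never exceeds the univariate RSS in floating point, so F >= 0 exactly.
    """
    n_ch, n_samp = window.shape
    n_obs = n_samp - p
    lags = np.stack([lag_matrix(window[c], p) for c in range(n_ch)])  # (N, n_obs, p)
    ys = window[:, p:]

    q_own, r_own = np.linalg.qr(lags)
    diag_own = np.abs(np.diagonal(r_own, axis1=1, axis2=2))
    col_scale = diag_own.max(axis=1)
    bad = diag_own.min(axis=1) <= _RANK_RTOL * np.maximum(col_scale, 1e-300)
    if bad.any():
        raise SingularDesignError(
            f"rank-deficient lag design for channel {int(np.flatnonzero(bad)[0])}"
        )
    qty = np.einsum("cap,ca->cp", q_own, ys)
    u = ys - np.einsum("cap,cp->ca", q_own, qty)  # univariate residuals
    rss_uni = np.einsum("ca,ca->c", u, u)
    power = np.einsum("ca,ca->c", ys, ys)

    lag_flat = np.ascontiguousarray(lags.transpose(1, 0, 2)).reshape(n_obs, n_ch * p)
    weights = np.zeros((n_ch, n_ch))
    for tgt in range(n_ch):
        # residuals of every source-lag block against the target's own basis
        cross = q_own[tgt].T @ lag_flat                     # (p, N*p)
        m = (lag_flat - q_own[tgt] @ cross).reshape(n_obs, n_ch, p)
        srcs = np.array([j for j in range(n_ch) if j != tgt])
        q_m, r_m = np.linalg.qr(np.ascontiguousarray(m[:, srcs, :].transpose(1, 0, 2)))
        diag_m = np.abs(np.diagonal(r_m, axis1=1, axis2=2))
        collinear = diag_m.min(axis=1) <= _RANK_RTOL * np.maximum(
            col_scale[srcs], 1e-300
        )
        if collinear.any():
            src = int(srcs[np.flatnonzero(collinear)[0]])
            raise SingularDesignError(
                f"rank-deficient lagged design for channel pair ({src} -> {tgt})"
            )
        w = np.einsum("kap,a->kp", q_m, u[tgt])
        resid = u[tgt][None, :] - np.einsum("kap,kp->ka", q_m, w)
        rss_biv = np.einsum("ka,ka->k", resid, resid)
        degenerate = rss_biv <= _DEGENERATE_RTOL * max(power[tgt], 1e-300)
        if degenerate.any():
            src = int(srcs[np.flatnonzero(degenerate)[0]])
            raise DegenerateSeriesError(
                f"zero bivariate residual variance for channel pair ({src} -> {tgt})"
            )
        weights[srcs, tgt] = np.log(rss_uni[tgt] / rss_biv)
    return weights


def gc_matrix(window_data: np.ndarray, p: int, **meta) -> GCMatrix:
    """Directed GC matrix of a window, averaged across trials.

    ``window_data`` is (n_trials, n_channels, n_samples) or a single
    (n_channels, n_samples) window.  Each trial window is mean-subtracted per
    channel, all ordered pairs are evaluated, and per-trial matrices are
    averaged.  Pair-level failures propagate with the pair identified.
    """
    window_data = np.asarray(window_data, dtype=float)
    if window_data.ndim == 2:
        window_data = window_data[None]
    if window_data.ndim != 3:
        raise ValueError("window_data must be (trials, channels, samples)")
    if window_data.shape[1] < 2:
        raise ValueError("Granger causality needs at least 2 channels")
    demeaned = window_data - window_data.mean(axis=2, keepdims=True)
    acc = np.zeros(window_data.shape[1:2] * 2)
    for trial in demeaned:
        acc += _gc_single(trial, p)
    return GCMatrix(weights=acc / window_data.shape[0], order=p, **meta)


def aic(n_obs: int, rss: float, k: int) -> float:
    """Akaike information criterion: n ln(RSS/n) + 2k."""
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    if rss <= 0:
        raise ValueError("AIC undefined for nonpositive RSS (log divergence)")
    return n_obs * float(np.log(rss / n_obs)) + 2 * k


@dataclass
class OrderSelection:
    """AIC-selected model order and the averaged AIC trace that chose it."""

    p0: int
    trace: pd.DataFrame  # columns p, mean_aic


def _select_trials(meta: pd.DataFrame, n_lead: int, fraction: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Lead collision trials plus a random fraction of the remainder."""
    idx = np.arange(len(meta))
    if "condition" in meta.columns:
        lead = idx[meta["condition"].to_numpy() == "collision"][:n_lead]
    else:
        lead = idx[:n_lead]
    rest = np.setdiff1d(idx, lead)
    n_sub = int(round(fraction * len(rest)))
    subsample = rng.choice(rest, size=n_sub, replace=False) if n_sub else np.array([], int)
    return np.sort(np.concatenate([lead, subsample]))


def select_order(
    epochs: EpochSet,
    p_range: tuple = (1, 15),
    trial_subsample: float = 0.1,
    n_lead_trials: int = 5,
    window_spec: SlidingWindowSpec | None = None,
    channel_pairs: list | None = None,
    seed: int = 0,
) -> OrderSelection:
    """Select the AR order p0 by the averaged bivariate-AIC protocol.

    The lead collision trials (default: first five) plus a random trial
    subsample (default 10%) are evaluated; for each candidate p the AIC of
    every bivariate target equation is averaged across channel pairs, trials
    and sliding windows, and p0 is the argmin (ties broken toward smaller p).
    """
    lo, hi = int(p_range[0]), int(p_range[1])
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid order range {p_range}")
    rng = np.random.default_rng(seed)
    trials = _select_trials(epochs.trial_meta, n_lead_trials, trial_subsample, rng)
    if trials.size == 0:
        raise ValueError("empty trial selection for order search")

    if window_spec is not None:
        windows = make_windows(window_spec, epochs.sample_rate)
    else:
        windows = make_windows(SlidingWindowSpec(), epochs.sample_rate)
        if not windows or windows[-1][1] != epochs.n_samples:
            windows = [(0, epochs.n_samples)]

    n_ch = epochs.n_channels
    if channel_pairs is None:
        channel_pairs = [(i, j) for i in range(n_ch) for j in range(i + 1, n_ch)]

    rows = []
    for p in range(lo, hi + 1):
        scores = []
        for t in trials:
            for start, end in windows:
                seg = epochs.data[t, :, start:end]
                seg = seg - seg.mean(axis=1, keepdims=True)
                lags = {}
                for i, j in channel_pairs:
                    for c in (i, j):
                        if c not in lags:
                            lags[c] = lag_matrix(seg[c], p)
                    for tgt, src in ((i, j), (j, i)):
                        _, rss_b, n_obs = _pair_rss(
                            lags[tgt], lags[src], seg[tgt, p:], f"pair ({src}->{tgt})"
                        )
                        scores.append(aic(n_obs, rss_b, 2 * p))
        rows.append({"p": p, "mean_aic": float(np.mean(scores))})
    trace = pd.DataFrame(rows)
    p0 = int(trace.loc[trace["mean_aic"].idxmin(), "p"])  # idxmin -> first = smallest p
    return OrderSelection(p0=p0, trace=trace)


def gc_cells(
    epochs: EpochSet,
    p: int,
    window_spec: SlidingWindowSpec | None = None,
    subject: str | None = None,
    group: str | None = None,
) -> tuple:
    """GC matrices for every (condition, window) cell of one subject's epochs.

    Per-trial matrices are averaged within each cell.  Returns the list of
    :class:`GCMatrix` and a long-format DataFrame with one row per directed
    channel pair (subject, group, band, condition, window, source, target, F).
    """
    spec = window_spec or SlidingWindowSpec()
    windows = make_windows(spec, epochs.sample_rate)
    meta = epochs.trial_meta
    subject = subject or (meta["subject_id"].iloc[0] if "subject_id" in meta else None)
    group = group or (meta["group"].iloc[0] if "group" in meta else None)
    conditions = (
        list(dict.fromkeys(meta["condition"])) if "condition" in meta else [None]
    )

    matrices, rows = [], []
    src_idx, tgt_idx = np.nonzero(~np.eye(epochs.n_channels, dtype=bool))
    for condition in conditions:
        mask = (
            (meta["condition"] == condition).to_numpy()
            if condition is not None
            else np.ones(len(meta), bool)
        )
        if not mask.any():
            continue
        trials = epochs.data[mask]
        for w, (start, end) in enumerate(windows):
            m = gc_matrix(
                trials[:, :, start:end],
                p,
                window=(start, end),
                window_id=f"SW{w + 1}",
                band=epochs.band,
                condition=condition,
                subject=subject,
                group=group,
            )
            matrices.append(m)
            rows.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "group": group,
                        "band": epochs.band,
                        "condition": condition,
                        "window": m.window_id,
                        "source": src_idx,
                        "target": tgt_idx,
                        "F": m.weights[src_idx, tgt_idx],
                    }
                )
            )
    long = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return matrices, long
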