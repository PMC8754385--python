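"""Task-weighted ROI-to-ROI functional connectivity.

Connectivity during a task condition is estimated as a weighted Pearson
correlation between node time series, with per-volume weights given by the
condition's boxcar convolved with a canonical hemodynamic response function
(HRF). Correlations are Fisher-z transformed; the nociceptive contrast is
the elementwise difference of the reinforced-cue and unreinforced-cue
connectivity matrices. Time series are confound-regressed and band-pass
filtered first; spatial smoothing is never applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .containers import (
    CS_PLUS_NOUS,
    CS_PLUS_US,
    MOTION_COLUMNS,
    US,
    FCMatrixStack,
    RoiTimeSeries,
    validate_events,
)

logger = logging.getLogger("twinconn")

Z_CAP = np.arctanh(1 - 1e-7)


@dataclass
class ConditionWeights:
    """Per-volume nonnegative weights for one task condition."""

    weights: np.ndarray
    condition: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be 1-D")
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")
        if not (self.weights > 0).any():
            raise ValueError("weights must not be all zero")


def canonical_hrf(dt: float) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds on [0, 32] s.

    Response gamma with peak delay 6 s, undershoot gamma with delay 16 s,
    unit dispersions, undershoot ratio 1/6; normalized so the positive part
    sums to one.
    """
    if not 0 < dt <= 32:
        raise ValueError("dt must be in (0, 32]")
    t = np.arange(0.0, 32.0 + 1e-9, dt)
    h = sstats.gamma.pdf(t, a=6, scale=1.0) - sstats.gamma.pdf(t, a=16, scale=1.0) / 6.0
    return h / h[h > 0].sum()


def condition_weight_series(
    events: pd.DataFrame,
    condition: str | Sequence[str],
    n_vols: int,
    tr: float,
) -> ConditionWeights:
    """HRF-convolved boxcar of a condition, sampled at volume times.

    ``condition`` may be a single trial_type or a list of trial_types whose
    event intervals are merged into one boxcar (used for the combined
    reinforced-cue-plus-stimulus condition). Negative convolution lobes are
    rectified to zero so the result is a valid weight series.
    """
    events = validate_events(events)
    labels = [condition] if isinstance(condition, str) else list(condition)
    sel = events[events["trial_type"].isin(labels)]
    if sel.empty:
        raise ValueError(f"no events with trial_type in {labels}")
    t = np.arange(n_vols) * tr
    box = np.zeros(n_vols)
    for onset, dur in zip(sel["onset"], sel["duration"]):
        box[(t >= onset) & (t < onset + dur)] = 1.0
    w = np.convolve(box, canonical_hrf(tr))[:n_vols]
    return ConditionWeights(np.clip(w, 0.0, None), "+".join(labels))


def regress_confounds(ts: RoiTimeSeries, confounds: pd.DataFrame | np.ndarray) -> RoiTimeSeries:
    """OLS-residualize every node series against [intercept | confounds].

    Collinear confound columns are dropped with a logged warning; residuals
    are exactly orthogonal to every retained column.
    """
    X = np.asarray(confounds, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != ts.n_volumes:
        raise ValueError("confound rows must match volume count")
    if X.shape[1] >= ts.n_volumes:
        raise ValueError("more confounds than volumes")
    design = np.column_stack([np.ones(ts.n_volumes), X])
    _, R = np.linalg.qr(design)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    keep = np.ones(design.shape[1], dtype=bool)
    if (diag <= tol).any() or np.linalg.matrix_rank(design) < design.shape[1]:
        # greedy forward selection of independent columns
        keep[:] = False
        basis = np.empty((design.shape[0], 0))
        for k in range(design.shape[1]):
            cand = np.column_stack([basis, design[:, k]])
            if np.linalg.matrix_rank(cand) > basis.shape[1]:
                keep[k] = True
                basis = cand
        logger.warning("dropped %d collinear confound column(s)", (~keep).sum())
    D = design[:, keep]
    beta, *_ = np.linalg.lstsq(D, ts.data, rcond=None)
    resid = ts.data - D @ beta
    return RoiTimeSeries(resid, tr=ts.tr, subject_id=ts.subject_id, node_ids=list(ts.node_ids))


def bandpass_filter(ts: RoiTimeSeries, low: float = 0.008, high: float = 0.09) -> RoiTimeSeries:
    """Zero-phase ideal band-pass via an FFT mask (idempotent by construction)."""
    nyq = 1.0 / (2.0 * ts.tr)
    if not 0 <= low < high:
        raise ValueError("require 0 <= low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyq} Hz")
    n = ts.n_volumes
    freqs = np.fft.rfftfreq(n, d=ts.tr)
    mask = (freqs >= low - 1e-12) & (freqs <= high + 1e-12)
    spec = np.fft.rfft(ts.data, axis=0)
    spec[~mask] = 0.0
    out = np.fft.irfft(spec, n=n, axis=0)
    return RoiTimeSeries(out, tr=ts.tr, subject_id=ts.subject_id, node_ids=list(ts.node_ids))


def weighted_fc(ts: RoiTimeSeries, w: ConditionWeights) -> np.ndarray:
    """Weighted Pearson correlation between all node pairs, Fisher-z scale.

    r_ij = sum w (x_i - xbar_w)(x_j - xbar_w) / sqrt(...) with weighted
    means; z = atanh(r) clipped to |z| <= atanh(1 - 1e-7). Nodes with zero
    weighted variance get a zeroed row/column with a logged warning.
    """
    wt = w.weights
    if len(wt) != ts.n_volumes:
        raise ValueError("weight length must match volume count")
    if (wt > 0).sum() < 3:
        raise ValueError("need at least 3 positively weighted volumes")
    p = wt / wt.sum()
    X = ts.data
    xbar = p @ X
    Xc = X - xbar
    cov = Xc.T @ (p[:, None] * Xc)
    var = np.diag(cov).copy()
    dead = var <= 0
    if dead.any():
        logger.warning("%d node(s) with zero weighted variance; zeroing", dead.sum())
        var[dead] = 1.0
    denom = np.sqrt(np.outer(var, var))
    r = np.clip(cov / denom, -1 + 1e-7, 1 - 1e-7)
    z = np.arctanh(r)
    z[dead, :] = 0.0
    z[:, dead] = 0.0
    np.fill_diagonal(z, 0.0)
    return (z + z.T) / 2.0


def condition_contrast(z_a: np.ndarray, z_b: np.ndarray) -> np.ndarray:
    """Elementwise difference of two Fisher-z matrices (condition A minus B)."""
    z_a, z_b = np.asarray(z_a, float), np.asarray(z_b, float)
    if z_a.shape != z_b.shape:
        raise ValueError("contrast requires equal shapes")
    out = z_a - z_b
    np.fill_diagonal(out, 0.0)
    return out


def network_summary(m: np.ndarray, labels) -> pd.DataFrame:
    """Summarize an edge matrix at the level of network pairs.

    For distinct networks A, B the summary is the sum of all A-B edge
    values divided by |A| + |B|; within a network it is the sum over
    unordered node pairs divided by |A|.
    """
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    labels = np.asarray(list(labels.values()) if isinstance(labels, dict) else labels)
    if len(labels) != n or pd.isna(labels).any():
        raise ValueError("every node needs a network label")
    nets = sorted(pd.unique(labels))
    idx = {net: np.flatnonzero(labels == net) for net in nets}
    out = pd.DataFrame(0.0, index=nets, columns=nets)
    for a in nets:
        ia = idx[a]
        sub = m[np.ix_(ia, ia)]
        out.loc[a, a] = np.triu(sub, k=1).sum() / len(ia)
        for b in nets:
            if b <= a:
                continue
            ib = idx[b]
            val = m[np.ix_(ia, ib)].sum() / (len(ia) + len(ib))
            out.loc[a, b] = out.loc[b, a] = val
    return out


def build_confounds(
    motion: pd.DataFrame,
    events: pd.DataFrame,
    n_vols: int,
    tr: float,
    scrub_volumes: Sequence[int] = (),
) -> pd.DataFrame:
    """Standard confound design: task means, motion (+quadratic), scrubbing.

    One HRF-convolved regressor per trial_type removes constant task-evoked
    mean responses; 6 motion parameters and their squares absorb residual
    motion; each scrubbed volume gets a one-hot regressor that forces its
    residual to zero.
    """
    cols = {}
    for tt in pd.unique(validate_events(events)["trial_type"]):
        cols[f"task_{tt}"] = condition_weight_series(events, tt, n_vols, tr).weights
    mo = motion[MOTION_COLUMNS].to_numpy(float)
    if len(mo) != n_vols:
        raise ValueError("motion rows must match volume count")
    for k, name in enumerate(MOTION_COLUMNS):
        cols[name] = mo[:, k]
        cols[name + "_sq"] = mo[:, k] ** 2
    for v in scrub_volumes:
        oh = np.zeros(n_vols)
        oh[int(v)] = 1.0
        cols[f"scrub_{int(v):04d}"] = oh
    return pd.DataFrame(cols)


def contrast_fc_stack(
    timeseries: dict,
    events: pd.DataFrame,
    motion: dict = None,
    band: tuple[float, float] = (0.008, 0.09),
    condition_a: Sequence[str] = (CS_PLUS_US, US),
    condition_b: Sequence[str] = (CS_PLUS_NOUS,),
    node_meta: pd.DataFrame = None,
    fd_scrub_thresh: float = None,
) -> FCMatrixStack:
    """Per-subject nociceptive-contrast FC from raw ROI time series.

    Applies confound regression (when motion tables are supplied), band-pass
    filtering, weighted FC per condition and the A-minus-B contrast.
    ``fd_scrub_thresh`` optionally adds one-hot scrub regressors for volumes
    whose framewise displacement exceeds the threshold.
    """
    from .qc import framewise_displacement

    mats, sids = [], []
    for sid, ts in timeseries.items():
        if motion is not None:
            scrub = ()
            if fd_scrub_thresh is not None:
                fd = framewise_displacement(motion[sid])
                scrub = np.flatnonzero(fd > fd_scrub_thresh)
            conf = build_confounds(motion[sid], events, ts.n_volumes, ts.tr, scrub)
            ts = regress_confounds(ts, conf)
        if band is not None:
            ts = bandpass_filter(ts, *band)
        wa = condition_weight_series(events, list(condition_a), ts.n_volumes, ts.tr)
        wb = condition_weight_series(events, list(condition_b), ts.n_volumes, ts.tr)
        mats.append(condition_contrast(weighted_fc(ts, wa), weighted_fc(ts, wb)))
        sids.append(sid)
    return FCMatrixStack(np.stack(mats), sids, node_meta=node_meta)
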