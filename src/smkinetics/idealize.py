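"""Two-state segmental k-means (SKM) idealization and dwell extraction.

SKM alternates Viterbi segmentation of the intensity series under
Gaussian emissions with re-estimation of the class means, per-class
standard deviations and the transition matrix from the segmentation,
until the label assignment is fixed (or an iteration cap is reached).
The joint log-likelihood of the Viterbi path is non-decreasing across
iterations.  A simple threshold idealizer is provided as an independent
baseline/oracle.

Dwells are maximal runs of equal state labels; durations are integer
multiples of the frame interval.  The first and last runs of a trace are
flagged censored (their true duration extends beyond the observation
window), as are bound runs truncated by acceptor photobleaching when the
bleach frames are known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Idealization", "DwellSet", "skm_idealize", "threshold_idealize", "extract_dwells"]

UNBOUND, BOUND = 0, 1
_LOG_2PI = math.log(2.0 * math.pi)
_TRANS_FLOOR = 0.002


def _robust_sd(sel: np.ndarray, spread: float) -> float:
    """MAD-based class sd, floored to stay positive and nonsingular."""
    mad = float(np.median(np.abs(sel - np.median(sel))))
    sd = 1.4826 * mad
    if sd <= 0:
        sd = float(sel.std())
    return max(sd, 1e-3 * spread, 1e-12)


def _viterbi_py(x, means, sds, log_trans, log_pi):
    n = x.shape[0]
    ll0 = np.empty(n)
    ll1 = np.empty(n)
    for i in range(n):
        z0 = (x[i] - means[0]) / sds[0]
        z1 = (x[i] - means[1]) / sds[1]
        ll0[i] = -0.5 * z0 * z0 - math.log(sds[0]) - 0.5 * _LOG_2PI
        ll1[i] = -0.5 * z1 * z1 - math.log(sds[1]) - 0.5 * _LOG_2PI
    back = np.zeros((n, 2), dtype=np.int8)
    d0 = log_pi[0] + ll0[0]
    d1 = log_pi[1] + ll1[0]
    for i in range(1, n):
        a00 = d0 + log_trans[0, 0]
        a10 = d1 + log_trans[1, 0]
        # ties broken toward the lower (unbound) class: >= keeps state 0
        if a00 >= a10:
            nd0 = a00 + ll0[i]
            back[i, 0] = 0
        else:
            nd0 = a10 + ll0[i]
            back[i, 0] = 1
        a01 = d0 + log_trans[0, 1]
        a11 = d1 + log_trans[1, 1]
        if a01 >= a11:
            nd1 = a01 + ll1[i]
            back[i, 1] = 0
        else:
            nd1 = a11 + ll1[i]
            back[i, 1] = 1
        d0, d1 = nd0, nd1
    states = np.empty(n, dtype=np.int8)
    if d0 >= d1:
        states[n - 1] = 0
        loglik = d0
    else:
        states[n - 1] = 1
        loglik = d1
    for i in range(n - 2, -1, -1):
        states[i] = back[i + 1, states[i + 1]]
    return states, loglik


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _viterbi = njit(cache=True)(_viterbi_py)
except Exception:  # pragma: no cover
    _viterbi = _viterbi_py


@dataclass
class Idealization:
    """Per-frame two-state labels plus the fitted emission model."""

    states: np.ndarray  # int8, 0 = unbound, 1 = bound
    means: np.ndarray  # class means (unbound, bound), a.u.
    sds: np.ndarray  # per-class emission sd, a.u.
    trans: np.ndarray  # 2x2 transition probability matrix
    n_iterations: int
    converged: bool
    log_likelihood: float
    log_likelihood_path: list[float] = None

    @property
    def n_frames(self) -> int:
        return len(self.states)

    @property
    def bound_fraction(self) -> float:
        return float(np.mean(self.states == BOUND))


@dataclass
class DwellSet:
    """Alternating dwell segments tiling the analyzed span of one trace.

    ``table`` columns: state ("bound"/"unbound"), start_frame, n_frames,
    start_s, duration_s, censored (bool), censor_reason.
    """

    table: pd.DataFrame
    frame_interval_s: float

    def durations(self, state: str, include_censored: bool = False) -> np.ndarray:
        t = self.table[self.table["state"] == state]
        if not include_censored:
            t = t[~t["censored"]]
        return t["duration_s"].to_numpy()

    def censored_flags(self, state: str) -> np.ndarray:
        return self.table[self.table["state"] == state]["censored"].to_numpy()

    def all_durations(self, state: str) -> tuple[np.ndarray, np.ndarray]:
        """(durations, censored flags) for one state, censored included."""
        t = self.table[self.table["state"] == state]
        return t["duration_s"].to_numpy(), t["censored"].to_numpy()

    def survival_inputs(
        self, state: str, residual_start_complete: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """(durations, right-censor flags) ready for survival fitting.

        With ``residual_start_complete`` the run at the start of the
        trace is treated as a complete observation rather than censored:
        for an exponential dwell distribution the residual lifetime seen
        from an arbitrary observation start is itself exponential with
        the same rate (memorylessness), so counting it censored would
        bias the rate low.  Runs spanning the whole trace stay censored.
        """
        t = self.table[self.table["state"] == state]
        cens = t["censored"].to_numpy().copy()
        if residual_start_complete:
            cens = cens & (t["censor_reason"].to_numpy() != "left")
        return t["duration_s"].to_numpy(), cens

    @property
    def total_duration_s(self) -> float:
        return float(self.table["duration_s"].sum())


def _kmeans_1d(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-level split of a 1-D series for SKM initialization.

    The high level is seeded from the mean of the brightest frames and
    the low level from a low percentile, so rare short events are not
    swamped by the noise tail of the baseline (plain Lloyd iterations
    collapse onto the baseline when bound frames are sparse).  Returns
    (means, labels) with means sorted ascending.
    """
    lo = float(np.percentile(x, 5))
    k = min(10, len(x))
    hi = float(np.mean(np.partition(x, -k)[-k:]))
    mid = 0.5 * (lo + hi)
    labels = (x >= mid).astype(np.int8)
    c = np.empty(2)
    for j in (0, 1):
        sel = x[labels == j]
        c[j] = sel.mean() if len(sel) else (lo if j == 0 else hi)
    order = np.argsort(c)
    return c[order], order.argsort()[labels].astype(np.int8)


def skm_idealize(series: np.ndarray, max_iter: int = 100) -> Idealization:
    """Idealize a 1-D intensity series with a two-state SKM model.

    Initialization: 1-D 2-means with farthest-point seeding; a sticky
    transition prior (P(stay) = 0.98).  Each iteration runs Viterbi under
    Gaussian emissions with per-class variances, then re-estimates the
    class means/sds and transition matrix from the segmentation.  Stops
    when the labels are fixed or after ``max_iter`` iterations.

    Degenerate single-class data returns ``converged=False`` with the
    empty class retaining its initial parameters.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("series too short to idealize")
    means, labels = _kmeans_1d(x)
    spread = float(x.std())
    if means[1] - means[0] <= 1e-12 * max(abs(means).max(), 1.0):
        return Idealization(
            states=np.zeros(len(x), dtype=np.int8),
            means=means,
            sds=np.array([max(spread, 1e-12)] * 2),
            trans=np.array([[0.98, 0.02], [0.02, 0.98]]),
            n_iterations=0,
            converged=False,
            log_likelihood=-np.inf,
        )
    sds = np.empty(2)
    for j in (0, 1):
        sel = x[labels == j]
        sds[j] = _robust_sd(sel, spread) if len(sel) else max(spread, 1e-12)
    trans = np.array([[0.98, 0.02], [0.02, 0.98]])
    log_pi = np.log(np.array([0.5, 0.5]))

    states = labels
    loglik = -np.inf
    best = None  # (states, means, sds, trans, loglik) of the best iterate
    ll_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_states, loglik = _viterbi(x, means, sds, np.log(trans), log_pi)
        if best is not None and loglik < best[4] - 1e-9:
            # robust re-estimation can occasionally lower the Viterbi
            # objective; stop and keep the best iterate so the reported
            # objective path is non-decreasing
            states, means, sds, trans, loglik = best
            converged = True
            break
        ll_path.append(float(loglik))
        best = (new_states, means.copy(), sds.copy(), trans.copy(), float(loglik))
        if np.array_equal(new_states, states) and it > 1:
            converged = True
            states = new_states
            break
        states = new_states
        ok = True
        for j in (0, 1):
            sel = x[states == j]
            if len(sel) < 2:
                ok = False
                break
            # median/MAD rather than mean/sd: frames straddling an event
            # edge sit at intermediate levels and would otherwise inflate
            # the class width and mask short events
            means[j] = float(np.median(sel))
            sds[j] = _robust_sd(sel, spread)
        if not ok:
            converged = False
            break
        counts = np.ones((2, 2))  # +1 pseudo-count keeps probabilities finite
        n01 = int(np.sum((states[:-1] == 0) & (states[1:] == 1)))
        n10 = int(np.sum((states[:-1] == 1) & (states[1:] == 0)))
        n00 = int(np.sum((states[:-1] == 0) & (states[1:] == 0)))
        n11 = int(np.sum((states[:-1] == 1) & (states[1:] == 1)))
        counts += np.array([[n00, n01], [n10, n11]])
        trans = counts / counts.sum(axis=1, keepdims=True)
        # floor rare transitions: an over-sticky matrix suppresses the
        # detection of short events in a feedback loop
        trans = np.clip(trans, _TRANS_FLOOR, 1.0 - _TRANS_FLOOR)
        trans = trans / trans.sum(axis=1, keepdims=True)
        if means[1] < means[0]:  # keep bound = high-intensity class
            means = means[::-1].copy()
            sds = sds[::-1].copy()
            trans = trans[::-1, ::-1].copy()
            states = (1 - states).astype(np.int8)

    return Idealization(
        states=states.astype(np.int8),
        means=means,
        sds=sds,
        trans=trans,
        n_iterations=it,
        converged=converged,
        log_likelihood=float(loglik),
        log_likelihood_path=ll_path,
    )


def threshold_idealize(series: np.ndarray, level: float) -> Idealization:
    """Label frames bound iff intensity >= level (no iteration)."""
    x = np.asarray(series, dtype=float)
    states = (x >= level).astype(np.int8)
    means = np.empty(2)
    sds = np.empty(2)
    for j in (0, 1):
        sel = x[states == j]
        means[j] = sel.mean() if len(sel) else np.nan
        sds[j] = sel.std() if len(sel) else np.nan
    return Idealization(
        states=states,
        means=means,
        sds=sds,
        trans=np.full((2, 2), np.nan),
        n_iterations=0,
        converged=True,
        log_likelihood=np.nan,
    )


def extract_dwells(
    idealization: Idealization,
    frame_interval_s: float,
    bleach_frames: list[int] | None = None,
) -> DwellSet:
    """Convert per-frame labels to alternating dwell segments.

    Runs of equal labels become dwells of duration (run length x frame
    interval).  The first and last runs are right/left-censored by the
    observation window; bound runs ending within one frame of a known
    acceptor bleach are flagged censored with reason ``bleach``.
    """
    states = idealization.states
    n = len(states)
    if n == 0:
        raise ValueError("empty idealization")
    change = np.nonzero(np.diff(states))[0]
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [n]))
    rows = []
    bleach_set = set(bleach_frames or [])
    for i, (s, e) in enumerate(zip(starts, ends)):
        censored = i == 0 or i == len(starts) - 1
        reason = ""
        if i == 0:
            reason = "left"
        if i == len(starts) - 1:
            reason = "right" if reason == "" else "left+right"
        state = "bound" if states[s] == BOUND else "unbound"
        if state == "bound" and not censored and bleach_set:
            if any(abs(int(e) - b) <= 1 for b in bleach_set):
                censored = True
                reason = "bleach"
        rows.append(
            {
                "state": state,
                "start_frame": int(s),
                "n_frames": int(e - s),
                "start_s": s * frame_interval_s,
                "duration_s": (e - s) * frame_interval_s,
                "censored": censored,
                "censor_reason": reason,
            }
        )
    return DwellSet(table=pd.DataFrame(rows), frame_interval_s=frame_interval_s)
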