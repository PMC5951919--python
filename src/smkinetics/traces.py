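"""Intensity-trace container, TSV I/O, photobleach detection and trace QC.

A single immobilized molecule observed on a TIRF microscope yields one
donor (Cy3) and one acceptor (Cy5) intensity series sampled at a fixed
frame interval (100 ms in the experiments this package models).  Traces
are screened before analysis: genuine single molecules photobleach in a
single step, have adequate signal-to-noise, sufficient total intensity
(to exclude background impurities) and last long enough to be informative.
Two QC modes are provided: ``smfret`` for FRET trajectories under donor
excitation, and ``binding`` for direct-excitation binding assays where
the acceptor channel spikes on each transient binding event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntensityTrace",
    "BleachStep",
    "QcReport",
    "detect_photobleach_step",
    "compute_snr",
    "count_binding_events",
    "qc_smfret_trace",
    "qc_binding_trace",
    "select_traces",
    "write_trace_tsv",
    "read_trace_tsv",
    "SMFRET_MIN_SNR",
    "SMFRET_MIN_TOTAL_INTENSITY",
    "SMFRET_MIN_DURATION_S",
    "BINDING_MIN_SNR",
    "BINDING_MIN_EVENTS",
]

# Trace-selection thresholds for the two assay modes.
SMFRET_MIN_SNR = 4.0
SMFRET_MIN_TOTAL_INTENSITY = 300.0
SMFRET_MIN_DURATION_S = 10.0
BINDING_MIN_SNR = 3.0
BINDING_MIN_EVENTS = 2

_MIN_SERIES_FOR_STEP = 10


@dataclass
class IntensityTrace:
    """Per-frame donor/acceptor intensities for one molecule.

    Parameters
    ----------
    frame_interval_s : float
        Acquisition interval in seconds (> 0).
    donor, acceptor : ndarray
        Equal-length intensity series in arbitrary camera units.
    excitation_mode : {"fret", "direct"}
        ``fret``: donor excitation, acceptor lit by energy transfer.
        ``direct``: both dyes directly excited (binding assay).
    background_donor, background_acceptor : float
        Per-frame background levels subtracted before computing FRET.
    """

    frame_interval_s: float
    donor: np.ndarray
    acceptor: np.ndarray
    excitation_mode: str = "fret"
    background_donor: float = 0.0
    background_acceptor: float = 0.0
    molecule_id: str | None = None

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.donor.ndim != 1 or self.acceptor.ndim != 1:
            raise ValueError("intensity series must be 1-D")
        if len(self.donor) != len(self.acceptor):
            raise ValueError("donor and acceptor series must have equal length")
        if len(self.donor) < 1:
            raise ValueError("intensity series must have length >= 1")
        if self.excitation_mode not in ("fret", "direct"):
            raise ValueError(f"unknown excitation_mode {self.excitation_mode!r}")

    @property
    def n_frames(self) -> int:
        return len(self.donor)

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    @property
    def total(self) -> np.ndarray:
        """Per-frame donor + acceptor intensity."""
        return self.donor + self.acceptor


@dataclass(frozen=True)
class BleachStep:
    """Result of change-point photobleach detection on one series."""

    step_frame: int | None
    single_step: bool
    drop: float = 0.0
    residual_sd: float = 0.0


@dataclass
class QcReport:
    """Outcome of trace selection for one molecule.

    ``passed`` is true exactly when ``failure_reasons`` is empty.
    """

    molecule_id: str | None
    mode: str
    snr: float
    total_intensity: float
    duration_s: float
    bleach_frame_donor: int | None
    bleach_frame_acceptor: int | None
    single_step_bleach: bool
    n_binding_events: int
    failure_reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failure_reasons


def _best_split(x: np.ndarray) -> tuple[int, float, float, float] | None:
    """Best two-segment piecewise-constant split of ``x``.

    Returns (split index k where the right segment starts, left mean,
    right mean, pooled residual sd), or None when the series is too short.
    Runs in O(n) using prefix sums.
    """
    n = len(x)
    if n < 4:
        return None
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    ks = np.arange(2, n - 1)  # left segment has >= 2 points, right >= 2
    sl, sl2 = c1[ks - 1], c2[ks - 1]
    sr, sr2 = c1[-1] - sl, c2[-1] - sl2
    nl = ks.astype(float)
    nr = n - nl
    sse = (sl2 - sl * sl / nl) + (sr2 - sr * sr / nr)
    i = int(np.argmin(sse))
    k = int(ks[i])
    mean_l = sl[i] / nl[i]
    mean_r = sr[i] / nr[i]
    sd = math.sqrt(max(sse[i], 0.0) / max(n - 2, 1))
    return k, mean_l, mean_r, sd


def _significant_step(x: np.ndarray, signed: bool = True) -> tuple[int, float, float] | None:
    """Best split of ``x`` if the level change is significant, else None.

    A step is significant when the level change exceeds 3x the pooled
    residual sd (any nonzero change for noiseless data).  With
    ``signed=True`` only downward steps (bleaching) count; otherwise any
    direction (a second step of either sign disqualifies a single-step
    trace).
    """
    res = _best_split(x)
    if res is None:
        return None
    k, mean_l, mean_r, sd = res
    change = mean_l - mean_r
    mag = change if signed else abs(change)
    scale = max(abs(mean_l), abs(mean_r), 1e-12)
    if sd <= 1e-12 * scale:
        ok = mag > 1e-9 * scale
    else:
        ok = mag > 3.0 * sd
    if not ok:
        return None
    return k, change, sd


def detect_photobleach_step(series: np.ndarray) -> BleachStep:
    """Detect a photobleach step by two-segment least-squares change-point.

    The series is split at the point minimizing the total squared error of
    a piecewise-constant two-level model.  A step is reported when the
    level drop exceeds 3x the pooled residual standard deviation.  The
    trace qualifies as single-step when the post-bleach segment contains
    no second significant step.

    Series shorter than 10 frames yield ``BleachStep(None, False)`` (a QC
    failure downstream, not an exception).
    """
    series = np.asarray(series, dtype=float)
    if len(series) < _MIN_SERIES_FOR_STEP:
        return BleachStep(None, False)
    first = _significant_step(series, signed=True)
    if first is None:
        return BleachStep(None, False)
    k, drop, sd = first
    single = True
    # a second significant level change on either side of the step marks
    # a multi-step trace (aggregate or impurity)
    for segment in (series[:k], series[k:]):
        if len(segment) >= 4 and _significant_step(segment, signed=False) is not None:
            single = False
            break
    return BleachStep(k, single, drop, sd)


def compute_snr(series: np.ndarray, on_mask: np.ndarray, off_mask: np.ndarray) -> float:
    """Signal-to-noise ratio (mean_on - mean_off) / sd_off.

    Returns NaN when either mask is empty (undefined S/N) and +inf for a
    noiseless step (zero off-segment sd); callers treat NaN as a QC
    failure and cap infinities.
    """
    series = np.asarray(series, dtype=float)
    on = series[np.asarray(on_mask, dtype=bool)]
    off = series[np.asarray(off_mask, dtype=bool)]
    if len(on) == 0 or len(off) == 0:
        return float("nan")
    sd_off = float(np.std(off))
    diff = float(np.mean(on) - np.mean(off))
    if sd_off == 0.0:
        return float("inf") if diff > 0 else 0.0
    return diff / sd_off


def _provisional_level(series: np.ndarray) -> tuple[float, bool]:
    """Mid-level threshold between the low and high intensity plateaus.

    Used for a provisional event-count idealization during QC, avoiding a
    circular dependence on the SKM module.  Returns (level, separable)
    where ``separable`` is False when the series has no discernible high
    level (no events).
    """
    lo = float(np.percentile(series, 5))
    # top-frames mean rather than a fixed percentile: a rare fast binder
    # may occupy far fewer than 0.5% of frames yet be clearly discernible
    k = min(10, len(series))
    hi = float(np.mean(np.partition(series, -k)[-k:]))
    level = 0.5 * (lo + hi)
    low = series[series < level]
    sd_low = float(np.std(low)) if len(low) else 0.0
    separable = (hi - lo) > max(5.0 * sd_low, 1e-9)
    return level, separable


def count_binding_events(series: np.ndarray, level: float | None = None) -> int:
    """Number of above-threshold runs (provisional binding-event count)."""
    series = np.asarray(series, dtype=float)
    if level is None:
        level, separable = _provisional_level(series)
        if not separable:
            return 0
    mask = series >= level
    if not mask.any():
        return 0
    rises = np.diff(mask.astype(np.int8)) == 1
    return int(rises.sum()) + int(mask[0])


def qc_smfret_trace(trace: IntensityTrace) -> QcReport:
    """Apply smFRET-mode selection criteria to one trace.

    Criteria: single-step photobleaching of the total (donor + acceptor)
    signal, S/N > 4:1 across the bleach step, median per-frame total
    intensity > 300 a.u. before bleaching, and total fluorescence duration
    (time to donor bleach) > 10 s.
    """
    total = trace.total
    step_total = detect_photobleach_step(total)
    step_d = detect_photobleach_step(trace.donor)
    step_a = detect_photobleach_step(trace.acceptor)

    reasons: list[str] = []
    if step_total.step_frame is None or not step_total.single_step:
        reasons.append("no_single_step_bleach")
    n_pre = step_total.step_frame if step_total.step_frame is not None else trace.n_frames
    duration_s = n_pre * trace.frame_interval_s
    if step_total.step_frame is not None:
        on = np.zeros(trace.n_frames, dtype=bool)
        on[:n_pre] = True
        snr = compute_snr(total, on, ~on)
    else:
        snr = float("nan")
    total_intensity = float(np.median(total[:n_pre])) if n_pre > 0 else 0.0
    if not (snr > SMFRET_MIN_SNR):  # NaN fails
        reasons.append("snr_below_threshold")
    if not (total_intensity > SMFRET_MIN_TOTAL_INTENSITY):
        reasons.append("total_intensity_below_threshold")
    if not (duration_s > SMFRET_MIN_DURATION_S):
        reasons.append("duration_below_threshold")

    return QcReport(
        molecule_id=trace.molecule_id,
        mode="smfret",
        snr=min(snr, 1e6) if np.isfinite(snr) or np.isnan(snr) else 1e6,
        total_intensity=total_intensity,
        duration_s=duration_s,
        bleach_frame_donor=step_d.step_frame,
        bleach_frame_acceptor=step_a.step_frame,
        single_step_bleach=bool(step_total.step_frame is not None and step_total.single_step),
        n_binding_events=0,
        failure_reasons=reasons,
    )


def qc_binding_trace(trace: IntensityTrace) -> QcReport:
    """Apply binding-mode selection criteria to one trace.

    Criteria: acceptor-channel (Cy5) S/N > 3:1 over the provisional
    event idealization, at least two binding events, and a visible donor
    (Cy3) signal identifying an immobilized riboswitch molecule.
    """
    acc = trace.acceptor
    level, separable = _provisional_level(acc)
    reasons: list[str] = []
    if separable:
        mask = acc >= level
        n_events = count_binding_events(acc, level)
        snr = compute_snr(acc, mask, ~mask)
    else:
        mask = np.zeros(trace.n_frames, dtype=bool)
        n_events = 0
        snr = float("nan")

    if not (snr > BINDING_MIN_SNR):
        reasons.append("snr_below_threshold")
    if n_events < BINDING_MIN_EVENTS:
        reasons.append("fewer_than_two_events")

    # donor must be visible at the start of the movie (identifies a real
    # immobilized molecule); later Cy3 bleach does not disqualify a trace
    head = trace.donor[: min(10, trace.n_frames)]
    donor_level = float(np.median(head))
    donor_sd = float(np.std(head))
    if donor_level <= max(3.0 * donor_sd, 1e-9):
        reasons.append("no_donor_signal")

    step_d = detect_photobleach_step(trace.donor)
    return QcReport(
        molecule_id=trace.molecule_id,
        mode="binding",
        snr=min(snr, 1e6) if np.isfinite(snr) or np.isnan(snr) else 1e6,
        total_intensity=float(np.median(trace.total)),
        duration_s=trace.duration_s,
        bleach_frame_donor=step_d.step_frame,
        bleach_frame_acceptor=None,
        single_step_bleach=step_d.single_step,
        n_binding_events=n_events,
        failure_reasons=reasons,
    )


def select_traces(
    traces: list[IntensityTrace], mode: str
) -> tuple[list[IntensityTrace], list[QcReport]]:
    """Filter traces by the selection criteria of ``mode``.

    Returns the kept traces and one :class:`QcReport` per input trace (in
    input order); every rejection carries named failure reasons.
    """
    if not traces:
        raise ValueError("traces must be nonempty")
    if mode == "smfret":
        qc = qc_smfret_trace
    elif mode == "binding":
        qc = qc_binding_trace
    else:
        raise ValueError(f"unknown QC mode {mode!r}")
    reports = [qc(t) for t in traces]
    kept = [t for t, r in zip(traces, reports) if r.passed]
    return kept, reports


def reports_to_frame(reports: list[QcReport]) -> pd.DataFrame:
    """Tabulate QC reports (one row per molecule) for TSV export."""
    rows = []
    for r in reports:
        rows.append(
            {
                "molecule_id": r.molecule_id,
                "mode": r.mode,
                "snr": r.snr,
                "total_intensity": r.total_intensity,
                "duration_s": r.duration_s,
                "bleach_frame_donor": r.bleach_frame_donor,
                "bleach_frame_acceptor": r.bleach_frame_acceptor,
                "single_step_bleach": r.single_step_bleach,
                "n_binding_events": r.n_binding_events,
                "passed": r.passed,
                "failure_reasons": ";".join(r.failure_reasons),
            }
        )
    return pd.DataFrame(rows)


def write_trace_tsv(trace: IntensityTrace, path) -> None:
    """Write a trace as TSV (frame, donor, acceptor) with metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# frame_interval_s={trace.frame_interval_s}\n")
        fh.write(f"# excitation_mode={trace.excitation_mode}\n")
        fh.write(f"# background_donor={trace.background_donor}\n")
        fh.write(f"# background_acceptor={trace.background_acceptor}\n")
        if trace.molecule_id is not None:
            fh.write(f"# molecule_id={trace.molecule_id}\n")
        fh.write("frame\tdonor\tacceptor\n")
        for i, (d, a) in enumerate(zip(trace.donor, trace.acceptor)):
            fh.write(f"{i}\t{d:.6g}\t{a:.6g}\n")


def read_trace_tsv(path) -> IntensityTrace:
    """Read a trace written by :func:`write_trace_tsv`."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return IntensityTrace(
        frame_interval_s=float(meta.get("frame_interval_s", 0.1)),
        donor=df["donor"].to_numpy(),
        acceptor=df["acceptor"].to_numpy(),
        excitation_mode=meta.get("excitation_mode", "fret"),
        background_donor=float(meta.get("background_donor", 0.0)),
        background_acceptor=float(meta.get("background_acceptor", 0.0)),
        molecule_id=meta.get("molecule_id"),
    )
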