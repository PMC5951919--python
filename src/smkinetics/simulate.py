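"""Synthetic single-molecule fluorescence data generators.

Every input the analysis pipeline consumes can be generated here with the
statistical structure the analysis assumes: two-state Markov binding
traces (continuous-time Gillespie simulation binned to camera frames),
multi-state smFRET trajectories with anti-correlated donor/acceptor
channels, exponential loss of colocalized spots in time-lapse imaging,
Hill-shaped titrations and 2-D spot fields for colocalization.

The generators emulate a prism-TIRF experiment on riboswitch-tRNA
binding: a surface-immobilized Cy3-labelled riboswitch visited by Cy5-
labelled tRNA from solution.  Binding and dissociation follow a
continuous-time two-state Markov chain (unbound -> bound at kon*c, bound
-> unbound at a per-molecule-class koff, modelling static kinetic
heterogeneity).  Cy5 photobleaches once per binding event with an
exponential lifetime (~64 s under the modelled imaging conditions); a
bleached tRNA stays bound but dark until it dissociates.  Cy3 bleaches
once per trace.  A fraction of molecules is binding-incompetent
(inactive) and produces no events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import IntensityTrace

__all__ = [
    "MoleculeClass",
    "FretState",
    "SimulationConfig",
    "GroundTruth",
    "TimeLapseCounts",
    "simulate_dwells",
    "discretize_durations",
    "simulate_binding_trace",
    "simulate_binding_batch",
    "simulate_smfret_trace",
    "simulate_smfret_batch",
    "simulate_timelapse",
    "simulate_titration",
    "simulate_spot_field",
    "E_CLAMP",
]

#: FRET efficiencies are clamped to this range throughout the package.
E_CLAMP = (-0.2, 1.2)


@dataclass(frozen=True)
class MoleculeClass:
    """One static kinetic class: molecules keep their koff for the whole trace."""

    label: str
    koff_per_s: float
    weight: float


@dataclass(frozen=True)
class FretState:
    """One Gaussian FRET state (mean efficiency, frame-to-frame sd, weight)."""

    mean: float
    sd: float
    weight: float


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults describe the wild-type riboswitch core condition: kon =
    0.75e6 /M/s at 16 nM tRNA, a 72/28 mixture of fast (0.23 /s) and
    medium (1/34.2 /s) dissociation classes, ~40% binding-incompetent
    molecules, Cy5 bleach lifetime 64 s, and intensity levels giving a
    signal-to-noise ratio of (on - off)/noise_sd = 6.
    """

    frame_interval_s: float = 0.1
    n_frames: int = 6000
    trna_conc_nM: float = 16.0
    kon_per_M_s: float = 0.75e6
    molecule_classes: tuple[MoleculeClass, ...] = (
        MoleculeClass("fast", 0.23, 0.72),
        MoleculeClass("medium", 1.0 / 34.2, 0.28),
    )
    inactive_fraction: float = 0.4
    fret_states: tuple[FretState, ...] = (
        FretState(0.52, 0.12, 0.90),
        FretState(0.09, 0.12, 0.09),
        FretState(0.92, 0.07, 0.01),
    )
    fret_transition_rate_per_s: float = 0.0
    intensity_on: float = 400.0
    intensity_off: float = 100.0
    noise_sd: float = 50.0
    bleach_lifetime_cy5_s: float = 64.0
    bleach_lifetime_cy3_s: float = 90.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.trna_conc_nM <= 0 or self.kon_per_M_s <= 0:
            raise ValueError("concentration and kon must be > 0")
        if not 0.0 <= self.inactive_fraction <= 1.0:
            raise ValueError("inactive_fraction must be in [0, 1]")
        if self.bleach_lifetime_cy5_s <= 0 or self.bleach_lifetime_cy3_s <= 0:
            raise ValueError("bleach lifetimes must be > 0")
        if not self.molecule_classes:
            raise ValueError("molecule_classes must be nonempty")
        w = sum(c.weight for c in self.molecule_classes)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"molecule class weights sum to {w}, expected 1")
        for c in self.molecule_classes:
            if c.koff_per_s <= 0:
                raise ValueError(f"koff for class {c.label!r} must be > 0")
        if self.fret_states:
            wf = sum(s.weight for s in self.fret_states)
            if abs(wf - 1.0) > 1e-9:
                raise ValueError(f"fret state weights sum to {wf}, expected 1")
            for s in self.fret_states:
                if s.sd < 0:
                    raise ValueError("fret state sd must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def kon_c_per_s(self) -> float:
        """Pseudo-first-order binding rate kon * [tRNA] in 1/s."""
        return self.kon_per_M_s * self.trna_conc_nM * 1e-9

    @property
    def total_duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


@dataclass
class GroundTruth:
    """Generator-side truth for one simulated molecule.

    ``dwells`` is the exact continuous-time binding history tiling
    [0, total duration]; ``state_seq`` marks frames where the molecule was
    bound for more than half the frame.  ``bright_intervals`` are the
    observable (pre-bleach) portions of bound events; events shorter than
    a frame may be invisible in the binned trace.
    """

    class_label: str
    active: bool
    state_seq: np.ndarray
    bright_seq: np.ndarray
    dwells: pd.DataFrame
    bright_intervals: list[tuple[float, float]]
    bleach_frames_cy5: list[int]
    bleach_frame_cy3: int | None
    fret_state_seq: np.ndarray | None = None
    e_true: np.ndarray | None = None


@dataclass
class TimeLapseCounts:
    """Spot counts over a time-lapse, plus the initial spot number."""

    times_min: np.ndarray
    counts: np.ndarray
    n0: int

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / float(self.n0)


def _rng(seed, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def simulate_dwells(
    rate_components: list[tuple[float, float]],
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` dwell durations from an exponential mixture.

    Each duration is drawn by first sampling a component by weight, then
    an exponential with that component's rate.  Durations are continuous
    (seconds); see :func:`discretize_durations` for camera-frame rounding.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rates = np.array([r for r, _ in rate_components], dtype=float)
    weights = np.array([w for _, w in rate_components], dtype=float)
    if np.any(rates <= 0):
        raise ValueError("rates must be > 0")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    gen = _rng(seed, rng)
    comp = gen.choice(len(rates), size=n, p=weights)
    return gen.exponential(1.0 / rates[comp])


def discretize_durations(durations_s: np.ndarray, frame_interval_s: float) -> np.ndarray:
    """Round continuous durations to whole camera frames (nearest frame).

    Durations rounding to zero frames correspond to sub-frame events that
    a frame-binned trace cannot resolve; they are returned as 0 and are
    excluded by the dead-time rule of the survival fitters.
    """
    d = np.asarray(durations_s, dtype=float)
    frames = np.floor(d / frame_interval_s + 0.5)
    return frames * frame_interval_s


def _occupancy(intervals, n_frames: int, dt: float) -> np.ndarray:
    """Fraction of each frame covered by the given time intervals."""
    occ = np.zeros(n_frames, dtype=float)
    t_end = n_frames * dt
    for a, b in intervals:
        a = max(0.0, a)
        b = min(t_end, b)
        if b <= a:
            continue
        i0 = int(a // dt)
        i1 = min(int(math.ceil(b / dt)), n_frames)
        idx = np.arange(i0, i1)
        lo = np.maximum(idx * dt, a)
        hi = np.minimum((idx + 1) * dt, b)
        occ[idx] += (hi - lo) / dt
    return np.clip(occ, 0.0, 1.0)


def simulate_binding_trace(
    config: SimulationConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[IntensityTrace, GroundTruth]:
    """Simulate one direct-excitation binding trace.

    The binding history is a continuous-time two-state Markov chain
    (Gillespie simulation) binned to frames, so no geometric-
    discretization bias is introduced at the 0.1 s frame interval.  The
    Cy5 channel reads ``intensity_on`` while a fluorescent tRNA is bound
    and ``intensity_off`` otherwise (frame-averaged at event edges), plus
    Gaussian camera noise.  Cy5 photobleaching truncates the bright
    portion of each event; Cy3 bleaches once per trace.
    """
    config.validate()
    gen = _rng(seed if seed is not None else config.seed, rng)
    dt = config.frame_interval_s
    n = config.n_frames
    t_end = config.total_duration_s

    active = bool(gen.random() >= config.inactive_fraction)
    cls_weights = np.array([c.weight for c in config.molecule_classes])
    cls = config.molecule_classes[int(gen.choice(len(cls_weights), p=cls_weights))]

    dwell_rows: list[tuple[str, float, float]] = []
    bright: list[tuple[float, float]] = []
    bleach_times: list[float] = []
    bound_intervals: list[tuple[float, float]] = []

    t = 0.0
    if not active:
        dwell_rows.append(("unbound", 0.0, t_end))
    else:
        state = 0  # start unbound
        while t < t_end:
            if state == 0:
                dur = gen.exponential(1.0 / config.kon_c_per_s)
                dwell_rows.append(("unbound", t, min(t + dur, t_end) - t))
                t += dur
                state = 1
            else:
                dur = gen.exponential(1.0 / cls.koff_per_s)
                tb = gen.exponential(config.bleach_lifetime_cy5_s)
                end = min(t + dur, t_end)
                dwell_rows.append(("bound", t, end - t))
                bound_intervals.append((t, end))
                bright_end = min(t + min(dur, tb), t_end)
                bright.append((t, bright_end))
                if tb < dur and bright_end < t_end:
                    bleach_times.append(bright_end)
                t += dur
                state = 0

    occ_bright = _occupancy(bright, n, dt)
    occ_true = _occupancy(bound_intervals, n, dt)
    acceptor = config.intensity_off + occ_bright * (config.intensity_on - config.intensity_off)
    if config.noise_sd > 0:
        acceptor = acceptor + gen.normal(0.0, config.noise_sd, n)

    cy3_bleach_t = gen.exponential(config.bleach_lifetime_cy3_s)
    cy3_frame = int(cy3_bleach_t / dt) if cy3_bleach_t < t_end else None
    donor = np.full(n, config.intensity_on)
    if cy3_frame is not None:
        donor[cy3_frame:] = 0.0
    if config.noise_sd > 0:
        donor = donor + gen.normal(0.0, config.noise_sd, n)

    dwells = pd.DataFrame(dwell_rows, columns=["state", "start_s", "duration_s"])
    truth = GroundTruth(
        class_label=cls.label if active else "inactive",
        active=active,
        state_seq=occ_true > 0.5,
        bright_seq=occ_bright > 0.5,
        dwells=dwells,
        bright_intervals=bright,
        bleach_frames_cy5=[int(tb / dt) for tb in bleach_times],
        bleach_frame_cy3=cy3_frame,
    )
    trace = IntensityTrace(
        frame_interval_s=dt,
        donor=donor,
        acceptor=acceptor,
        excitation_mode="direct",
        background_donor=0.0,
        background_acceptor=config.intensity_off,
    )
    return trace, truth


def simulate_binding_batch(
    config: SimulationConfig,
    n_molecules: int,
    seed: int | None = None,
) -> tuple[list[IntensityTrace], list[GroundTruth]]:
    """Simulate a field of molecules with independent per-molecule streams."""
    ss = np.random.SeedSequence(seed if seed is not None else config.seed)
    traces, truths = [], []
    for i, child in enumerate(ss.spawn(n_molecules)):
        tr, gt = simulate_binding_trace(config, rng=np.random.default_rng(child))
        tr.molecule_id = f"mol{i:04d}"
        traces.append(tr)
        truths.append(gt)
    return traces, truths


def simulate_smfret_trace(
    config: SimulationConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[IntensityTrace, GroundTruth]:
    """Simulate one donor-excitation smFRET trace.

    The hidden FRET state is drawn per molecule from ``fret_states``
    (static heterogeneity); with ``fret_transition_rate_per_s > 0`` the
    molecule instead hops between states as a CTMC with stationary
    weights.  Per-frame apparent efficiency is N(mean, sd) truncated to
    the clamp range; donor/acceptor intensities are anti-correlated with
    conserved total T = ``intensity_on``.  The acceptor bleaches first
    (E drops to 0), then the donor (both channels drop), each with an
    exponential lifetime.
    """
    config.validate()
    if not config.fret_states:
        raise ValueError("fret_states must be nonempty")
    gen = _rng(seed if seed is not None else config.seed, rng)
    dt = config.frame_interval_s
    n = config.n_frames
    states = config.fret_states
    weights = np.array([s.weight for s in states])

    state_seq = np.empty(n, dtype=np.int64)
    if config.fret_transition_rate_per_s > 0 and len(states) > 1:
        t, s = 0.0, int(gen.choice(len(states), p=weights))
        i = 0
        while i < n:
            dur = gen.exponential(1.0 / config.fret_transition_rate_per_s)
            j = min(int(math.ceil((t + dur) / dt)), n)
            state_seq[i:j] = s
            i, t = j, t + dur
            others = np.delete(np.arange(len(states)), s)
            p = weights[others] / weights[others].sum()
            s = int(gen.choice(others, p=p))
    else:
        state_seq[:] = int(gen.choice(len(states), p=weights))

    means = np.array([s.mean for s in states])[state_seq]
    sds = np.array([s.sd for s in states])[state_seq]
    e_true = np.clip(gen.normal(means, sds), *E_CLAMP)

    t_bleach_a = gen.exponential(config.bleach_lifetime_cy5_s)
    t_bleach_d = gen.exponential(config.bleach_lifetime_cy3_s)
    f_a = int(t_bleach_a / dt) if t_bleach_a < n * dt else None
    f_d = int(t_bleach_d / dt) if t_bleach_d < n * dt else None
    if f_a is not None and f_d is not None and f_d < f_a:
        f_a = None  # donor died first: acceptor never visibly bleaches

    total = config.intensity_on
    acceptor = total * e_true
    donor = total * (1.0 - e_true)
    if f_a is not None:
        acceptor[f_a:] = 0.0
        donor[f_a:] = total
    if f_d is not None:
        acceptor[f_d:] = 0.0
        donor[f_d:] = 0.0
    if config.noise_sd > 0:
        acceptor = acceptor + gen.normal(0.0, config.noise_sd, n)
        donor = donor + gen.normal(0.0, config.noise_sd, n)

    truth = GroundTruth(
        class_label="smfret",
        active=True,
        state_seq=np.zeros(n, dtype=bool),
        bright_seq=np.zeros(n, dtype=bool),
        dwells=pd.DataFrame(columns=["state", "start_s", "duration_s"]),
        bright_intervals=[],
        bleach_frames_cy5=[f_a] if f_a is not None else [],
        bleach_frame_cy3=f_d,
        fret_state_seq=state_seq,
        e_true=e_true,
    )
    trace = IntensityTrace(
        frame_interval_s=dt,
        donor=donor,
        acceptor=acceptor,
        excitation_mode="fret",
    )
    return trace, truth


def simulate_smfret_batch(
    config: SimulationConfig,
    n_molecules: int,
    seed: int | None = None,
) -> tuple[list[IntensityTrace], list[GroundTruth]]:
    ss = np.random.SeedSequence(seed if seed is not None else config.seed)
    traces, truths = [], []
    for i, child in enumerate(ss.spawn(n_molecules)):
        tr, gt = simulate_smfret_trace(config, rng=np.random.default_rng(child))
        tr.molecule_id = f"mol{i:04d}"
        traces.append(tr)
        truths.append(gt)
    return traces, truths


def simulate_timelapse(
    n0: int,
    ultrastable_fraction: float,
    lifetime_min: float,
    interval_s: float = 20.0,
    duration_min: float = 20.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TimeLapseCounts:
    """Simulate the slow decay of colocalized spot counts.

    Each of ``n0`` initially surface-bound complexes is ultra-stable with
    probability ``ultrastable_fraction`` and then survives exponentially
    with the given lifetime; non-ultra-stable complexes dissociate before
    the first frame.  Counts at each time point are the number of spots
    still present, so P(spot present at t) = f * exp(-t / lifetime).
    """
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    if not 0.0 <= ultrastable_fraction <= 1.0:
        raise ValueError("ultrastable_fraction must be in [0, 1]")
    if lifetime_min <= 0:
        raise ValueError("lifetime_min must be > 0")
    gen = _rng(seed, rng)
    times_min = np.arange(0.0, duration_min + 1e-9, interval_s / 60.0)
    ultra = gen.random(n0) < ultrastable_fraction
    surv = gen.exponential(lifetime_min, n0)
    counts = (ultra[:, None] & (surv[:, None] > times_min[None, :])).sum(axis=0)
    return TimeLapseCounts(times_min=times_min, counts=counts.astype(int), n0=n0)


def simulate_titration(
    kd_nM: float,
    hill_n: float,
    conc_nM: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a binding titration with Hill-shaped response.

    fraction = c^n / (kd^n + c^n) + Gaussian noise, clipped to [0, 1.2].
    """
    if kd_nM <= 0 or hill_n <= 0:
        raise ValueError("kd and hill coefficient must be > 0")
    c = np.asarray(conc_nM, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    gen = _rng(seed, rng)
    frac = c**hill_n / (kd_nM**hill_n + c**hill_n)
    if noise_sd > 0:
        frac = frac + gen.normal(0.0, noise_sd, len(c))
    frac = np.clip(frac, 0.0, 1.2)
    return pd.DataFrame({"conc_nM": c, "fraction": frac})


def simulate_spot_field(
    n_spots: int,
    image_size: tuple[int, int] = (256, 256),
    psf_sigma_px: float = 1.5,
    intensity: float = 500.0,
    noise_sd: float = 10.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    min_separation_px: float = 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a TIRF field of diffraction-limited spots.

    2-D Gaussian point-spread functions of the given amplitude at
    uniformly random, non-overlapping sub-pixel centers, plus Gaussian
    background noise.  Returns (image, centers) with centers as (x, y)
    rows in 0-based, center-of-pixel coordinates.
    """
    if n_spots < 0:
        raise ValueError("n_spots must be >= 0")
    gen = _rng(seed, rng)
    h, w = image_size
    margin = 4.0 * psf_sigma_px
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_spots:
        attempts += 1
        if attempts > 1000 * max(n_spots, 1):
            raise RuntimeError("could not place non-overlapping spots; field too dense")
        x = gen.uniform(margin, w - 1 - margin)
        y = gen.uniform(margin, h - 1 - margin)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_separation_px**2 for cx, cy in centers):
            centers.append((x, y))
    image = np.zeros((h, w), dtype=float)
    half = int(math.ceil(4 * psf_sigma_px))
    for cx, cy in centers:
        x0, y0 = int(round(cx)), int(round(cy))
        xs = np.arange(max(0, x0 - half), min(w, x0 + half + 1))
        ys = np.arange(max(0, y0 - half), min(h, y0 + half + 1))
        gx = np.exp(-((xs - cx) ** 2) / (2 * psf_sigma_px**2))
        gy = np.exp(-((ys - cy) ** 2) / (2 * psf_sigma_px**2))
        image[np.ix_(ys, xs)] += intensity * gy[:, None] * gx[None, :]
    if noise_sd > 0:
        image = image + gen.normal(0.0, noise_sd, (h, w))
    return image, np.array(centers, dtype=float).reshape(-1, 2)
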