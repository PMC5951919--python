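"""FRET efficiencies, ensemble histograms, Gaussian-mixture fits and
Förster-distance conversions.

Apparent FRET efficiency is computed per frame as E = I_A/(I_A + I_D)
from background-corrected intensities, without gamma correction.  The
donor-acceptor distance follows from the Förster relation
E = 1/(1 + (R/R0)^6) with R0 = 54 Å for the Cy3-Cy5 pair, inverted as
R = R0 * ((1-E)/E)^(1/6).  Ensemble histograms pool the first 50 frames
of each selected trace and are fit with a sum of Gaussians to estimate
state means and fractional populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .simulate import E_CLAMP
from .traces import IntensityTrace, detect_photobleach_step

__all__ = [
    "FretTrace",
    "FretHistogram",
    "GaussianMixtureFit",
    "ForsterModel",
    "fret_efficiency",
    "build_fret_histogram",
    "fit_gaussian_mixture",
    "fret_to_distance",
    "distance_to_fret",
    "transition_density",
    "DEFAULT_R0_A",
    "DEFAULT_BIN_WIDTH",
]

DEFAULT_R0_A = 54.0
DEFAULT_BIN_WIDTH = 0.02


@dataclass(frozen=True)
class ForsterModel:
    """Förster relation parameterized by the 50%-transfer distance R0 (Å)."""

    r0: float = DEFAULT_R0_A

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be > 0")


@dataclass
class FretTrace:
    """Per-frame apparent FRET efficiency with a validity mask.

    ``valid`` is False for frames after the first photobleach and for
    frames whose background-corrected total intensity is non-positive.
    """

    e_series: np.ndarray
    valid: np.ndarray
    frame_interval_s: float

    @property
    def valid_e(self) -> np.ndarray:
        return self.e_series[self.valid]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class FretHistogram:
    counts: np.ndarray
    bin_edges: np.ndarray
    n_samples: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def density(self) -> np.ndarray:
        width = np.diff(self.bin_edges)
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / (total * width)


@dataclass
class GaussianMixtureFit:
    """Sum-of-Gaussians fit to a binned FRET distribution.

    Components are sorted by ascending mean; ``fractions`` are the
    normalized component areas and sum to 1.
    """

    means: np.ndarray
    sds: np.ndarray
    fractions: np.ndarray
    residual_norm: float
    n_samples: int
    converged: bool
    message: str = ""

    @property
    def components(self) -> list[tuple[float, float, float]]:
        return list(zip(self.means, self.sds, self.fractions))

    @property
    def major_mean(self) -> float:
        return float(self.means[np.argmax(self.fractions)])


def fret_efficiency(trace: IntensityTrace, bleach_frame: int | None = None) -> FretTrace:
    """Compute the per-frame apparent FRET efficiency of one trace.

    E = (I_A - bg_A) / ((I_A - bg_A) + (I_D - bg_D)), clamped to the
    standard range.  Frames at or after the first photobleach step
    (auto-detected on each channel unless ``bleach_frame`` is given) are
    excluded via the validity mask, as are frames with non-positive
    denominator.
    """
    d = trace.donor - trace.background_donor
    a = trace.acceptor - trace.background_acceptor
    denom = d + a
    valid = denom > 0
    e = np.full(trace.n_frames, np.nan)
    e[valid] = np.clip(a[valid] / denom[valid], *E_CLAMP)

    if bleach_frame is None:
        candidates = []
        for series in (trace.donor, trace.acceptor):
            step = detect_photobleach_step(series)
            if step.step_frame is not None:
                candidates.append(step.step_frame)
        bleach_frame = min(candidates) if candidates else None
    if bleach_frame is not None:
        valid = valid & (np.arange(trace.n_frames) < bleach_frame)
    if not valid.any():
        raise ValueError("no valid pre-bleach frames in trace")
    return FretTrace(e_series=e, valid=valid, frame_interval_s=trace.frame_interval_s)


def build_fret_histogram(
    fret_traces: list[FretTrace],
    frames_per_trace: int = 50,
    bin_width: float = DEFAULT_BIN_WIDTH,
    e_range: tuple[float, float] = E_CLAMP,
) -> FretHistogram:
    """Pool the first ``frames_per_trace`` valid frames of each trace.

    Total counts equal the sum over traces of min(frames_per_trace,
    valid frames).
    """
    if not fret_traces:
        raise ValueError("need at least one FRET trace")
    pooled = []
    for ft in fret_traces:
        vals = ft.valid_e
        pooled.append(vals[:frames_per_trace])
    samples = np.concatenate(pooled) if pooled else np.array([])
    n_bins = int(round((e_range[1] - e_range[0]) / bin_width))
    edges = e_range[0] + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(samples, bins=edges)
    return FretHistogram(counts=counts, bin_edges=edges, n_samples=len(samples))


def _gauss_sum(x, *params):
    k = len(params) // 3
    y = np.zeros_like(x, dtype=float)
    for i in range(k):
        amp, mu, sd = params[3 * i : 3 * i + 3]
        y = y + amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return y


def _init_means(hist: FretHistogram, k: int) -> np.ndarray:
    """Initial component means from density peaks, quantiles as fallback.

    Local maxima of the lightly smoothed density are taken in height
    order (at least 4 bins apart); if fewer than ``k`` peaks exist the
    remainder is filled from distribution quantiles away from the chosen
    peaks, so minor components far from the bulk can still be seeded.
    """
    x = hist.centers
    y = np.convolve(hist.density, np.ones(3) / 3, mode="same")
    is_peak = np.r_[False, (y[1:-1] >= y[:-2]) & (y[1:-1] > y[2:]), False] & (y > 0)
    order = np.argsort(y)[::-1]
    chosen: list[int] = []
    for i in order:
        if not is_peak[i]:
            continue
        if all(abs(i - j) >= 4 for j in chosen):
            chosen.append(int(i))
        if len(chosen) == k:
            break
    means = [x[i] for i in chosen]
    if len(means) < k:
        total = max(hist.counts.sum(), 1)
        cdf = np.cumsum(hist.counts) / total
        for q in (np.arange(k) + 0.5) / k:
            if len(means) == k:
                break
            cand = float(np.interp(q, cdf, x))
            if all(abs(cand - m) > 0.08 for m in means):
                means.append(cand)
        while len(means) < k:  # degenerate fallback
            means.append(float(x[int(len(x) * (len(means) + 0.5) / k)]))
    return np.sort(np.array(means))


def fit_gaussian_mixture(hist: FretHistogram, k: int) -> GaussianMixtureFit:
    """Nonlinear least-squares sum-of-Gaussians fit to a binned density.

    Requires at least 3*k occupied bins.  Non-convergence returns a fit
    object with ``converged=False`` and diagnostics rather than raising.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    occupied = int((hist.counts > 0).sum())
    if occupied < 3 * k:
        raise ValueError(f"need >= {3 * k} occupied bins for k={k}, got {occupied}")
    x = hist.centers
    y = hist.density
    mus0 = _init_means(hist, k)
    sd0 = max(0.05, float(np.std(np.repeat(x, hist.counts))) / max(k, 1))
    p0 = []
    for mu in mus0:
        p0 += [float(y.max()) / k + 1e-6, float(mu), sd0]
    lo = [0.0, hist.bin_edges[0], 1e-3] * k
    hi = [np.inf, hist.bin_edges[-1], 1.0] * k
    try:
        popt, _ = curve_fit(_gauss_sum, x, y, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError as exc:
        return GaussianMixtureFit(
            means=np.array(mus0),
            sds=np.full(k, sd0),
            fractions=np.full(k, 1.0 / k),
            residual_norm=float("inf"),
            n_samples=hist.n_samples,
            converged=False,
            message=str(exc),
        )
    amps = popt[0::3]
    mus = popt[1::3]
    sds = popt[2::3]
    areas = amps * sds * np.sqrt(2 * np.pi)
    fractions = areas / areas.sum()
    order = np.argsort(mus)
    resid = float(np.linalg.norm(y - _gauss_sum(x, *popt)))
    return GaussianMixtureFit(
        means=mus[order],
        sds=sds[order],
        fractions=fractions[order],
        residual_norm=resid,
        n_samples=hist.n_samples,
        converged=True,
    )


def fret_to_distance(e: float, model: ForsterModel | None = None) -> float:
    """Invert the Förster relation: R = R0 * ((1-E)/E)^(1/6), in Å.

    Defined for 0 < E < 1; strictly decreasing in E.
    """
    model = model or ForsterModel()
    e = float(e)
    if not 0.0 < e < 1.0:
        raise ValueError("FRET efficiency must be strictly between 0 and 1")
    return model.r0 * ((1.0 - e) / e) ** (1.0 / 6.0)


def distance_to_fret(r: float, model: ForsterModel | None = None) -> float:
    """E = 1 / (1 + (R/R0)^6); exact inverse of :func:`fret_to_distance`."""
    model = model or ForsterModel()
    r = float(r)
    if r <= 0:
        raise ValueError("distance must be > 0")
    return 1.0 / (1.0 + (r / model.r0) ** 6)


def transition_density(
    idealized_seqs: list[np.ndarray],
    bin_width: float = 0.05,
    e_range: tuple[float, float] = E_CLAMP,
) -> tuple[np.ndarray, np.ndarray]:
    """2-D transition density (E before, E after) from idealized traces.

    Each change of idealized FRET level contributes one count at
    (E_before, E_after).  Traces without transitions contribute nothing;
    an all-static input yields an empty (all-zero) density, which is
    valid.  Axes are symmetric over the clamp range.
    """
    n_bins = int(round((e_range[1] - e_range[0]) / bin_width))
    edges = e_range[0] + bin_width * np.arange(n_bins + 1)
    before, after = [], []
    for seq in idealized_seqs:
        seq = np.asarray(seq, dtype=float)
        if len(seq) < 2:
            continue
        change = np.nonzero(np.diff(seq) != 0)[0]
        before.append(seq[change])
        after.append(seq[change + 1])
    if before:
        b = np.concatenate(before)
        a = np.concatenate(after)
        counts, _, _ = np.histogram2d(b, a, bins=[edges, edges])
    else:
        counts = np.zeros((n_bins, n_bins))
    return counts, edges
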