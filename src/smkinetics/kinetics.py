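"""Exponential dwell-time kinetics: survival fits, rate constants,
heterogeneity classes and ultra-stable complex decay.

Dwell times from idealized traces are modelled as draws from a one- or
two-component exponential mixture.  Two fitting routes are exposed:

* ``mle`` (default): maximum likelihood of the exponential mixture with
  right-censoring, the route used for all derived rate constants;
* ``ls``: least squares on the empirical survival function of the
  complete dwells, the classical cumulative-distribution fit.

Dead time: durations are recorded as whole camera frames, so a kept
dwell of >= ``min_frames`` frames corresponds to an underlying duration
longer than (min_frames - 1/2) frames.  The likelihood is therefore
renormalized on [t0, inf) with t0 = (min_frames - 1/2) * frame interval,
which removes the discretization bias to first order (see methods note).

Rate constants follow the standard single-molecule estimators:
koff = 1/tau_bound, kon = 1/(tau_unbound * c), Kd = koff/kon.  Slow
(ultra-stable) dissociation is measured from the exponential decay of
colocalized-spot fractions in time-lapse imaging.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, minimize

__all__ = [
    "KineticFit",
    "RateSummary",
    "TimeLapseDecay",
    "UltrastableFit",
    "fit_exponential_survival",
    "select_model",
    "kon_from_unbound",
    "koff_from_bound",
    "kd_from_rates",
    "classify_heterogeneity",
    "fit_ultrastable_decay",
    "fraction_at_time",
    "subtract_bleach_rate",
]


@dataclass
class KineticFit:
    """Fitted exponential-survival model (1 or 2 components).

    Rates are sorted descending (fast component first); weights are the
    pre-truncation mixture fractions and sum to 1; lifetimes = 1/rate.
    Standard errors come from a seeded nonparametric bootstrap.
    """

    n_components: int
    rates: np.ndarray  # 1/s, descending
    weights: np.ndarray
    rate_se: np.ndarray
    weight_se: np.ndarray
    log_likelihood: float
    bic: float
    n_dwells: int
    n_censored: int
    method: str
    dead_time_s: float
    converged: bool = True
    degenerate: bool = False

    @property
    def lifetimes(self) -> np.ndarray:
        return 1.0 / self.rates

    @property
    def fast_rate(self) -> float:
        return float(self.rates[0])

    @property
    def slow_rate(self) -> float:
        return float(self.rates[-1])


@dataclass
class RateSummary:
    """Bimolecular association and dissociation rate constants.

    ``kd_M`` is koff_reference / kon with the reference component noted.
    """

    kon_per_M_s: float
    koff_per_s: np.ndarray
    koff_weights: np.ndarray
    concentration_M: float
    kd_M: float | None = None
    kd_reference: str = ""


@dataclass
class TimeLapseDecay:
    """Colocalized-fraction time course."""

    times_min: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.times_min) != len(self.fractions):
            raise ValueError("times and fractions must have equal length")
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class UltrastableFit:
    """Single-exponential fit f(t) = A0 * exp(-t/tau) to a slow decay."""

    a0: float
    lifetime_min: float
    koff_slow_per_s: float
    increasing_warning: bool = False


def _prepare(durations_s, censored, frame_interval_s, min_frames):
    d = np.asarray(durations_s, dtype=float)
    if censored is None:
        cens = np.zeros(len(d), dtype=bool)
    else:
        cens = np.asarray(censored, dtype=bool)
    if len(cens) != len(d):
        raise ValueError("censored flags must match durations")
    frames = np.round(d / frame_interval_s).astype(int)
    keep = frames >= min_frames
    t0 = (min_frames - 0.5) * frame_interval_s
    return d[keep], cens[keep], t0


def _mixture_nll(params, t, cens, t0, k):
    """Negative log-likelihood, pre-truncation weights, right-censoring."""
    rates = np.exp(params[:k])
    if k == 2:
        w1 = 1.0 / (1.0 + math.exp(-params[2]))
        w = np.array([w1, 1.0 - w1])
    else:
        w = np.array([1.0])
    norm = float(np.sum(w * np.exp(-rates * t0)))
    tc = t[~cens]
    f = (w * rates)[None, :] * np.exp(-np.outer(tc, rates))
    ll = np.sum(np.log(np.maximum(f.sum(axis=1), 1e-300))) - len(tc) * math.log(norm)
    tx = t[cens]
    if len(tx):
        s = (w[None, :] * np.exp(-np.outer(tx, rates))).sum(axis=1)
        ll += np.sum(np.log(np.maximum(s, 1e-300))) - len(tx) * math.log(norm)
    return -ll


def _fit_mle(t, cens, t0, k):
    n_complete = int((~cens).sum())
    if n_complete == 0:
        raise ValueError("all dwells censored; cannot fit")
    if k == 1:
        # closed form for censored exponential with left truncation at t0
        rate = n_complete / float(np.sum(t - t0))
        ll = -_mixture_nll(np.array([math.log(rate)]), t, cens, t0, 1)
        return np.array([rate]), np.array([1.0]), ll
    mean = float(np.mean(t[~cens] - t0)) + 1e-9
    lo = np.sort(t[~cens] - t0)
    split = lo[: max(len(lo) // 2, 1)].mean() + 1e-9
    slow0 = max(2.0 * mean - split, split * 1.5)
    starts = [
        np.array([math.log(1.0 / split), math.log(1.0 / slow0), 0.0]),
        np.array([math.log(3.0 / mean), math.log(0.3 / mean), 0.0]),
        np.array([math.log(10.0 / mean), math.log(0.5 / mean), 1.0]),
    ]
    best = None
    for p0 in starts:
        res = minimize(
            _mixture_nll, p0, args=(t, cens, t0, 2), method="L-BFGS-B",
            bounds=[(-12, 8), (-12, 8), (-8, 8)],
        )
        if best is None or res.fun < best.fun:
            best = res
    rates = np.exp(best.x[:2])
    w1 = 1.0 / (1.0 + math.exp(-best.x[2]))
    w = np.array([w1, 1.0 - w1])
    order = np.argsort(rates)[::-1]
    return rates[order], w[order], -best.fun


def _fit_ls(t, cens, t0, k):
    """Least squares on the empirical survival of complete dwells."""
    tc = np.sort(t[~cens])
    if len(tc) < 5:
        raise ValueError("too few complete dwells for a survival fit")
    n = len(tc)
    s_emp = 1.0 - (np.arange(1, n + 1) - 0.5) / n

    if k == 1:
        def model(x, lam):
            return np.exp(-lam * (x - t0))
        p0 = [1.0 / max(tc.mean() - t0, 1e-6)]
        popt, _ = curve_fit(model, tc, s_emp, p0=p0, bounds=(1e-9, np.inf), maxfev=20000)
        rates = np.array([popt[0]])
        w = np.array([1.0])
    else:
        def model(x, lam1, lam2, a):
            w1 = 1.0 / (1.0 + np.exp(-a))
            return w1 * np.exp(-lam1 * (x - t0)) + (1 - w1) * np.exp(-lam2 * (x - t0))
        mean = max(tc.mean() - t0, 1e-6)
        p0 = [3.0 / mean, 0.3 / mean, 0.0]
        popt, _ = curve_fit(
            model, tc, s_emp, p0=p0,
            bounds=([1e-9, 1e-9, -8], [np.inf, np.inf, 8]), maxfev=40000,
        )
        rates = np.array([popt[0], popt[1]])
        w1 = 1.0 / (1.0 + math.exp(-popt[2]))
        w = np.array([w1, 1.0 - w1])
        order = np.argsort(rates)[::-1]
        rates, w = rates[order], w[order]
    # report the likelihood of the LS solution so BIC is comparable
    if k == 2:
        params = np.array([math.log(rates[0]), math.log(rates[1]),
                           math.log(w[0] / max(w[1], 1e-12))])
    else:
        params = np.array([math.log(rates[0])])
    ll = -_mixture_nll(params, t, cens, t0, k)
    return rates, w, ll


def fit_exponential_survival(
    durations_s,
    censored=None,
    n_components: int = 1,
    method: str = "mle",
    frame_interval_s: float = 0.1,
    min_frames: int = 2,
    n_bootstrap: int = 200,
    seed: int | None = None,
) -> KineticFit:
    """Fit a 1- or 2-component exponential survival model to dwell times.

    Parameters
    ----------
    durations_s : array
        Dwell durations in seconds (whole camera frames).
    censored : bool array, optional
        Right-censoring flags (trace boundary / photobleach truncation).
        Censored dwells enter the MLE likelihood through the survival
        term; the LS route drops them.
    n_components : {1, 2}
    method : {"mle", "ls"}
    min_frames : int
        Dead-time rule: dwells shorter than this many frames are
        excluded and the model renormalized on [t0, inf) with
        t0 = (min_frames - 1/2) x frame interval.
    n_bootstrap : int
        Resamples for standard errors (0 disables).
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if method not in ("mle", "ls"):
        raise ValueError("method must be 'mle' or 'ls'")
    t, cens, t0 = _prepare(durations_s, censored, frame_interval_s, min_frames)
    n_complete = int((~cens).sum())
    min_needed = 20 if n_components == 1 else 50
    if n_complete < min_needed:
        raise ValueError(
            f"need >= {min_needed} complete dwells for {n_components} component(s), "
            f"got {n_complete}"
        )

    fit_fn = _fit_mle if method == "mle" else _fit_ls
    rates, weights, ll = fit_fn(t, cens, t0, n_components)

    degenerate = False
    if n_components == 2:
        if rates[0] / rates[1] < 1.2 or min(weights) < 0.01:
            degenerate = True

    k_params = 1 if n_components == 1 else 3
    bic = -2.0 * ll + k_params * math.log(max(len(t), 1))

    rate_se = np.zeros(n_components)
    weight_se = np.zeros(n_components)
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boot_rates = np.empty((n_bootstrap, n_components))
        boot_w = np.empty((n_bootstrap, n_components))
        idx_all = np.arange(len(t))
        for b in range(n_bootstrap):
            idx = rng.choice(idx_all, size=len(t), replace=True)
            tb, cb = t[idx], cens[idx]
            if (~cb).sum() < 2:
                boot_rates[b] = rates
                boot_w[b] = weights
                continue
            try:
                rb, wb, _ = fit_fn(tb, cb, t0, n_components)
            except (ValueError, RuntimeError):
                rb, wb = rates, weights
            boot_rates[b] = rb
            boot_w[b] = wb
        rate_se = boot_rates.std(axis=0)
        weight_se = boot_w.std(axis=0)

    return KineticFit(
        n_components=n_components,
        rates=rates,
        weights=weights,
        rate_se=rate_se,
        weight_se=weight_se,
        log_likelihood=ll,
        bic=bic,
        n_dwells=len(t),
        n_censored=int(cens.sum()),
        method=method,
        dead_time_s=t0,
        degenerate=degenerate,
    )


def select_model(fit1: KineticFit, fit2: KineticFit, min_delta_bic: float = 10.0) -> KineticFit:
    """Choose between 1- and 2-component fits of the same dwell set.

    The 2-component model is accepted only when it improves BIC by more
    than ``min_delta_bic`` and is not degenerate (a strong-evidence rule;
    the simpler model wins otherwise).
    """
    if fit1.n_dwells != fit2.n_dwells:
        raise ValueError("fits must be on the same dwell set")
    delta = fit1.bic - fit2.bic  # positive favours the 2-component model
    if delta > min_delta_bic and not fit2.degenerate:
        return fit2
    return fit1


def kon_from_unbound(tau_unbound_s: float, conc_M: float) -> float:
    """Association rate constant: kon = 1 / (tau_unbound * c), in 1/M/s."""
    if tau_unbound_s <= 0 or conc_M <= 0:
        raise ValueError("tau_unbound and concentration must be > 0")
    return 1.0 / (tau_unbound_s * conc_M)


def koff_from_bound(tau_bound_s: float) -> float:
    """Dissociation rate constant: koff = 1 / tau_bound, in 1/s."""
    if tau_bound_s <= 0:
        raise ValueError("tau_bound must be > 0")
    return 1.0 / tau_bound_s


def kd_from_rates(koff_per_s: float, kon_per_M_s: float) -> float:
    """Equilibrium dissociation constant Kd = koff / kon, in molar."""
    if koff_per_s <= 0 or kon_per_M_s <= 0:
        raise ValueError("rates must be > 0")
    return koff_per_s / kon_per_M_s


def subtract_bleach_rate(fit: KineticFit, bleach_rate_per_s: float) -> KineticFit:
    """Correct fitted bound-state rates for acceptor photobleaching.

    A bound event ends observably either by dissociation or by single-
    step bleaching of its dye, so each observed component decays at
    koff + k_bleach with unchanged mixture weights; subtracting the
    independently known bleach rate recovers koff.
    """
    if bleach_rate_per_s < 0:
        raise ValueError("bleach rate must be >= 0")
    rates = np.maximum(fit.rates - bleach_rate_per_s, 1e-9)
    return KineticFit(
        n_components=fit.n_components,
        rates=rates,
        weights=fit.weights.copy(),
        rate_se=fit.rate_se.copy(),
        weight_se=fit.weight_se.copy(),
        log_likelihood=fit.log_likelihood,
        bic=fit.bic,
        n_dwells=fit.n_dwells,
        n_censored=fit.n_censored,
        method=fit.method,
        dead_time_s=fit.dead_time_s,
        converged=fit.converged,
        degenerate=fit.degenerate,
    )


def classify_heterogeneity(
    molecule_durations: dict,
    fit: KineticFit,
) -> dict:
    """Assign each molecule a kinetic class under a 2-component fit.

    ``molecule_durations`` maps molecule id -> array of complete bound
    dwell durations.  Each dwell is posterior-assigned to the mixture
    component maximizing w_i * lam_i * exp(-lam_i * (t - t0)); a molecule
    is ``fast``/``medium`` when >= 80% of its dwells assign to that
    component, ``mixed`` otherwise, and ``indeterminate`` with fewer than
    two complete dwells.
    """
    if fit.n_components != 2:
        raise ValueError("heterogeneity classification requires a 2-component fit")
    labels = {}
    lam = fit.rates
    w = fit.weights
    t0 = fit.dead_time_s
    for mol, durs in molecule_durations.items():
        durs = np.asarray(durs, dtype=float)
        durs = durs[durs >= t0]
        if len(durs) < 2:
            labels[mol] = "indeterminate"
            continue
        post_fast = w[0] * lam[0] * np.exp(-lam[0] * (durs - t0))
        post_slow = w[1] * lam[1] * np.exp(-lam[1] * (durs - t0))
        frac_fast = float(np.mean(post_fast >= post_slow))
        if frac_fast >= 0.8:
            labels[mol] = "fast"
        elif frac_fast <= 0.2:
            labels[mol] = "medium"
        else:
            labels[mol] = "mixed"
    return labels


def fit_ultrastable_decay(decay: TimeLapseDecay) -> UltrastableFit:
    """Single-exponential fit to a colocalized-fraction time course.

    f(t) = A0 * exp(-t / tau) with t in minutes; the slow dissociation
    rate constant is 1/tau converted to 1/s.  A0 extrapolates the
    ultra-stable fraction to time zero.  Requires >= 5 time points; a
    rising trend raises a warning flag instead of failing.
    """
    t = decay.times_min
    f = decay.fractions
    if len(t) < 5:
        raise ValueError("need >= 5 time points")
    slope = np.polyfit(t, f, 1)[0]
    increasing = bool(slope > 0)
    if increasing:
        warnings.warn("colocalized fraction increases over time", stacklevel=2)

    def model(x, a0, tau):
        return a0 * np.exp(-x / tau)

    p0 = [max(f[0], 1e-3), max(t[-1], 1.0)]
    popt, _ = curve_fit(
        model, t, f, p0=p0, bounds=([0.0, 1e-6], [1.5, np.inf]), maxfev=20000
    )
    a0, tau = float(popt[0]), float(popt[1])
    return UltrastableFit(
        a0=a0,
        lifetime_min=tau,
        koff_slow_per_s=1.0 / (tau * 60.0),
        increasing_warning=increasing,
    )


def fraction_at_time(a0: float, lifetime_min: float, t_min: float) -> float:
    """Surviving fraction A0 * exp(-t / tau) at time t (minutes)."""
    if lifetime_min <= 0:
        raise ValueError("lifetime must be > 0")
    return a0 * math.exp(-t_min / lifetime_min)
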