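"""End-to-end run orchestration: simulate -> QC -> idealize -> kinetics.

One :func:`run_pipeline` call executes the whole analysis for a named
condition with a single seed fanned out to per-stage substreams, so the
report is reproducible byte-for-byte.  The report bundles the kinetic
fits, derived rate constants, FRET-histogram mixture fit, ultra-stable
decay fit (where the condition forms such complexes) and a QC summary,
together with provenance (config hash, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .conditions import CONDITIONS, make_simulation_config
from .fret import build_fret_histogram, fit_gaussian_mixture, fret_efficiency
from .idealize import extract_dwells, skm_idealize
from .kinetics import (
    TimeLapseDecay,
    fit_exponential_survival,
    fit_ultrastable_decay,
    kd_from_rates,
    kon_from_unbound,
    select_model,
    subtract_bleach_rate,
)
from .simulate import simulate_binding_batch, simulate_smfret_batch, simulate_timelapse
from .traces import select_traces

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Serializes losslessly to/from YAML; unknown keys are rejected.
    """

    condition: str = "core"
    seed: int = 0
    n_molecules: int = 150
    n_frames: int = 9000
    n_fret_molecules: int = 120
    n_fret_frames: int = 600
    run_qc: bool = True
    run_fret: bool = True
    run_timelapse: bool = True
    timelapse_n0: int = 2000
    n_bootstrap: int = 100
    bleach_correction: bool = True
    min_frames: int = 2
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; choose from {sorted(CONDITIONS)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _fit_to_dict(fit) -> dict:
    return {
        "n_components": fit.n_components,
        "rates_per_s": [float(r) for r in fit.rates],
        "lifetimes_s": [float(l) for l in fit.lifetimes],
        "weights": [float(w) for w in fit.weights],
        "rate_se": [float(s) for s in fit.rate_se],
        "weight_se": [float(s) for s in fit.weight_se],
        "bic": float(fit.bic),
        "n_dwells": int(fit.n_dwells),
        "n_censored": int(fit.n_censored),
        "method": fit.method,
        "degenerate": bool(fit.degenerate),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> QC -> SKM -> dwell kinetics for one condition.

    Deterministic for a fixed config (single seed, per-stage substreams).
    Returns the report as a JSON-serializable dict; when ``out_dir`` is
    set the report and intermediate tables are also written there, with
    partial outputs preserved on stage failure.
    """
    cond = CONDITIONS[config.condition]
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ["simulate", "bootstrap", "fret", "timelapse"], ss.spawn(4)
        )
    }
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "condition": config.condition,
        "description": cond.description,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "version": __version__,
        "truth": {
            "kon_per_M_s": cond.kon_per_M_s,
            "conc_nM": cond.conc_nM,
            "koff_per_s": [c.koff_per_s for c in cond.classes],
            "koff_weights": [c.weight for c in cond.classes],
        },
    }

    def _finish(stage, exc):
        if out:
            (out / "report_partial.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        raise PipelineStageError(stage, str(exc)) from exc

    # --- simulate ---------------------------------------------------------
    try:
        simcfg = make_simulation_config(cond, n_frames=config.n_frames)
        traces, truths = simulate_binding_batch(
            simcfg, config.n_molecules, seed=seeds["simulate"]
        )
    except Exception as exc:  # noqa: BLE001 - stage-named abort
        _finish("simulate", exc)

    # --- qc ---------------------------------------------------------------
    try:
        if config.run_qc:
            kept, reports = select_traces(traces, mode="binding")
            kept_ids = {t.molecule_id for t in kept}
        else:
            kept, reports = traces, []
            kept_ids = {t.molecule_id for t in traces}
        n_active = sum(t.active for t in truths)
        report["qc"] = {
            "n_traces": len(traces),
            "n_active_truth": int(n_active),
            "n_kept": len(kept),
            "rejection_reasons": sorted(
                {r for rep in reports for r in rep.failure_reasons}
            ),
        }
    except Exception as exc:
        _finish("qc", exc)

    # --- idealize + dwells ------------------------------------------------
    try:
        bound_d, bound_c = [], []
        unbound_d, unbound_c = [], []
        per_molecule: dict[str, np.ndarray] = {}
        for tr in kept:
            ideal = skm_idealize(tr.acceptor)
            ds = extract_dwells(ideal, tr.frame_interval_s)
            d, c = ds.all_durations("bound")
            bound_d.append(d)
            bound_c.append(c)
            per_molecule[tr.molecule_id] = d[~c]
            # start-of-trace unbound runs are residual lifetimes of an
            # exponential and therefore complete observations
            d, c = ds.survival_inputs("unbound", residual_start_complete=True)
            unbound_d.append(d)
            unbound_c.append(c)
        bound_d = np.concatenate(bound_d) if bound_d else np.array([])
        bound_c = np.concatenate(bound_c) if bound_c else np.array([], dtype=bool)
        unbound_d = np.concatenate(unbound_d) if unbound_d else np.array([])
        unbound_c = np.concatenate(unbound_c) if unbound_c else np.array([], dtype=bool)
        report["dwells"] = {
            "n_bound": int(len(bound_d)),
            "n_bound_censored": int(bound_c.sum()),
            "n_unbound": int(len(unbound_d)),
        }
    except Exception as exc:
        _finish("idealize", exc)

    # --- kinetics ---------------------------------------------------------
    try:
        dt = simcfg.frame_interval_s
        fit_u = fit_exponential_survival(
            unbound_d, unbound_c, n_components=1, frame_interval_s=dt,
            min_frames=config.min_frames, n_bootstrap=config.n_bootstrap,
            seed=seeds["bootstrap"],
        )
        tau_unbound = float(fit_u.lifetimes[0])

        common = dict(
            frame_interval_s=dt, min_frames=config.min_frames,
            n_bootstrap=config.n_bootstrap, seed=seeds["bootstrap"],
        )
        fit1 = fit_exponential_survival(bound_d, bound_c, n_components=1, **common)
        try:
            fit2 = fit_exponential_survival(bound_d, bound_c, n_components=2, **common)
            chosen = select_model(fit1, fit2)
        except ValueError:
            fit2, chosen = None, fit1
        bleach_rate = 1.0 / simcfg.bleach_lifetime_cy5_s
        corrected = (
            subtract_bleach_rate(chosen, bleach_rate)
            if config.bleach_correction
            else chosen
        )

        # Correct tau_unbound for two artifacts of the binding assay:
        # (1) bound events shorter than the dead time are invisible and
        #     merge the flanking unbound dwells (events rounding to zero
        #     frames are always missed; one-frame events are missed about
        #     half the time depending on frame phase);
        # (2) an event ending by Cy5 bleach rather than dissociation
        #     leaves the tRNA bound-but-dark, appending its residual
        #     bound lifetime to the apparent unbound dwell.
        # Both use only the fitted bound components and the known bleach
        # rate, so the correction is available to a real experiment.
        tau_unbound_corr = tau_unbound
        if config.bleach_correction:
            lam_obs = np.asarray(chosen.rates)
            lam_true = np.asarray(corrected.rates)
            w = np.asarray(chosen.weights)
            p0f = 1.0 - np.exp(-lam_obs * 0.5 * dt)
            p1f = np.exp(-lam_obs * 0.5 * dt) - np.exp(-lam_obs * 1.5 * dt)
            p_miss = float(np.sum(w * (p0f + 0.5 * p1f)))
            dark_s = float(np.sum(w * (bleach_rate / lam_obs) / np.maximum(lam_true, 1e-9)))
            tau_unbound_corr = max((tau_unbound - dark_s) * (1.0 - p_miss), 1e-9)
        kon = kon_from_unbound(tau_unbound_corr, cond.conc_nM * 1e-9)

        kd_ref = "fast"
        kd = kd_from_rates(corrected.fast_rate, kon)
        report["kinetics"] = {
            "tau_unbound_s": tau_unbound,
            "tau_unbound_corrected_s": tau_unbound_corr,
            "kon_per_M_s": kon,
            "unbound_fit": _fit_to_dict(fit_u),
            "bound_fit_1": _fit_to_dict(fit1),
            "bound_fit_2": _fit_to_dict(fit2) if fit2 is not None else None,
            "chosen_components": chosen.n_components,
            "bleach_rate_subtracted_per_s": bleach_rate if config.bleach_correction else 0.0,
            "koff_per_s": [float(r) for r in corrected.rates],
            "koff_weights": [float(w) for w in corrected.weights],
            "kd_nM": kd * 1e9,
            "kd_reference_component": kd_ref,
        }
        if corrected.n_components == 2:
            from .kinetics import classify_heterogeneity

            labels = classify_heterogeneity(per_molecule, corrected)
            vals = list(labels.values())
            report["heterogeneity"] = {
                lab: vals.count(lab) for lab in ("fast", "medium", "mixed", "indeterminate")
            }
    except Exception as exc:
        _finish("kinetics", exc)

    # --- fret histogram ---------------------------------------------------
    if config.run_fret:
        try:
            fretcfg = make_simulation_config(
                cond, n_frames=config.n_fret_frames, inactive_fraction=0.0,
                intensity_on=600.0, noise_sd=30.0,
            )
            ftraces, _ = simulate_smfret_batch(
                fretcfg, config.n_fret_molecules, seed=seeds["fret"]
            )
            kept_f, _ = select_traces(ftraces, mode="smfret")
            efs = [fret_efficiency(t) for t in kept_f]
            hist = build_fret_histogram(efs)
            gmm = fit_gaussian_mixture(hist, k=len(cond.fret_states))
            report["fret"] = {
                "n_traces_kept": len(kept_f),
                "n_samples": hist.n_samples,
                "means": [float(m) for m in gmm.means],
                "sds": [float(s) for s in gmm.sds],
                "fractions": [float(f) for f in gmm.fractions],
                "converged": bool(gmm.converged),
            }
        except Exception as exc:
            _finish("fret", exc)

    # --- ultra-stable time-lapse -----------------------------------------
    if config.run_timelapse and cond.ultrastable_fraction is not None:
        try:
            counts = simulate_timelapse(
                n0=config.timelapse_n0,
                ultrastable_fraction=cond.ultrastable_fraction,
                lifetime_min=cond.ultrastable_lifetime_min,
                seed=seeds["timelapse"],
            )
            decay = TimeLapseDecay(counts.times_min, counts.fractions)
            us = fit_ultrastable_decay(decay)
            report["ultrastable"] = {
                "a0": us.a0,
                "lifetime_min": us.lifetime_min,
                "koff_slow_per_s": us.koff_slow_per_s,
            }
        except Exception as exc:
            _finish("timelapse", exc)

    if out:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
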