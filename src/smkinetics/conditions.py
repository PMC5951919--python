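"""Shipped experimental-condition parameter sets.

Each condition bundles the ground-truth kinetic and FRET parameters of
one construct/ligand combination studied in the glyQS T-box riboswitch
system, for use as generator truth in end-to-end runs:

* ``stem1`` — isolated Stem-I fragment binding uncharged tRNA:
  homogeneous fast kinetics (single koff ~0.24 /s).
* ``core`` — full riboswitch core (Stem-I + antiterminator) with
  uncharged tRNA: biphasic dissociation (fast ~0.23 /s, 72%; medium
  1/34.2 /s, 28%) plus an ultra-stable subpopulation (~69% of binding-
  competent molecules, lifetime ~69.8 min) measured by time-lapse.
* ``delta_dtm`` — core variant lacking the double T-loop (elbow) motif:
  halved kon, biphasic dissociation, no ultra-stable complexes.
* ``charged`` — core with glycyl-charged tRNA: Stem-I-like kinetics,
  ultra-stable complexes suppressed.
* ``ternary`` — core with the aa-tRNA:EF-Tu:GTP ternary complex.

Dissociation-class rates are specified as 1/tau from the measured bound
lifetimes.  Concentrations are the free labelled-tRNA concentrations of
the corresponding kinetic assays.
"""

from __future__ import annotations

from dataclasses import dataclass

from .simulate import FretState, MoleculeClass, SimulationConfig

__all__ = ["Condition", "CONDITIONS", "make_simulation_config"]


@dataclass(frozen=True)
class Condition:
    label: str
    kon_per_M_s: float
    conc_nM: float
    classes: tuple[MoleculeClass, ...]
    fret_states: tuple[FretState, ...]
    ultrastable_fraction: float | None = None
    ultrastable_lifetime_min: float | None = None
    description: str = ""


CONDITIONS: dict[str, Condition] = {
    "stem1": Condition(
        label="stem1",
        kon_per_M_s=0.79e6,
        conc_nM=25.0,
        classes=(MoleculeClass("fast", 0.24, 1.0),),
        fret_states=(FretState(0.28, 0.13, 1.0),),
        description="Isolated Stem-I fragment, uncharged tRNA",
    ),
    "core": Condition(
        label="core",
        kon_per_M_s=0.75e6,
        conc_nM=16.0,
        classes=(
            MoleculeClass("fast", 0.23, 0.72),
            MoleculeClass("medium", 1.0 / 34.2, 0.28),
        ),
        fret_states=(
            FretState(0.52, 0.12, 0.90),
            FretState(0.09, 0.12, 0.09),
            FretState(0.92, 0.07, 0.01),
        ),
        ultrastable_fraction=0.69,
        ultrastable_lifetime_min=69.8,
        description="Riboswitch core, uncharged tRNA",
    ),
    "delta_dtm": Condition(
        label="delta_dtm",
        kon_per_M_s=0.38e6,
        conc_nM=16.0,
        classes=(
            MoleculeClass("fast", 1.4, 0.27),
            MoleculeClass("medium", 1.0 / 29.4, 0.73),
        ),
        fret_states=(
            FretState(0.31, 0.11, 0.78),
            FretState(0.02, 0.08, 0.22),
        ),
        description="Core lacking the distal T-loop motif",
    ),
    "charged": Condition(
        label="charged",
        kon_per_M_s=0.75e6,
        conc_nM=12.5,
        classes=(
            MoleculeClass("fast", 0.19, 0.46),
            MoleculeClass("medium", 1.0 / 24.5, 0.54),
        ),
        fret_states=(FretState(0.23, 0.13, 0.97), FretState(0.02, 0.08, 0.03)),
        description="Riboswitch core, glycyl-charged tRNA",
    ),
    "ternary": Condition(
        label="ternary",
        kon_per_M_s=0.76e6,
        conc_nM=12.5,
        classes=(
            MoleculeClass("fast", 0.25, 0.55),
            MoleculeClass("medium", 1.0 / 24.5, 0.45),
        ),
        fret_states=(FretState(0.23, 0.13, 0.97), FretState(0.02, 0.08, 0.03)),
        description="Riboswitch core, charged tRNA:EF-Tu:GTP ternary complex",
    ),
}


def make_simulation_config(
    condition: Condition,
    n_frames: int = 9000,
    frame_interval_s: float = 0.1,
    inactive_fraction: float = 0.4,
    seed: int | None = None,
    **overrides,
) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a condition parameter set."""
    kwargs = dict(
        frame_interval_s=frame_interval_s,
        n_frames=n_frames,
        trna_conc_nM=condition.conc_nM,
        kon_per_M_s=condition.kon_per_M_s,
        molecule_classes=condition.classes,
        inactive_fraction=inactive_fraction,
        fret_states=condition.fret_states,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
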