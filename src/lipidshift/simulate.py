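"""Synthetic MeasurementSet generator with the study's measurement structure.

The generator emulates a two-group (control vs treated) targeted shotgun-MS
experiment: per-class deuterated standards spiked before extraction, ~80.7%
extraction recovery, per-injection technical scatter (~6.5% CV), day-to-day
drift, and small matrix-effect perturbations of the standard signals.  All
noise is multiplicative log-normal (MS signal noise is non-negative and
roughly scale-proportional, and variability is quoted as CV); the underlying
normal sigma is sqrt(ln(1+CV^2)) with mean -sigma^2/2 so every factor has
expectation 1.

Generating model for a measured species ``s`` in injection ``j`` of mouse
``m`` (group ``g``, tissue ``t``, day ``d``)::

    counts(s, j) = baseline_s * effect(t, s, g) * bio(m, s) * day(d)
                   * tech(j) * recovery

Standards share the injection's recovery, day and technical factors and get
an additional matrix-effect factor per (injection x class).  Because the
technical/day/recovery factors are common to an injection, they cancel in
every lipid/standard ratio: after normalization, the only stochastic
component of a per-mouse value is the biological factor ``bio(m, s)``, drawn
independently per (mouse x species).  The exact generating ratio of every
species is returned alongside the data as ground truth.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .nomenclature import LipidClass
from .panel import MeasurementSet, PanelDefinition, SampleMeta, default_panel

__all__ = [
    "EffectSpec",
    "NoiseSpec",
    "GeneratorConfig",
    "GeneratorConfigError",
    "generate",
    "study_presets",
    "simulate_matrix_experiment",
    "simulate_recovery_experiment",
    "default_baselines",
    "BRAIN_CLASS_EFFECTS",
    "LIVER_CLASS_EFFECTS",
]


class GeneratorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EffectSpec:
    """Treated/control multipliers for one (tissue, class).

    ``class_effect`` multiplies every species of the class in the treated
    group; ``species_effects`` are extra per-species multipliers on top.
    """

    class_effect: float = 1.0
    species_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.class_effect <= 0:
            raise GeneratorConfigError("class_effect must be > 0")
        for lab, mult in self.species_effects.items():
            if mult <= 0:
                raise GeneratorConfigError(f"species effect for {lab!r} must be > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Coefficients of variation of the multiplicative noise sources.

    Defaults reproduce the study's QC figures: technical CV 6.5%
    (intra/inter-day), extraction recovery 80.7%, matrix-effect perturbations
    giving a mean absolute standard-ratio change of ~1.4% (2*sigma*sqrt(2/pi)
    with sigma = 0.0088) and a maximum rarely above ~3.2%.  The biological CV
    (mouse-to-mouse, per species) is not reported in the study; 0.15 is a
    calibration choice under which, at n = 5 per group, most species-level
    t-tests are non-significant while class means are.
    """

    biological_cv: float = 0.15
    technical_cv: float = 0.065
    day_cv: float = 0.02
    matrix_effect_cv: float = 0.0088
    recovery: float = 0.807

    def __post_init__(self) -> None:
        for name in ("biological_cv", "technical_cv", "day_cv", "matrix_effect_cv"):
            if getattr(self, name) < 0:
                raise GeneratorConfigError(f"{name} must be >= 0")
        if not 0 < self.recovery <= 1:
            raise GeneratorConfigError("recovery must be in (0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    panel: PanelDefinition
    n_per_group: int = 5
    n_replicates: int = 3
    n_days: int = 2
    # "per_mouse": a mouse's whole triplicate is acquired on one day (mice
    # alternate days); "split": replicates of one mouse span the days.
    day_layout: str = "per_mouse"
    baselines: dict[str, float] | None = None
    effects: dict[tuple[str, LipidClass], EffectSpec] = field(default_factory=dict)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise GeneratorConfigError("n_per_group must be >= 2 (t-tests need df >= 1)")
        if self.n_replicates < 1:
            raise GeneratorConfigError("n_replicates must be >= 1")
        if self.day_layout not in ("per_mouse", "split"):
            raise GeneratorConfigError(
                f"day_layout must be 'per_mouse' or 'split', got {self.day_layout!r}"
            )
        panel_labels = {s.label for s in self.panel.measured_species}
        for (tissue, cls), eff in self.effects.items():
            if tissue not in self.panel.tissue_list:
                raise GeneratorConfigError(
                    f"effects refer to tissue {tissue!r} not in panel tissues "
                    f"{self.panel.tissue_list}"
                )
            for lab in eff.species_effects:
                if lab not in panel_labels:
                    raise GeneratorConfigError(
                        f"species effect for {lab!r} but species not in panel"
                    )


def _sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one log-normal factors with the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    s = _sigma(cv)
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def default_baselines(labels: list[str]) -> dict[str, float]:
    """Log-uniform baselines over [1e3, 1e6] cps, stable per label.

    Each species' baseline is derived from a CRC32 of its label so the same
    species always gets the same intensity regardless of panel composition.
    """
    out = {}
    for lab in labels:
        u = np.random.default_rng(zlib.crc32(lab.encode("utf-8"))).random()
        out[lab] = 10.0 ** (3.0 + 3.0 * u)
    return out


def generate(
    config: GeneratorConfig,
) -> tuple[MeasurementSet, dict[tuple[str, str], float]]:
    """Simulate a MeasurementSet; returns (data, ground-truth ratios).

    Ground truth maps (tissue, species label) to the exact generating
    treated/control ratio.  Identical seeds give bit-identical output.
    """
    panel = config.panel
    noise = config.noise
    rng = np.random.default_rng(config.seed)

    species = panel.measured_species
    standards = panel.standards
    sp_labels = [s.label for s in species]
    std_labels = [s.label for s in standards]
    baselines = config.baselines or default_baselines(sp_labels + std_labels)
    base_sp = np.array([baselines[lab] for lab in sp_labels])
    base_std = np.array([baselines[lab] for lab in std_labels])
    classes = list(panel.class_standard_map)
    std_class_idx = np.array([classes.index(s.lipid_class) for s in standards])

    day_factors = _lognormal(rng, noise.day_cv, config.n_days)

    samples: list[SampleMeta] = []
    columns: dict[str, np.ndarray] = {}
    ground_truth: dict[tuple[str, str], float] = {}

    for tissue in panel.tissue_list:
        treated_mult = np.ones(len(species))
        for i, s in enumerate(species):
            eff = config.effects.get((tissue, s.lipid_class))
            if eff is not None:
                treated_mult[i] = eff.class_effect * eff.species_effects.get(
                    s.label, 1.0
                )
            ground_truth[(tissue, s.label)] = float(treated_mult[i])

        for group in ("control", "treated"):
            mult = treated_mult if group == "treated" else np.ones(len(species))
            for i in range(1, config.n_per_group + 1):
                mouse_id = f"{tissue}_{group}_{i:02d}"
                bio = _lognormal(rng, noise.biological_cv, len(species))
                for rep in range(1, config.n_replicates + 1):
                    inj = f"{tissue}_{group}{i:02d}_r{rep}"
                    if config.day_layout == "per_mouse":
                        day = 1 + (i - 1) % config.n_days
                    else:
                        day = 1 + (rep - 1) * config.n_days // config.n_replicates
                    tech = float(_lognormal(rng, noise.technical_cv, 1)[0])
                    matrix = _lognormal(rng, noise.matrix_effect_cv, len(classes))
                    shared = day_factors[day - 1] * tech * noise.recovery
                    col_sp = base_sp * mult * bio * shared
                    col_std = base_std * shared * matrix[std_class_idx]
                    columns[inj] = np.concatenate([col_sp, col_std])
                    samples.append(
                        SampleMeta(inj, mouse_id, tissue, group, rep, day)
                    )

    counts = pd.DataFrame(columns, index=sp_labels + std_labels)
    data = MeasurementSet(panel, samples, counts)
    return data, ground_truth


# --- study presets ---------------------------------------------------------

# Class-level effect directions follow the study's summary (brain: TAG, PCaa,
# SM and carnitines down, plasmalogens up, lyso-PC unchanged; liver: TAG,
# PCaa, plasmalogens and carnitines up, SM down, lyso-PC unchanged).  The
# plasmalogen magnitudes are the study's printed class means (110.86% brain,
# 105.01% liver); the remaining magnitudes are not printed and are fixed
# calibration choices.
BRAIN_CLASS_EFFECTS: dict[LipidClass, float] = {
    LipidClass.TAG: 0.85,
    LipidClass.PCAA: 0.88,
    LipidClass.PCAE: 1.1086,
    LipidClass.LYSO_PC: 1.0,
    LipidClass.SM: 0.90,
    LipidClass.CAR: 0.85,
}
LIVER_CLASS_EFFECTS: dict[LipidClass, float] = {
    LipidClass.TAG: 1.25,
    LipidClass.PCAA: 1.15,
    LipidClass.PCAE: 1.0501,
    LipidClass.LYSO_PC: 1.0,
    LipidClass.SM: 0.92,
    LipidClass.CAR: 1.15,
}


def _effects_for(tissue: str, table: dict[LipidClass, float]):
    return {
        (tissue, cls): EffectSpec(class_effect=mult)
        for cls, mult in table.items()
        if mult != 1.0
    }


def study_presets(seed: int = 0) -> dict[str, GeneratorConfig]:
    """Named generator configurations matching the study conditions.

    All presets use 5 mice per group and technical triplicates.  Single-tissue
    presets: ``brain_pcae`` / ``liver_pcae`` (plasmalogen class effect only,
    at the study's printed class means), ``brain_all`` / ``liver_all`` (all
    six class effects), ``null_brain`` (no effects).  ``two_tissue_all``
    combines brain_all and liver_all in one dataset for cross-tissue
    comparisons.
    """
    presets = {
        "brain_pcae": GeneratorConfig(
            panel=default_panel(("brain",)),
            effects={("brain", LipidClass.PCAE): EffectSpec(class_effect=1.1086)},
            seed=seed,
        ),
        "liver_pcae": GeneratorConfig(
            panel=default_panel(("liver",)),
            effects={("liver", LipidClass.PCAE): EffectSpec(class_effect=1.0501)},
            seed=seed,
        ),
        "brain_all": GeneratorConfig(
            panel=default_panel(("brain",)),
            effects=_effects_for("brain", BRAIN_CLASS_EFFECTS),
            seed=seed,
        ),
        "liver_all": GeneratorConfig(
            panel=default_panel(("liver",)),
            effects=_effects_for("liver", LIVER_CLASS_EFFECTS),
            seed=seed,
        ),
        "null_brain": GeneratorConfig(
            panel=default_panel(("brain",)), effects={}, seed=seed
        ),
        "two_tissue_all": GeneratorConfig(
            panel=default_panel(("brain", "liver")),
            effects={
                **_effects_for("brain", BRAIN_CLASS_EFFECTS),
                **_effects_for("liver", LIVER_CLASS_EFFECTS),
            },
            seed=seed,
        ),
    }
    return presets


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    return replace(config, seed=seed)


# --- dedicated QC experiments ----------------------------------------------


def simulate_matrix_experiment(
    panel: PanelDefinition | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Simulate the standard-ratio matrix-effect experiment.

    Mirrors the study's design: the deuterated standard mix is measured in
    the presence of lipid extract from each group (two matrices A/B); each
    standard's signal is perturbed by a per-matrix log-normal factor with CV
    ``matrix_effect_cv``.  Returns the ordered-pair standard ratios per
    matrix, ready for :func:`lipidshift.qc.matrix_effect`.
    """
    panel = panel or default_panel(("brain",))
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    std_labels = [s.label for s in panel.standards]
    base = np.array([default_baselines(std_labels)[lab] for lab in std_labels])
    out: list[dict[str, float]] = []
    for _ in range(2):
        m = _lognormal(rng, noise.matrix_effect_cv, len(std_labels))
        signal = base * m
        ratios = {
            f"{a}/{b}": float(signal[i] / signal[j])
            for i, a in enumerate(std_labels)
            for j, b in enumerate(std_labels)
            if i != j
        }
        out.append(ratios)
    return out[0], out[1]


def simulate_recovery_experiment(
    panel: PanelDefinition | None = None,
    recovery: float = 0.807,
    intra_day_cv: float = 0.039,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Simulate a spike-recovery experiment (measured vs expected signals).

    Standards are spiked at known amounts; the measured signal is
    expected * recovery * log-normal(intra-day CV).  Defaults reproduce the
    study's extraction QC (80.7% mean recovery, 3.9% intra-day variance).
    """
    panel = panel or default_panel(("brain",))
    rng = np.random.default_rng(seed)
    std_labels = [s.label for s in panel.standards]
    expected = default_baselines(std_labels)
    factors = _lognormal(rng, intra_day_cv, len(std_labels))
    measured = {
        lab: expected[lab] * recovery * float(f)
        for lab, f in zip(std_labels, factors)
    }
    return measured, {lab: float(v) for lab, v in expected.items()}
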