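"""Standard normalization, class-relative renormalization and fold changes."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from lipidshift import (
    LipidClass,
    LipidSpecies,
    MeasurementSet,
    NormalizationError,
    PanelDefinition,
    SampleMeta,
    class_relative,
    fold_changes,
    normalize_to_standards,
)
from conftest import make_sample


def tiny_measurement_set(counts_by_injection):
    """Two PCaa species + one standard; injections given as {inj: [a, b, std]}."""
    sp_a = LipidSpecies(LipidClass.PCAA, 36, 4)
    sp_b = LipidSpecies(LipidClass.PCAA, 38, 6)
    std = LipidSpecies(LipidClass.PCAA, 12, 0, is_standard=True)
    panel = PanelDefinition(
        [sp_a, sp_b, std], {LipidClass.PCAA: [std.label]}, ["brain"]
    )
    samples = [
        SampleMeta(inj, "m1", "brain", "control", i + 1, 1)
        for i, inj in enumerate(counts_by_injection)
    ]
    counts = pd.DataFrame(
        counts_by_injection, index=[sp_a.label, sp_b.label, std.label]
    )
    return MeasurementSet(panel, samples, counts)


def test_ratio_to_class_standard():
    ms = tiny_measurement_set({"i1": [2000.0, 1000.0, 500.0]})
    (sample,) = normalize_to_standards(ms)
    assert sample.values["PCaa C36:4"] == pytest.approx(4.0)
    assert sample.values["PCaa C38:6"] == pytest.approx(2.0)


def test_triplicate_mean_per_mouse():
    ms = tiny_measurement_set(
        {
            "i1": [2000.0, 500.0, 500.0],
            "i2": [2200.0, 500.0, 500.0],
            "i3": [1800.0, 500.0, 500.0],
        }
    )
    (sample,) = normalize_to_standards(ms)
    # ratios 4.0, 4.4, 3.6 average to 4.0
    assert sample.values["PCaa C36:4"] == pytest.approx(4.0)


def test_per_injection_scale_invariance():
    ms1 = tiny_measurement_set({"i1": [2000.0, 1000.0, 500.0]})
    ms2 = tiny_measurement_set({"i1": [4000.0, 2000.0, 1000.0]})
    v1 = normalize_to_standards(ms1)[0].values
    v2 = normalize_to_standards(ms2)[0].values
    pd.testing.assert_series_equal(v1, v2)


def test_zero_standard_count_names_injection_and_class():
    ms = tiny_measurement_set({"i1": [2000.0, 1000.0, 0.0]})
    with pytest.raises(NormalizationError, match=r"PCaa.*'i1'"):
        normalize_to_standards(ms)


def test_class_relative_fractions_and_sum():
    s = make_sample("m1", "control", {"SM C24:1": 3.0, "SM C22:3": 1.0})
    (rel,) = class_relative([s])
    assert rel.values["SM C24:1"] == pytest.approx(0.75)
    assert rel.values["SM C22:3"] == pytest.approx(0.25)
    assert rel.values.sum() == pytest.approx(1.0)


def test_class_relative_sums_to_one_per_class(presets):
    from lipidshift import generate, with_seed

    data, _ = generate(with_seed(presets["brain_all"], 5))
    rel = class_relative(normalize_to_standards(data))
    for sample in rel:
        for cls in LipidClass:
            labels = [
                s.label for s in data.panel.species_of_class(cls)
            ]
            assert sample.values[labels].sum() == pytest.approx(1.0)


def test_class_relative_scale_invariance():
    s1 = make_sample("m1", "control", {"SM C24:1": 3.0, "SM C22:3": 1.0})
    s2 = make_sample("m1", "control", {"SM C24:1": 30.0, "SM C22:3": 10.0})
    (r1,), (r2,) = class_relative([s1]), class_relative([s2])
    pd.testing.assert_series_equal(r1.values, r2.values)


def test_class_relative_zero_total_rejected():
    s = make_sample("m1", "control", {"SM C24:1": 0.0, "SM C22:3": 0.0})
    with pytest.raises(NormalizationError, match="SM"):
        class_relative([s])


def _samples_from_values(control, treated, label="SM C24:1"):
    out = []
    for i, v in enumerate(control):
        out.append(make_sample(f"c{i}", "control", {label: v}))
    for i, v in enumerate(treated):
        out.append(make_sample(f"t{i}", "treated", {label: v}))
    return out


def test_fold_change_constant_groups():
    samples = _samples_from_values([1.0] * 5, [1.2] * 5)
    (rec,) = fold_changes(samples, "brain")
    assert rec.fold_change == pytest.approx(1.2)
    assert rec.sem == pytest.approx(0.0)


def test_identical_groups_give_unit_fold_change_and_p_one():
    samples = _samples_from_values([1.0, 1.1, 0.9, 1.05, 0.95],
                                   [1.0, 1.1, 0.9, 1.05, 0.95])
    (rec,) = fold_changes(samples, "brain")
    assert rec.fold_change == pytest.approx(1.0)
    assert rec.p_value == pytest.approx(1.0)


def test_fold_change_against_pooled_t_oracle():
    """Hand-computed pooled-variance two-sample t (df = 8) as oracle."""
    control = [0.9, 1.0, 1.1, 1.0, 1.0]
    treated = [1.1, 1.2, 1.3, 1.2, 1.2]
    samples = _samples_from_values(control, treated)
    (rec,) = fold_changes(samples, "brain")
    assert rec.fold_change == pytest.approx(1.2)
    # pooled variance: s2 = 0.005 in both groups, se = sqrt(0.005 * 2/5)
    se = math.sqrt(0.005 * (1 / 5 + 1 / 5))
    t = (np.mean(treated) - np.mean(control)) / se
    assert t == pytest.approx(4.47213595, rel=1e-8)
    from scipy.stats import t as t_dist

    p_oracle = 2 * t_dist.sf(abs(t), df=8)
    assert rec.p_value == pytest.approx(p_oracle, rel=1e-9)
    # SEM of the fold change: treated-group SEM / control mean
    sem_oracle = np.std(treated, ddof=1) / math.sqrt(5) / np.mean(control)
    assert rec.sem == pytest.approx(sem_oracle, rel=1e-12)


def test_welch_and_log_transform_variants():
    control = [0.9, 1.0, 1.1, 1.0, 1.0]
    treated = [1.3, 1.6, 1.2, 1.5, 1.4]
    samples = _samples_from_values(control, treated)
    (student,) = fold_changes(samples, "brain", test="student")
    (welch,) = fold_changes(samples, "brain", test="welch")
    (logged,) = fold_changes(samples, "brain", log_transform=True)
    assert welch.fold_change == student.fold_change
    assert welch.p_value != student.p_value
    assert 0.0 <= logged.p_value <= 1.0


def test_delta_method_sem_exceeds_treated_only_sem():
    control = [0.9, 1.0, 1.1, 1.0, 1.0]
    treated = [1.1, 1.2, 1.3, 1.2, 1.2]
    samples = _samples_from_values(control, treated)
    (plain,) = fold_changes(samples, "brain", sem_basis="treated")
    (delta,) = fold_changes(samples, "brain", sem_basis="delta")
    assert delta.sem > plain.sem


def test_bh_correction_never_decreases_p():
    rng = np.random.default_rng(0)
    labels = [f"SM C{c}:0" for c in (14, 16, 18, 20, 22)]
    samples = []
    for i in range(5):
        samples.append(
            make_sample(f"c{i}", "control",
                        dict(zip(labels, rng.lognormal(0, 0.2, 5))))
        )
        samples.append(
            make_sample(f"t{i}", "treated",
                        dict(zip(labels, rng.lognormal(0.2, 0.2, 5))))
        )
    raw = fold_changes(samples, "brain")
    adj = fold_changes(samples, "brain", multiple_testing="bh")
    for r, a in zip(raw, adj):
        assert a.p_value >= r.p_value - 1e-12


def test_too_few_mice_rejected():
    samples = _samples_from_values([1.0], [1.2, 1.3])
    with pytest.raises(NormalizationError, match="2 mice"):
        fold_changes(samples, "brain")


def test_zero_control_mean_rejected():
    samples = _samples_from_values([0.0] * 5, [1.2] * 5)
    with pytest.raises(NormalizationError, match="control mean"):
        fold_changes(samples, "brain")
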