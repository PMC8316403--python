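"""Eight-square classification, exact shift tests and cross-tissue comparisons."""

from __future__ import annotations

import itertools
import math
import random

import numpy as np
import pytest

from lipidshift import (
    FoldChangeRecord,
    LipidClass,
    binomial_shift,
    class_mean_effect,
    classify,
    compare_class_between_tissues,
    fisher_tissue,
    generate,
    fold_changes,
    normalize_to_standards,
    parse_species,
    summarize_class,
    with_seed,
)

# ---------------------------------------------------------------------------
# helpers / independent oracles
# ---------------------------------------------------------------------------


def rec(label, fc, p, sem=0.05, tissue="brain", mode="absolute"):
    return FoldChangeRecord(
        species=parse_species(label),
        tissue=tissue,
        mode=mode,
        fold_change=fc,
        sem=sem,
        p_value=p,
    )


def binomial_oracle(k: int, n: int) -> float:
    """Exact two-sided (minimum-likelihood) binomial p at p0 = 1/2 by enumeration."""
    probs = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
    p_obs = probs[k]
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-12)))


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x: int) -> float:
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return min(
        1.0,
        sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12)),
    )


# ---------------------------------------------------------------------------
# eight-square classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "fc, p, direction, color",
    [
        (1.20, 0.01, "up", "red"),
        (0.98, 0.60, "down", "grey"),
        (0.90, 0.03, "down", "red"),
        (1.20, 0.60, "up", "green"),
        (1.02, 0.01, "up", "blue"),
    ],
)
def test_classification_rule(fc, p, direction, color):
    # all records share sem 0.05 so the reference (average) SEM is 0.05
    records = [rec("SM C24:1", fc, p), rec("SM C22:3", 1.0, 0.9)]
    out = classify(records, sem_scope="global")
    assert out[0].category.direction == direction
    assert out[0].category.color == color


def test_classification_boundaries_are_strict():
    # binary-exact values: |fc - 1| == reference SEM and p == alpha must
    # NOT qualify (strict inequalities on both axes)
    records = [
        rec("SM C24:1", 1.0625, 0.05, sem=0.0625),
        rec("SM C22:3", 1.0, 0.9, sem=0.0625),
    ]
    out = classify(records, sem_scope="global")
    assert out[0].category.direction == "up"
    assert out[0].category.color == "grey"


def test_classification_partitions_records():
    rng = random.Random(42)
    records = [
        rec(f"C{c}", rng.uniform(0.5, 1.5), rng.random(), sem=rng.uniform(0, 0.2))
        for c in range(2, 60)
    ]
    out = classify(records, sem_scope="global")
    cells = {}
    for r in out:
        key = (r.category.direction, r.category.significant, r.category.beyond_sem)
        cells[key] = cells.get(key, 0) + 1
    assert sum(cells.values()) == len(records)
    assert len(cells) <= 8


def test_classification_order_invariant():
    rng = random.Random(7)
    records = [
        rec(f"C{c}", rng.uniform(0.5, 1.5), rng.random(), sem=rng.uniform(0, 0.2))
        for c in range(2, 30)
    ]
    shuffled = records[:]
    rng.shuffle(shuffled)
    by_label = {
        r.species.label: r.category for r in classify(records, sem_scope="global")
    }
    for r in classify(shuffled, sem_scope="global"):
        assert r.category == by_label[r.species.label]


def test_per_class_reference_sem_is_class_local():
    # SM records have large SEMs, TAG records small ones
    records = [
        rec("SM C24:1", 1.10, 0.5, sem=0.30),
        rec("SM C22:3", 1.0, 0.5, sem=0.30),
        rec("TAG C54:9", 1.10, 0.5, sem=0.02),
        rec("TAG C58:5", 1.0, 0.5, sem=0.02),
    ]
    per_class = classify(records, sem_scope="per_class")
    # |1.10 - 1| = 0.10 < 0.30 (SM reference) but > 0.02 (TAG reference)
    assert not per_class[0].category.beyond_sem
    assert per_class[2].category.beyond_sem


def test_classify_rejects_empty_and_mixed_inputs():
    with pytest.raises(ValueError):
        classify([])
    mixed = [rec("C2", 1.0, 0.5, tissue="brain"), rec("C3", 1.0, 0.5, tissue="liver")]
    with pytest.raises(ValueError, match="tissue"):
        classify(mixed)


# ---------------------------------------------------------------------------
# exact tests vs enumeration oracles
# ---------------------------------------------------------------------------


def test_binomial_study_counts_highly_significant():
    assert binomial_shift(114, 176) < 0.001
    assert binomial_shift(178, 93) < 0.001


def test_binomial_symmetric_and_trivial_cases():
    assert binomial_shift(10, 10) == pytest.approx(1.0)
    assert binomial_shift(0, 5) == pytest.approx(0.0625)  # 2 * 0.5**5
    for a, b in [(3, 9), (0, 7), (5, 5), (2, 18)]:
        assert binomial_shift(a, b) == pytest.approx(binomial_shift(b, a))


def test_binomial_matches_enumeration_oracle_exhaustively():
    for n in range(1, 21):
        for k in range(n + 1):
            assert binomial_shift(k, n - k) == pytest.approx(
                binomial_oracle(k, n), rel=1e-10
            ), (k, n)


def test_fisher_identical_proportions():
    assert fisher_tissue([[5, 5], [5, 5]]) == pytest.approx(1.0)


def test_fisher_study_counts_significant_and_match_oracle():
    p = fisher_tissue([[114, 176], [178, 93]])
    assert p < 1e-6
    assert p == pytest.approx(fisher_oracle(114, 176, 178, 93), rel=1e-6)


def test_fisher_matches_enumeration_oracle_exhaustively():
    """All 2x2 tables with grand total <= 20 and no zero margin."""
    for n in range(2, 21):
        for a, b, c in itertools.product(range(n + 1), repeat=3):
            d = n - a - b - c
            if d < 0:
                continue
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            assert fisher_tissue([[a, b], [c, d]]) == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-8, abs=1e-12
            ), (a, b, c, d)


def test_fisher_zero_margin_convention():
    assert fisher_tissue([[0, 0], [3, 4]]) == 1.0
    assert fisher_tissue([[0, 3], [0, 4]]) == 1.0


def test_fisher_invariant_to_simultaneous_row_column_swap():
    for a, b, c, d in [(2, 7, 5, 3), (1, 9, 9, 1), (4, 4, 6, 2)]:
        assert fisher_tissue([[a, b], [c, d]]) == pytest.approx(
            fisher_tissue([[d, c], [b, a]])
        )


def test_binomial_rejects_invalid_counts():
    with pytest.raises(ValueError):
        binomial_shift(-1, 5)
    with pytest.raises(ValueError):
        binomial_shift(0, 0)


# ---------------------------------------------------------------------------
# class-level statistics
# ---------------------------------------------------------------------------


def test_class_mean_effect_no_change():
    records = [rec(f"SM C{c}:0", 1.0, 0.5) for c in (14, 16, 18)]
    mean_pct, sem_pct, p = class_mean_effect(records, LipidClass.SM)
    assert (mean_pct, sem_pct, p) == (pytest.approx(100.0), pytest.approx(0.0), 1.0)


def test_class_mean_effect_closed_form_t():
    """fcs {1.1, 1.2, 1.3}: t = 3.4641, df 2; p from the df=2 closed form."""
    records = [
        rec("SM C14:0", 1.1, 0.5),
        rec("SM C16:0", 1.2, 0.5),
        rec("SM C18:0", 1.3, 0.5),
    ]
    mean_pct, sem_pct, p = class_mean_effect(records, LipidClass.SM)
    assert mean_pct == pytest.approx(120.0)
    assert sem_pct == pytest.approx(100 * 0.1 / math.sqrt(3), rel=1e-9)
    t = 0.2 / (0.1 / math.sqrt(3))
    # survival function of Student's t with df=2: 0.5 * (1 - t/sqrt(t^2+2))
    p_oracle = 2 * 0.5 * (1 - t / math.sqrt(t * t + 2))
    assert p == pytest.approx(p_oracle, rel=1e-9)
    assert p == pytest.approx(0.0742, abs=2e-4)


def test_carnitine_aggregate_excludes_free_and_acetyl_carnitine():
    acyl = [rec(f"C{c}", 1.2, 0.5) for c in (4, 6, 8, 10)]
    short = [rec("C0", 5.0, 0.5), rec("C2", 5.0, 0.5), rec("C3", 5.0, 0.5)]
    with pytest.warns(UserWarning, match="zero variance"):
        mean_pct, _, p = class_mean_effect(acyl + short, LipidClass.CAR)
    assert mean_pct == pytest.approx(120.0)
    assert p == 0.0
    mean_all, _, _ = class_mean_effect(
        acyl + short, LipidClass.CAR, acyl_carnitines_only=False
    )
    assert mean_all > 120.0


def test_summarize_class_counts_and_binomial():
    records = classify(
        [
            rec("SM C24:1", 1.30, 0.01, sem=0.05),
            rec("SM C22:3", 1.20, 0.20, sem=0.05),
            rec("SM C14:0", 1.02, 0.50, sem=0.05),
            rec("SM C16:0", 0.80, 0.50, sem=0.05),
        ],
        sem_scope="per_class",
    )
    s = summarize_class(records, LipidClass.SM)
    assert (s.n_up_total, s.n_down_total) == (3, 1)
    assert (s.n_up_beyond, s.n_down_beyond) == (2, 1)
    assert s.binomial_p == pytest.approx(binomial_oracle(2, 3))


# ---------------------------------------------------------------------------
# cross-tissue comparison
# ---------------------------------------------------------------------------


def _classified(pairs, tissue):
    return classify(
        [rec(lab, fc, p, sem=0.05, tissue=tissue) for lab, fc, p in pairs],
        sem_scope="per_class",
    )


def test_venn_partition_set_algebra():
    brain = _classified(
        [("SM C14:0", 0.8, 0.5), ("SM C16:0", 0.8, 0.5), ("SM C18:0", 1.01, 0.5)],
        "brain",
    )
    liver = _classified(
        [("SM C14:0", 1.01, 0.5), ("SM C16:0", 1.3, 0.5), ("SM C18:0", 1.3, 0.5)],
        "liver",
    )
    comp = compare_class_between_tissues(brain, liver, LipidClass.SM)
    assert comp.venn.brain_only == {"SM C14:0": "down"}
    assert comp.venn.both == {"SM C16:0": {"brain": "down", "liver": "up"}}
    assert comp.venn.liver_only == {"SM C18:0": "up"}
    union = set(comp.venn.brain_only) | set(comp.venn.both) | set(comp.venn.liver_only)
    assert union == {"SM C14:0", "SM C16:0", "SM C18:0"}


def test_identical_tissues_give_p_one():
    pairs = [("SM C14:0", 0.8, 0.5), ("SM C16:0", 1.3, 0.5), ("SM C18:0", 1.01, 0.5)]
    comp = compare_class_between_tissues(
        _classified(pairs, "brain"), _classified(pairs, "liver")
    )
    assert comp.fisher_p == pytest.approx(1.0)
    assert comp.two_sample_p == pytest.approx(1.0)


def test_species_set_mismatch_rejected():
    brain = _classified([("SM C14:0", 0.8, 0.5), ("SM C16:0", 0.9, 0.5)], "brain")
    liver = _classified([("SM C14:0", 0.8, 0.5), ("SM C18:0", 0.9, 0.5)], "liver")
    with pytest.raises(ValueError, match="SM C18:0"):
        compare_class_between_tissues(brain, liver)


def test_opposite_tag_shifts_detected_by_fisher(presets):
    """Simulated brain/liver datasets with opposite TAG class effects:
    the cross-tissue Fisher test flags the TAG distribution difference in
    at least 95 of 100 seeded runs."""
    hits = 0
    for seed in range(100):
        brain_data, _ = generate(with_seed(presets["brain_all"], 3000 + seed))
        liver_data, _ = generate(with_seed(presets["liver_all"], 60000 + seed))
        brain = classify(
            fold_changes(normalize_to_standards(brain_data), "brain"),
            sem_scope="per_class",
        )
        liver = classify(
            fold_changes(normalize_to_standards(liver_data), "liver"),
            sem_scope="per_class",
        )
        comp = compare_class_between_tissues(brain, liver, LipidClass.TAG)
        if comp.fisher_p < 0.05:
            hits += 1
    assert hits >= 95
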