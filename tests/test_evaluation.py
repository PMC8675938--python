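"""Metrics, fusion, DeLong machinery and LOSO hygiene."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from cardiomech import (
    RunConfig,
    SubjectRisk,
    SynthSpec,
    aggregate_subject,
    compare_models,
    compute_metrics,
    delong_auc_ci,
    delong_paired_test,
    fuse,
    generate_cohort,
    generate_subject,
    loso_run,
)
from cardiomech.errors import (
    AggregationError,
    FusionError,
    LeakageError,
    MetricsError,
    TrainingError,
    ValidationError,
)


def _risk(sid, label, p):
    return SubjectRisk(
        subject_id=sid, label=label,
        channel_risks={c: p for c in
                       ("scg_x", "scg_y", "scg_z", "gcg_x", "gcg_y", "gcg_z")},
    )


def _toy_risks(cad=(0.9, 0.8), non=(0.1, 0.2)):
    risks = [_risk(f"c{i}", "CAD", p) for i, p in enumerate(cad)]
    risks += [_risk(f"n{i}", "nonCAD", p) for i, p in enumerate(non)]
    return risks


def test_aggregate_subject_is_the_mean():
    assert aggregate_subject([0.2, 0.4, 0.9]) == pytest.approx(0.5)
    assert aggregate_subject([0.7] * 13) == pytest.approx(0.7)
    assert aggregate_subject([0.9, 0.2, 0.4]) == pytest.approx(0.5)
    with pytest.raises(AggregationError):
        aggregate_subject([])


def test_fuse_arithmetic_and_idempotence():
    fused = fuse({"scg_x": 0.9, "scg_y": 0.9, "scg_z": 0.9,
                  "gcg_x": 0.3, "gcg_y": 0.3, "gcg_z": 0.3})
    assert fused == {"all_axes": pytest.approx(0.6),
                     "scg_axes": pytest.approx(0.9),
                     "gcg_axes": pytest.approx(0.3)}
    same = fuse({c: 0.42 for c in
                 ("scg_x", "scg_y", "scg_z", "gcg_x", "gcg_y", "gcg_z")})
    assert all(v == pytest.approx(0.42) for v in same.values())
    with pytest.raises(FusionError):
        fuse({"scg_x": 0.5})


@given(st.lists(st.floats(0.0, 1.0), min_size=6, max_size=6))
def test_fused_values_equal_brute_force_means(ps):
    names = ("scg_x", "scg_y", "scg_z", "gcg_x", "gcg_y", "gcg_z")
    fused = fuse(dict(zip(names, ps)))
    assert fused["all_axes"] == pytest.approx(np.mean(ps), abs=1e-12)
    assert fused["scg_axes"] == pytest.approx(np.mean(ps[:3]), abs=1e-12)
    assert fused["gcg_axes"] == pytest.approx(np.mean(ps[3:]), abs=1e-12)


def test_perfectly_separated_toy_risks():
    report = compute_metrics(_toy_risks())
    m = report.models["all_axes"]
    assert m.auc == pytest.approx(1.0)
    assert m.sensitivity == pytest.approx(1.0)
    assert m.specificity == pytest.approx(1.0)
    assert m.f1 == pytest.approx(1.0)
    assert m.discrimination_slope == pytest.approx(0.70)


def test_tied_risks_are_chance_level():
    report = compute_metrics(_toy_risks(cad=(0.5, 0.5), non=(0.5, 0.5)))
    m = report.models["scg_axes"]
    assert m.auc == pytest.approx(0.5)
    assert m.discrimination_slope == pytest.approx(0.0)


def test_single_class_rejected():
    with pytest.raises(MetricsError):
        compute_metrics([_risk("a", "CAD", 0.9), _risk("b", "CAD", 0.8)])


def test_auc_matches_sklearn_and_is_monotone_invariant():
    rng = np.random.default_rng(0)
    scores = rng.random(60)
    labels = rng.integers(0, 2, 60)
    auc, (lo, hi) = delong_auc_ci(scores, labels)
    assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
    assert lo <= auc <= hi
    warped, _ = delong_auc_ci(np.exp(3 * scores), labels)
    assert warped == pytest.approx(auc, abs=1e-12)


def test_null_delong_ci_covers_half_in_at_least_90_percent_of_runs():
    rng = np.random.default_rng(123)
    covered = 0
    runs = 200
    for _ in range(runs):
        scores = rng.random(40)
        labels = rng.permutation(np.repeat([0, 1], 20))
        _, (lo, hi) = delong_auc_ci(scores, labels)
        covered += lo <= 0.5 <= hi
    assert covered / runs >= 0.90


def test_discrimination_slope_bounds_and_null_centre():
    rng = np.random.default_rng(5)
    slopes = []
    for _ in range(200):
        risks = [_risk(f"s{i}", lab, rng.random())
                 for i, lab in enumerate(["CAD"] * 10 + ["nonCAD"] * 10)]
        s = compute_metrics(risks).models["all_axes"].discrimination_slope
        assert -1.0 <= s <= 1.0
        slopes.append(s)
    assert abs(np.mean(slopes)) < 3 * np.std(slopes) / np.sqrt(len(slopes))


class TestCompareModels:
    def test_model_compared_with_itself_is_one(self):
        risks = _toy_risks(cad=(0.9, 0.7, 0.8), non=(0.2, 0.3, 0.1))
        assert compare_models(risks, "scg_axes", "scg_axes") == 1.0

    def test_perfect_vs_coin_flip_is_significant(self):
        rng = np.random.default_rng(8)
        risks = []
        for i in range(40):
            label = "CAD" if i < 20 else "nonCAD"
            perfect = 0.9 if label == "CAD" else 0.1
            noise = float(rng.random())
            channel_risks = {"scg_x": perfect, "scg_y": perfect, "scg_z": perfect,
                             "gcg_x": noise, "gcg_y": noise, "gcg_z": noise}
            risks.append(SubjectRisk(f"s{i}", label, channel_risks))
        assert compare_models(risks, "scg_axes", "gcg_axes") < 0.05

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(200):
            labels = np.repeat([0, 1], 15)
            a, b = rng.random(30), rng.random(30)
            pvals.append(delong_paired_test(a, b, labels))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestLosoGuards:
    def _cohort(self, n=2, seed=0):
        return generate_cohort(SynthSpec(n_per_class=n, duration_s=30.0, seed=seed))

    def test_duplicated_recording_is_detected_by_checksum(self):
        cohort = self._cohort()
        clone = generate_subject(
            SynthSpec(n_per_class=2, duration_s=30.0, seed=0),
            "CAD",
            int(np.random.SeedSequence(0).spawn(4)[0].generate_state(1)[0]),
            "impostor",
        )
        clone.label = "nonCAD"  # same samples, new identity
        with pytest.raises(LeakageError):
            loso_run(cohort + [clone], RunConfig(epochs=1))

    def test_unlabelled_subject_rejected(self):
        cohort = self._cohort()
        cohort[0].label = "unknown"
        with pytest.raises(TrainingError):
            loso_run(cohort, RunConfig(epochs=1))

    def test_short_recording_rejected(self):
        cohort = self._cohort()
        short = generate_subject(
            SynthSpec(duration_s=20.0, seed=1), "CAD", 5, "short"
        )
        with pytest.raises(ValidationError):
            loso_run(cohort + [short], RunConfig(epochs=1))

    def test_minimum_class_counts_enforced(self):
        cohort = self._cohort()
        with pytest.raises(ValidationError):
            loso_run(cohort[:3], RunConfig(epochs=1))


class TestLosoResults:
    def test_one_risk_per_subject_with_valid_fusion(self, separable_loso):
        risks = separable_loso["risks"]
        cohort = separable_loso["cohort"]
        assert len(risks) == len(cohort)
        assert {r.subject_id for r in risks} == {c.subject_id for c in cohort}
        for r in risks:
            assert set(r.channel_risks) == {
                "scg_x", "scg_y", "scg_z", "gcg_x", "gcg_y", "gcg_z"}
            expected = np.mean(list(r.channel_risks.values()))
            assert r.fused["all_axes"] == pytest.approx(expected, abs=1e-12)

    def test_strong_separation_ranks_every_cad_above_every_noncad(
        self, separable_loso
    ):
        risks = separable_loso["risks"]
        cad = [r.fused["all_axes"] for r in risks if r.label == "CAD"]
        non = [r.fused["all_axes"] for r in risks if r.label == "nonCAD"]
        assert min(cad) > max(non)
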