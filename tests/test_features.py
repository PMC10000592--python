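"""Signal operators: baseline, variability, event detectors, fuzzy
memberships, deceleration typing, sinusoidal pattern, assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctgkit.events import DECELERATION, Event, EventLog
from ctgkit.features import (
    baseline_series,
    build_feature_vector,
    classify_baseline,
    classify_deceleration,
    classify_variability,
    compute_variability,
    detect_accelerations,
    detect_contractions,
    detect_decelerations_fuzzy,
    detect_shr,
    estimate_baseline,
    extract_features,
    fuzzy_membership,
)
from ctgkit.synth import SynthConfig, generate_cohort, generate_record

FS = 4.0


def _flat(minutes=30, level=140.0):
    n = int(minutes * 60 * FS)
    return np.full(n, level), np.ones(n, bool)


def _bump(fhr, start_s, dur_s, depth):
    s, n = int(start_s * FS), int(dur_s * FS)
    x = np.arange(n)
    fhr[s : s + n] += depth * 0.5 * (1 - np.cos(2 * np.pi * (x + 0.5) / n))
    return fhr


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------


def test_constant_trace_fixed_point():
    fhr, mask = _flat()
    ests = estimate_baseline(fhr, mask, FS)
    assert all(e.identifiable for e in ests)
    assert all(e.value == pytest.approx(140.0) for e in ests)
    assert all(e.iterations_used <= 2 for e in ests)


def test_acceleration_excluded_from_baseline():
    fhr, mask = _flat()
    fhr = _bump(fhr, 200, 60, 20.0)
    ests = estimate_baseline(fhr, mask, FS)
    # oracle: median of the event-free samples
    assert ests[0].value == pytest.approx(140.0, abs=1.0)


def test_all_masked_window_unidentifiable():
    fhr, mask = _flat(minutes=10)
    mask[:] = False
    ests = estimate_baseline(fhr, mask, FS)
    assert len(ests) == 1 and not ests[0].identifiable


def test_short_record_rejected():
    fhr, mask = _flat(minutes=5)
    with pytest.raises(ValueError, match="10-min"):
        estimate_baseline(fhr, mask, FS)


def test_baseline_recovery_under_drift(cohort300):
    """Mean |estimate − truth| stays within 5 bpm across a cohort with
    drifting baselines (subset for speed; the full-cohort check lives
    in the acceptance suite)."""
    errs = []
    for rec, truth in cohort300[:60]:
        ests = estimate_baseline(rec.fhr, rec.mask, rec.sample_rate)
        for e in ests:
            if e.identifiable:
                errs.append(abs(e.value - truth.baseline_in_window(*e.window)))
    assert np.mean(errs) <= 5.0


def test_baseline_idempotent_after_event_excision():
    fhr, mask = _flat()
    fhr = _bump(fhr, 300, 60, 22.0)
    fhr = _bump(fhr, 800, 80, -30.0)
    ests1 = estimate_baseline(fhr, mask, FS)
    base = baseline_series(ests1, len(fhr))
    log = EventLog(
        [
            *detect_accelerations(fhr, mask, base, FS),
            *detect_decelerations_fuzzy(fhr, mask, base, FS),
        ]
    )
    mask2 = mask.copy()
    for e in log:
        mask2[e.start : e.end] = False
    ests2 = estimate_baseline(fhr, mask2, FS)
    for e1, e2 in zip(ests1, ests2):
        if e1.identifiable and e2.identifiable:
            assert abs(e1.value - e2.value) < 1.0


@pytest.mark.parametrize(
    "value,expected",
    [(140, "Normal"), (110, "Normal"), (160, "Normal"),
     (100, "Bradycardia"), (109.9, "Bradycardia"),
     (161, "Tachycardia"), (None, "Undetermined")],
)
def test_baseline_bands(value, expected):
    assert classify_baseline(value) == expected


# ---------------------------------------------------------------------------
# variability
# ---------------------------------------------------------------------------


def test_constant_trace_variability_undetermined():
    fhr, mask = _flat()
    base = np.full_like(fhr, 140.0)
    assert compute_variability(fhr, mask, base, FS) is None


def test_sinusoid_sd_closed_form():
    """A pure sinusoid of amplitude a oscillating about the baseline
    has per-segment SD a/sqrt(2)."""
    a = 8.0
    n = int(30 * 60 * FS)
    t = np.arange(n) / FS
    fhr = 140 + a * np.sin(2 * np.pi * t / 20)  # 3 cycles per minute
    base = np.full(n, 140.0)
    v = compute_variability(fhr, np.ones(n, bool), base, FS)
    assert v == pytest.approx(a / np.sqrt(2), rel=0.02)


def test_sum_mode_scales_with_qualifying_segments():
    a, n = 8.0, int(30 * 60 * FS)
    t = np.arange(n) / FS
    fhr = 140 + a * np.sin(2 * np.pi * t / 20)
    base = np.full(n, 140.0)
    mean_v = compute_variability(fhr, np.ones(n, bool), base, FS, slice_mode="mean")
    sum_v = compute_variability(fhr, np.ones(n, bool), base, FS, slice_mode="sum")
    assert sum_v == pytest.approx(10 * mean_v, rel=1e-6)  # 10 segments/slice


def test_variability_recovery_on_cohort(cohort300):
    errs = []
    for rec, truth in cohort300[:60]:
        fv, _ = extract_features(rec)
        if fv.variability is not None:
            errs.append(abs(fv.variability - truth.true_variability_bpm))
    assert np.mean(errs) <= 1.5


@pytest.mark.parametrize(
    "v,expected",
    [(0, "Absent"), (0.4, "Absent"), (3, "Minimal"), (5, "Minimal"),
     (10, "Moderate"), (25, "Moderate"), (26, "Marked"),
     (None, "Undetermined")],
)
def test_variability_bands(v, expected):
    assert classify_variability(v) == expected


def test_negative_variability_rejected():
    with pytest.raises(ValueError):
        classify_variability(-1.0)


# ---------------------------------------------------------------------------
# accelerations
# ---------------------------------------------------------------------------


def test_single_bump_detected():
    fhr, mask = _flat()
    fhr = _bump(fhr, 400, 60, 20.0)
    base = np.full_like(fhr, 140.0)
    log = detect_accelerations(fhr, mask, base, FS)
    assert len(log.accelerations) == 1
    e = log.accelerations[0]
    assert e.amplitude == pytest.approx(20.0, abs=1.0)
    assert 400 * FS * 0.9 <= e.extremum <= (400 + 60) * FS * 1.1


def test_too_short_bump_ignored():
    fhr, mask = _flat()
    fhr = _bump(fhr, 400, 10, 20.0)
    base = np.full_like(fhr, 140.0)
    assert len(detect_accelerations(fhr, mask, base, FS).accelerations) == 0


def test_overlong_excursion_is_baseline_change():
    fhr, mask = _flat(minutes=30)
    fhr = _bump(fhr, 100, 660, 20.0)  # 11 minutes
    base = np.full_like(fhr, 140.0)
    log = detect_accelerations(fhr, mask, base, FS)
    assert len(log.accelerations) == 0
    assert len(log.of_kind("baseline_change")) == 1


# ---------------------------------------------------------------------------
# fuzzy decelerations
# ---------------------------------------------------------------------------


def test_crisp_event_membership_one():
    assert fuzzy_membership(60.0, 20.0) == 1.0


def test_partial_depth_membership_linear():
    # (12 - 10) / (15 - 10) = 0.4
    assert fuzzy_membership(60.0, 12.0) == pytest.approx(0.4)


def test_below_support_membership_zero():
    assert fuzzy_membership(60.0, 5.0) == 0.0
    assert fuzzy_membership(8.0, 30.0) == 0.0


def test_shallow_dip_not_emitted_at_default_threshold():
    fhr, mask = _flat()
    fhr = _bump(fhr, 400, 60, -12.0)
    base = np.full_like(fhr, 140.0)
    log = detect_decelerations_fuzzy(fhr, mask, base, FS, threshold=0.5)
    assert len(log.decelerations) == 0
    # same dip clears a lower emission threshold
    log2 = detect_decelerations_fuzzy(fhr, mask, base, FS, threshold=0.3)
    assert len(log2.decelerations) == 1
    assert log2.decelerations[0].membership < 0.6


@settings(max_examples=200, derandomize=True)
@given(
    d1=st.floats(10.5, 590), d2=st.floats(10.5, 590),
    a1=st.floats(0, 60), a2=st.floats(0, 60),
)
def test_membership_monotone(d1, d2, a1, a2):
    """Membership never decreases with duration (below 10 min) or depth."""
    lo = fuzzy_membership(min(d1, d2), min(a1, a2))
    hi = fuzzy_membership(max(d1, d2), max(a1, a2))
    assert hi >= lo - 1e-12


def test_fuzzy_equals_crisp_on_unambiguous_events():
    """On clearly NICHD-conforming synthetic events the fuzzy detector
    emits exactly the crisp detector's set (mirror-image oracle: the
    acceleration detector applied to the negated deviation)."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        fhr, mask = _flat()
        n_ev = rng.integers(1, 4)
        for i in range(n_ev):
            start = 150 + i * 500 + rng.integers(0, 100)
            fhr = _bump(fhr, start, rng.uniform(30, 120), -rng.uniform(18, 40))
        base = np.full_like(fhr, 140.0)
        fuzzy = detect_decelerations_fuzzy(fhr, mask, base, FS).decelerations
        crisp = detect_accelerations(2 * base - fhr, mask, base, FS).accelerations
        assert len(fuzzy) == len(crisp)
        for f, c in zip(fuzzy, crisp):
            assert (f.start, f.end) == (c.start, c.end)
            assert f.membership == 1.0


# ---------------------------------------------------------------------------
# contractions + typing
# ---------------------------------------------------------------------------


def test_flat_ucp_no_contractions():
    assert len(detect_contractions(np.full(7200, 10.0), FS)) == 0


def test_synthetic_contraction_train_recovered():
    rec, truth = generate_record(SynthConfig(seed=12, contraction_period_s=150))
    found = detect_contractions(rec.ucp, FS)
    assert len(found) == len(truth.events.contractions)
    for f, t in zip(found, truth.events.contractions):
        assert abs(f.extremum - t.extremum) <= 2


def _decel(start, nadir, end):
    return Event(DECELERATION, start, nadir, end, 30.0, FS, membership=1.0)


def test_typing_rules():
    contractions = EventLog(
        [Event("contraction", 1000, 1200, 1400, 40.0, FS)]
    )
    gradual_aligned = _decel(1000, 1200, 1420)   # nadir on the peak
    gradual_late = _decel(1160, 1360, 1560)      # nadir 40 s after peak
    abrupt = _decel(1150, 1190, 1400)            # 10 s onset-to-nadir
    uncoupled = _decel(2000, 2200, 2400)         # no contraction near
    assert classify_deceleration(gradual_aligned, contractions, FS) == "early"
    assert classify_deceleration(gradual_late, contractions, FS) == "late"
    assert classify_deceleration(abrupt, contractions, FS) == "variable"
    assert classify_deceleration(uncoupled, contractions, FS) == "variable"


def test_empty_contraction_log_warns_variable():
    with pytest.warns(UserWarning, match="no contractions"):
        assert classify_deceleration(_decel(0, 200, 400), EventLog(), FS) == "variable"


# ---------------------------------------------------------------------------
# sinusoidal pattern
# ---------------------------------------------------------------------------


def test_pure_sinusoid_present():
    n = int(25 * 60 * FS)
    t = np.arange(n) / FS
    fhr = 140 + 10 * np.sin(2 * np.pi * (4 / 60) * t)
    base = np.full(n, 140.0)
    assert detect_shr(fhr, np.ones(n, bool), base, FS) == "Present"


def test_flat_trace_absent():
    fhr, mask = _flat(minutes=25)
    assert detect_shr(fhr, mask, np.full_like(fhr, 140.0), FS) == "Absent"


def test_short_record_undetermined():
    fhr, mask = _flat(minutes=10)
    assert detect_shr(fhr, mask, np.full_like(fhr, 140.0), FS) == "Undetermined"


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def test_flat_record_feature_vector():
    rec, _ = generate_record(SynthConfig(
        n_accelerations=0, decel_spec=(), variability_sd_bpm=0,
        baseline_drift_bpm=0, baseline_bpm=140,
    ))
    fv, _ = extract_features(rec)
    assert fv.baseline == pytest.approx(140.0)
    assert fv.baseline_type == "Normal"
    assert fv.variability_type == "Undetermined"
    assert fv.acceleration_present is False
    assert (fv.n_accelerations, fv.n_early, fv.n_late, fv.n_variable) == (0, 0, 0, 0)
    assert fv.shr == "Absent"
    assert fv.stage == "stage1"


def test_decel_counts_by_type():
    rec, _ = generate_record(SynthConfig(
        decel_spec=(("late", 35, 90), ("late", 35, 90), ("variable", 30, 40)),
        variability_sd_bpm=3, n_accelerations=0, seed=21,
        contraction_period_s=200,
    ))
    fv, _ = extract_features(rec)
    assert fv.n_late == 2
    assert fv.n_variable == 1


def test_counting_conservation(cohort300):
    for rec, _ in cohort300[:30]:
        fv, log = extract_features(rec)
        assert fv.n_early + fv.n_late + fv.n_variable == len(log.decelerations)


def test_feature_table_complete(feature_table300):
    assert feature_table300.shape[1] == 11
    assert not feature_table300[
        ["baseline_type", "variability_type", "shr", "stage",
         "n_accelerations", "n_early", "n_late", "n_variable"]
    ].isna().any().any()
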