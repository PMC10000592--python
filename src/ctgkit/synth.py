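"""Synthetic cardiotocograph generator with exact ground truth.

Builds paired FHR/UCP traces from known components so that every
detector downstream can be scored against construction-time truth:

* a slowly drifting baseline in the normal 110–160 bpm band;
* band-limited Gaussian beat-to-beat variability (a stand-in — the
  true noise spectrum of clinical FHR is not characterised here);
* episodic accelerations (raised-cosine bumps >= 15 bpm, 15 s–10 min);
* a uterine-contraction train (raised-cosine pressure bumps over a
  resting tonus) with decelerations time-locked to it: early
  decelerations mirror the contraction, late ones are delayed
  raised-cosines, variable ones are abrupt piecewise-linear V-shapes;
* an optional sinusoidal heart-rate pattern (2–5 cycles/min);
* missing-signal gaps up to 50% of samples;
* simulated multi-rater annotations with adjacent-class confusion.

Second-stage records use a shorter contraction period with deeper,
recurrent decelerations, mimicking active pushing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .events import (
    ACCELERATION,
    CONTRACTION,
    DECELERATION,
    Event,
    EventLog,
)
from .record import CTGRecord, RecordMeta

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "PlacementError",
    "generate_record",
    "generate_cohort",
    "simulate_raters",
    "majority_vote",
]

FHR_MIN, FHR_MAX = 50.0, 220.0
UCP_TONUS = 10.0
DRIFT_PERIOD_MIN = 25.0       # period of the slow baseline drift
CONTRACTION_DURATION_S = 70.0
CONTRACTION_AMPLITUDE = 45.0
VARIABLE_ONSET_S = 12.0       # onset-to-nadir of a variable decel (abrupt, < 30 s)
SHR_FREQ_CPM = 3.5            # sinusoidal pattern frequency, cycles/min
SHR_AMPLITUDE_BPM = 10.0


class PlacementError(ValueError):
    """A configured event cannot be placed without overlap."""


@dataclass(frozen=True)
class SynthConfig:
    """Full description of one synthetic CTG record.

    ``decel_spec`` entries are ``(type, depth_bpm, duration_s)`` with
    type in {early, late, variable}; decelerations are attached to
    successive contractions. ``late_lag_s`` is the lag of a late
    deceleration's nadir behind the contraction peak.
    """

    duration_min: float = 30.0
    sample_rate: float = 4.0          # Hz, the conventional CTG rate
    baseline_bpm: float = 140.0
    baseline_drift_bpm: float = 3.0   # amplitude of the slow drift
    variability_sd_bpm: float = 6.0
    n_accelerations: int = 3
    contraction_period_s: float = 180.0
    decel_spec: tuple[tuple[str, float, float], ...] = ()
    late_lag_s: float = 40.0
    gap_fraction: float = 0.0
    shr: str = "absent"               # {present, absent}
    stage: int = 1                    # {1, 2}
    label: int = 1                    # ground-truth class 1/2/3
    rater_concordance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not 0 <= self.gap_fraction <= 0.5:
            raise ValueError("gap_fraction must lie in [0, 0.5]")
        if self.shr not in ("present", "absent"):
            raise ValueError("shr must be 'present' or 'absent'")
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")
        if self.label not in (1, 2, 3):
            raise ValueError("label must be in {1, 2, 3}")
        for entry in self.decel_spec:
            if entry[0] not in ("early", "late", "variable"):
                raise ValueError(f"unknown deceleration type in {entry!r}")


@dataclass
class GroundTruth:
    """Construction-time truth for one synthetic record."""

    events: EventLog
    true_baseline_bpm: np.ndarray     # per-sample baseline + drift series
    true_variability_bpm: float
    label: int
    rater_labels: tuple[int, ...]

    def baseline_in_window(self, start: int, end: int) -> float:
        return float(np.mean(self.true_baseline_bpm[start:end]))


def _raised_cosine(n: int) -> np.ndarray:
    """Unit-peak raised-cosine bump over n samples."""
    x = np.arange(n)
    return 0.5 * (1 - np.cos(2 * np.pi * (x + 0.5) / n))


def _vee(n: int, nadir_idx: int) -> np.ndarray:
    """Unit-depth piecewise-linear V with nadir at nadir_idx."""
    out = np.zeros(n)
    out[: nadir_idx + 1] = np.linspace(0, 1, nadir_idx + 1)
    out[nadir_idx:] = np.linspace(1, 0, n - nadir_idx)
    return out


def _bandlimited_noise(n: int, fs: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise band-limited to 0.04–1 Hz, rescaled to ``sd`` bpm."""
    if sd <= 0 or n < 64:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = sps.butter(2, [0.04, min(1.0, 0.45 * fs)], btype="band", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white)
    s = shaped.std()
    return shaped * (sd / s) if s > 0 else shaped


def _gap_mask(n: int, fraction: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Validity mask with ~fraction of samples in contiguous gaps."""
    mask = np.ones(n, dtype=bool)
    target = int(round(fraction * n))
    placed = 0
    attempts = 0
    while placed < target and attempts < 10_000:
        attempts += 1
        run = int(rng.uniform(15, 120) * fs)
        run = min(run, target - placed)
        if run <= 0:
            break
        start = int(rng.integers(0, max(1, n - run)))
        seg = mask[start : start + run]
        if not seg.all():
            continue
        seg[:] = False
        placed += run
    return mask


def _contraction_train(
    n: int, fs: float, period_s: float, rng: np.random.Generator
) -> tuple[np.ndarray, list[Event]]:
    ucp = np.full(n, UCP_TONUS)
    dur = int(CONTRACTION_DURATION_S * fs)
    events: list[Event] = []
    t = period_s / 2
    while True:
        center = t + rng.uniform(-0.05, 0.05) * period_s
        start = int(center * fs) - dur // 2
        end = start + dur
        if end >= n:
            break
        if start >= 0:
            amp = CONTRACTION_AMPLITUDE * rng.uniform(0.8, 1.2)
            ucp[start:end] += amp * _raised_cosine(dur)
            peak = start + int(np.argmax(ucp[start:end]))
            events.append(
                Event(CONTRACTION, start, peak, end, amp, fs)
            )
        t += period_s
    return ucp, events


def _place_decelerations(
    cfg: SynthConfig,
    contractions: list[Event],
    n: int,
    fs: float,
) -> tuple[np.ndarray, list[Event]]:
    """Deceleration deflection series + truth events, tied to contractions."""
    deflect = np.zeros(n)
    events: list[Event] = []
    occupied: list[tuple[int, int]] = []
    if cfg.decel_spec and not contractions:
        raise PlacementError(
            "decelerations configured but no contraction fits in the record"
        )
    for i, (dtype, depth, dur_s) in enumerate(cfg.decel_spec):
        if i >= len(contractions):
            raise PlacementError(
                f"decel_spec[{i}]={(dtype, depth, dur_s)}: only "
                f"{len(contractions)} contractions available"
            )
        peak = contractions[i].extremum
        dur = max(int(dur_s * fs), 8)
        if dtype == "early":
            # mirror of the contraction: nadir at the contraction peak
            start = peak - dur // 2
            shape = -depth * _raised_cosine(dur)
            nadir_off = int(np.argmin(shape))
        elif dtype == "late":
            # same gradual shape, nadir lagging the peak by late_lag_s
            start = peak + int(cfg.late_lag_s * fs) - dur // 2
            shape = -depth * _raised_cosine(dur)
            nadir_off = int(np.argmin(shape))
        else:  # variable: abrupt onset (< 30 s to nadir)
            nadir_off = int(VARIABLE_ONSET_S * fs)
            start = peak - nadir_off
            shape = -depth * _vee(dur, nadir_off)
        end = start + dur
        if start < 0 or end > n:
            raise PlacementError(
                f"decel_spec[{i}]={(dtype, depth, dur_s)} falls outside the record"
            )
        for s0, e0 in occupied:
            if start < e0 and s0 < end:
                raise PlacementError(
                    f"decel_spec[{i}]={(dtype, depth, dur_s)} overlaps a "
                    f"previously placed deceleration"
                )
        occupied.append((start, end))
        deflect[start:end] += shape
        events.append(
            Event(
                DECELERATION, start, start + nadir_off, end, depth, fs,
                membership=1.0, decel_type=dtype,
            )
        )
    return deflect, events


def _place_accelerations(
    cfg: SynthConfig,
    occupied: list[tuple[int, int]],
    n: int,
    fs: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[Event]]:
    deflect = np.zeros(n)
    events: list[Event] = []
    margin = int(30 * fs)
    taken = list(occupied)
    for i in range(cfg.n_accelerations):
        placed = False
        for _ in range(200):
            dur = int(rng.uniform(30, 90) * fs)
            depth = rng.uniform(18, 25)
            start = int(rng.integers(margin, max(margin + 1, n - dur - margin)))
            end = start + dur
            pad = int(20 * fs)  # keep events separated for clean truth
            if any(start - pad < e0 and s0 < end + pad for s0, e0 in taken):
                continue
            taken.append((start, end))
            deflect[start:end] += depth * _raised_cosine(dur)
            peak = start + int(np.argmax(deflect[start:end]))
            events.append(Event(ACCELERATION, start, peak, end, depth, fs))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place acceleration {i + 1}/{cfg.n_accelerations} "
                f"without overlap"
            )
    return deflect, events


def generate_record(config: SynthConfig) -> tuple[CTGRecord, GroundTruth]:
    """Synthesize one CTG record and its exact ground truth.

    The FHR trace is baseline + drift + band-limited variability noise
    + summed event deflections, clipped to [50, 220] bpm; the UCP trace
    is tonus + the contraction train. Identical configs (same seed)
    produce bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate
    n = int(round(cfg.duration_min * 60 * fs))
    t = np.arange(n) / fs

    drift = cfg.baseline_drift_bpm * np.sin(
        2 * np.pi * t / (DRIFT_PERIOD_MIN * 60) + rng.uniform(0, 2 * np.pi)
    )
    baseline = cfg.baseline_bpm + drift

    ucp, contraction_events = _contraction_train(n, fs, cfg.contraction_period_s, rng)
    decel_deflect, decel_events = _place_decelerations(cfg, contraction_events, n, fs)
    accel_deflect, accel_events = _place_accelerations(
        cfg, [(e.start, e.end) for e in decel_events], n, fs, rng
    )

    noise = _bandlimited_noise(n, fs, cfg.variability_sd_bpm, rng)
    shr_wave = (
        SHR_AMPLITUDE_BPM * np.sin(2 * np.pi * (SHR_FREQ_CPM / 60) * t)
        if cfg.shr == "present"
        else 0.0
    )

    fhr = np.clip(baseline + noise + shr_wave + accel_deflect + decel_deflect,
                  FHR_MIN, FHR_MAX)
    mask = _gap_mask(n, cfg.gap_fraction, fs, rng)

    raters = simulate_raters(
        cfg.label, cfg.rater_concordance, int(rng.integers(2**31))
    )

    record = CTGRecord(
        fhr=fhr,
        ucp=ucp,
        mask=mask,
        sample_rate=fs,
        stage1_span=(0, n) if cfg.stage == 1 else (0, 1),
        stage2_span=None if cfg.stage == 1 else (1, n),
        meta=RecordMeta(ph=7.25, gestation_weeks=40, maternal_age=28,
                        delivery="vaginal", end_to_birth_min=10.0),
        record_id=f"synth-{cfg.seed}",
    )
    # stage-2 records keep a 1-sample stage-1 stub; analysis targets stage 2
    truth = GroundTruth(
        events=EventLog([*accel_events, *decel_events, *contraction_events]),
        true_baseline_bpm=baseline,
        true_variability_bpm=cfg.variability_sd_bpm,
        label=cfg.label,
        rater_labels=raters,
    )
    return record, truth


# ---------------------------------------------------------------------------
# raters
# ---------------------------------------------------------------------------

N_RATERS = 6
_ADJACENT = {1: (2,), 2: (1, 3), 3: (2,)}


def simulate_raters(
    truth_label: int, concordance: float, seed: int
) -> tuple[int, ...]:
    """Six independent annotations with adjacent-class confusion.

    Each rater reports the true class with probability ``concordance``,
    otherwise an adjacent class (the clinical gray zone: Normal and
    Pathological are never confused with each other directly).
    """
    if not 0 <= concordance <= 1:
        raise ValueError("concordance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = []
    for _ in range(N_RATERS):
        if rng.random() < concordance:
            labels.append(truth_label)
        else:
            adj = _ADJACENT[truth_label]
            labels.append(int(adj[rng.integers(len(adj))]))
    return tuple(labels)


def majority_vote(labels: Sequence[int]) -> int:
    """Modal class of the rater labels; ties break to the more severe class."""
    counts = np.bincount(labels, minlength=4)[1:4]
    best = counts.max()
    # argmax over {1,2,3} preferring the highest class among ties
    return int(max(c for c in (1, 2, 3) if counts[c - 1] == best))


# ---------------------------------------------------------------------------
# cohort recipes
# ---------------------------------------------------------------------------


def _normal_recipe(rng: np.random.Generator, stage: int) -> dict:
    period = rng.uniform(150, 240) if stage == 1 else rng.uniform(80, 110)
    decels: list[tuple[str, float, float]] = []
    if rng.random() < 0.4:  # occasional benign early decelerations
        decels = [("early", rng.uniform(18, 25), rng.uniform(80, 100))]
    return dict(
        baseline_bpm=rng.uniform(120, 150),
        variability_sd_bpm=rng.uniform(6, 10),
        n_accelerations=int(rng.integers(3, 6)),
        contraction_period_s=period,
        decel_spec=tuple(decels),
    )


def _suspicious_recipe(rng: np.random.Generator, stage: int) -> dict:
    period = rng.uniform(140, 220) if stage == 1 else rng.uniform(75, 105)
    mode = rng.integers(3)
    depth_boost = 10.0 if stage == 2 else 0.0
    if mode == 0:  # reduced variability
        return dict(
            baseline_bpm=rng.uniform(115, 155),
            variability_sd_bpm=rng.uniform(2.5, 4.5),
            n_accelerations=int(rng.integers(0, 2)),
            contraction_period_s=period,
            decel_spec=(),
        )
    if mode == 1:  # mild tachy/bradycardia
        base = rng.uniform(162, 175) if rng.random() < 0.7 else rng.uniform(95, 108)
        return dict(
            baseline_bpm=base,
            variability_sd_bpm=rng.uniform(5, 7),
            n_accelerations=int(rng.integers(0, 3)),
            contraction_period_s=period,
            decel_spec=(),
        )
    n_var = int(rng.integers(2, 4))
    decels = tuple(
        ("variable", rng.uniform(28, 45) + depth_boost, rng.uniform(30, 55))
        for _ in range(n_var)
    )
    return dict(
        baseline_bpm=rng.uniform(118, 152),
        variability_sd_bpm=rng.uniform(5, 8),
        n_accelerations=int(rng.integers(0, 2)),
        contraction_period_s=period,
        decel_spec=decels,
    )


def _pathological_recipe(rng: np.random.Generator, stage: int, duration_min: float) -> dict:
    period = rng.uniform(130, 180) if stage == 1 else rng.uniform(80, 110)
    if rng.random() < 0.2:  # sinusoidal pattern variant
        return dict(
            baseline_bpm=rng.uniform(120, 150),
            variability_sd_bpm=rng.uniform(0.3, 1.0),
            n_accelerations=0,
            contraction_period_s=period,
            decel_spec=(),
            shr="present",
        )
    n_contr = int(duration_min * 60 / period) - 1
    depth_lo, depth_hi = (30, 55) if stage == 1 else (45, 70)
    # gradual (late) decelerations: keep onset-to-nadir well above the
    # 30-s abrupt cut, yet short enough not to overlap across the train
    dur_lo = 80.0 if stage == 1 else 0.55 * period
    dur_hi = min(110.0, 0.7 * period)
    n_late = max(2, n_contr - int(rng.integers(0, 2)))
    decels = tuple(
        ("late", rng.uniform(depth_lo, depth_hi), rng.uniform(dur_lo, dur_hi))
        for _ in range(n_late)
    )
    return dict(
        baseline_bpm=rng.uniform(115, 160),
        variability_sd_bpm=rng.uniform(0.5, 2.0),
        n_accelerations=0,
        contraction_period_s=period,
        decel_spec=decels,
    )


_RECIPES = {1: _normal_recipe, 2: _suspicious_recipe}


def class_counts(n: int, class_mix: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n records over the class mix."""
    mix = np.asarray(class_mix, dtype=float)
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    raw = mix * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def generate_cohort(
    n: int,
    class_mix: Sequence[float] = (0.34, 0.39, 0.27),
    stage: int = 1,
    seed: int = 0,
    duration_min: float = 30.0,
    gap_fraction: float = 0.0,
    rater_concordance: float = 1.0,
) -> list[tuple[CTGRecord, GroundTruth]]:
    """Generate a labelled cohort with class-conditional recipes.

    Normal records have moderate variability, accelerations and at most
    benign early decelerations; Suspicious ones show reduced
    variability, mild tachy/bradycardia or variable decelerations;
    Pathological ones show near-absent variability with recurrent late
    decelerations or a sinusoidal pattern. Stage-2 cohorts use shorter
    contraction periods and deeper, recurrent decelerations.
    """
    counts = class_counts(n, class_mix)
    if sum(1 for c in counts if c > 0) > n:
        raise ValueError(f"infeasible mix: cannot realise {class_mix} with n={n}")
    rng = np.random.default_rng(seed)
    cohort = []
    for label, count in zip((1, 2, 3), counts):
        for _ in range(count):
            sub = np.random.default_rng(int(rng.integers(2**31)))
            for attempt in range(20):
                if label == 3:
                    recipe = _pathological_recipe(sub, stage, duration_min)
                else:
                    recipe = _RECIPES[label](sub, stage)
                cfg = SynthConfig(
                    duration_min=duration_min,
                    stage=stage,
                    label=label,
                    gap_fraction=gap_fraction,
                    rater_concordance=rater_concordance,
                    seed=int(sub.integers(2**31)),
                    **recipe,
                )
                try:
                    cohort.append(generate_record(cfg))
                    break
                except PlacementError:
                    continue
            else:  # pragma: no cover - recipes are feasible by construction
                raise PlacementError(f"could not realise a class-{label} record")
    return cohort
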