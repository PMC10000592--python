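"""Bespoke FHR signal operators and the 11-feature vector.

The extraction chain is: iterative windowed baseline -> variability
from qualifying 1-min segments -> acceleration detection by crisp
NICHD rules -> deceleration detection by fuzzy (trapezoidal) duration
and depth memberships -> deceleration typing against the uterine
contraction train -> sinusoidal-pattern check -> feature assembly.

Baseline estimation runs in 10-min windows with 3 min of overlap. Each
window starts from a robust virtual baseline (modal bpm of the valid
samples) and iteratively re-estimates after excluding samples outside
an event envelope around the current estimate, so accelerations and
decelerations stop biasing the level. A window's value is accepted
only when samples near the estimate total more than 2 minutes (not
necessarily contiguous); otherwise the window is unidentifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .events import (
    ACCELERATION,
    BASELINE_CHANGE,
    CONTRACTION,
    DECELERATION,
    Event,
    EventLog,
)
from .record import CTGRecord

__all__ = [
    "BaselineEstimate",
    "FeatureVector",
    "FEATURE_COLUMNS",
    "estimate_baseline",
    "baseline_series",
    "classify_baseline",
    "compute_variability",
    "classify_variability",
    "detect_accelerations",
    "detect_decelerations_fuzzy",
    "detect_contractions",
    "classify_deceleration",
    "type_decelerations",
    "detect_shr",
    "build_feature_vector",
    "extract_features",
    "CTGFeatureExtractor",
]

WINDOW_MIN = 10.0          # baseline window length
OVERLAP_MIN = 3.0          # overlap between consecutive windows
ENVELOPE_BPM = 10.0        # event envelope excluded during iteration
BASELINE_TOL_BPM = 0.5     # convergence tolerance
BASELINE_MAX_ITER = 20
MIN_IDENTIFIABLE_S = 120.0  # >2 min of near-baseline signal required
EVENT_MIN_S = 15.0
EVENT_MAX_S = 600.0
EVENT_MIN_BPM = 15.0
FUZZY_DUR_SUPPORT_S = 10.0   # membership support edges
FUZZY_DEPTH_SUPPORT_BPM = 10.0
ABRUPT_ONSET_S = 30.0        # onset-to-nadir below this is "abrupt"
EARLY_LAG_S = 15.0           # |nadir - contraction peak| for early
COUPLING_WINDOW_S = 120.0    # max nadir-to-peak distance to couple
SMOOTH_S = 9.0               # detection pre-smoothing
MAX_BRIDGE_GAP_S = 15.0      # events may not span a longer masked run
SHR_MIN_VALID_MIN = 20.0
SHR_BAND_CPM = (2.0, 5.0)
SHR_AMP_BPM = (5.0, 15.0)


@dataclass
class BaselineEstimate:
    """Baseline level for one 10-min window (or 'unidentifiable')."""

    window: tuple[int, int]          # sample span [start, end)
    value: float | None              # bpm; None when unidentifiable
    iterations_used: int
    identifiable_duration_s: float

    @property
    def identifiable(self) -> bool:
        return self.value is not None


def _window_spans(n: int, fs: float) -> list[tuple[int, int]]:
    win = int(WINDOW_MIN * 60 * fs)
    step = int((WINDOW_MIN - OVERLAP_MIN) * 60 * fs)
    if n < win:
        raise ValueError(
            f"record of {n / fs / 60:.1f} min is shorter than the "
            f"{WINDOW_MIN:.0f}-min baseline window"
        )
    spans = []
    start = 0
    while start + win <= n:
        spans.append((start, start + win))
        start += step
    if spans[-1][1] < n:  # cover the tail with a final clamped window
        spans.append((n - win, n))
    return spans


def _virtual_baseline(x: np.ndarray) -> float:
    """Initial modal estimate: densest 1-bpm bin of the valid samples."""
    lo, hi = np.floor(x.min()), np.ceil(x.max())
    if hi - lo < 1:
        return float(x.mean())
    bins = np.arange(lo, hi + 1.0)
    hist, edges = np.histogram(x, bins=bins)
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def estimate_baseline(
    fhr: np.ndarray,
    mask: np.ndarray,
    sample_rate: float,
    envelope_bpm: float = ENVELOPE_BPM,
    tol_bpm: float = BASELINE_TOL_BPM,
    max_iter: int = BASELINE_MAX_ITER,
) -> list[BaselineEstimate]:
    """Iterative baseline per sliding 10-min window (3-min overlap).

    Each iteration keeps only samples within ``envelope_bpm`` of the
    current estimate (discarding acceleration/deceleration excursions)
    and re-averages, until the change drops below ``tol_bpm``. The
    window is unidentifiable when fewer than 2 min of samples end up
    near the estimate, or when it is entirely masked.
    """
    fhr = np.asarray(fhr, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    fs = sample_rate
    estimates = []
    for start, end in _window_spans(len(fhr), fs):
        x = fhr[start:end][mask[start:end]]
        if x.size == 0:
            estimates.append(BaselineEstimate((start, end), None, 0, 0.0))
            continue
        b = _virtual_baseline(x)
        iters = 0
        for iters in range(1, max_iter + 1):
            near = np.abs(x - b) <= envelope_bpm
            if not near.any():
                break
            b_new = float(x[near].mean())
            if abs(b_new - b) < tol_bpm:
                b = b_new
                break
            b = b_new
        near = np.abs(x - b) <= envelope_bpm
        ident_s = float(np.count_nonzero(near)) / fs
        if ident_s > MIN_IDENTIFIABLE_S and 50.0 <= b <= 220.0:
            estimates.append(BaselineEstimate((start, end), b, iters, ident_s))
        else:
            estimates.append(BaselineEstimate((start, end), None, iters, ident_s))
    return estimates


def baseline_series(
    estimates: Sequence[BaselineEstimate], n: int
) -> np.ndarray:
    """Per-sample baseline interpolated between window centres.

    Each identifiable window contributes its value at the window
    centre; samples in between are linearly interpolated (tracking
    slow baseline drift better than a stepwise series), constant
    beyond the outermost centres. All-unidentifiable input yields NaN
    everywhere.
    """
    centers = [
        (0.5 * (est.window[0] + est.window[1]), est.value)
        for est in estimates
        if est.identifiable
    ]
    if not centers:
        return np.full(n, np.nan)
    xs, ys = zip(*centers)
    return np.interp(np.arange(n), xs, ys)


def classify_baseline(value: float | None) -> str:
    """Normal 110–160 bpm; below is Bradycardia, above Tachycardia."""
    if value is None:
        return "Undetermined"
    if value < 110:
        return "Bradycardia"
    if value > 160:
        return "Tachycardia"
    return "Normal"


# ---------------------------------------------------------------------------
# variability
# ---------------------------------------------------------------------------


def compute_variability(
    fhr: np.ndarray,
    mask: np.ndarray,
    baseline: np.ndarray,
    sample_rate: float,
    events: EventLog | None = None,
    slice_mode: Literal["mean", "sum"] = "mean",
) -> float | None:
    """Record variability (bpm) from qualifying 1-min segments.

    Within each discrete 10-min slice, every 1-min segment contributes
    the standard deviation of (FHR − baseline) provided its oscillation
    completes more than one cycle (cycles = baseline crossings / 2).
    Slice values combine the qualifying segments (``mean`` by default;
    ``sum`` follows the alternative convention) and the record value is
    the mean over slices. Samples inside supplied events or under the
    mask are excluded. Returns ``None`` (Undetermined) when no segment
    anywhere qualifies.
    """
    fhr = np.asarray(fhr, dtype=float)
    fs = sample_rate
    valid = np.asarray(mask, dtype=bool) & np.isfinite(baseline)
    if events is not None:
        for e in events:
            if e.kind in (ACCELERATION, DECELERATION, BASELINE_CHANGE):
                valid[e.start : e.end] = False
    dev = fhr - baseline
    slice_len = int(WINDOW_MIN * 60 * fs)
    seg_len = int(60 * fs)
    slice_values = []
    for s0 in range(0, len(fhr) - slice_len + 1, slice_len):
        seg_sds = []
        for g0 in range(s0, s0 + slice_len, seg_len):
            v = valid[g0 : g0 + seg_len]
            d = dev[g0 : g0 + seg_len][v]
            if d.size < 4:
                continue
            signs = np.sign(d[d != 0])
            crossings = int(np.count_nonzero(np.diff(signs) != 0))
            if crossings / 2.0 > 1.0:
                seg_sds.append(float(d.std()))
        if seg_sds:
            slice_values.append(
                float(np.sum(seg_sds)) if slice_mode == "sum" else float(np.mean(seg_sds))
            )
    if not slice_values:
        return None
    return float(np.mean(slice_values))


def classify_variability(v: float | None) -> str:
    """NICHD amplitude bands: Absent (~0), Minimal <=5, Moderate 6-25,
    Marked >25 bpm."""
    if v is None:
        return "Undetermined"
    if v < 0:
        raise ValueError("variability cannot be negative")
    if v <= 0.5:
        return "Absent"
    if v <= 5:
        return "Minimal"
    if v <= 25:
        return "Moderate"
    return "Marked"


# ---------------------------------------------------------------------------
# excursion machinery shared by acceleration / deceleration detectors
# ---------------------------------------------------------------------------


def _smooth_valid(fhr: np.ndarray, mask: np.ndarray, fs: float) -> np.ndarray:
    """Moving-average smoothing with masked samples interpolated."""
    x = np.asarray(fhr, dtype=float).copy()
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.full_like(x, np.nan)
    idx = np.arange(len(x))
    x[~m] = np.interp(idx[~m], idx[m], x[m])
    w = max(int(SMOOTH_S * fs) | 1, 1)
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def _long_gap_mask(mask: np.ndarray, fs: float) -> np.ndarray:
    """True where a sample sits inside a masked run longer than 15 s."""
    out = np.zeros(len(mask), dtype=bool)
    limit = int(MAX_BRIDGE_GAP_S * fs)
    n = len(mask)
    i = 0
    while i < n:
        if not mask[i]:
            j = i
            while j < n and not mask[j]:
                j += 1
            if j - i > limit:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def _excursion_runs(
    above: np.ndarray, breaks: np.ndarray
) -> list[tuple[int, int]]:
    """Maximal runs of ``above`` split wherever ``breaks`` is set."""
    flag = above & ~breaks
    if not flag.any():
        return []
    d = np.diff(flag.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if flag[0]:
        starts.insert(0, 0)
    if flag[-1]:
        ends.append(len(flag))
    return list(zip(starts, ends))


def _excursions(
    fhr: np.ndarray,
    mask: np.ndarray,
    baseline: np.ndarray,
    fs: float,
    sign: int,
) -> list[tuple[int, int, int, float]]:
    """(start, extremum, end, amplitude) for baseline excursions of one
    polarity, on the smoothed trace."""
    smooth = _smooth_valid(fhr, mask, fs)
    dev = sign * (smooth - baseline)
    above = np.nan_to_num(dev, nan=-1.0) > 0
    breaks = _long_gap_mask(mask, fs)
    out = []
    for s, e in _excursion_runs(above, breaks):
        if e - s < 3:
            continue
        ext = s + int(np.argmax(dev[s:e]))
        amp = float(dev[ext])
        # an extremum on the run boundary (record-edge clipping) is
        # nudged inward to keep start < extremum < end strict
        ext = min(max(ext, s + 1), e - 2)
        out.append((s, ext, e, amp))
    return out


def detect_accelerations(
    fhr: np.ndarray,
    mask: np.ndarray,
    baseline: np.ndarray,
    sample_rate: float,
) -> EventLog:
    """Crisp NICHD acceleration detector.

    Positive baseline excursions are kept when 15 s <= duration <=
    10 min and peak − baseline > 15 bpm; longer qualifying excursions
    are flagged as baseline changes rather than events.
    """
    fs = sample_rate
    events = []
    for s, ext, e, amp in _excursions(fhr, mask, baseline, fs, +1):
        dur = (e - s) / fs
        if amp <= EVENT_MIN_BPM:
            continue
        if dur < EVENT_MIN_S:
            continue
        kind = ACCELERATION if dur <= EVENT_MAX_S else BASELINE_CHANGE
        events.append(Event(kind, s, ext, e, amp, fs))
    return EventLog(events)


def fuzzy_membership(
    duration_s: float,
    depth_bpm: float,
    dur_support_s: float = FUZZY_DUR_SUPPORT_S,
    dur_core_s: float = EVENT_MIN_S,
    depth_support_bpm: float = FUZZY_DEPTH_SUPPORT_BPM,
    depth_core_bpm: float = EVENT_MIN_BPM,
    max_s: float = EVENT_MAX_S,
) -> float:
    """min of trapezoidal duration and depth memberships.

    Duration: 0 below 10 s, rising linearly to 1 at 15 s, 1 up to
    10 min, 0 beyond (a baseline change). Depth: 0 below 10 bpm,
    rising to 1 at 15 bpm.
    """
    if duration_s > max_s:
        return 0.0
    mu_dur = float(np.clip((duration_s - dur_support_s) / (dur_core_s - dur_support_s), 0, 1))
    mu_depth = float(
        np.clip((depth_bpm - depth_support_bpm) / (depth_core_bpm - depth_support_bpm), 0, 1)
    )
    return min(mu_dur, mu_depth)


def detect_decelerations_fuzzy(
    fhr: np.ndarray,
    mask: np.ndarray,
    baseline: np.ndarray,
    sample_rate: float,
    threshold: float = 0.5,
) -> EventLog:
    """Fuzzy deceleration detector.

    Negative excursions are scored min(mu_duration, mu_depth) with
    trapezoidal memberships and emitted when the membership reaches
    ``threshold``; unambiguous NICHD events (>=15 s, >=15 bpm) always
    score 1. Excursions beyond 10 min are flagged as baseline changes.
    """
    fs = sample_rate
    events = []
    for s, ext, e, amp in _excursions(fhr, mask, baseline, fs, -1):
        dur = (e - s) / fs
        if dur > EVENT_MAX_S and amp > EVENT_MIN_BPM:
            events.append(Event(BASELINE_CHANGE, s, ext, e, amp, fs, membership=0.0))
            continue
        mu = fuzzy_membership(dur, amp)
        if mu >= threshold:
            events.append(Event(DECELERATION, s, ext, e, amp, fs, membership=mu))
    return EventLog(events)


def detect_contractions(
    ucp: np.ndarray,
    sample_rate: float,
    prominence: float = 15.0,
    min_separation_s: float = 45.0,
) -> EventLog:
    """Prominence-based uterine-contraction peaks with onset/offset at
    90% prominence drop. A flat channel yields an empty log."""
    ucp = np.asarray(ucp, dtype=float)
    fs = sample_rate
    peaks, props = sps.find_peaks(
        ucp, prominence=prominence, distance=int(min_separation_s * fs)
    )
    if len(peaks) == 0:
        return EventLog()
    widths, _, lips, rips = sps.peak_widths(ucp, peaks, rel_height=0.9)
    events = []
    for p, prom, li, ri in zip(peaks, props["prominences"], lips, rips):
        s, e = int(np.floor(li)), int(np.ceil(ri)) + 1
        s, e = max(0, s), min(len(ucp), e)
        if not s < p < e - 1:
            s, e = max(0, p - 1), min(len(ucp), p + 2)
        events.append(Event(CONTRACTION, s, int(p), e, float(prom), fs))
    return EventLog(events)


def classify_deceleration(
    decel: Event,
    contractions: EventLog,
    sample_rate: float,
) -> str:
    """Type one deceleration against the contraction train.

    Abrupt descent (onset-to-nadir < 30 s) is variable. Gradual
    decelerations are early when the nadir sits within 15 s of the
    nearest contraction peak, late when it lags the peak by more than
    15 s, and variable when no contraction lies within ±120 s (or the
    nadir leads the peak — an uncoupled dip).
    """
    fs = sample_rate
    onset_to_nadir_s = (decel.extremum - decel.start) / fs
    if onset_to_nadir_s < ABRUPT_ONSET_S:
        return "variable"
    if len(contractions) == 0:
        warnings.warn("no contractions detected; gradual deceleration left variable")
        return "variable"
    peaks = np.array([c.extremum for c in contractions])
    lags_s = (decel.extremum - peaks) / fs  # >0: nadir after peak
    j = int(np.argmin(np.abs(lags_s)))
    lag = lags_s[j]
    if abs(lag) > COUPLING_WINDOW_S:
        return "variable"
    if abs(lag) <= EARLY_LAG_S:
        return "early"
    if lag > EARLY_LAG_S:
        return "late"
    return "variable"


def type_decelerations(
    decels: EventLog, contractions: EventLog, sample_rate: float
) -> EventLog:
    """Return the deceleration log with types filled in."""
    return EventLog(
        e.with_type(classify_deceleration(e, contractions, sample_rate))
        if e.kind == DECELERATION
        else e
        for e in decels
    )


def detect_shr(
    fhr: np.ndarray,
    mask: np.ndarray,
    baseline: np.ndarray,
    sample_rate: float,
    accelerations: EventLog | None = None,
) -> str:
    """Sinusoidal-pattern check: Present / Absent / Undetermined.

    Present requires >=20 min of valid signal whose deviation from
    baseline concentrates its power in the 2–5 cycles/min band with an
    equivalent sine amplitude of 5–15 bpm, with no accelerations.
    Records with less than 20 min of valid signal are Undetermined.
    """
    fs = sample_rate
    valid = np.asarray(mask, dtype=bool) & np.isfinite(baseline)
    if np.count_nonzero(valid) / fs / 60 < SHR_MIN_VALID_MIN:
        return "Undetermined"
    dev = (np.asarray(fhr, float) - baseline)[valid]
    var_total = float(dev.var())
    if var_total < 0.25:  # essentially flat trace
        return "Absent"
    nperseg = min(len(dev), int(256 * fs))
    freqs, psd = sps.welch(dev, fs=fs, nperseg=nperseg)
    band = (freqs >= SHR_BAND_CPM[0] / 60) & (freqs <= SHR_BAND_CPM[1] / 60)
    band_frac = float(psd[band].sum() / psd.sum()) if psd.sum() > 0 else 0.0
    amp = float(np.sqrt(2 * band_frac * var_total))
    has_accel = accelerations is not None and len(accelerations.accelerations) > 0
    if band_frac >= 0.5 and SHR_AMP_BPM[0] <= amp <= SHR_AMP_BPM[1] and not has_accel:
        return "Present"
    return "Absent"


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = [
    "baseline",
    "baseline_type",
    "variability",
    "variability_type",
    "acceleration_present",
    "n_accelerations",
    "n_early",
    "n_late",
    "n_variable",
    "shr",
    "stage",
]


@dataclass
class FeatureVector:
    """The 11 features describing one CTG trace."""

    baseline: float | None
    baseline_type: str
    variability: float | None
    variability_type: str
    acceleration_present: bool
    n_accelerations: int
    n_early: int
    n_late: int
    n_variable: int
    shr: str
    stage: str  # {normal, stage1, stage2}

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in FEATURE_COLUMNS}


def build_feature_vector(
    baseline_value: float | None,
    variability_value: float | None,
    accelerations: EventLog,
    decelerations: EventLog,
    shr: str,
    stage: str,
) -> FeatureVector:
    """Assemble the 11-feature vector from the detector outputs.

    Undetermined core quantities propagate as explicit categories
    (baseline/variability value ``None``), never silently imputed.
    """
    n_acc = len(accelerations.accelerations)
    counts = decelerations.count_decel_types()
    return FeatureVector(
        baseline=baseline_value,
        baseline_type=classify_baseline(baseline_value),
        variability=variability_value,
        variability_type=classify_variability(variability_value),
        acceleration_present=n_acc > 0,
        n_accelerations=n_acc,
        n_early=counts["early"],
        n_late=counts["late"],
        n_variable=counts["variable"],
        shr=shr,
        stage=stage,
    )


def extract_features(
    record: CTGRecord,
    stage: int | None = None,
    fuzzy_threshold: float = 0.5,
    slice_mode: Literal["mean", "sum"] = "mean",
) -> tuple[FeatureVector, EventLog]:
    """Run the full detector chain on one record.

    Returns the feature vector and the combined event log
    (accelerations, typed decelerations, contractions). ``stage``
    defaults to whichever stage span dominates the record.
    """
    if stage is None:
        stage = 2 if (
            record.stage2_span is not None
            and (record.stage2_span[1] - record.stage2_span[0])
            > (record.stage1_span[1] - record.stage1_span[0])
        ) else 1
    sl = record.stage_slice(stage)
    fhr = record.fhr[sl]
    ucp = record.ucp[sl]
    mask = record.mask[sl]
    fs = record.sample_rate

    estimates = estimate_baseline(fhr, mask, fs)
    base = baseline_series(estimates, len(fhr))
    ident = [e.value for e in estimates if e.identifiable]
    baseline_value = float(np.mean(ident)) if ident else None

    accels = detect_accelerations(fhr, mask, base, fs)
    decels = detect_decelerations_fuzzy(fhr, mask, base, fs, threshold=fuzzy_threshold)
    contractions = detect_contractions(ucp, fs)
    decels = type_decelerations(decels, contractions, fs)

    variability = compute_variability(
        fhr, mask, base, fs,
        events=EventLog([*accels, *decels]),
        slice_mode=slice_mode,
    )
    shr = detect_shr(fhr, mask, base, fs, accelerations=accels)

    fv = build_feature_vector(
        baseline_value, variability, accels, decels, shr, f"stage{stage}"
    )
    return fv, EventLog([*accels, *decels, *contractions])


class CTGFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer: list of :class:`CTGRecord` -> 11-column feature table.

    Parameters
    ----------
    stage : int or None
        Analyse this stage span of every record (None: per-record
        dominant stage).
    fuzzy_threshold : float
        Emission threshold for the fuzzy deceleration detector.
    slice_mode : {"mean", "sum"}
        How qualifying 1-min variability segments combine per 10-min
        slice.
    """

    def __init__(
        self,
        stage: int | None = None,
        fuzzy_threshold: float = 0.5,
        slice_mode: str = "mean",
    ) -> None:
        self.stage = stage
        self.fuzzy_threshold = fuzzy_threshold
        self.slice_mode = slice_mode

    def fit(self, X: Sequence[CTGRecord], y=None) -> "CTGFeatureExtractor":
        self.n_features_in_ = 1  # one record object per row
        return self

    def transform(self, X: Sequence[CTGRecord]) -> pd.DataFrame:
        rows = []
        index = []
        for rec in X:
            fv, _ = extract_features(
                rec,
                stage=self.stage,
                fuzzy_threshold=self.fuzzy_threshold,
                slice_mode=self.slice_mode,
            )
            rows.append(fv.as_dict())
            index.append(rec.record_id)
        return pd.DataFrame(rows, index=index, columns=FEATURE_COLUMNS)
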