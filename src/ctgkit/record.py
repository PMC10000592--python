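"""CTG record model, CSV/JSON persistence, signal-quality windows and
the cohort inclusion rules.

A record pairs a fetal-heart-rate trace (bpm) with the maternal
uterine-contraction-pressure channel, sampled at a common fixed rate,
plus a per-sample validity mask (signal loss and gross noise are both
encoded as invalid — the two are not distinguished) and clinical
metadata used by the inclusion rules (umbilical pH, stage durations,
gestation, maternal age).

Spans use 0-based sample indices, half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RecordMeta",
    "CTGRecord",
    "QualityReport",
    "read_record",
    "write_record",
    "read_wfdb_record",
    "quality_windows",
    "select_record",
    "stage1_analysis_span",
]

#: inclusion thresholds (minutes / percent / years / weeks)
STAGE1_MIN_LOW_PH = 30.0     # required stage-1 length when pH <= 7.15
STAGE1_MIN_HIGH_PH = 40.0    # required stage-1 length when pH > 7.15
STAGE1_MAX_MIN = 60.0        # analysis window cap for stage 1
STAGE2_MAX_MIN = 30.0        # recording cap for stage 2
END_TO_BIRTH_MAX_MIN = 30.0
MISSING_MAX_PCT = 50.0
PH_SPLIT = 7.15
GESTATION_MIN_WEEKS = 36
MATERNAL_AGE_MIN = 18


@dataclass
class RecordMeta:
    """Clinical metadata attached to one labor record."""

    ph: float | None = None                 # umbilical artery pH
    be: float | None = None                 # base excess, mmol/L
    bdecf: float | None = None              # base deficit (ecf), mmol/L
    apgar: int | None = None                # 5-min Apgar score
    gestation_weeks: float | None = None
    maternal_age: float | None = None
    delivery: str | None = None             # "vaginal" | "caesarean"
    end_to_birth_min: float | None = None   # signal end to birth, minutes


@dataclass
class CTGRecord:
    """Paired FHR/UCP series with validity mask and stage spans."""

    fhr: np.ndarray
    ucp: np.ndarray
    mask: np.ndarray            # True = valid sample
    sample_rate: float
    stage1_span: tuple[int, int]
    stage2_span: tuple[int, int] | None = None
    meta: RecordMeta = field(default_factory=RecordMeta)
    record_id: str = "record"

    def __post_init__(self) -> None:
        self.fhr = np.asarray(self.fhr, dtype=float)
        self.ucp = np.asarray(self.ucp, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.fhr)
        if not (len(self.ucp) == n and len(self.mask) == n):
            raise ValueError(
                f"channel length mismatch: fhr={len(self.fhr)}, "
                f"ucp={len(self.ucp)}, mask={len(self.mask)}"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self._check_span(self.stage1_span, "stage1_span")
        if self.stage2_span is not None:
            self._check_span(self.stage2_span, "stage2_span")
            if self.stage2_span[0] < self.stage1_span[1]:
                raise ValueError("stage spans must be disjoint and ordered")
            stage2_min = (self.stage2_span[1] - self.stage2_span[0]) / self.sample_rate / 60
            if stage2_min > STAGE2_MAX_MIN + 1e-9:
                raise ValueError(
                    f"stage-2 span is {stage2_min:.1f} min; at most "
                    f"{STAGE2_MAX_MIN:.0f} min of stage 2 is recorded"
                )

    def _check_span(self, span: tuple[int, int], name: str) -> None:
        s, e = span
        if not (0 <= s < e <= len(self.fhr)):
            raise ValueError(f"{name}={span} outside record of {len(self.fhr)} samples")

    @property
    def n_samples(self) -> int:
        return len(self.fhr)

    @property
    def duration_min(self) -> float:
        return self.n_samples / self.sample_rate / 60

    def stage1_duration_min(self) -> float:
        s, e = self.stage1_span
        return (e - s) / self.sample_rate / 60

    def stage_slice(self, stage: int) -> slice:
        span = self.stage1_span if stage == 1 else self.stage2_span
        if span is None:
            raise ValueError(f"record has no stage-{stage} span")
        return slice(*span)


@dataclass
class QualityReport:
    """Percentage of invalid signal per analysis window.

    Window 1 is the stage-1 span, window 2 the stage-2 span; ``overall``
    covers the whole record. All values in [0, 100].
    """

    window1_missing_pct: float
    window2_missing_pct: float | None
    overall_missing_pct: float


def _missing_pct(mask: np.ndarray, span: tuple[int, int]) -> float:
    s, e = span
    if e <= s:
        raise ValueError("empty span: quality window undefined")
    sub = mask[s:e]
    return 100.0 * float(np.count_nonzero(~sub)) / (e - s)


def quality_windows(record: CTGRecord) -> QualityReport:
    """Missing-signal percentages for the stage windows of a record."""
    w1 = _missing_pct(record.mask, record.stage1_span)
    w2 = (
        _missing_pct(record.mask, record.stage2_span)
        if record.stage2_span is not None
        else None
    )
    overall = _missing_pct(record.mask, (0, record.n_samples))
    return QualityReport(w1, w2, overall)


def stage1_analysis_span(record: CTGRecord) -> tuple[int, int]:
    """Stage-1 span truncated to the final 60 minutes.

    Longer first stages are analysed over their last hour — the portion
    adjacent to stage 2, where fetal state is most informative.
    """
    s, e = record.stage1_span
    cap = int(round(STAGE1_MAX_MIN * 60 * record.sample_rate))
    return (max(s, e - cap), e)


def select_record(record: CTGRecord) -> tuple[bool, list[str]]:
    """Apply the cohort inclusion rules; return (included, reasons).

    Rules (all must hold):

    * pH <= 7.15 requires stage-1 duration >= 30 min; pH > 7.15
      requires >= 40 min (durations are wall-clock, not mask-valid).
    * time from signal end to birth < 30 min;
    * stage-1 missing signal <= 50%;
    * gestational age > 36 weeks; maternal age >= 18 years.

    ``reasons`` lists every violated rule. A missing pH is an error —
    the record cannot be silently included or excluded.
    """
    meta = record.meta
    if meta.ph is None:
        raise ValueError("record not evaluable: meta.ph is missing")
    reasons: list[str] = []
    td = record.stage1_duration_min()
    if meta.ph <= PH_SPLIT:
        if td < STAGE1_MIN_LOW_PH:
            reasons.append(f"Td<{STAGE1_MIN_LOW_PH:.0f} for pH<={PH_SPLIT}")
    else:
        if td < STAGE1_MIN_HIGH_PH:
            reasons.append(f"Td<{STAGE1_MIN_HIGH_PH:.0f} for pH>{PH_SPLIT}")
    if meta.end_to_birth_min is not None and meta.end_to_birth_min >= END_TO_BIRTH_MAX_MIN:
        reasons.append(f"end_to_birth>={END_TO_BIRTH_MAX_MIN:.0f}min")
    missing = _missing_pct(record.mask, stage1_analysis_span(record))
    if missing > MISSING_MAX_PCT:
        reasons.append(f"missing>{MISSING_MAX_PCT:.0f}%")
    if meta.gestation_weeks is not None and meta.gestation_weeks <= GESTATION_MIN_WEEKS:
        reasons.append(f"gestation<={GESTATION_MIN_WEEKS}wk")
    if meta.maternal_age is not None and meta.maternal_age < MATERNAL_AGE_MIN:
        reasons.append(f"maternal_age<{MATERNAL_AGE_MIN}")
    return (not reasons, reasons)


# ---------------------------------------------------------------------------
# persistence: two-column CSV per channel + JSON sidecar
# ---------------------------------------------------------------------------

def _mask_to_runs(mask: np.ndarray) -> list[list[int]]:
    """Invalid stretches as [start, end) pairs (compact text encoding)."""
    invalid = ~mask
    runs = []
    edges = np.flatnonzero(np.diff(invalid.astype(np.int8)))
    starts = [0] if invalid[0] else []
    for i in edges:
        if invalid[i + 1]:
            starts.append(int(i) + 1)
        else:
            runs.append([starts.pop(), int(i) + 1])
    if starts:
        runs.append([starts.pop(), len(mask)])
    return runs


def _runs_to_mask(runs: list[list[int]], n: int) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    for s, e in runs:
        mask[s:e] = False
    return mask


def write_record(record: CTGRecord, path: str | Path) -> Path:
    """Write a record to ``path/`` as fhr.csv, ucp.csv and record.json.

    Channels are (time_s, value) CSVs at full float precision so the
    write→read round trip is exact.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    t = np.arange(record.n_samples) / record.sample_rate
    for name, chan in (("fhr", record.fhr), ("ucp", record.ucp)):
        arr = np.column_stack([t, chan])
        np.savetxt(
            path / f"{name}.csv", arr, fmt="%.17g", delimiter=",",
            header="time_s,value", comments="",
        )
    sidecar = {
        "record_id": record.record_id,
        "sample_rate": record.sample_rate,
        "n_samples": record.n_samples,
        "stage1_span": list(record.stage1_span),
        "stage2_span": list(record.stage2_span) if record.stage2_span else None,
        "invalid_runs": _mask_to_runs(record.mask),
        "meta": asdict(record.meta),
    }
    (path / "record.json").write_text(json.dumps(sidecar, indent=1))
    return path


def _read_channel(path: Path, name: str) -> np.ndarray:
    f = path / f"{name}.csv"
    if not f.exists():
        raise FileNotFoundError(f"missing channel file {f}")
    df = pd.read_csv(f, float_precision="round_trip")
    if "value" not in df.columns:
        raise ValueError(f"{f}: expected columns time_s,value")
    return df["value"].to_numpy(dtype=float)


def read_record(path: str | Path) -> CTGRecord:
    """Read a record written by :func:`write_record`."""
    path = Path(path)
    sidecar_file = path / "record.json"
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    for key in ("sample_rate", "n_samples", "stage1_span", "invalid_runs"):
        if key not in sidecar:
            raise ValueError(f"malformed sidecar: missing field {key!r}")
    fhr = _read_channel(path, "fhr")
    ucp = _read_channel(path, "ucp")
    n = sidecar["n_samples"]
    if len(fhr) != n or len(ucp) != n:
        raise ValueError(
            f"channel length mismatch: sidecar says {n}, "
            f"fhr has {len(fhr)}, ucp has {len(ucp)}"
        )
    return CTGRecord(
        fhr=fhr,
        ucp=ucp,
        mask=_runs_to_mask(sidecar["invalid_runs"], n),
        sample_rate=sidecar["sample_rate"],
        stage1_span=tuple(sidecar["stage1_span"]),
        stage2_span=tuple(sidecar["stage2_span"]) if sidecar.get("stage2_span") else None,
        meta=RecordMeta(**sidecar.get("meta", {})),
        record_id=sidecar.get("record_id", path.name),
    )


def read_wfdb_record(path: str | Path, **meta_kwargs) -> CTGRecord:
    """Read a WFDB-format intrapartum record (FHR + UC channels).

    Requires the optional ``wfdb`` package (``pip install ctgkit[wfdb]``).
    """
    try:
        import wfdb  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "WFDB support needs the optional 'wfdb' package: "
            "pip install ctgkit[wfdb]"
        ) from exc
    rec = wfdb.rdrecord(str(path))  # pragma: no cover - optional dependency
    sig = rec.p_signal  # pragma: no cover
    fhr, ucp = sig[:, 0], sig[:, 1]  # pragma: no cover
    mask = np.isfinite(fhr) & (fhr > 0)  # pragma: no cover
    return CTGRecord(  # pragma: no cover
        fhr=np.where(mask, fhr, 0.0),
        ucp=np.nan_to_num(ucp),
        mask=mask,
        sample_rate=float(rec.fs),
        stage1_span=(0, len(fhr)),
        meta=RecordMeta(**meta_kwargs),
        record_id=str(path),
    )
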