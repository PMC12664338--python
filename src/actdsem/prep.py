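"""Accelerometer-count preprocessing and wear-protocol application.

Implements the measurement protocol used throughout: 10 s vertical-axis
counts are collapsed to 60 s epochs (counts per minute, cpm); non-wear time
is any stretch of >= 60 consecutive low-count minutes (all counts <= 100)
containing at most 2 minutes with counts in (0, 100]; wear minutes below
100 cpm are sedentary behavior (SB), at or above 100 cpm physical activity
(PA). A day is valid at >= 500 wear minutes, and a participant is included
with >= 4 valid days of which at least one falls on a weekend.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    PREDICTOR_COLUMNS,
    DayRecord,
    EpochSeries,
    MinuteLabel,
    PanelDataset,
    ParticipantValidity,
)

DEFAULT_MIN_WEAR = 500
DEFAULT_MIN_VALID_DAYS = 4
DEFAULT_REQUIRE_WEEKEND_DAYS = 1
DEFAULT_CUTPOINT_CPM = 100
DEFAULT_NONWEAR_WINDOW_MIN = 60
DEFAULT_ALLOWANCE_MIN = 2
DEFAULT_LOW_COUNT_MAX = 100


def collapse_epochs(raw: EpochSeries) -> EpochSeries:
    """Collapse a 10 s count series to 60 s epochs (cpm).

    Each minute's count is the sum of its six 10 s counts. Leading epochs
    before the first minute boundary and any trailing incomplete minute are
    dropped (counts are never fabricated by padding).
    """
    if raw.epoch_length_s != 10:
        raise ValueError(
            f"unsupported resolution: epoch_length_s={raw.epoch_length_s}, expected 10"
        )
    start = raw.start_time
    counts = raw.counts
    offset_s = (start - start.floor("min")).total_seconds()
    if offset_s:
        skip = int(round((60 - offset_s) / 10))
        warnings.warn(
            f"series for {raw.person_id} does not start on a minute boundary; "
            f"dropping {skip} leading epoch(s)",
            stacklevel=2,
        )
        counts = counts[skip:]
        start = start.ceil("min")
    n_minutes, rem = divmod(counts.size, 6)
    if rem:
        warnings.warn(
            f"dropping {rem} trailing epoch(s) of an incomplete minute "
            f"for {raw.person_id}",
            stacklevel=2,
        )
        counts = counts[: n_minutes * 6]
    per_minute = counts.reshape(n_minutes, 6).sum(axis=1)
    return EpochSeries(
        person_id=raw.person_id,
        epoch_length_s=60,
        start_time=start,
        counts=per_minute,
    )


def detect_nonwear(
    series: EpochSeries,
    min_window_min: int = DEFAULT_NONWEAR_WINDOW_MIN,
    allowance_min: int = DEFAULT_ALLOWANCE_MIN,
    low_count_max: int = DEFAULT_LOW_COUNT_MAX,
) -> np.ndarray:
    """Flag non-wear minutes of a 60 s series.

    A minute is non-wear iff it lies inside some window of length
    >= ``min_window_min`` in which every count is <= ``low_count_max`` and
    at most ``allowance_min`` minutes have counts in (0, ``low_count_max``].
    Any count above ``low_count_max`` terminates every window through it.
    Allowance minutes inside a qualifying window count as non-wear time.

    Returns
    -------
    wear : boolean array, one per minute, True = wear.
    """
    if series.epoch_length_s != 60:
        raise ValueError("detect_nonwear expects a 60 s series")
    counts = series.counts
    n = counts.size
    wear = np.ones(n, dtype=bool)
    if n == 0:
        return wear

    low = counts <= low_count_max
    nonzero_low = low & (counts > 0)
    # Sliding window over each maximal low run: for each right end r the
    # longest admissible window is [l(r), r] with at most `allowance_min`
    # nonzero minutes; any admissible window ending at r is inside it.
    i = 0
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while j < n and low[j]:
            j += 1
        # run is [i, j)
        left = i
        nz_in = 0
        painted_to = i  # minutes < painted_to already marked
        for r in range(i, j):
            if nonzero_low[r]:
                nz_in += 1
            while nz_in > allowance_min:
                if nonzero_low[left]:
                    nz_in -= 1
                left += 1
            if r - left + 1 >= min_window_min:
                a = max(left, painted_to)
                wear[a : r + 1] = False
                painted_to = r + 1
        i = j
    return wear


def classify_minutes(
    series: EpochSeries,
    wear: np.ndarray,
    cutpoint_cpm: int = DEFAULT_CUTPOINT_CPM,
) -> np.ndarray:
    """Label each minute NONWEAR, SB (< cut-point) or PA (>= cut-point)."""
    if series.epoch_length_s != 60:
        raise ValueError("classify_minutes expects a 60 s series")
    wear = np.asarray(wear, dtype=bool)
    if wear.shape != series.counts.shape:
        raise ValueError(
            f"wear mask length {wear.size} does not match series length {series.counts.size}"
        )
    labels = np.full(series.counts.size, MinuteLabel.NONWEAR, dtype=np.int8)
    labels[wear & (series.counts < cutpoint_cpm)] = MinuteLabel.SB
    labels[wear & (series.counts >= cutpoint_cpm)] = MinuteLabel.PA
    return labels


def summarize_day(
    labels: np.ndarray,
    date: pd.Timestamp,
    person_id: str,
    min_wear: int = DEFAULT_MIN_WEAR,
) -> DayRecord:
    """Summarize one calendar day of minute labels into a DayRecord."""
    labels = np.asarray(labels)
    if labels.size > 1440:
        raise ValueError(f"day {date} has {labels.size} > 1440 minutes")
    date = pd.Timestamp(date).normalize()
    sb = int((labels == MinuteLabel.SB).sum())
    pa = int((labels == MinuteLabel.PA).sum())
    wear = sb + pa
    return DayRecord(
        person_id=person_id,
        date=date,
        is_weekend=date.dayofweek >= 5,
        wear_min=wear,
        sb_min=sb,
        pa_min=pa,
        valid_day=wear >= min_wear,
    )


def summarize_days(
    series: EpochSeries,
    labels: np.ndarray,
    min_wear: int = DEFAULT_MIN_WEAR,
) -> list[DayRecord]:
    """Split a labeled 60 s series into calendar days and summarize each.

    First and last partial days are processed as-is; the validity
    threshold deals with their shortness.
    """
    times = series.times()
    if times.duplicated().any():
        raise ValueError("duplicate minutes in series")
    frame = pd.DataFrame({"label": labels, "date": times.normalize()})
    records = []
    for date, group in frame.groupby("date", sort=True):
        records.append(
            summarize_day(group["label"].to_numpy(), date, series.person_id, min_wear)
        )
    return records


def apply_protocol(
    days: Sequence[DayRecord],
    min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
    require_weekend_days: int = DEFAULT_REQUIRE_WEEKEND_DAYS,
) -> ParticipantValidity:
    """Decide inclusion: >= `min_valid_days` valid days, enough on weekends."""
    ids = {d.person_id for d in days}
    if len(ids) > 1:
        raise ValueError(f"mixed person_ids in day records: {sorted(ids)}")
    person_id = days[0].person_id if days else ""
    n_valid = sum(d.valid_day for d in days)
    n_weekend = sum(d.valid_day and d.is_weekend for d in days)
    return ParticipantValidity(
        person_id=person_id,
        n_valid_days=n_valid,
        n_valid_weekend_days=n_weekend,
        included=n_valid >= min_valid_days and n_weekend >= require_weekend_days,
    )


def process_person(
    raw: EpochSeries,
    min_wear: int = DEFAULT_MIN_WEAR,
    cutpoint_cpm: int = DEFAULT_CUTPOINT_CPM,
    min_window_min: int = DEFAULT_NONWEAR_WINDOW_MIN,
    allowance_min: int = DEFAULT_ALLOWANCE_MIN,
    low_count_max: int = DEFAULT_LOW_COUNT_MAX,
) -> list[DayRecord]:
    """Full per-person chain: collapse -> non-wear -> classify -> day records."""
    series = collapse_epochs(raw) if raw.epoch_length_s == 10 else raw
    wear = detect_nonwear(series, min_window_min, allowance_min, low_count_max)
    labels = classify_minutes(series, wear, cutpoint_cpm)
    return summarize_days(series, labels, min_wear)


def build_panel(
    day_records: Iterable[DayRecord],
    predictors: pd.DataFrame | Mapping[str, Mapping[str, float]],
    min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
    require_weekend_days: int = DEFAULT_REQUIRE_WEEKEND_DAYS,
    max_days: int = 7,
    predictor: str = "pain",
) -> tuple[PanelDataset, list[ParticipantValidity]]:
    """Join included persons' day records with person-level predictors.

    Day indices run 1..`max_days` by calendar offset from each person's
    first recorded day; invalid days appear as missing. Persons without a
    predictor row are dropped with a warning.

    Returns the panel and the per-person inclusion decisions (all persons,
    including the excluded ones, for the run manifest).
    """
    if not isinstance(predictors, pd.DataFrame):
        predictors = pd.DataFrame.from_dict(predictors, orient="index")
    if predictors.index.name != "person_id" and "person_id" in predictors.columns:
        predictors = predictors.set_index("person_id")
    predictors.index = predictors.index.astype(str)

    by_person: dict[str, list[DayRecord]] = {}
    for rec in day_records:
        by_person.setdefault(rec.person_id, []).append(rec)

    validities = []
    rows = []
    for pid, recs in by_person.items():
        validity = apply_protocol(recs, min_valid_days, require_weekend_days)
        validities.append(validity)
        if not validity.included:
            continue
        if pid not in predictors.index:
            warnings.warn(f"no predictor for included person {pid}; dropped", stacklevel=2)
            continue
        pred_row = predictors.loc[pid]
        recs = sorted(recs, key=lambda r: r.date)
        first = recs[0].date
        for rec in recs:
            day_index = (rec.date - first).days + 1
            if day_index > max_days:
                continue
            row = {
                "person_id": pid,
                "day_index": day_index,
                "date": rec.date,
                "is_weekend": rec.is_weekend,
                "wear_min": rec.wear_min,
                "sb_min": float(rec.sb_min) if rec.valid_day else np.nan,
                "pa_min": float(rec.pa_min) if rec.valid_day else np.nan,
                "valid_day": rec.valid_day,
            }
            for col in PREDICTOR_COLUMNS:
                row[col] = float(pred_row[col]) if col in pred_row.index else np.nan
            rows.append(row)
    if not rows:
        raise ValueError("no included persons with predictors; cannot build panel")
    data = pd.DataFrame(rows).sort_values(["person_id", "day_index"]).reset_index(drop=True)
    return PanelDataset(data=data, predictor=predictor), validities
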