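"""Epoch-level accelerometer processing: wear screening and intensity bands.

Input is a stream of 60-second epochs, each carrying an estimated MET value;
a MET of exactly 0 is the sentinel for "no acceleration signal" (the device
reports >= 0.9 MET whenever it is worn).  The processing chain is:

1. non-wear detection — a run of consecutive zero-MET epochs longer than
   60 minutes is non-wear;
2. intensity banding of worn epochs — SB at <= 1.5 MET, MVPA at >= 3.0 MET,
   LPA in between;
3. valid-day screening — a day counts if wear time is at least 600 minutes
   (10 hours);
4. valid-participant screening — a participant is included with 4 or more
   valid days;
5. composition — pooled band minutes over valid days divided by pooled wear
   time (a day-mean variant is available for sensitivity analyses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coda import close

EPOCHS_PER_DAY = 1440

SB_MAX_MET = 1.5
MVPA_MIN_MET = 3.0
NONWEAR_RUN_MIN = 60
VALID_DAY_WEAR_MIN = 600
MIN_VALID_DAYS = 4

#: integer band codes used in vectorized classification
NONWEAR, SB, LPA, MVPA = 0, 1, 2, 3


@dataclass(frozen=True)
class DaySummary:
    """Wear and band minutes for one participant-day."""

    participant_id: str
    date: str
    wear_minutes: int
    sb_minutes: int
    lpa_minutes: int
    mvpa_minutes: int
    nonwear_minutes: int
    valid: bool


@dataclass(frozen=True)
class ParticipantActivity:
    """Screened per-participant totals over valid days."""

    participant_id: str
    n_days: int
    n_valid_days: int
    total_wear: int
    total_sb: int
    total_lpa: int
    total_mvpa: int
    mean_wear: float
    mean_sb: float
    mean_lpa: float
    mean_mvpa: float
    included: bool
    exclusion_reason: str | None


def _check_day(met) -> np.ndarray:
    a = np.asarray(met, dtype=float)
    if a.ndim != 1 or a.size != EPOCHS_PER_DAY:
        raise ValueError(f"a day is {EPOCHS_PER_DAY} epochs, got shape {a.shape}")
    if np.any(a < 0) or not np.all(np.isfinite(a)):
        raise ValueError("MET values must be finite and non-negative")
    return a


def detect_nonwear(met, run_minutes: int = NONWEAR_RUN_MIN, *, strict: bool = True) -> np.ndarray:
    """Boolean mask over a 1440-epoch day marking non-wear epochs.

    An epoch is non-wear when it belongs to a run of consecutive zero-MET
    epochs whose length exceeds ``run_minutes`` (strictly by default; set
    ``strict=False`` for the >=-threshold convention used by some groups).
    """
    a = _check_day(met)
    zero = a == 0.0
    mask = np.zeros(a.size, dtype=bool)
    if not zero.any():
        return mask
    # run-length encode the zero indicator
    edges = np.flatnonzero(np.diff(zero.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges + 1, a.size]
    for s, e in zip(starts, ends):
        if not zero[s]:
            continue
        length = e - s
        if (length > run_minutes) if strict else (length >= run_minutes):
            mask[s:e] = True
    return mask


def classify_intensity(met):
    """Band worn epochs: SB (<=1.5 MET), LPA, or MVPA (>=3.0 MET).

    Accepts a scalar or array of strictly positive MET values; classifying a
    zero (non-worn) epoch is a contract violation and raises.
    Returns the integer codes ``SB``/``LPA``/``MVPA``.
    """
    a = np.asarray(met, dtype=float)
    if np.any(a <= 0):
        raise ValueError("cannot classify a non-worn (MET == 0) epoch")
    band = np.where(a <= SB_MAX_MET, SB, np.where(a >= MVPA_MIN_MET, MVPA, LPA))
    return band.item() if np.isscalar(met) or a.ndim == 0 else band


def summarize_day(
    met,
    participant_id: str = "",
    date: str = "",
    *,
    nonwear_run: int = NONWEAR_RUN_MIN,
    strict_nonwear: bool = True,
    valid_wear: int = VALID_DAY_WEAR_MIN,
) -> DaySummary:
    """Screen one day: wear epochs are worn (MET > 0) and not in a non-wear run."""
    a = _check_day(met)
    nonwear_mask = detect_nonwear(a, nonwear_run, strict=strict_nonwear)
    worn = (a > 0) & ~nonwear_mask
    bands = np.zeros(a.size, dtype=int)
    bands[worn] = classify_intensity(a[worn])
    sb = int(np.count_nonzero(bands == SB))
    lpa = int(np.count_nonzero(bands == LPA))
    mvpa = int(np.count_nonzero(bands == MVPA))
    wear = sb + lpa + mvpa
    return DaySummary(
        participant_id=participant_id,
        date=date,
        wear_minutes=wear,
        sb_minutes=sb,
        lpa_minutes=lpa,
        mvpa_minutes=mvpa,
        nonwear_minutes=int(nonwear_mask.sum()),
        valid=wear >= valid_wear,
    )


def screen_participant(
    days: list[DaySummary], *, min_valid_days: int = MIN_VALID_DAYS
) -> ParticipantActivity:
    """Aggregate day summaries; totals and means use valid days only."""
    if not days:
        raise ValueError("screen_participant needs at least one DaySummary")
    pid = days[0].participant_id
    valid = [d for d in days if d.valid]
    n_valid = len(valid)
    included = n_valid >= min_valid_days
    tw = sum(d.wear_minutes for d in valid)
    ts = sum(d.sb_minutes for d in valid)
    tl = sum(d.lpa_minutes for d in valid)
    tm = sum(d.mvpa_minutes for d in valid)
    denom = max(n_valid, 1)
    return ParticipantActivity(
        participant_id=pid,
        n_days=len(days),
        n_valid_days=n_valid,
        total_wear=tw,
        total_sb=ts,
        total_lpa=tl,
        total_mvpa=tm,
        mean_wear=tw / denom,
        mean_sb=ts / denom,
        mean_lpa=tl / denom,
        mean_mvpa=tm / denom,
        included=included,
        exclusion_reason=None if included else "insufficient_valid_days",
    )


def participant_composition(activity: ParticipantActivity, *, method: str = "pooled", days: list[DaySummary] | None = None) -> np.ndarray:
    """3-part wear-time composition (SB, LPA, MVPA) of an included participant.

    ``method="pooled"`` (default) divides pooled band minutes over valid days
    by pooled wear time; ``method="day_mean"`` averages the daily proportion
    vectors instead and needs the day summaries.  Zero parts are preserved
    (they sum to 1 with the rest) and must be handled downstream by the zero
    replacement policy before any log-ratio step.
    """
    if not activity.included:
        raise ValueError(f"participant {activity.participant_id} is not included")
    if method == "pooled":
        if activity.total_wear <= 0:
            raise ValueError("composition undefined for zero total wear")
        return close([activity.total_sb, activity.total_lpa, activity.total_mvpa])
    if method == "day_mean":
        if days is None:
            raise ValueError("day_mean composition needs the day summaries")
        mats = [
            close([d.sb_minutes, d.lpa_minutes, d.mvpa_minutes])
            for d in days
            if d.valid and d.wear_minutes > 0
        ]
        return close(np.mean(mats, axis=0))
    raise ValueError(f"unknown composition method {method!r}")


# ---------------------------------------------------------------------------
# DataFrame-level drivers for the epochs CSV dialect
# ---------------------------------------------------------------------------

def process_epochs(
    epochs: pd.DataFrame,
    *,
    nonwear_run: int = NONWEAR_RUN_MIN,
    strict_nonwear: bool = True,
    valid_wear: int = VALID_DAY_WEAR_MIN,
    min_valid_days: int = MIN_VALID_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full screen over a long-format epochs table.

    Expects columns ``participant_id, date, epoch_index, met_value`` with one
    row per epoch (0..1439 per day).  Returns (day table, participant table);
    the participant table carries the pooled composition columns ``t_sb``,
    ``t_lpa``, ``t_mvpa`` for included participants and the exclusion reason
    otherwise.
    """
    required = {"participant_id", "date", "epoch_index", "met_value"}
    missing = required - set(epochs.columns)
    if missing:
        raise ValueError(f"epochs table is missing columns: {sorted(missing)}")

    day_rows: list[DaySummary] = []
    part_rows: list[dict] = []
    for pid, pgrp in epochs.groupby("participant_id", sort=True):
        summaries: list[DaySummary] = []
        for date, dgrp in pgrp.groupby("date", sort=True):
            idx = dgrp["epoch_index"].to_numpy()
            if len(idx) != EPOCHS_PER_DAY or not np.array_equal(np.sort(idx), np.arange(EPOCHS_PER_DAY)):
                raise ValueError(f"participant {pid} day {date}: need exactly one row per epoch 0..1439")
            met = dgrp.sort_values("epoch_index")["met_value"].to_numpy()
            summaries.append(
                summarize_day(
                    met, str(pid), str(date),
                    nonwear_run=nonwear_run, strict_nonwear=strict_nonwear,
                    valid_wear=valid_wear,
                )
            )
        day_rows.extend(summaries)
        act = screen_participant(summaries, min_valid_days=min_valid_days)
        row = act.__dict__.copy()
        if act.included:
            comp = participant_composition(act)
            row.update(t_sb=comp[0], t_lpa=comp[1], t_mvpa=comp[2])
        else:
            row.update(t_sb=np.nan, t_lpa=np.nan, t_mvpa=np.nan)
        part_rows.append(row)

    day_df = pd.DataFrame([d.__dict__ for d in day_rows])
    part_df = pd.DataFrame(part_rows)
    return day_df, part_df


def read_epochs_csv(path) -> pd.DataFrame:
    """Read the epochs CSV dialect written by the synthetic generator."""
    return pd.read_csv(path, dtype={"participant_id": str, "date": str})
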