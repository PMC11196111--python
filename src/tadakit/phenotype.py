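"""Drosophila activity-monitor (DAM) analysis.

Beam-crossing counts per fly per time bin are annotated for sleep (the fly
convention: five or more consecutive minutes without a beam crossing),
censored at death (terminal immobility longer than 24 h), summarised into
daily activity/sleep statistics and anticipation indices around light
transitions, folded into actograms, and tested for rhythmicity with the
chi-square periodogram.  The corrected-total-cell-fluorescence formula used
for immunofluorescence quantification lives here too, since it shares the
phenotype reporting surface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

logger = logging.getLogger("tadakit")

MIN_PER_DAY = 1440
DEATH_IMMOBILITY_MIN = 1440  # immobility strictly longer than 24 h = death
SLEEP_RUN_MIN = 5


@dataclass
class ActivitySeries:
    """Per-fly binned beam-crossing counts with an optional light schedule."""

    fly_id: str
    bin_minutes: int
    counts: np.ndarray
    light: np.ndarray | None = None  # 'L'/'D' per bin
    start: datetime | None = None

    def __post_init__(self) -> None:
        if MIN_PER_DAY % self.bin_minutes != 0:
            raise ValueError("bin width must divide 1440 minutes")
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.light is not None:
            self.light = np.asarray(self.light)
            if len(self.light) != len(self.counts):
                raise ValueError("light schedule length != counts length")

    @property
    def bins_per_day(self) -> int:
        return MIN_PER_DAY // self.bin_minutes

    @property
    def n_days(self) -> int:
        return len(self.counts) // self.bins_per_day


def make_light_schedule(
    n_bins: int,
    bin_minutes: int,
    photoperiod_hours: float = 12.0,
    dd_from_day: int | None = None,
) -> np.ndarray:
    """L/D label per bin for a recording starting at lights-on (ZT0).

    Days counted from 0; from ``dd_from_day`` on the flies are in constant
    darkness.
    """
    t_min = np.arange(n_bins) * bin_minutes
    day = t_min // MIN_PER_DAY
    in_photo = (t_min % MIN_PER_DAY) < photoperiod_hours * 60
    light = np.where(in_photo, "L", "D")
    if dd_from_day is not None:
        light = np.where(day >= dd_from_day, "D", light)
    return light


def parse_dam_file(path_or_lines, bin_minutes: int) -> list[ActivitySeries]:
    """Parse a Trikinetics DAM monitor text file.

    Tab-delimited rows: record index, date (``1 Jan 20`` style), time,
    monitor status, any number of device columns, and finally 32 per-channel
    count columns.  Rows whose status is not 1 are excluded with a warning;
    a gap in the timestamp sequence is an error listing the missing
    interval.
    """
    if isinstance(path_or_lines, (str, Path)):
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    times: list[datetime] = []
    rows: list[list[int] | None] = []
    start: datetime | None = None
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 4 + 32:
            raise ValueError(f"malformed DAM row at line {ln}: too few columns")
        try:
            stamp = datetime.strptime(f[1] + " " + f[2], "%d %b %y %H:%M:%S")
            status = int(f[3])
            counts = [int(x) for x in f[-32:]]
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed DAM row at line {ln}: {exc}") from exc
        if times:
            expected = times[-1] + timedelta(minutes=bin_minutes)
            if stamp != expected:
                raise ValueError(
                    f"timestamp gap before line {ln}: expected {expected}, got {stamp}"
                )
        else:
            start = stamp
        times.append(stamp)
        if status != 1:
            logger.warning("line %d: monitor status %d, row excluded", ln, status)
            rows.append(None)
        else:
            rows.append(counts)
    valid = [r for r in rows if r is not None]
    if not valid:
        raise ValueError("no valid rows in DAM file")
    mat = np.array(valid, dtype=int)
    return [
        ActivitySeries(f"ch{i + 1}", bin_minutes, mat[:, i], start=start)
        for i in range(32)
    ]


def detect_death(series: ActivitySeries, death_anywhere: bool = False) -> int | None:
    """First bin of a death event, or None.

    Death is a zero-count run longer than 24 h that extends to the end of
    the record (the record-ending semantics of monitor censoring); with
    ``death_anywhere`` any such run qualifies and the earliest wins.
    """
    counts = series.counts
    run_bins_needed = DEATH_IMMOBILITY_MIN // series.bin_minutes
    if death_anywhere:
        run = 0
        for i, c in enumerate(counts):
            run = run + 1 if c == 0 else 0
            if c == 0 and run > run_bins_needed:
                return i - run + 1
        return None
    n = len(counts)
    i = n
    while i > 0 and counts[i - 1] == 0:
        i -= 1
    terminal_run = n - i
    if terminal_run > run_bins_needed:
        return i
    return None


def censor_at_death(series: ActivitySeries, death_anywhere: bool = False
                    ) -> tuple[ActivitySeries, int | None]:
    """Drop all data from the death bin on (no-op for living flies)."""
    death = detect_death(series, death_anywhere=death_anywhere)
    if death is None:
        return series, None
    return (
        ActivitySeries(
            series.fly_id, series.bin_minutes, series.counts[:death],
            None if series.light is None else series.light[:death],
            series.start,
        ),
        death,
    )


@dataclass
class SleepAnnotation:
    sleep: np.ndarray  # bool per (censored) bin
    bouts: list[tuple[int, int]]  # maximal sleep runs, [start, end] inclusive bins
    death_bin: int | None


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask) - 1))
    return out


def score_sleep(series: ActivitySeries) -> SleepAnnotation:
    """Sleep = >=5 consecutive minutes of inactivity.

    On 1-min bins a bin is asleep when it belongs to a run of >=5 zero
    bins; on 5-min bins every zero bin counts as sleep.  Bouts are maximal
    sleep runs.  Death is detected first and sleep is only scored before it.
    """
    if series.bin_minutes not in (1, 5):
        raise ValueError("sleep scoring defined for 1- or 5-min bins")
    censored, death = censor_at_death(series)
    zero = censored.counts == 0
    if series.bin_minutes == 1:
        sleep = np.zeros(len(zero), dtype=bool)
        for s, e in _runs(zero):
            if e - s + 1 >= SLEEP_RUN_MIN:
                sleep[s : e + 1] = True
    else:
        sleep = zero.copy()
    return SleepAnnotation(sleep, _runs(sleep), death)


def behavior_summary(series_list: Sequence[ActivitySeries]) -> pd.DataFrame:
    """Per fly per day: mean activity/bin, sleep minutes (total and per
    12-h photophase/scotophase half, anchored at the day start = lights-on),
    and sleep-bout counts per half.  Only full, death-censored days enter.
    """
    rows = []
    for series in series_list:
        censored, death = censor_at_death(series)
        ann = score_sleep(series)
        bpd = series.bins_per_day
        half = bpd // 2
        for day in range(len(censored.counts) // bpd):
            sl = slice(day * bpd, (day + 1) * bpd)
            counts = censored.counts[sl]
            sleep = ann.sleep[sl]
            bouts_day = _runs(sleep)
            photo = sleep[:half]
            scoto = sleep[half:]
            rows.append(
                {
                    "fly_id": series.fly_id,
                    "day": day,
                    "mean_activity": float(counts.mean()),
                    "sleep_min": int(sleep.sum()) * series.bin_minutes,
                    "sleep_min_photophase": int(photo.sum()) * series.bin_minutes,
                    "sleep_min_scotophase": int(scoto.sum()) * series.bin_minutes,
                    "bouts_photophase": len(_runs(photo)),
                    "bouts_scotophase": len(_runs(scoto)),
                    "n_bouts": len(bouts_day),
                }
            )
    return pd.DataFrame(rows)


def group_mean_sd(summary: pd.DataFrame, column: str) -> tuple[float, float]:
    """Group mean and SD across flies of the per-fly mean of ``column``."""
    per_fly = summary.groupby("fly_id")[column].mean()
    return float(per_fly.mean()), float(per_fly.std(ddof=1))


def anticipation_index(
    series: ActivitySeries,
    transition: str = "lights_on",
    photoperiod_hours: float = 12.0,
) -> tuple[float, list[float]]:
    """Anticipation ratio: activity in the 3 h before a light transition over
    activity in the 6 h before it, averaged over days.

    The recording is assumed to start at lights-on (ZT0); lights-on
    transitions then fall at day boundaries and lights-off at ZT
    ``photoperiod_hours``.  Days where the 6-h window has no activity are
    excluded with a warning.  Ratios lie in [0, 1].
    """
    bpd = series.bins_per_day
    per_hour = 60 // series.bin_minutes
    w6, w3 = 6 * per_hour, 3 * per_hour
    if transition == "lights_on":
        # transition at the start of each day d>=1
        points = [d * bpd for d in range(1, series.n_days + 1)]
    elif transition == "lights_off":
        off = int(photoperiod_hours * per_hour)
        points = [d * bpd + off for d in range(series.n_days)]
    else:
        raise ValueError(f"unknown transition {transition!r}")
    ratios = []
    for t in points:
        if t - w6 < 0 or t > len(series.counts):
            continue
        window6 = series.counts[t - w6 : t]
        window3 = series.counts[t - w3 : t]
        total = window6.sum()
        if total == 0:
            logger.warning("%s: no activity in 6-h window before bin %d; day skipped",
                           series.fly_id, t)
            continue
        ratios.append(float(window3.sum() / total))
    mean = float(np.mean(ratios)) if ratios else float("nan")
    return mean, ratios


def resample_to_5min(series: ActivitySeries) -> ActivitySeries:
    """Sum 1-min counts into 5-min bins (no-op on 5-min data)."""
    if series.bin_minutes == 5:
        return series
    if series.bin_minutes != 1:
        raise ValueError("resampling defined from 1-min data")
    n = len(series.counts) // 5 * 5
    counts = series.counts[:n].reshape(-1, 5).sum(axis=1)
    light = None
    if series.light is not None:
        light = series.light[:n:5]
    return ActivitySeries(series.fly_id, 5, counts, light, series.start)


def actogram_matrix(series: ActivitySeries, double_plot: bool = False) -> np.ndarray:
    """Day x 288 matrix of 5-min counts; double-plot concatenates day d with
    day d+1 (rows = n_days - 1).  A partial final day is dropped with a
    warning."""
    s5 = resample_to_5min(series)
    bpd = s5.bins_per_day  # 288
    n_days = len(s5.counts) // bpd
    if len(s5.counts) % bpd:
        logger.warning("%s: partial final day dropped from actogram", series.fly_id)
    mat = s5.counts[: n_days * bpd].reshape(n_days, bpd)
    if not double_plot:
        return mat
    if n_days < 2:
        raise ValueError("double plot needs >=2 full days")
    return np.hstack([mat[:-1], mat[1:]])


@dataclass
class PeriodogramResult:
    periods_min: np.ndarray  # tested periods, minutes
    qp: np.ndarray
    critical: np.ndarray
    power: np.ndarray  # qp - critical
    best_period_min: float
    rhythmic: bool


def chi_square_periodogram(
    series: ActivitySeries,
    period_min_minutes: float = 18 * 60,
    period_max_minutes: float = 30 * 60,
    alpha: float = 0.05,
) -> PeriodogramResult:
    """Chi-square periodogram over candidate periods in 1-bin steps.

    For a candidate period of P bins, the record is cut into K = floor(N/P)
    complete cycles (N' = K*P bins used); with column means M_h over the K
    cycles and grand mean M,

        Qp = K * sum_h (M_h - M)^2 / ((1/N') * sum_i (X_i - M)^2),

    which is ~ chi-square with P-1 df under an iid null.  Power is Qp minus
    the (1-alpha) chi-square critical value; the best period maximises
    power, and the fly is rhythmic when the maximum power is positive.  A
    constant record gives Qp = 0 everywhere (zero denominator guarded).
    """
    counts = series.counts.astype(float)
    n = len(counts)
    bw = series.bin_minutes
    p_lo = max(2, int(np.ceil(period_min_minutes / bw)))
    p_hi = int(np.floor(period_max_minutes / bw))
    if p_hi < p_lo:
        raise ValueError("period search range is empty at this bin width")
    if n < 3 * p_hi:
        logger.warning("%s: fewer than 3 cycles of data at the longest tested "
                       "period", series.fly_id)
    periods = np.arange(p_lo, p_hi + 1)
    qp = np.zeros(len(periods))
    for i, P in enumerate(periods):
        K = n // P
        if K < 1:
            qp[i] = 0.0
            continue
        x = counts[: K * P]
        grand = x.mean()
        col_means = x.reshape(K, P).mean(axis=0)
        denom = ((x - grand) ** 2).sum() / (K * P)
        if denom == 0:
            qp[i] = 0.0
        else:
            qp[i] = K * ((col_means - grand) ** 2).sum() / denom
    critical = chi2.ppf(1.0 - alpha, periods - 1)
    power = qp - critical
    best = int(np.argmax(power))
    return PeriodogramResult(
        periods_min=periods * bw,
        qp=qp,
        critical=critical,
        power=power,
        best_period_min=float(periods[best] * bw),
        rhythmic=bool(power[best] > 0),
    )


def percent_rhythmic(results: Sequence[PeriodogramResult]) -> dict:
    """Fraction of rhythmic flies and the per-fly classification table.

    Flies whose best period is strictly above 1440 min are classified
    long-period.  Pass only non-censored (living) flies.
    """
    if not results:
        raise ValueError("empty group")
    table = pd.DataFrame(
        {
            "rhythmic": [r.rhythmic for r in results],
            "best_period_min": [r.best_period_min for r in results],
        }
    )
    table["long_period"] = table["best_period_min"] > MIN_PER_DAY
    return {
        "fraction_rhythmic": float(table["rhythmic"].mean()),
        "table": table,
    }


def ctcf(integrated_density: float, area: float, mean_background: float) -> float:
    """Corrected total cell fluorescence:
    integrated density - area * mean background.  May be negative."""
    if area < 0:
        raise ValueError("area must be non-negative")
    return float(integrated_density - area * mean_background)
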