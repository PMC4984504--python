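"""Mesopelagic excursion (ME) detection and environmental annotation.

An ME is a maximal run of at least 5 consecutive records strictly below
the 200 m isobath, bounded on both sides by a record strictly above
200 m: the last above-200 record is the start of the excursion and the
first above-200 record after the run is its end, so every ME spans at
least 7 records.  Records at exactly 200.0 m count as neither above nor
below: they break a run and cannot serve as bounding records (ties are
resolved conservatively, yielding fewer MEs).  Runs touching a series or
segment boundary lack a bounding record and are discarded.

Each detected ME can be annotated with its diel period (dawn/day/dusk/
night from solar geometry), lunar phase quarter, date, OMZ class
(oxygen <= 3.5 mL/L), and an optional location.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import astro
from .errors import AnnotationError
from .tag_io import TagSeries

ME_DEPTH_M = 200.0
ME_MIN_RUN = 5
OMZ_THRESHOLD_ML_L = 3.5

OMZ_CLASSES = ("none", "apex_within", "passed_through")


@dataclass
class Excursion:
    """One detected mesopelagic excursion.

    ``record_slice`` is the inclusive [start, end] index pair into the
    parent series; ``frame`` carries the corresponding records.  The
    annotation fields (diel, lunar, OMZ class, location) are ``None``
    until filled by :func:`annotate_excursions` or the individual
    assign/classify operations.
    """

    individual_id: str
    record_slice: tuple
    frame: pd.DataFrame = field(repr=False)
    apex_index: int  # absolute index into the parent series
    max_depth: float
    min_temperature: float
    duration_min: float
    descent_duration_min: float
    ascent_duration_min: float
    diel_period: str | None = None
    lunar_phase: str | None = None
    date: dt.date | None = None
    location: tuple | None = None
    omz_class: str | None = None
    min_oxygen: float | None = None

    @property
    def start_time(self) -> pd.Timestamp:
        return self.frame["timestamp"].iloc[0]

    @property
    def end_time(self) -> pd.Timestamp:
        return self.frame["timestamp"].iloc[-1]

    @property
    def apex_time(self) -> pd.Timestamp:
        return self.frame["timestamp"].iloc[self.apex_index - self.record_slice[0]]

    @property
    def n_records(self) -> int:
        return len(self.frame)


def detect_excursions(
    series: TagSeries,
    depth_threshold_m: float = ME_DEPTH_M,
    min_run: int = ME_MIN_RUN,
) -> list[Excursion]:
    """Detect all qualifying mesopelagic excursions in a series.

    Gap-free segments are scanned independently; runs of fewer than
    ``min_run`` below-threshold records, and runs not bounded by strictly
    above-threshold records, are omitted.  Returns time-ordered,
    non-overlapping excursions (empty list when none qualify).
    """
    depth = series.depth
    out: list[Excursion] = []
    for seg_start, seg_end in series.segments():
        below = depth[seg_start : seg_end + 1] > depth_threshold_m
        n = below.size
        j = 0
        while j < n:
            if not below[j]:
                j += 1
                continue
            k = j
            while k + 1 < n and below[k + 1]:
                k += 1
            run_len = k - j + 1
            if (
                run_len >= min_run
                and j > 0
                and k < n - 1
                and depth[seg_start + j - 1] < depth_threshold_m
                and depth[seg_start + k + 1] < depth_threshold_m
            ):
                a = seg_start + j - 1  # bounding start record (above threshold)
                b = seg_start + k + 1  # bounding end record
                sl = series.frame.iloc[a : b + 1].reset_index(drop=True)
                d = sl["depth"].to_numpy()
                apex_rel = int(np.argmax(d))  # first occurrence of the maximum
                t = sl["timestamp"]
                dur = (t.iloc[-1] - t.iloc[0]).total_seconds() / 60.0
                desc = (t.iloc[apex_rel] - t.iloc[0]).total_seconds() / 60.0
                out.append(
                    Excursion(
                        individual_id=series.individual_id,
                        record_slice=(a, b),
                        frame=sl,
                        apex_index=a + apex_rel,
                        max_depth=float(d[apex_rel]),
                        min_temperature=float(sl["temperature"].min()),
                        duration_min=dur,
                        descent_duration_min=desc,
                        ascent_duration_min=dur - desc,
                    )
                )
            j = k + 1
    return out


# ---------------------------------------------------------------------------
# annotation

def classify_omz(exc: Excursion, oxygen) -> str:
    """OMZ encounter class for one excursion; also sets ``min_oxygen``.

    ``oxygen`` is either an :class:`~divetrace.synthetic_tracks.
    EnvironmentModel` or a two-column table/array of (depth_m,
    oxygen_ml_l) interpolated linearly.  Classes: ``none`` (no record at
    oxygen <= 3.5), ``apex_within`` (oxygen at the maximum depth <=
    3.5), ``passed_through`` (some record <= 3.5 but the apex has
    recovered above the threshold — the dive crossed the OMZ into
    oxygen-rich water).
    """
    depths = exc.frame["depth"].to_numpy(dtype=float)
    o = _resolve_oxygen(oxygen, depths)
    exc.min_oxygen = float(o.min())
    apex_o = float(o[np.argmax(depths)])
    if not np.any(o <= OMZ_THRESHOLD_ML_L):
        exc.omz_class = "none"
    elif apex_o <= OMZ_THRESHOLD_ML_L:
        exc.omz_class = "apex_within"
    else:
        exc.omz_class = "passed_through"
    return exc.omz_class


def _resolve_oxygen(oxygen, depths: np.ndarray) -> np.ndarray:
    from .synthetic_tracks import EnvironmentModel, oxygen_at_depth

    if isinstance(oxygen, EnvironmentModel):
        return np.asarray(oxygen_at_depth(oxygen, depths))
    table = np.asarray(
        oxygen[["depth_m", "oxygen_ml_l"]] if isinstance(oxygen, pd.DataFrame) else oxygen,
        dtype=float,
    )
    order = np.argsort(table[:, 0])
    td, to = table[order, 0], table[order, 1]
    if depths.max() > td.max() or depths.min() < td.min():
        raise AnnotationError(
            f"oxygen profile covers [{td.min()}, {td.max()}] m but the "
            f"excursion reaches {depths.max():.1f} m"
        )
    return np.interp(depths, td, to)


def assign_diel(
    timestamp, lat: float, lon: float, zenith_deg: float = 90.0
) -> tuple[str, dict]:
    """Diel period of a UTC timestamp plus the four period durations (h).

    Dawn is [sunrise - 1 h, sunrise + 1 h), dusk is [sunset - 1 h,
    sunset + 1 h), day and night are the remainder; the four durations
    partition the 24 h day.  Polar latitudes (|lat| > 66°) are
    unsupported.
    """
    ts = pd.Timestamp(timestamp)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    sr, ss = astro.sun_events_utc(ts.date(), lat, lon, zenith_deg)
    h = dt.timedelta(hours=1)
    t = ts.to_pydatetime()
    if sr - h <= t < sr + h:
        period = "dawn"
    elif ss - h <= t < ss + h:
        period = "dusk"
    elif sr + h <= t < ss - h:
        period = "day"
    else:
        period = "night"
    daylen_h = (ss - sr).total_seconds() / 3600.0
    durations = {
        "dawn": 2.0,
        "day": max(daylen_h - 2.0, 0.0),
        "dusk": 2.0,
        "night": max(24.0 - daylen_h - 2.0, 0.0),
    }
    return period, durations


def assign_lunar(date) -> str:
    """Lunar-phase quarter (new/first_quarter/full/last_quarter) of a date."""
    return astro.lunar_phase(pd.Timestamp(date).date() if not isinstance(date, dt.date) else date)


def daily_sst(series: TagSeries) -> dict:
    """Daily sea-surface temperature estimate: per-date maximum temperature."""
    f = series.frame
    grouped = f.groupby(f["timestamp"].dt.date)["temperature"].max()
    return {d: float(v) for d, v in grouped.items()}


def annotate_excursions(
    excursions: list[Excursion],
    lat: float,
    lon: float,
    oxygen=None,
    locations: dict | None = None,
    zenith_deg: float = 90.0,
) -> list[Excursion]:
    """Fill diel, lunar, date, location and OMZ annotations in place.

    ``locations`` optionally maps dates to (lat, lon) (e.g. filtered
    daily geolocations); absent dates fall back to the tagging-site
    coordinates given by ``lat``/``lon``.
    """
    for exc in excursions:
        exc.date = exc.start_time.date()
        loc = (locations or {}).get(exc.date, (lat, lon))
        exc.location = loc
        exc.diel_period, _ = assign_diel(exc.start_time, loc[0], loc[1], zenith_deg)
        exc.lunar_phase = assign_lunar(exc.date)
        if oxygen is not None:
            classify_omz(exc, oxygen)
    return excursions


def excursions_to_frame(excursions: list[Excursion]) -> pd.DataFrame:
    """One row per ME — the unit of analysis for all downstream stages."""
    rows = []
    for i, e in enumerate(excursions):
        rows.append(
            {
                "me_id": f"{e.individual_id}_{i:04d}",
                "individual_id": e.individual_id,
                "start": e.start_time.isoformat(),
                "end": e.end_time.isoformat(),
                "n_records": e.n_records,
                "max_depth_m": e.max_depth,
                "min_temperature_c": e.min_temperature,
                "duration_min": e.duration_min,
                "descent_duration_min": e.descent_duration_min,
                "ascent_duration_min": e.ascent_duration_min,
                "diel_period": e.diel_period,
                "lunar_phase": e.lunar_phase,
                "omz_class": e.omz_class,
                "min_oxygen_ml_l": e.min_oxygen,
            }
        )
    return pd.DataFrame(rows)
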