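"""Synthetic archival-tag tracks with ground-truth mesopelagic excursions.

The simulator emulates the vertical behaviour of an epipelagic shark
carrying a 2-min archival tag: a mean-reverting random walk in the mixed
layer (~90% of time above 100 m), rare excursions beyond 200 m with short
descents and longer ascents, three descent shape archetypes (linear,
slowing, delayed) and three ascent archetypes (linear, transition-point,
variable), a thermocline temperature–depth relation, and an oxygen
minimum zone (OMZ, oxygen <= 3.5 mL/L).

Every generated excursion satisfies the detection rule by construction:
its below-200 m records are parameterized between the 200 m crossing and
the apex on the sampling grid, so the interior run is strictly below
200 m and is bounded on both sides by above-200 m records.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .astro import sun_events_utc
from .errors import ConfigError
from .tag_io import TagSeries, write_tag_series

OMZ_THRESHOLD_ML_L = 3.5

DESCENT_SHAPES = ("linear", "slowing", "delayed")
ASCENT_SHAPES = ("linear", "transition_point", "variable")


@dataclass
class EnvironmentModel:
    """Idealized tropical water column: thermocline + OMZ.

    Temperature relaxes exponentially from the sea-surface temperature
    toward the deep value, ``T(d) = deep_temp + (sst - deep_temp) *
    exp(-d / thermocline_scale)``.  Oxygen is a continuous piecewise-
    linear "bathtub": it declines from the surface value to the OMZ
    threshold (3.5 mL/L) at ``omz_top``, dips to ``omz_min_oxygen`` at
    the band's core, returns to the threshold at ``omz_bottom`` and
    recovers to ``oxygen_deep`` below (oxygen-rich deep water), so the
    set {oxygen <= 3.5} is exactly [omz_top, omz_bottom].
    """

    sst: float = 27.5
    deep_temp: float = 4.5
    thermocline_scale: float = 350.0
    oxygen_surface: float = 4.8
    omz_top: float = 480.0
    omz_bottom: float = 820.0
    omz_min_oxygen: float = 2.8
    oxygen_deep: float = 4.3
    omz_recovery_scale: float = 60.0


def temperature_at_depth(env: EnvironmentModel, depth) -> np.ndarray | float:
    """Water temperature (°C) at depth (m); monotone non-increasing."""
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be non-negative")
    t = env.deep_temp + (env.sst - env.deep_temp) * np.exp(-d / env.thermocline_scale)
    return float(t) if np.isscalar(depth) else t


def oxygen_at_depth(env: EnvironmentModel, depth) -> np.ndarray | float:
    """Dissolved oxygen (mL/L) at depth (m); continuous piecewise linear."""
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be non-negative")
    boundary = OMZ_THRESHOLD_ML_L if env.omz_min_oxygen <= OMZ_THRESHOLD_ML_L else env.omz_min_oxygen
    mid = 0.5 * (env.omz_top + env.omz_bottom)
    knots_d = [0.0, env.omz_top, mid, env.omz_bottom, env.omz_bottom + env.omz_recovery_scale]
    knots_o = [env.oxygen_surface, boundary, env.omz_min_oxygen, boundary, env.oxygen_deep]
    o = np.interp(d, knots_d, knots_o)
    return float(o) if np.isscalar(depth) else o


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    Defaults follow the observed excursion regime: a 2-min sampling
    interval, ~0.2–0.3 excursions per day, apex depths 202–1190 m,
    descents around 6.6 ± 3.5 min and longer ascents around 14.4 ±
    7.2 min, and shape mixtures matching the relative abundance of the
    six profile clusters.
    """

    n_individuals: int = 10
    days: float = 30.0
    interval_s: float = 120.0
    me_rate_per_day: float = 0.25
    descent_shape_mix: dict = field(
        default_factory=lambda: {"linear": 0.58, "slowing": 0.33, "delayed": 0.09}
    )
    ascent_shape_mix: dict = field(
        default_factory=lambda: {"linear": 0.47, "transition_point": 0.37, "variable": 0.16}
    )
    apex_depth_range: tuple = (202.0, 1190.0)
    descent_duration_range: tuple = (2.0, 18.0)  # minutes
    ascent_duration_range: tuple = (4.0, 36.0)  # minutes
    descent_duration_mean_sd: tuple = (6.61, 3.53)  # minutes
    ascent_duration_mean_sd: tuple = (14.40, 7.16)  # minutes
    epipelagic_mixing_depth: float = 150.0
    depth_noise_sd: float = 1.0
    temp_noise_sd: float = 0.1
    seed: int = 0
    lat: float = 24.12
    lon: float = -75.28
    start_date: str = "2012-05-01"
    diel_rate_multipliers: dict | None = None
    pre_me_cooling_c: float = 0.0

    def __post_init__(self) -> None:
        for mix, shapes in (
            (self.descent_shape_mix, DESCENT_SHAPES),
            (self.ascent_shape_mix, ASCENT_SHAPES),
        ):
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ConfigError(f"shape mix must sum to 1: {mix}")
            if set(mix) - set(shapes):
                raise ConfigError(f"unknown shapes in mix: {mix}")
        if self.apex_depth_range[0] <= 200.0:
            raise ConfigError("apex depths must exceed 200 m")
        if self.me_rate_per_day < 0:
            raise ConfigError("me_rate_per_day must be >= 0")
        if self.epipelagic_mixing_depth >= 199.0:
            raise ConfigError("epipelagic mixing depth must stay above 199 m")
        d_lo, d_hi = self.descent_duration_range
        a_lo, a_hi = self.ascent_duration_range
        if not (0 < d_lo < d_hi and 0 < a_lo < a_hi):
            raise ConfigError("duration ranges must be increasing and positive")


@dataclass
class TruthExcursion:
    """Ground truth for one inserted excursion.

    ``start``/``end`` are the bounding above-200 m records.  For
    transition-point ascents, ``true_changepoint_s`` is measured from
    the apex record and ``segment_slopes`` are the two signed vertical
    velocities (m/s, ascending => negative, |slope1| > |slope2|).
    """

    individual_id: str
    start: dt.datetime
    end: dt.datetime
    apex_time: dt.datetime
    apex_depth: float
    descent_shape: str
    ascent_shape: str
    true_changepoint_s: float | None = None
    segment_slopes: tuple | None = None


# ---------------------------------------------------------------------------
# phase shape primitives (normalized progress curves f: [0,1] -> [0,1])

def _progress_linear(u: np.ndarray) -> np.ndarray:
    return u


def _progress_slowing(u: np.ndarray) -> np.ndarray:
    # decelerating approach to the apex: increments strictly decreasing
    return np.sin(0.5 * np.pi * u)


def _progress_delayed(u: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
    # slow start, acceleration toward the apex, with bounded reversals.
    # Shape parameters scatter tightly around the class archetype: each
    # class emulates an empirically discovered cluster (a compact shape
    # family), not a continuum of dive geometries.
    if rng is None:
        freq, phase, amp = 2.2, 0.5, 0.07
    else:
        freq = rng.uniform(2.0, 2.4)
        phase = rng.uniform(0.3, 0.7)
        amp = rng.uniform(0.05, 0.09)
    f = u**2.2 + amp * np.sin(2 * np.pi * freq * u + phase) * np.sin(np.pi * u)
    return np.clip(f, 0.0, 1.0)


def _progress_variable(u: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
    # low-frequency, high-amplitude meander: reverses vertical direction
    # and stays expressible at 2-min sampling of the shortest phases
    if rng is None:
        freq, phase, amp = 1.8, 2.5, 0.24
    else:
        freq = rng.uniform(1.6, 2.0)
        phase = rng.uniform(2.2, 2.8)
        amp = rng.uniform(0.19, 0.29)
    f = u + amp * np.sin(2 * np.pi * freq * u + phase) * np.sin(np.pi * u)
    return np.clip(f, 0.0, 1.0)


def _progress_transition(u: np.ndarray, f1: float, g1: float) -> np.ndarray:
    """Two linear segments in normalized time/depth, corner at (f1, g1)."""
    return np.where(u <= f1, g1 * u / f1, g1 + (1.0 - g1) * (u - f1) / (1.0 - f1))


def make_phase_profile(
    shape: str,
    apex_depth: float,
    start_depth: float,
    duration_s: float,
    interval_s: float,
    rng: np.random.Generator | None = None,
    kind: str | None = None,
    changepoint_s: float | None = None,
    slopes: tuple | None = None,
) -> np.ndarray:
    """Depth sequence for one dive phase sampled every ``interval_s``.

    Descent shapes (``linear``, ``slowing``, ``delayed``) run from
    ``start_depth`` down to ``apex_depth``; ascent shapes (``linear``
    with ``kind='ascent'``, ``transition_point``, ``variable``) run from
    the apex back up.  For ``transition_point``, explicit signed
    ``slopes`` (m/s) and ``changepoint_s`` override ``start_depth``.
    """
    if not apex_depth > 200.0 > start_depth:
        raise ValueError("require apex_depth > 200 m > start_depth")
    n = int(round(duration_s / interval_s))
    if n < 1:
        raise ValueError("duration shorter than one sampling interval")
    t = np.arange(n + 1) * interval_s
    u = t / (n * interval_s)
    rng_ = rng

    if shape == "transition_point":
        if slopes is not None and changepoint_s is not None:
            s1, s2 = abs(slopes[0]), abs(slopes[1])
            if not s1 > s2:
                raise ValueError("transition_point requires |slope1| > |slope2|")
            return apex_depth - s1 * np.minimum(t, changepoint_s) - s2 * np.maximum(
                t - changepoint_s, 0.0
            )
        # corner placement follows the observed segment structure: the fast
        # first segment covers ~1/3 of the time but ~2/3 of the depth range
        f1 = rng_.uniform(0.31, 0.38) if rng_ is not None else 0.34
        g1 = rng_.uniform(0.66, 0.75) if rng_ is not None else 0.70
        prog = _progress_transition(u, f1, g1)
        return apex_depth - (apex_depth - start_depth) * prog
    if shape == "variable":
        prog = _progress_variable(u, rng_)
        return apex_depth - (apex_depth - start_depth) * prog
    if shape == "linear" and kind == "ascent":
        return apex_depth - (apex_depth - start_depth) * u
    if shape == "linear":
        return start_depth + (apex_depth - start_depth) * u
    if shape == "slowing":
        return start_depth + (apex_depth - start_depth) * _progress_slowing(u)
    if shape == "delayed":
        return start_depth + (apex_depth - start_depth) * _progress_delayed(u, rng_)
    raise ValueError(f"unknown phase shape {shape!r}")


# ---------------------------------------------------------------------------
# track assembly

def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(200):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def _baseline_walk(rng, n, mixing_depth):
    """Mean-reverting reflected walk in the mixed layer."""
    x = np.empty(n)
    x[0] = rng.uniform(10.0, 80.0)
    steps = rng.normal(0.0, 6.5, size=n - 1)
    mu, theta = 55.0, 0.02
    lo, hi = 2.0, mixing_depth
    for j in range(1, n):
        v = x[j - 1] + theta * (mu - x[j - 1]) + steps[j - 1]
        if v < lo:
            v = 2 * lo - v
        if v > hi:
            v = 2 * hi - v
        x[j] = min(max(v, lo), hi)
    return x


def _diel_period_of(ts: pd.Timestamp, lat: float, lon: float) -> str:
    sr, ss = sun_events_utc(ts.date(), lat, lon)
    h = dt.timedelta(hours=1)
    t = ts.to_pydatetime()
    if sr - h <= t < sr + h:
        return "dawn"
    if ss - h <= t < ss + h:
        return "dusk"
    if sr + h <= t < ss - h:
        return "day"
    return "night"


def _build_excursion_interior(cfg, rng, apex):
    """Excursion depth sequence on the sample grid plus truth metadata.

    Returns (interior, start_bound, end_bound, k_d, descent_shape,
    ascent_shape, changepoint_s, slopes) where ``interior`` holds the
    strictly-below-200 m records (interior[k_d - 1] is the apex) and the
    bounding records continue the class trajectory one sample beyond the
    200 m crossing, so the standardized profile carries the class shape.
    """
    dlo, dhi = cfg.descent_duration_range
    alo, ahi = cfg.ascent_duration_range
    dmin = _truncnorm(rng, *cfg.descent_duration_mean_sd, dlo, dhi)
    amin = _truncnorm(rng, *cfg.ascent_duration_mean_sd, alo, ahi)
    k_d = max(2, int(round(dmin * 60.0 / cfg.interval_s)))
    k_a = max(3, int(round(amin * 60.0 / cfg.interval_s)))
    while k_d + k_a - 1 < 5:
        k_a += 1

    desc_shape = rng.choice(
        list(cfg.descent_shape_mix), p=list(cfg.descent_shape_mix.values())
    )
    asc_shape = rng.choice(
        list(cfg.ascent_shape_mix), p=list(cfg.ascent_shape_mix.values())
    )

    eps = min(2.5, 0.4 * (apex - 200.0))  # interior clearance below the isobath
    amp = apex - 200.0 - eps

    u_d = np.arange(1, k_d + 1) / k_d
    if desc_shape == "linear":
        f = u_d
    elif desc_shape == "slowing":
        f = _progress_slowing(u_d)
    else:
        f = np.clip(_progress_delayed(u_d, rng), 0.005, 1.0)
    desc = 200.0 + eps + amp * f

    u_a = np.arange(1, k_a) / k_a
    changepoint_s = None
    slopes = None
    if asc_shape == "linear":
        g = u_a
    elif asc_shape == "variable":
        g = np.clip(_progress_variable(u_a, rng), 0.0, 0.995)
    else:
        f1 = rng.uniform(0.31, 0.38)
        g1 = rng.uniform(0.66, 0.75)
        g = _progress_transition(u_a, f1, g1)
        T_a = k_a * cfg.interval_s
        changepoint_s = f1 * T_a
        slopes = (-amp * g1 / (f1 * T_a), -amp * (1.0 - g1) / ((1.0 - f1) * T_a))
    asc = 200.0 + eps + amp * (1.0 - g)

    # bounding records extrapolate the phase trajectory one sample past
    # the crossing (clipped into the epipelagic layer)
    start_bound = float(np.clip(2.0 * desc[0] - desc[1] if k_d > 1 else desc[0] - amp / k_d,
                                2.0, 199.0))
    if len(asc):
        end_bound = float(np.clip(2.0 * asc[-1] - (asc[-2] if len(asc) > 1 else apex),
                                  2.0, 199.0))
    else:
        end_bound = float(np.clip(2.0 * (200.0 + eps) - apex, 2.0, 199.0))

    interior = np.concatenate([desc, asc])
    return interior, start_bound, end_bound, k_d, desc_shape, asc_shape, changepoint_s, slopes


def simulate_track(
    config: SimulationConfig, env: EnvironmentModel | None = None
) -> tuple[list[TagSeries], list[TruthExcursion]]:
    """Simulate tag series for all individuals with known excursion truth.

    Reproducible given ``config.seed``.  Excursion counts are Poisson
    per individual; placements are rejection-sampled so that excursions
    (plus a 1 h guard either side) do not overlap.
    """
    env = env or EnvironmentModel()
    rng = np.random.default_rng(config.seed)
    n_per = int(round(config.days * 86400.0 / config.interval_s))
    if n_per < 100:
        raise ConfigError("track too short")
    start = pd.Timestamp(config.start_date, tz="UTC")
    times = start + pd.to_timedelta(np.arange(n_per) * config.interval_s, unit="s")

    guard = int(math.ceil(3600.0 / config.interval_s))  # 1 h, in records
    multipliers = config.diel_rate_multipliers
    max_mult = max(multipliers.values()) if multipliers else None

    series_list: list[TagSeries] = []
    truths: list[TruthExcursion] = []

    for i in range(config.n_individuals):
        ind = f"sim{i + 1:02d}"
        depth = _baseline_walk(rng, n_per, config.epipelagic_mixing_depth)
        occupied = np.zeros(n_per, dtype=bool)
        n_me = rng.poisson(config.me_rate_per_day * config.days)
        placed = 0
        tries = 0
        while placed < n_me:
            tries += 1
            if tries > 200 * max(1, n_me):
                raise ConfigError("excursion density too high to place without overlap")
            apex = rng.uniform(*config.apex_depth_range)
            interior, start_b, end_b, k_d, dsh, ash, cp_s, slopes = (
                _build_excursion_interior(config, rng, apex)
            )
            m = len(interior)
            j0 = int(rng.integers(guard, n_per - m - guard - 2))
            lo, hi = j0 - guard, j0 + m + 2 + guard
            if occupied[max(lo, 0) : hi].any():
                continue
            if multipliers is not None:
                period = _diel_period_of(times[j0], config.lat, config.lon)
                if rng.uniform() > multipliers.get(period, 1.0) / max_mult:
                    continue
            # j0 / j0+m+1 = bounding records (< 200 m); interior between
            depth[j0] = start_b
            depth[j0 + 1 : j0 + 1 + m] = interior
            depth[j0 + m + 1] = end_b
            occupied[max(lo, 0) : hi] = True
            truths.append(
                TruthExcursion(
                    individual_id=ind,
                    start=times[j0].to_pydatetime(),
                    end=times[j0 + m + 1].to_pydatetime(),
                    apex_time=times[j0 + k_d].to_pydatetime(),
                    apex_depth=float(apex),
                    descent_shape=str(dsh),
                    ascent_shape=str(ash),
                    true_changepoint_s=cp_s,
                    segment_slopes=slopes,
                )
            )
            placed += 1

        if config.depth_noise_sd > 0:
            depth = depth + rng.normal(0.0, config.depth_noise_sd, size=n_per)
        # preserve the detection criteria against noise at the 200 m isobath
        interior_mask = np.zeros(n_per, dtype=bool)
        for tr in truths:
            if tr.individual_id != ind:
                continue
            a = int((pd.Timestamp(tr.start) - start).total_seconds() / config.interval_s)
            b = int((pd.Timestamp(tr.end) - start).total_seconds() / config.interval_s)
            interior_mask[a + 1 : b] = True
        depth[interior_mask] = np.maximum(depth[interior_mask], 200.6)
        depth[~interior_mask] = np.clip(depth[~interior_mask], 0.0, 199.0)

        temp = temperature_at_depth(env, depth)
        if config.temp_noise_sd > 0:
            temp = temp + rng.normal(0.0, config.temp_noise_sd, size=n_per)
        if config.pre_me_cooling_c != 0.0:
            tsec = np.arange(n_per) * config.interval_s
            for tr in truths:
                if tr.individual_id != ind:
                    continue
                s = (pd.Timestamp(tr.start) - start).total_seconds()
                w = (tsec >= s - 5 * 3600.0) & (tsec <= s)
                ramp = 1.0 - (s - tsec[w]) / (5 * 3600.0)
                temp[w] = temp[w] - config.pre_me_cooling_c * ramp

        frame = pd.DataFrame(
            {"timestamp": times, "depth": depth, "temperature": temp}
        )
        series_list.append(
            TagSeries(
                individual_id=ind,
                frame=frame,
                nominal_interval_s=float(config.interval_s),
            )
        )
    return series_list, truths


def write_simulation(
    outdir: str | Path, series_list: list[TagSeries], truths: list[TruthExcursion]
) -> None:
    """Emit per-individual CSVs plus a ``truth.json`` ground-truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in series_list:
        write_tag_series(s, outdir / f"{s.individual_id}.csv")
    recs = []
    for t in truths:
        d = dataclasses.asdict(t)
        for k in ("start", "end", "apex_time"):
            d[k] = d[k].isoformat()
        recs.append(d)
    (outdir / "truth.json").write_text(json.dumps(recs, indent=2))
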