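"""Broken-stick (two-segment continuous piecewise-linear) ascent regression.

A transition-point ascent has a fast initial linear segment followed by
an abruptly slower linear segment.  The model is the sharp-hinge broken
stick

    depth(t) = b0 + b1 * t + b2 * max(t - c, 0)

fit by least squares over the ascent's non-standardized (time, depth)
records with time origin at the apex record.  The change point ``c`` is
profiled: for each candidate ``c`` the remaining parameters are solved
by ordinary least squares, a fine grid locates the global residual
minimum, and a bounded scalar optimization refines it within the best
inter-record interval.  A 95% confidence interval comes from inverting
the Gaussian profile likelihood, n*log(RSS(c)/RSS(c_hat)) <= chi2(1, .95).

The transition point is the first record strictly after the real-valued
change-point estimate; it marks the start of the second segment and
carries that record's depth and temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .errors import InsufficientRecordsError
from .profile_clustering import PhaseProfile

MIN_RECORDS = 5
CHI2_95_DF1 = float(chi2.ppf(0.95, 1))


@dataclass
class BrokenStickFit:
    """Fitted two-segment ascent model.

    Slopes are signed depth-versus-time velocities (ascending =>
    negative).  ``delta_velocity`` is |slope2| - |slope1|: negative
    values mean the ascent decelerated at the transition point.
    ``identifiable`` is False when the profile is consistent with a
    single straight line (no interior residual minimum).
    """

    changepoint_s: float
    ci95: tuple
    slope1: float
    slope2: float
    intercept: float
    rss: float
    identifiable: bool
    transition_index: int | None = None
    transition_depth: float | None = None
    transition_temperature: float | None = None
    transition_time_s: float | None = None

    @property
    def delta_velocity(self) -> float:
        return abs(self.slope2) - abs(self.slope1)


def _hinge_ols(t: np.ndarray, d: np.ndarray, c: float):
    X = np.column_stack([np.ones_like(t), t, np.maximum(t - c, 0.0)])
    beta, *_ = np.linalg.lstsq(X, d, rcond=None)
    resid = d - X @ beta
    return beta, float(resid @ resid)


def fit_broken_stick(
    ascent: PhaseProfile, grid_points: int = 200, refine: bool = True
) -> BrokenStickFit:
    """Fit the broken-stick model to one ascent profile.

    Requires at least 5 records (4 parameters + residual degree of
    freedom); shorter ascents raise :class:`InsufficientRecordsError`
    and are omitted from the transition-point analysis.  A profile whose
    best two-segment fit is not meaningfully better than a single line
    is returned with ``identifiable=False`` rather than raising.
    """
    t = np.asarray(ascent.t_s, dtype=float)
    d = np.asarray(ascent.depth, dtype=float)
    n = t.size
    if n < MIN_RECORDS:
        raise InsufficientRecordsError(
            f"{n} records; at least {MIN_RECORDS} needed for a transition point"
        )

    lo, hi = t[1], t[-2]  # keep >= 2 records on each side of the hinge
    if hi <= lo:
        raise InsufficientRecordsError("degenerate time grid")
    grid = np.linspace(lo, hi, grid_points)
    rss_grid = np.empty(grid.size)
    for i, c in enumerate(grid):
        _, rss_grid[i] = _hinge_ols(t, d, c)
    i0 = int(np.argmin(rss_grid))

    c_hat = float(grid[i0])
    if refine:
        a = grid[max(i0 - 1, 0)]
        b = grid[min(i0 + 1, grid.size - 1)]
        if b > a:
            res = minimize_scalar(
                lambda c: _hinge_ols(t, d, float(c))[1],
                bounds=(a, b),
                method="bounded",
                options={"xatol": 1e-6},
            )
            if res.fun <= rss_grid[i0] + 1e-12:
                c_hat = float(res.x)
    beta, rss = _hinge_ols(t, d, c_hat)
    slope1 = float(beta[1])
    slope2 = float(beta[1] + beta[2])

    # single straight line comparison
    X1 = np.column_stack([np.ones_like(t), t])
    b1, *_ = np.linalg.lstsq(X1, d, rcond=None)
    r1 = d - X1 @ b1
    rss_line = float(r1 @ r1)
    scale = float(d @ d) + 1e-12
    if rss_line - rss <= 1e-10 * scale:
        # no interior minimum: the ascent is a straight line
        return BrokenStickFit(
            changepoint_s=c_hat,
            ci95=(lo, hi),
            slope1=float(b1[1]),
            slope2=float(b1[1]),
            intercept=float(b1[0]),
            rss=rss_line,
            identifiable=False,
        )

    # profile-likelihood CI on the grid
    if rss <= 1e-12 * scale:
        ci = (c_hat, c_hat)  # noise-free: likelihood collapses at the truth
    else:
        prof = n * np.log(rss_grid / rss)
        inside = grid[prof <= CHI2_95_DF1]
        if inside.size:
            ci = (min(float(inside.min()), c_hat), max(float(inside.max()), c_hat))
        else:
            ci = (c_hat, c_hat)

    return BrokenStickFit(
        changepoint_s=c_hat,
        ci95=ci,
        slope1=slope1,
        slope2=slope2,
        intercept=float(beta[0]),
        rss=rss,
        identifiable=True,
    )


def transition_point(fit: BrokenStickFit, ascent: PhaseProfile) -> tuple:
    """(index, depth, temperature, time_s) of the transition record.

    The transition point is the first record strictly after the
    real-valued change-point estimate (a change point landing exactly on
    a record time points to the next record).  The result is also
    written back onto ``fit``.
    """
    t = np.asarray(ascent.t_s, dtype=float)
    after = np.nonzero(t > fit.changepoint_s)[0]
    if after.size == 0:
        raise ValueError("change point lies at or after the last record")
    idx = int(after[0])
    fit.transition_index = idx
    fit.transition_depth = float(ascent.depth[idx])
    fit.transition_time_s = float(t[idx])
    if ascent.temperature is not None:
        fit.transition_temperature = float(ascent.temperature[idx])
    return idx, fit.transition_depth, fit.transition_temperature, fit.transition_time_s


def segment_velocity_table(
    fits: list[BrokenStickFit],
    ascents: list[PhaseProfile],
    linear_ascents: list[PhaseProfile] | None = None,
) -> pd.DataFrame:
    """Per-ascent segment velocity comparison table.

    Transition-point ascents contribute |slope1|, |slope2|, the two
    segment durations (which partition the ascent) and the velocity
    change at the transition; linear ascents contribute their endpoint
    mean vertical velocity as the single-segment equivalent.
    """
    rows = []
    for fit, asc in zip(fits, ascents):
        total = asc.duration_s
        rows.append(
            {
                "me_id": asc.me_id,
                "ascent_type": "transition_point",
                "segment1_velocity_m_s": abs(fit.slope1),
                "segment2_velocity_m_s": abs(fit.slope2),
                "segment1_duration_s": fit.changepoint_s,
                "segment2_duration_s": total - fit.changepoint_s,
                "delta_velocity_m_s": fit.delta_velocity,
            }
        )
    for asc in linear_ascents or []:
        v = asc.mean_vertical_velocity
        rows.append(
            {
                "me_id": asc.me_id,
                "ascent_type": "linear",
                "segment1_velocity_m_s": np.nan,
                "segment2_velocity_m_s": v,
                "segment1_duration_s": np.nan,
                "segment2_duration_s": asc.duration_s,
                "delta_velocity_m_s": np.nan,
            }
        )
    return pd.DataFrame(rows)
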