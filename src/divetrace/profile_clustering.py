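"""Dive-phase shape clustering.

Each excursion is split at its apex (first occurrence of the maximum
depth, which both phases share) into a descent and an ascent profile.
Profiles are standardized — time and depth each affinely mapped to
[0, 1] and resampled by linear interpolation onto P uniform time points
— and clustered by k-means with Euclidean distance, separately for
descents and ascents.  R² (between-cluster over total sum of squares)
versus k guides the choice of cluster count; k = 3 is the default
replication setting (three descent and three ascent archetypes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import DegenerateDataError
from .excursion_detection import Excursion

#: standardized profile length: resolves 2-min sampling of phases >= 4 min
DEFAULT_P = 20
DEFAULT_K = 3
DEFAULT_RESTARTS = 25


@dataclass
class PhaseProfile:
    """A descent or ascent as (seconds-from-phase-start, depth) points."""

    me_id: str
    kind: str  # "descent" | "ascent"
    t_s: np.ndarray
    depth: np.ndarray
    temperature: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("descent", "ascent"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if len(self.t_s) != len(self.depth):
            raise ValueError("time and depth lengths differ")

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0

    @property
    def mean_vertical_velocity(self) -> float:
        """|endpoint depth range| / duration, m/s."""
        if self.duration_s <= 0:
            raise ValueError("zero-duration phase")
        return abs(float(self.depth[-1] - self.depth[0])) / self.duration_s


def split_phases(exc: Excursion) -> tuple[PhaseProfile, PhaseProfile]:
    """Split an excursion into descent and ascent profiles at the apex.

    The descent runs from the first record down to and including the
    maximum-depth record; the ascent runs from that record to the last.
    When the maximum depth repeats, the first occurrence is the apex.
    """
    f = exc.frame
    d = f["depth"].to_numpy(dtype=float)
    t = (f["timestamp"] - f["timestamp"].iloc[0]).dt.total_seconds().to_numpy()
    temp = f["temperature"].to_numpy(dtype=float)
    a = int(np.argmax(d))
    me_id = f"{exc.individual_id}_{exc.start_time.isoformat()}"
    descent = PhaseProfile(me_id, "descent", t[: a + 1] - t[0], d[: a + 1], temp[: a + 1])
    ascent = PhaseProfile(me_id, "ascent", t[a:] - t[a], d[a:], temp[a:])
    return descent, ascent


def standardize_profile(phase: PhaseProfile, P: int = DEFAULT_P) -> np.ndarray:
    """Standardized fixed-length representation of a phase.

    Time is mapped to [0, 1]; depth is mapped to [0, 1] by
    (d - d_min) / (d_max - d_min); the curve is then resampled by linear
    interpolation onto P uniform time points.  Invariant to affine
    changes of the raw depth and time units.  Descents start at 0 and
    end at 1; ascents start at 1 and end at 0.
    """
    if len(phase.t_s) < 2:
        raise DegenerateDataError("need at least 2 points to standardize")
    d = phase.depth.astype(float)
    rng_d = d.max() - d.min()
    if rng_d <= 0:
        raise DegenerateDataError("zero depth range in phase profile")
    u = (phase.t_s - phase.t_s[0]) / (phase.t_s[-1] - phase.t_s[0])
    d01 = (d - d.min()) / rng_d
    grid = np.linspace(0.0, 1.0, P)
    return np.interp(grid, u, d01)


@dataclass
class ClusterModel:
    """k-means result over standardized phase vectors.

    Clusters are canonically relabelled by descending membership count
    (cluster 1 is the most common shape).  ``r_squared`` is
    1 - within_ss / total_ss.
    """

    kind: str
    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    within_ss: float
    total_ss: float
    seed: int | None = None
    r_squared: float = field(init=False)

    def __post_init__(self) -> None:
        self.r_squared = 1.0 - self.within_ss / self.total_ss


def fit_kmeans(
    profiles: np.ndarray,
    k: int,
    seed: int | None = 0,
    n_restarts: int = DEFAULT_RESTARTS,
    kind: str = "phase",
    extra_inits: np.ndarray | None = None,
) -> ClusterModel:
    """Best-of-restarts k-means on standardized profile vectors.

    ``extra_inits`` optionally supplies explicit initial centroid sets
    (used by :func:`r2_by_k` to warm-start from the k-1 solution, which
    makes R² non-decreasing in k).
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2:
        raise ValueError("profiles must be a 2-D array (n_profiles, P)")
    total_ss = float(((X - X.mean(axis=0)) ** 2).sum())
    if total_ss <= 0:
        raise DegenerateDataError("all profiles identical (total_ss = 0)")
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct profiles")

    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    km.fit(X)
    best_inertia, best_labels, best_centers = km.inertia_, km.labels_, km.cluster_centers_
    if extra_inits is not None:
        for init in np.atleast_3d(extra_inits.reshape(-1, k, X.shape[1])):
            km2 = KMeans(n_clusters=k, init=init, n_init=1, algorithm="lloyd")
            km2.fit(X)
            if km2.inertia_ < best_inertia:
                best_inertia, best_labels, best_centers = (
                    km2.inertia_,
                    km2.labels_,
                    km2.cluster_centers_,
                )

    # canonical order: descending membership (ties by first appearance)
    counts = np.bincount(best_labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return ClusterModel(
        kind=kind,
        k=k,
        centroids=best_centers[order],
        assignments=remap[best_labels],
        within_ss=float(best_inertia),
        total_ss=total_ss,
        seed=seed,
    )


def r2_by_k(
    profiles: np.ndarray,
    k_range=range(2, 11),
    seed: int | None = 0,
    n_restarts: int = DEFAULT_RESTARTS,
) -> dict:
    """R² for each candidate cluster count (operator selects k manually).

    Each k is fitted best-of-restarts and additionally warm-started from
    the previous k's centroids plus the point farthest from them, which
    guarantees the R² sequence is non-decreasing.
    """
    X = np.asarray(profiles, dtype=float)
    out = {}
    prev_centers = None
    for k in k_range:
        extra = None
        if prev_centers is not None:
            d2 = ((X[:, None, :] - prev_centers[None]) ** 2).sum(-1).min(1)
            far = X[int(np.argmax(d2))]
            extra = np.vstack([prev_centers, far[None]])
        model = fit_kmeans(X, k, seed=seed, n_restarts=n_restarts, extra_inits=extra)
        out[k] = model.r_squared
        prev_centers = model.centroids
    return out


def cross_tabulate(
    descent_assignments, ascent_assignments, me_ids=None
) -> pd.DataFrame:
    """Ascent-by-descent cluster contingency table with totals and percentages.

    Rows are ascent clusters, columns descent clusters; each cell holds
    the pair count and its percentage of all MEs (rounded to 2
    decimals); marginal totals appended.
    """
    da = np.asarray(descent_assignments)
    aa = np.asarray(ascent_assignments)
    if da.shape != aa.shape:
        raise ValueError("descent and ascent assignments cover different ME sets")
    if me_ids is not None and len(me_ids) != len(da):
        raise ValueError("me_ids length mismatch")
    total = len(da)
    tab = pd.crosstab(
        pd.Series(aa, name="ascent"), pd.Series(da, name="descent")
    )
    counts = tab.to_numpy()
    pct = np.round(counts / total * 100.0, 2)
    out = pd.DataFrame(
        {
            f"descent_{c + 1}_n": counts[:, j]
            for j, c in enumerate(tab.columns)
        },
        index=[f"ascent_{r + 1}" for r in tab.index],
    )
    for j, c in enumerate(tab.columns):
        out[f"descent_{c + 1}_pct"] = pct[:, j]
    out["row_total"] = counts.sum(axis=1)
    col_tot = {f"descent_{c + 1}_n": counts[:, j].sum() for j, c in enumerate(tab.columns)}
    col_tot.update(
        {f"descent_{c + 1}_pct": np.round(counts[:, j].sum() / total * 100, 2) for j, c in enumerate(tab.columns)}
    )
    col_tot["row_total"] = total
    out.loc["column_total"] = col_tot
    return out
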