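"""Count models, window sampling, mixed models and correlations for
excursion behaviour.

Excursion frequency is modelled with negative-binomial (NB2) regression
with a log link, a log exposure offset (time tracked in each category,
so coefficients are rates) and a Gaussian random intercept per
individual.  No Python library in the stack fits this model, so the
marginal likelihood is maximized directly, integrating the random
intercept by Gauss–Hermite quadrature; significance of a term is an
analysis-of-deviance (likelihood-ratio) test against the null model.

Dive-characteristic models are linear mixed models (statsmodels
``MixedLM``) on Box–Cox transformed responses with additive cluster
factors, followed by Tukey single-step pairwise contrasts with a
compact letter display.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.optimize import minimize
from scipy.special import boxcox as _boxcox_branch
from scipy.special import gammaln, logsumexp

from .errors import DegenerateDataError
from .excursion_detection import Excursion, assign_diel, assign_lunar, daily_sst
from .tag_io import TagSeries

ALPHA = 0.05  # study-wide significance level


# ---------------------------------------------------------------------------
# category counting with exposure offsets

@dataclass
class CategoryCounts:
    """ME count for one individual in one factor category.

    ``exposure`` is the time tracked in that category, in hours, and
    enters count models as a log offset.  ``covariate`` optionally
    carries a continuous predictor (e.g. monthly mean SST, °C).
    """

    individual_id: str
    category: str
    count: int
    exposure: float
    covariate: float | None = None


def build_category_counts(
    excursions: list[Excursion],
    series_list: list[TagSeries],
    factor: str,
    lat: float | None = None,
    lon: float | None = None,
    zenith_deg: float = 90.0,
) -> list[CategoryCounts]:
    """Per-individual ME counts and exposures for a temporal factor.

    ``factor`` is ``"diel"`` (exposure: summed daily period durations),
    ``"lunar"`` (exposure: 24 h per tracked day in each phase) or
    ``"month"`` (exposure: 24 h per tracked day in each month, with the
    monthly mean of daily SST as covariate).  Excursions must already be
    annotated.  Individuals with zero total exposure are excluded with a
    warning.
    """
    if factor not in ("diel", "lunar", "month"):
        raise ValueError(f"unknown factor {factor!r}")
    by_ind = {s.individual_id: s for s in series_list}
    out: list[CategoryCounts] = []
    for ind, series in by_ind.items():
        dates = sorted(set(series.timestamps.dt.date))
        if not dates:
            warnings.warn(f"individual {ind} has zero exposure; excluded")
            continue
        excs = [e for e in excursions if e.individual_id == ind]
        if factor == "diel":
            if lat is None or lon is None:
                raise ValueError("diel exposures need lat/lon")
            expo = {p: 0.0 for p in ("dawn", "day", "dusk", "night")}
            for d in dates:
                _, dur = assign_diel(
                    pd.Timestamp(d).tz_localize("UTC") + pd.Timedelta(hours=12),
                    lat,
                    lon,
                    zenith_deg,
                )
                for p, h in dur.items():
                    expo[p] += h
            cnt = {p: 0 for p in expo}
            for e in excs:
                cnt[e.diel_period] += 1
            for p in expo:
                out.append(CategoryCounts(ind, p, cnt[p], expo[p]))
        elif factor == "lunar":
            expo = {p: 0.0 for p in ("new", "first_quarter", "full", "last_quarter")}
            for d in dates:
                expo[assign_lunar(d)] += 24.0
            cnt = {p: 0 for p in expo}
            for e in excs:
                cnt[e.lunar_phase] += 1
            for p in expo:
                if expo[p] > 0:
                    out.append(CategoryCounts(ind, p, cnt[p], expo[p]))
        else:  # month
            sst = daily_sst(series)
            months = {}
            for d in dates:
                months.setdefault((d.year, d.month), []).append(d)
            for (y, m), ds in sorted(months.items()):
                n_me = sum(1 for e in excs if (e.date.year, e.date.month) == (y, m))
                msst = float(np.mean([sst[d] for d in ds if d in sst]))
                out.append(
                    CategoryCounts(ind, f"{y:04d}-{m:02d}", n_me, 24.0 * len(ds), msst)
                )
    return out


# ---------------------------------------------------------------------------
# negative-binomial GLMM (Gauss–Hermite marginal likelihood)

@dataclass
class MixedModelFit:
    """Fitted mixed-model summary shared by the count and LME routes."""

    formula: str
    model_type: str  # "nb_glmm" | "lme"
    params: pd.Series
    cov: pd.DataFrame
    coefficients: pd.DataFrame  # estimate, se
    random_intercept_sd: float
    loglik: float
    n_obs: int
    n_groups: int
    tests: dict = field(default_factory=dict)  # per-term chi2/F results
    factor_levels: dict = field(default_factory=dict)
    dispersion_alpha: float | None = None
    contrasts: pd.DataFrame | None = None
    _predict_ref: dict = field(default_factory=dict, repr=False)

    def predict_rate(self, category: str | None = None, covariate: float | None = None) -> float:
        """Expected count per unit exposure on the response scale."""
        eta = self.params["Intercept"]
        if category is not None:
            key = f"category[T.{category}]"
            if key in self.params.index:
                eta += self.params[key]
            elif category != self._predict_ref.get("reference"):
                raise KeyError(f"unknown category {category!r}")
        if covariate is not None:
            eta += self.params["covariate"] * covariate
        return float(np.exp(eta))


def _nb_loglik_rows(y, mu, alpha):
    r = 1.0 / alpha
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * (np.log(r) - np.log(r + mu))
        + y * (np.log(mu) - np.log(r + mu))
    )


def _nb_glmm_nll(theta, X, y, offset, group_idx, n_groups, gh_x, gh_w):
    p = X.shape[1]
    beta = theta[:p]
    alpha = np.exp(np.clip(theta[p], -12.0, 6.0))
    sigma = np.exp(np.clip(theta[p + 1], -8.0, 3.0))
    eta = X @ beta + offset
    b = np.sqrt(2.0) * sigma * gh_x  # (Q,)
    # rows x nodes log-likelihood; clip linear predictor against overflow
    mu = np.exp(np.clip(eta[:, None] + b[None, :], -30.0, 30.0))
    ll_rows = _nb_loglik_rows(y[:, None], mu, alpha)
    ll_groups = np.zeros((n_groups, gh_x.size))
    np.add.at(ll_groups, group_idx, ll_rows)
    log_w = np.log(gh_w) - 0.5 * np.log(np.pi)
    return -float(np.sum(logsumexp(ll_groups + log_w[None, :], axis=1)))


def _fit_nb_glmm_design(X, y, offset, group_idx, n_groups, names, gh_points=20):
    gh_x, gh_w = np.polynomial.hermite.hermgauss(gh_points)
    p = X.shape[1]
    beta0 = np.zeros(p)
    beta0[0] = np.log(max(y.sum(), 0.5) / np.exp(offset).sum())
    theta0 = np.concatenate([beta0, [np.log(0.5), np.log(0.5)]])
    bounds = [(-30.0, 30.0)] * p + [(-12.0, 6.0), (-8.0, 3.0)]
    args = (X, y, offset, group_idx, n_groups, gh_x, gh_w)
    res = minimize(_nb_glmm_nll, theta0, args=args, method="L-BFGS-B", bounds=bounds)
    if not res.success:
        res2 = minimize(_nb_glmm_nll, res.x, args=args, method="Nelder-Mead",
                        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if res2.fun <= res.fun:
            res = res2
    from statsmodels.tools.numdiff import approx_hess

    H = approx_hess(res.x, _nb_glmm_nll, args=args)
    try:
        cov_all = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(H)
    return res.x, -res.fun, cov_all, names


def fit_count_model(
    counts: list[CategoryCounts],
    use_covariate: bool = False,
    gh_points: int = 20,
) -> MixedModelFit:
    """Negative-binomial GLMM of category counts with a log exposure offset.

    Fixed effects are either the category factor (treatment coding,
    first sorted level as reference) or, with ``use_covariate=True``,
    the continuous covariate stored on the counts.  Fits by maximum
    likelihood (Gauss–Hermite quadrature over the individual random
    intercept) and reports an analysis-of-deviance χ² comparing the null
    (intercept + random intercept) model to the full model.
    """
    df = pd.DataFrame(
        {
            "individual": [c.individual_id for c in counts],
            "category": [c.category for c in counts],
            "count": [c.count for c in counts],
            "exposure": [c.exposure for c in counts],
            "covariate": [c.covariate for c in counts],
        }
    )
    if (df["exposure"] <= 0).any():
        bad = df[df["exposure"] <= 0]
        if (bad["count"] > 0).any():
            raise ValueError("positive count with non-positive exposure")
        df = df[df["exposure"] > 0]
    groups = sorted(df["individual"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 individuals for a random intercept")
    group_idx = df["individual"].map({g: i for i, g in enumerate(groups)}).to_numpy()
    y = df["count"].to_numpy(dtype=float)
    offset = np.log(df["exposure"].to_numpy(dtype=float))

    levels = sorted(df["category"].unique())
    if use_covariate:
        if df["covariate"].isna().any():
            raise ValueError("use_covariate=True but covariates missing")
        X = np.column_stack([np.ones(len(df)), df["covariate"].to_numpy(dtype=float)])
        names = ["Intercept", "covariate"]
        formula = "count ~ covariate + offset(log(exposure)) + (1 | individual)"
        test_name, q = "covariate", 1
    else:
        if len(levels) < 2:
            raise ValueError("need >= 2 categories (or a covariate)")
        X = np.column_stack(
            [np.ones(len(df))]
            + [(df["category"] == lv).to_numpy(dtype=float) for lv in levels[1:]]
        )
        names = ["Intercept"] + [f"category[T.{lv}]" for lv in levels[1:]]
        formula = "count ~ category + offset(log(exposure)) + (1 | individual)"
        test_name, q = "category", len(levels) - 1

    theta, ll_full, cov_all, names = _fit_nb_glmm_design(
        X, y, offset, group_idx, len(groups), names, gh_points
    )
    X0 = X[:, :1]
    theta0, ll_null, _, _ = _fit_nb_glmm_design(
        X0, y, offset, group_idx, len(groups), ["Intercept"], gh_points
    )
    chi2_stat = max(2.0 * (ll_full - ll_null), 0.0)
    p_val = float(st.chi2.sf(chi2_stat, q))

    p = X.shape[1]
    params = pd.Series(theta[:p], index=names)
    cov = pd.DataFrame(cov_all[:p, :p], index=names, columns=names)
    se = np.sqrt(np.maximum(np.diag(cov.to_numpy()), 0.0))
    fit = MixedModelFit(
        formula=formula,
        model_type="nb_glmm",
        params=params,
        cov=cov,
        coefficients=pd.DataFrame({"estimate": params, "se": se}),
        random_intercept_sd=float(np.exp(theta[p + 1])),
        loglik=ll_full,
        n_obs=len(df),
        n_groups=len(groups),
        tests={
            test_name: {
                "statistic": chi2_stat,
                "df": q,
                "p": p_val,
                "kind": "analysis_of_deviance_chi2",
            }
        },
        factor_levels={} if use_covariate else {"category": levels},
        dispersion_alpha=float(np.exp(theta[p])),
    )
    fit._predict_ref["reference"] = None if use_covariate else levels[0]
    return fit


# ---------------------------------------------------------------------------
# temperature window sampling

@dataclass
class TemperatureWindow:
    individual_id: str
    kind: str  # "pre_me" | "non_me"
    width_min: float
    mean_temperature: float
    start: pd.Timestamp
    end: pd.Timestamp


def sample_temperature_windows(
    series: TagSeries,
    excursions: list[Excursion],
    width_min: float = 300.0,
    n_per_individual: int = 50,
    seed: int = 0,
) -> list[TemperatureWindow]:
    """Pre-ME windows plus random non-ME temperature windows.

    A pre-ME window covers the ``width_min`` minutes ending at each ME's
    start record.  Non-ME windows are drawn uniformly without
    replacement from record-aligned start times whose window overlaps no
    ME interval ± 1 h and no pre-ME window.  If fewer than
    ``n_per_individual`` eligible windows exist, all are returned with a
    warning.
    """
    rng = np.random.default_rng(seed)
    t = series.timestamps
    temp = series.temperature
    n = len(series)
    W = pd.Timedelta(minutes=width_min)
    guard = pd.Timedelta(hours=1)
    out: list[TemperatureWindow] = []

    exclusions = []
    for e in excursions:
        exclusions.append((e.start_time - guard, e.end_time + guard))
        exclusions.append((e.start_time - W, e.start_time))  # pre-ME window
        if e.start_time - W >= t.iloc[0]:
            mask = (t >= e.start_time - W) & (t <= e.start_time)
            out.append(
                TemperatureWindow(
                    series.individual_id,
                    "pre_me",
                    width_min,
                    float(temp[mask.to_numpy()].mean()),
                    e.start_time - W,
                    e.start_time,
                )
            )

    starts = t.dt.tz_convert("UTC").dt.tz_localize(None).to_numpy()
    ends = starts + np.timedelta64(int(width_min * 60), "s")
    eligible = ends <= starts[-1]
    for lo, hi in exclusions:
        lo64 = np.datetime64(pd.Timestamp(lo).tz_convert("UTC").tz_localize(None))
        hi64 = np.datetime64(pd.Timestamp(hi).tz_convert("UTC").tz_localize(None))
        overlap = (starts <= hi64) & (ends >= lo64)
        eligible &= ~overlap
    idx = np.nonzero(eligible)[0]
    if idx.size < n_per_individual:
        warnings.warn(
            f"{series.individual_id}: only {idx.size} eligible non-ME windows "
            f"(requested {n_per_individual})"
        )
        chosen = idx
    else:
        chosen = rng.choice(idx, size=n_per_individual, replace=False)
    for i in sorted(int(j) for j in chosen):
        mask = (t >= t.iloc[i]) & (t <= t.iloc[i] + W)
        out.append(
            TemperatureWindow(
                series.individual_id,
                "non_me",
                width_min,
                float(temp[mask.to_numpy()].mean()),
                t.iloc[i],
                t.iloc[i] + W,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Box–Cox, LME, post hoc

def boxcox_transform(y, grid=None) -> tuple[float, np.ndarray]:
    """Profile-ML Box–Cox transform over a λ grid (λ=0 is the log branch)."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive responses")
    if grid is None:
        grid = np.arange(-2.0, 2.0 + 1e-9, 0.01)
    ll = np.array([st.boxcox_llf(lam, y) for lam in grid])
    lam = float(grid[int(np.argmax(ll))])
    return lam, _boxcox_branch(y, lam)


def fit_lme(
    data: pd.DataFrame,
    response: str,
    factors: list[str],
    group: str = "individual",
) -> MixedModelFit:
    """Linear mixed model with additive fixed factors and a random intercept.

    Per-factor significance is an approximate F-test (Wald χ² divided by
    its degrees of freedom, residual denominator df = n − rank(X)); the
    method label is recorded with each test.  A singular random-effect
    variance is floored at 0 with a warning rather than raising.
    """
    import statsmodels.formula.api as smf

    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")
    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in factors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data[group])
        res = None
        last_exc = None
        for method in ("lbfgs", "powell", "cg"):
            try:
                res = model.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
        if res is None:
            raise last_exc

    fe_names = list(res.fe_params.index)
    params = pd.Series(res.fe_params.to_numpy(), index=fe_names)
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[: len(fe_names), : len(fe_names)],
        index=fe_names,
        columns=fe_names,
    )
    n = int(res.nobs)
    rank = len(fe_names)
    tests = {}
    for f in factors:
        idx = [i for i, nm in enumerate(fe_names) if nm.startswith(f"C({f})[")]
        est = params.iloc[idx].to_numpy()
        V = cov.to_numpy()[np.ix_(idx, idx)]
        chi2_stat = float(est @ np.linalg.pinv(V) @ est)
        q = len(idx)
        ddf = max(n - rank, 1)
        F = chi2_stat / q
        tests[f] = {
            "statistic": F,
            "df": (q, ddf),
            "p": float(st.f.sf(F, q, ddf)),
            "kind": "wald_F_approx",
        }
    sd_re = float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0)))
    levels = {f: sorted(map(str, data[f].unique())) for f in factors}
    return MixedModelFit(
        formula=formula,
        model_type="lme",
        params=params,
        cov=cov,
        coefficients=pd.DataFrame(
            {"estimate": params, "se": np.sqrt(np.diag(cov.to_numpy()))}
        ),
        random_intercept_sd=sd_re,
        loglik=float(res.llf),
        n_obs=n,
        n_groups=int(data[group].nunique()),
        tests=tests,
        factor_levels=levels,
    )


def _pair_contrast_vectors(fit: MixedModelFit, factor: str):
    levels = fit.factor_levels[factor]
    names = list(fit.params.index)

    def colvec(level):
        v = np.zeros(len(names))
        for i, nm in enumerate(names):
            if nm == f"C({factor})[T.{level}]" or nm == f"category[T.{level}]":
                v[i] = 1.0
        return v

    pairs = list(itertools.combinations(levels, 2))
    L = np.array([colvec(a) - colvec(b) for a, b in pairs])
    return pairs, L


def tukey_contrasts(fit: MixedModelFit, factor: str | None = None) -> pd.DataFrame:
    """All pairwise level contrasts with single-step adjusted p-values.

    Adjusted p for each pair is P(max_j |Z_j| ≥ |z_k|) under the joint
    normal distribution of all contrast statistics (the single-step
    multiple-comparison adjustment behind Tukey-type simultaneous
    tests).  A compact letter display is appended: levels sharing no
    letter differ significantly at α = 0.05, with 'a' assigned to the
    largest estimated level mean.
    """
    if factor is None:
        if len(fit.factor_levels) != 1:
            raise ValueError("specify the factor for the contrasts")
        factor = next(iter(fit.factor_levels))
    pairs, L = _pair_contrast_vectors(fit, factor)
    beta = fit.params.to_numpy()
    V = fit.cov.to_numpy()
    est = L @ beta
    cov_c = L @ V @ L.T
    se = np.sqrt(np.diag(cov_c))
    z = est / se
    R = cov_c / np.outer(se, se)
    R = (R + R.T) / 2 + 1e-10 * np.eye(len(se))

    mvn = st.multivariate_normal(mean=np.zeros(len(se)), cov=R, allow_singular=True)
    adj_p = []
    for zk in z:
        a = abs(zk) * np.ones(len(se))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            inside = float(mvn.cdf(a, lower_limit=-a))
        adj_p.append(min(max(1.0 - inside, 0.0), 1.0))

    table = pd.DataFrame(
        {
            "level_a": [p[0] for p in pairs],
            "level_b": [p[1] for p in pairs],
            "estimate": est,
            "se": se,
            "z": z,
            "p_adjusted": adj_p,
        }
    )
    letters = _compact_letter_display(fit, factor, pairs, np.array(adj_p))
    table.attrs["letters"] = letters
    fit.contrasts = table
    return table


def _level_means(fit: MixedModelFit, factor: str) -> dict:
    levels = fit.factor_levels[factor]
    means = {}
    for lv in levels:
        eta = 0.0
        for nm, val in fit.params.items():
            if nm == f"C({factor})[T.{lv}]" or nm == f"category[T.{lv}]":
                eta = val
        means[lv] = float(eta)
    return means


def _compact_letter_display(fit, factor, pairs, adj_p, alpha=ALPHA) -> dict:
    """Insert-and-absorb compact letter display from pairwise p-values."""
    levels = fit.factor_levels[factor]
    sig = [p for p, pv in zip(pairs, adj_p) if pv < alpha]
    groups: list[set] = [set(levels)]
    for a, b in sig:
        updated = []
        for g in groups:
            if a in g and b in g:
                updated.extend([g - {a}, g - {b}])
            else:
                updated.append(g)
        # absorb: keep maximal, non-empty, unique sets
        groups = []
        for g in updated:
            if g and not any(g < h for h in updated) and g not in groups:
                groups.append(g)
    means = _level_means(fit, factor)
    groups.sort(key=lambda g: -max(means[lv] for lv in g))
    display = {lv: "" for lv in levels}
    for letter, g in zip(string.ascii_lowercase, groups):
        for lv in g:
            display[lv] += letter
    return display


# ---------------------------------------------------------------------------
# correlations

def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation (midrank ties) with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need n >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = st.pearsonr(x, y)
    elif method == "spearman":
        r, p = st.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
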