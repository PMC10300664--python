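"""Habitat-stratified statistics for a single tracked animal.

Three single-factor models of per-second track samples against habitat type
(river / mountain / urban):

* **attack** — presence/absence of an attack in each second, logistic
  regression (binomial GLM) fitted by IRLS; reported as per-habitat attack
  probabilities with asymptotic (Wald) intervals and pairwise odds ratios.
* **altitude** — above-ground altitude, Gaussian with *habitat-specific
  variance* (a location–scale model: the heteroscedasticity across habitats
  is structural, not noise), fitted by maximum likelihood.
* **speed** — ground speed, ordinary least squares with pooled variance.

Because the track is a dense time series, the altitude and speed models are
fitted on balanced random subsamples (40 and 76 points per habitat) to
blunt temporal autocorrelation and unbalanced group sizes.  All pairwise
post-hoc contrasts are Bonferroni-adjusted; model-vs-null comparison is
available both as a Wald chi-square test and as a parametric bootstrap of
the likelihood-ratio statistic.

All fits are fixed-effects only: the data come from one individual, so the
models describe within-individual patterns and support no population-level
inference (every fit result carries that note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "SubsampleSpec",
    "HabitatFitResult",
    "summarize_habitats",
    "subsample_balanced",
    "fit_attack_model",
    "fit_altitude_model",
    "fit_speed_model",
    "fit_null_model",
    "parametric_bootstrap_test",
    "pairwise_contrasts",
]

SINGLE_ANIMAL_NOTE = (
    "fixed-effects fit on data from a single individual: estimates describe "
    "within-individual patterns only and do not generalize to a population"
)

#: balanced subsample sizes per habitat (speed model, altitude model)
SPEED_SUBSAMPLE_N = 76
ALTITUDE_SUBSAMPLE_N = 40


@dataclass(frozen=True)
class SubsampleSpec:
    """Per-habitat subsample size and seed for balanced random subsampling."""

    n_per_habitat: int
    seed: int = 0

    def __post_init__(self):
        if self.n_per_habitat <= 0:
            raise ValueError("subsample size must be positive")


@dataclass
class HabitatFitResult:
    """A fitted single-factor habitat model.

    ``estimates`` holds one row per habitat (estimate, SE, df, 95% CI);
    ``contrasts`` one row per habitat pair with the Bonferroni-adjusted p;
    ``overall`` is the joint Wald test of the habitat factor.  ``y`` and
    ``labels`` keep the fitted data so the parametric bootstrap can
    simulate from the fit.
    """

    model: str                       # "attack" | "altitude" | "speed"
    family: str                      # "binomial" | "gaussian_het" | "gaussian_hom"
    levels: list[str]
    estimates: pd.DataFrame
    contrasts: pd.DataFrame
    overall: dict
    loglik: float
    n: int
    params: dict = field(default_factory=dict)
    dispersion: pd.DataFrame | None = None
    y: np.ndarray | None = None
    labels: np.ndarray | None = None
    note: str = SINGLE_ANIMAL_NOTE


# ---------------------------------------------------------------------------
# descriptive summary

def summarize_habitats(track: pd.DataFrame, attacks: pd.DataFrame) -> pd.DataFrame:
    """Per-habitat attack counts, percentages, exposure minutes, rates, and
    mean ± sd of altitude and speed.

    Percentages are count/total × 100 (1 decimal); minutes are 1 s track
    samples / 60; the attack rate is count/minutes.
    """
    if "habitat" not in attacks:
        raise ValueError("every attack must carry a habitat label")
    levels = sorted(track["habitat"].unique())
    counts = attacks["habitat"].value_counts()
    total = int(counts.sum())
    rows = []
    for h in levels:
        sel = track["habitat"] == h
        minutes = float(sel.sum()) / 60.0
        n_att = int(counts.get(h, 0))
        if n_att > 0 and minutes == 0:
            raise ValueError(f"attacks recorded in habitat {h!r} with zero track minutes")
        rows.append({
            "habitat": h,
            "attacks": n_att,
            "attack_pct": round(n_att / total * 100.0, 1) if total else 0.0,
            "minutes": minutes,
            "attack_rate_per_min": n_att / minutes if minutes else np.nan,
            "agl_mean_m": float(track.loc[sel, "alt_agl_m"].mean()) if "alt_agl_m" in track else np.nan,
            "agl_sd_m": float(track.loc[sel, "alt_agl_m"].std()) if "alt_agl_m" in track else np.nan,
            "speed_mean_ms": float(track.loc[sel, "speed_ms"].mean()) if "speed_ms" in track else np.nan,
            "speed_sd_ms": float(track.loc[sel, "speed_ms"].std()) if "speed_ms" in track else np.nan,
        })
    return pd.DataFrame(rows)


def subsample_balanced(df: pd.DataFrame, spec: SubsampleSpec,
                       habitat_col: str = "habitat") -> pd.DataFrame:
    """Uniform random subsample without replacement, *n* rows per habitat."""
    rng = np.random.default_rng(spec.seed)
    parts = []
    for h, grp in df.groupby(habitat_col, sort=True):
        if len(grp) < spec.n_per_habitat:
            raise ValueError(
                f"habitat {h!r} has {len(grp)} samples, fewer than the "
                f"requested {spec.n_per_habitat}")
        take = rng.choice(len(grp), size=spec.n_per_habitat, replace=False)
        parts.append(grp.iloc[np.sort(take)])
    return pd.concat(parts).reset_index(drop=True)


# ---------------------------------------------------------------------------
# shared pieces

def _prepare(y, labels) -> tuple[np.ndarray, np.ndarray, list[str]]:
    y = np.asarray(y, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(str)
    if len(y) != len(labels):
        raise ValueError("outcome and habitat labels disagree in length")
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise ValueError("need at least 2 habitats present")
    return y, labels, levels


def _wald_joint(coef: np.ndarray, cov: np.ndarray) -> dict:
    """Joint Wald chi-square test that all level coefficients are equal.

    For a single factor in a cell-means parameterization this is the
    type-II Wald test of the factor (type II and III coincide with one
    factor).
    """
    k = len(coef)
    L = np.zeros((k - 1, k))
    for i in range(k - 1):
        L[i, i] = 1.0
        L[i, i + 1] = -1.0
    d = L @ coef
    V = L @ cov @ L.T
    stat = float(d @ np.linalg.solve(V, d))
    df = k - 1
    return {"stat": stat, "df": df, "p": float(stats.chi2.sf(stat, df))}


def pairwise_contrasts(raw: pd.DataFrame, n_pairs: int | None = None) -> pd.DataFrame:
    """Bonferroni adjustment: p_adj = min(1, m × p_raw) over all level pairs."""
    out = raw.copy()
    m = n_pairs if n_pairs is not None else len(out)
    out["p_adj"] = np.minimum(1.0, m * out["p_raw"].to_numpy(float))
    return out


def _pairs(levels: list[str]):
    return [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]


# ---------------------------------------------------------------------------
# attack probability: binomial GLM

def fit_attack_model(y, labels) -> HabitatFitResult:
    """Logistic regression of per-second attack presence on habitat type.

    Cell-means coding, so each coefficient is the log-odds of an attack in
    one habitat and the back-transformed fit reproduces the raw per-habitat
    frequencies exactly (the model is saturated).  Confidence intervals are
    asymptotic on the link scale, back-transformed; pairwise comparisons
    are odds ratios with Bonferroni-adjusted normal p-values.
    """
    y, labels, levels = _prepare(y, labels)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("attack outcomes must be 0/1")
    for h in levels:
        p_raw = y[labels == h].mean()
        if p_raw in (0.0, 1.0):
            raise ValueError(
                f"complete separation: habitat {h!r} has attack frequency "
                f"{p_raw:.0f}; the log-odds is unbounded")
    X = pd.get_dummies(pd.Categorical(labels, categories=levels), dtype=float)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    coef = fit.params.to_numpy()
    cov = fit.cov_params().to_numpy()
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(0.975)
    expit = lambda u: 1.0 / (1.0 + np.exp(-u))
    est = pd.DataFrame({
        "habitat": levels,
        "estimate": expit(coef),
        "se": se * expit(coef) * (1 - expit(coef)),  # delta method, descriptive
        "df": np.inf,
        "ci_lo": expit(coef - z * se),
        "ci_hi": expit(coef + z * se),
    })
    rows = []
    for a, b in _pairs(levels):
        i, j = levels.index(a), levels.index(b)
        d = coef[i] - coef[j]
        sed = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
        zstat = d / sed
        rows.append({
            "contrast": f"{a}/{b}", "estimate": d, "odds_ratio": float(np.exp(d)),
            "se": sed * float(np.exp(d)),  # SE of the OR (delta method)
            "df": np.inf, "stat": zstat,
            "p_raw": float(2 * stats.norm.sf(abs(zstat))),
        })
    contrasts = pairwise_contrasts(pd.DataFrame(rows))
    return HabitatFitResult(
        model="attack", family="binomial", levels=levels, estimates=est,
        contrasts=contrasts, overall=_wald_joint(coef, cov),
        loglik=float(fit.llf), n=len(y),
        params={"logit_p": dict(zip(levels, coef))},
        y=y, labels=labels)


# ---------------------------------------------------------------------------
# altitude: heteroscedastic Gaussian (habitat-specific mean and variance)

def _het_ml(y, labels, levels):
    """Closed-form ML for the saturated location–scale model: per-group mean
    and biased variance."""
    means, variances, ns = {}, {}, {}
    ll = 0.0
    for h in levels:
        g = y[labels == h]
        n = len(g)
        m = g.mean()
        v = np.mean((g - m) ** 2)
        means[h], variances[h], ns[h] = float(m), float(v), n
        ll += -0.5 * n * (np.log(2 * np.pi * v) + 1.0)
    return means, variances, ns, float(ll)


def fit_altitude_model(y, labels, spec: SubsampleSpec | None = None) -> HabitatFitResult:
    """Gaussian model of above-ground altitude with habitat-specific mean
    *and* habitat-specific variance, fitted by maximum likelihood.

    With one factor the model is saturated and the ML solution is closed
    form: group means and biased group variances.  Residual df is
    n − 2k (k means + k log-variances).  Pairwise mean differences use
    Welch-type standard errors from the per-habitat variances.

    If *spec* is given, (y, labels) are first balanced-subsampled to
    ``spec.n_per_habitat`` rows per habitat.
    """
    y, labels, levels = _prepare(y, labels)
    if spec is not None:
        df = subsample_balanced(pd.DataFrame({"y": y, "habitat": labels}), spec)
        y, labels = df["y"].to_numpy(), df["habitat"].to_numpy()
    for h in levels:
        if (labels == h).sum() < 2:
            raise ValueError(f"habitat {h!r} has fewer than 2 samples")
    means, variances, ns, ll = _het_ml(y, labels, levels)
    k = len(levels)
    n = len(y)
    df_resid = n - 2 * k
    tq = stats.t.ppf(0.975, df_resid)
    mvec = np.array([means[h] for h in levels])
    se = np.array([np.sqrt(variances[h] / ns[h]) for h in levels])
    est = pd.DataFrame({
        "habitat": levels, "estimate": mvec, "se": se,
        "df": float(df_resid),
        "ci_lo": mvec - tq * se, "ci_hi": mvec + tq * se,
    })
    disp = pd.DataFrame({
        "habitat": levels,
        "variance": [variances[h] for h in levels],
        "sd": [np.sqrt(variances[h]) for h in levels],
        "log_var_se": [np.sqrt(2.0 / ns[h]) for h in levels],
    })
    cov = np.diag(se ** 2)
    rows = []
    for a, b in _pairs(levels):
        i, j = levels.index(a), levels.index(b)
        d = mvec[i] - mvec[j]
        sed = float(np.sqrt(se[i] ** 2 + se[j] ** 2))
        tstat = d / sed
        rows.append({
            "contrast": f"{a}-{b}", "estimate": float(d), "se": sed,
            "df": float(df_resid), "stat": tstat,
            "p_raw": float(2 * stats.t.sf(abs(tstat), df_resid)),
        })
    contrasts = pairwise_contrasts(pd.DataFrame(rows))
    return HabitatFitResult(
        model="altitude", family="gaussian_het", levels=levels, estimates=est,
        contrasts=contrasts, overall=_wald_joint(mvec, cov),
        loglik=ll, n=n,
        params={"means": means, "variances": variances, "ns": ns},
        dispersion=disp, y=y, labels=labels)


# ---------------------------------------------------------------------------
# speed: one-factor OLS

def fit_speed_model(y, labels, spec: SubsampleSpec | None = None) -> HabitatFitResult:
    """Ordinary least squares of ground speed on habitat type.

    Cell-means coding: estimates are group sample means with a pooled
    residual variance; the overall test is the one-way F; pairwise
    differences use the pooled SE, Bonferroni-adjusted.
    """
    y, labels, levels = _prepare(y, labels)
    if spec is not None:
        df = subsample_balanced(pd.DataFrame({"y": y, "habitat": labels}), spec)
        y, labels = df["y"].to_numpy(), df["habitat"].to_numpy()
    for h in levels:
        if (labels == h).sum() < 2:
            raise ValueError(f"habitat {h!r} has fewer than 2 samples")
    X = pd.get_dummies(pd.Categorical(labels, categories=levels), dtype=float)
    fit = sm.OLS(y, X).fit()
    coef = fit.params.to_numpy()
    cov = fit.cov_params().to_numpy()
    se = np.sqrt(np.diag(cov))
    df_resid = int(fit.df_resid)
    tq = stats.t.ppf(0.975, df_resid)
    est = pd.DataFrame({
        "habitat": levels, "estimate": coef, "se": se, "df": float(df_resid),
        "ci_lo": coef - tq * se, "ci_hi": coef + tq * se,
    })
    k = len(levels)
    L = np.zeros((k - 1, k))
    for i in range(k - 1):
        L[i, i], L[i, i + 1] = 1.0, -1.0
    ftest = fit.f_test(L)
    overall = {"stat": float(ftest.fvalue), "df": (int(ftest.df_num), int(ftest.df_denom)),
               "p": float(ftest.pvalue)}
    rows = []
    for a, b in _pairs(levels):
        i, j = levels.index(a), levels.index(b)
        d = coef[i] - coef[j]
        sed = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
        tstat = d / sed
        rows.append({
            "contrast": f"{a}-{b}", "estimate": float(d), "se": sed,
            "df": float(df_resid), "stat": tstat,
            "p_raw": float(2 * stats.t.sf(abs(tstat), df_resid)),
        })
    contrasts = pairwise_contrasts(pd.DataFrame(rows))
    # ML log-likelihood (biased variance), so LR statistics nest cleanly
    resid = y - X.to_numpy() @ coef
    v_ml = float(np.mean(resid ** 2))
    ll = -0.5 * len(y) * (np.log(2 * np.pi * v_ml) + 1.0)
    return HabitatFitResult(
        model="speed", family="gaussian_hom", levels=levels, estimates=est,
        contrasts=contrasts, overall=overall, loglik=ll, n=len(y),
        params={"means": dict(zip(levels, coef)), "variance": v_ml,
                "mse": float(fit.mse_resid)},
        y=y, labels=labels)


# ---------------------------------------------------------------------------
# null fits and the parametric bootstrap

def _fit_ml(family: str, y: np.ndarray, labels: np.ndarray,
            levels: list[str], null: bool) -> tuple[dict, float]:
    """Fast closed-form ML fits used inside the bootstrap loop."""
    n = len(y)
    if family == "binomial":
        if null:
            p = y.mean()
            p = min(max(p, 1e-12), 1 - 1e-12)
            ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
            return {"p": p}, ll
        ll = 0.0
        ps = {}
        for h in levels:
            g = y[labels == h]
            p = min(max(g.mean(), 1e-12), 1 - 1e-12)
            ps[h] = p
            ll += float(np.sum(g * np.log(p) + (1 - g) * np.log(1 - p)))
        return {"p": ps}, ll
    if family == "gaussian_hom":
        if null:
            m = y.mean()
            v = np.mean((y - m) ** 2)
            return {"mean": m, "variance": v}, -0.5 * n * (np.log(2 * np.pi * v) + 1)
        means = {h: y[labels == h].mean() for h in levels}
        resid = y - np.array([means[h] for h in labels])
        v = np.mean(resid ** 2)
        return {"means": means, "variance": v}, -0.5 * n * (np.log(2 * np.pi * v) + 1)
    if family == "gaussian_het":
        if null:
            m = y.mean()
            v = np.mean((y - m) ** 2)
            return {"mean": m, "variance": v}, -0.5 * n * (np.log(2 * np.pi * v) + 1)
        means, variances, ns, ll = _het_ml(y, labels, levels)
        return {"means": means, "variances": variances}, ll
    raise ValueError(f"unknown family {family!r}")


def fit_null_model(fit: HabitatFitResult) -> HabitatFitResult:
    """Intercept-only null for a fitted model (same family, same data)."""
    params, ll = _fit_ml(fit.family, fit.y, fit.labels, fit.levels, null=True)
    return HabitatFitResult(
        model=fit.model + "_null", family=fit.family, levels=fit.levels,
        estimates=pd.DataFrame(), contrasts=pd.DataFrame(),
        overall={}, loglik=ll, n=fit.n, params=params,
        y=fit.y, labels=fit.labels)


def _simulate_null(family: str, params: dict, labels: np.ndarray, rng) -> np.ndarray:
    n = len(labels)
    if family == "binomial":
        return (rng.random(n) < params["p"]).astype(float)
    return rng.normal(params["mean"], np.sqrt(params["variance"]), n)


def parametric_bootstrap_test(full: HabitatFitResult, null: HabitatFitResult,
                              B: int = 1000, seed: int = 0) -> dict:
    """Parametric bootstrap of the likelihood-ratio statistic.

    The observed LR = 2(ℓ_full − ℓ_null) is compared against *B* refits on
    data simulated from the fitted null; p = (1 + #{LR* ≥ LR}) / (B + 1).
    The null must be the intercept-only model of the same family on the
    same data (nested by construction).
    """
    if B <= 0:
        raise ValueError("B must be positive")
    if full.family != null.family:
        raise ValueError(
            f"models are not nested: families {full.family!r} vs {null.family!r}")
    if full.n != null.n:
        raise ValueError("models are not fitted to the same data")
    y, labels, levels = full.y, full.labels, full.levels
    rng = np.random.default_rng(seed)
    _, ll_full = _fit_ml(full.family, y, labels, levels, null=False)
    null_params, ll_null = _fit_ml(full.family, y, labels, levels, null=True)
    lr_obs = 2.0 * (ll_full - ll_null)
    count = 0
    boot = np.empty(B)
    for b in range(B):
        y_b = _simulate_null(full.family, null_params, labels, rng)
        _, lf = _fit_ml(full.family, y_b, labels, levels, null=False)
        _, ln = _fit_ml(full.family, y_b, labels, levels, null=True)
        boot[b] = 2.0 * (lf - ln)
        if boot[b] >= lr_obs:
            count += 1
    return {"stat": float(lr_obs), "p": (1 + count) / (B + 1),
            "B": B, "boot": boot}
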