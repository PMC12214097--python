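"""Statistical battery for mVAHD-based outcome prediction.

The predictive surface of the analysis is the empirical Mann-Whitney ROC AUC
of a posture/phase mVAHD for a binary outcome, with a Youden-index cutoff,
adjusted logistic (odds ratios) and Cox proportional-hazards (hazard ratios)
models, Kaplan-Meier curves with a log-rank comparison, and the usual
baseline-table group comparisons (Shapiro-Wilk-gated t vs Mann-Whitney,
chi-square/Fisher, Wilcoxon signed-rank).

The empirical AUC, its DeLong confidence interval, the exhaustive Youden
scan and the binormal closed form are implemented here; ordinary model fits
delegate to statsmodels (logistic) and lifelines (Cox, Kaplan-Meier,
log-rank, restricted mean survival time), univariate tests to scipy.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ROCResult",
    "CutoffResult",
    "EffectEstimate",
    "LogisticResult",
    "CoxResult",
    "KMCurve",
    "LogRankResult",
    "GroupComparison",
    "empirical_auc",
    "youden_cutoff",
    "binormal_auc",
    "fit_logistic_adjusted",
    "fit_cox",
    "km_logrank",
    "compare_groups",
]

Orientation = Literal["higher_is_positive", "lower_is_positive"]
DEFAULT_COVARIATES = ("age", "sex", "side")
_Z95 = sps.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    orientation: Orientation
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


def _check_binary(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if labels.all() or not labels.any():
        raise ValueError("both a positive and a negative example are required")
    return scores, labels


def empirical_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    orientation: Orientation = "higher_is_positive",
) -> ROCResult:
    """Empirical Mann-Whitney AUC with a DeLong 95% confidence interval.

    The AUC is the probability that a positive outranks a negative under the
    stated orientation, counting ties as 1/2, computed from midranks. The
    variance uses the DeLong placement-value decomposition; the CI is Wald on
    the AUC scale, clipped to [0, 1].
    """
    scores, labels = _check_binary(np.asarray(scores), np.asarray(labels))
    s = scores if orientation == "higher_is_positive" else -scores
    if orientation not in ("higher_is_positive", "lower_is_positive"):
        raise ValueError(f"unknown orientation {orientation!r}")
    pos, neg = s[labels], s[~labels]
    m, n = len(pos), len(neg)
    r_all = sps.rankdata(s)  # midranks
    auc = (r_all[labels].sum() - m * (m + 1) / 2) / (m * n)
    # DeLong placement values via midranks: O(N log N)
    v10 = (r_all[labels] - sps.rankdata(pos)) / n
    v01 = 1.0 - (r_all[~labels] - sps.rankdata(neg)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    return ROCResult(
        auc=float(auc),
        ci_low=float(max(0.0, auc - _Z95 * se)),
        ci_high=float(min(1.0, auc + _Z95 * se)),
        orientation=orientation,
        n_pos=m,
        n_neg=n,
    )


def youden_cutoff(
    scores: Sequence[float],
    labels: Sequence[bool],
    orientation: Orientation = "higher_is_positive",
) -> CutoffResult:
    """Cutoff maximizing the Youden index J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints between consecutive sorted unique
    scores plus the two infinities; a case is called positive when its score
    is above the threshold (below, for ``lower_is_positive``). Ties in J are
    broken toward higher sensitivity, then toward the lower threshold.
    """
    scores, labels = _check_binary(np.asarray(scores), np.asarray(labels))
    uniq = np.unique(scores)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
    pos, neg = scores[labels], scores[~labels]
    best: tuple[float, float, float] | None = None  # (J, sens, -threshold)
    best_result: CutoffResult | None = None
    for thr in candidates:
        if orientation == "higher_is_positive":
            sens = float(np.mean(pos > thr))
            spec = float(np.mean(neg <= thr))
        else:
            sens = float(np.mean(pos < thr))
            spec = float(np.mean(neg >= thr))
        j = sens + spec - 1.0
        key = (j, sens, -thr)
        if best is None or key > best:
            best = key
            best_result = CutoffResult(
                threshold=float(thr), sensitivity=sens, specificity=spec, youden_j=j
            )
    assert best_result is not None
    return best_result


def binormal_auc(mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float) -> float:
    """Closed-form AUC for two normal score distributions.

    Equals ``Phi((mu_pos - mu_neg) / sqrt(sd_pos**2 + sd_neg**2))`` — the
    probability that a draw from the positive normal exceeds an independent
    draw from the negative normal. Serves as the analytic oracle for the
    group-conditional cohort simulations.
    """
    if sd_pos <= 0 or sd_neg <= 0:
        raise ValueError("standard deviations must be positive")
    return float(sps.norm.cdf((mu_pos - mu_neg) / np.hypot(sd_pos, sd_neg)))


# ---------------------------------------------------------------------------
# Regression models


@dataclass(frozen=True)
class EffectEstimate:
    estimate: float  # OR or HR
    ci_low: float
    ci_high: float


@dataclass
class LogisticResult:
    predictor: str
    covariates: tuple[str, ...]
    estimates: dict[str, EffectEstimate]  # term -> OR with 95% CI
    n: int
    ci_reliable: bool = True

    @property
    def odds_ratio(self) -> EffectEstimate:
        return self.estimates[self.predictor]


@dataclass
class CoxResult:
    predictor: str
    covariates: tuple[str, ...]
    estimates: dict[str, EffectEstimate]  # term -> HR with 95% CI
    n: int
    n_events: int

    @property
    def hazard_ratio(self) -> EffectEstimate:
        return self.estimates[self.predictor]


def _design_matrix(
    df: pd.DataFrame, columns: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Numeric design matrix; categoricals dummy-coded dropping the first level.

    Returns the matrix and a map from design column back to the source term.
    """
    parts: list[pd.DataFrame] = []
    origin: dict[str, str] = {}
    for col in columns:
        if df[col].isna().any():
            raise ValueError(f"missing values in column {col!r}")
        if pd.api.types.is_numeric_dtype(df[col]) and not pd.api.types.is_bool_dtype(
            df[col]
        ):
            parts.append(df[[col]].astype(float))
            origin[col] = col
        else:
            dummies = pd.get_dummies(df[col], prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
            for c in dummies.columns:
                origin[c] = col
    X = pd.concat(parts, axis=1)
    return X, origin


def fit_logistic_adjusted(
    cohort: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> LogisticResult:
    """Adjusted logistic regression; odds ratios with Wald 95% CIs.

    Maximum-likelihood fit via statsmodels. Perfect or quasi-perfect
    separation is reported as a warning and flags the CI as unreliable.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    y = cohort[outcome].astype(float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary with both classes")
    X, origin = _design_matrix(cohort, [predictor, *covariates])
    X = sm.add_constant(X)
    ci_reliable = True
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            conf = fit.conf_int(alpha=0.05)
        for w in caught:
            if issubclass(w.category, (PerfectSeparationWarning, RuntimeWarning)):
                ci_reliable = False
                warnings.warn(
                    f"possible separation in logistic fit: {w.message}", stacklevel=2
                )
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        # singular Hessian / separation: IRLS with pinv still yields a fit
        ci_reliable = False
        warnings.warn(
            f"separation-degenerate logistic fit ({exc}); CI unreliable",
            stacklevel=2,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            conf = fit.conf_int(alpha=0.05)
    estimates: dict[str, EffectEstimate] = {}
    for col in X.columns:
        if col == "const":
            continue
        estimates[origin[col]] = EffectEstimate(
            estimate=float(np.exp(fit.params[col])),
            ci_low=float(np.exp(conf.loc[col, 0])),
            ci_high=float(np.exp(conf.loc[col, 1])),
        )
    return LogisticResult(
        predictor=predictor,
        covariates=tuple(covariates),
        estimates=estimates,
        n=len(cohort),
        ci_reliable=ci_reliable,
    )


def fit_cox(
    cohort: pd.DataFrame,
    time: str,
    event: str,
    predictor: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties); HRs with Wald 95% CIs."""
    from lifelines import CoxPHFitter

    if (cohort[time] <= 0).any():
        raise ValueError("survival times must be positive")
    if cohort[event].sum() == 0:
        raise ValueError("at least one event is required")
    if cohort[time].nunique() == 1:
        warnings.warn("all survival times are tied", stacklevel=2)
    X, origin = _design_matrix(cohort, [predictor, *covariates])
    data = X.copy()
    data["_time"] = cohort[time].astype(float).to_numpy()
    data["_event"] = cohort[event].astype(int).to_numpy()
    cph = CoxPHFitter()
    cph.fit(data, duration_col="_time", event_col="_event")
    summary = cph.summary
    estimates: dict[str, EffectEstimate] = {}
    for col in X.columns:
        estimates[origin[col]] = EffectEstimate(
            estimate=float(summary.loc[col, "exp(coef)"]),
            ci_low=float(summary.loc[col, "exp(coef) lower 95%"]),
            ci_high=float(summary.loc[col, "exp(coef) upper 95%"]),
        )
    return CoxResult(
        predictor=predictor,
        covariates=tuple(covariates),
        estimates=estimates,
        n=len(cohort),
        n_events=int(cohort[event].sum()),
    )


# ---------------------------------------------------------------------------
# Survival curves


@dataclass
class KMCurve:
    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    mean_time: float  # restricted mean survival time
    mean_ci_low: float
    mean_ci_high: float
    n: int
    n_events: int


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float


def _rmst_and_se(kmf, tau: float) -> tuple[float, float]:
    """Restricted mean survival time to ``tau`` and its Greenwood-based SE.

    The RMST is the area under the KM step function on [0, tau]; its
    variance is ``sum_j A_j^2 d_j / (n_j (n_j - d_j))`` over event times
    ``t_j <= tau``, where ``A_j`` is the remaining area from ``t_j`` to
    ``tau`` — the standard large-sample form built on the Greenwood
    decomposition.
    """
    table = kmf.event_table
    knots = table.index.to_numpy(dtype=float)  # includes time 0
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    # area of each step [t_k, min(t_{k+1}, tau))
    upper = np.append(knots[1:], np.inf)
    widths = np.clip(np.minimum(upper, tau) - np.minimum(knots, tau), 0.0, None)
    areas = surv * widths
    rmst = float(areas.sum())
    tail_area = np.cumsum(areas[::-1])[::-1]  # A_j = area under S from t_j to tau
    d = table["observed"].to_numpy(dtype=float)
    n_at_risk = table["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = tail_area**2 * d / (n_at_risk * (n_at_risk - d))
    ok = (knots <= tau) & (d > 0) & (n_at_risk > d)
    return rmst, float(np.sqrt(terms[ok].sum()))


def km_logrank(
    times: Sequence[float],
    events: Sequence[int],
    group: Sequence[str],
) -> tuple[dict[str, KMCurve], LogRankResult]:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    The per-group mean survival time is the restricted mean (area under the
    KM curve) up to the largest observed time pooled across groups, with a
    Greenwood-based 95% CI.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    names = sorted(pd.unique(group).tolist())
    if len(names) != 2:
        raise ValueError(f"exactly two groups required, got {names}")
    for g in names:
        if not np.any(group == g):
            raise ValueError(f"empty group {g!r}")
    tau = float(times.max())
    curves: dict[str, KMCurve] = {}
    for g in names:
        mask = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        rmst, se = _rmst_and_se(kmf, tau)
        sf = kmf.survival_function_
        table = kmf.event_table
        curves[str(g)] = KMCurve(
            group=str(g),
            times=sf.index.to_numpy(dtype=float),
            survival=sf.iloc[:, 0].to_numpy(dtype=float),
            at_risk=table["at_risk"].to_numpy(dtype=float),
            mean_time=float(rmst),
            mean_ci_low=float(rmst - _Z95 * se),
            mean_ci_high=float(rmst + _Z95 * se),
            n=int(mask.sum()),
            n_events=int(events[mask].sum()),
        )
    m0, m1 = (group == names[0]), (group == names[1])
    res = logrank_test(times[m0], times[m1], events[m0], events[m1])
    return curves, LogRankResult(
        chi_square=float(res.test_statistic), p_value=float(res.p_value)
    )


# ---------------------------------------------------------------------------
# Group comparisons (baseline tables)


@dataclass
class GroupComparison:
    variable: str
    test: str
    statistic: float
    p_value: float
    descriptives: dict[str, dict[str, float]]
    warnings: list[str] = field(default_factory=list)


def _mean_descriptives(x: np.ndarray) -> dict[str, float]:
    n = len(x)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n) if n > 1 else 0.0
    return {"n": n, "mean": mean, "sd": sd, "ci_low": mean - half, "ci_high": mean + half}


def compare_groups(
    cohort: pd.DataFrame,
    variable: str | tuple[str, str],
    group: str | None = None,
    paired: bool = False,
    categorical: bool | None = None,
) -> GroupComparison:
    """Two-sample comparison with the test chosen the way clinical tables do.

    Continuous unpaired: Shapiro-Wilk on each group at alpha 0.05 gates an
    independent t-test (both normal) vs the Mann-Whitney U test; groups of
    fewer than 3 observations fall back to Mann-Whitney with a warning.
    Continuous paired (``variable`` is a pair of columns): Wilcoxon
    signed-rank. Categorical: chi-square, or Fisher's exact test when any
    expected cell count is below 5 on a 2x2 table.
    """
    notes: list[str] = []
    if paired:
        if not isinstance(variable, tuple) or len(variable) != 2:
            raise ValueError("paired comparison needs variable=(before, after)")
        before = cohort[variable[0]].to_numpy(dtype=float)
        after = cohort[variable[1]].to_numpy(dtype=float)
        stat, p = sps.wilcoxon(before, after)
        return GroupComparison(
            variable=f"{variable[0]} vs {variable[1]}",
            test="wilcoxon_signed_rank",
            statistic=float(stat),
            p_value=float(p),
            descriptives={
                variable[0]: _mean_descriptives(before),
                variable[1]: _mean_descriptives(after),
            },
        )
    if group is None:
        raise ValueError("group column required for unpaired comparison")
    values = cohort[variable]
    if categorical is None:
        categorical = not pd.api.types.is_numeric_dtype(values) or pd.api.types.is_bool_dtype(values)
    names = sorted(pd.unique(cohort[group]).tolist())
    if len(names) != 2:
        raise ValueError(f"exactly two groups required, got {names}")
    if categorical:
        table = pd.crosstab(cohort[group], values)
        chi2, p, _, expected = sps.chi2_contingency(table.to_numpy(), correction=False)
        test = "chi_square"
        stat = chi2
        if (expected < 5).any() and table.shape == (2, 2):
            odds, p = sps.fisher_exact(table.to_numpy())
            test, stat = "fisher_exact", odds
            notes.append("expected cell < 5: Fisher's exact test used")
        desc = {
            str(g): {
                "n": int(table.loc[g].sum()),
                **{
                    f"count_{lvl}": int(table.loc[g, lvl]) for lvl in table.columns
                },
                **{
                    f"percent_{lvl}": float(100 * table.loc[g, lvl] / table.loc[g].sum())
                    for lvl in table.columns
                },
            }
            for g in table.index
        }
        return GroupComparison(
            variable=str(variable), test=test, statistic=float(stat),
            p_value=float(p), descriptives=desc, warnings=notes,
        )
    a = cohort.loc[cohort[group] == names[0], variable].to_numpy(dtype=float)
    b = cohort.loc[cohort[group] == names[1], variable].to_numpy(dtype=float)
    if min(len(a), len(b)) < 3:
        notes.append("group too small for normality testing: Mann-Whitney used")
        normal = False
    else:
        normal = sps.shapiro(a).pvalue > 0.05 and sps.shapiro(b).pvalue > 0.05
    if normal:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        test = "t_test"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney_u"
    return GroupComparison(
        variable=str(variable),
        test=test,
        statistic=float(stat),
        p_value=float(p),
        descriptives={str(names[0]): _mean_descriptives(a), str(names[1]): _mean_descriptives(b)},
        warnings=notes,
    )
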