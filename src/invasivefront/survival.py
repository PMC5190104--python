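"""Survival statistics for the candidate and novel prognostic parameters.

Implements the clinical-statistics half of the pipeline:

* :func:`optimal_cutpoint` — maximally selected log-rank cut-point search
  over candidate thresholds, with a Monte-Carlo (label permutation)
  correction of the p-value for the multiplicity of the scan.
* :func:`dichotomize` — categorize patients above/below the training-set
  cut-offs (:class:`CutoffConfig` carries the published defaults: 287 buds,
  16 minimal-LVI events, 35 PDCs, 21% tumor:stroma, 35,647 um^2 AreaPDC).
* :func:`km_logrank` — Kaplan-Meier curves with the log-rank test;
  :func:`bh_adjust` — Benjamini-Hochberg FDR across a parameter family.
* :func:`cox_univariate` / :func:`cox_backward_aic` — proportional-hazards
  regression (Efron ties) and multivariate backward elimination with an
  AIC stopping rule.
* :func:`build_npi` — the composite prognostic index: high risk when at
  least 2 of {AreaPDC above cut-off, pT4 stage, poor differentiation} hold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class PatientRecord:
    """One patient: outcome, clinical covariates and feature values."""

    id: str
    time_months: float
    event: int
    pt_stage: str = "pT3"                  # pT3 | pT4
    differentiation: str = "moderate"      # well | moderate | poor
    covariates: dict[str, float] = dc_field(default_factory=dict)
    features: dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise ValueError("survival time must be nonnegative")
        if self.event not in (0, 1):
            raise ValueError("event flag must be 0 or 1")


@dataclass(frozen=True)
class Cutoff:
    threshold: float
    high_risk_group: int = 2   # which side carries the risk: 2 = above cut-off


@dataclass
class CutoffConfig:
    """Training-set dichotomization thresholds with comparison direction.

    Group 2 is always "value strictly above threshold" (values exactly at
    the threshold stay in group 1). For the tumor:stroma ratio the *low*
    group carries the risk; the grouping rule is unchanged, only the risk
    direction differs.
    """

    cutoffs: dict[str, Cutoff] = dc_field(default_factory=lambda: {
        "n_buds": Cutoff(287.0),
        "n_minimal_lvi": Cutoff(16.0),
        "n_pdc": Cutoff(35.0),
        "tumor_stroma_pct": Cutoff(21.0, high_risk_group=1),
        "area_pdc_um2": Cutoff(35_647.0),
    })

    def group(self, feature: str, value: float) -> int:
        cut = self.cutoffs[feature]
        return 2 if value > cut.threshold else 1


def dichotomize(
    patients: pd.DataFrame | list[PatientRecord],
    cutoffs: CutoffConfig | None = None,
) -> pd.DataFrame:
    """Per configured feature, assign each patient to group 1 (<=cut-off) or 2 (>).

    Patients with a missing feature value get NA for that feature (logged).
    """
    cutoffs = cutoffs or CutoffConfig()
    if not isinstance(patients, pd.DataFrame):
        from invasivefront.synthetic import cohort_to_frame

        patients = cohort_to_frame(patients)
    out = pd.DataFrame(index=patients.index)
    for feature, cut in cutoffs.cutoffs.items():
        if feature not in patients.columns:
            logger.info("feature %s absent from cohort table: skipped", feature)
            continue
        vals = pd.to_numeric(patients[feature], errors="coerce")
        grp = pd.Series(
            np.where(vals > cut.threshold, 2, 1), index=patients.index, dtype="Int64"
        )
        grp[vals.isna()] = pd.NA
        n_missing = int(vals.isna().sum())
        if n_missing:
            logger.info("feature %s: %d patients excluded (missing value)",
                        feature, n_missing)
        out[feature] = grp
    return out


# ---------------------------------------------------------------------------
# maximally selected log-rank cut-point
# ---------------------------------------------------------------------------

def _logrank_chi2_scan(
    values: np.ndarray, time: np.ndarray, event: np.ndarray, thresholds: np.ndarray
) -> np.ndarray:
    """Two-group log-rank chi-square for every candidate threshold (vectorized).

    Group membership for threshold c is ``value > c``. Returns one
    chi-square per threshold (0 where a split is degenerate).
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    v = values[order]
    n = len(t)

    uniq, starts = np.unique(t, return_index=True)
    # totals at risk / events per distinct time
    n_at_risk = n - starts                       # (K,)
    d_total = np.add.reduceat(e, starts)         # (K,)

    G = v[None, :] > thresholds[:, None]         # (T, n)
    Gf = G.astype(float)
    # suffix sums: group-1 members at risk at each distinct time
    suffix = np.cumsum(Gf[:, ::-1], axis=1)[:, ::-1]
    n1 = suffix[:, starts]                       # (T, K)
    d1 = np.add.reduceat(Gf * e[None, :], starts, axis=1)  # (T, K)

    has_event = d_total > 0
    nk = n_at_risk[has_event].astype(float)
    dk = d_total[has_event].astype(float)
    n1k = n1[:, has_event]
    d1k = d1[:, has_event]

    expected = dk * n1k / nk
    with np.errstate(divide="ignore", invalid="ignore"):
        var = dk * (n1k / nk) * (1 - n1k / nk) * (nk - dk) / np.maximum(nk - 1, 1)
    var[~np.isfinite(var)] = 0.0
    U = (d1k - expected).sum(axis=1)
    V = var.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, U**2 / V, 0.0)
    return chi2


@dataclass
class CutpointResult:
    feature: str
    threshold: float
    chi2: float
    p_naive: float
    p_corrected: float
    n_simulations: int
    n_candidates: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"value": [self.threshold, self.chi2, self.p_naive,
                       self.p_corrected, self.n_simulations]},
            index=["threshold", "chi2", "p_naive", "p_corrected", "n_simulations"],
        )


def optimal_cutpoint(
    values,
    time,
    event,
    n_sim: int = 1000,
    quantile_range: tuple[float, float] = (0.10, 0.90),
    seed: int = 0,
    feature: str = "feature",
) -> CutpointResult:
    """Optimal survival cut-point by maximally selected log-rank statistic.

    Candidate thresholds are the midpoints between consecutive sorted unique
    values, restricted to the inner quantile range (default 10th-90th
    percentile) to avoid degenerate tail splits. The naive p treats the
    maximal chi-square as a single 1-df test; the corrected p is the
    fraction of ``n_sim`` label-permuted datasets whose own maximal
    chi-square reaches the observed one (Monte-Carlo correction for the
    multiplicity of the scan).
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events for a cut-point search")
    uniq = np.unique(values)
    if len(uniq) < 2:
        raise ValueError("all feature values identical: no cut-point exists")

    lo, hi = np.quantile(values, quantile_range)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cand = mids[(mids >= lo) & (mids <= hi)]
    if len(cand) == 0:
        cand = mids  # tiny samples: fall back to the full scan

    chi2 = _logrank_chi2_scan(values, time, event, cand)
    best = int(np.argmax(chi2))
    obs = float(chi2[best])
    p_naive = float(stats.chi2.sf(obs, df=1))

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_sim):
        perm = rng.permutation(values)
        if _logrank_chi2_scan(perm, time, event, cand).max() >= obs:
            exceed += 1
    p_mc = (exceed + 1) / (n_sim + 1)
    p_corrected = float(max(p_mc, p_naive))  # the scan maximum can only inflate p

    return CutpointResult(
        feature=feature,
        threshold=float(cand[best]),
        chi2=obs,
        p_naive=p_naive,
        p_corrected=p_corrected,
        n_simulations=n_sim,
        n_candidates=len(cand),
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank / BH
# ---------------------------------------------------------------------------

@dataclass
class KMResult:
    curves: dict[object, pd.DataFrame]   # group -> survival function table
    chi2: float | None
    p: float | None
    group_sizes: dict[object, int]

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, curve in self.curves.items():
            ax.step(curve.index, curve.iloc[:, 0], where="post", label=str(label))
        ax.set_xlabel("time (months)")
        ax.set_ylabel("disease-specific survival")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax


def km_logrank(groups, time, event) -> KMResult:
    """Product-limit curves per group plus the (multi-group) log-rank test."""
    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = [g for g in pd.unique(groups) if not pd.isna(g)]
    if len(labels) == 0:
        raise ValueError("no groups provided")

    curves = {}
    sizes = {}
    for g in labels:
        m = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], label=str(g))
        curves[g] = kmf.survival_function_
        sizes[g] = int(m.sum())

    if len(labels) < 2:
        logger.warning("single group: Kaplan-Meier curves only, no log-rank test")
        return KMResult(curves, None, None, sizes)

    res = multivariate_logrank_test(time, groups, event)
    return KMResult(curves, float(res.test_statistic), float(res.p_value), sizes)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Hazard ratios with Wald 95% CIs, p-values and model AIC."""

    table: pd.DataFrame          # index: covariate; columns hr, ci_low, ci_high, p
    aic: float
    covariates: list[str]
    converged: bool = True
    elimination_trace: list[tuple[str | None, float]] | None = None

    def summary(self) -> pd.DataFrame:
        return self.table.round(4)

    def hr(self, name: str) -> float:
        return float(self.table.loc[name, "hr"])


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[["time", "event"] + covariates],
                duration_col="time", event_col="event")
    return cph


def _cox_table(cph: CoxPHFitter) -> pd.DataFrame:
    s = cph.summary
    return pd.DataFrame(
        {
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )


def _null_partial_loglik(time: np.ndarray, event: np.ndarray) -> float:
    """Efron partial log-likelihood of the null (no-covariate) Cox model."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = len(t)
    ll = 0.0
    uniq, starts = np.unique(t, return_index=True)
    n_at_risk = n - starts
    d = np.add.reduceat(e, starts)
    for nk, dk in zip(n_at_risk, d):
        for j in range(int(dk)):
            ll -= np.log(nk - j)
    return float(ll)


def cox_univariate(covariate, time, event, name: str = "covariate") -> CoxResult:
    """Single-covariate proportional-hazards fit (Efron ties, Wald CI)."""
    x = np.asarray(covariate, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    if len(np.unique(x)) < 2:
        raise ValueError("covariate is constant")

    df = pd.DataFrame({"time": time, "event": event, name: x})
    try:
        cph = _fit_cox(df, [name])
    except ConvergenceError as err:
        logger.warning("Cox fit did not converge (%s): likely monotone separation", err)
        return CoxResult(
            table=pd.DataFrame(
                {"hr": [np.nan], "ci_low": [np.nan], "ci_high": [np.nan], "p": [np.nan]},
                index=[name],
            ),
            aic=np.nan,
            covariates=[name],
            converged=False,
        )
    return CoxResult(_cox_table(cph), float(cph.AIC_partial_), [name])


def cox_backward_aic(
    covariates: pd.DataFrame, time, event
) -> CoxResult:
    """Multivariate Cox with backward elimination under an AIC stopping rule.

    Starting from the full model, repeatedly remove the covariate whose
    removal most decreases the (partial) AIC; stop when no removal decreases
    it. Collinear covariates are dropped with a warning before fitting. The
    retained set may be empty if nothing is informative.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = covariates.astype(float).copy()
    if X.shape[1] < 2:
        raise ValueError("backward elimination needs at least 2 covariates")

    # drop constant then collinear columns
    for col in list(X.columns):
        if X[col].nunique() < 2:
            warnings.warn(f"dropping constant covariate {col}", stacklevel=2)
            X = X.drop(columns=col)
    corr = X.corr().abs()
    dropped = set()
    cols = list(X.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if b not in dropped and a not in dropped and corr.loc[a, b] > 0.999:
                warnings.warn(f"dropping covariate {b}: collinear with {a}", stacklevel=2)
                dropped.add(b)
    X = X.drop(columns=list(dropped))

    df = pd.DataFrame({"time": time, "event": event}).join(X.reset_index(drop=True))
    current = list(X.columns)
    null_aic = -2.0 * _null_partial_loglik(time, event)

    def aic_of(subset: list[str]) -> float:
        if not subset:
            return null_aic
        return float(_fit_cox(df, subset).AIC_partial_)

    trace: list[tuple[str | None, float]] = [(None, aic_of(current))]
    while current:
        best_drop, best_aic = None, trace[-1][1]
        for cov in current:
            cand = [c for c in current if c != cov]
            a = aic_of(cand)
            if a < best_aic:
                best_drop, best_aic = cov, a
        if best_drop is None:
            break
        current.remove(best_drop)
        trace.append((best_drop, best_aic))

    if current:
        cph = _fit_cox(df, current)
        table = _cox_table(cph)
        aic = float(cph.AIC_partial_)
    else:
        table = pd.DataFrame(columns=["hr", "ci_low", "ci_high", "p"])
        aic = null_aic
    return CoxResult(table, aic, current, elimination_trace=trace)


# ---------------------------------------------------------------------------
# novel prognostic index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrognosticIndex:
    """Composite risk classification from three dichotomized parameters."""

    area_pdc_high: bool
    pt4: bool
    poor_differentiation: bool

    @property
    def score(self) -> int:
        return int(self.area_pdc_high) + int(self.pt4) + int(self.poor_differentiation)

    @property
    def group(self) -> str:
        return "high" if self.score >= 2 else "low"


def build_npi(
    patient: PatientRecord | dict,
    cutoffs: CutoffConfig | None = None,
) -> PrognosticIndex:
    """Composite prognostic index: high risk when >=2 of the three
    significant parameters are above cut-off (AreaPDC > 35,647 um^2,
    pT4 stage, poor differentiation).
    """
    cutoffs = cutoffs or CutoffConfig()
    if isinstance(patient, PatientRecord):
        area = patient.features.get("area_pdc_um2")
        pt_stage = patient.pt_stage
        diff = patient.differentiation
    else:
        area = patient.get("area_pdc_um2")
        pt_stage = patient.get("pt_stage")
        diff = patient.get("differentiation")
    if area is None or pd.isna(area):
        raise ValueError("NPI undefined: AreaPDC value missing")
    if pt_stage not in ("pT3", "pT4"):
        raise ValueError(f"NPI undefined: pT stage {pt_stage!r} not in {{pT3, pT4}}")
    if diff not in ("well", "moderate", "poor"):
        raise ValueError(f"NPI undefined: differentiation {diff!r} invalid")

    return PrognosticIndex(
        area_pdc_high=cutoffs.group("area_pdc_um2", float(area)) == 2,
        pt4=pt_stage == "pT4",
        poor_differentiation=diff == "poor",
    )
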