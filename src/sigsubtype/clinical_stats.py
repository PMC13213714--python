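"""Survival and categorical statistics for subtype comparison.

The clinical table is one row per sample with columns

    sample_id, cohort, os_months, os_event, response, age, sex, smoking, subtype

where ``os_months`` is overall survival in months, ``os_event`` 1 for
death and 0 for censoring, ``response`` in {responder, nonresponder},
``sex`` in {male, female}, ``smoking`` in {current, former, never} and
``subtype`` in {MUT1, MUT2}; any field may be missing (NaN). Rows with
missing OS are dropped from survival analyses; multivariate Cox models
are complete-case with a logged count.

Kaplan-Meier curves and Cox proportional-hazards fits delegate to
lifelines. The two-group log-rank test is computed directly so that the
per-event-time observed/expected/variance decomposition is available for
audit; the Pearson chi-square uses scipy. Cox models code MUT1 as the
reference level, so a hazard ratio above 1 means excess mortality in
MUT2; sex is coded male vs female reference and smoking as former/current
dummies vs never, with Efron tie handling by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import chi2, chi2_contingency

from sigsubtype.errors import SigsubtypeError, UndefinedStatisticError

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = [
    "sample_id",
    "cohort",
    "os_months",
    "os_event",
    "response",
    "age",
    "sex",
    "smoking",
    "subtype",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    event_times: np.ndarray  # distinct times with >= 1 death, ascending
    n_at_risk: np.ndarray  # at risk just before each event time
    n_events: np.ndarray
    survival: np.ndarray  # S(t) at each event time, non-increasing from 1
    median_survival: float | None  # smallest t with S(t) <= 0.5; None if never
    n: int
    n_observed_events: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )


def _extract_os(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    sub = records.dropna(subset=["os_months", "os_event"])
    if len(sub) == 0:
        raise UndefinedStatisticError("no records with overall-survival data")
    t = sub["os_months"].to_numpy(dtype=float)
    e = sub["os_event"].to_numpy(dtype=float).astype(int)
    if (t < 0).any():
        raise SigsubtypeError("negative survival times")
    return t, e


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one group of records.

    Censorings at an event time count as at-risk at that time (the
    standard convention). The median is the smallest observed time at
    which the curve reaches 0.5 or below, None if it never does.
    """
    from lifelines import KaplanMeierFitter

    t, e = _extract_os(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    mask = table["observed"] > 0
    times = table.index.to_numpy(dtype=float)[mask]
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    return KMCurve(
        event_times=times,
        n_at_risk=table.loc[mask, "at_risk"].to_numpy(dtype=int),
        n_events=table.loc[mask, "observed"].to_numpy(dtype=int),
        survival=surv,
        median_survival=None if np.isinf(median) else median,
        n=len(t),
        n_observed_events=int(e.sum()),
    )


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    observed: np.ndarray  # per-group total observed events (2,)
    expected: np.ndarray  # per-group total expected events (2,)
    table: pd.DataFrame  # per-event-time decomposition for group A

    @property
    def z_score(self) -> float:
        """Standardized O-E score for group A; chi_square == z_score**2."""
        v = self.table["variance"].sum()
        return float((self.observed[0] - self.expected[0]) / np.sqrt(v))


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> LogRankResult:
    """Two-group log-rank test on the clinical-table OS columns.

    At each distinct event time t with d deaths among n at risk (n_a in
    group A): O_a = deaths in A, E_a = n_a d / n, and hypergeometric
    variance V = d (n_a/n)(1 - n_a/n)(n - d)/(n - 1). The statistic is
    (sum O_a - sum E_a)^2 / sum V on 1 df.
    """
    ta, ea = _extract_os(group_a)
    tb, eb = _extract_os(group_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(len(ta), dtype=int), np.ones(len(tb), dtype=int)])
    if e.sum() == 0:
        raise UndefinedStatisticError("log-rank undefined with zero events")

    event_times, d = np.unique(t[e == 1], return_counts=True)
    t_sorted = np.sort(t)
    ta_sorted = np.sort(t[g == 0])
    n_risk = len(t) - np.searchsorted(t_sorted, event_times, side="left")
    na_risk = len(ta_sorted) - np.searchsorted(ta_sorted, event_times, side="left")
    d_a = np.zeros_like(d)
    ua, ca = np.unique(t[(e == 1) & (g == 0)], return_counts=True)
    d_a[np.searchsorted(event_times, ua)] = ca
    frac_a = na_risk / n_risk
    exp_a = frac_a * d
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(
            n_risk > 1, d * frac_a * (1 - frac_a) * (n_risk - d) / (n_risk - 1), 0.0
        )
    table = pd.DataFrame(
        {
            "time": event_times,
            "n_at_risk": n_risk,
            "n_at_risk_a": na_risk,
            "d": d,
            "observed": d_a,
            "expected": exp_a,
            "variance": var,
        }
    )
    O_a = float(table["observed"].sum())
    E_a = float(table["expected"].sum())
    V = float(table["variance"].sum())
    D = float(e.sum())
    if V == 0.0:
        raise UndefinedStatisticError("log-rank variance is zero")
    stat = (O_a - E_a) ** 2 / V
    p = float(chi2.sf(stat, df=1))
    return LogRankResult(
        chi_square=float(stat),
        df=1,
        p_value=p,
        observed=np.array([O_a, D - O_a]),
        expected=np.array([E_a, D - E_a]),
        table=table,
    )


@dataclass
class CoxCovariate:
    name: str
    coef: float
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float


@dataclass
class CoxResult:
    covariates: list[CoxCovariate]
    n: int
    n_events: int
    tie_method: str
    n_dropped_missing: int = 0
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> CoxCovariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "covariate": c.name,
                    "coef": c.coef,
                    "hazard_ratio": c.hazard_ratio,
                    "ci_lower": c.ci_lower,
                    "ci_upper": c.ci_upper,
                    "p_value": c.p_value,
                }
                for c in self.covariates
            ]
        )


_ENCODERS = {
    "subtype": ("subtype_MUT2", lambda s: (s == "MUT2").astype(float)),
    "sex": ("sex_male", lambda s: (s == "male").astype(float)),
}


def _design_matrix(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        if cov in _ENCODERS:
            name, enc = _ENCODERS[cov]
            cols[name] = enc(records[cov])
        elif cov == "smoking":
            cols["smoking_former"] = (records["smoking"] == "former").astype(float)
            cols["smoking_current"] = (records["smoking"] == "current").astype(float)
        else:
            cols[cov] = pd.to_numeric(records[cov], errors="coerce")
    return pd.DataFrame(cols, index=records.index)


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    tie_method: str = "efron",
) -> CoxResult:
    """Cox proportional-hazards regression on the clinical table.

    Categorical covariates are encoded with fixed references (MUT1,
    female, never-smoker) so that hazard ratios read as excess hazard of
    MUT2 / male / former / current. Missing-covariate rows are dropped
    complete-case with a logged count. Fitting delegates to lifelines'
    partial-likelihood maximization.
    """
    from lifelines import CoxPHFitter

    sub = records.dropna(subset=["os_months", "os_event"]).copy()
    if len(sub) == 0:
        raise UndefinedStatisticError("no records with overall-survival data")
    design = _design_matrix(sub, covariates)
    # complete-case: drop rows where any *source* covariate is missing
    source_missing = sub[covariates].isna().any(axis=1) | design.isna().any(axis=1)
    n_dropped = int(source_missing.sum())
    if n_dropped:
        logger.info("Cox: dropped %d row(s) with missing covariates", n_dropped)
    design = design[~source_missing.to_numpy()]
    sub = sub[~source_missing.to_numpy()]
    for col in design.columns:
        if design[col].nunique() < 2:
            raise SigsubtypeError(f"constant covariate {col!r}")
    n_events = int(sub["os_event"].sum())
    if n_events < design.shape[1] + 1:
        raise SigsubtypeError(
            f"too few events ({n_events}) for {design.shape[1]} covariates"
        )
    df = design.assign(
        os_months=sub["os_months"].to_numpy(dtype=float),
        os_event=sub["os_event"].to_numpy(dtype=float),
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="os_months", event_col="os_event", robust=False)
    if tie_method != "efron":
        raise SigsubtypeError("only Efron tie handling is supported")
    summary = cph.summary
    covs = [
        CoxCovariate(
            name=str(idx),
            coef=float(row["coef"]),
            hazard_ratio=float(row["exp(coef)"]),
            ci_lower=float(np.exp(row["coef lower 95%"])),
            ci_upper=float(np.exp(row["coef upper 95%"])),
            p_value=float(row["p"]),
        )
        for idx, row in summary.iterrows()
    ]
    return CoxResult(
        covariates=covs,
        n=len(sub),
        n_events=n_events,
        tie_method=tie_method,
        n_dropped_missing=n_dropped,
        metadata={"log_likelihood": float(cph.log_likelihood_)},
    )


def chi_square_test(
    contingency, yates: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a counts table.

    Continuity correction is off by default (``yates=True`` enables it
    for 2x2 tables). Returns (statistic, df, p).
    """
    table = np.asarray(contingency, dtype=float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise SigsubtypeError("contingency table must hold nonnegative integer counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise UndefinedStatisticError("chi-square undefined with a zero margin")
    stat, p, dof, _ = chi2_contingency(table, correction=yates)
    return float(stat), int(dof), float(p)


def response_table(records: pd.DataFrame) -> np.ndarray:
    """2x2 (subtype x response) counts from the clinical table."""
    sub = records.dropna(subset=["subtype", "response"])
    out = np.zeros((2, 2), dtype=int)
    for i, st in enumerate(["MUT1", "MUT2"]):
        grp = sub[sub["subtype"] == st]
        out[i, 0] = int((grp["response"] == "responder").sum())
        out[i, 1] = int((grp["response"] == "nonresponder").sum())
    return out


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0." + "0" * ndigits), rounding=ROUND_HALF_UP))


def percent(count: float, total: float, ndigits: int = 1) -> float:
    """Percentage rounded half-up to ``ndigits`` decimals (table formatting)."""
    return _round_half_up(100.0 * count / total, ndigits)


def cohort_summary(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pool per-cohort categorical count tables into one summary.

    Each value of ``tables`` is a long-format count table with columns
    (characteristic, category, count); within a cohort every
    characteristic's counts must sum to the cohort size. Returns a long
    table with per-cohort counts/percentages (of cohort n) and pooled
    counts/percentages (of pooled n), percentages rounded half-up to one
    decimal.
    """
    sizes = {}
    for cohort, tab in tables.items():
        sums = tab.groupby("characteristic")["count"].sum()
        n = int(sums.max())
        if (sums != n).any():
            logger.warning(
                "cohort %s: characteristic sums %s differ; using n=%d",
                cohort,
                dict(sums),
                n,
            )
        sizes[cohort] = n
    total_n = sum(sizes.values())

    long = pd.concat(
        [tab.assign(cohort=cohort) for cohort, tab in tables.items()], ignore_index=True
    )
    rows = []
    for (char, cat), grp in long.groupby(["characteristic", "category"], sort=False):
        pooled = int(grp["count"].sum())
        row = {
            "characteristic": char,
            "category": cat,
            "pooled_count": pooled,
            "pooled_percent": percent(pooled, total_n),
        }
        for cohort in tables:
            c = int(grp.loc[grp["cohort"] == cohort, "count"].sum())
            row[f"{cohort}_count"] = c
            row[f"{cohort}_percent"] = percent(c, sizes[cohort])
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["cohort_sizes"] = sizes
    out.attrs["total_n"] = total_n
    return out


def load_published_demographics() -> dict[str, pd.DataFrame]:
    """Per-cohort demographic count tables of six published UC cohorts.

    Counts transcribed from the published cohort descriptions (IMvigor210,
    UC-GENOME, TCGA, MSK2022, MSK2015, Tongji); percentages are always
    recomputed, never stored.
    """
    from importlib.resources import files

    path = files("sigsubtype.data").joinpath("uc_cohort_demographics.tsv")
    long = pd.read_csv(path, sep="\t", keep_default_na=False)  # "NA" is a category
    return {
        cohort: grp.drop(columns="cohort").reset_index(drop=True)
        for cohort, grp in long.groupby("cohort", sort=False)
    }


def records_to_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Summarize raw clinical records into the long count-table format."""
    rows = []
    n = len(records)

    def tally(char: str, series: pd.Series, categories: list[str]) -> None:
        counted = 0
        for cat in categories:
            c = int((series == cat).sum())
            counted += c
            rows.append({"characteristic": char, "category": cat, "count": c})
        rows.append({"characteristic": char, "category": "NA", "count": n - counted})

    tally("sex", records["sex"], ["female", "male"])
    tally("smoking", records["smoking"], ["former", "never", "current"])
    os_known = records.dropna(subset=["os_months", "os_event"])
    rows.append(
        {"characteristic": "os", "category": "event", "count": int((os_known["os_event"] == 1).sum())}
    )
    rows.append(
        {"characteristic": "os", "category": "censored", "count": int((os_known["os_event"] == 0).sum())}
    )
    rows.append({"characteristic": "os", "category": "NA", "count": n - len(os_known)})
    tally("ms_subtype", records["subtype"], ["MUT1", "MUT2"])
    return pd.DataFrame(rows)
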