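"""10-year overall-survival analysis: Kaplan-Meier, log-rank and Cox PH models.

Follow-up is administratively capped at 120 months before any fit (a death
after 10 years counts as censored at 120).  Cox models use Breslow tie
handling with Wald 95% confidence intervals exp(beta +/- 1.96 se); covariates
are binary indicators coded with the adverse level as 1 (LVI+, size >= 2 cm,
node+, grade 3, ER-, PR-, HER2+, genomic subtype 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import norm
from statsmodels.duration.hazard_regression import PHReg

from .errors import ConvergenceError, DomainError, FitError, GroupSizeError
from .io import ClinicalTable

logger = logging.getLogger(__name__)

TEN_YEARS_MONTHS = 120.0

#: clinical factor -> (adverse level, indicator column)
COVARIATE_CODING = {
    "lvi_status": ("positive", "lvi_positive"),
    "tumour_size": ("ge2cm", "size_ge2cm"),
    "nodal_status": ("positive", "node_positive"),
    "grade": ("grade3", "grade3"),
    "er": ("negative", "er_negative"),
    "pr": ("negative", "pr_negative"),
    "her2": ("positive", "her2_positive"),
}

DEFAULT_COVARIATES = ["lvi_positive", "size_ge2cm", "node_positive", "grade3",
                      "er_negative", "pr_negative", "her2_positive", "subtype2"]


@dataclass
class KMCurve:
    """Product-limit estimate for one group."""

    group: str
    times: np.ndarray        # event/censoring time grid
    survival: np.ndarray     # S(t) at those times
    at_risk: np.ndarray
    n: int
    events: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxResult:
    covariate: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    mode: str
    n: int
    events: int
    log_hr: float = np.nan
    se: float = np.nan


def build_survival_records(clinical: ClinicalTable | pd.DataFrame,
                           subtype_labels: pd.Series | None = None) -> pd.DataFrame:
    """Per-sample survival frame: time, event (0/1) and binary covariates.

    Unknown factor levels become NaN indicators (excluded listwise by the
    multivariate fit, per covariate by univariate fits).
    """
    df = clinical.data if isinstance(clinical, ClinicalTable) else clinical
    out = pd.DataFrame(index=df.index)
    out["time"] = df["followup_time"].astype(float)
    out["event"] = (df["event"].astype(str) == "death").astype(int)
    if (out["time"] <= 0).any():
        raise DomainError("survival records require time > 0")
    for factor, (adverse, indicator) in COVARIATE_CODING.items():
        vals = df[factor].astype(str)
        ind = pd.Series(np.nan, index=df.index)
        ind[vals != "unknown"] = (vals[vals != "unknown"] == adverse).astype(float)
        out[indicator] = ind
    if subtype_labels is not None:
        out["subtype2"] = (subtype_labels.reindex(df.index).astype(float) == 2).astype(float)
    return out


def cap_followup(records: pd.DataFrame, cap: float = TEN_YEARS_MONTHS) -> pd.DataFrame:
    """Administrative cap: any follow-up beyond ``cap`` becomes censored at ``cap``."""
    out = records.copy()
    over = out["time"] > cap
    out.loc[over, "time"] = cap
    out.loc[over, "event"] = 0
    return out


def km_estimate(records: pd.DataFrame,
                groups: pd.Series | None = None) -> dict[str, KMCurve]:
    """Kaplan-Meier curve per group (single group "all" when ``groups`` is None)."""
    if len(records) == 0:
        raise GroupSizeError("no survival records")
    if groups is None:
        groups = pd.Series("all", index=records.index)
    groups = groups.reindex(records.index)
    curves: dict[str, KMCurve] = {}
    for name in sorted(groups.dropna().unique(), key=str):
        sub = records[groups == name]
        if len(sub) == 0:
            raise GroupSizeError(f"empty survival group {name!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        times = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index)
        curves[str(name)] = KMCurve(group=str(name), times=times, survival=surv,
                                    at_risk=at_risk.to_numpy(dtype=float),
                                    n=len(sub), events=int(sub["event"].sum()))
    return curves


def logrank_test(records: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Two-group log-rank test -> (chi-squared statistic, p)."""
    groups = groups.reindex(records.index)
    levels = sorted(groups.dropna().unique(), key=str)
    if len(levels) != 2:
        raise GroupSizeError(f"log-rank needs exactly 2 groups, got {len(levels)}")
    a = records[groups == levels[0]]
    b = records[groups == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise GroupSizeError("empty group in log-rank test")
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"],
                      event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def _fit_single(frame: pd.DataFrame, covariates: list[str], mode: str) -> list[CoxResult]:
    if frame["event"].sum() == 0:
        raise FitError("no events; cannot fit Cox model")
    exog = frame[covariates].to_numpy(dtype=float)
    try:
        model = PHReg(frame["time"].to_numpy(dtype=float), exog,
                      status=frame["event"].to_numpy(dtype=int), ties="breslow")
        res = model.fit(disp=False)
    except Exception as exc:  # singular information matrix, separation, ...
        raise ConvergenceError(f"Cox fit failed for {covariates}: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not (np.isfinite(params).all() and np.isfinite(bse).all()):
        raise ConvergenceError(f"Cox fit did not converge for {covariates} "
                               "(non-finite estimate; possible complete separation)")
    out = []
    for name, beta, se in zip(covariates, params, bse):
        p = 2.0 * float(norm.sf(abs(beta / se))) if se > 0 else np.nan
        out.append(CoxResult(
            covariate=name, hr=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.96 * se)), ci_high=float(np.exp(beta + 1.96 * se)),
            p=p, mode=mode, n=len(frame), events=int(frame["event"].sum()),
            log_hr=float(beta), se=float(se)))
    return out


def cox_fit(records: pd.DataFrame, covariates: list[str] | None = None,
            mode: str = "univariate") -> list[CoxResult]:
    """Cox proportional-hazards fits.

    mode="univariate" fits one single-covariate model per covariate (dropping
    samples unknown for that covariate only); mode="multivariate" fits one
    joint model with listwise exclusion of any sample unknown for any
    configured covariate.
    """
    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES if c in records.columns]
    missing = [c for c in covariates if c not in records.columns]
    if missing:
        raise DomainError(f"covariates not present in records: {missing}")
    if mode == "univariate":
        results = []
        for cov in covariates:
            frame = records[["time", "event", cov]].dropna()
            results.extend(_fit_single(frame, [cov], "univariate"))
        return results
    if mode == "multivariate":
        frame = records[["time", "event", *covariates]].dropna()
        usable = _drop_degenerate(frame, covariates)
        return _fit_single(frame, usable, "multivariate")
    raise DomainError(f"mode must be univariate/multivariate, got {mode!r}")


def _drop_degenerate(frame: pd.DataFrame, covariates: list[str]) -> list[str]:
    """Remove constant columns and exact duplicates before a joint fit.

    Identical indicator columns make the partial-likelihood information matrix
    singular; among duplicates the last-listed covariate is retained (the
    variable added last to the base model, e.g. the genomic subtype).
    """
    keep: list[str] = []
    seen: dict[bytes, str] = {}
    for cov in covariates:
        col = frame[cov].to_numpy(dtype=float)
        if np.all(col == col[0]):
            logger.warning("multivariate Cox: dropping constant covariate %r", cov)
            continue
        key = col.tobytes()
        if key in seen:
            logger.warning("multivariate Cox: %r identical to %r; keeping %r",
                           seen[key], cov, cov)
            keep.remove(seen[key])
        seen[key] = cov
        keep.append(cov)
    if not keep:
        raise FitError("no usable covariates after removing degenerate columns")
    return keep


def cox_table(results: list[CoxResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "covariate": [r.covariate for r in results],
            "mode": [r.mode for r in results],
            "HR": [r.hr for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p": [r.p for r in results],
            "n": [r.n for r in results],
            "events": [r.events for r in results],
        }
    )


def km_curve_table(curves: dict[str, KMCurve]) -> pd.DataFrame:
    rows = []
    for name, c in curves.items():
        for t, s, r in zip(c.times, c.survival, c.at_risk):
            rows.append({"group": name, "time": t, "survival": s, "at_risk": r})
    return pd.DataFrame(rows)


def plot_km(curves: dict[str, KMCurve], path) -> None:
    """Step plot of the per-group survival curves (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, c in curves.items():
        ax.step(c.times, c.survival, where="post", label=f"{name} (n={c.n})")
    ax.set_xlabel("months")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
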