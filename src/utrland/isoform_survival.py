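"""Isoform relative abundance (PSI) and survival stratification.

Computes per-transcript PSI from a transcript TPM matrix, splice-event
ratios between named isoform sets, quartile patient stratification,
Kaplan-Meier curves, the log-rank test and univariate Cox
proportional-hazards regression (Breslow or Efron ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalData",
    "StratifiedGroups",
    "KmCurve",
    "LogRankResult",
    "CoxResult",
    "psi_per_isoform",
    "splice_event_ratio",
    "quartile_stratify",
    "km_estimator",
    "logrank_test",
    "cox_univariate",
]


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored survival observations.

    ``time`` in months (> 0); ``event`` 1 = death observed, 0 = censored.
    """

    patient_ids: tuple[str, ...]
    time: np.ndarray
    event: np.ndarray

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalData":
        """Build from a frame with columns patient_id, time_months, event."""
        t = df["time_months"].to_numpy(dtype=float)
        e = df["event"].to_numpy(dtype=int)
        if np.any(t <= 0):
            raise ValueError("survival times must be positive")
        if not np.all(np.isin(e, (0, 1))):
            raise ValueError("event flags must be 0 or 1")
        return cls(tuple(df["patient_id"].astype(str)), t, e)

    def subset(self, ids: Sequence[str]) -> "SurvivalData":
        index = {p: i for i, p in enumerate(self.patient_ids)}
        idx = [index[p] for p in ids if p in index]
        return SurvivalData(
            tuple(self.patient_ids[i] for i in idx), self.time[idx], self.event[idx]
        )

    def __len__(self) -> int:
        return len(self.time)


def psi_per_isoform(
    transcript_tpm: pd.DataFrame,
    gene_map: Mapping[str, str],
) -> pd.DataFrame:
    """Relative transcript abundance: tpm_t / sum of tpm over the gene.

    ``transcript_tpm`` has transcripts as rows and patients as columns.
    PSI is missing (NaN) for patients where the gene's total TPM is 0.
    """
    missing = [t for t in transcript_tpm.index if t not in gene_map]
    if missing:
        raise KeyError(f"transcripts without gene mapping: {missing[:5]}")
    genes = pd.Series({t: gene_map[t] for t in transcript_tpm.index}, name="gene")
    gene_totals = transcript_tpm.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = transcript_tpm / gene_totals
    return psi.where(gene_totals > 0)


def splice_event_ratio(
    psi: pd.DataFrame,
    numerator_transcripts: Sequence[str],
    denominator_transcripts: Sequence[str],
    pseudocount: float = 0.0,
) -> pd.Series:
    """Per-patient ratio between summed PSI of two isoform sets.

    ratio = (sum PSI over numerator + pseudocount) /
            (sum PSI over denominator + pseudocount);
    a zero denominator with pseudocount 0 yields a missing value.
    """
    num = psi.loc[list(numerator_transcripts)].sum(axis=0, min_count=1) + pseudocount
    den = psi.loc[list(denominator_transcripts)].sum(axis=0, min_count=1) + pseudocount
    ratio = num / den.where(den != 0)
    ratio.name = "splice_event_ratio"
    return ratio


@dataclass(frozen=True)
class StratifiedGroups:
    """Bottom- and top-quartile patient sets for a stratifying value."""

    low_group: tuple[str, ...]
    high_group: tuple[str, ...]
    degenerate: bool = False


def quartile_stratify(values: pd.Series, min_patients: int = 8) -> StratifiedGroups:
    """Nearest-rank bottom/top quartiles of the non-missing values.

    Group size is floor(n/4); ties are broken by stable patient-id
    order.  All-equal values are flagged degenerate.
    """
    v = values.dropna()
    n = len(v)
    if n < min_patients:
        raise ValueError(f"need >= {min_patients} patients with values, got {n}")
    k = n // 4
    order = v.reset_index()
    order.columns = ["patient_id", "value"]
    order = order.sort_values(["value", "patient_id"], kind="stable")
    low = tuple(order["patient_id"].iloc[:k])
    high = tuple(order["patient_id"].iloc[-k:])
    return StratifiedGroups(
        low_group=low,
        high_group=high,
        degenerate=bool(v.nunique() == 1),
    )


@dataclass(frozen=True)
class KmCurve:
    """Kaplan-Meier product-limit curve."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    median_survival: Optional[float]

    def at(self, t: float) -> float:
        """S(t): survival probability at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimator(data: SurvivalData) -> KmCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Median survival is the first event time with S <= 0.5, or None if
    the curve never reaches 0.5.
    """
    if len(data) == 0:
        raise ValueError("empty survival group")
    order = np.argsort(data.time, kind="stable")
    time, event = data.time[order], data.event[order]
    event_times = np.unique(time[event == 1])
    surv = []
    s = 1.0
    for t in event_times:
        n_at_risk = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    surv_arr = np.asarray(surv)
    median = None
    reached = np.nonzero(surv_arr <= 0.5)[0]
    if reached.size:
        median = float(event_times[reached[0]])
    return KmCurve(times=event_times, survival=surv_arr, median_survival=median)


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p: float


def logrank_test(group_a: SurvivalData, group_b: SurvivalData) -> LogRankResult:
    """Two-group log-rank test.

    chi_square = (sum_t (O_a - E_a))^2 / sum_t V_t over distinct event
    times, with hypergeometric expectation and variance at each time;
    p from the chi-square distribution with 1 df.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    all_time = np.concatenate([group_a.time, group_b.time])
    all_event = np.concatenate([group_a.event, group_b.event])
    group = np.concatenate([np.zeros(len(group_a)), np.ones(len(group_b))])
    if all_event.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    event_times = np.unique(all_time[all_event == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = all_time >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & (group == 0)).sum())
        dying = (all_time == t) & (all_event == 1)
        d = int(dying.sum())
        d_a = int((dying & (group == 0)).sum())
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return LogRankResult(chi_square=0.0, p=1.0)
    chi2 = o_minus_e**2 / var
    return LogRankResult(chi_square=float(chi2), p=float(stats.chi2.sf(chi2, df=1)))


@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox proportional-hazards fit."""

    beta: float
    hr: float
    se: float
    p: float
    n_iter: int


def _cox_derivatives(
    beta: float,
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str,
) -> tuple[float, float, float]:
    """Log partial likelihood, gradient and negative Hessian at beta.

    Inputs must be sorted by descending time so that risk sets are
    prefix sums.
    """
    eta = beta * x
    w = np.exp(eta)
    # running risk-set sums (descending time => cumulative from the top)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x)
    s2 = np.cumsum(w * x * x)
    loglik = grad = info = 0.0
    i = 0
    n = len(x)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        # risk set at this time = indices 0..j-1 (all with time >= time[i])
        r0, r1, r2 = s0[j - 1], s1[j - 1], s2[j - 1]
        deaths = np.nonzero(event[i:j] == 1)[0] + i
        d = len(deaths)
        if d:
            xsum = float(np.sum(x[deaths]))
            loglik += beta * xsum
            if ties == "breslow":
                loglik -= d * math.log(r0)
                grad += xsum - d * r1 / r0
                info += d * (r2 / r0 - (r1 / r0) ** 2)
            else:  # efron
                wd = w[deaths]
                d0 = float(np.sum(wd))
                d1 = float(np.sum(wd * x[deaths]))
                d2 = float(np.sum(wd * x[deaths] ** 2))
                for l in range(d):
                    f = l / d
                    e0 = r0 - f * d0
                    e1 = r1 - f * d1
                    e2 = r2 - f * d2
                    loglik -= math.log(e0)
                    grad += xsum / d - e1 / e0
                    info += e2 / e0 - (e1 / e0) ** 2
        i = j
    return loglik, grad, info


def cox_univariate(
    covariate: Sequence[float],
    data: SurvivalData,
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxResult:
    """Fit a univariate Cox model by Newton-Raphson on the partial likelihood.

    ``ties`` selects Breslow (default) or Efron tie handling.  Raises on
    constant covariates, absence of events or non-convergence; the
    standard error comes from the observed information and the p-value
    is a Wald test.
    """
    x = np.asarray(covariate, dtype=float)
    if len(x) != len(data):
        raise ValueError("covariate and survival data lengths differ")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: hazard ratio is not identifiable")
    if data.event.sum() == 0:
        raise ValueError("Cox fit requires at least one event")
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie handling {ties!r}")
    # center for numerical stability; beta is invariant under shifts
    x = x - x.mean()
    order = np.argsort(-data.time, kind="stable")
    xs, ts, es = x[order], data.time[order], data.event[order]
    beta = 0.0
    for it in range(1, max_iter + 1):
        _, grad, info = _cox_derivatives(beta, xs, ts, es, ties)
        if info <= 0:
            raise RuntimeError("non-positive information in Cox fit")
        step = grad / info
        # dampen huge steps to keep exp() finite
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(grad) < tol:
            se = 1.0 / math.sqrt(info)
            z = beta / se
            return CoxResult(
                beta=float(beta),
                hr=float(math.exp(beta)),
                se=float(se),
                p=float(2 * stats.norm.sf(abs(z))),
                n_iter=it,
            )
    raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations")
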