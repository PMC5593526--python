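"""Median-split Kaplan-Meier analysis, log-rank testing, and the
mutation-association test.

Patients are dichotomized per gene at the cohort median of that gene's
expression (strictly greater than the median -> High, else Low), the
product-limit survival curves of the two groups are compared with the
two-group log-rank test (chi-square, 1 df), and the association between p53
mutation status and expression group is tested with the two-sided Fisher
exact test.  The per-gene prognosis screen reports nominal p-values at
alpha = 0.05 by default; Benjamini-Hochberg adjustment is available but off.

Kaplan-Meier estimation and the log-rank statistic are computed with
lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .data_model import GeneSet, ValidationError
from .enrichment import ContingencyTable2x2, fisher_exact_two_sided

METADATA_COLUMNS = ("patient_id", "p53_status", "time_days", "event")


@dataclass
class CohortTable:
    """Per-patient expression, p53 status and survival outcome.

    ``table`` columns: patient_id, p53_status (wt|mut), time_days, event
    (1 = death observed, 0 = censored), then one column per gene.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(METADATA_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
        if (self.table["time_days"] < 0).any():
            raise ValidationError("negative survival time")
        if not self.table["p53_status"].isin(["wt", "mut"]).all():
            raise ValidationError("p53_status must be wt|mut")
        if not self.table["event"].isin([0, 1, True, False]).all():
            raise ValidationError("event must be boolean")
        expr = self.table[self.gene_columns]
        if expr.isna().any().any():
            raise ValidationError("missing expression values in cohort")

    @property
    def gene_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in METADATA_COLUMNS]


def read_cohort_table(path: str | Path) -> CohortTable:
    return CohortTable(table=pd.read_csv(path, sep="\t"))


def write_cohort_table(cohort: CohortTable, path: str | Path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# median split
# ---------------------------------------------------------------------------

def median_split(cohort: CohortTable, gene: str) -> pd.Series:
    """Assign each patient to "High" (expression strictly greater than the
    cohort median) or "Low".  A constant expression column cannot be split
    and raises."""
    if gene not in cohort.gene_columns:
        raise ValidationError(f"gene {gene!r} not in cohort")
    values = cohort.table[gene].to_numpy(dtype=float)
    if np.all(values == values[0]):
        raise ValidationError(f"expression of {gene!r} is constant; no median split")
    cutoff = float(np.median(values))
    groups = np.where(values > cutoff, "High", "Low")
    return pd.Series(groups, index=cohort.table.index, name=f"{gene}_group")


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KmCurve:
    """Product-limit survival estimate at each distinct event time."""

    times: np.ndarray       # distinct event times, ascending
    at_risk: np.ndarray     # number at risk just before each event time
    survival: np.ndarray    # S(t) just after each event time
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KmCurve:
    """Kaplan-Meier product-limit estimator (via lifelines); data with no
    events yields a flat curve at 1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValidationError("no observations")
    if (times < 0).any():
        raise ValidationError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    event_rows = tab[tab["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    event_times = event_rows.index.to_numpy(dtype=float)
    return KmCurve(
        times=event_times,
        at_risk=event_rows["at_risk"].to_numpy(dtype=float),
        survival=surv.loc[event_rows.index].to_numpy(dtype=float),
        censor_times=np.sort(times[~events]),
    )


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    df: int = 1


def logrank_test(
    groups: Sequence[str],
    times: Sequence[float],
    events: Sequence[bool],
) -> LogrankResult:
    """Two-group log-rank test: observed-minus-expected event counts over
    the hypergeometric variance, summed across distinct event times;
    p from chi-square with 1 df."""
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.unique(groups)
    if len(labels) != 2:
        # a group with zero patients collapses the labels to one
        raise ValidationError(f"log-rank needs exactly two non-empty groups, got {list(labels)}")
    in_a = groups == labels[0]
    res = _ll_logrank(
        times[in_a], times[~in_a], event_observed_A=events[in_a],
        event_observed_B=events[~in_a],
    )
    return LogrankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


# ---------------------------------------------------------------------------
# mutation association
# ---------------------------------------------------------------------------

def mutation_association(cohort: CohortTable, gene: str, split: pd.Series | None = None):
    """Two-sided Fisher exact test of p53 status x expression group.

    Returns (p_value, table); the table rows are (mut, wt) and the columns
    (High, Low), so its margins equal the status-group and split-group sizes
    exactly.
    """
    split = median_split(cohort, gene) if split is None else split
    status = cohort.table["p53_status"]
    if not (status == "mut").any() or not (status == "wt").any():
        raise ValidationError("both p53 status groups must be non-empty")
    a = int(((status == "mut") & (split == "High")).sum())
    b = int(((status == "mut") & (split == "Low")).sum())
    c = int(((status == "wt") & (split == "High")).sum())
    d = int(((status == "wt") & (split == "Low")).sum())
    table = ContingencyTable2x2(a, b, c, d)
    return fisher_exact_two_sided(table), table


# ---------------------------------------------------------------------------
# prognosis screen
# ---------------------------------------------------------------------------

def _restricted_mean(curve: KmCurve, horizon: float) -> float:
    """Area under the KM curve up to ``horizon`` (restricted mean survival
    time); used only to orient which group fares worse."""
    ts = np.concatenate([[0.0], curve.times[curve.times <= horizon], [horizon]])
    widths = np.diff(ts)
    # S is a right-continuous step function, constant on [t_i, t_{i+1})
    heights = np.array([curve.survival_at(t) for t in ts[:-1]])
    return float(np.sum(widths * heights))


def prognosis_screen(
    cohort: CohortTable,
    module: GeneSet,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Median-split log-rank screen over a gene set.

    Returns one row per gene: log-rank p, which group has worse survival
    (by restricted mean survival time), and a significance flag at ``alpha``
    on the nominal p (or the BH-adjusted p when ``bh_correct``).
    """
    genes = sorted(g for g in module.members if g in cohort.gene_columns)
    if not genes:
        raise ValidationError("no module genes present in cohort")
    times = cohort.table["time_days"].to_numpy(dtype=float)
    events = cohort.table["event"].to_numpy(dtype=bool)
    horizon = float(times.max())
    rows = {}
    for gene in genes:
        split = median_split(cohort, gene)
        res = logrank_test(split.to_numpy(), times, events)
        high = split == "High"
        rms_high = _restricted_mean(km_estimate(times[high], events[high]), horizon)
        rms_low = _restricted_mean(km_estimate(times[~high], events[~high]), horizon)
        rows[gene] = {
            "logrank_p": res.p_value,
            "statistic": res.statistic,
            "worse_group": "High" if rms_high < rms_low else "Low",
            "n_high": int(high.sum()),
            "n_low": int((~high).sum()),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        out["p_adjusted"] = multipletests(out["logrank_p"], method="fdr_bh")[1]
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["logrank_p"] < alpha
    return out
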