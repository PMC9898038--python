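"""Sample composition, Shannon-entropy ITH, median splits and survival analysis.

A sample's intratumoral heterogeneity (ITH) is the Shannon entropy (base 2) of
its six-state composition among leukemia-like cells: 0 for a monoclonal
sample, log2(6) when all six states are equally represented.  Samples are
stratified by the median of a per-sample statistic and compared with
Kaplan-Meier estimates and the log-rank test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .synthetic import STATE_ORDER

log = logging.getLogger("lscape")


class HeterogeneityError(ValueError):
    pass


@dataclass
class CompositionRecord:
    sample: str
    proportions: pd.Series     # over the six states, sums to 1
    n_leukemia_cells: int
    ith: float


def shannon_ith(p, normalized: bool = False) -> float:
    """Shannon entropy (base 2) of a composition vector; 0*log0 := 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise HeterogeneityError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise HeterogeneityError(f"proportions must sum to 1 (got {p.sum()})")
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    if normalized and len(p) > 1:
        h /= math.log2(len(p))
    return h


def composition(states: pd.Series, samples: pd.Series,
                state_order: list[str] | None = None,
                normalized_entropy: bool = False) -> list[CompositionRecord]:
    """Per-sample state proportions (among leukemia-like cells) with ITH.

    ``states`` holds the assigned state of each leukemia-like cell and
    ``samples`` the sample id of the same cells.  Samples with no leukemia-like
    cell simply do not appear (their absence is logged).
    """
    order = list(state_order or STATE_ORDER)
    samples = samples.loc[states.index]
    records = []
    for sample, idx in states.groupby(samples.astype(str)).groups.items():
        counts = states.loc[idx].value_counts().reindex(order).fillna(0).astype(int)
        n = int(counts.sum())
        props = counts / n
        records.append(CompositionRecord(
            sample=str(sample), proportions=props, n_leukemia_cells=n,
            ith=shannon_ith(props.to_numpy(), normalized=normalized_entropy),
        ))
    return records


def composition_frame(records: list[CompositionRecord]) -> pd.DataFrame:
    """Records as a samples x (states + ITH + n) DataFrame."""
    rows = {}
    for r in records:
        row = r.proportions.to_dict()
        row["ITH"] = r.ith
        row["n_leukemia_cells"] = r.n_leukemia_cells
        rows[r.sample] = row
    return pd.DataFrame(rows).T


def median_split(values: pd.Series) -> pd.Series:
    """High/Low labels by the median; ties go to Low."""
    if len(values) < 2:
        raise HeterogeneityError("need at least 2 samples to split")
    med = float(values.median())
    labels = pd.Series(np.where(values > med, "High", "Low"),
                       index=values.index, name="group")
    if labels.nunique() < 2:
        raise HeterogeneityError("degenerate split: all values on one side of the median")
    return labels


def median_cross_split(a: pd.Series, b: pd.Series,
                       names: tuple[str, str] = ("A", "B")) -> pd.Series:
    """Four-way grouping by the medians of two per-sample statistics
    (e.g. QSC-high/PSP-low vs QSC-low/PSP-high)."""
    ga, gb = median_split(a), median_split(b.loc[a.index])
    return pd.Series([f"{names[0]}{x}_{names[1]}{y}" for x, y in zip(ga, gb)],
                     index=a.index, name="group")


def km_estimate(table: pd.DataFrame, group_col: str = "group") -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group.

    ``table`` needs ``time`` and ``event`` columns (event in {0, 1}); returns
    per group a DataFrame with ``time`` and ``survival`` columns (step values
    at event times).
    """
    _check_table(table)
    out = {}
    groups = table[group_col].unique() if group_col in table.columns else ["all"]
    for g in groups:
        sub = table if g == "all" and group_col not in table.columns else table[table[group_col] == g]
        if sub["event"].sum() == 0:
            log.warning("km_estimate: group %s has no events; curve is flat at 1", g)
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        out[str(g)] = pd.DataFrame({"time": sf.index.to_numpy(),
                                    "survival": sf.iloc[:, 0].to_numpy()})
    return out


def logrank_test(table: pd.DataFrame, group_col: str = "group") -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    _check_table(table)
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise HeterogeneityError(f"log-rank needs exactly 2 groups, got {groups}")
    a = table[table[group_col] == groups[0]]
    b = table[table[group_col] == groups[1]]
    if len(a) == 0 or len(b) == 0:
        raise HeterogeneityError("both groups must be nonempty")
    if table["event"].sum() == 0:
        raise HeterogeneityError("no events: log-rank variance is zero")
    res = _ll_logrank(a["time"], b["time"],
                      event_observed_A=a["event"], event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def _check_table(table: pd.DataFrame) -> None:
    for col in ("time", "event"):
        if col not in table.columns:
            raise HeterogeneityError(f"survival table missing column {col!r}")
    if (table["time"] <= 0).any():
        raise HeterogeneityError("times must be positive")
    if not set(np.unique(table["event"])) <= {0, 1}:
        raise HeterogeneityError("event flags must be 0/1")
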