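"""Discrimination layer: Z-scores, composite score, ROC/cut-offs, regression.

Each per-image readout is standardized to a Z-score within a stratum
(by default the week, so the steady age-related drift of cell counts does
not leak into between-week comparisons) and the composite score is the
unweighted mean of the component Z-scores — by default CC and SuA, the two
readouts that separate immunized from control animals. Discrimination is
quantified by an ROC over the score, with the immunized group as the
positive class; the AUC equals the Mann-Whitney pair probability with
ties counted 1/2. A cut-off is chosen from the full candidate table by a
named strategy (balanced sensitivity/specificity by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Bonferroni-adjusted significance level used in summary outputs
ALPHA = 0.025

COMPONENT_COLUMNS = ("cc", "sua", "mvi", "mcb", "ava")


def zscore(values, strata=None) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (n-1 denominator) within strata.

    A stratum with fewer than two values or zero spread is an explicit
    error: silently emitting zeros would fabricate a signal.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("zscore expects a 1D sequence")
    out = np.empty_like(x)
    if strata is None:
        groups = [np.arange(len(x))]
    else:
        s = np.asarray(strata)
        if len(s) != len(x):
            raise ValueError("strata length does not match values")
        groups = [np.flatnonzero(s == u) for u in pd.unique(s)]
    for idx in groups:
        if len(idx) < 2:
            raise ValueError(f"stratum with {len(idx)} value(s): need >= 2")
        sd = float(np.std(x[idx], ddof=1))
        if sd == 0:
            raise ValueError("constant stratum: zero standard deviation")
        out[idx] = (x[idx] - np.mean(x[idx])) / sd
    return out


def composite_score(table: pd.DataFrame, components=("cc", "sua"),
                    strata: str | None = "week") -> pd.DataFrame:
    """Add z_<component> columns and their unweighted mean ``composite``.

    ``strata`` names a column of the table (default "week"); None pools
    all rows into one standardization stratum.
    """
    missing = [c for c in components if c not in table.columns]
    if missing:
        raise KeyError(f"missing component column(s) {missing}")
    if strata is not None and strata not in table.columns:
        raise KeyError(f"missing strata column {strata!r}")
    out = table.copy()
    svals = out[strata].to_numpy() if strata is not None else None
    zcols = []
    for c in components:
        vals = out[c].to_numpy(dtype=np.float64)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"component {c!r} contains non-finite values")
        out[f"z_{c}"] = zscore(vals, svals)
        zcols.append(f"z_{c}")
    out["composite"] = out[zcols].mean(axis=1)
    return out


@dataclass
class RocResult:
    """ROC of a score against a binary label, higher score = positive.

    ``thresholds`` are the unique score values in ascending order; a frame
    is called positive when its score >= threshold, so sensitivity is
    non-increasing and specificity non-decreasing along the list.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    positive_label: object
    chosen_cutoff: float | None = None
    sens_at_cutoff: float | None = None
    spec_at_cutoff: float | None = None
    _scores: np.ndarray = field(default=None, repr=False)
    _positive: np.ndarray = field(default=None, repr=False)


def roc(scores, labels, positive) -> RocResult:
    """ROC curve and AUC (trapezoid == Mann-Whitney with ties at 1/2)."""
    s = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    y = labels == positive
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"both classes required: {n_pos} positive / {n_neg} negative "
            f"for positive label {positive!r}"
        )
    thr = np.unique(s)  # ascending
    sens = np.array([(s[y] >= t).mean() for t in thr])
    spec = np.array([(s[~y] < t).mean() for t in thr])
    # curve in descending-threshold order, with the empty and full calls
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    fpr = np.concatenate([[0.0], 1.0 - spec[::-1], [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thr, sensitivity=sens, specificity=spec,
                     auc=auc, positive_label=positive, _scores=s, _positive=y)


def _cutoff_candidates(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


def cutoff_table(r: RocResult) -> pd.DataFrame:
    """Sensitivity/specificity at every candidate cut-off (call: score >= cutoff)."""
    s, y = r._scores, r._positive
    rows = []
    for c in _cutoff_candidates(s):
        rows.append({
            "cutoff": float(c),
            "sensitivity": float((s[y] >= c).mean()),
            "specificity": float((s[~y] < c).mean()),
        })
    return pd.DataFrame(rows)


def choose_cutoff(r: RocResult, strategy: str = "balanced",
                  floor: float | None = None) -> tuple[float, float, float]:
    """Pick a cut-off from the candidate table by a named strategy.

    balanced      minimize |sens - spec|; ties -> larger sens + spec,
                  then lower cutoff
    youden        maximize sens + spec - 1; ties -> lower cutoff
    sens_floor    maximize specificity subject to sensitivity >= floor
    spec_floor    maximize sensitivity subject to specificity >= floor

    Returns (cutoff, sensitivity, specificity) and records them on ``r``.
    """
    tab = cutoff_table(r)
    c = tab["cutoff"].to_numpy()
    sens = tab["sensitivity"].to_numpy()
    spec = tab["specificity"].to_numpy()
    if strategy == "balanced":
        order = np.lexsort((c, -(sens + spec), np.abs(sens - spec)))
        best = order[0]
    elif strategy == "youden":
        order = np.lexsort((c, -(sens + spec)))
        best = order[0]
    elif strategy in ("sens_floor", "spec_floor"):
        if floor is None:
            raise ValueError(f"{strategy} requires a floor value")
        primary, secondary = (sens, spec) if strategy == "sens_floor" else (spec, sens)
        ok = np.flatnonzero(primary >= floor)
        if len(ok) == 0:
            raise ValueError(f"infeasible floor {floor} for {strategy}")
        order = ok[np.lexsort((c[ok], -primary[ok], -secondary[ok]))]
        best = order[0]
    else:
        raise ValueError(f"unknown cut-off strategy {strategy!r}")
    r.chosen_cutoff = float(c[best])
    r.sens_at_cutoff = float(sens[best])
    r.spec_at_cutoff = float(spec[best])
    return r.chosen_cutoff, r.sens_at_cutoff, r.spec_at_cutoff


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares y ~ x; R^2 is the squared Pearson correlation."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 3:
        raise ValueError(f"need n >= 3, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    res = stats.linregress(x, y)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue) ** 2,
                     p_value=float(res.pvalue), n=len(x))
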