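"""Evaluation metrics for effect-detection methods.

Accuracy is plain proportion of agreement with the true labels; the Type I
error rate is P(detect | no true effect) and power is P(detect | true
effect).  Uncertainty on every proportion is a Wald 95% binomial interval,
and differences are flagged by the point-versus-interval rule: a proportion
is "significantly" different from a comparison value when it falls outside
the comparison's interval.  Metrics can be stratified by any of the six
manipulated graph characteristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ABGraph, DatasetManifest

__all__ = [
    "accuracy",
    "type1_rate",
    "power",
    "agreement_matrix",
    "binomial_ci",
    "significance_flag",
    "stratify",
    "MetricsReport",
    "evaluate_method",
    "CHARACTERISTICS",
]

#: z for a two-sided 95% normal interval.
Z_95 = 1.959964

#: The six stratification variables and how to read each off a graph.
CHARACTERISTICS = {
    "n_a": lambda g: g.spec.n_a,
    "n_b": lambda g: g.spec.n_b,
    "autocorr": lambda g: g.spec.autocorr,
    "trend": lambda g: g.spec.trend_deg,
    "variability": lambda g: g.spec.var_level,
    "smd": lambda g: g.spec.smd,
}


class UndefinedMetricError(ValueError):
    """The metric's conditioning set is empty."""


def _as_binary(vec, name: str) -> np.ndarray:
    arr = np.asarray(vec, dtype=int)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return arr


def _check_lengths(pred: np.ndarray, truth: np.ndarray) -> None:
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(truth)} truths")


def accuracy(pred, truth) -> float:
    """Proportion of positions where the two 0/1 vectors agree."""
    pred = _as_binary(pred, "pred")
    truth = _as_binary(truth, "truth")
    _check_lengths(pred, truth)
    return float((pred == truth).mean())


def type1_rate(pred, truth) -> float:
    """P(pred = 1 | truth = 0): false detections among no-effect graphs."""
    pred = _as_binary(pred, "pred")
    truth = _as_binary(truth, "truth")
    _check_lengths(pred, truth)
    neg = truth == 0
    if not neg.any():
        raise UndefinedMetricError("no graphs without a true effect; Type I rate undefined")
    return float(pred[neg].mean())


def power(pred, truth) -> float:
    """P(pred = 1 | truth = 1): detections among graphs with a true effect."""
    pred = _as_binary(pred, "pred")
    truth = _as_binary(truth, "truth")
    _check_lengths(pred, truth)
    pos = truth == 1
    if not pos.any():
        raise UndefinedMetricError("no graphs with a true effect; power undefined")
    return float(pred[pos].mean())


def agreement_matrix(
    preds: dict[str, np.ndarray], truth: np.ndarray | None = None
) -> pd.DataFrame:
    """Pairwise proportion-of-agreement matrix between methods.

    Parameters
    ----------
    preds : dict mapping method id to 0/1 decision vector
    truth : optional true-label vector; adds a "True" row/column

    Returns
    -------
    DataFrame, symmetric with unit diagonal.
    """
    vectors = {k: _as_binary(v, k) for k, v in preds.items()}
    if truth is not None:
        vectors = {"True": _as_binary(truth, "truth"), **vectors}
    names = list(vectors)
    lengths = {len(v) for v in vectors.values()}
    if len(lengths) > 1:
        raise ValueError(f"prediction vectors have differing lengths: {sorted(lengths)}")
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i:]:
            p = float((vectors[a] == vectors[b]).mean())
            mat.loc[a, b] = p
            mat.loc[b, a] = p
    return mat


def binomial_ci(p: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wald binomial interval ``p ± z * sqrt(p(1-p)/n)``, clipped to [0, 1]."""
    if not 0 <= p <= 1:
        raise ValueError("p must be a proportion")
    if n < 1:
        raise ValueError("n must be at least 1")
    if level == 0.95:
        z = Z_95
    else:
        from scipy.stats import norm

        z = float(norm.ppf(0.5 + level / 2))
    half = z * np.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def significance_flag(p1: float, n1: int, p2: float, n2: int, level: float = 0.95) -> bool:
    """True when ``p1`` lies outside the binomial interval around ``p2``.

    The rule is asymmetric (it uses only the comparison value's interval);
    callers interested in both orientations should evaluate both orderings.
    ``n1`` is accepted for a symmetric call signature but unused.
    """
    lo, hi = binomial_ci(p2, n2, level=level)
    return bool(p1 < lo or p1 > hi)


@dataclass
class MetricsReport:
    """Accuracy / Type I / power for one method, with Wald 95% intervals.

    Missing (undefined) metrics are NaN, never 0 — e.g. power in a stratum
    that contains no true-effect graphs.
    """

    method_id: str
    n: int
    accuracy: float
    type1_rate: float
    power: float
    accuracy_ci: tuple[float, float]
    type1_ci: tuple[float, float]
    power_ci: tuple[float, float]
    n_neg: int = 0
    n_pos: int = 0
    strata: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (stratum, metric)."""
        rows = []

        def add(var, lev, metric, est, ci, n):
            lo, hi = ci if est == est else (float("nan"), float("nan"))
            rows.append(
                {
                    "method": self.method_id,
                    "stratum_variable": var,
                    "stratum_level": lev,
                    "metric": metric,
                    "estimate": est,
                    "ci_low": lo,
                    "ci_high": hi,
                    "n": n,
                }
            )

        add("overall", "", "accuracy", self.accuracy, self.accuracy_ci, self.n)
        add("overall", "", "type1_rate", self.type1_rate, self.type1_ci, self.n_neg)
        add("overall", "", "power", self.power, self.power_ci, self.n_pos)
        for var, levels in self.strata.items():
            for lev, sub in levels.items():
                add(var, lev, "type1_rate", sub["type1_rate"], sub["type1_ci"], sub["n_neg"])
                add(var, lev, "power", sub["power"], sub["power_ci"], sub["n_pos"])
        return pd.DataFrame(rows)


def _safe(metric_fn, pred, truth):
    try:
        return metric_fn(pred, truth)
    except UndefinedMetricError:
        return float("nan")


def _ci_or_nan(p: float, n: int) -> tuple[float, float]:
    if n == 0 or p != p:
        return (float("nan"), float("nan"))
    return binomial_ci(p, n)


def stratify(
    pred,
    truth,
    manifest: DatasetManifest,
    characteristic: str,
) -> dict:
    """Type I rate and power per level of one graph characteristic.

    For ``smd`` the no-effect level 0 yields only a Type I rate and the
    effect levels 1-5 only power; those undefined entries are NaN.
    """
    if characteristic not in CHARACTERISTICS:
        raise ValueError(
            f"unknown characteristic {characteristic!r}; "
            f"expected one of {sorted(CHARACTERISTICS)}"
        )
    pred = _as_binary(pred, "pred")
    truth = _as_binary(truth, "truth")
    _check_lengths(pred, truth)
    if len(pred) != len(manifest):
        raise ValueError("prediction length does not match manifest size")
    getter = CHARACTERISTICS[characteristic]
    values = np.array([getter(g) for g in manifest])
    out: dict = {}
    for level in sorted(set(values.tolist())):
        mask = values == level
        p, t = pred[mask], truth[mask]
        n_neg = int((t == 0).sum())
        n_pos = int((t == 1).sum())
        t1 = _safe(type1_rate, p, t)
        pw = _safe(power, p, t)
        out[level] = {
            "n": int(mask.sum()),
            "n_neg": n_neg,
            "n_pos": n_pos,
            "type1_rate": t1,
            "power": pw,
            "type1_ci": _ci_or_nan(t1, n_neg),
            "power_ci": _ci_or_nan(pw, n_pos),
        }
    return out


def evaluate_method(
    method_id: str,
    pred,
    truth,
    manifest: DatasetManifest | None = None,
    characteristics: tuple[str, ...] = tuple(CHARACTERISTICS),
) -> MetricsReport:
    """Full metrics report for one method, with optional stratification."""
    pred = _as_binary(pred, "pred")
    truth = _as_binary(truth, "truth")
    _check_lengths(pred, truth)
    n = len(truth)
    n_neg = int((truth == 0).sum())
    n_pos = int((truth == 1).sum())
    acc = accuracy(pred, truth)
    t1 = _safe(type1_rate, pred, truth)
    pw = _safe(power, pred, truth)
    report = MetricsReport(
        method_id=method_id,
        n=n,
        accuracy=acc,
        type1_rate=t1,
        power=pw,
        accuracy_ci=binomial_ci(acc, n),
        type1_ci=_ci_or_nan(t1, n_neg),
        power_ci=_ci_or_nan(pw, n_pos),
        n_neg=n_neg,
        n_pos=n_pos,
    )
    if manifest is not None:
        for c in characteristics:
            report.strata[c] = stratify(pred, truth, manifest, c)
    return report
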