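"""Conservative dual-criteria (CDC) decision rule for AB graphs.

The rule projects two reference lines from the baseline phase into the
treatment phase — the baseline mean (a constant) and the baseline OLS trend
line (extrapolated over the treatment session indices) — raises both by
0.25 baseline standard deviations, and declares an effect when the number
of treatment points strictly above both raised lines reaches a threshold:
5 of 5 points when Phase B has five sessions, 8 of 10 when it has ten.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import ABGraph, DatasetManifest

__all__ = ["CDCResult", "cdc_classify", "cdc_batch", "THRESHOLDS"]

#: Required count of qualifying Phase B points, keyed by Phase B length.
THRESHOLDS = {5: 5, 10: 8}

#: Reference lines are shifted by this many baseline SDs.
SD_MULTIPLIER = 0.25


class UnsupportedLengthError(ValueError):
    """Phase B length has no defined decision threshold."""


@dataclass(frozen=True)
class CDCResult:
    """Outcome of the CDC rule on one graph."""

    mean_line: np.ndarray   # raised mean line at each B session
    trend_line: np.ndarray  # raised trend line at each B session
    n_above: int            # B points strictly above both lines
    threshold: int
    decision: int           # 1 = effect detected


def _baseline_ols(phase_a: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS of baseline values on session index 0..n_a-1."""
    n = len(phase_a)
    idx = np.arange(n, dtype=float)
    xm = idx.mean()
    ym = phase_a.mean()
    slope = float(((idx - xm) * (phase_a - ym)).sum() / ((idx - xm) ** 2).sum())
    intercept = ym - slope * xm
    return intercept, slope


def cdc_classify(graph: ABGraph, direction: str = "increase") -> CDCResult:
    """Apply the conservative dual-criteria rule to one graph.

    Parameters
    ----------
    graph : ABGraph
    direction : {"increase", "decrease"}
        Direction of the hypothesized change.  For a decrease the lines are
        lowered by 0.25 SD and points must fall strictly below both.

    Notes
    -----
    The SD used for the 0.25-SD shift is the sample SD (n-1 denominator) of
    Phase A only.  A Phase B point exactly on a raised line does not count.
    A constant baseline (SD 0) is legal: the lines are shifted by 0.
    """
    n_a, n_b = graph.n_a, graph.n_b
    if n_b not in THRESHOLDS:
        raise UnsupportedLengthError(
            f"no decision threshold defined for Phase B length {n_b}; "
            f"supported lengths: {sorted(THRESHOLDS)}"
        )
    if n_a < 2:
        raise ValueError("need at least two baseline points to fit a trend line")
    if direction not in ("increase", "decrease"):
        raise ValueError(f"unknown direction {direction!r}")

    a = graph.phase_a
    b = graph.phase_b
    sd_a = float(a.std(ddof=1))
    shift = SD_MULTIPLIER * sd_a if direction == "increase" else -SD_MULTIPLIER * sd_a

    b_idx = np.arange(n_a, n_a + n_b, dtype=float)
    mean_line = np.full(n_b, a.mean()) + shift
    intercept, slope = _baseline_ols(a)
    trend_line = intercept + slope * b_idx + shift

    if direction == "increase":
        above = (b > mean_line) & (b > trend_line)
    else:
        above = (b < mean_line) & (b < trend_line)
    n_above = int(above.sum())
    threshold = THRESHOLDS[n_b]
    return CDCResult(
        mean_line=mean_line,
        trend_line=trend_line,
        n_above=n_above,
        threshold=threshold,
        decision=int(n_above >= threshold),
    )


def cdc_batch(manifest: DatasetManifest, direction: str = "increase") -> np.ndarray:
    """CDC decisions (0/1) for every graph of a manifest, in manifest order."""
    return np.array(
        [cdc_classify(g, direction=direction).decision for g in manifest], dtype=int
    )
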