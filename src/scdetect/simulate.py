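"""Simulation of single-case AB graphs.

Each graph is a short interrupted time series: a baseline phase (A) followed
by a treatment phase (B).  Series are built in four steps, in this order:

1. an AR(1) process ``x_t = a * x_{t-1} + e_t`` with ``e_t ~ N(0, 1)`` and
   ``x_1 = e_1`` (no burn-in, no stationary-variance rescaling);
2. an optional linear trend, realized as a shear about the series midpoint
   (``apply_trend``);
3. an additive level constant controlling the variability coefficient
   (``apply_offset``: +10 for stable graphs, +4 for variable ones);
4. a standardized mean difference (SMD) added to every Phase B point
   (``apply_effect``).

Two dataset builders produce the counterbalanced collections used for
evaluation (1,024 graphs) and for classifier training (96,000 graphs by
default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GraphSpec",
    "ABGraph",
    "DatasetManifest",
    "VAR_OFFSETS",
    "generate_series",
    "apply_trend",
    "apply_offset",
    "apply_effect",
    "generate_test_dataset",
    "generate_training_dataset",
]

#: Additive level constant per variability label.  With series SD 1 these
#: yield variability coefficients (SD / mean) of 0.10 and 0.25.
VAR_OFFSETS = {"stable": 10.0, "variable": 4.0}

#: Table-1 levels of the five binary characteristics, in canonical order.
BINARY_LEVELS = {
    "n_a": (3, 5),
    "n_b": (5, 10),
    "autocorr": (0.0, 0.2),
    "trend_deg": (0, 30),
    "var_level": ("stable", "variable"),
}

#: Effect sizes used by the dataset builders (0 = no effect).
SMD_LEVELS = (0, 1, 2, 3, 4, 5)


class InvalidSpecError(ValueError):
    """Raised when a graph specification is unusable."""


@dataclass(frozen=True)
class GraphSpec:
    """The six manipulated parameters of one AB graph.

    Parameters
    ----------
    n_a, n_b : int
        Number of sessions in Phase A and Phase B.
    autocorr : float
        First-order autocorrelation coefficient ``a`` of the error series.
    trend_deg : float
        Trend rotation in degrees (0 = no trend).
    var_level : str
        ``"stable"`` (+10 level constant) or ``"variable"`` (+4).
    smd : float
        Standardized mean difference added to Phase B; 0 means no effect.
    """

    n_a: int
    n_b: int
    autocorr: float = 0.0
    trend_deg: float = 0.0
    var_level: str = "stable"
    smd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_a < 1 or self.n_b < 1:
            raise InvalidSpecError(
                f"phase lengths must be positive, got n_a={self.n_a}, n_b={self.n_b}"
            )
        if self.var_level not in VAR_OFFSETS:
            raise InvalidSpecError(
                f"unknown variability level {self.var_level!r}; "
                f"expected one of {sorted(VAR_OFFSETS)}"
            )
        if self.trend_deg < 0:
            raise InvalidSpecError("trend_deg must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_a + self.n_b

    @property
    def label(self) -> int:
        """True class: 1 if an effect was simulated (smd > 0), else 0."""
        return int(self.smd > 0)


@dataclass(frozen=True)
class ABGraph:
    """A realized AB data series together with the spec that produced it."""

    values: np.ndarray
    spec: GraphSpec

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.values) != self.spec.n_total:
            raise InvalidSpecError(
                f"series length {len(self.values)} != n_a + n_b = {self.spec.n_total}"
            )

    @property
    def n_a(self) -> int:
        return self.spec.n_a

    @property
    def n_b(self) -> int:
        return self.spec.n_b

    @property
    def label(self) -> int:
        return self.spec.label

    @property
    def phase_a(self) -> np.ndarray:
        return self.values[: self.n_a]

    @property
    def phase_b(self) -> np.ndarray:
        return self.values[self.n_a:]


@dataclass
class DatasetManifest:
    """An ordered collection of graphs plus the seed that generated it."""

    graphs: list[ABGraph]
    seed: int | None = None
    scheme: str = "custom"
    _labels: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self):
        return iter(self.graphs)

    def __getitem__(self, i):
        return self.graphs[i]

    @property
    def labels(self) -> np.ndarray:
        """True 0/1 labels in manifest order."""
        if self._labels is None:
            self._labels = np.array([g.label for g in self.graphs], dtype=int)
        return self._labels


def generate_series(spec: GraphSpec, rng: np.random.Generator) -> ABGraph:
    """Simulate one AB graph from its spec.

    The construction order is AR(1) noise, then trend, then level offset,
    then treatment effect; see the module docstring.
    """
    e = rng.standard_normal(spec.n_total)
    x = np.empty(spec.n_total)
    x[0] = e[0]
    a = spec.autocorr
    for t in range(1, spec.n_total):
        x[t] = a * x[t - 1] + e[t]
    if spec.trend_deg > 0:
        x = apply_trend(x, spec.trend_deg)
    x = apply_offset(x, spec.var_level)
    x = apply_effect(x, spec.n_a, spec.smd)
    return ABGraph(values=x, spec=spec)


def apply_trend(values: np.ndarray, degrees: float) -> np.ndarray:
    """Add a linear trend of the given angle, pivoting on the series midpoint.

    Implemented as a shear: the i-th point gains ``tan(degrees) * (i - m)``
    where ``m = (len - 1) / 2`` (fractional for even lengths).  At 30 degrees
    every consecutive difference grows by tan(30°) ≈ 0.577, i.e. about 0.58
    per session.
    """
    values = np.asarray(values, dtype=float)
    if degrees == 0:
        return values
    if degrees < 0:
        raise InvalidSpecError("degrees must be non-negative")
    n = len(values)
    if n < 2:
        raise InvalidSpecError("need at least two points to add a trend")
    idx = np.arange(n, dtype=float)
    m = (n - 1) / 2.0
    return values + np.tan(np.deg2rad(degrees)) * (idx - m)


def apply_offset(values: np.ndarray, var_level: str) -> np.ndarray:
    """Shift the whole series by the level constant for ``var_level``.

    With unit series SD the shift sets the variability coefficient
    (SD / mean): 1/10 = 0.10 for stable graphs, 1/4 = 0.25 for variable ones.
    """
    try:
        offset = VAR_OFFSETS[var_level]
    except KeyError:
        raise InvalidSpecError(
            f"unknown variability level {var_level!r}; expected one of {sorted(VAR_OFFSETS)}"
        ) from None
    return np.asarray(values, dtype=float) + offset


def apply_effect(values: np.ndarray, n_a: int, smd: float) -> np.ndarray:
    """Add the standardized mean difference to every Phase B point."""
    values = np.asarray(values, dtype=float)
    if not 0 < n_a < len(values):
        raise InvalidSpecError(f"n_a={n_a} out of range for series of length {len(values)}")
    out = values.copy()
    out[n_a:] += smd
    return out


def _binary_combinations() -> list[dict]:
    """The 2^5 = 32 combinations of the binary characteristics, fixed order."""
    keys = list(BINARY_LEVELS)
    return [
        dict(zip(keys, combo))
        for combo in itertools.product(*(BINARY_LEVELS[k] for k in keys))
    ]


def generate_test_dataset(seed: int) -> DatasetManifest:
    """Build the 1,024-graph counterbalanced evaluation set.

    For each of the 32 combinations of the five binary characteristics the
    set holds 12 no-effect graphs (SMD 0) and 4 graphs at each SMD 1-5, for
    32 graphs per combination.  Graph order is shuffled (recorded via the
    seed) so the true-label vector carries no structure.
    """
    rng = np.random.default_rng(seed)
    specs: list[GraphSpec] = []
    for combo in _binary_combinations():
        specs.extend(GraphSpec(smd=0, **combo) for _ in range(12))
        for smd in SMD_LEVELS[1:]:
            specs.extend(GraphSpec(smd=smd, **combo) for _ in range(4))
    graphs = [generate_series(s, rng) for s in specs]
    rng.shuffle(graphs)
    return DatasetManifest(graphs=graphs, seed=seed, scheme="test_1024")


def generate_training_dataset(seed: int, total: int = 96_000) -> DatasetManifest:
    """Build the counterbalanced training set (default 96,000 graphs).

    Half the graphs have SMD 0; the other half are split equally across
    SMD 1-5.  The five binary characteristics are perfectly counterbalanced
    within each class, so ``total`` must be divisible by 32 * 2 * 5 = 320.
    At the default size every (combination x positive SMD) cell holds 300
    graphs and every (combination x SMD 0) cell holds 1,500.
    """
    cell_unit = 32 * 2 * 5
    if total % cell_unit != 0:
        suggestion = max(cell_unit, ((total // cell_unit) + 1) * cell_unit)
        raise InvalidSpecError(
            f"training size {total} does not counterbalance exactly; "
            f"use a multiple of {cell_unit} (e.g. {suggestion})"
        )
    per_null = total // 2 // 32          # SMD-0 graphs per combination
    per_effect = total // 2 // 32 // 5   # graphs per (combination, SMD>0)
    rng = np.random.default_rng(seed)
    specs: list[GraphSpec] = []
    for combo in _binary_combinations():
        specs.extend(GraphSpec(smd=0, **combo) for _ in range(per_null))
        for smd in SMD_LEVELS[1:]:
            specs.extend(GraphSpec(smd=smd, **combo) for _ in range(per_effect))
    graphs = [generate_series(s, rng) for s in specs]
    rng.shuffle(graphs)
    return DatasetManifest(graphs=graphs, seed=seed, scheme=f"training_{total}")
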