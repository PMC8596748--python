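import numpy as np
import pytest

from scdetect.simulate import ABGraph, GraphSpec


class StubRng:
    """Random source whose 'normal deviates' are a fixed sequence.

    Lets tests force the error terms of the AR(1) recurrence to known
    values (zeros, ones, ...) so the series can be computed by hand.
    """

    def __init__(self, values):
        self._values = np.asarray(values, dtype=float)

    def standard_normal(self, n):
        if n > len(self._values):
            raise ValueError("stub exhausted")
        out, self._values = self._values[:n], self._values[n:]
        return out.copy()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_graph(a_values, b_values, **spec_kwargs):
    """An ABGraph with explicit values, bypassing the simulator."""
    a_values = list(a_values)
    b_values = list(b_values)
    defaults = dict(n_a=len(a_values), n_b=len(b_values))
    defaults.update(spec_kwargs)
    spec = GraphSpec(**defaults)
    return ABGraph(values=np.array(a_values + b_values, dtype=float), spec=spec)


@pytest.fixture
def random_graph_factory(rng):
    """Factory for random small graphs with study-design phase lengths."""

    def factory(n=1, smd_choices=(0, 1, 2, 3, 4, 5)):
        graphs = []
        for _ in range(n):
            spec = GraphSpec(
                n_a=int(rng.choice([3, 5])),
                n_b=int(rng.choice([5, 10])),
                autocorr=float(rng.choice([0.0, 0.2])),
                trend_deg=float(rng.choice([0, 30])),
                var_level=str(rng.choice(["stable", "variable"])),
                smd=int(rng.choice(smd_choices)),
            )
            from scdetect.simulate import generate_series

            graphs.append(generate_series(spec, rng))
        return graphs if n > 1 else graphs[0]

    return factory
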