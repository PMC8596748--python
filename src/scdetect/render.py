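"""Rendering of AB graphs to a multi-page PDF, one graph per page.

Pages follow manifest order; each page shows the session series with a
vertical phase-change line between the last A session and the first B
session, and no annotation that would reveal the generating parameters.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.backends.backend_pdf import PdfPages

from .simulate import DatasetManifest

__all__ = ["render_graphs"]


def render_graphs(manifest: DatasetManifest, path: str | Path) -> int:
    """Render every graph of a manifest to one PDF page each.

    Returns the number of pages written.  The y-range is the graph's data
    range padded by 10% so scale differences stay visible.
    """
    if len(manifest) == 0:
        raise ValueError("cannot render an empty manifest")
    path = Path(path)
    with PdfPages(path) as pdf:
        for g in manifest:
            fig, ax = plt.subplots(figsize=(6, 4))
            sessions = range(1, len(g.values) + 1)
            ax.plot(sessions, g.values, marker="o", color="black", linewidth=1)
            ax.axvline(g.n_a + 0.5, color="black", linestyle="--", linewidth=1)
            lo, hi = g.values.min(), g.values.max()
            pad = 0.1 * max(hi - lo, 1e-9)
            ax.set_ylim(lo - pad, hi + pad)
            ax.set_xlabel("Session")
            ax.set_ylabel("Behavior")
            ax.set_xticks(list(sessions))
            pdf.savefig(fig)
            plt.close(fig)
    return len(manifest)
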