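"""File formats: decision vectors, manifests, rater spreadsheets, configs.

Decision vectors (true labels, method decisions, human ratings) are
headerless single-column CSV files of 0/1 in manifest order.  Manifests are
CSV with one row per graph: the spec columns followed by the session values.
Run configurations round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import ABGraph, DatasetManifest, GraphSpec

__all__ = [
    "write_vector",
    "read_vector",
    "read_ratings",
    "write_manifest",
    "read_manifest",
    "RunConfig",
]


class VectorParseError(ValueError):
    pass


def write_vector(path: str | Path, decisions) -> None:
    """Write a 0/1 decision vector as headerless single-column CSV."""
    arr = np.asarray(decisions, dtype=int)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("decisions must be 0/1")
    Path(path).write_text("".join(f"{v}\n" for v in arr))


def read_vector(path: str | Path) -> np.ndarray:
    """Read a 0/1 vector written by :func:`write_vector` (exact inverse)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if token == "" and lineno > len(out):
                continue  # trailing blank line
            if token not in ("0", "1"):
                raise VectorParseError(
                    f"{path}: line {lineno}: expected 0 or 1, got {token!r}"
                )
            out.append(int(token))
    return np.array(out, dtype=int)


def read_ratings(path: str | Path, rater_id: str | None = None) -> np.ndarray:
    """Read one rater's 0/1 judgments from a CSV or Excel file.

    The file must hold one judgment per graph, in graph order, in its first
    column (a header row is tolerated and skipped).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        frame = pd.read_excel(path, header=None)
    else:
        frame = pd.read_csv(path, header=None)
    col = frame.iloc[:, 0]
    # tolerate a single header cell
    if len(col) and isinstance(col.iloc[0], str) and col.iloc[0].strip() not in ("0", "1"):
        col = col.iloc[1:]
    values = []
    for row, v in enumerate(col, start=1):
        if pd.isna(v):
            raise VectorParseError(f"{path}: row {row}: empty rating")
        try:
            iv = int(v)
        except (TypeError, ValueError):
            raise VectorParseError(f"{path}: row {row}: non-numeric rating {v!r}") from None
        if iv not in (0, 1):
            raise VectorParseError(f"{path}: row {row}: rating must be 0 or 1, got {iv}")
        values.append(iv)
    if not values:
        raise VectorParseError(f"{path}: no ratings found")
    return np.array(values, dtype=int)


def write_manifest(path: str | Path, manifest: DatasetManifest) -> None:
    """Serialize a manifest: one CSV row per graph, spec columns then values."""
    rows = []
    for i, g in enumerate(manifest):
        row = {
            "graph_id": i,
            "n_a": g.spec.n_a,
            "n_b": g.spec.n_b,
            "autocorr": g.spec.autocorr,
            "trend_deg": g.spec.trend_deg,
            "var_level": g.spec.var_level,
            "smd": g.spec.smd,
            "label": g.label,
        }
        row.update({f"v{j}": v for j, v in enumerate(g.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_manifest(path: str | Path) -> DatasetManifest:
    """Inverse of :func:`write_manifest` (values to 12 significant digits)."""
    frame = pd.read_csv(path)
    graphs = []
    for _, row in frame.iterrows():
        spec = GraphSpec(
            n_a=int(row["n_a"]),
            n_b=int(row["n_b"]),
            autocorr=float(row["autocorr"]),
            trend_deg=float(row["trend_deg"]),
            var_level=str(row["var_level"]),
            smd=float(row["smd"]),
        )
        values = row[[f"v{j}" for j in range(spec.n_total)]].to_numpy(dtype=float)
        graphs.append(ABGraph(values=values, spec=spec))
    return DatasetManifest(graphs=graphs, scheme="custom")


@dataclass
class RunConfig:
    """Every knob of a full pipeline run, serializable for reproducibility."""

    dataset_seed: int = 0
    training_seed: int = 1
    scheme: str = "test_1024"
    training_total: int = 96_000
    model_kind: str = "sgd_hinge"
    svc_subsample: int | None = 20_000
    ci_level: float = 0.95
    out_dir: str = "results"
    hyperparameters: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
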