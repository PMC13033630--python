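"""Readers/writers and ID reconciliation for the three input files.

The node universe is defined by the expression matrix (every node needs
features); the essential-protein list and the optional PPI edge list are
reconciled onto it by exact string match (after whitespace trimming), with
unmatched IDs logged and dropped.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["DatasetBundle", "load_expression", "load_edges", "load_labels",
           "load_bundle", "write_predictions", "write_metrics"]


@dataclasses.dataclass
class DatasetBundle:
    node_ids: list[str]
    expression: np.ndarray          # (N, M)
    timepoint_labels: list[str]
    labels: np.ndarray              # (N,) binary
    edges: np.ndarray | None        # (n_edges, 2) node indices
    id_map: dict[str, int]


def load_expression(path: str | Path):
    """Parse an expression TSV/CSV (header row, first column = protein ID).

    Duplicate IDs are collapsed by mean and non-numeric cells imputed with
    the row mean, both with logged warnings.

    Returns (node_ids, values, timepoint_labels).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed expression file {path}: {err}") from err
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need an ID column plus >= 2 time points")
    id_col = df.columns[0]
    df[id_col] = df[id_col].str.strip()

    def _parse(cell):
        # float() is correctly rounded; pandas' fast parser is not bit-exact
        try:
            return float(cell)
        except (TypeError, ValueError):
            return np.nan

    values = df.iloc[:, 1:].map(_parse)
    n_bad = int(values.isna().to_numpy().sum())
    if n_bad:
        logger.warning("%s: imputing %d non-numeric cells with row means", path, n_bad)
        row_means = values.mean(axis=1)
        values = values.apply(lambda col: col.fillna(row_means))
    values.insert(0, id_col, df[id_col])
    n_dups = int(values[id_col].duplicated().sum())
    if n_dups:
        logger.warning("%s: collapsing %d duplicate IDs by mean", path, n_dups)
        values = values.groupby(id_col, sort=False, as_index=False).mean()
    node_ids = values[id_col].tolist()
    matrix = values.iloc[:, 1:].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(matrix)):
        raise ValueError(f"{path}: rows with no numeric values cannot be imputed")
    return node_ids, matrix, list(df.columns[1:])


def load_edges(path: str | Path, id_map: dict[str, int]) -> np.ndarray:
    """Two-column undirected edge list: deduplicated by unordered pair,
    self-loops removed, unknown IDs skipped with a logged count."""
    path = Path(path)
    seen: set[frozenset] = set()
    edges: list[tuple[int, int]] = []
    unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected two IDs, got {len(fields)}")
            a, b = (f.strip() for f in fields)
            if a not in id_map or b not in id_map:
                unknown += 1
                continue
            i, j = id_map[a], id_map[b]
            if i == j:
                continue
            key = frozenset((i, j))
            if key in seen:
                continue
            seen.add(key)
            edges.append((min(i, j), max(i, j)))
    if unknown:
        logger.warning("%s: skipped %d edges with unknown IDs", path, unknown)
    return np.asarray(edges, dtype=np.int64).reshape(-1, 2)


def load_labels(path: str | Path, id_map: dict[str, int]) -> np.ndarray:
    """One essential-protein ID per line -> binary indicator vector."""
    listed = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    labels = np.zeros(len(id_map), dtype=np.int64)
    unmatched = 0
    for nid in listed:
        if nid in id_map:
            labels[id_map[nid]] = 1
        else:
            unmatched += 1
    if unmatched:
        logger.warning("%s: %d listed IDs not in the expression universe", path, unmatched)
    if labels.sum() == 0:
        logger.warning("%s: no listed ID matched any node", path)
    return labels


def load_bundle(expression_path, labels_path=None, edges_path=None) -> DatasetBundle:
    node_ids, values, tp_labels = load_expression(expression_path)
    id_map = {nid: i for i, nid in enumerate(node_ids)}
    labels = (load_labels(labels_path, id_map) if labels_path
              else np.zeros(len(node_ids), dtype=np.int64))
    edges = load_edges(edges_path, id_map) if edges_path else None
    return DatasetBundle(node_ids, values, tp_labels, labels, edges, id_map)


def write_predictions(path, node_ids, result) -> None:
    """TSV: node_id, probability, hard_label, rank (1 = highest score)."""
    rank_of = np.empty(len(node_ids), dtype=np.int64)
    rank_of[result.ranking] = np.arange(1, len(node_ids) + 1)
    with open(path, "w") as fh:
        fh.write("node_id\tprobability\thard_label\trank\n")
        for i, nid in enumerate(node_ids):
            fh.write(f"{nid}\t{result.probabilities[i]:.10g}\t"
                     f"{result.hard_labels[i]}\t{rank_of[i]}\n")


def write_metrics(path, report) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for key, value in report.as_dict().items():
            fh.write(f"{key}\t{value:.10g}\n")
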