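"""Synthetic benchmark generator with planted co-expression modules.

Emulates the statistical structure the pipeline assumes in real data:
groups of proteins ("modules") share a periodic temporal expression
programme (cell-cycle-like sinusoids), essentiality concentrates in a
subset of "core" modules, and an optional planted-partition interaction
network is dense within modules and sparse between them.  Everything is
driven by a single integer seed so that fixtures are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset", "dataset_to_files"]

#: candidate waveform periods, in time points (sub-multiples of a typical series)
_PERIOD_CHOICES = (6, 8, 12)


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-module generator.

    Defaults are the benchmark conditions used throughout the test suite:
    600 nodes in 12 modules observed over 24 time points, moderate noise,
    with 40% of modules "core" where essentiality is concentrated.
    """

    n_nodes: int = 600
    n_modules: int = 12
    n_timepoints: int = 24
    module_size_mean: float | None = None  # derived as n_nodes / n_modules
    signal_amplitude: float = 1.0
    noise_sd: float = 0.3
    baseline_level: float = 2.0
    essential_prob_core: float = 0.8
    essential_prob_background: float = 0.05
    core_module_fraction: float = 0.4
    with_edges: bool = True
    edge_p_in: float = 0.3
    edge_p_out: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_modules < 1 or self.n_nodes < self.n_modules:
            raise ValueError("need n_nodes >= n_modules >= 1")
        if self.n_timepoints < 4:
            raise ValueError("need n_timepoints >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("essential_prob_core", "essential_prob_background",
                     "core_module_fraction", "edge_p_in", "edge_p_out"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclasses.dataclass
class SyntheticDataset:
    node_ids: list[str]
    expression: np.ndarray            # (n_nodes, n_timepoints)
    timepoint_labels: list[str]
    labels: np.ndarray                # binary, (n_nodes,)
    module_assignment: np.ndarray     # int, (n_nodes,)
    core_modules: np.ndarray          # int, sorted module indices
    edges: np.ndarray | None          # (n_edges, 2) int node indices, i < j

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


def _module_sizes(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Multinomial sizes around n_nodes/n_modules, every module non-empty."""
    extra = rng.multinomial(cfg.n_nodes - cfg.n_modules,
                            np.full(cfg.n_modules, 1.0 / cfg.n_modules))
    return extra + 1


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset from the planted-module model.

    Node ``i`` in module ``k`` has expression
    ``x[i, t] = baseline + amplitude * sin(2*pi*t/P_k + phi_k) + eps`` with
    ``eps ~ N(0, noise_sd^2)``.  Module phases are spread around the circle
    (evenly spaced base angle plus a seeded jitter) so distinct modules are
    decorrelated by construction.  Nodes in core modules are labelled
    essential with probability ``essential_prob_core``, all others with
    ``essential_prob_background``.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    sizes = _module_sizes(cfg, rng)
    module_assignment = np.repeat(np.arange(cfg.n_modules), sizes)

    # Distinct modules must be mutually near-uncorrelated for the planted
    # structure to be meaningful: sinusoids of different periods (6/8/12 over
    # a 24-point common cycle) are orthogonal, and same-period modules are
    # placed on a quadrature (90 degree) phase grid, where pairwise waveform
    # correlation is 0 or -1.  A small seeded jitter keeps phases generic.
    ks = np.arange(cfg.n_modules)
    periods = np.asarray(_PERIOD_CHOICES)[ks % len(_PERIOD_CHOICES)]
    base = (np.pi / 2.0) * (ks // len(_PERIOD_CHOICES))
    phases = base + rng.uniform(-np.pi / 18.0, np.pi / 18.0, size=cfg.n_modules)

    t = np.arange(cfg.n_timepoints)
    waveforms = np.sin(2.0 * np.pi * t[None, :] / periods[:, None] + phases[:, None])

    expression = (cfg.baseline_level
                  + cfg.signal_amplitude * waveforms[module_assignment]
                  + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_nodes, cfg.n_timepoints)))

    n_core = int(round(cfg.core_module_fraction * cfg.n_modules))
    core_modules = np.sort(rng.choice(cfg.n_modules, size=n_core, replace=False))
    is_core = np.isin(module_assignment, core_modules)
    p = np.where(is_core, cfg.essential_prob_core, cfg.essential_prob_background)
    labels = (rng.random(cfg.n_nodes) < p).astype(np.int64)

    edges = None
    if cfg.with_edges:
        same = module_assignment[:, None] == module_assignment[None, :]
        prob = np.where(same, cfg.edge_p_in, cfg.edge_p_out)
        draw = rng.random((cfg.n_nodes, cfg.n_nodes)) < prob
        iu, ju = np.triu_indices(cfg.n_nodes, k=1)
        keep = draw[iu, ju]
        edges = np.column_stack([iu[keep], ju[keep]]).astype(np.int64)

    width = max(4, len(str(cfg.n_nodes)))
    node_ids = [f"P{i:0{width}d}" for i in range(cfg.n_nodes)]
    timepoint_labels = [f"t{j}" for j in range(cfg.n_timepoints)]
    return SyntheticDataset(node_ids, expression, timepoint_labels, labels,
                            module_assignment, core_modules, edges)


def dataset_to_files(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset in the loader's plain-text formats.

    Produces ``expression.tsv`` (ID column + one column per time point),
    ``essential.txt`` (one essential-protein ID per line), ``modules.tsv``
    (node ID, module index) and, when edges exist, ``edges.tsv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    expr = pd.DataFrame(dataset.expression, columns=dataset.timepoint_labels)
    expr.insert(0, "id", dataset.node_ids)
    paths["expression"] = directory / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t", index=False, float_format="%.17g")

    paths["labels"] = directory / "essential.txt"
    essential = [nid for nid, y in zip(dataset.node_ids, dataset.labels) if y == 1]
    paths["labels"].write_text("".join(f"{nid}\n" for nid in essential))

    paths["modules"] = directory / "modules.tsv"
    with open(paths["modules"], "w") as fh:
        fh.write("id\tmodule\n")
        for nid, m in zip(dataset.node_ids, dataset.module_assignment):
            fh.write(f"{nid}\t{m}\n")

    if dataset.edges is not None and len(dataset.edges):
        paths["edges"] = directory / "edges.tsv"
        with open(paths["edges"], "w") as fh:
            for i, j in dataset.edges:
                fh.write(f"{dataset.node_ids[i]}\t{dataset.node_ids[j]}\n")
    return paths
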