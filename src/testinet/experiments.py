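"""Declarative factorial parameter sweeps and figure-style plotting.

An :class:`ExperimentSpec` names the factor levels of a full-factorial
design (strategy x network size x world accuracy x rewiring x activity x
communication probability x assertion threshold) plus a replicate count and
a base seed.  ``run_experiment`` executes every cell x replicate through
the engine, aggregates the per-condition measures into a tidy table and can
persist per-cell results so interrupted sweeps resume where they stopped.

Per-replicate seeds are derived deterministically from (base seed, cell
index, replicate index), so cells are independent, may run in any order or
in parallel, and the merged output is identical regardless.

The presets mirror the package's standard experiment designs: the headline
3-sizes x 3-accuracies comparison of the two trust strategies, the
network-size sweeps under communication-heavy vs world-heavy information
regimes, the rewiring-probability heatmap design and the
assertion-threshold robustness sweep.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import CommConfig, RunRecord, SimConfig, Strategy, WorldConfig, run_simulation
from .metrics import TIDY_COLUMNS, aggregate

__all__ = [
    "ExperimentSpec",
    "SizeRegime",
    "cell_seed",
    "run_experiment",
    "preset_fig1",
    "preset_size_sweep",
    "preset_rewiring_heatmap",
    "preset_threshold_sweep",
    "plot_summary",
    "SIZE_GRID",
    "ACCURACY_GRID_21",
]

#: network sizes for the size sweeps: 4, then every multiple of 5 up to 100
SIZE_GRID: Tuple[int, ...] = (4,) + tuple(range(5, 101, 5))

#: 21 evenly spaced world accuracies strictly inside (.5, 1); the degenerate
#: perfectly-reliable world is excluded because a report of certain accuracy
#: has an undefined likelihood ratio
ACCURACY_GRID_21: Tuple[float, ...] = tuple(
    float(a) for a in np.linspace(0.5, 1.0, 23)[1:-1]
)


class SizeRegime:
    """Information regimes for the size sweep."""

    HIGH_COMM = "high_comm"    # activity .20, p_communicate .50
    HIGH_WORLD = "high_world"  # activity .50, p_communicate .20


@dataclass(frozen=True)
class ExperimentSpec:
    """Full-factorial design: every combination of the factor levels below
    is run ``replicates`` times (each run carries its paired shadow
    population, so networked-vs-shadow needs no extra factor)."""

    name: str
    n_values: Tuple[int, ...]
    accuracies: Tuple[float, ...]
    strategies: Tuple[Strategy, ...]
    p_rewires: Tuple[float, ...] = (0.2,)
    activities: Tuple[float, ...] = (0.1,)
    p_communicates: Tuple[float, ...] = (0.25,)
    thresholds: Tuple[float, ...] = (0.8,)
    replicates: int = 100
    base_seed: int = 0
    steps: int = 50
    k: int = 2
    p_truth: float = 0.6
    grid_size: int = 201
    fixed_trust: float = 0.66

    def __post_init__(self) -> None:
        for name in (
            "n_values", "accuracies", "strategies", "p_rewires",
            "activities", "p_communicates", "thresholds",
        ):
            if not getattr(self, name):
                raise ValueError(f"factor {name} has no levels")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        for t in self.thresholds:
            if not 0.5 < t < 1.0:
                raise ValueError(f"threshold must lie in (0.5, 1), got {t}")

    @property
    def n_cells(self) -> int:
        return (
            len(self.strategies) * len(self.n_values) * len(self.accuracies)
            * len(self.p_rewires) * len(self.activities)
            * len(self.p_communicates) * len(self.thresholds)
        )

    @property
    def total_runs(self) -> int:
        return self.n_cells * self.replicates

    def cells(self) -> Iterator[Tuple[int, dict]]:
        """Enumerate (cell index, factor assignment) in a fixed order."""
        levels = itertools.product(
            self.strategies, self.n_values, self.accuracies, self.p_rewires,
            self.activities, self.p_communicates, self.thresholds,
        )
        for idx, (strategy, n, acc, p_r, act, p_c, thr) in enumerate(levels):
            yield idx, {
                "strategy": strategy,
                "n": n,
                "accuracy": acc,
                "p_rewire": p_r,
                "activity": act,
                "p_communicate": p_c,
                "threshold": thr,
            }

    def cell_config(self, cell: dict, seed: int) -> SimConfig:
        return SimConfig(
            world=WorldConfig(
                p_truth=self.p_truth,
                accuracy=cell["accuracy"],
                activity=cell["activity"],
            ),
            comm=CommConfig(
                threshold=cell["threshold"],
                p_communicate=cell["p_communicate"],
            ),
            n=cell["n"],
            k=self.k,
            p_rewire=cell["p_rewire"],
            strategy=cell["strategy"],
            steps=self.steps,
            seed=seed,
            grid_size=self.grid_size,
            fixed_trust=self.fixed_trust,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["strategies"] = [s.value for s in self.strategies]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentSpec":
        d = dict(d)
        d["strategies"] = tuple(Strategy(s) for s in d["strategies"])
        for name in ("n_values", "accuracies", "p_rewires", "activities",
                     "p_communicates", "thresholds"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentSpec":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def cell_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic, well-mixed seed for one (cell, replicate) run."""
    ss = np.random.SeedSequence([int(base_seed), int(cell_index), int(replicate)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# sweep execution


def _labels(cell: dict) -> dict:
    labels = dict(cell)
    labels["strategy"] = cell["strategy"].value
    return labels


def _run_cell(spec: ExperimentSpec, idx: int, cell: dict) -> Tuple[int, pd.DataFrame, list]:
    records = []
    for rep in range(spec.replicates):
        config = spec.cell_config(cell, seed=cell_seed(spec.base_seed, idx, rep))
        records.append(run_simulation(config))
    rows = aggregate(records, _labels(cell))
    return idx, rows, records


def run_experiment(
    spec: ExperimentSpec,
    out_dir: Optional[Path] = None,
    resume: bool = False,
    jobs: int = 1,
    progress: bool = False,
) -> Tuple[pd.DataFrame, list]:
    """Execute a full sweep; return (tidy metric table, raw run records).

    With ``out_dir`` set, per-cell metric tables and JSON-lines run records
    are written as each cell finishes, plus a merged ``metrics.csv``,
    ``runs.jsonl`` and a ``manifest.json`` recording the resolved spec.
    ``resume=True`` skips cells whose per-cell files already exist (their
    records are reloaded from disk).  Cells are independent; with
    ``jobs > 1`` they execute in parallel and are merged by cell index, so
    the output does not depend on execution order.
    """
    cells = list(spec.cells())
    cell_dir = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        cell_dir = out_dir / "cells"
        cell_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(spec.to_dict(), fh, indent=2, sort_keys=True)

    done: dict = {}
    todo = []
    for idx, cell in cells:
        if resume and cell_dir is not None:
            rows_path = cell_dir / f"cell_{idx:05d}.csv"
            runs_path = cell_dir / f"cell_{idx:05d}.jsonl"
            if rows_path.exists() and runs_path.exists():
                rows = pd.read_csv(rows_path)
                with open(runs_path, "r", encoding="utf-8") as fh:
                    records = [RunRecord.from_json(line) for line in fh if line.strip()]
                done[idx] = (rows, records)
                continue
        todo.append((idx, cell))

    if jobs > 1 and todo:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=jobs)(
            delayed(_run_cell)(spec, idx, cell) for idx, cell in todo
        )
    else:
        iterator: Iterable = todo
        if progress:
            from tqdm import tqdm

            iterator = tqdm(todo, desc=spec.name, unit="cell")
        results = [_run_cell(spec, idx, cell) for idx, cell in iterator]

    for idx, rows, records in results:
        done[idx] = (rows, records)
        if cell_dir is not None:
            rows.to_csv(cell_dir / f"cell_{idx:05d}.csv", index=False)
            with open(cell_dir / f"cell_{idx:05d}.jsonl", "w", encoding="utf-8") as fh:
                for r in records:
                    fh.write(r.to_json() + "\n")

    all_rows = pd.concat(
        [done[idx][0] for idx in sorted(done)], ignore_index=True
    )[TIDY_COLUMNS]
    all_records = [r for idx in sorted(done) for r in done[idx][1]]

    if out_dir is not None:
        all_rows.to_csv(out_dir / "metrics.csv", index=False)
        with open(out_dir / "runs.jsonl", "w", encoding="utf-8") as fh:
            for r in all_records:
                fh.write(r.to_json() + "\n")
    return all_rows, all_records


# ---------------------------------------------------------------------------
# presets


def preset_fig1(replicates: int = 100, base_seed: int = 0) -> ExperimentSpec:
    """Headline design: N in {30, 60, 90} x accuracy in {.55, .66, .75} x
    both trust strategies, at the standard parameters (activity .1,
    p_communicate .25, threshold .8, p_truth .6, small world k = 2 with
    rewiring .2, 50 steps)."""
    return ExperimentSpec(
        name="fig1",
        n_values=(30, 60, 90),
        accuracies=(0.55, 0.66, 0.75),
        strategies=(Strategy.UPDATER, Strategy.FIXED),
        replicates=replicates,
        base_seed=base_seed,
    )


def preset_size_sweep(
    regime: str, replicates: int = 100, base_seed: int = 0
) -> ExperimentSpec:
    """Network-size sweep (n = 4 and all multiples of 5 up to 100) under a
    communication-heavy (activity .20, p_communicate .50) or world-heavy
    (activity .50, p_communicate .20) information regime."""
    if regime == SizeRegime.HIGH_COMM:
        activity, p_comm = 0.20, 0.50
    elif regime == SizeRegime.HIGH_WORLD:
        activity, p_comm = 0.50, 0.20
    else:
        raise ValueError(f"unknown regime: {regime!r}")
    return ExperimentSpec(
        name=f"size_sweep_{regime}",
        n_values=SIZE_GRID,
        accuracies=(0.55, 0.66, 0.75),
        strategies=(Strategy.UPDATER, Strategy.FIXED),
        activities=(activity,),
        p_communicates=(p_comm,),
        replicates=replicates,
        base_seed=base_seed,
    )


def preset_rewiring_heatmap(
    replicates: int = 100,
    base_seed: int = 0,
    n_values: Sequence[int] = SIZE_GRID,
    accuracies: Sequence[float] = ACCURACY_GRID_21,
    p_rewires: Sequence[float] = (0.0, 0.5, 1.0),
) -> ExperimentSpec:
    """Size x accuracy heatmap design across rewiring probabilities, from
    the regular lattice (0) through small world to the random graph (1)."""
    return ExperimentSpec(
        name="rewiring_heatmap",
        n_values=tuple(int(n) for n in n_values),
        accuracies=tuple(float(a) for a in accuracies),
        strategies=(Strategy.UPDATER, Strategy.FIXED),
        p_rewires=tuple(float(p) for p in p_rewires),
        replicates=replicates,
        base_seed=base_seed,
    )


def preset_threshold_sweep(
    thresholds: Sequence[float], replicates: int = 100, base_seed: int = 0
) -> ExperimentSpec:
    """Headline design crossed with a list of assertion thresholds."""
    if not thresholds:
        raise ValueError("thresholds must be a non-empty list")
    base = preset_fig1(replicates, base_seed)
    return dataclasses.replace(
        base, name="threshold_sweep", thresholds=tuple(float(t) for t in thresholds)
    )


# ---------------------------------------------------------------------------
# plotting


def plot_summary(
    rows: pd.DataFrame, kind: str, destination, measure: str = "mse"
) -> None:
    """Render a tidy metric table to an image.

    BARS    grouped bars (x = network size, shade = accuracy), one panel per
            strategy x population;
    LINES   size-sweep lines per accuracy with min/max shading across
            accuracies, one panel per strategy x population;
    HEATMAP size (x) by accuracy (y) heatmaps, one panel per strategy x
            population.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if rows is None or len(rows) == 0:
        raise ValueError("no metric rows to plot")
    if measure not in set(rows["measure"]):
        raise ValueError(f"measure {measure!r} not present in the table")
    data = rows[rows["measure"] == measure]
    strategies = sorted(data["strategy"].unique())
    populations = ["networked", "shadow"]
    fig, axes = plt.subplots(
        len(strategies), len(populations),
        figsize=(5 * len(populations), 3.5 * len(strategies)),
        squeeze=False,
    )
    cmap = plt.get_cmap("Blues")

    for i, strategy in enumerate(strategies):
        for j, population in enumerate(populations):
            ax = axes[i][j]
            panel = data[(data["strategy"] == strategy) & (data["population"] == population)]
            accs = sorted(panel["accuracy"].unique())
            ns = sorted(panel["n"].unique())
            pivot = panel.pivot_table(index="n", columns="accuracy", values="value", aggfunc="mean")
            if kind == "BARS":
                width = 0.8 / max(len(accs), 1)
                x = np.arange(len(ns))
                for a_i, acc in enumerate(accs):
                    ax.bar(
                        x + a_i * width, pivot[acc].reindex(ns), width,
                        color=cmap(0.35 + 0.6 * a_i / max(len(accs) - 1, 1)),
                        label=f"acc={acc:g}",
                    )
                ax.set_xticks(x + 0.4 - width / 2)
                ax.set_xticklabels([str(n) for n in ns])
                ax.set_xlabel("network size n")
            elif kind == "LINES":
                for a_i, acc in enumerate(accs):
                    ax.plot(
                        ns, pivot[acc].reindex(ns),
                        color=cmap(0.35 + 0.6 * a_i / max(len(accs) - 1, 1)),
                        linestyle="--" if a_i in (0, len(accs) - 1) else "-",
                        label=f"acc={acc:g}",
                    )
                if len(accs) > 1:
                    lo = pivot.reindex(ns).min(axis=1)
                    hi = pivot.reindex(ns).max(axis=1)
                    ax.fill_between(ns, lo, hi, alpha=0.2, color=cmap(0.6))
                ax.set_xlabel("network size n")
            elif kind == "HEATMAP":
                grid = pivot.T.reindex(index=accs, columns=ns)
                im = ax.pcolormesh(ns, accs, grid.values, shading="nearest", cmap="viridis")
                fig.colorbar(im, ax=ax, shrink=0.8)
                ax.set_xlabel("network size n")
                ax.set_ylabel("world accuracy")
            else:
                plt.close(fig)
                raise ValueError(f"unknown plot kind: {kind!r}")
            ax.set_title(f"{strategy} / {population}")
            if kind != "HEATMAP":
                ax.set_ylabel(measure)
                ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(destination, dpi=150)
    plt.close(fig)
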