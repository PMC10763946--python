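"""Accuracy and polarisation measures over final belief vectors.

Accuracy is scored against the run's ground truth as the mean squared error
of beliefs (the Brier score: 0 is perfect, .25 is the score of the agnostic
belief .5).  Polarisation is summarised three ways:

* *minimal polarisation* — the population simultaneously contains an agent
  with belief > .999 and one with belief < .001 (strict);
* *maximal gap* — the largest difference between adjacent values of the
  sorted belief vector, measuring how far apart belief "camps" sit;
* *belief SD* — the population standard deviation of beliefs.

``aggregate`` folds a batch of replicate runs for one experimental
condition into tidy rows: per-run measures are averaged (minimal
polarisation as a proportion of runs), separately for the networked and
shadow populations, always on the final-step beliefs.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import RunRecord

__all__ = [
    "mean_squared_error",
    "minimal_polarisation",
    "max_gap",
    "belief_sd",
    "aggregate",
    "CONDITION_COLUMNS",
    "TIDY_COLUMNS",
    "MEASURES",
]

#: upper / lower extremist thresholds for minimal polarisation (strict)
POLARISATION_HI = 0.999
POLARISATION_LO = 0.001

CONDITION_COLUMNS = [
    "strategy",
    "population",
    "n",
    "accuracy",
    "p_rewire",
    "activity",
    "p_communicate",
    "threshold",
]
TIDY_COLUMNS = CONDITION_COLUMNS + ["measure", "value", "n_runs"]
MEASURES = ["mse", "minimal_polarisation", "max_gap", "belief_sd"]


def _as_beliefs(beliefs: Sequence[float]) -> np.ndarray:
    arr = np.asarray(beliefs, dtype=float)
    if arr.size == 0:
        raise ValueError("belief vector must be non-empty")
    return arr


def mean_squared_error(beliefs: Sequence[float], truth: bool) -> float:
    """Brier score: mean over agents of (belief - 1[truth])^2."""
    arr = _as_beliefs(beliefs)
    target = 1.0 if truth else 0.0
    return float(np.mean((arr - target) ** 2))


def minimal_polarisation(beliefs: Sequence[float]) -> bool:
    """True iff the population holds extremists on both sides.

    At least one agent with belief > .999 and at least one with
    belief < .001 (both strict).
    """
    arr = _as_beliefs(beliefs)
    return bool(arr.max() > POLARISATION_HI and arr.min() < POLARISATION_LO)


def max_gap(beliefs: Sequence[float]) -> float:
    """Span of the largest gap between adjacent sorted beliefs (0 if n = 1)."""
    arr = np.sort(_as_beliefs(beliefs))
    if arr.size < 2:
        return 0.0
    return float(np.max(np.diff(arr)))


def belief_sd(beliefs: Sequence[float]) -> float:
    """Population standard deviation of the belief vector."""
    return float(np.std(_as_beliefs(beliefs)))


def _summarise(vectors: list, truths: list, gap_summary: str) -> dict:
    mses = [mean_squared_error(v, t) for v, t in zip(vectors, truths)]
    pols = [minimal_polarisation(v) for v in vectors]
    gaps = [max_gap(v) for v in vectors]
    sds = [belief_sd(v) for v in vectors]
    gap_value = float(np.median(gaps)) if gap_summary == "median" else float(np.mean(gaps))
    return {
        "mse": float(np.mean(mses)),
        "minimal_polarisation": float(np.mean(pols)),
        "max_gap": gap_value,
        "belief_sd": float(np.mean(sds)),
    }


def aggregate(
    records: Iterable[RunRecord],
    labels: Mapping[str, object],
    gap_summary: str = "mean",
) -> pd.DataFrame:
    """Tidy per-condition metric rows from a batch of replicate runs.

    One row per (population, measure): the mean of the per-run MSE, max-gap
    and belief-SD, and the proportion of runs that are minimally polarised,
    computed separately for networked and shadow populations.  ``labels``
    supplies the condition columns (missing ones are filled with NA).
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one run record")
    sizes = {len(r.final_beliefs) for r in records}
    if len(sizes) != 1:
        raise ValueError(f"inconsistent population sizes across records: {sorted(sizes)}")
    if gap_summary not in ("mean", "median"):
        raise ValueError(f"gap_summary must be 'mean' or 'median', got {gap_summary!r}")

    truths = [r.truth for r in records]
    rows = []
    for population, vectors in (
        ("networked", [r.final_beliefs for r in records]),
        ("shadow", [r.final_shadow_beliefs for r in records]),
    ):
        summary = _summarise(vectors, truths, gap_summary)
        for measure in MEASURES:
            row = {col: labels.get(col, pd.NA) for col in CONDITION_COLUMNS}
            row["population"] = population
            row["measure"] = measure
            row["value"] = summary[measure]
            row["n_runs"] = len(records)
            rows.append(row)
    return pd.DataFrame(rows, columns=TIDY_COLUMNS)
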