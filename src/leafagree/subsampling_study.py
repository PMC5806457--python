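"""Monte-Carlo observer subsampling: how many annotations keep the inference?

Each trial draws a binary sampling matrix with exactly K ones per row (a row
is one plant-time observation), selecting which observers' annotations feed
that row's consensus (the mean of the selected counts).  The longitudinal
interaction ANOVA runs on every trial's consensus table and the distribution
of interaction p-values over trials is summarized by min, max, mean, sample
SD and raw (non-excess) kurtosis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InfeasibleAssignmentError,
    InsufficientDataError,
    MissingDataError,
    ModelError,
    ShapeError,
)
from .longitudinal_model import fit_interaction_anova

__all__ = [
    "SamplingMatrix",
    "PValueSummary",
    "draw_sampling_matrix",
    "matrix_consensus",
    "run_subsampling_study",
    "summarize_pvalues",
    "subsampling_table",
]


@dataclass
class SamplingMatrix:
    """Binary n_rows x pool_size matrix with exactly K ones per row."""

    matrix: np.ndarray
    K: int

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def pool_size(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PValueSummary:
    """Summary of the p-value distribution across Monte-Carlo trials.

    ``kurtosis`` is the raw moment ratio m4/m2² (3 for a normal sample),
    NaN when the trials are constant.
    """

    minimum: float
    maximum: float
    mean: float
    sd: float
    kurtosis: float
    n_trials: int
    K: Optional[int] = None
    pool: Optional[str] = None
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "pool": self.pool,
            "K": self.K,
            "min": self.minimum,
            "max": self.maximum,
            "mean": self.mean,
            "sd": self.sd,
            "kurtosis": self.kurtosis,
            "n_trials": self.n_trials,
            "n_failed": self.n_failed,
        }


def draw_sampling_matrix(
    n_rows: int, pool_size: int, K: int, seed=0
) -> SamplingMatrix:
    """Draw a sampling matrix: per row, K distinct columns chosen uniformly.

    Rows are independent.  ``seed`` may be an integer or a Generator.
    """
    if K < 1 or K > pool_size:
        raise InfeasibleAssignmentError(
            f"need 1 <= K <= pool_size, got K={K}, pool_size={pool_size}"
        )
    if n_rows < 1:
        raise InfeasibleAssignmentError("n_rows must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # uniform without-replacement selection via random keys per row
    keys = rng.random((n_rows, pool_size))
    chosen = np.argpartition(keys, K - 1, axis=1)[:, :K]
    matrix = np.zeros((n_rows, pool_size), dtype=np.int8)
    np.put_along_axis(matrix, chosen, 1, axis=1)
    return SamplingMatrix(matrix=matrix, K=K)


def matrix_consensus(matrix: SamplingMatrix, counts_by_observer) -> np.ndarray:
    """Row-wise mean of the selected observers' counts.

    ``counts_by_observer`` is an (n_rows x pool_size) array or DataFrame,
    column j holding observer j's counts over the same ordered rows as the
    matrix.
    """
    counts = np.asarray(getattr(counts_by_observer, "values", counts_by_observer),
                        dtype=float)
    if counts.shape != matrix.matrix.shape:
        raise ShapeError(
            f"counts shape {counts.shape} does not match sampling matrix "
            f"{matrix.matrix.shape}"
        )
    return (matrix.matrix * counts).sum(axis=1) / matrix.K


def observer_count_matrix(
    annotations: pd.DataFrame, design: pd.DataFrame, pool: Sequence[str]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Align each pool observer's counts with the design's plant-time rows.

    Returns ``(rows, counts)`` where ``rows`` is the design sorted by
    (plant_id, time_days) and ``counts[i, j]`` is observer ``pool[j]``'s
    count for row i.  Every pool observer must cover every design image.
    """
    rows = design.sort_values(["plant_id", "time_days"]).reset_index(drop=True)
    counts = np.empty((len(rows), len(pool)))
    for j, obs in enumerate(pool):
        sub = annotations[annotations["observer_id"] == obs]
        series = sub.set_index("image_id")["count"]
        missing = [i for i in rows["image_id"] if i not in series.index]
        if missing:
            raise MissingDataError(
                f"observer {obs!r} lacks counts for {len(missing)} images",
                image_ids=missing,
            )
        counts[:, j] = series.loc[rows["image_id"]].to_numpy(dtype=float)
    return rows, counts


def run_subsampling_study(
    annotations: pd.DataFrame,
    design: pd.DataFrame,
    pool: Sequence[str],
    K: int,
    n_trials: int = 500,
    seed: int = 0,
    pool_label: Optional[str] = None,
) -> PValueSummary:
    """Run the Monte-Carlo subsampling experiment for one (pool, K) setting.

    Per trial: draw a sampling matrix, average the selected observers'
    counts per plant-time row, fit the interaction ANOVA and record the
    interaction p-value.  Trials whose model fit fails are excluded and
    counted in ``n_failed``.  Trial t uses the seed stream
    ``SeedSequence([seed, t])`` so any single trial is reproducible on its
    own.
    """
    if K > len(pool):
        raise InfeasibleAssignmentError(f"K={K} exceeds pool size {len(pool)}")
    rows, counts = observer_count_matrix(annotations, design, pool)
    base = rows[["plant_id", "cultivar", "time_days"]].copy()
    pvals = []
    n_failed = 0
    for trial in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence([seed, trial]))
        matrix = draw_sampling_matrix(len(rows), len(pool), K, seed=rng)
        table = base.copy()
        table["count"] = matrix_consensus(matrix, counts)
        try:
            res = fit_interaction_anova(table)
            pvals.append(res.interaction_p)
        except (ModelError, np.linalg.LinAlgError):
            n_failed += 1
    summary = summarize_pvalues(pvals)
    summary.K = K
    summary.pool = pool_label if pool_label is not None else f"{len(pool)} observers"
    summary.n_failed = n_failed
    return summary


def summarize_pvalues(p_list: Sequence[float]) -> PValueSummary:
    """Min/max/mean/sample-SD/raw-kurtosis summary of a p-value list."""
    p = np.asarray(list(p_list), dtype=float)
    if len(p) == 0:
        raise InsufficientDataError("no p-values to summarize")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    sd = float(np.std(p, ddof=1)) if len(p) > 1 else 0.0
    if np.ptp(p) == 0:
        kurt = float("nan")
    else:
        kurt = float(stats.kurtosis(p, fisher=False, bias=True))
    return PValueSummary(
        minimum=float(np.min(p)),
        maximum=float(np.max(p)),
        mean=float(np.mean(p)),
        sd=sd,
        kurtosis=kurt,
        n_trials=len(p),
    )


def subsampling_table(
    annotations: pd.DataFrame,
    design: pd.DataFrame,
    pools: dict,
    k_values: Sequence[int],
    n_trials: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Full study over named pools x K values, one summary row each.

    ``pools`` maps a label (e.g. "Any", "ExP only") to a list of observer
    ids.  K values exceeding a pool's size are skipped for that pool.
    """
    rows = []
    for label, pool in pools.items():
        for K in k_values:
            if K > len(pool):
                continue
            summary = run_subsampling_study(
                annotations, design, pool, K,
                n_trials=n_trials, seed=seed, pool_label=label,
            )
            rows.append(summary.to_dict())
    return pd.DataFrame(rows)
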