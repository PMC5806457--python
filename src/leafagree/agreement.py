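"""Agreement metrics between a reference observer and another count source.

The suite follows common practice for evaluating discrete count annotations:
signed and absolute count differences (DiC, |DiC|), mean squared error, the
squared Pearson correlation (R²), and Krippendorff's alpha on a ratio scale,
where the disagreement between two counts c and k is ((c-k)/(c+k))².  Counts
are heavily zero-inflated in their differences, which is why the whole suite
is reported rather than a single index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, NoOverlapError

__all__ = [
    "PairedCounts",
    "AgreementReport",
    "TimingSummary",
    "counts_by_image",
    "pair_counts",
    "agreement_report",
    "krippendorff_alpha",
    "within_one_fraction",
    "timing_summary",
    "ratings_matrix",
]


@dataclass
class PairedCounts:
    """Aligned reference/other count vectors over a shared image list."""

    image_ids: list
    x_ref: np.ndarray
    x_other: np.ndarray
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.image_ids)

    @property
    def diffs(self) -> np.ndarray:
        """Signed differences, reference minus other."""
        return self.x_ref - self.x_other


@dataclass
class AgreementReport:
    """The five agreement statistics for one observer pair.

    ``r2`` is NaN with ``r2_defined=False`` when either vector has zero
    variance (the statistic is undefined, not an error).
    """

    dic_mean: float
    dic_sd: float
    adic_mean: float
    adic_sd: float
    mse: float
    r2: float
    alpha: float
    n: int
    r2_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "dic_mean": self.dic_mean,
            "dic_sd": self.dic_sd,
            "adic_mean": self.adic_mean,
            "adic_sd": self.adic_sd,
            "mse": self.mse,
            "r2": self.r2,
            "alpha": self.alpha,
            "n": self.n,
            "r2_defined": self.r2_defined,
        }


@dataclass
class TimingSummary:
    """Per-plant annotation durations and per-leaf gaps from dot timestamps."""

    durations_s: np.ndarray
    duration_mean_s: float
    duration_sd_s: float
    gap_mean_s: float
    gap_sd_s: float
    n_excluded: int
    n_no_duration: int
    outlier_s: float


def counts_by_image(source, **selector) -> pd.Series:
    """Reduce a count source to one count per image.

    ``source`` is either an annotation frame (column ``count``; filtered by
    equality on any ``selector`` columns such as ``observer_id``, ``mode``,
    ``dataset_label``, ``reading_index``) or a consensus result carrying a
    ``frame`` with (``image_id``, ``value``).
    """
    frame = getattr(source, "frame", source)
    value_col = "value" if "value" in frame.columns else "count"
    sub = frame
    for col, val in selector.items():
        if val is None:
            continue
        if col not in sub.columns:
            raise KeyError(f"selector column {col!r} not in source")
        sub = sub[sub[col] == val]
    if sub["image_id"].duplicated().any():
        dupes = sub.loc[sub["image_id"].duplicated(), "image_id"].unique()
        raise ValueError(
            f"multiple counts per image after filtering (e.g. {dupes[0]!r}); "
            "tighten the selector or aggregate first"
        )
    return sub.set_index("image_id")[value_col].astype(float)


def pair_counts(set_a, set_b, selector_a=None, selector_b=None) -> PairedCounts:
    """Align two count sources on their common images (sorted by image id).

    Images present in only one source are dropped and counted in
    ``n_dropped``.  An empty intersection raises :class:`NoOverlapError`.
    """
    a = counts_by_image(set_a, **(selector_a or {}))
    b = counts_by_image(set_b, **(selector_b or {}))
    common = sorted(set(a.index) & set(b.index))
    if not common:
        raise NoOverlapError("no image is shared by both sources after filtering")
    dropped = (len(a) - len(common)) + (len(b) - len(common))
    return PairedCounts(
        image_ids=common,
        x_ref=a.loc[common].to_numpy(),
        x_other=b.loc[common].to_numpy(),
        n_dropped=dropped,
    )


def agreement_report(paired: PairedCounts) -> AgreementReport:
    """Compute DiC, |DiC|, MSE, R² and ratio-scale alpha for a pair.

    Sign convention: differences are reference minus other, so a positive
    DiC means the other source undercounts relative to the reference.
    SDs use the sample (n-1) denominator.
    """
    if paired.n < 2:
        raise InsufficientDataError("need at least 2 pairs")
    d = paired.diffs.astype(float)
    x, y = paired.x_ref.astype(float), paired.x_other.astype(float)
    r2_defined = bool(np.ptp(x) > 0 and np.ptp(y) > 0)
    if r2_defined:
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    else:
        r2 = float("nan")
    matrix = np.column_stack([x, y])
    return AgreementReport(
        dic_mean=float(np.mean(d)),
        dic_sd=float(np.std(d, ddof=1)),
        adic_mean=float(np.mean(np.abs(d))),
        adic_sd=float(np.std(np.abs(d), ddof=1)),
        mse=float(np.mean(d**2)),
        r2=r2,
        alpha=krippendorff_alpha(matrix),
        n=paired.n,
        r2_defined=r2_defined,
    )


def _ratio_delta_sq(values: np.ndarray) -> np.ndarray:
    """Pairwise ratio-scale disagreement ((c-k)/(c+k))²; δ²(0,0) = 0."""
    c = values[:, None]
    k = values[None, :]
    denom = c + k
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(denom != 0, ((c - k) / np.where(denom == 0, 1, denom)) ** 2, 0.0)
    np.fill_diagonal(delta, 0.0)
    return delta


def krippendorff_alpha(ratings, metric: str = "ratio") -> float:
    """Krippendorff's alpha over a units x raters matrix of counts.

    ``ratings`` is a 2-D array or DataFrame (rows = units/images, columns =
    raters) with NaN marking missing entries.  Units with fewer than two
    non-missing ratings are unpairable and ignored.  Alpha is
    ``1 - D_o / D_e`` with observed and expected disagreement computed from
    the coincidence matrix of pairable values and, on the ratio scale,
    ``δ²(c, k) = ((c - k) / (c + k))²`` (``δ²(0, 0) = 0`` by continuity).
    Returns exactly 1.0 when every unit is internally unanimous.
    """
    if metric != "ratio":
        raise ValueError(f"only the ratio metric is implemented, got {metric!r}")
    arr = np.asarray(getattr(ratings, "values", ratings), dtype=float)
    if arr.ndim != 2:
        raise ValueError("ratings must be 2-D (units x raters)")
    units = [row[~np.isnan(row)] for row in arr]
    units = [u for u in units if len(u) >= 2]
    if len(units) < 2:
        raise InsufficientDataError(
            "need at least 2 units with >= 2 ratings each"
        )
    if any((u < 0).any() for u in units):
        raise ValueError("ratio-scale alpha requires non-negative values")

    values = np.unique(np.concatenate(units))
    index = {v: i for i, v in enumerate(values)}
    v = len(values)
    coincidence = np.zeros((v, v))
    for u in units:
        m = len(u)
        idx = np.array([index[x] for x in u])
        cnt = np.bincount(idx, minlength=v).astype(float)
        # ordered within-unit pairs: outer(cnt, cnt) minus the m self-pairs
        coincidence += (np.outer(cnt, cnt) - np.diag(cnt)) / (m - 1)
    n_c = coincidence.sum(axis=1)
    n = n_c.sum()
    delta = _ratio_delta_sq(values)
    d_obs = float((coincidence * delta).sum())
    if d_obs == 0.0:
        return 1.0
    d_exp = float((np.outer(n_c, n_c) * delta).sum()) / (n - 1)
    if d_exp == 0.0:
        return 1.0
    return 1.0 - d_obs / d_exp


def within_one_fraction(paired: PairedCounts) -> float:
    """Fraction of pairs agreeing to within +/- one count."""
    if paired.n < 1:
        raise InsufficientDataError("need at least 1 pair")
    return float(np.mean(np.abs(paired.diffs) <= 1))


def timing_summary(
    annotations: pd.DataFrame, outlier_s: float = 200.0
) -> TimingSummary:
    """Summarize annotation timing from per-leaf dot timestamps.

    Per plant image, the duration is the elapsed time between the first and
    last dot.  Durations above ``outlier_s`` (default 200 s) are treated as
    interrupted sessions: excluded from every summary and counted in
    ``n_excluded``.  Per-leaf gaps pool the successive dot-time differences
    of the included records.  Records with fewer than two dots contribute no
    duration and are counted in ``n_no_duration``.
    """
    if "dot_times_s" not in annotations.columns:
        raise ValueError("annotations carry no dot_times_s column")
    durations, gaps = [], []
    n_excluded = n_no_duration = 0
    for times in annotations["dot_times_s"]:
        if times is None or len(times) < 2:
            n_no_duration += 1
            continue
        t = np.asarray(times, dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError("dot_times_s must be non-decreasing")
        duration = float(t[-1] - t[0])
        if duration > outlier_s:
            n_excluded += 1
            continue
        durations.append(duration)
        gaps.extend(np.diff(t).tolist())
    durations = np.asarray(durations)
    gaps = np.asarray(gaps)

    def _mean_sd(x):
        if len(x) == 0:
            return float("nan"), float("nan")
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        return float(np.mean(x)), sd

    dur_mean, dur_sd = _mean_sd(durations)
    gap_mean, gap_sd = _mean_sd(gaps)
    return TimingSummary(
        durations_s=durations,
        duration_mean_s=dur_mean,
        duration_sd_s=dur_sd,
        gap_mean_s=gap_mean,
        gap_sd_s=gap_sd,
        n_excluded=n_excluded,
        n_no_duration=n_no_duration,
        outlier_s=outlier_s,
    )


def ratings_matrix(annotations: pd.DataFrame, **selector) -> pd.DataFrame:
    """Pivot an annotation frame into a units x raters ratings matrix.

    Rows are image ids, columns observer ids, entries counts (NaN where an
    observer did not annotate an image).  ``selector`` filters as in
    :func:`counts_by_image`.
    """
    sub = annotations
    for col, val in selector.items():
        if val is None:
            continue
        sub = sub[sub[col] == val]
    return sub.pivot_table(
        index="image_id", columns="observer_id", values="count", aggfunc="first"
    )
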