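"""Aggregation of citizen annotations into consensus counts.

A "consensus citizen" is a virtual observer whose per-image count is an
aggregate of the citizen pool: the arithmetic mean, the maximum, or one
randomly selected annotation.  Under miss-dominated noise the mean
underestimates the true count while the maximum does not, which is why both
are of interest.  The module also relates the citizens' self-reported
confidence (3 = all leaves annotated, 2 = not sure, 1 = missed leaves) to
the per-image spread of their counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidMethodError

CONSENSUS_METHODS = ("average", "max", "single_random")


@dataclass
class ConsensusCounts:
    """Per-image consensus values.

    ``frame`` has columns (image_id, value, n_annotations); ``method``
    records how the value was formed.  For ``max`` the value is an integer.
    """

    frame: pd.DataFrame
    method: str


@dataclass
class ConfidenceSpread:
    """Per-image count spread vs mean confidence, and their 2-D histogram.

    ``per_image`` columns: image_id, count_sd (sample SD), mean_confidence,
    n.  ``hist`` is normalized to sum to 1 over (sd bin, confidence bin);
    the first SD bin holds exactly-zero spread ("none", full agreement).
    ``quadrant_fraction`` is the fraction of images in the low-spread /
    high-confidence region (count_sd < sd_threshold and mean_confidence >
    conf_threshold), computed from the raw per-image values.
    """

    per_image: pd.DataFrame
    hist: np.ndarray
    sd_bin_labels: list
    conf_bin_edges: np.ndarray
    quadrant_fraction: float
    sd_threshold: float
    conf_threshold: float
    n_excluded: int


def consensus_counts(
    study: pd.DataFrame, method: str = "average", seed: int = 0
) -> ConsensusCounts:
    """Aggregate a citizen study into one consensus count per image."""
    if method not in CONSENSUS_METHODS:
        raise InvalidMethodError(
            f"method must be one of {CONSENSUS_METHODS}, got {method!r}"
        )
    if len(study) == 0:
        raise InsufficientDataError("empty citizen study")
    grouped = study.sort_values("image_id").groupby("image_id")["count"]
    n = grouped.size()
    if method == "average":
        value = grouped.mean()
    elif method == "max":
        value = grouped.max()
    else:  # single_random
        rng = np.random.default_rng(seed)
        value = grouped.apply(lambda x: float(x.iloc[rng.integers(len(x))]))
    frame = pd.DataFrame(
        {"image_id": value.index, "value": value.to_numpy(dtype=float),
         "n_annotations": n.loc[value.index].to_numpy()}
    ).reset_index(drop=True)
    return ConsensusCounts(frame=frame, method=method)


def confidence_spread(
    study: pd.DataFrame,
    sd_threshold: float = 1.0,
    conf_threshold: float = 2.0,
    sd_bins: Optional[Sequence[float]] = None,
    conf_bins: Optional[Sequence[float]] = None,
) -> ConfidenceSpread:
    """Relate per-image count spread to mean self-reported confidence.

    Images with a single annotation have no sample SD; they are excluded
    and counted.  ``sd_bins`` are the right edges of the positive-SD bins
    (an exact-zero "none" bin is always prepended); ``conf_bins`` are the
    histogram edges on the confidence axis over [1, 3].
    """
    grouped = study.groupby("image_id")
    per_image = grouped.agg(
        count_sd=("count", lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else np.nan),
        mean_confidence=("confidence", "mean"),
        n=("count", "size"),
    ).reset_index()
    n_excluded = int(per_image["count_sd"].isna().sum())
    per_image = per_image.dropna(subset=["count_sd"]).reset_index(drop=True)
    if len(per_image) == 0:
        raise InsufficientDataError("no image has >= 2 annotations")

    sd = per_image["count_sd"].to_numpy()
    conf = per_image["mean_confidence"].to_numpy()
    quadrant = float(np.mean((sd < sd_threshold) & (conf > conf_threshold)))

    if sd_bins is None:
        sd_bins = (0.5, 1.0, 1.5, 2.0, np.inf)
    if conf_bins is None:
        conf_bins = (1.0, 1.5, 2.0, 2.5, 3.0)
    conf_bins = np.asarray(conf_bins, dtype=float)
    sd_labels = ["none"]
    lo = 0.0
    for hi in sd_bins:
        sd_labels.append(f"({lo:g}, {hi:g}]")
        lo = hi

    hist = np.zeros((len(sd_labels), len(conf_bins) - 1))
    sd_idx = np.zeros(len(sd), dtype=int)
    positive = sd > 0
    sd_idx[positive] = 1 + np.searchsorted(np.asarray(sd_bins), sd[positive],
                                           side="left")
    sd_idx = np.clip(sd_idx, 0, len(sd_labels) - 1)
    conf_idx = np.clip(
        np.searchsorted(conf_bins, conf, side="right") - 1, 0, len(conf_bins) - 2
    )
    np.add.at(hist, (sd_idx, conf_idx), 1.0)
    hist /= hist.sum()
    return ConfidenceSpread(
        per_image=per_image,
        hist=hist,
        sd_bin_labels=sd_labels,
        conf_bin_edges=conf_bins,
        quadrant_fraction=quadrant,
        sd_threshold=sd_threshold,
        conf_threshold=conf_threshold,
        n_excluded=n_excluded,
    )
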