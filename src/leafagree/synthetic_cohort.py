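"""Synthetic study cohort: design grid and ground-truth longitudinal leaf counts.

The generator emulates a two-cultivar *Arabidopsis thaliana* top-view imaging
study: a wild-type and a slower-growing starch mutant, R replicates each,
imaged every 48 h for T time points, at two optical resolutions, optionally
with geometrically transformed copies used to probe intra-observer memory
effects.  Each plant carries a latent linear leaf-emergence process; the
integer leaf count visible at a time point is the rounded latent count, and
per-leaf emergence times drive the observer model's young-leaf miss
mechanism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidDesignError

CULTIVARS = ("wild_type", "mutant")

#: Nominal square pixel size of each resolution variant.
RESOLUTION_PX = {"low": 300, "high": 470}

#: Appearance-only transforms applied to the duplicated datasets.
TRANSFORMS = ("rot90", "rot180", "rot270", "hflip", "vflip")

#: Dataset label as a function of (resolution variant, transformed flag).
DATASET_LABELS = {
    ("low", False): "A",
    ("high", False): "B",
    ("low", True): "C",
    ("high", True): "D",
}

DESIGN_COLUMNS = [
    "image_id",
    "plant_id",
    "cultivar",
    "replicate",
    "timepoint",
    "time_days",
    "resolution",
    "transform",
    "dataset_label",
]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the latent leaf-emergence process.

    Parameters
    ----------
    n0 : int
        Leaf count at the first imaging day (all plants start equal).
    rate_per_cultivar : mapping
        Mean emergence rate in leaves/day per cultivar.  The default gives
        the wild type 0.50 and the mutant 0.35 leaves/day, i.e. phyllochrons
        of 2 and ~2.9 days, so end-of-study counts of roughly 14 vs 10
        over a 24-day window.
    plant_effect_sd : float
        Standard deviation (leaves/day) of the zero-mean Gaussian per-plant
        deviation added to the cultivar rate.
    young_age_days : float
        A leaf younger than this at imaging time counts as "young" for the
        observer miss model.
    """

    n0: int = 2
    rate_per_cultivar: Mapping[str, float] = field(
        default_factory=lambda: {"wild_type": 0.50, "mutant": 0.35}
    )
    plant_effect_sd: float = 0.05
    young_age_days: float = 2.0

    def __post_init__(self):
        if self.n0 < 0:
            raise ConfigurationError("n0 must be >= 0")
        if self.plant_effect_sd < 0:
            raise ConfigurationError("plant_effect_sd must be >= 0")
        if self.young_age_days <= 0:
            raise ConfigurationError("young_age_days must be > 0")
        for cultivar, rate in self.rate_per_cultivar.items():
            if rate < 0:
                raise ConfigurationError(f"rate for {cultivar!r} must be >= 0")


@dataclass
class GroundTruth:
    """Latent truth behind a simulated cohort.

    Attributes
    ----------
    counts : pandas.DataFrame
        Columns ``image_id``, ``true_count``; one row per design image.
    emergence_times : dict
        ``plant_id -> np.ndarray`` of non-decreasing emergence days, one
        entry per leaf the plant ever produces within the study window.
    young_age_days : float
        Age threshold below which a leaf is "young" (copied from the
        generating :class:`GrowthParams` so downstream consumers need no
        extra hand-off).
    """

    counts: pd.DataFrame
    emergence_times: dict
    young_age_days: float = 2.0

    def count_map(self) -> pd.Series:
        """Return ``image_id -> true_count`` as a Series."""
        return self.counts.set_index("image_id")["true_count"]

    def age_table(self, design: pd.DataFrame) -> pd.DataFrame:
        """Per-image leaf age breakdown.

        Returns a frame with columns ``image_id``, ``true_count``,
        ``n_young``, ``n_old`` where young/old splits the leaves present at
        the image's time point by ``young_age_days``.
        """
        rows = []
        for image_id, plant_id, t in design[
            ["image_id", "plant_id", "time_days"]
        ].itertuples(index=False):
            emerg = self.emergence_times[plant_id]
            present = emerg <= t + 1e-12
            age = t - emerg[present]
            n_young = int(np.sum(age < self.young_age_days - 1e-12))
            n_present = int(np.sum(present))
            rows.append((image_id, n_present, n_young, n_present - n_young))
        return pd.DataFrame(rows, columns=["image_id", "true_count", "n_young", "n_old"])


def build_design(
    cultivars: Sequence[str] = CULTIVARS,
    n_replicates: int = 5,
    n_timepoints: int = 13,
    interval_h: float = 48.0,
    resolution_variants: Sequence[str] = ("low",),
    include_transformed: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Build the study-design grid.

    One row per (cultivar, replicate, time point) for every resolution
    variant, plus a transformed duplicate of each set when
    ``include_transformed`` is true.  The only randomness is the choice of
    transform for duplicated images, driven by ``seed``.

    Returns a DataFrame with columns :data:`DESIGN_COLUMNS`.  Plants are
    identified by ``plant_id = "<cultivar>_r<replicate>"``; all variants of
    the same plant/time share that identity (the transform and the optics
    change the appearance, never the plant).
    """
    if n_replicates < 1 or n_timepoints < 2:
        raise InvalidDesignError(
            f"need n_replicates >= 1 and n_timepoints >= 2, "
            f"got {n_replicates} and {n_timepoints}"
        )
    if interval_h <= 0:
        raise InvalidDesignError(f"interval_h must be > 0, got {interval_h}")
    if len(cultivars) == 0:
        raise InvalidDesignError("at least one cultivar required")
    if len(set(cultivars)) != len(cultivars):
        raise InvalidDesignError("duplicate cultivar names")
    for res in resolution_variants:
        if res not in RESOLUTION_PX:
            raise InvalidDesignError(f"unknown resolution variant {res!r}")
    if len(resolution_variants) == 0:
        raise InvalidDesignError("at least one resolution variant required")

    rng = np.random.default_rng(seed)
    interval_days = interval_h / 24.0
    rows = []
    transformed_flags = (False, True) if include_transformed else (False,)
    for resolution in resolution_variants:
        for transformed in transformed_flags:
            label = DATASET_LABELS[(resolution, transformed)]
            for cultivar in cultivars:
                for rep in range(1, n_replicates + 1):
                    plant_id = f"{cultivar}_r{rep}"
                    for tp in range(1, n_timepoints + 1):
                        transform = (
                            rng.choice(TRANSFORMS) if transformed else "identity"
                        )
                        rows.append(
                            (
                                f"{label}_{cultivar}_r{rep}_t{tp:02d}",
                                plant_id,
                                cultivar,
                                rep,
                                tp,
                                (tp - 1) * interval_days,
                                resolution,
                                transform,
                                label,
                            )
                        )
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    return design


def _half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def simulate_growth(
    design: pd.DataFrame, params: GrowthParams = GrowthParams(), seed: int = 0
) -> GroundTruth:
    """Simulate ground-truth counts for every plant in ``design``.

    Each plant p draws a rate deviation ``u_p ~ N(0, plant_effect_sd^2)``;
    its latent count is ``n0 + max(0, rate(cultivar) + u_p) * t`` and the
    visible count is the half-up-rounded latent count, forced non-decreasing
    along time.  Leaf k (k > n0) emerges when the latent count crosses
    k - 1/2, i.e. at ``(k - 0.5 - n0) / slope`` days; the first n0 leaves
    are assigned emergence day 0.  All resolution/transform variants of the
    same plant/time share one truth.
    """
    if len(design) == 0:
        raise InvalidDesignError("empty design")
    plants = (
        design[["plant_id", "cultivar"]]
        .drop_duplicates()
        .sort_values("plant_id")
        .reset_index(drop=True)
    )
    for cultivar in plants["cultivar"].unique():
        if cultivar not in params.rate_per_cultivar:
            raise ConfigurationError(f"no growth rate configured for {cultivar!r}")

    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, params.plant_effect_sd, size=len(plants))

    max_t = float(design["time_days"].max())
    emergence: dict[str, np.ndarray] = {}
    slope_by_plant: dict[str, float] = {}
    for (plant_id, cultivar), u_p in zip(
        plants.itertuples(index=False), u, strict=True
    ):
        slope = max(0.0, params.rate_per_cultivar[cultivar] + u_p)
        slope_by_plant[plant_id] = slope
        final = _half_up(params.n0 + slope * max_t)
        times = [0.0] * params.n0
        for k in range(params.n0 + 1, final + 1):
            times.append((k - 0.5 - params.n0) / slope)
        emergence[plant_id] = np.asarray(times, dtype=float)

    counts = []
    # running maximum per plant guards monotonicity against any float edge case
    last: dict[str, int] = {}
    ordered = design.sort_values(["plant_id", "time_days"])
    for image_id, plant_id, t in ordered[
        ["image_id", "plant_id", "time_days"]
    ].itertuples(index=False):
        c = _half_up(params.n0 + slope_by_plant[plant_id] * t)
        c = max(c, last.get(plant_id, 0))
        last[plant_id] = c
        counts.append((image_id, c))
    frame = pd.DataFrame(counts, columns=["image_id", "true_count"])
    # restore the design's image order
    frame = (
        design[["image_id"]].merge(frame, on="image_id", how="left")
    )
    return GroundTruth(
        counts=frame,
        emergence_times=emergence,
        young_age_days=params.young_age_days,
    )
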