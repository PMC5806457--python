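"""Simulated observers: experts, non-experts and a citizen annotation pool.

The noise model is deliberately mechanistic rather than cognitive: every
true leaf is detected independently, with a miss probability that depends on
whether the leaf is young (recently emerged) and on the image resolution;
a spurious extra count can occur; counting without the dot-annotation tool
(spreadsheet mode) adds a discretized zero-mean perturbation emulating lost
track / restarted counts.  Experts are resolution-sensitive on young leaves,
non-experts miss young leaves regardless of resolution, and citizens behave
like non-experts with slightly worse baseline attention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InfeasibleAssignmentError, InvalidModeError
from .synthetic_cohort import GroundTruth

MODES = ("tool", "spreadsheet")

ANNOTATION_COLUMNS = [
    "observer_id",
    "experience",
    "image_id",
    "dataset_label",
    "mode",
    "reading_index",
    "count",
]

CITIZEN_COLUMNS = ["user_id", "logged_in", "image_id", "count", "confidence"]

#: P(confidence = 3, 2, 1) conditioned on how many leaves the user missed.
DEFAULT_CONFIDENCE_TABLE = {
    0: (0.80, 0.15, 0.05),
    1: (0.50, 0.30, 0.20),
    2: (0.20, 0.40, 0.40),  # applies to >= 2 missed leaves
}


@dataclass(frozen=True)
class ObserverProfile:
    """Error profile of one simulated observer.

    ``p_miss_young`` maps resolution variant -> probability of missing a
    young leaf; ``p_miss_old`` applies to established leaves at any
    resolution; ``p_spurious`` is the chance of one extra (phantom) count;
    ``sd_extra_noise`` is the spreadsheet-mode perturbation SD in leaves.
    """

    observer_id: str
    experience: str  # ExP | NExP | citizen
    p_miss_young: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.30, "high": 0.10}
    )
    p_miss_old: float = 0.01
    p_spurious: float = 0.0
    sd_extra_noise: float = 0.0

    def __post_init__(self):
        probs = [self.p_miss_old, self.p_spurious, *self.p_miss_young.values()]
        if any(p < 0 or p > 1 for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if self.sd_extra_noise < 0:
            raise ConfigurationError("sd_extra_noise must be >= 0")


def expert_profile(observer_id: str = "ExP1", **overrides) -> ObserverProfile:
    """Experienced observer: resolution-sensitive young-leaf misses."""
    kw = dict(
        observer_id=observer_id,
        experience="ExP",
        p_miss_young={"low": 0.30, "high": 0.10},
        p_miss_old=0.01,
        p_spurious=0.01,
        sd_extra_noise=0.5,
    )
    kw.update(overrides)
    return ObserverProfile(**kw)


def nonexpert_profile(observer_id: str = "NExP1", **overrides) -> ObserverProfile:
    """Non-experienced observer: misses young leaves at any resolution."""
    kw = dict(
        observer_id=observer_id,
        experience="NExP",
        p_miss_young={"low": 0.35, "high": 0.35},
        p_miss_old=0.02,
        p_spurious=0.02,
        sd_extra_noise=0.8,
    )
    kw.update(overrides)
    return ObserverProfile(**kw)


def citizen_profile(observer_id: str = "citizen", **overrides) -> ObserverProfile:
    """Default citizen: non-expert young-leaf behaviour, worse baseline, miss-only."""
    kw = dict(
        observer_id=observer_id,
        experience="citizen",
        p_miss_young={"low": 0.35, "high": 0.35},
        p_miss_old=0.04,
        p_spurious=0.0,
        sd_extra_noise=0.0,
    )
    kw.update(overrides)
    return ObserverProfile(**kw)


def default_observer_pool(n_experienced: int = 5, n_non_experienced: int = 4):
    """Roster emulating the controlled study: 5 experts + 4 non-experts.

    Miss probabilities are jittered deterministically across observers so
    the pool is heterogeneous but reproducible.
    """
    pool = []
    for i in range(n_experienced):
        jitter = 0.02 * (i - (n_experienced - 1) / 2)
        pool.append(
            expert_profile(
                f"ExP{i + 1}",
                p_miss_young={
                    "low": min(1.0, max(0.0, 0.30 + jitter)),
                    "high": min(1.0, max(0.0, 0.10 + jitter)),
                },
            )
        )
    for i in range(n_non_experienced):
        jitter = 0.02 * (i - (n_non_experienced - 1) / 2)
        p = min(1.0, max(0.0, 0.35 + jitter))
        pool.append(
            nonexpert_profile(f"NExP{i + 1}", p_miss_young={"low": p, "high": p})
        )
    return pool


def _observe_images(age_tab: pd.DataFrame, resolutions, profile, rng):
    """Vectorized single-pass detection over images.

    Returns (counts_before_mode_noise, n_missed) integer arrays aligned with
    ``age_tab`` rows.
    """
    n_young = age_tab["n_young"].to_numpy()
    n_old = age_tab["n_old"].to_numpy()
    p_young = np.array([profile.p_miss_young[r] for r in resolutions])
    det_young = rng.binomial(n_young, 1.0 - p_young)
    det_old = rng.binomial(n_old, 1.0 - profile.p_miss_old)
    spurious = (rng.random(len(age_tab)) < profile.p_spurious).astype(int)
    counts = det_young + det_old + spurious
    missed = (n_young - det_young) + (n_old - det_old)
    return counts, missed


def simulate_observer_counts(
    truth: GroundTruth,
    design: pd.DataFrame,
    profile: ObserverProfile,
    mode: str = "tool",
    reading_index: int = 1,
    seed: int = 0,
    dot_times: bool = False,
    dot_gap_mean_s: float = 1.1,
) -> pd.DataFrame:
    """Simulate one observer's reading of every image in ``design``.

    Returns an annotation frame with columns :data:`ANNOTATION_COLUMNS`,
    plus a ``dot_times_s`` object column (list of cumulative annotation
    times, one per counted leaf) when ``dot_times`` is requested in tool
    mode.  Identical arguments and seed reproduce the frame exactly.
    """
    if mode not in MODES:
        raise InvalidModeError(f"mode must be one of {MODES}, got {mode!r}")
    rng = np.random.default_rng(seed)
    age_tab = truth.age_table(design)
    missing = set(design["image_id"]) - set(age_tab["image_id"])
    if missing:
        raise ConfigurationError(f"truth does not cover images: {sorted(missing)[:5]}")
    counts, _ = _observe_images(age_tab, design["resolution"].to_numpy(), profile, rng)
    if mode == "spreadsheet" and profile.sd_extra_noise > 0:
        noise = np.rint(rng.normal(0.0, profile.sd_extra_noise, size=len(counts)))
        counts = counts + noise.astype(int)
    counts = np.clip(counts, 0, None)

    frame = pd.DataFrame(
        {
            "observer_id": profile.observer_id,
            "experience": profile.experience,
            "image_id": age_tab["image_id"],
            "dataset_label": design["dataset_label"].to_numpy(),
            "mode": mode,
            "reading_index": reading_index,
            "count": counts.astype(int),
        }
    )
    if dot_times and mode == "tool":
        times = [
            np.cumsum(rng.exponential(dot_gap_mean_s, size=c)).tolist()
            for c in frame["count"]
        ]
        frame["dot_times_s"] = times
    return frame


def simulate_citizen_study(
    truth: GroundTruth,
    design: pd.DataFrame,
    pool_size: int = 60,
    activity_skew: float = 1.2,
    base_profile: Optional[ObserverProfile] = None,
    confidence_table: Optional[Mapping[int, Sequence[float]]] = None,
    seed: int = 0,
    p_logged_in: float = 0.7,
) -> pd.DataFrame:
    """Simulate a citizen-powered annotation round over ``design``.

    Each image receives a uniform 3..8 annotations from distinct users drawn
    from a pool of ``pool_size`` with Zipf-like activity weights
    ``w_i ∝ 1/i^activity_skew`` (a few users contribute a large share).
    Counts follow ``base_profile`` (default: :func:`citizen_profile`); the
    self-reported confidence (3 = yes all annotated, 2 = not sure,
    1 = missed leaves) is drawn conditioned on how many leaves that user
    actually missed.

    Returns a frame with columns :data:`CITIZEN_COLUMNS`; no
    (user, image) pair occurs twice.
    """
    if pool_size < 8:
        raise InfeasibleAssignmentError(
            f"pool_size must be >= 8 to place up to 8 distinct users per image, "
            f"got {pool_size}"
        )
    profile = base_profile if base_profile is not None else citizen_profile()
    table = dict(DEFAULT_CONFIDENCE_TABLE if confidence_table is None else confidence_table)
    for k, probs in table.items():
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError(f"confidence probabilities for {k} missed "
                                     "leaves must sum to 1")

    rng = np.random.default_rng(seed)
    users = np.array([f"user_{i + 1:03d}" for i in range(pool_size)])
    weights = 1.0 / np.arange(1, pool_size + 1) ** activity_skew
    weights /= weights.sum()
    logged_in = rng.random(pool_size) < p_logged_in

    age_tab = truth.age_table(design).set_index("image_id")
    rows = []
    for image_id, resolution in design[["image_id", "resolution"]].itertuples(
        index=False
    ):
        n_u = int(rng.integers(3, 9))
        chosen = rng.choice(pool_size, size=n_u, replace=False, p=weights)
        rec = age_tab.loc[image_id]
        p_y = profile.p_miss_young[resolution]
        det_y = rng.binomial(int(rec["n_young"]), 1.0 - p_y, size=n_u)
        det_o = rng.binomial(int(rec["n_old"]), 1.0 - profile.p_miss_old, size=n_u)
        spurious = (rng.random(n_u) < profile.p_spurious).astype(int)
        counts = det_y + det_o + spurious
        missed = (int(rec["n_young"]) - det_y) + (int(rec["n_old"]) - det_o)
        for u, c, m in zip(chosen, counts, missed):
            probs = table[min(int(m), 2)]
            conf = int(rng.choice((3, 2, 1), p=probs))
            rows.append((users[u], bool(logged_in[u]), image_id, int(c), conf))
    return pd.DataFrame(rows, columns=CITIZEN_COLUMNS)
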