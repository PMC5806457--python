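"""CSV/JSON readers and writers, the citizen-export dialect, and run config.

All tables are RFC 4180 CSV with a mandatory header row, UTF-8 encoded.
The citizen export emulates a crowdsourcing platform's classification dump:
one row per annotation with the dot payload as a JSON array of {x, y}
objects whose length is the reported count, plus the confidence answer
(either the literal codes 1/2/3 or the phrases yes / not sure / missed
leaves).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .agreement import AgreementReport
from .ba_concordance import BAGrid
from .citizen_consensus import ConfidenceSpread, ConsensusCounts
from .errors import ConfigurationError, ParseError
from .longitudinal_model import AnovaResult
from .observer_model import ANNOTATION_COLUMNS, CITIZEN_COLUMNS
from .subsampling_study import PValueSummary
from .synthetic_cohort import DESIGN_COLUMNS, RESOLUTION_PX, GroundTruth

logger = logging.getLogger("leafagree")

CONFIDENCE_WORDS = {
    "yes": 3,
    "not sure": 2,
    "not_sure": 2,
    "missed leaves": 1,
    "missed_leaves": 1,
}


# ---------------------------------------------------------------------------
# design / truth
# ---------------------------------------------------------------------------

def write_design_csv(design: pd.DataFrame, path) -> None:
    design[DESIGN_COLUMNS].to_csv(path, index=False)


def read_design_csv(path) -> pd.DataFrame:
    design = pd.read_csv(path)
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ParseError(f"design file lacks columns {sorted(missing)}")
    return design[DESIGN_COLUMNS]


def write_truth_csv(truth: GroundTruth, path) -> None:
    truth.counts.to_csv(path, index=False)


def write_emergence_json(truth: GroundTruth, path) -> None:
    payload = {
        "young_age_days": truth.young_age_days,
        "emergence_times": {k: list(map(float, v))
                            for k, v in truth.emergence_times.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_ground_truth(counts_path, emergence_path) -> GroundTruth:
    counts = pd.read_csv(counts_path)
    if not {"image_id", "true_count"} <= set(counts.columns):
        raise ParseError("truth file needs columns image_id, true_count")
    payload = json.loads(Path(emergence_path).read_text(encoding="utf-8"))
    return GroundTruth(
        counts=counts[["image_id", "true_count"]],
        emergence_times={k: np.asarray(v, dtype=float)
                         for k, v in payload["emergence_times"].items()},
        young_age_days=float(payload["young_age_days"]),
    )


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def write_annotation_csv(annotations: pd.DataFrame, path) -> None:
    annotations[ANNOTATION_COLUMNS].to_csv(path, index=False)


def read_annotation_csv(path) -> pd.DataFrame:
    """Read a controlled-study annotation table, validating counts.

    Raises :class:`ParseError` naming the 1-based data row and column for a
    missing column, a non-integer count or a negative count.  An empty file
    with only a header yields an empty frame (with a warning).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(raw.columns)
    if missing:
        raise ParseError(f"annotation file lacks columns {sorted(missing)}")
    if len(raw) == 0:
        logger.warning("annotation file %s contains a header but no rows", path)
    counts = []
    for i, text in enumerate(raw["count"], start=1):
        try:
            value = int(text)
        except ValueError:
            raise ParseError(
                f"row {i}: count {text!r} is not an integer", row=i, column="count"
            ) from None
        if value < 0:
            raise ParseError(
                f"row {i}: count {value} is negative", row=i, column="count"
            )
        counts.append(value)
    readings = pd.to_numeric(raw["reading_index"], errors="coerce")
    if readings.isna().any():
        bad = int(readings.isna().idxmax()) + 1
        raise ParseError(f"row {bad}: reading_index not an integer",
                         row=bad, column="reading_index")
    out = raw[ANNOTATION_COLUMNS].copy()
    out["count"] = counts
    out["reading_index"] = readings.astype(int)
    return out


# ---------------------------------------------------------------------------
# citizen export
# ---------------------------------------------------------------------------

def write_citizen_export(
    study: pd.DataFrame, design: pd.DataFrame, path, seed: int = 0
) -> None:
    """Write a citizen study in the platform-export dialect.

    Dot coordinates are fabricated uniformly inside the nominal pixel size
    of each image's resolution variant; their number equals the count.
    """
    rng = np.random.default_rng(seed)
    px = design.set_index("image_id")["resolution"].map(RESOLUTION_PX)
    rows = []
    for cid, rec in enumerate(study.itertuples(index=False), start=1):
        size = int(px.get(rec.image_id, 300))
        dots = [
            {"x": int(rng.integers(0, size)), "y": int(rng.integers(0, size))}
            for _ in range(int(rec.count))
        ]
        rows.append(
            {
                "classification_id": cid,
                "user_id": rec.user_id,
                "logged_in": bool(rec.logged_in),
                "image_id": rec.image_id,
                "annotation_json": json.dumps(dots),
                "confidence": int(rec.confidence),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def _parse_confidence(text: str, row: int) -> int:
    t = str(text).strip().lower()
    if t in {"1", "2", "3"}:
        return int(t)
    if t in CONFIDENCE_WORDS:
        return CONFIDENCE_WORDS[t]
    raise ParseError(
        f"row {row}: confidence {text!r} outside the 1/2/3 or "
        "yes / not sure / missed leaves encoding",
        row=row,
        column="confidence",
    )


def read_citizen_export(path) -> pd.DataFrame:
    """Parse a citizen export back into a study frame.

    The count is the length of the JSON dot array; the confidence accepts
    literal codes or the answer phrases.  Malformed JSON raises
    :class:`ParseError` with the row number.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"user_id", "image_id", "annotation_json", "confidence"}
    missing = required - set(raw.columns)
    if missing:
        raise ParseError(f"citizen export lacks columns {sorted(missing)}")
    rows = []
    for i, rec in enumerate(raw.itertuples(index=False), start=1):
        try:
            dots = json.loads(rec.annotation_json)
        except json.JSONDecodeError:
            raise ParseError(
                f"row {i}: annotation_json is not valid JSON",
                row=i, column="annotation_json",
            ) from None
        if not isinstance(dots, list):
            raise ParseError(
                f"row {i}: annotation_json must be a JSON array",
                row=i, column="annotation_json",
            )
        logged = str(getattr(rec, "logged_in", "false")).strip().lower() in (
            "true", "1", "yes"
        )
        rows.append(
            (
                rec.user_id,
                logged,
                rec.image_id,
                len(dots),
                _parse_confidence(rec.confidence, i),
            )
        )
    return pd.DataFrame(rows, columns=CITIZEN_COLUMNS)


# ---------------------------------------------------------------------------
# analysis outputs
# ---------------------------------------------------------------------------

def read_ratings_csv(path) -> pd.DataFrame:
    """Wide ratings matrix: image_id column + one column per rater."""
    frame = pd.read_csv(path)
    if "image_id" not in frame.columns:
        raise ParseError("ratings file needs an image_id column")
    return frame.set_index("image_id").astype(float)


def write_ratings_csv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index=True)


def write_agreement_report(report: AgreementReport, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(report.to_dict(), indent=1), encoding="utf-8")
    else:
        pd.DataFrame([report.to_dict()]).to_csv(path, index=False)


def write_ba_grid(grid: BAGrid, csv_path, json_path=None) -> None:
    grid.cells.to_csv(csv_path, index=False)
    if json_path is not None:
        sidecar = {
            "bias": grid.bias,
            "loa_low": grid.loa_low,
            "loa_high": grid.loa_high,
            "sd_diff": grid.sd_diff,
            "n": grid.n,
        }
        Path(json_path).write_text(json.dumps(sidecar, indent=1), encoding="utf-8")


def write_anova_csv(result: AnovaResult, path) -> None:
    frame = result.terms.rename(columns={"f_value": "F", "p_value": "p"})
    frame[["term", "sum_sq", "F", "p"]].to_csv(path, index=False)


def write_pvalue_summary_csv(summaries: Sequence[PValueSummary], path) -> None:
    pd.DataFrame([s.to_dict() for s in summaries]).to_csv(path, index=False)


def write_consensus_csv(consensus: ConsensusCounts, path) -> None:
    frame = consensus.frame.copy()
    frame.insert(1, "method", consensus.method)
    frame.to_csv(path, index=False)


def read_consensus_csv(path) -> ConsensusCounts:
    frame = pd.read_csv(path)
    if not {"image_id", "method", "value", "n_annotations"} <= set(frame.columns):
        raise ParseError("consensus file lacks required columns")
    methods = frame["method"].unique()
    if len(methods) != 1:
        raise ParseError("consensus file mixes methods")
    return ConsensusCounts(
        frame=frame[["image_id", "value", "n_annotations"]], method=methods[0]
    )


def write_confidence_spread(spread: ConfidenceSpread, csv_path, json_path) -> None:
    spread.per_image.to_csv(csv_path, index=False)
    sidecar = {
        "quadrant_fraction": spread.quadrant_fraction,
        "sd_threshold": spread.sd_threshold,
        "conf_threshold": spread.conf_threshold,
        "sd_bin_labels": spread.sd_bin_labels,
        "conf_bin_edges": list(map(float, spread.conf_bin_edges)),
        "hist": spread.hist.tolist(),
        "n_excluded": spread.n_excluded,
    }
    Path(json_path).write_text(json.dumps(sidecar, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# configuration and manifest
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """One-file configuration of the full pipeline (TOML on disk)."""

    seed: int = 20180209
    outdir: str = "leafagree_out"
    # design
    cultivars: tuple = ("wild_type", "mutant")
    n_replicates: int = 5
    n_timepoints: int = 13
    interval_h: float = 48.0
    resolution_variants: tuple = ("low", "high")
    include_transformed: bool = True
    # growth
    n0: int = 2
    rate_per_cultivar: Mapping[str, float] = field(
        default_factory=lambda: {"wild_type": 0.50, "mutant": 0.35}
    )
    plant_effect_sd: float = 0.05
    young_age_days: float = 2.0
    # observers
    n_experienced: int = 5
    n_non_experienced: int = 4
    # citizen pool
    pool_size: int = 60
    activity_skew: float = 1.2
    # analysis
    outlier_s: float = 200.0
    sd_threshold: float = 1.0
    conf_threshold: float = 2.0
    n_trials: int = 500
    k_values: tuple = (1, 2, 3)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cultivars"] = list(self.cultivars)
        d["resolution_variants"] = list(self.resolution_variants)
        d["k_values"] = list(self.k_values)
        d["rate_per_cultivar"] = dict(self.rate_per_cultivar)
        return d


_SECTION_KEYS = {
    "design": {"cultivars", "n_replicates", "n_timepoints", "interval_h",
               "resolution_variants", "include_transformed"},
    "growth": {"n0", "rate_per_cultivar", "plant_effect_sd", "young_age_days"},
    "observers": {"n_experienced", "n_non_experienced"},
    "citizen": {"pool_size", "activity_skew"},
    "analysis": {"outlier_s", "sd_threshold", "conf_threshold", "n_trials",
                 "k_values"},
}


def load_config(path) -> PipelineConfig:
    """Load a TOML config; unknown keys raise :class:`ConfigurationError`."""
    data = tomllib.loads(Path(path).read_text(encoding="utf-8"))
    kwargs = {}
    for key, value in data.items():
        if key in ("seed", "outdir"):
            kwargs[key] = value
        elif key in _SECTION_KEYS:
            unknown = set(value) - _SECTION_KEYS[key]
            if unknown:
                raise ConfigurationError(
                    f"unknown keys {sorted(unknown)} in section [{key}]"
                )
            kwargs.update(value)
        else:
            raise ConfigurationError(f"unknown config section or key {key!r}")
    if "seed" not in kwargs:
        raise ConfigurationError("config must set an explicit seed")
    for tuple_key in ("cultivars", "resolution_variants", "k_values"):
        if tuple_key in kwargs:
            kwargs[tuple_key] = tuple(kwargs[tuple_key])
    return PipelineConfig(**kwargs)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def write_manifest(outdir, config: PipelineConfig, extra: Optional[dict] = None):
    """Record everything needed to reproduce a run bit-for-bit."""
    import statsmodels

    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "config_sha256": config_hash(config),
        "seed": config.seed,
        "versions": {
            "leafagree": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return path
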