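"""CSV/JSON input-output and the end-to-end analysis pipeline.

The pipeline mirrors the workflow for auditing a possibly non-linear
predictor: estimate the raw-scale AUROC in both orientations, inspect the
ROC shape and its diagonal crossings, re-estimate after each candidate
transform (typically squared-distance centering at the mean and at the
median), and test each transform against the raw predictor with a paired
comparison.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .inference import auroc_estimate, compare_paired_aurocs
from .roc_core import ROCCurve, empirical_roc
from .sample import BinaryOutcomeSample, Direction
from .shape_diagnostics import DEFAULT_TOLERANCE, classify_shape
from .simulate import preset_model, simulate_dataset
from .transforms import TransformSpec, apply_transform, center_from_sample

__all__ = [
    "TransformRequest",
    "AnalysisConfig",
    "read_sample_csv",
    "write_sample_csv",
    "write_roc_csv",
    "write_lr_table_csv",
    "write_json_atomic",
    "run_analysis",
    "validate_report",
]

logger = logging.getLogger("rocshape")

_TRUE_LABELS = {"1", "true"}
_FALSE_LABELS = {"0", "false"}


def read_sample_csv(
    path: str | Path, value_col: str = "value", label_col: str = "label"
) -> BinaryOutcomeSample:
    """Load a sample from a headered CSV file.

    Labels are accepted as 0/1 integers or case-insensitive "true"/"false".
    Rows with missing or unparseable entries are dropped; the drop count is
    logged at WARNING level.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except Exception as exc:  # malformed CSV
        raise InputError(f"could not parse CSV {path}: {exc}") from exc
    for col in (value_col, label_col):
        if col not in df.columns:
            raise InputError(
                f"column {col!r} not found in {path}; available: {list(df.columns)}"
            )
    values = pd.to_numeric(df[value_col], errors="coerce")
    raw_labels = df[label_col].astype(str).str.strip().str.lower()
    labels = pd.Series(np.nan, index=df.index, dtype=float)
    labels[raw_labels.isin(_TRUE_LABELS)] = 1.0
    labels[raw_labels.isin(_FALSE_LABELS)] = 0.0
    ok = values.notna() & np.isfinite(values.fillna(np.nan)) & labels.notna()
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("dropped %d unusable row(s) from %s", dropped, path)
    if ok.sum() == 0:
        raise InputError(f"no usable rows in {path}")
    return BinaryOutcomeSample(
        values[ok].to_numpy(dtype=float), labels[ok].to_numpy(dtype=int)
    )


def write_sample_csv(
    sample: BinaryOutcomeSample,
    path: str | Path,
    value_col: str = "value",
    label_col: str = "label",
    extra_columns: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a sample (12 significant digits: lossless round-trip)."""
    cols = {value_col: sample.values, label_col: sample.labels.astype(int)}
    if extra_columns:
        cols.update(extra_columns)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def write_roc_csv(curve: ROCCurve, path: str | Path) -> None:
    """ROC points as threshold,fpr,tpr (infinite sentinel spelled "inf")."""
    pd.DataFrame(
        {"threshold": curve.thresholds, "fpr": curve.fpr, "tpr": curve.tpr}
    ).to_csv(path, index=False, float_format="%.12g")


def write_lr_table_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Likelihood-ratio table; NaN cells are left empty, inf spelled "inf"."""
    table.to_csv(path, index=False, float_format="%.12g")


def _jsonify(obj):
    """Recursively convert to JSON-safe values; NaN -> None, +/-inf -> strings."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, Direction):
        return obj.value
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        if math.isnan(x):
            return None
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
        return x
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_json_atomic(report: dict, path: str | Path) -> None:
    """Write JSON via a temp file + rename: no partial output on failure."""
    path = Path(path)
    payload = json.dumps(_jsonify(report), indent=2)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(payload)
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


@dataclass(frozen=True)
class TransformRequest:
    """A transform to analyse, with a lazily-resolved center.

    ``center_spec`` may be "mean", "median", or a numeric literal; it is
    resolved against the loaded sample.  ``direction`` defaults to
    higher-predicts-event for the distance-like kinds (center_square, fold,
    square) since larger distance from the nadir means larger risk.
    """

    kind: str
    center_spec: str | float | None = None
    direction: Direction = Direction.HIGHER_PREDICTS_EVENT

    @classmethod
    def parse(cls, text: str) -> "TransformRequest":
        """Parse "kind" or "kind:center" (center = mean | median | number)."""
        kind, _, center = text.partition(":")
        kind = kind.strip()
        center = center.strip()
        if not center:
            return cls(kind=kind)
        if center in ("mean", "median"):
            return cls(kind=kind, center_spec=center)
        try:
            return cls(kind=kind, center_spec=float(center))
        except ValueError:
            raise InputError(
                f"bad center {center!r} in transform {text!r}: "
                "expected 'mean', 'median' or a number"
            )

    def resolve(self, values: np.ndarray) -> TransformSpec:
        if isinstance(self.center_spec, str):
            center = center_from_sample(values, self.center_spec)
        else:
            center = self.center_spec
        return TransformSpec(kind=self.kind, center=center)

    def name(self) -> str:
        if self.center_spec is None:
            return self.kind
        return f"{self.kind}:{self.center_spec}"


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything :func:`run_analysis` needs; one top-level seed."""

    input_path: str | None = None
    preset: str | None = None
    n: int = 5000
    value_col: str = "value"
    label_col: str = "label"
    direction: Direction = Direction.HIGHER_PREDICTS_EVENT
    transforms: tuple[TransformRequest, ...] = ()
    alpha: float = 0.05
    tolerance: float = DEFAULT_TOLERANCE
    method: str = "hanley_mcneil"
    seed: int = 0
    report_path: str | None = None
    roc_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.preset is None):
            raise ConfigurationError(
                "exactly one of input_path and preset must be given"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be positive")


def _load(config: AnalysisConfig) -> BinaryOutcomeSample:
    if config.preset is not None:
        return simulate_dataset(preset_model(config.preset), config.n, config.seed)
    return read_sample_csv(config.input_path, config.value_col, config.label_col)


def _analysis_entry(
    name: str,
    values: np.ndarray,
    sample: BinaryOutcomeSample,
    direction: Direction,
    alpha: float,
    tolerance: float,
) -> tuple[dict, ROCCurve]:
    s = sample.with_values(values)
    est_fwd = auroc_estimate(s, direction, alpha)
    flipped = (
        Direction.LOWER_PREDICTS_EVENT
        if direction is Direction.HIGHER_PREDICTS_EVENT
        else Direction.HIGHER_PREDICTS_EVENT
    )
    est_rev = auroc_estimate(s, flipped, alpha)
    curve = empirical_roc(s, direction)
    shape = classify_shape(curve, tolerance)
    entry = {
        "name": name,
        "direction": direction.value,
        "estimate": est_fwd,
        "estimate_flipped": est_rev,
        "shape": shape,
    }
    return entry, curve


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full raw-vs-transformed ROC audit and return the report.

    The report contains, for the identity scoring and each requested
    transform: AUROC estimates in both orientations, the shape report with
    diagonal crossings, and (per transform) the paired comparison against
    the identity scoring.  Deterministic given (input, config, seed).
    If ``config.report_path`` is set the report is also written atomically;
    if ``config.roc_dir`` is set, one ROC-point CSV per scoring is written.
    """
    sample = _load(config)
    sample.require_both_classes()

    analyses: list[dict] = []
    comparisons: list[dict] = []
    curves: dict[str, ROCCurve] = {}

    entry, curve = _analysis_entry(
        "identity", sample.values, sample, config.direction,
        config.alpha, config.tolerance,
    )
    analyses.append(entry)
    curves["identity"] = curve

    for i, req in enumerate(config.transforms):
        spec = req.resolve(sample.values)
        tvalues = apply_transform(sample.values, spec)
        name = req.name()
        entry, curve = _analysis_entry(
            name, tvalues, sample, req.direction, config.alpha, config.tolerance
        )
        entry["resolved_center"] = spec.center
        analyses.append(entry)
        curves[name] = curve
        comparison = compare_paired_aurocs(
            sample.values,
            tvalues,
            sample.labels,
            direction_a=config.direction,
            direction_b=req.direction,
            method=config.method,
            alpha=config.alpha,
            seed=config.seed + 1 + i,
        )
        comparisons.append({"a": "identity", "b": name, "result": comparison})

    report = {
        "input": config.input_path or f"preset:{config.preset}",
        "n": len(sample),
        "n_pos": sample.n_pos,
        "n_neg": sample.n_neg,
        "alpha": config.alpha,
        "tolerance": config.tolerance,
        "method": config.method,
        "seed": config.seed,
        "analyses": analyses,
        "comparisons": comparisons,
    }
    report = _jsonify(report)
    validate_report(report)

    if config.roc_dir is not None:
        out = Path(config.roc_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, c in curves.items():
            safe = name.replace(":", "_").replace("/", "_")
            write_roc_csv(c, out / f"roc_{safe}.csv")
    if config.report_path is not None:
        write_json_atomic(report, config.report_path)
    return report


_ESTIMATE_KEYS = {"auroc", "se", "ci_low", "ci_high", "n_pos", "n_neg", "alpha"}
_COMPARISON_KEYS = {
    "auroc_a", "auroc_b", "diff", "se_diff", "ci_low", "ci_high", "z", "p", "r",
    "method",
}
_SHAPE_KEYS = {
    "label", "crossings", "max_excursion_above", "max_excursion_below", "tolerance",
}


def validate_report(report: dict) -> None:
    """Structural validation of a JSON-ready analysis report.

    Checks the key layout produced by :func:`run_analysis` (a lightweight,
    dependency-free schema check); raises :class:`InputError` on violation.
    """
    required = {"input", "n", "n_pos", "n_neg", "analyses", "comparisons"}
    missing = required - set(report)
    if missing:
        raise InputError(f"report missing keys: {sorted(missing)}")
    if not report["analyses"]:
        raise InputError("report must contain at least the identity analysis")
    if report["analyses"][0]["name"] != "identity":
        raise InputError("first analysis must be the identity scoring")
    for entry in report["analyses"]:
        for key in ("name", "direction", "estimate", "estimate_flipped", "shape"):
            if key not in entry:
                raise InputError(f"analysis entry missing {key!r}")
        if not _ESTIMATE_KEYS <= set(entry["estimate"]):
            raise InputError("estimate entry missing fields")
        if not _SHAPE_KEYS <= set(entry["shape"]):
            raise InputError("shape entry missing fields")
    for comp in report["comparisons"]:
        if not {"a", "b", "result"} <= set(comp):
            raise InputError("comparison entry missing fields")
        if not _COMPARISON_KEYS <= set(comp["result"]):
            raise InputError("comparison result missing fields")
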