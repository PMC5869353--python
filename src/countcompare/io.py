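"""Dataset and configuration I/O.

Datasets travel as delimited tables with a header row (default
comma-separated): one non-negative integer response column and one
explanatory column, either categorical labels or reals.  Run
configuration is a flat YAML mapping mirroring :class:`RunConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .datasets import CountDataset
from .transforms import TransformSpec

__all__ = ["RunConfig", "read_dataset", "read_config"]


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with the conventions spelled out.

    The back-transformation convention in force (log base, offsets, sign
    rule for squared estimates) is derived from these fields and logged
    per run, since convention ambiguity is a reproducibility hazard.
    """

    alpha: float = 0.05
    sqrt_offset: float = 0.0
    log_offset: float = 1.0
    log_base: Literal["e", "10"] = "e"
    family_threshold: float = 1.5
    smoothing_span: float = 0.75
    fan_margin: float = 0.1
    seed: int = 0
    output_dir: str = "."
    delimiter: str = ","

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("family_threshold", "smoothing_span", "fan_margin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def sqrt_spec(self) -> TransformSpec:
        return TransformSpec("sqrt", offset=self.sqrt_offset)

    @property
    def log_spec(self) -> TransformSpec:
        return TransformSpec("log", offset=self.log_offset, log_base=self.log_base)

    def describe_conventions(self) -> str:
        return (
            f"sqrt route: OLS on sqrt(y+{self.sqrt_offset:g}), back-transform by signed square; "
            f"log route: OLS on {self.log_spec.label}, back-transform base^m - 1 (base {self.log_base}); "
            f"glm route: log link, family by Pearson dispersion > {self.family_threshold:g}, "
            f"means exp(b0+b), regression slope exp(b1) - 1"
        )


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def read_dataset(
    path: str | Path,
    response_column: str = "y",
    predictor_column: str = "x",
    predictor_kind: Literal["oneway", "regression"] = "oneway",
    delimiter: str = ",",
) -> CountDataset:
    """Read a delimited count table into a :class:`CountDataset`.

    The response column must parse as non-negative integers; offending
    rows are reported by number (1-based, excluding the header).
    """
    frame = pd.read_csv(path, sep=delimiter)
    for col in (response_column, predictor_column):
        if col not in frame.columns:
            raise ValueError(f"column {col!r} not found in {path} (has {list(frame.columns)})")
    missing = frame[[response_column, predictor_column]].isna().any(axis=1)
    if missing.any():
        rows = (np.flatnonzero(missing) + 1).tolist()
        raise ValueError(f"missing values in rows {rows} of {path}")
    y_raw = frame[response_column].to_numpy()
    y_float = np.asarray(y_raw, dtype=float)
    bad = (y_float != np.round(y_float)) | (y_float < 0)
    if bad.any():
        rows = (np.flatnonzero(bad) + 1).tolist()
        raise ValueError(
            f"response column {response_column!r} must be non-negative integers; "
            f"offending rows: {rows}"
        )
    return CountDataset(
        y=y_float.astype(np.int64),
        x=frame[predictor_column].to_numpy(),
        kind=predictor_kind,
        id=Path(path).stem,
    )
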