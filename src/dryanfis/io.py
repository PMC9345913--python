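"""CSV round-tripping, run configuration, and descriptive statistics.

The long-format drying table has one row per (sample, pretreatment,
temperature, time) with either a measured weight or a moisture ratio.
``describe`` emits the spreadsheet-style 13-statistic summary (mean through
count) commonly reported for drying datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidConfigError, SchemaError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample_id", "pretreatment_min", "temperature_C", "time_min")
FLOAT_FORMAT = "%.10g"

DESCRIBE_ROWS = (
    "Mean", "Standard error", "Median", "Mode", "Standard deviation",
    "Sample variance", "Kurtosis", "Skewness", "Range", "Minimum",
    "Maximum", "Sum", "Count",
)


def read_drying_csv(path) -> pd.DataFrame:
    """Read and validate a long-format drying table.

    Requires ``sample_id, pretreatment_min, temperature_C, time_min`` plus
    either ``moisture_ratio`` or ``weight_g``.  Weights are converted to
    moisture ratio per cell as (w - w_end) / (w0 - w_end), taking the final
    constant weight as the equilibrium weight (logged).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if "moisture_ratio" not in df.columns:
        if "weight_g" not in df.columns:
            raise SchemaError(f"{path}: needs a moisture_ratio or weight_g column")
        logger.info("converting weights to moisture ratio "
                    "(final weight per cell taken as equilibrium weight)")
        def _to_mr(grp: pd.DataFrame) -> pd.Series:
            grp = grp.sort_values("time_min")
            w = grp["weight_g"].to_numpy(dtype=float)
            if w[0] == w[-1]:
                raise SchemaError(
                    f"cell {grp.name}: no weight loss, cannot form moisture ratio")
            return pd.Series((w - w[-1]) / (w[0] - w[-1]), index=grp.index)
        parts = [_to_mr(grp) for _, grp in
                 df.groupby(["pretreatment_min", "temperature_C"])]
        df["moisture_ratio"] = pd.concat(parts).sort_index()
    return df


def write_csv(df: pd.DataFrame, path) -> None:
    """Write a table with the package's documented float formatting
    (10 significant digits), so write -> read round-trips bit-identically."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def describe(df: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Spreadsheet-style descriptive statistics, one column per variable.

    Skewness and kurtosis use the bias-corrected sample formulas; kurtosis
    is excess (normal = 0).  Both are NA for constant columns, where they
    are undefined.
    """
    if columns is None:
        columns = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    if not columns:
        raise SchemaError("describe needs at least one numeric column")
    out = {}
    for col in columns:
        x = df[col].dropna().astype(float)
        n = len(x)
        if n == 0:
            out[col] = pd.Series([np.nan] * len(DESCRIBE_ROWS), index=DESCRIBE_ROWS)
            continue
        sd = x.std(ddof=1) if n > 1 else 0.0
        constant = sd == 0
        mode = x.mode()
        out[col] = pd.Series({
            "Mean": x.mean(),
            "Standard error": sd / np.sqrt(n) if n > 1 else np.nan,
            "Median": x.median(),
            "Mode": mode.iloc[0] if not mode.empty else np.nan,
            "Standard deviation": sd,
            "Sample variance": sd**2,
            "Kurtosis": np.nan if constant or n < 4 else x.kurt(),
            "Skewness": np.nan if constant or n < 3 else x.skew(),
            "Range": x.max() - x.min(),
            "Minimum": x.min(),
            "Maximum": x.max(),
            "Sum": x.sum(),
            "Count": float(n),
        })
    return pd.DataFrame(out).loc[list(DESCRIBE_ROWS)]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class KineticsOptions:
    radius_m: float = 0.02
    mode: str = "table"
    min_mr: float = 0.01
    me: float = 0.0


@dataclass
class RunConfig:
    """Resolved run options; unknown keys in a config file are rejected."""

    seed: int = 0
    verbosity: int = 0
    input: str | None = None
    output: str | None = None
    kinetics: KineticsOptions = field(default_factory=KineticsOptions)
    train: dict = field(default_factory=dict)      # TrainConfig overrides
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InvalidConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        kin = raw.pop("kinetics", {})
        kin_known = {f.name for f in fields(KineticsOptions)}
        if not set(kin) <= kin_known:
            raise InvalidConfigError(
                f"{path}: unknown kinetics keys {sorted(set(kin) - kin_known)}")
        cfg = cls(**{**raw, "kinetics": KineticsOptions(**kin)})
        logger.info("resolved config: %s", cfg)
        return cfg
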