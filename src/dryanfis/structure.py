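"""Structure search over membership-function family and count.

The predictive quality of a grid-partition ANFIS hinges on two structural
choices: the membership-function family and the number of functions per
input.  This module trains every combination of the four families (trimf,
pimf, gbellmf, gaussmf) with 2, 3 or 5 functions per input — 12 structures
for the 3-factor drying problem (8, 27 or 125 rules) — on identical data
partitions, and ranks them by test-partition R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anfis import ANFISModel, TrainConfig, train
from .errors import InvalidInputError, SchemaError

logger = logging.getLogger(__name__)

DEFAULT_FAMILIES = ("trimf", "gbellmf", "gaussmf", "pimf")
DEFAULT_N_MF = (2, 3, 5)
#: The drying factors, in the column order models are trained with.
DEFAULT_FEATURES = ("time_min", "temperature_C", "pretreatment_min")
DEFAULT_TARGET = "moisture_ratio"


@dataclass(frozen=True)
class StructureSpec:
    """One candidate network structure."""

    family: str
    n_mf: int
    n_inputs: int = 3

    @property
    def n_rules(self) -> int:
        return self.n_mf**self.n_inputs


@dataclass
class GridRow:
    """Outcome of training one structure (or the failure that prevented it)."""

    spec: StructureSpec
    best_epoch: int | None = None
    test_r2: float | None = None
    test_rmse: float | None = None
    error: str | None = None


@dataclass
class GridSearchResult:
    """All 12 structure outcomes plus the selected best structure."""

    rows: list[GridRow]
    best: StructureSpec
    best_result: object = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            dict(family=r.spec.family, n_mf=r.spec.n_mf,
                 best_epoch=r.best_epoch, test_r2=r.test_r2,
                 test_rmse=r.test_rmse, n_rules=r.spec.n_rules,
                 error=r.error)
            for r in self.rows
        ])


def _check_dataset(df: pd.DataFrame, features, target) -> None:
    missing = [c for c in (*features, target) if c not in df.columns]
    if missing:
        raise SchemaError(f"dataset missing columns: {missing}")


def run_grid(df: pd.DataFrame, train_config: TrainConfig | None = None,
             families=DEFAULT_FAMILIES, n_mf_values=DEFAULT_N_MF,
             features=DEFAULT_FEATURES, target=DEFAULT_TARGET
             ) -> GridSearchResult:
    """Train every family x count structure on identical data partitions.

    All cells share the same split seed, so performance differences reflect
    structure only.  A training failure in one cell is recorded on its row
    and the grid continues.  The best structure maximizes test R^2; ties
    break toward fewer rules, then the lower best epoch.
    """
    train_config = train_config or TrainConfig(max_epochs=500)
    _check_dataset(df, features, target)
    X = df.loc[:, list(features)].to_numpy(dtype=float)
    y = df[target].to_numpy(dtype=float)

    rows, results = [], {}
    for family in families:
        for n_mf in n_mf_values:
            spec = StructureSpec(family=family, n_mf=n_mf, n_inputs=len(features))
            try:
                model = ANFISModel.from_data(X, list(features), n_mf, family,
                                             seed=train_config.seed)
                res = train(model, X, y, train_config)
                rows.append(GridRow(spec=spec, best_epoch=res.best_epoch,
                                    test_r2=res.test_r2, test_rmse=res.test_rmse))
                results[spec] = res
            except Exception as exc:  # noqa: BLE001 - grid must survive one bad cell
                logger.warning("structure %s/%d failed: %s", family, n_mf, exc)
                rows.append(GridRow(spec=spec, error=str(exc)))

    scored = [r for r in rows if r.error is None]
    if not scored:
        raise InvalidInputError("every structure in the grid failed to train")
    best_row = min(scored, key=lambda r: (-r.test_r2, r.spec.n_rules, r.best_epoch))
    result = GridSearchResult(rows=rows, best=best_row.spec,
                              best_result=results[best_row.spec])
    logger.info("structure grid (family, n_mf, best_epoch, test R2, test RMSE):")
    for r in rows:
        logger.info("  %-8s %d  %s  %s  %s", r.spec.family, r.spec.n_mf,
                    r.best_epoch, r.test_r2, r.test_rmse)
    logger.info("best structure: %s with %d mfs (test R2 %.4f)",
                best_row.spec.family, best_row.spec.n_mf, best_row.test_r2)
    return result
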