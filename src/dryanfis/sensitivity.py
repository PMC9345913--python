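"""Factor sensitivity by subset retraining.

A drying factor (or pair of factors) is judged by how well an ANFIS that
sees only that subset can predict the moisture ratio: the lower the
prediction RMSE of the subset-only model, the more sensitive the moisture
ratio is to that subset.  The three singletons and the three pairs of
{drying time, drying temperature, pretreatment} are each retrained with
the winning structure's membership family and count (the rule base shrinks
to m^|subset|), under the same split seed and training configuration, and
ranked separately by arity.

The reported ranking uses the full-dataset prediction RMSE of each
best-epoch model; the per-partition RMSEs are emitted alongside.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anfis import ANFISModel, TrainConfig, rmse, train
from .errors import SchemaError
from .structure import DEFAULT_FEATURES, DEFAULT_TARGET, StructureSpec, _check_dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FactorSubset:
    """A non-empty subset of the drying factors."""

    factors: tuple

    def __post_init__(self) -> None:
        if not self.factors:
            raise SchemaError("factor subset must be non-empty")

    @property
    def label(self) -> str:
        return "+".join(self.factors)


@dataclass
class SubsetResult:
    subset: FactorSubset
    rmse_full: float | None = None
    rmse_train: float | None = None
    rmse_check: float | None = None
    rmse_test: float | None = None
    best_epoch: int | None = None
    degenerate: bool = False
    error: str | None = None


@dataclass
class SensitivityReport:
    """RMSE per factor subset and the induced sensitivity rankings.

    ``singleton_ranking`` and ``pair_ranking`` list subsets in ascending
    full-dataset RMSE (most sensitive first); degenerate subsets are
    excluded from the rankings.
    """

    results: list[SubsetResult]
    singleton_ranking: list[FactorSubset]
    pair_ranking: list[FactorSubset]

    def to_frame(self) -> pd.DataFrame:
        ranks = {}
        for ranking in (self.singleton_ranking, self.pair_ranking):
            for pos, sub in enumerate(ranking, start=1):
                ranks[sub] = pos
        return pd.DataFrame([
            dict(subset=r.subset.label, n_factors=len(r.subset.factors),
                 rmse_full=r.rmse_full, rmse_train=r.rmse_train,
                 rmse_check=r.rmse_check, rmse_test=r.rmse_test,
                 rank_within_arity=ranks.get(r.subset))
            for r in self.results
        ])


def run_sensitivity(df: pd.DataFrame, structure: StructureSpec,
                    train_config: TrainConfig | None = None,
                    features=DEFAULT_FEATURES, target=DEFAULT_TARGET
                    ) -> SensitivityReport:
    """Retrain the winning structure on every singleton and pair of factors.

    All subset models share the same split seed, membership family and
    count; a constant input column makes a subset degenerate — it is
    flagged and excluded from the ranking rather than failing the run.
    """
    train_config = train_config or TrainConfig()
    _check_dataset(df, features, target)
    y = df[target].to_numpy(dtype=float)

    subsets = [FactorSubset(s) for r in (1, 2)
               for s in itertools.combinations(features, r)]
    results = []
    for subset in subsets:
        X = df.loc[:, list(subset.factors)].to_numpy(dtype=float)
        try:
            model = ANFISModel.from_data(X, list(subset.factors),
                                         structure.n_mf, structure.family,
                                         seed=train_config.seed)
            res = train(model, X, y, train_config)
            best = res.model_at_best
            idx = res.split_indices
            results.append(SubsetResult(
                subset=subset,
                rmse_full=rmse(y, best.predict(X)),
                rmse_train=rmse(y[idx["train"]], best.predict(X[idx["train"]])),
                rmse_check=rmse(y[idx["check"]], best.predict(X[idx["check"]])),
                rmse_test=res.test_rmse,
                best_epoch=res.best_epoch,
            ))
        except Exception as exc:  # noqa: BLE001 - flag, keep evaluating others
            logger.warning("subset %s degenerate/failed: %s", subset.label, exc)
            results.append(SubsetResult(subset=subset, degenerate=True,
                                        error=str(exc)))

    def ranking(arity: int) -> list[FactorSubset]:
        ok = [r for r in results
              if len(r.subset.factors) == arity and not r.degenerate]
        return [r.subset for r in sorted(ok, key=lambda r: r.rmse_full)]

    report = SensitivityReport(results=results,
                               singleton_ranking=ranking(1),
                               pair_ranking=ranking(2))
    logger.info("sensitivity (full-dataset RMSE, ascending = most sensitive):")
    for r in sorted((r for r in results if not r.degenerate),
                    key=lambda r: (len(r.subset.factors), r.rmse_full)):
        logger.info("  %-45s %.5f", r.subset.label, r.rmse_full)
    return report
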