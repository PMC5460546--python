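"""Cross-validated predictive ability for the repeatability model.

The scheme partitions phenotype *records* (not plants) into k folds of
approximately equal size; each fold is predicted from a model trained on
the remaining folds, the whole procedure is repeated with fresh random
partitions, and every fold yields one replicate of (h2, R, predictive
ability). With the defaults (k = 5, 100 repetitions) this gives 500
replicates per trait and cross. Predictive ability is the Pearson
correlation between observed and predicted phenotypes in the validation
set.

A published per-cross results table ships as a fixture
(``data/table2.csv``) so that trait-level averages can be recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .gblup import (
    MixedModelFit,
    ReMLError,
    build_design,
    fit_repeatability,
    gebv_accuracy,
    gibbs_fit,
    predict_records,
    reml_fit,
)
from .kinship import KinshipMatrix

logger = logging.getLogger(__name__)


def partition_records(
    n_records: int,
    k: int = 5,
    seed: int = 0,
    groups: Optional[Sequence] = None,
) -> np.ndarray:
    """Random fold labels in {0, ..., k-1}; fold sizes differ by <= 1.

    With ``groups`` given (e.g. plant ids), whole groups are assigned to
    folds instead of single records, so all records of a plant share a
    fold.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n_records:
        raise ValueError(f"cannot split {n_records} records into {k} folds")
    rng = np.random.default_rng(seed)
    labels = np.empty(n_records, dtype=int)
    if groups is None:
        order = rng.permutation(n_records)
        labels[order] = np.arange(n_records) % k
    else:
        groups = np.asarray(groups, dtype=object)
        uniq = list(dict.fromkeys(groups))
        if k > len(uniq):
            raise ValueError(
                f"cannot split {len(uniq)} groups into {k} folds"
            )
        order = rng.permutation(len(uniq))
        fold_of = {uniq[g]: f % k for f, g in enumerate(order)}
        labels = np.array([fold_of[g] for g in groups], dtype=int)
    return labels


@dataclass
class CVReplicate:
    """One training/validation split with its estimates."""

    repetition: int
    fold: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    h2: float
    R: float
    pa: float
    solver: str


@dataclass
class CVSummary:
    """Table-row summary over replicates, with breeding-value accuracy
    ``mean(PA) / sqrt(mean(h2))``."""

    trait: str
    cross: str
    n_replicates: int
    n_failed: int
    mean_h2: float
    sd_h2: float
    mean_R: float
    sd_R: float
    mean_pa: float
    sd_pa: float
    gebv_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) < 1e-12 or np.std(y) < 1e-12:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def run_cv(
    records: pd.DataFrame,
    kinship: KinshipMatrix,
    k: int = 5,
    repetitions: int = 100,
    solver: str = "auto",
    seed: int = 0,
    group_by_plant: bool = False,
    pooled_pa: bool = False,
    trait: Optional[str] = None,
    reml_kwargs: Optional[dict] = None,
    gibbs_kwargs: Optional[dict] = None,
) -> Tuple[List[CVReplicate], int]:
    """k-fold cross-validation repeated ``repetitions`` times.

    Returns one replicate per fold (``k * repetitions`` in total) and the
    number of dropped replicates whose training fit failed under both
    solvers. ``pooled_pa=True`` instead pools validation predictions
    within a repetition and returns one replicate per repetition
    (fold = -1).
    """
    df = records
    if trait is not None:
        df = df[df["trait"] == trait]
    df = df.reset_index(drop=True)
    n = len(df)
    replicates: List[CVReplicate] = []
    n_failed = 0
    for rep in range(repetitions):
        rep_seed = int(
            np.random.default_rng(
                np.random.SeedSequence([seed, rep])
            ).integers(2**31)
        )
        folds = partition_records(
            n, k=k, seed=rep_seed,
            groups=df["plant"].to_numpy() if group_by_plant else None,
        )
        pooled_obs: List[np.ndarray] = []
        pooled_pred: List[np.ndarray] = []
        rep_h2: List[float] = []
        rep_R: List[float] = []
        rep_solver = ""
        for fold in range(k):
            val = np.flatnonzero(folds == fold)
            train = np.flatnonzero(folds != fold)
            train_df = df.iloc[train]
            try:
                spec = build_design(train_df, kinship)
                fit = fit_repeatability(
                    spec,
                    solver=solver,
                    seed=rep_seed + fold,
                    reml_kwargs=reml_kwargs,
                    gibbs_kwargs=gibbs_kwargs,
                )
            except (ReMLError, RuntimeError, ValueError) as exc:
                logger.warning(
                    "repetition %d fold %d dropped: %s", rep + 1, fold + 1, exc
                )
                n_failed += 1
                continue
            val_df = df.iloc[val]
            targets = list(zip(val_df["plant"], val_df["year"]))
            pred = predict_records(fit, targets)
            obs = val_df["value"].to_numpy(dtype=float)
            if pooled_pa:
                pooled_obs.append(obs)
                pooled_pred.append(pred)
                rep_h2.append(fit.params.h2)
                rep_R.append(fit.params.R)
                rep_solver = fit.solver
            else:
                replicates.append(
                    CVReplicate(
                        repetition=rep + 1,
                        fold=fold + 1,
                        train_idx=train,
                        val_idx=val,
                        h2=fit.params.h2,
                        R=fit.params.R,
                        pa=_pearson(pred, obs),
                        solver=fit.solver,
                    )
                )
        if pooled_pa and pooled_obs:
            replicates.append(
                CVReplicate(
                    repetition=rep + 1,
                    fold=-1,
                    train_idx=np.arange(0),
                    val_idx=np.arange(0),
                    h2=float(np.mean(rep_h2)),
                    R=float(np.mean(rep_R)),
                    pa=_pearson(
                        np.concatenate(pooled_pred), np.concatenate(pooled_obs)
                    ),
                    solver=rep_solver,
                )
            )
    if not replicates:
        raise RuntimeError("all cross-validation replicates failed")
    return replicates, n_failed


def replicates_frame(replicates: Sequence[CVReplicate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "repetition": r.repetition,
                "fold": r.fold,
                "h2": r.h2,
                "R": r.R,
                "pa": r.pa,
                "solver": r.solver,
            }
            for r in replicates
        ]
    )


def summarize_cv(
    replicates: Sequence[CVReplicate],
    trait: str = "",
    cross: str = "",
    n_failed: int = 0,
) -> CVSummary:
    """Means and standard deviations over successful replicates."""
    if len(replicates) < 2:
        raise ValueError("need at least two successful replicates")
    h2 = np.array([r.h2 for r in replicates])
    R = np.array([r.R for r in replicates])
    pa = np.array([r.pa for r in replicates])
    mean_h2 = float(h2.mean())
    mean_pa = float(pa.mean())
    acc = (
        gebv_accuracy(mean_pa, mean_h2) if mean_h2 > 0 else float("nan")
    )
    return CVSummary(
        trait=trait,
        cross=cross,
        n_replicates=len(replicates),
        n_failed=n_failed,
        mean_h2=mean_h2,
        sd_h2=float(h2.std(ddof=1)),
        mean_R=float(R.mean()),
        sd_R=float(R.std(ddof=1)),
        mean_pa=mean_pa,
        sd_pa=float(pa.std(ddof=1)),
        gebv_accuracy=acc,
    )


# ---------------------------------------------------------------------------
# Published results fixture
# ---------------------------------------------------------------------------

_METRIC_COLUMNS = {
    "h2": "Avg_h2",
    "R": "Avg_R",
    "PA": "Avg_PA",
    "sd_h2": "Sd_h2",
    "sd_R": "Sd_R",
    "sd_PA": "Sd_PA",
}


def load_published_table() -> pd.DataFrame:
    """Per-cross published averages of h2, R and PA (packaged fixture)."""
    with resources.files("repeatgs.data").joinpath("table2.csv").open() as fh:
        return pd.read_csv(fh)


def average_published_table(
    trait: str, metric: str, table: Optional[pd.DataFrame] = None
) -> float:
    """Unweighted mean over crosses of a published per-cross metric,
    rounded to two decimals."""
    if table is None:
        table = load_published_table()
    if metric not in _METRIC_COLUMNS:
        raise KeyError(
            f"unknown metric {metric!r}; choose from {sorted(_METRIC_COLUMNS)}"
        )
    rows = table[table["Trait"] == trait]
    if len(rows) == 0:
        raise KeyError(f"unknown trait {trait!r}")
    return round(float(rows[_METRIC_COLUMNS[metric]].mean()), 2)
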