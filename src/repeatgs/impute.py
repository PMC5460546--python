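"""Imputation benchmark: pluggable imputers and the masking experiment.

The benchmark is imputer-agnostic: any callable satisfying the
:class:`Imputer` contract (complete output, observed entries untouched)
can be scored. Two reference imputers ship with the package — a per-locus
mode imputer and an LD-aware k-nearest-neighbour haplotype imputer — plus
a hook for external command-line tools.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, MissingMask
from .simulate import inject_missing

logger = logging.getLogger(__name__)

#: Missing-rate grid of the standard masking experiment (1% ... 30%).
DEFAULT_RATES: Tuple[float, ...] = (
    0.01, 0.025, 0.05, 0.075, 0.10, 0.125, 0.15,
    0.175, 0.20, 0.225, 0.25, 0.275, 0.30,
)


class Imputer(ABC):
    """Fill every missing entry of a genotype matrix.

    Implementations must leave observed entries untouched and return
    codes in {0, 1, 2}.
    """

    name: str = "imputer"

    @abstractmethod
    def impute(self, g: GenotypeMatrix) -> GenotypeMatrix:
        ...

    def __call__(self, g: GenotypeMatrix) -> GenotypeMatrix:
        out = self.impute(g)
        observed = g.codes != MISSING
        if (out.codes[observed] != g.codes[observed]).any():
            raise RuntimeError(f"{self.name}: modified observed entries")
        if (out.codes == MISSING).any():
            raise RuntimeError(f"{self.name}: left missing entries")
        return out


def _column_modes(codes: np.ndarray) -> np.ndarray:
    """Most frequent observed genotype per column, ties to the lower code."""
    counts = np.stack([(codes == c).sum(axis=0) for c in (0, 1, 2)])
    empty = counts.sum(axis=0) == 0
    if empty.any():
        raise ValueError(
            f"{int(empty.sum())} loci have no observed call; cannot impute"
        )
    return counts.argmax(axis=0).astype(np.int16)  # argmax -> lowest on ties


class ModeImputer(Imputer):
    """Baseline: replace missing calls with the per-locus modal genotype."""

    name = "mode"

    def impute(self, g: GenotypeMatrix) -> GenotypeMatrix:
        out = g.copy()
        modes = _column_modes(g.codes)
        rows, cols = np.nonzero(g.codes == MISSING)
        out.codes[rows, cols] = modes[cols]
        return out


class KnnHaplotypeImputer(Imputer):
    """LD-aware imputer: vote of the k most concordant samples.

    For each missing cell the ``window`` SNPs flanking the locus (same
    chromosome when a map is attached) define a local haplotype; the k
    samples with the highest genotype concordance over positions observed
    in both vote with their genotype at the locus. Ties fall back to the
    mode imputer's answer, as do cells with no informative neighbour.
    Deterministic; sensitive to SNP order by construction.
    """

    name = "knn"

    def __init__(self, k: int = 5, window: int = 20) -> None:
        if k < 1 or window < 1:
            raise ValueError("k and window must be positive")
        self.k = k
        self.window = window

    def _window_columns(self, g: GenotypeMatrix, j: int) -> np.ndarray:
        if g.chrom is not None:
            same = np.flatnonzero(g.chrom == g.chrom[j])
        else:
            same = np.arange(g.n_snps)
        same = same[same != j]
        order = np.argsort(np.abs(same - j), kind="stable")
        return same[order[: self.window]]

    def impute(self, g: GenotypeMatrix) -> GenotypeMatrix:
        out = g.copy()
        modes = _column_modes(g.codes)
        codes = g.codes
        n = g.n_plants
        for j in np.flatnonzero((codes == MISSING).any(axis=0)):
            targets = np.flatnonzero(codes[:, j] == MISSING)
            win = self._window_columns(g, j)
            if len(win) == 0:
                out.codes[targets, j] = modes[j]
                logger.info("knn: no window around SNP %s; mode fallback",
                            g.snp_ids[j])
                continue
            W = codes[:, win]  # n x w
            obs = W != MISSING
            T, Tobs = W[targets], obs[targets]
            # concordance counts between each target and every sample
            both = Tobs[:, None, :] & obs[None, :, :]
            agree = (T[:, None, :] == W[None, :, :]) & both
            score = agree.sum(axis=2)
            informative = both.any(axis=2) & (codes[:, j] != MISSING)[None, :]
            for t_pos, i in enumerate(targets):
                s = score[t_pos].copy()
                s[~informative[t_pos]] = -1
                s[i] = -1
                if (s < 0).all():
                    out.codes[i, j] = modes[j]
                    continue
                k = min(self.k, int((s >= 0).sum()))
                order = np.lexsort((np.arange(n), -s))  # stable: low index wins
                neighbours = order[:k]
                votes = np.bincount(codes[neighbours, j], minlength=3)
                top = votes.max()
                winners = np.flatnonzero(votes == top)
                if len(winners) == 1:
                    out.codes[i, j] = winners[0]
                else:
                    out.codes[i, j] = (
                        modes[j] if modes[j] in winners else winners[0]
                    )
        return out


class ExternalImputer(Imputer):
    """Adapter for an external command-line imputation tool.

    The command is formatted with ``{input}`` and ``{output}`` paths of
    delimited genotype matrices (see :mod:`repeatgs.io`).
    """

    name = "external"

    def __init__(self, command: str) -> None:
        self.command = command

    def impute(self, g: GenotypeMatrix) -> GenotypeMatrix:
        from .io import read_genotype_matrix, write_genotype_matrix

        with tempfile.TemporaryDirectory() as tmp:
            src = str(Path(tmp) / "input.csv")
            dst = str(Path(tmp) / "output.csv")
            write_genotype_matrix(g, src)
            cmd = self.command.format(input=src, output=dst)
            subprocess.run(cmd, shell=True, check=True)
            out = read_genotype_matrix(dst)
        out.chrom, out.pos_cm = g.chrom, g.pos_cm
        out.cross = g.cross
        return out


def imputation_accuracy(imputed: GenotypeMatrix, mask: MissingMask) -> float:
    """Exact genotype-match proportion over the masked cells."""
    if len(mask) == 0:
        raise ValueError("empty mask: imputation accuracy undefined")
    predicted = imputed.codes[mask.rows, mask.cols]
    return float((predicted == mask.values).mean())


@dataclass
class ImputationCurve:
    """Accuracy-vs-missing-rate curve from repeated random masking."""

    cross: str
    rates: np.ndarray
    accuracies: np.ndarray  # (n_rates, n_replicates)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if (np.diff(self.rates) <= 0).any():
            raise ValueError("rate grid must be strictly increasing")
        if ((self.accuracies < 0) | (self.accuracies > 1)).any():
            raise ValueError("accuracies outside [0, 1]")

    @property
    def mean(self) -> np.ndarray:
        return self.accuracies.mean(axis=1)

    @property
    def sd(self) -> np.ndarray:
        return self.accuracies.std(axis=1, ddof=1)

    def to_dataframe(self) -> pd.DataFrame:
        n_rep = self.accuracies.shape[1]
        rows = [
            (self.cross, r, rep + 1, self.accuracies[i, rep])
            for i, r in enumerate(self.rates)
            for rep in range(n_rep)
        ]
        return pd.DataFrame(
            rows, columns=["cross", "rate", "replicate", "accuracy"]
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cross": self.cross,
                "rate": self.rates,
                "mean": self.mean,
                "sd": self.sd,
            }
        )


def run_masking_experiment(
    g_complete: GenotypeMatrix,
    imputer: Imputer,
    rates: Sequence[float] = DEFAULT_RATES,
    replicates: int = 10,
    seed: int = 0,
    cross: Optional[str] = None,
) -> ImputationCurve:
    """Mask, impute and score at each rate x replicate.

    A fresh uniform random mask is drawn for every replicate; accuracy is
    the proportion of masked cells imputed to their true genotype.
    """
    if len(rates) == 0:
        raise ValueError("empty rate grid")
    if not g_complete.is_complete:
        raise ValueError(
            "masking experiment requires a complete matrix "
            "(extract a no-missing subset first)"
        )
    if cross is None:
        labels = set(g_complete.cross) if g_complete.cross is not None else set()
        cross = labels.pop() if len(labels) == 1 else "all"
    acc = np.empty((len(rates), replicates))
    for i, rate in enumerate(rates):
        for rep in range(replicates):
            sub_seed = int(
                np.random.default_rng(
                    np.random.SeedSequence([seed, 3, i, rep])
                ).integers(2**31)
            )
            masked, mask = inject_missing(g_complete, rate, seed=sub_seed)
            imputed = imputer(masked)
            acc[i, rep] = imputation_accuracy(imputed, mask)
    return ImputationCurve(cross=cross, rates=np.asarray(rates), accuracies=acc)


def impute_mode(g: GenotypeMatrix) -> GenotypeMatrix:
    """Functional shorthand for :class:`ModeImputer`."""
    return ModeImputer()(g)


def impute_knn_haplotype(
    g: GenotypeMatrix, k: int = 5, window: int = 20
) -> GenotypeMatrix:
    """Functional shorthand for :class:`KnnHaplotypeImputer`."""
    return KnnHaplotypeImputer(k=k, window=window)(g)
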