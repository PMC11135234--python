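"""Rank surveys: multi-restart NMF over a grid of candidate ranks.

For every candidate rank the survey runs ``n_run`` seeded restarts and
records (a) the best (minimum over restarts) residual sum of squares — the
RSS curve whose knee is the selected rank — and (b) the consensus matrix of
the restarts' sample clusterings together with its cophenetic correlation
coefficient, the classical comparator metric.  Per-(rank, restart) seeds are
derived deterministically from one base seed, so an entire survey is
reproducible and independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import ConsensusMatrix, connectivity, consensus, cophenetic_coefficient
from .errors import ArgumentError, RankError
from .matrix import TargetMatrix
from .nmf import AlgorithmSpec, derive_seed, fit

__all__ = ["SurveyResult", "run_survey"]


@dataclass
class SurveyResult:
    """RSS and cophenetic curves over a rank grid, plus per-rank consensus."""

    ranks: list[int]
    rss_curve: list[float]
    cophenetic_curve: list[float]  # NaN where the coefficient is undefined
    consensus_per_rank: list[ConsensusMatrix]
    n_run: int
    algorithm: AlgorithmSpec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": self.ranks,
                "rss": self.rss_curve,
                "cophenetic": self.cophenetic_curve,
                "n_run": self.n_run,
            }
        )

    def write_tsv(self, path: str | Path, consensus_dir: str | Path | None = None) -> None:
        """Write the survey table; optionally one consensus TSV per rank."""
        self.to_frame().to_csv(path, sep="\t", index=False)
        if consensus_dir is not None:
            out = Path(consensus_dir)
            out.mkdir(parents=True, exist_ok=True)
            for r, C in zip(self.ranks, self.consensus_per_rank):
                pd.DataFrame(C.values).to_csv(
                    out / f"consensus_rank{r}.tsv", sep="\t", index=False, header=False
                )

    def plot(self, path: str | Path, knee=None) -> None:
        """Rank-survey plot: RSS and cophenetic coefficient versus rank.

        ``knee`` may be a :class:`~uiknmf.knee.KneeEstimate`; its selected
        rank and knee range are then marked on the RSS panel.
        """
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
        ax1.plot(self.ranks, self.rss_curve, "o-", color="tab:blue")
        ax1.set_xlabel("factorization rank r")
        ax1.set_ylabel("RSS (best of restarts)")
        ax1.set_title("RSS rank survey")
        if knee is not None:
            ax1.axvline(knee.selected, color="tab:red", ls="--", lw=1)
            ax1.axvspan(knee.knee_start, knee.knee_end, color="tab:red", alpha=0.1)
            ax1.annotate(f"selected r={knee.selected}", (knee.selected, max(self.rss_curve)))
        ax2.plot(self.ranks, self.cophenetic_curve, "s-", color="tab:green")
        ax2.set_xlabel("factorization rank r")
        ax2.set_ylabel("cophenetic coefficient")
        ax2.set_title("Consensus stability")
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


def run_survey(
    V: TargetMatrix,
    ranks: list[int],
    n_run: int = 10,
    spec: AlgorithmSpec = AlgorithmSpec(),
) -> SurveyResult:
    """Survey a grid of candidate ranks with ``n_run`` restarts each.

    The RSS per rank is the minimum over restarts (the best fit, as a survey
    curve plots one RSS per rank); the consensus per rank averages the
    connectivity matrices of all restarts.  Restart ``k`` at rank ``r`` uses
    seed ``derive_seed(spec.seed, r, k)``.

    Ranks must be strictly increasing, at least 2 (a rank-1 consensus is
    degenerate for the cophenetic metric), and at most ``min(m, n)``.
    """
    if not isinstance(V, TargetMatrix):
        V = TargetMatrix(np.asarray(V, dtype=float))
    if len(ranks) == 0:
        raise ArgumentError("empty rank list")
    ranks = [int(r) for r in ranks]
    if any(b <= a for a, b in zip(ranks, ranks[1:])):
        raise ArgumentError(f"ranks must be strictly increasing, got {ranks}")
    m, n = V.shape
    if ranks[0] < 2:
        raise RankError(f"ranks below 2 are rejected (got {ranks[0]})")
    if ranks[-1] > min(m, n):
        raise RankError(f"rank {ranks[-1]} exceeds min(m, n) = {min(m, n)}")
    if n_run < 1:
        raise ArgumentError("n_run must be >= 1")

    rss_curve: list[float] = []
    coph_curve: list[float] = []
    consensus_per_rank: list[ConsensusMatrix] = []
    for r in ranks:
        fits = [
            fit(V, r, replace(spec, seed=derive_seed(spec.seed, r, k))) for k in range(n_run)
        ]
        rss_curve.append(min(f.rss for f in fits))
        conns = [connectivity(f.H, derived_from=f"rank{r}_run{k}") for k, f in enumerate(fits)]
        C = consensus(conns)
        consensus_per_rank.append(C)
        coph_curve.append(cophenetic_coefficient(C))
    return SurveyResult(
        ranks=ranks,
        rss_curve=rss_curve,
        cophenetic_curve=coph_curve,
        consensus_per_rank=consensus_per_rank,
        n_run=n_run,
        algorithm=spec,
    )
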