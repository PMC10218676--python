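"""Search-space reduction: correlation ranking and greedy LD pruning.

SNPs are first ranked by the magnitude of their Pearson correlation with
the trait on the *training* partition, then scanned in rank order and
kept only if their LD (r², squared Pearson correlation of the numeric
allele codes) with every already-kept SNP does not exceed the cutoff
``alpha``.  The surviving ordered index list is the candidate set over
which the genetic algorithm searches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix, Locus

log = logging.getLogger("gaselect")

__all__ = [
    "PreprocessConfig",
    "CandidateSet",
    "pearson_corr",
    "rank_by_correlation",
    "pairwise_ld",
    "greedy_ld_prune",
    "preprocess_candidates",
    "write_candidates_tsv",
    "read_candidates_tsv",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Pre-processing knobs.

    ld_cutoff
        Maximum pairwise r² allowed among retained SNPs, in (0, 1].
        Higher cutoffs admit more correlated candidates.
    use_absolute_pcc
        Rank by |PCC| (default); SNPs with strong negative effects are as
        informative as positive ones.  Signed ranking available for
        diagnostic use.
    top_k
        Optional cap on the ranked list before pruning; disabled by
        default (LD pruning alone controls the candidate count).
    """

    ld_cutoff: float = 0.4
    use_absolute_pcc: bool = True
    top_k: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.ld_cutoff <= 1.0:
            raise ValueError(f"ld_cutoff must lie in (0, 1], got {self.ld_cutoff}")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1 when set")


@dataclass
class CandidateSet:
    """Ordered SNP indices surviving pre-processing for one trait."""

    indices: np.ndarray  # positions into the GenotypeMatrix, ranking order
    scores: np.ndarray  # ranking statistic per kept SNP (same order)
    ld_cutoff: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.indices.size < 1:
            raise ValueError("candidate set must contain at least one SNP")
        if self.indices.size != np.unique(self.indices).size:
            raise ValueError("candidate indices must be unique")
        if self.scores.shape != self.indices.shape:
            raise ValueError("scores and indices must have equal length")

    def __len__(self) -> int:
        return int(self.indices.size)

    def loci(self, G: GenotypeMatrix) -> list[Locus]:
        return [G.loci[i] for i in self.indices]


def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; 0.0 if either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return 0.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def pairwise_ld(x: np.ndarray, y: np.ndarray) -> float:
    """LD between two numerically coded biallelic loci: squared Pearson r."""
    return pearson_corr(x, y) ** 2


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    """Center/scale columns so Z.T @ Z gives correlations; constant cols -> 0."""
    X = np.asarray(X, dtype=float)
    Z = X - X.mean(axis=0)
    norms = np.sqrt((Z**2).sum(axis=0))
    nonzero = norms > 0
    Z[:, nonzero] /= norms[nonzero]
    Z[:, ~nonzero] = 0.0
    return Z


def rank_by_correlation(
    G_train: GenotypeMatrix,
    y_train: np.ndarray,
    cfg: PreprocessConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Order SNP column indices by trait correlation, strongest first.

    Returns ``(indices, scores)`` sorted by non-increasing score
    (|PCC| by default); ties break toward the lower column index.
    """
    cfg = cfg or PreprocessConfig()
    y = np.asarray(y_train, dtype=float)
    if G_train.n_samples != y.size:
        raise ValueError("genotype rows and trait length differ")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    Z = _standardize_columns(G_train.codes)
    yc = y - y.mean()
    ynorm = np.sqrt(yc @ yc)
    if ynorm == 0.0:
        corr = np.zeros(G_train.n_loci)
    else:
        corr = np.clip(Z.T @ (yc / ynorm), -1.0, 1.0)
    scores = np.abs(corr) if cfg.use_absolute_pcc else corr
    order = np.lexsort((np.arange(scores.size), -scores))
    return order, scores[order]


def greedy_ld_prune(
    ranked: np.ndarray,
    G_train: GenotypeMatrix,
    alpha: float,
    scores: np.ndarray | None = None,
) -> CandidateSet:
    """Scan SNPs in ranking order, keeping each iff r² <= alpha with all kept.

    The top-ranked SNP is always kept; every dropped SNP is in LD
    (r² > alpha) with at least one kept, higher-ranked SNP.
    """
    ranked = np.asarray(ranked, dtype=int)
    if ranked.size == 0:
        raise ValueError("ranked index list must be non-empty")
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    Z = _standardize_columns(G_train.codes[:, ranked])
    kept_pos: list[int] = []
    for j in range(ranked.size):
        if kept_pos:
            r = Z[:, kept_pos].T @ Z[:, j]
            if np.max(r * r) > alpha:
                continue
        kept_pos.append(j)
    kept_pos_arr = np.asarray(kept_pos, dtype=int)
    kept_scores = (
        np.asarray(scores, dtype=float)[kept_pos_arr]
        if scores is not None
        else np.full(kept_pos_arr.size, np.nan)
    )
    return CandidateSet(indices=ranked[kept_pos_arr], scores=kept_scores, ld_cutoff=alpha)


def preprocess_candidates(
    G_train: GenotypeMatrix,
    y_train: np.ndarray,
    cfg: PreprocessConfig,
) -> CandidateSet:
    """Rank by trait correlation then LD-prune; the full first stage."""
    order, scores = rank_by_correlation(G_train, y_train, cfg)
    if cfg.top_k is not None:
        order, scores = order[: cfg.top_k], scores[: cfg.top_k]
    cand = greedy_ld_prune(order, G_train, cfg.ld_cutoff, scores=scores)
    log.info(
        "pre-processing kept %d of %d SNPs at LD cutoff %.3g",
        len(cand),
        G_train.n_loci,
        cfg.ld_cutoff,
    )
    return cand


def write_candidates_tsv(cand: CandidateSet, G: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "rank": np.arange(len(cand)),
            "id": [G.loci[i].id for i in cand.indices],
            "column": cand.indices,
            "score": cand.scores,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path: str | Path, G: GenotypeMatrix, ld_cutoff: float) -> CandidateSet:
    df = pd.read_csv(path, sep="\t")
    index = G.locus_index()
    missing = [i for i in df["id"] if i not in index]
    if missing:
        raise ValueError(f"candidate loci absent from genotype matrix: {missing[:5]}")
    return CandidateSet(
        indices=np.array([index[i] for i in df["id"]]),
        scores=df["score"].to_numpy(),
        ld_cutoff=ld_cutoff,
    )
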