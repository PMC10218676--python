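"""Multi-run consensus, held-out prediction metrics and LD concordance.

The GA is stochastic, so it is repeated (three runs by default) and the
intersection of the selected SNP sets is taken as the final set; the
intersection-over-union (I/U) ratio measures run-to-run stability.  The
consensus features are then refitted on the training partition and
evaluated on the held-out partition with MAE, MSE and Pearson
correlation.  Against an external reference QTL list, concordance is
summarized per reference locus as the maximum LD r² with any detected
SNP — detections that tag the same haplotype block score high even when
the exact positions differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from dataclasses import replace as dc_replace

import numpy as np
from sklearn.metrics import mean_absolute_error, mean_squared_error

from .data_io import DataSplit, GenotypeMatrix, Locus, PhenotypeTable, join_and_split
from .ga_engine import GAConfig, SelectionResult, fit_linear_ridge, run_ga
from .preprocess import PreprocessConfig, pairwise_ld, pearson_corr, preprocess_candidates

log = logging.getLogger("gaselect")

__all__ = [
    "ConsensusResult",
    "PredictionReport",
    "ConcordanceReport",
    "intersect_runs",
    "evaluate_prediction",
    "ld_concordance",
    "full_pipeline",
    "kfold_cv",
    "combine_across_cutoffs",
]


@dataclass
class ConsensusResult:
    per_run: list[SelectionResult]
    consensus_loci: list[Locus]
    iu_ratio: float
    fallback_to_best_run: bool = False

    @property
    def consensus_ids(self) -> list[str]:
        return [loc.id for loc in self.consensus_loci]


@dataclass
class PredictionReport:
    mae: float
    mse: float
    pcc: float
    n_test: int
    features_used: list[str]


@dataclass
class ConcordanceReport:
    """Per reference QTL, the max r² to any detected SNP (violin-plot data)."""

    per_reference_qtl: dict[str, float]
    skipped: list[str] = field(default_factory=list)
    trait: str | None = None
    ld_cutoff: float | None = None

    @property
    def values(self) -> np.ndarray:
        return np.asarray(list(self.per_reference_qtl.values()), dtype=float)


def intersect_runs(results: list[SelectionResult]) -> ConsensusResult:
    """Intersect per-run selected sets; I/U = |intersection| / |union|."""
    if not results:
        raise ValueError("need at least one run result")
    first_ids = results[0].candidate_ids
    for r in results[1:]:
        if r.candidate_ids != first_ids:
            raise ValueError("runs were produced over different candidate sets")
    sets = [{loc.id for loc in r.selected_loci} for r in results]
    inter = set.intersection(*sets)
    union = set.union(*sets)
    if not union:
        log.warning("all runs selected empty sets; I/U defined as 1")
        iu = 1.0
    else:
        iu = len(inter) / len(union)
    by_id = {loc.id: loc for r in results for loc in r.selected_loci}
    # report consensus loci in candidate (ranking) order
    consensus = [by_id[i] for i in first_ids if i in inter]
    return ConsensusResult(per_run=list(results), consensus_loci=consensus, iu_ratio=iu)


def evaluate_prediction(
    G_train: GenotypeMatrix,
    y_train: np.ndarray,
    G_test: GenotypeMatrix,
    y_test: np.ndarray,
    features: list[Locus] | list[str],
) -> PredictionReport:
    """Refit the ridge model on the selected features; score the held-out set."""
    ids = [f.id if isinstance(f, Locus) else str(f) for f in features]
    if not ids:
        raise ValueError("feature list must be non-empty")
    tr_index = G_train.locus_index()
    te_index = G_test.locus_index()
    for i in ids:
        if i not in tr_index or i not in te_index:
            raise KeyError(f"feature {i} absent from genotype matrix")
    tr_cols = [tr_index[i] for i in ids]
    te_cols = [te_index[i] for i in ids]
    model = fit_linear_ridge(G_train.codes[:, tr_cols].astype(float), y_train)
    pred = model.predict(G_test.codes[:, te_cols].astype(float))
    if np.std(pred) == 0:
        log.warning("constant predictions on the test set; PCC reported as 0")
    return PredictionReport(
        mae=float(mean_absolute_error(y_test, pred)),
        mse=float(mean_squared_error(y_test, pred)),
        pcc=pearson_corr(pred, np.asarray(y_test, dtype=float)),
        n_test=int(np.asarray(y_test).size),
        features_used=ids,
    )


def ld_concordance(
    detected: list[Locus] | list[str],
    reference: list[Locus] | list[str],
    G: GenotypeMatrix,
    trait: str | None = None,
    ld_cutoff: float | None = None,
) -> ConcordanceReport:
    """Max LD r² between each reference QTL and the detected SNP set."""
    det_ids = [f.id if isinstance(f, Locus) else str(f) for f in detected]
    ref_ids = [f.id if isinstance(f, Locus) else str(f) for f in reference]
    if not det_ids:
        raise ValueError("detected set must be non-empty")
    index = G.locus_index()
    missing_det = [i for i in det_ids if i not in index]
    if missing_det:
        raise KeyError(f"detected loci absent from genotype matrix: {missing_det[:5]}")
    det_cols = G.codes[:, [index[i] for i in det_ids]].astype(float)
    per_ref: dict[str, float] = {}
    skipped: list[str] = []
    for rid in ref_ids:
        if rid not in index:
            log.warning("reference QTL %s not genotyped; skipped", rid)
            skipped.append(rid)
            continue
        ref_col = G.codes[:, index[rid]].astype(float)
        per_ref[rid] = max(pairwise_ld(ref_col, det_cols[:, j]) for j in range(det_cols.shape[1]))
    return ConcordanceReport(per_reference_qtl=per_ref, skipped=skipped, trait=trait, ld_cutoff=ld_cutoff)


def full_pipeline(
    G: GenotypeMatrix,
    P: PhenotypeTable,
    trait: str,
    pre_cfg: PreprocessConfig,
    ga_cfg: GAConfig,
    test_fraction: float = 0.1,
    split_seed: int | None = None,
) -> tuple[ConsensusResult, PredictionReport, DataSplit]:
    """Split, preprocess on the training partition, run the GA repeatedly,
    intersect, and evaluate on the held-out partition.

    Run r uses seed ``ga_cfg.seed + r``; the split seed defaults to
    ``ga_cfg.seed``.  An empty consensus falls back to the best single
    run's set (by adjusted R²) and is flagged in the result.
    """
    split_seed = ga_cfg.seed if split_seed is None else split_seed
    G_tr, y_tr, G_te, y_te, split = join_and_split(G, P, trait, test_fraction, split_seed)
    candidates = preprocess_candidates(G_tr, y_tr, pre_cfg)
    results = [
        run_ga(G_tr, y_tr, candidates, dc_replace(ga_cfg, seed=ga_cfg.seed + r))
        for r in range(ga_cfg.runs)
    ]
    consensus = intersect_runs(results)
    features: list[Locus] = consensus.consensus_loci
    if not features:
        best = max(results, key=lambda r: r.score.key)
        log.warning("empty consensus; falling back to the best single run (seed %d)", best.seed)
        consensus.fallback_to_best_run = True
        features = best.selected_loci
    report = evaluate_prediction(G_tr, y_tr, G_te, y_te, features)
    return consensus, report, split


def kfold_cv(
    G: GenotypeMatrix,
    P: PhenotypeTable,
    trait: str,
    pre_cfg: PreprocessConfig,
    ga_cfg: GAConfig,
    n_folds: int = 5,
    seed: int | None = None,
) -> list[PredictionReport]:
    """Seeded k-fold driver: one full selection + evaluation per fold.

    Usable samples are shuffled once with the seed and assigned to
    contiguous folds; fold i serves as the held-out set while the rest
    train.  Per-fold reports (including fold MSEs) are returned so any
    standard paired-comparison routine can be applied downstream.
    """
    seed = ga_cfg.seed if seed is None else seed
    if trait not in P.trait_names:
        raise KeyError(f"trait {trait!r} not found")
    y_all = P.traits[trait].reindex(G.samples).to_numpy(dtype=float)
    usable = np.flatnonzero(~np.isnan(y_all))
    if usable.size < n_folds:
        raise ValueError("fewer usable samples than folds")
    rng = np.random.default_rng(seed)
    perm = usable[rng.permutation(usable.size)]
    folds = np.array_split(perm, n_folds)
    reports: list[PredictionReport] = []
    for k, test_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != k])
        G_tr, G_te = G.subset_samples(np.sort(train_idx)), G.subset_samples(np.sort(test_idx))
        y_tr, y_te = y_all[np.sort(train_idx)], y_all[np.sort(test_idx)]
        candidates = preprocess_candidates(G_tr, y_tr, pre_cfg)
        results = [
            run_ga(G_tr, y_tr, candidates, dc_replace(ga_cfg, seed=ga_cfg.seed + r))
            for r in range(ga_cfg.runs)
        ]
        consensus = intersect_runs(results)
        features = consensus.consensus_loci or max(results, key=lambda r: r.score.key).selected_loci
        reports.append(evaluate_prediction(G_tr, y_tr, G_te, y_te, features))
    return reports


def combine_across_cutoffs(
    consensus_sets: list[ConsensusResult],
    mode: str = "intersection",
) -> list[str]:
    """Combine consensus sets obtained at different LD cutoffs.

    Whether detections should be pooled across cutoffs by intersection
    (strict, default) or union (permissive) is a user choice.
    """
    if not consensus_sets:
        raise ValueError("need at least one consensus result")
    sets = [set(c.consensus_ids) for c in consensus_sets]
    if mode == "intersection":
        combined = set.intersection(*sets)
    elif mode == "union":
        combined = set.union(*sets)
    else:
        raise ValueError(f"mode must be 'intersection' or 'union', got {mode!r}")
    return sorted(combined)
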