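"""LD-block genotype and planted-QTL phenotype simulator.

Emulates the structure of a biparental haploid-style cross panel:
biallelic markers coded -1/+1, organized in mutually independent LD
blocks.  Within a block, adjacent SNPs form a first-order Markov chain —
SNP j+1 equals SNP j with probability (1+rho)/2 per sample — giving an
exact adjacent-SNP correlation of ``rho`` and geometric LD decay
``rho**d`` at marker distance d, while keeping exact ±1 marginals.

Phenotypes are built from planted additive effects (optionally plus
pairwise products for epistasis) with Gaussian noise scaled so that the
genetic variance fraction of the trait equals the target heritability
h².  Everything is deterministic under the seed, and the ground truth
(causal loci, effects, realized h²) is returned for power evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import GenotypeMatrix, Locus

log = logging.getLogger("gaselect")

__all__ = ["SimulationConfig", "GroundTruth", "simulate_genotypes", "simulate_phenotype", "simulate_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation knobs.

    n
        Sample count.
    n_blocks, block_size
        LD-block layout: total markers m = n_blocks * block_size.
    rho
        Within-block adjacent-SNP correlation in [0, 1); 0 means fully
        independent markers.
    k_qtl
        Number of planted additive QTLs, drawn one per block while
        blocks remain.
    effect_sizes
        Additive effect per QTL; defaults to equal magnitudes with
        alternating signs (avoids sign-cancellation artifacts).
    epistatic_pairs
        Optional (locus_index, locus_index, effect) product terms.
    h2
        Target heritability in (0, 1]: var(genetic) / var(phenotype).
    seed
        Root seed; all randomness flows from it.
    """

    n: int = 500
    n_blocks: int = 30
    block_size: int = 10
    rho: float = 0.9
    k_qtl: int = 5
    effect_sizes: tuple[float, ...] | None = None
    epistatic_pairs: tuple[tuple[int, int, float], ...] = ()
    h2: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.n_blocks < 1 or self.block_size < 1:
            raise ValueError("n >= 2, n_blocks >= 1, block_size >= 1 required")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must lie in (0, 1]")
        if self.k_qtl < 0 or self.k_qtl > self.n_blocks * self.block_size:
            raise ValueError("k_qtl must lie in [0, n_blocks * block_size]")
        if self.effect_sizes is not None and len(self.effect_sizes) != self.k_qtl:
            raise ValueError("effect_sizes length must equal k_qtl")

    @property
    def m(self) -> int:
        return self.n_blocks * self.block_size

    def default_effects(self) -> np.ndarray:
        if self.effect_sizes is not None:
            return np.asarray(self.effect_sizes, dtype=float)
        return np.array([1.0 if i % 2 == 0 else -1.0 for i in range(self.k_qtl)])


@dataclass
class GroundTruth:
    causal_loci: list[Locus]
    effects: np.ndarray
    epistatic_pairs: list[tuple[str, str, float]]
    realized_h2: float
    causal_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Draw the ±1 chain-block genotype matrix; loci are chr1_P at 1 kb spacing."""
    rng = np.random.default_rng(cfg.seed)
    codes = np.empty((cfg.n, cfg.m), dtype=np.int8)
    copy_prob = (1.0 + cfg.rho) / 2.0
    for b in range(cfg.n_blocks):
        start = b * cfg.block_size
        col = rng.choice(np.array([-1, 1], dtype=np.int8), size=cfg.n)
        codes[:, start] = col
        for j in range(1, cfg.block_size):
            # equal to the previous SNP w.p. (1+rho)/2, flipped otherwise:
            # identical in law to "copy w.p. rho else resample uniformly",
            # and the adjacent correlation is exactly rho
            keep = rng.random(cfg.n) < copy_prob
            col = np.where(keep, col, -col).astype(np.int8)
            codes[:, j + start] = col
    loci = [Locus(chrom="chr1", pos=1000 * (j + 1)) for j in range(cfg.m)]
    samples = [f"s{i:05d}" for i in range(cfg.n)]
    return GenotypeMatrix(samples=samples, loci=loci, codes=codes)


def _pick_causal_indices(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """One causal SNP per block while blocks remain, then wrap around."""
    blocks = np.arange(cfg.n_blocks)
    chosen: list[int] = []
    order = rng.permutation(blocks)
    i = 0
    while len(chosen) < cfg.k_qtl:
        b = order[i % cfg.n_blocks]
        within = int(rng.integers(cfg.block_size))
        idx = int(b * cfg.block_size + within)
        if idx not in chosen:
            chosen.append(idx)
        i += 1
    return np.asarray(sorted(chosen), dtype=int)


def simulate_phenotype(G: GenotypeMatrix, cfg: SimulationConfig) -> tuple[np.ndarray, GroundTruth]:
    """y = sum_i beta_i g_i + sum_(a,b) gamma_ab g_a g_b + eps, with
    eps scaled so the genetic variance fraction equals h2."""
    rng = np.random.default_rng(cfg.seed + 1)  # independent of the genotype stream
    X = G.codes.astype(float)
    causal = _pick_causal_indices(cfg, rng) if cfg.k_qtl else np.array([], dtype=int)
    effects = cfg.default_effects()
    genetic = X[:, causal] @ effects if cfg.k_qtl else np.zeros(G.n_samples)
    epi_records: list[tuple[str, str, float]] = []
    for a, b, gamma in cfg.epistatic_pairs:
        genetic = genetic + gamma * X[:, a] * X[:, b]
        epi_records.append((G.loci[a].id, G.loci[b].id, float(gamma)))
    var_g = float(np.var(genetic))
    if var_g == 0.0 and (cfg.k_qtl or cfg.epistatic_pairs):
        log.warning("planted genetic signal has zero variance in this draw")
    if cfg.h2 >= 1.0 or var_g == 0.0:
        eps = np.zeros(G.n_samples)
    else:
        sigma = np.sqrt(var_g * (1.0 - cfg.h2) / cfg.h2)
        eps = rng.normal(0.0, sigma, size=G.n_samples)
    y = genetic + eps
    var_y = float(np.var(y))
    realized = var_g / var_y if var_y > 0 else 0.0
    truth = GroundTruth(
        causal_loci=[G.loci[i] for i in causal],
        effects=effects,
        epistatic_pairs=epi_records,
        realized_h2=realized,
        causal_indices=causal,
    )
    return y, truth


def simulate_dataset(cfg: SimulationConfig) -> tuple[GenotypeMatrix, np.ndarray, GroundTruth]:
    """Convenience: genotypes plus one simulated trait."""
    G = simulate_genotypes(cfg)
    y, truth = simulate_phenotype(G, cfg)
    return G, y, truth
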