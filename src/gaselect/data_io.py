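"""Reading, writing and splitting of genotype/phenotype/QTL data.

Genotypes are biallelic markers from a haploid-style cross, canonically
coded -1 (first parental allele) and +1 (second parental allele) per
sample.  Two on-disk dialects are accepted: a delimited matrix (first
column sample id, remaining columns ``chrN_P`` locus headers, values in
{-1,1} or {0,2}) and VCF restricted to biallelic, homozygous/haploid
genotype calls.  Phenotypes are a delimited table of real-valued traits,
one column per trait, with empty cells for missing measurements.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .consensus_eval import ConsensusResult

log = logging.getLogger("gaselect")

__all__ = [
    "Locus",
    "GenotypeMatrix",
    "PhenotypeTable",
    "DataSplit",
    "read_genotypes",
    "read_phenotypes",
    "read_qtl_list",
    "join_and_split",
    "write_selection",
    "write_genotypes_tsv",
    "write_phenotypes_tsv",
]


@dataclass(frozen=True, order=True)
class Locus:
    """A genotyped position, identified as ``chrN_P`` (1-based bp)."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus position must be >= 1, got {self.pos}")

    @property
    def id(self) -> str:
        return f"{self.chrom}_{self.pos}"

    @classmethod
    def parse(cls, token: str) -> "Locus":
        """Parse a ``chrN_P`` identifier; the position is the last ``_`` field."""
        token = token.strip()
        chrom, sep, pos = token.rpartition("_")
        if not sep or not chrom:
            raise ValueError(f"malformed locus id {token!r}: expected chrN_P")
        try:
            ipos = int(pos)
        except ValueError:
            raise ValueError(f"malformed locus id {token!r}: position {pos!r} is not an integer") from None
        return cls(chrom=chrom, pos=ipos)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs matrix of allele codes in {-1, +1}."""

    samples: list[str]
    loci: list[Locus]
    codes: np.ndarray  # shape (n_samples, n_loci), int8

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        n, m = self.codes.shape
        if n != len(self.samples):
            raise ValueError(f"{len(self.samples)} samples but {n} code rows")
        if m != len(self.loci):
            raise ValueError(f"{len(self.loci)} loci but {m} code columns")
        if n < 2 or m < 1:
            raise ValueError("need at least 2 samples and 1 locus")
        ids = [loc.id for loc in self.loci]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate locus ids: {dupes[:5]}")
        bad = set(np.unique(self.codes)) - {-1, 1}
        if bad:
            raise ValueError(f"allele codes must be -1/+1 after load, found {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    @property
    def locus_ids(self) -> list[str]:
        return [loc.id for loc in self.loci]

    def locus_index(self) -> dict[str, int]:
        return {loc.id: j for j, loc in enumerate(self.loci)}

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            loci=list(self.loci),
            codes=self.codes[idx],
        )


@dataclass
class PhenotypeTable:
    """Real-valued trait measurements per sample; NaN marks missing."""

    samples: list[str]
    traits: pd.DataFrame  # index = samples, one float column per trait

    def __post_init__(self) -> None:
        if list(self.traits.index) != list(self.samples):
            self.traits = self.traits.reindex(self.samples)

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)


@dataclass(frozen=True)
class DataSplit:
    """A deterministic, seeded train/test partition of usable samples."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    test_fraction: float

    def __post_init__(self) -> None:
        tr, te = set(self.train_indices.tolist()), set(self.test_indices.tolist())
        if tr & te:
            raise ValueError("train and test indices overlap")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


# ---------------------------------------------------------------------------
# genotype reading

_CODE_MAPS = (
    ({-1, 1}, {-1: -1, 1: 1}),
    ({0, 2}, {0: -1, 2: 1}),  # minor/alt dosage dialect, order-preserving
)


def _canonicalize_column(col: np.ndarray, locus_id: str) -> tuple[np.ndarray, int]:
    """Map one raw genotype column to {-1,+1}; impute missing to the mode.

    Returns the coded column and the number of imputed entries.
    """
    missing = np.isnan(col)
    observed = set(np.unique(col[~missing]).astype(int).tolist())
    if not observed:
        raise ValueError(f"column {locus_id} has no observed genotypes")
    for allowed, mapping in _CODE_MAPS:
        if observed <= allowed:
            out = np.zeros(col.shape, dtype=np.int8)
            for raw, canon in mapping.items():
                out[col == raw] = canon
            n_missing = int(missing.sum())
            if n_missing:
                vals, counts = np.unique(out[~missing], return_counts=True)
                out[missing] = vals[np.argmax(counts)]
            return out, n_missing
    raise ValueError(
        f"column {locus_id} contains unsupported genotype codes {sorted(observed)}; "
        "expected {-1,1} or {0,2}"
    )


def _read_genotypes_matrix(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except Exception as exc:  # noqa: BLE001 - reraise with file context
        raise ValueError(f"cannot parse genotype matrix {path}: {exc}") from exc
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no locus columns found")
    loci = [Locus.parse(str(c)) for c in df.columns]
    raw = df.to_numpy(dtype=float)
    codes = np.empty(raw.shape, dtype=np.int8)
    n_imputed = 0
    for j, loc in enumerate(loci):
        codes[:, j], nj = _canonicalize_column(raw[:, j], loc.id)
        n_imputed += nj
    if n_imputed:
        log.info("imputed %d missing genotype entries to per-SNP modes", n_imputed)
    return GenotypeMatrix(samples=[str(s) for s in df.index], loci=loci, codes=codes)


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[Locus] = []
    cols: list[np.ndarray] = []
    n_imputed = 0
    for variant in vcf:
        locus = Locus(chrom=str(variant.CHROM), pos=int(variant.POS))
        if len(variant.ALT) != 1:
            raise ValueError(f"{locus.id}: multi-allelic site; only biallelic VCF records are supported")
        # gt_types: 0=hom-ref, 1=het, 2=missing, 3=hom-alt (haploid calls
        # collapse onto the homozygous categories)
        gt = np.asarray(variant.gt_types)
        if np.any(gt == 1):
            raise ValueError(f"{locus.id}: heterozygous genotype found; cross-derived haploid-style calls expected")
        col = np.where(gt == 3, 1, -1).astype(np.int8)
        missing = gt == 2
        if missing.any():
            obs = col[~missing]
            if obs.size == 0:
                raise ValueError(f"{locus.id}: all genotypes missing")
            vals, counts = np.unique(obs, return_counts=True)
            col[missing] = vals[np.argmax(counts)]
            n_imputed += int(missing.sum())
        loci.append(locus)
        cols.append(col)
    if not cols:
        raise ValueError(f"{path}: VCF contains no variant records")
    if n_imputed:
        log.info("imputed %d missing genotype entries to per-SNP modes", n_imputed)
    return GenotypeMatrix(samples=samples, loci=loci, codes=np.column_stack(cols))


def read_genotypes(path: str | Path, dialect: str = "tsv_matrix") -> GenotypeMatrix:
    """Load genotypes from ``tsv_matrix`` or ``vcf``, canonicalized to -1/+1."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv_matrix":
        return _read_genotypes_matrix(path)
    if dialect == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}; expected 'tsv_matrix' or 'vcf'")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Load the trait table (first column sample id, empty cell = missing)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot parse phenotype table {path}: {exc}") from exc
    df = df.astype(float)
    df.index = df.index.map(str)
    return PhenotypeTable(samples=list(df.index), traits=df)


def read_qtl_list(path: str | Path) -> list[Locus]:
    """Read reference QTL ids (one ``chrN_P`` per line, or a TSV ``id`` column)."""
    path = Path(path)
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    tokens: list[str]
    header = lines[0].split("\t")
    if "id" in header:
        col = header.index("id")
        tokens = [ln.split("\t")[col] for ln in lines[1:]]
    else:
        tokens = [ln.split("\t")[0] for ln in lines]
    loci: list[Locus] = []
    seen: set[str] = set()
    for tok in tokens:
        loc = Locus.parse(tok)
        if loc.id in seen:
            log.warning("duplicate reference QTL %s dropped", loc.id)
            continue
        seen.add(loc.id)
        loci.append(loc)
    return loci


# ---------------------------------------------------------------------------
# alignment and splitting


def join_and_split(
    G: GenotypeMatrix,
    P: PhenotypeTable,
    trait: str,
    test_fraction: float,
    seed: int,
) -> tuple[GenotypeMatrix, np.ndarray, GenotypeMatrix, np.ndarray, DataSplit]:
    """Align genotypes and one trait by sample id, then split train/test.

    Samples with a missing trait value are dropped before the seeded
    shuffle; the same seed always yields the same partition.
    """
    if trait not in P.trait_names:
        raise KeyError(f"trait {trait!r} not found; available: {P.trait_names}")
    g_set, p_set = set(G.samples), set(P.samples)
    if g_set != p_set:
        only_g = sorted(g_set - p_set)[:10]
        only_p = sorted(p_set - g_set)[:10]
        raise ValueError(
            f"sample identifiers do not match: {len(g_set - p_set)} only in genotypes "
            f"(e.g. {only_g}), {len(p_set - g_set)} only in phenotypes (e.g. {only_p})"
        )
    y_all = P.traits[trait].reindex(G.samples).to_numpy(dtype=float)
    usable = np.flatnonzero(~np.isnan(y_all))
    if usable.size < 10:
        raise ValueError(f"only {usable.size} samples have a non-missing {trait!r} value; need >= 10")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = usable[rng.permutation(usable.size)]
    n_test = int(round(test_fraction * usable.size))
    n_test = min(max(n_test, 1), usable.size - 1)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    split = DataSplit(train_indices=train_idx, test_indices=test_idx, seed=seed, test_fraction=test_fraction)
    return (
        G.subset_samples(train_idx),
        y_all[train_idx],
        G.subset_samples(test_idx),
        y_all[test_idx],
        split,
    )


# ---------------------------------------------------------------------------
# writing


def write_selection(result: "ConsensusResult", path: str | Path) -> None:
    """Write consensus loci as TSV plus a JSON report alongside.

    The TSV has columns id/chrom/pos and one boolean membership column per
    GA run; the report records the I/U ratio, per-run fitness and seeds.
    Reading the TSV back through :func:`read_qtl_list` reproduces the
    selected loci.
    """
    if result is None:
        raise ValueError("result must not be None")
    path = Path(path)
    run_sets = [{loc.id for loc in r.selected_loci} for r in result.per_run]
    rows = []
    for loc in result.consensus_loci:
        row = {"id": loc.id, "chrom": loc.chrom, "pos": loc.pos}
        for k, s in enumerate(run_sets, start=1):
            row[f"run{k}"] = loc.id in s
        rows.append(row)
    cols = ["id", "chrom", "pos"] + [f"run{k}" for k in range(1, len(run_sets) + 1)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)

    report = {
        "iu_ratio": result.iu_ratio,
        "n_consensus": len(result.consensus_loci),
        "fallback_to_best_run": result.fallback_to_best_run,
        "runs": [
            {
                "seed": r.seed,
                "adj_r2": r.score.adj_r2,
                "r2": r.score.r2,
                "n_selected": len(r.selected_loci),
                "fitness_calls": r.fitness_calls,
                "tabu_hits": r.tabu_hits,
            }
            for r in result.per_run
        ],
    }
    report_path = path.parent / (path.stem + ".report.json")
    report_path.write_text(json.dumps(report, indent=2))


def write_genotypes_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(G.codes, index=G.samples, columns=G.locus_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def write_phenotypes_tsv(samples: Sequence[str], traits: dict[str, np.ndarray], path: str | Path) -> None:
    df = pd.DataFrame(traits, index=list(samples))
    df.index.name = "sample"
    df.to_csv(path, sep="\t")
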