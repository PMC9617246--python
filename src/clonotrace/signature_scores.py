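"""Cell QC, normalization, and gene-program scoring on expression matrices.

Two scoring flavours are provided: a bin-matched control score in the style
of Seurat's AddModuleScore (program mean minus expression-matched control
mean), and a signed rank-based pathway score (mean pathway rank centred at
zero, scale-free in (-0.5, 0.5)) used for metabolic pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from scipy.stats import pearsonr, rankdata, spearmanr

logger = logging.getLogger(__name__)

MITO_PREFIX = "MT-"


class ScoreError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered gene program."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")


@dataclass
class ExpressionMatrix:
    """Cells x genes counts (CSR sparse) with per-cell metadata.

    ``metadata`` is indexed by barcode and typically carries donor, group
    and cluster columns.  ``normalized`` flags log1p(CP10K) values.
    """

    matrix: sparse.csr_matrix
    barcodes: list[str]
    genes: list[str]
    metadata: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        n, g = self.matrix.shape
        if n != len(self.barcodes) or g != len(self.genes):
            raise ValueError("matrix shape inconsistent with barcodes/genes")
        if not self.metadata.index.equals(pd.Index(self.barcodes)):
            self.metadata = self.metadata.reindex(self.barcodes)

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def detected_genes(self) -> np.ndarray:
        return np.asarray((self.matrix > 0).sum(axis=1)).ravel()

    def mito_fraction(self, prefix: str = MITO_PREFIX) -> np.ndarray:
        totals = np.asarray(self.matrix.sum(axis=1)).ravel()
        mito_idx = [i for i, g in enumerate(self.genes) if g.upper().startswith(prefix)]
        if not mito_idx:
            return np.zeros(self.n_cells)
        mito = np.asarray(self.matrix[:, mito_idx].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
        return frac

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(mask, dtype=bool)
        return ExpressionMatrix(
            matrix=self.matrix[keep],
            barcodes=[b for b, k in zip(self.barcodes, keep) if k],
            genes=list(self.genes),
            metadata=self.metadata.loc[keep].copy(),
            normalized=self.normalized,
        )


def read_mtx_bundle(mtx_path, barcodes_path, features_path,
                    metadata_path=None) -> ExpressionMatrix:
    """Read a 10x-style MTX trio (genes x cells on disk) plus metadata CSV."""
    mat = sparse.csr_matrix(spio.mmread(mtx_path).T)
    barcodes = pd.read_csv(barcodes_path, header=None, sep="\t")[0].tolist()
    features = pd.read_csv(features_path, header=None, sep="\t")
    genes = features[features.shape[1] - 1 if features.shape[1] == 1 else 1].tolist()
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path, index_col=0)
    else:
        metadata = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return ExpressionMatrix(matrix=mat, barcodes=barcodes, genes=genes, metadata=metadata)


def write_mtx_bundle(matrix: ExpressionMatrix, outdir, metadata: bool = True) -> None:
    """Write the 10x-convention trio (genes x cells) and metadata CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(matrix.matrix.T))
    pd.Series(matrix.barcodes).to_csv(outdir / "barcodes.tsv", index=False, header=False)
    pd.DataFrame({"id": matrix.genes, "name": matrix.genes}).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False)
    if metadata:
        matrix.metadata.to_csv(outdir / "metadata.csv", index_label="barcode")


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = []
    with open(path) as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(name=parts[0], genes=tuple(dict.fromkeys(parts[2:]))))
    return sets


def write_gmt(sets: Iterable[GeneSet], path, description: str = "clonotrace") -> None:
    with open(path, "w") as handle:
        for s in sets:
            handle.write("\t".join([s.name, description, *s.genes]) + "\n")


def filter_cells_qc(matrix: ExpressionMatrix, min_genes: int = 500,
                    max_mito: float = 0.10, mito_prefix: str = MITO_PREFIX) -> ExpressionMatrix:
    """Keep cells with >= min_genes detected genes and mito fraction <= max_mito."""
    if matrix.normalized:
        raise ScoreError("QC filtering expects raw counts")
    keep = (matrix.detected_genes() >= min_genes) & (matrix.mito_fraction(mito_prefix) <= max_mito)
    return matrix.subset_cells(keep)


def log_normalize(matrix: ExpressionMatrix, scale: float = 10_000.0) -> ExpressionMatrix:
    """ln(1 + count / cell_total * scale) per entry."""
    if matrix.normalized:
        return matrix
    totals = np.asarray(matrix.matrix.sum(axis=1)).ravel()
    if (totals <= 0).any():
        raise ScoreError("cells with zero total counts present; run QC first")
    norm = matrix.matrix.astype(float).tocsr(copy=True)
    inv = scale / totals
    norm = sparse.diags(inv) @ norm
    norm.data = np.log1p(norm.data)
    return ExpressionMatrix(matrix=norm.tocsr(), barcodes=list(matrix.barcodes),
                            genes=list(matrix.genes), metadata=matrix.metadata.copy(),
                            normalized=True)


def _dense(matrix: ExpressionMatrix) -> np.ndarray:
    return np.asarray(matrix.matrix.todense(), dtype=float)


def _present_genes(matrix: ExpressionMatrix, program: GeneSet) -> list[int]:
    index = {g: i for i, g in enumerate(matrix.genes)}
    hits, missing = [], []
    for g in program.genes:
        (hits if g in index else missing).append(g)
    if missing:
        logger.warning("gene set %s: %d/%d genes absent from matrix",
                       program.name, len(missing), len(program.genes))
    if not hits:
        raise ScoreError(f"no genes of set {program.name!r} present in the matrix")
    return [index[g] for g in hits]


def module_score(matrix: ExpressionMatrix, program: GeneSet,
                 n_bins: int = 25, n_ctrl: int = 50, seed: int = 0) -> pd.Series:
    """Expression-bin-controlled program score per cell.

    All genes are binned into ``n_bins`` by mean expression; for every
    program gene, ``n_ctrl`` control genes are sampled (with replacement,
    seeded) from its bin.  The score is mean(program) - mean(controls).
    Genes are sorted canonically before binning so the result is invariant
    to input gene order.
    """
    if not matrix.normalized:
        raise ScoreError("module_score expects a normalized matrix")
    prog_idx = _present_genes(matrix, program)

    means = np.asarray(matrix.matrix.mean(axis=0)).ravel()
    # canonical order: mean then name, for determinism across gene orderings
    order = sorted(range(len(matrix.genes)), key=lambda i: (means[i], matrix.genes[i]))
    n_genes = len(order)
    bins = np.zeros(n_genes, dtype=int)
    bin_of_rank = (np.arange(n_genes) * n_bins) // n_genes
    bin_members: dict[int, list[int]] = {b: [] for b in range(n_bins)}
    for rank, gene_i in enumerate(order):
        bins[gene_i] = bin_of_rank[rank]
        # pools kept in canonical order so sampling is gene-order invariant
        bin_members[bin_of_rank[rank]].append(gene_i)

    rng = np.random.default_rng(seed)
    prog_set = set(prog_idx)
    ctrl_idx: list[int] = []
    for gi in sorted(prog_idx, key=lambda i: matrix.genes[i]):
        # program genes are excluded from their own control pool unless the
        # bin holds nothing else
        pool = [g for g in bin_members[bins[gi]] if g not in prog_set]
        if not pool:
            pool = bin_members[bins[gi]]
        picks = rng.integers(0, len(pool), size=n_ctrl)
        ctrl_idx.extend(pool[p] for p in picks)

    prog_mean = np.asarray(matrix.matrix[:, prog_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(matrix.matrix[:, ctrl_idx].mean(axis=1)).ravel()
    return pd.Series(prog_mean - ctrl_mean, index=matrix.barcodes, name=program.name)


def rank_signature_score(matrix: ExpressionMatrix, pathway: GeneSet) -> pd.Series:
    """Signed mean-rank pathway score per cell, in (-0.5, 0.5).

    score = (mean rank of pathway genes - (G+1)/2) / G with average ranks
    for ties; invariant to any per-cell monotone transform of expression.
    """
    path_idx = _present_genes(matrix, pathway)
    dense = _dense(matrix)
    g = dense.shape[1]
    ranks = np.apply_along_axis(rankdata, 1, dense)
    score = (ranks[:, path_idx].mean(axis=1) - (g + 1) / 2.0) / g
    return pd.Series(score, index=matrix.barcodes, name=pathway.name)


def score_signatures(matrix: ExpressionMatrix, pathways: Sequence[GeneSet]) -> pd.DataFrame:
    """Rank-based scores for several pathways; cells x pathways."""
    return pd.DataFrame({p.name: rank_signature_score(matrix, p) for p in pathways})


def comprehensive_metabolic_score(scores: pd.DataFrame, top_k: int = 20) -> pd.Series:
    """Mean per-cell score over the ``top_k`` pathways with highest grand-mean."""
    if scores.shape[1] == 0:
        raise ScoreError("no pathway scores provided")
    top = scores.mean(axis=0).nlargest(min(top_k, scores.shape[1])).index
    return scores[top].mean(axis=1).rename("comprehensive_metabolic")


def score_correlation(scores_a: pd.Series, scores_b: pd.Series) -> dict[str, float]:
    """Spearman rho (average ranks) and Pearson R^2 on paired per-donor means."""
    joined = pd.concat([scores_a, scores_b], axis=1, join="inner").dropna()
    if joined.shape[0] < 3:
        raise ScoreError("need at least 3 paired values")
    a, b = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ScoreError("correlation undefined for constant input")
    rho = spearmanr(a, b).statistic
    r = pearsonr(a, b).statistic
    return {"spearman_rho": float(rho), "pearson_r2": float(r * r),
            "spearman_rho2": float(rho * rho), "n": int(joined.shape[0])}


def donor_mean_scores(scores: pd.Series | pd.DataFrame, metadata: pd.DataFrame,
                      donor_col: str = "donor") -> pd.DataFrame:
    """Average per-cell scores within donors."""
    df = scores.to_frame() if isinstance(scores, pd.Series) else scores
    df = df.join(metadata[[donor_col]])
    return df.groupby(donor_col).mean()
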