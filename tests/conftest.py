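import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from clonotrace.repertoire_io import CellChainSet, ContigRecord
from clonotrace.signature_scores import ExpressionMatrix


def make_contig(barcode="cell1", locus="IGH", v="IGHV3-23*01", j="IGHJ4*01",
                junction="TGTGCGAGAGATACGTTTGACTACTGG", umis=5, productive=True,
                high_confidence=True, **kwargs):
    return ContigRecord(
        barcode=barcode, contig_id=kwargs.pop("contig_id", f"{barcode}_{locus}"),
        locus=locus, v_call=v, j_call=j, junction_nt=junction, umis=umis,
        productive=productive, high_confidence=high_confidence, **kwargs)


def make_bcr_cell(barcode, v="IGHV3-23*01", j="IGHJ4*01",
                  junction="TGTGCGAGAGATACGTTTGACTACTGG",
                  light_v="IGKV1-5*01", light_j="IGKJ1*01",
                  light_junction="TGTCAACAGTATAATAGTTAC"):
    heavy = make_contig(barcode, "IGH", v, j, junction)
    light = make_contig(barcode, "IGK", light_v, light_j, light_junction)
    return CellChainSet(barcode=barcode, receptor_type="BCR", chains=(heavy, light))


def make_tcr_cell(barcode, beta_v="TRBV7*01", beta_j="TRBJ1-1*01",
                  beta_junction="TGTGCCAGCAGCTTAGGTAGCTAC",
                  alpha_v="TRAV8*01", alpha_j="TRAJ4*01",
                  alpha_junction="TGTGCTGTGAGTGATAGCTGG"):
    beta = make_contig(barcode, "TRB", beta_v, beta_j, beta_junction)
    alpha = make_contig(barcode, "TRA", alpha_v, alpha_j, alpha_junction)
    return CellChainSet(barcode=barcode, receptor_type="TCR", chains=(beta, alpha))


def make_expression(counts: np.ndarray, genes=None, metadata=None,
                    normalized=False) -> ExpressionMatrix:
    counts = np.asarray(counts)
    n, g = counts.shape
    barcodes = [f"cell{i}" for i in range(n)]
    genes = genes or [f"G{i}" for i in range(g)]
    if metadata is None:
        metadata = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    else:
        metadata = metadata.copy()
        metadata.index = barcodes
    return ExpressionMatrix(matrix=sparse.csr_matrix(counts.astype(float)),
                            barcodes=barcodes, genes=list(genes),
                            metadata=metadata, normalized=normalized)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
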