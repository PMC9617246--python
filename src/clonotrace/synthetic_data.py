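"""Ground-truthed synthetic cohorts: paired-chain repertoires, expression
matrices with a planted gene program, and survival tables.

Everything is driven by a single seeded :class:`numpy.random.Generator`;
identical configs and seeds give byte-identical outputs.  The generator
enforces the separability contract the clonotyping recovery tests rely on:
within-clone junction distance stays below half the clustering threshold
and founder junctions of distinct clones in the same V/J/length partition
are kept more than twice the threshold apart.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .repertoire_io import ContigRecord, write_contigs
from .shm_selection import V_REGION_END, codon_replacement_fraction
from .signature_scores import ExpressionMatrix, GeneSet, write_gmt, write_mtx_bundle
from scipy import sparse

_BASES = np.array(list("ACGT"))

# Synthetic germline V segments (NOT biological sequences): 312 nt, in frame,
# stop-free, fixed for reproducibility.
_GERMLINE_SEED = 20240917


def _make_germline_pool(n: int = 4, length: int = V_REGION_END) -> tuple[str, ...]:
    rng = np.random.default_rng(_GERMLINE_SEED)
    stops = {"TAA", "TAG", "TGA"}
    pool = []
    for _ in range(n):
        codons = []
        while len(codons) < length // 3:
            codon = "".join(rng.choice(_BASES, size=3))
            if codon not in stops:
                codons.append(codon)
        pool.append("".join(codons))
    return tuple(pool)


GERMLINE_V_POOL: tuple[str, ...] = _make_germline_pool()

_V_GENES_H = [f"IGHV{i}-{j}" for i, j in [(1, 2), (1, 69), (3, 23), (3, 30), (4, 34), (4, 4), (2, 5), (7, 4)]]
_J_GENES_H = [f"IGHJ{i}" for i in range(1, 5)]
_V_GENES_L = [f"IGKV{i}-{j}" for i, j in [(1, 5), (1, 39), (3, 20), (4, 1)]]
_J_GENES_L = [f"IGKJ{i}" for i in range(1, 4)]
_V_GENES_B = [f"TRBV{i}" for i in (2, 5, 7, 9, 12, 20, 28, 30)]
_J_GENES_B = [f"TRBJ1-{i}" for i in range(1, 5)]
_V_GENES_A = [f"TRAV{i}" for i in (1, 8, 12, 17, 21, 26)]
_J_GENES_A = [f"TRAJ{i}" for i in (4, 9, 23, 33)]

ISOTYPES = ["IGHM", "IGHG1", "IGHG3", "IGHA1"]


@dataclass
class GroupConfig:
    """Per-group cohort structure."""

    name: str
    n_donors: int = 3
    cells_per_donor: int = 100
    clone_size_dist: str = "geometric"   # or "powerlaw"
    clone_size_param: float = 0.8        # geometric p, or power-law exponent
    isg_shift: float = 0.0               # log-scale program shift delta
    hazard: float = 0.5                  # survival events per year


@dataclass
class RepertoireConfig:
    receptor: str = "BCR"                # BCR or TCR
    junction_lengths: tuple[int, ...] = (30, 36, 42, 48)
    clone_mutation_rate: float = 0.01    # per-site, member vs founder junction
    cluster_threshold: float = 0.1       # separability is enforced against this
    shm_rate: float = 0.02               # per-site V-region mutation rate
    replacement_bias: float = 1.0        # 1.0 = neutral R/S targeting
    defect_fraction: float = 0.0         # cells given a QC/pairing defect


@dataclass
class ExpressionConfig:
    n_genes: int = 300
    n_mito: int = 10
    n_isg: int = 10
    n_decoy: int = 50                    # unshifted genes at the ISG baseline
    dispersion: float = 0.5
    base_log_mean: float = 1.5
    base_log_sd: float = 1.0
    isg_base_mean: float = 8.0           # high baseline so log1p shift ~ delta
    mito_fraction: float = 0.03
    qc_fail_fraction: float = 0.0
    qc_min_genes: int = 100              # threshold the planted failures target


@dataclass
class SurvivalConfig:
    n_patients: int = 30
    hazard_high: float = 2.0             # events per year, marker-high stratum
    hazard_low: float = 0.3
    marker_cutpoint: float = 20.0
    marker_spread: float = 5.0
    censor_time: float = 730.0           # administrative censoring, days
    censoring_rate: float = 0.2          # extra uniform random censoring

    def __post_init__(self) -> None:
        if self.hazard_high <= 0 or self.hazard_low <= 0:
            raise ValueError("hazards must be positive")


@dataclass
class SimulationConfig:
    seed: int
    groups: list[GroupConfig] = field(default_factory=lambda: [
        GroupConfig("HD", clone_size_param=0.9),
        GroupConfig("Act", clone_size_dist="powerlaw", clone_size_param=1.7, isg_shift=1.0),
    ])
    repertoire: RepertoireConfig = field(default_factory=RepertoireConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        groups = [GroupConfig(**g) for g in raw.pop("groups", [])]
        rep = RepertoireConfig(**raw.pop("repertoire", {}))
        rep.junction_lengths = tuple(rep.junction_lengths)
        expr = ExpressionConfig(**raw.pop("expression", {}))
        surv = SurvivalConfig(**raw.pop("survival", {}))
        cfg = cls(seed=raw.pop("seed", 0), groups=groups or cls(seed=0).groups,
                  repertoire=rep, expression=expr, survival=surv)
        return cfg

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["repertoire"]["junction_lengths"] = list(raw["repertoire"]["junction_lengths"])
        with open(path, "w") as handle:
            yaml.safe_dump(raw, handle, sort_keys=False)


@dataclass
class SyntheticDataset:
    """In-memory simulation output plus planted ground truth."""

    contigs: list[ContigRecord] = field(default_factory=list)
    cell_metadata: pd.DataFrame | None = None
    expression: ExpressionMatrix | None = None
    survival: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)


def _random_junction(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _mutate_junction(rng: np.random.Generator, founder: str, rate: float,
                     max_mut: int) -> str:
    """Mutate per site at ``rate``, truncated to at most ``max_mut`` changes."""
    n = rng.binomial(len(founder), rate)
    n = min(n, max_mut)
    if n == 0:
        return founder
    positions = rng.choice(len(founder), size=n, replace=False)
    seq = list(founder)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alternatives[rng.integers(0, 3)]
    return "".join(seq)


def mutate_v_region(rng: np.random.Generator, germline: str, rate: float,
                    replacement_bias: float = 1.0,
                    replacement_prob: float | None = None) -> str:
    """Apply SHM to a germline V segment with tunable R/S targeting.

    Mutated sites are Binomial(L, rate).  At each site the three alternative
    bases are weighted ``replacement_bias`` if the one-change substitution is
    non-synonymous and 1 otherwise; bias 1.0 reproduces the uniform neutral
    model underlying the codon-enumeration expectation.  If
    ``replacement_prob`` is given it overrides the weighting: the mutation is
    made replacement with that probability (silent otherwise), falling back
    to whichever class exists at the site.
    """
    length = len(germline)
    n = rng.binomial(length, rate)
    if n == 0:
        return germline
    positions = rng.choice(length, size=n, replace=False)
    seq = list(germline)
    from Bio.Seq import Seq as _Seq
    for pos in positions:
        codon_start = (pos // 3) * 3
        germ_codon = germline[codon_start:codon_start + 3]
        aa = str(_Seq(germ_codon).translate())
        alternatives = [b for b in "ACGT" if b != germline[pos]]
        is_r = []
        for b in alternatives:
            variant = list(germ_codon)
            variant[pos - codon_start] = b
            is_r.append(str(_Seq("".join(variant)).translate()) != aa)
        if replacement_prob is not None:
            want_r = rng.random() < replacement_prob
            pool = [b for b, r in zip(alternatives, is_r) if r == want_r]
            if not pool:
                pool = alternatives
            seq[pos] = pool[rng.integers(0, len(pool))]
        else:
            weights = [replacement_bias if r else 1.0 for r in is_r]
            w = np.asarray(weights) / sum(weights)
            seq[pos] = alternatives[rng.choice(3, p=w)]
    return "".join(seq)


def _draw_clone_sizes(rng: np.random.Generator, group: GroupConfig, n_cells: int) -> list[int]:
    sizes: list[int] = []
    total = 0
    while total < n_cells:
        if group.clone_size_dist == "geometric":
            s = int(rng.geometric(group.clone_size_param))
        elif group.clone_size_dist == "powerlaw":
            s = int(rng.zipf(group.clone_size_param))
        elif group.clone_size_dist == "singleton":
            s = 1
        else:
            raise ValueError(f"unknown clone size distribution {group.clone_size_dist!r}")
        s = min(s, n_cells - total, 200)
        sizes.append(s)
        total += s
    return sizes


def simulate_repertoire(config: SimulationConfig) -> SyntheticDataset:
    """Generate paired-chain contigs with planted clone ground truth."""
    rng = np.random.default_rng(config.seed)
    rep = config.repertoire
    if rep.receptor not in ("BCR", "TCR"):
        raise ValueError("receptor must be BCR or TCR")
    is_bcr = rep.receptor == "BCR"
    vh, jh = (_V_GENES_H, _J_GENES_H) if is_bcr else (_V_GENES_B, _J_GENES_B)
    vl, jl = (_V_GENES_L, _J_GENES_L) if is_bcr else (_V_GENES_A, _J_GENES_A)

    max_member_mut = {
        L: max(0, int(np.ceil(rep.cluster_threshold * L / 2)) - 1)
        for L in rep.junction_lengths
    }
    founders_by_key: dict[tuple, list[str]] = {}

    contigs: list[ContigRecord] = []
    meta_rows = []
    truth_clones: dict[str, str] = {}
    truth_defects: list[str] = []
    truth_shm: dict[str, float] = {}
    contig_counter = 0

    for group in config.groups:
        for d in range(group.n_donors):
            donor = f"{group.name}_D{d}"
            sizes = _draw_clone_sizes(rng, group, group.cells_per_donor)
            cell_idx = 0
            for clone_i, size in enumerate(sizes):
                clone_id = f"{donor}_clone{clone_i}"
                length = int(rng.choice(rep.junction_lengths))
                v_gene = str(rng.choice(vh))
                j_gene = str(rng.choice(jh))
                key = (v_gene, j_gene, length)
                # keep founders of co-partitioned clones > 2*threshold apart
                min_sep = int(np.ceil(2 * rep.cluster_threshold * length)) + 1
                for _ in range(200):
                    founder = _random_junction(rng, length)
                    if all(_hamming(founder, f) >= min_sep for f in founders_by_key.get(key, [])):
                        break
                else:  # pragma: no cover - astronomically unlikely
                    raise RuntimeError("could not place a separable founder junction")
                founders_by_key.setdefault(key, []).append(founder)
                light_v, light_j = str(rng.choice(vl)), str(rng.choice(jl))
                light_junction = _random_junction(rng, 27)
                germline = GERMLINE_V_POOL[rng.integers(0, len(GERMLINE_V_POOL))]
                isotype = str(rng.choice(ISOTYPES)) if is_bcr else ""

                for member in range(size):
                    barcode = f"{donor}_c{cell_idx:04d}"
                    cell_idx += 1
                    if member == 0 or not is_bcr:
                        junction = founder
                    else:
                        junction = _mutate_junction(
                            rng, founder, rep.clone_mutation_rate, max_member_mut[length])
                    observed = mutate_v_region(rng, germline, rep.shm_rate,
                                               rep.replacement_bias) if is_bcr else None
                    if observed is not None:
                        truth_shm[barcode] = _hamming(observed, germline) / len(germline)

                    defect = None
                    if rep.defect_fraction > 0 and rng.random() < rep.defect_fraction:
                        defect = ["low_umi", "non_productive", "low_conf",
                                  "extra_chain", "missing_light"][rng.integers(0, 5)]
                        truth_defects.append(barcode)
                    else:
                        truth_clones[barcode] = clone_id

                    heavy = ContigRecord(
                        barcode=barcode, contig_id=f"contig_{contig_counter}",
                        locus="IGH" if is_bcr else "TRB",
                        v_call=v_gene + "*01", j_call=j_gene + "*01", c_call=isotype,
                        junction_nt=junction,
                        umis=1 if defect == "low_umi" else int(2 + rng.poisson(3)),
                        reads=int(50 + rng.poisson(100)),
                        productive=defect != "non_productive",
                        high_confidence=defect != "low_conf",
                        sequence_alignment=observed,
                        germline_alignment=germline if is_bcr else None,
                    )
                    contig_counter += 1
                    light = ContigRecord(
                        barcode=barcode, contig_id=f"contig_{contig_counter}",
                        locus=("IGK" if is_bcr else "TRA"),
                        v_call=light_v + "*01", j_call=light_j + "*01",
                        junction_nt=light_junction,
                        umis=int(2 + rng.poisson(3)), reads=int(50 + rng.poisson(100)),
                        productive=True, high_confidence=True,
                    )
                    contig_counter += 1
                    contigs.append(heavy)
                    if defect != "missing_light":
                        contigs.append(light)
                    if defect == "extra_chain":
                        extra = ContigRecord(
                            barcode=barcode, contig_id=f"contig_{contig_counter}",
                            locus="IGH" if is_bcr else "TRB",
                            v_call=v_gene + "*01", j_call=j_gene + "*01",
                            junction_nt=junction, umis=3, reads=60,
                            productive=True, high_confidence=True,
                        )
                        contig_counter += 1
                        contigs.append(extra)
                    meta_rows.append({"barcode": barcode, "donor": donor,
                                      "group": group.name})

    metadata = pd.DataFrame(meta_rows).set_index("barcode")
    truth = {
        "clone_of_cell": truth_clones,
        "defective_cells": truth_defects,
        "shm_frequency": truth_shm,
        "shm_rate": rep.shm_rate,
        "replacement_bias": rep.replacement_bias,
    }
    return SyntheticDataset(contigs=contigs, cell_metadata=metadata, truth=truth)


def simulate_expression(config: SimulationConfig,
                        barcodes_by_group: dict[str, list[str]] | None = None) -> SyntheticDataset:
    """Negative-binomial counts with a planted ISG program shift per group."""
    rng = np.random.default_rng(config.seed + 1)
    expr = config.expression
    if expr.n_mito + expr.n_isg + expr.n_decoy > expr.n_genes:
        raise ValueError("n_mito + n_isg + n_decoy must not exceed n_genes")

    isg_names = ["ISG15", "MX1", "IFI6", "OAS2"]
    isg_names += [f"ISGX{i}" for i in range(len(isg_names), expr.n_isg)]
    isg_names = isg_names[: expr.n_isg]
    mito_names = [f"MT-G{i}" for i in range(expr.n_mito)]
    decoy_names = [f"DECOY{i}" for i in range(expr.n_decoy)]
    n_other = expr.n_genes - expr.n_isg - expr.n_mito - expr.n_decoy
    genes = isg_names + mito_names + decoy_names + [f"GENE{i}" for i in range(n_other)]

    if barcodes_by_group is None:
        barcodes_by_group = {
            g.name: [f"{g.name}_D{d}_c{i:04d}" for d in range(g.n_donors)
                     for i in range(g.cells_per_donor)]
            for g in config.groups
        }
    group_of = {g.name: g for g in config.groups}

    base_means = np.exp(rng.normal(expr.base_log_mean, expr.base_log_sd, size=expr.n_genes))
    isg_slice = slice(0, expr.n_isg)
    mito_slice = slice(expr.n_isg, expr.n_isg + expr.n_mito)
    decoy_slice = slice(expr.n_isg + expr.n_mito, expr.n_isg + expr.n_mito + expr.n_decoy)
    base_means[isg_slice] = expr.isg_base_mean
    # decoys share the ISG baseline so bin-matched controls have clean pools
    base_means[decoy_slice] = expr.isg_base_mean
    # mito genes sized so their share of the base total is ~mito_fraction
    non_mito_total = base_means.sum() - base_means[mito_slice].sum()
    base_means[mito_slice] = (expr.mito_fraction * non_mito_total /
                              ((1 - expr.mito_fraction) * expr.n_mito))

    all_barcodes: list[str] = []
    rows = []
    meta_rows = []
    qc_fail: list[str] = []
    r_param = 1.0 / expr.dispersion
    for gname, barcodes in barcodes_by_group.items():
        gcfg = group_of.get(gname)
        shift = gcfg.isg_shift if gcfg is not None else 0.0
        means = base_means.copy()
        means[isg_slice] *= np.exp(shift)
        for bi, barcode in enumerate(barcodes):
            mu = means
            fail = expr.qc_fail_fraction > 0 and rng.random() < expr.qc_fail_fraction
            mode = None
            if fail:
                mode = "low_genes" if rng.random() < 0.5 else "high_mito"
                qc_fail.append(barcode)
            counts = rng.negative_binomial(r_param, r_param / (r_param + mu))
            if mode == "low_genes":
                keep = rng.choice(expr.n_genes, size=max(1, expr.qc_min_genes // 3),
                                  replace=False)
                mask = np.zeros(expr.n_genes, dtype=bool)
                mask[keep] = True
                counts = np.where(mask, counts, 0)
            elif mode == "high_mito":
                counts = counts.copy()
                counts[mito_slice] += rng.poisson(
                    base_means.sum() * 0.4 / expr.n_mito, size=expr.n_mito).astype(counts.dtype)
            rows.append(counts)
            all_barcodes.append(barcode)
            donor = barcode.rsplit("_c", 1)[0]
            meta_rows.append({"barcode": barcode, "donor": donor, "group": gname})

    matrix = sparse.csr_matrix(np.vstack(rows))
    metadata = pd.DataFrame(meta_rows).set_index("barcode")
    em = ExpressionMatrix(matrix=matrix, barcodes=all_barcodes, genes=genes,
                          metadata=metadata)
    truth = {
        "isg_genes": isg_names,
        "isg_shift": {g.name: g.isg_shift for g in config.groups},
        "qc_failing_cells": qc_fail,
        "qc_min_genes": expr.qc_min_genes,
    }
    return SyntheticDataset(expression=em, cell_metadata=metadata, truth=truth)


def simulate_survival(config: SimulationConfig) -> pd.DataFrame:
    """Exponential survival with hazard set by a marker-high/low stratum."""
    rng = np.random.default_rng(config.seed + 2)
    surv = config.survival
    rows = []
    for i in range(surv.n_patients):
        high = i % 2 == 0
        marker = surv.marker_cutpoint + (1 if high else -1) * (
            1.0 + abs(rng.normal(0, surv.marker_spread)))
        hazard = surv.hazard_high if high else surv.hazard_low
        event_time = rng.exponential(365.0 / hazard)
        censor_time = surv.censor_time
        if surv.censoring_rate >= 1.0:
            censor_time = 0.0
        elif surv.censoring_rate > 0 and rng.random() < surv.censoring_rate:
            censor_time = rng.uniform(1.0, surv.censor_time)
        time = min(event_time, censor_time)
        event = event_time <= censor_time
        rows.append({"id": f"P{i:03d}", "time_days": max(time, 1e-3),
                     "event": bool(event), "marker": float(marker),
                     "true_stratum": "high" if high else "low"})
    return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full cohort: repertoire + expression (shared barcodes) + survival."""
    rep_ds = simulate_repertoire(config)
    barcodes_by_group = {
        g.name: rep_ds.cell_metadata.index[rep_ds.cell_metadata["group"] == g.name].tolist()
        for g in config.groups
    }
    expr_ds = simulate_expression(config, barcodes_by_group)
    survival = simulate_survival(config)
    truth = {**rep_ds.truth, **expr_ds.truth,
             "hazard_ratio": config.survival.hazard_high / config.survival.hazard_low}
    return SyntheticDataset(contigs=rep_ds.contigs, cell_metadata=rep_ds.cell_metadata,
                            expression=expr_ds.expression, survival=survival, truth=truth)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write every artifact as plain text; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    if dataset.contigs:
        p10x = outdir / "contigs_10x.csv"
        pairr = outdir / "contigs_airr.tsv"
        write_contigs(dataset.contigs, p10x, dialect="10x-contig-csv")
        write_contigs(dataset.contigs, pairr, dialect="airr-tsv")
        paths["contigs_10x"] = str(p10x)
        paths["contigs_airr"] = str(pairr)
    if dataset.cell_metadata is not None:
        pmeta = outdir / "cell_metadata.csv"
        dataset.cell_metadata.to_csv(pmeta, index_label="barcode")
        paths["cell_metadata"] = str(pmeta)
    if dataset.expression is not None:
        write_mtx_bundle(dataset.expression, outdir / "expression")
        paths["expression"] = str(outdir / "expression")
        isg = dataset.truth.get("isg_genes")
        if isg:
            gmt = outdir / "gene_sets.gmt"
            write_gmt([GeneSet("ISG", tuple(isg))], gmt)
            paths["gene_sets"] = str(gmt)
    if dataset.survival is not None:
        psurv = outdir / "survival.csv"
        dataset.survival.to_csv(psurv, index=False)
        paths["survival"] = str(psurv)
    ptruth = outdir / "ground_truth.json"
    with open(ptruth, "w") as handle:
        json.dump(dataset.truth, handle, indent=1, sort_keys=True)
    paths["ground_truth"] = str(ptruth)
    return paths
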