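"""Clone assignment for BCR and TCR repertoires.

BCR clones: cells are first partitioned by heavy-chain V gene, J gene and
junction length, then single-linkage clustered within each partition using
a strict normalized Hamming distance threshold on the nucleotide junction.
TCR clonotypes: exact identity of the paired (V, J, junction_nt) tuples of
both chains.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .repertoire_io import CellChainSet

logger = logging.getLogger(__name__)

_ALLELE_SUFFIX = re.compile(r"\*.*$")

EXPANSION_BINS = (
    (1, 1, "unique"),
    (2, 2, "double"),
    (3, 5, "small"),
    (6, 20, "medium"),
    (21, None, "large"),
)


def strip_allele(gene: str) -> str:
    """Drop the IMGT allele suffix: ``IGHV3-23*01`` -> ``IGHV3-23``."""
    return _ALLELE_SUFFIX.sub("", gene.strip())


@dataclass(frozen=True)
class BcrCloneKey:
    v_gene: str
    j_gene: str
    junction_length: int

    def __post_init__(self) -> None:
        if self.junction_length <= 0:
            raise ValueError("junction_length must be positive")
        if not self.v_gene or not self.j_gene:
            raise ValueError("gene names must be non-empty")


@dataclass
class CloneAssignment:
    """Cell-to-clone mapping with per-clone sizes and expansion labels."""

    receptor_type: str
    cell_to_clone: dict[str, str]
    clone_members: dict[str, list[str]]
    expansion_level: dict[str, str] = field(default_factory=dict)

    @property
    def clone_sizes(self) -> dict[str, int]:
        return {cid: len(members) for cid, members in self.clone_members.items()}

    @property
    def n_cells(self) -> int:
        return len(self.cell_to_clone)

    def expanded(self, clone_id: str) -> bool:
        return len(self.clone_members[clone_id]) > 1


def normalized_hamming(junction_a: str, junction_b: str) -> float:
    """Fraction of mismatching positions between two equal-length strings.

    Comparison is case-insensitive.  Unequal lengths are a contract
    violation (the V/J/length partition guarantees equality upstream).
    """
    if len(junction_a) != len(junction_b):
        raise ValueError(
            f"junction lengths differ ({len(junction_a)} vs {len(junction_b)})"
        )
    if not junction_a:
        raise ValueError("junctions must be non-empty")
    a, b = junction_a.upper(), junction_b.upper()
    return sum(x != y for x, y in zip(a, b)) / len(a)


def _connected_components(n: int, edges: list[tuple[int, int]]) -> list[int]:
    """Union-find component labels, relabeled by first member index."""
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = [find(i) for i in range(n)]
    order: dict[int, int] = {}
    labels = []
    for r in roots:
        if r not in order:
            order[r] = len(order)
        labels.append(order[r])
    return labels


def group_bcr_clones(cells: Sequence[CellChainSet], threshold: float = 0.1) -> CloneAssignment:
    """Assign BCR cells to clones by V/J/junction-length partition plus
    single-linkage clustering at strict normalized Hamming ``< threshold``.

    Clone IDs are deterministic: partition key plus component index in
    first-cell order.  Cells lacking a heavy-chain junction are excluded
    with a warning.
    """
    partitions: dict[BcrCloneKey, list[CellChainSet]] = {}
    for cell in cells:
        heavy = cell.heavy
        if not heavy.junction_nt:
            logger.warning("cell %s lacks a heavy-chain junction; excluded", cell.barcode)
            continue
        key = BcrCloneKey(
            v_gene=strip_allele(heavy.v_call),
            j_gene=strip_allele(heavy.j_call),
            junction_length=len(heavy.junction_nt),
        )
        partitions.setdefault(key, []).append(cell)

    cell_to_clone: dict[str, str] = {}
    clone_members: dict[str, list[str]] = {}
    for key, members in partitions.items():
        junctions = [c.heavy.junction_nt for c in members]
        n = len(members)
        edges = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if normalized_hamming(junctions[i], junctions[j]) < threshold
        ]
        labels = _connected_components(n, edges)
        prefix = f"{key.v_gene}|{key.j_gene}|{key.junction_length}"
        for cell, lab in zip(members, labels):
            clone_id = f"{prefix}|c{lab}"
            cell_to_clone[cell.barcode] = clone_id
            clone_members.setdefault(clone_id, []).append(cell.barcode)

    return assign_expansion_level(
        CloneAssignment("BCR", cell_to_clone, clone_members)
    )


def call_tcr_clonotypes(cells: Sequence[CellChainSet]) -> CloneAssignment:
    """Exact paired-chain TCR clonotypes.

    Two cells share a clonotype iff both the TRA and the TRB
    (v_gene, j_gene, junction_nt) tuples are identical (allele-stripped).
    """
    cell_to_clone: dict[str, str] = {}
    clone_members: dict[str, list[str]] = {}
    key_to_id: dict[tuple, str] = {}
    for cell in cells:
        alpha, beta = cell.light, cell.heavy
        key = (
            strip_allele(alpha.v_call), strip_allele(alpha.j_call), alpha.junction_nt.upper(),
            strip_allele(beta.v_call), strip_allele(beta.j_call), beta.junction_nt.upper(),
        )
        if key not in key_to_id:
            key_to_id[key] = f"tcr_c{len(key_to_id)}"
        clone_id = key_to_id[key]
        cell_to_clone[cell.barcode] = clone_id
        clone_members.setdefault(clone_id, []).append(cell.barcode)
    return assign_expansion_level(
        CloneAssignment("TCR", cell_to_clone, clone_members)
    )


def expansion_label(size: int) -> str:
    """Map a clone size onto the expansion-level bins."""
    if size < 1:
        raise ValueError("clone size must be >= 1")
    for low, high, label in EXPANSION_BINS:
        if size >= low and (high is None or size <= high):
            return label
    raise AssertionError("unreachable")


def assign_expansion_level(assignment: CloneAssignment) -> CloneAssignment:
    """Populate expansion-level labels from clone sizes (in place)."""
    assignment.expansion_level = {
        cid: expansion_label(size) for cid, size in assignment.clone_sizes.items()
    }
    return assignment


def clone_table(assignment: CloneAssignment) -> "list[dict]":
    """Flat per-clone rows for TSV export."""
    rows = []
    for cid, members in assignment.clone_members.items():
        rows.append({
            "clone_id": cid,
            "receptor": assignment.receptor_type,
            "size": len(members),
            "expansion_level": assignment.expansion_level.get(cid, expansion_label(len(members))),
            "members": ";".join(members),
        })
    return rows
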