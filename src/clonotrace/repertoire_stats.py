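"""Diversity, clonality, sharing, usage-preference and transition statistics.

Entropy is in bits throughout so that clonality = 1 - H/log2(N) lies in
[0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clonotyping import CloneAssignment


class UndefinedStatisticError(ValueError):
    """A statistic has no defined value on the given input."""


@dataclass
class CloneFrequencyTable:
    """Clone cell-counts within one stratum (donor, group, or cluster)."""

    stratum: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise UndefinedStatisticError(f"empty clone table for stratum {self.stratum!r}")
        for cid, c in self.counts.items():
            if c <= 0 or c != int(c):
                raise ValueError(f"clone {cid!r}: count must be a positive integer, got {c!r}")

    @property
    def total_cells(self) -> int:
        return sum(self.counts.values())

    @property
    def n_clones(self) -> int:
        return len(self.counts)

    @property
    def frequencies(self) -> np.ndarray:
        arr = np.asarray(list(self.counts.values()), dtype=float)
        return arr / arr.sum()

    @classmethod
    def from_assignment(cls, assignment: CloneAssignment, stratum: str = "all",
                        cells: Iterable[str] | None = None) -> "CloneFrequencyTable":
        """Build from a clone assignment, optionally restricted to a cell subset."""
        counts: dict[str, int] = {}
        pool = assignment.cell_to_clone.items()
        if cells is not None:
            keep = set(cells)
            pool = ((b, c) for b, c in pool if b in keep)
        for _, clone in pool:
            counts[clone] = counts.get(clone, 0) + 1
        return cls(stratum=stratum, counts=counts)


@dataclass(frozen=True)
class RepertoireMetrics:
    stratum: str
    entropy_bits: float
    clonality: float
    n_clones: int
    total_cells: int


@dataclass(frozen=True)
class ClonotypeSet:
    stratum: str
    clone_ids: frozenset[str]
    expanded_only: bool = False

    @classmethod
    def from_assignment(cls, assignment: CloneAssignment, stratum: str = "all",
                        cells: Iterable[str] | None = None,
                        expanded_only: bool = False) -> "ClonotypeSet":
        table = CloneFrequencyTable.from_assignment(assignment, stratum, cells)
        ids = {
            cid for cid, _ in table.counts.items()
            if not expanded_only or len(assignment.clone_members[cid]) > 1
        }
        return cls(stratum=stratum, clone_ids=frozenset(ids), expanded_only=expanded_only)


def shannon_entropy(table: CloneFrequencyTable) -> float:
    """Shannon entropy H = -sum p_i log2 p_i in bits; empty p terms contribute 0."""
    p = table.frequencies
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def clonality(table: CloneFrequencyTable) -> float:
    """1 - H/log2(N).  A single-clone repertoire is maximally clonal (1.0)."""
    n = table.n_clones
    if n == 1:
        return 1.0
    value = 1.0 - shannon_entropy(table) / math.log2(n)
    # clamp float-noise at the uniform boundary
    return float(min(1.0, max(0.0, value)))


def repertoire_metrics(table: CloneFrequencyTable) -> RepertoireMetrics:
    return RepertoireMetrics(
        stratum=table.stratum,
        entropy_bits=shannon_entropy(table),
        clonality=clonality(table),
        n_clones=table.n_clones,
        total_cells=table.total_cells,
    )


def jaccard_index(a: ClonotypeSet, b: ClonotypeSet) -> float:
    """|A intersect B| / |A union B|.  Both-empty is undefined."""
    union = a.clone_ids | b.clone_ids
    if not union:
        raise UndefinedStatisticError("Jaccard index undefined: both sets empty")
    return len(a.clone_ids & b.clone_ids) / len(union)


def top_n_frequency(table: CloneFrequencyTable, n: int = 20) -> float:
    """Summed frequency of the ``n`` largest clones (all of them if N < n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    freqs = np.sort(table.frequencies)[::-1]
    return float(freqs[:n].sum())


@dataclass
class GroupPreferenceMatrix:
    """Observed vs independence-expected cell counts per cluster x group."""

    observed: pd.DataFrame       # clusters x groups
    expected: pd.DataFrame
    roe: pd.DataFrame            # observed / expected; NaN where expected == 0


def roe(observed: pd.DataFrame) -> GroupPreferenceMatrix:
    """Ratio of observed to randomly expected cell counts, R_O/E.

    ``expected[c, g] = row_total_c * col_total_g / grand_total``; rows or
    columns with a zero margin yield NaN ratios for that slice.
    """
    obs = observed.astype(float)
    if (obs.to_numpy() < 0).any():
        raise ValueError("observed counts must be non-negative")
    grand = obs.to_numpy().sum()
    if grand == 0:
        raise UndefinedStatisticError("empty contingency table")
    expected = pd.DataFrame(
        np.outer(obs.sum(axis=1), obs.sum(axis=0)) / grand,
        index=obs.index, columns=obs.columns,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = obs / expected
    return GroupPreferenceMatrix(observed=obs, expected=expected, roe=ratio)


@dataclass(frozen=True)
class TransitionIndex:
    cluster_i: str
    cluster_j: str
    ptran: float
    n_clones: int


def pairwise_transition_index(
    assignment: CloneAssignment,
    cluster_labels: Mapping[str, str],
    cluster_i: str,
    cluster_j: str,
) -> TransitionIndex:
    """Clonal transition index between two clusters (pairwise STARTRAC-tran).

    Each clone is restricted to its cells in the two clusters; its
    contribution is the binary Shannon entropy of the split, weighted by the
    clone's cell count there.  0 means every clone is confined to one
    cluster; 1 means all shared clones split 50/50.
    """
    if cluster_i == cluster_j:
        raise ValueError("clusters must differ")
    weights: list[int] = []
    entropies: list[float] = []
    n_contributing = 0
    for clone_id, members in assignment.clone_members.items():
        n_i = sum(1 for b in members if cluster_labels.get(b) == cluster_i)
        n_j = sum(1 for b in members if cluster_labels.get(b) == cluster_j)
        m = n_i + n_j
        if m == 0:
            continue
        h = 0.0
        for n_k in (n_i, n_j):
            if n_k > 0:
                q = n_k / m
                h -= q * math.log2(q)
        weights.append(m)
        entropies.append(h)
        n_contributing += 1
    total = sum(weights)
    if total == 0:
        raise UndefinedStatisticError(
            f"no cells in clusters {cluster_i!r} or {cluster_j!r}"
        )
    ptran = sum(w * h for w, h in zip(weights, entropies)) / total
    return TransitionIndex(cluster_i, cluster_j, float(ptran), n_contributing)


def transition_matrix(assignment: CloneAssignment,
                      cluster_labels: Mapping[str, str]) -> pd.DataFrame:
    """Symmetric matrix of pairwise transition indices over all clusters."""
    clusters = sorted(set(cluster_labels.values()))
    mat = pd.DataFrame(np.nan, index=clusters, columns=clusters)
    for i, ci in enumerate(clusters):
        for cj in clusters[i + 1:]:
            try:
                t = pairwise_transition_index(assignment, cluster_labels, ci, cj)
            except UndefinedStatisticError:
                continue
            mat.loc[ci, cj] = mat.loc[cj, ci] = t.ptran
    return mat


@dataclass
class VGeneUsageTable:
    """Per-group V-gene usage frequencies (each group sums to 1)."""

    counts: pd.DataFrame  # genes x groups, integer counts

    @property
    def frequencies(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        return self.counts / totals

    @classmethod
    def from_gene_lists(cls, usage_by_group: Mapping[str, Sequence[str]]) -> "VGeneUsageTable":
        series = {g: pd.Series(genes).value_counts() for g, genes in usage_by_group.items()}
        counts = pd.DataFrame(series).fillna(0).astype(int)
        return cls(counts=counts)


def vgene_log2fc(usage: VGeneUsageTable, group_a: str, group_b: str,
                 pseudocount: float = 0.5) -> pd.Series:
    """Per-gene log2 fold change of usage frequency, group_a over group_b.

    A pseudocount is added to both counts and totals so genes absent from
    one group stay finite.
    """
    counts = usage.counts
    for g in (group_a, group_b):
        if g not in counts.columns or counts[g].sum() == 0:
            raise ValueError(f"group {g!r} absent or empty")
    k = counts.shape[0]
    fa = (counts[group_a] + pseudocount) / (counts[group_a].sum() + pseudocount * k)
    fb = (counts[group_b] + pseudocount) / (counts[group_b].sum() + pseudocount * k)
    return np.log2(fa / fb).rename(f"log2fc_{group_a}_vs_{group_b}")
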