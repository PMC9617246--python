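"""Somatic hypermutation quantification and selection-strength estimation.

Mutations are counted against an IMGT-gapped germline over the V-region
framework and CDR1/2 (nt positions 1-312; the junction/CDR3 has no germline
and is excluded).  Each mismatch is classified replacement (R) or silent
(S) by substituting the observed base into the germline codon one change at
a time.  Selection strength is a signed Beta-binomial log-odds statistic:
the posterior mean log2-odds of the replacement fraction minus the neutral
log2-odds expected from single-nucleotide codon enumeration.  Positive
values indicate enrichment of replacement mutations (positive selection).

This is a uniform-targeting simplification of full BASELINe-style
frameworks: no mutability hot/cold-spot model is applied, so absolute
magnitudes are not comparable with those tools, but the sign and ordering
semantics are preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import psi
from scipy.stats import beta as beta_dist

from Bio.Seq import Seq

# IMGT V-region nucleotide boundaries (1-based, inclusive)
REGION_BOUNDS: dict[str, tuple[int, int]] = {
    "FWR1": (1, 78),
    "CDR1": (79, 114),
    "FWR2": (115, 165),
    "CDR2": (166, 195),
    "FWR3": (196, 312),
}
V_REGION_END = 312
CDR_REGIONS = ("CDR1", "CDR2")
FWR_REGIONS = ("FWR1", "FWR2", "FWR3")

_BASES = "ACGT"


class AlignmentError(ValueError):
    """Alignment structure violates the analysis frame assumptions."""


class UndefinedSelectionError(ValueError):
    """Selection strength is undefined (e.g. no observed mutations)."""


def region_of(position: int) -> str | None:
    """IMGT region name for a 1-based nt position, or None beyond the V region."""
    for name, (lo, hi) in REGION_BOUNDS.items():
        if lo <= position <= hi:
            return name
    return None


@dataclass(frozen=True)
class GermlineAlignment:
    """Equal-length observed/germline IMGT-gapped nucleotide strings."""

    observed: str
    germline: str

    def __post_init__(self) -> None:
        if len(self.observed) != len(self.germline):
            raise AlignmentError("observed and germline lengths differ")
        if len(self.germline) < 3:
            raise AlignmentError("alignment shorter than one codon")


@dataclass
class MutationProfile:
    """Replacement/silent counts per region plus coverage information."""

    r_counts: dict[str, int]
    s_counts: dict[str, int]
    informative_positions: int

    @property
    def total_mismatches(self) -> int:
        return sum(self.r_counts.values()) + sum(self.s_counts.values())

    def region_class_counts(self, region_class: str) -> tuple[int, int]:
        """(R, m) summed over CDR1+2 or FWR1+2+3."""
        regions = CDR_REGIONS if region_class == "CDR" else FWR_REGIONS
        r = sum(self.r_counts[x] for x in regions)
        s = sum(self.s_counts[x] for x in regions)
        return r, r + s


@dataclass(frozen=True)
class SelectionResult:
    region_class: str
    p_exp: float
    r: int
    m: int
    sigma: float
    ci_low: float
    ci_high: float


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def count_mutations(aln: GermlineAlignment) -> MutationProfile:
    """Classify every informative mismatch in the V region as R or S.

    A position is informative when both the observed and germline characters
    are in ACGT.  Classification substitutes the observed base into the
    germline codon at that position alone; an amino-acid change or a new
    stop codon counts as replacement.
    """
    obs = aln.observed.upper()
    germ = aln.germline.upper()
    limit = min(len(germ), V_REGION_END)

    r_counts = {name: 0 for name in REGION_BOUNDS}
    s_counts = {name: 0 for name in REGION_BOUNDS}
    informative = 0
    for idx in range(limit):
        pos = idx + 1
        region = region_of(pos)
        if region is None:
            continue
        o, g = obs[idx], germ[idx]
        if o not in _BASES or g not in _BASES:
            continue
        informative += 1
        if o == g:
            continue
        codon_start = (idx // 3) * 3
        germ_codon = germ[codon_start:codon_start + 3]
        if len(germ_codon) < 3 or any(c not in _BASES for c in germ_codon):
            continue  # codon not readable; mismatch uninformative for R/S
        mutated = list(germ_codon)
        mutated[idx - codon_start] = o
        if _translate("".join(mutated)) != _translate(germ_codon):
            r_counts[region] += 1
        else:
            s_counts[region] += 1
    return MutationProfile(r_counts=r_counts, s_counts=s_counts,
                           informative_positions=informative)


def shm_frequency(profile: MutationProfile) -> float:
    """Total mismatches over informative V-region positions."""
    if profile.informative_positions == 0:
        raise UndefinedSelectionError("no informative positions")
    return profile.total_mismatches / profile.informative_positions


def expected_replacement_fraction(germline: str, region_class: str) -> float:
    """Neutral replacement fraction from exhaustive single-nt codon variants.

    For each readable germline codon in the region class, all 9 single-base
    variants are enumerated; the fraction that change the amino acid (or
    create a stop) is the uniform-targeting expectation.
    """
    germ = germline.upper()
    regions = CDR_REGIONS if region_class == "CDR" else FWR_REGIONS
    n_variants = 0
    n_replacement = 0
    limit = min(len(germ), V_REGION_END)
    for codon_start in range(0, limit - 2, 3):
        # codon must lie wholly within one region of the requested class
        codon_regions = {region_of(codon_start + k + 1) for k in range(3)}
        if len(codon_regions) != 1 or codon_regions.pop() not in regions:
            continue
        codon = germ[codon_start:codon_start + 3]
        if any(c not in _BASES for c in codon):
            continue
        aa = _translate(codon)
        for k in range(3):
            for base in _BASES:
                if base == codon[k]:
                    continue
                variant = codon[:k] + base + codon[k + 1:]
                n_variants += 1
                if _translate(variant) != aa:
                    n_replacement += 1
    if n_variants == 0:
        raise AlignmentError(f"no readable codons in {region_class} regions")
    return n_replacement / n_variants


def codon_replacement_fraction(codon: str) -> float:
    """Neutral replacement fraction of a single codon (9-variant enumeration)."""
    codon = codon.upper()
    if len(codon) != 3 or any(c not in _BASES for c in codon):
        raise ValueError(f"invalid codon {codon!r}")
    aa = _translate(codon)
    changed = 0
    for k in range(3):
        for base in _BASES:
            if base == codon[k]:
                continue
            if _translate(codon[:k] + base + codon[k + 1:]) != aa:
                changed += 1
    return changed / 9


def selection_sigma(r: int, m: int, p_exp: float,
                    ci: float = 0.95, region_class: str = "") -> SelectionResult:
    """Posterior-mean log2-odds selection strength with a credible interval.

    The replacement probability p has posterior Beta(r+1, m-r+1) under a
    uniform prior; sigma = E[log2(p/(1-p))] - log2(p_exp/(1-p_exp)).  The
    credible interval maps Beta quantiles through the same monotone
    transform.
    """
    if m < 1:
        raise UndefinedSelectionError("no observed mutations (m = 0)")
    if not (0 <= r <= m):
        raise ValueError("require 0 <= r <= m")
    if not (0.0 < p_exp < 1.0):
        raise ValueError("require 0 < p_exp < 1")
    a, b = r + 1, m - r + 1
    base_odds = math.log2(p_exp / (1.0 - p_exp))
    sigma = (psi(a) - psi(b)) / math.log(2) - base_odds
    alpha = (1.0 - ci) / 2.0
    q_low, q_high = beta_dist.ppf([alpha, 1.0 - alpha], a, b)
    ci_low = math.log2(q_low / (1.0 - q_low)) - base_odds
    ci_high = math.log2(q_high / (1.0 - q_high)) - base_odds
    return SelectionResult(region_class=region_class, p_exp=p_exp, r=r, m=m,
                           sigma=float(sigma), ci_low=float(ci_low),
                           ci_high=float(ci_high))


def analyze_sequence(aln: GermlineAlignment) -> dict[str, object]:
    """Per-sequence SHM frequency and CDR/FWR selection strengths.

    Selection values are None when a region class has no mutations.
    """
    profile = count_mutations(aln)
    out: dict[str, object] = {
        "shm_frequency": shm_frequency(profile),
        "total_mutations": profile.total_mismatches,
    }
    for region_class in ("CDR", "FWR"):
        r, m = profile.region_class_counts(region_class)
        key = region_class.lower()
        if m == 0:
            out[f"sigma_{key}"] = None
            continue
        p_exp = expected_replacement_fraction(aln.germline, region_class)
        result = selection_sigma(r, m, p_exp, region_class=region_class)
        out[f"sigma_{key}"] = result.sigma
        out[f"sigma_{key}_ci_low"] = result.ci_low
        out[f"sigma_{key}_ci_high"] = result.ci_high
    return out
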