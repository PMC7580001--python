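"""Recurrence screen for burdened domain families.

A family makes the final list only if its in-domain mutations are
(1) spread over enough genomes (an absolute count, or a ceiling of a
cohort fraction — 6.4% of a 468-patient cohort gives 30), (2) unlikely
under the uniform-placement null (exact tail p < 0.05), and (3) spread
evenly rather than driven by one member gene (normalized Shannon entropy
>= 0.71).  Benjamini-Hochberg q-values are reported alongside but the
default pass/fail uses the raw p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .burden import DomainFamilyStats

__all__ = [
    "ScreenThresholds",
    "normalized_entropy",
    "family_entropy",
    "bh_fdr",
    "annotate",
    "screen_families",
]

EntropyAxis = Literal["gene", "patient", "position"]


@dataclass
class ScreenThresholds:
    """Thresholds of the three-part recurrence screen.

    min_genome_fraction is turned into an absolute cutoff by ceiling
    (ceil(0.064 * 468) = 30); an explicit ``min_genomes`` overrides it.
    p is compared strictly (< p_max); genomes and entropy are non-strict
    (>=).
    """

    min_genome_fraction: float = 0.064
    min_genomes: Optional[int] = None
    p_max: float = 0.05
    entropy_min: float = 0.71
    fdr_q: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.min_genome_fraction < 1.0):
            raise ValueError("min_genome_fraction must lie in (0, 1)")
        if self.min_genomes is not None and self.min_genomes < 1:
            raise ValueError("min_genomes must be positive")
        if not (0.0 < self.p_max <= 1.0):
            raise ValueError("p_max must lie in (0, 1]")
        if not (0.0 <= self.entropy_min <= 1.0):
            raise ValueError("entropy_min must lie in [0, 1]")

    def genome_cutoff(self, cohort_size: int) -> int:
        if self.min_genomes is not None:
            return self.min_genomes
        return math.ceil(self.min_genome_fraction * cohort_size)


def normalized_entropy(counts, m: Optional[int] = None) -> float:
    """Normalized Shannon entropy H = -sum f_i ln f_i / ln m in [0, 1].

    ``m`` defaults to the number of categories carrying mass; H is 0 for a
    single category (or all mass concentrated in one) and 1 for uniform
    mass over m categories.
    """
    c = np.asarray(counts, dtype=float).ravel()
    if c.size == 0 or np.any(c < 0):
        raise ValueError("counts must be a non-empty non-negative vector")
    total = c.sum()
    if total <= 0:
        raise ValueError("counts must have positive total mass")
    nz = c[c > 0]
    if m is None:
        m = nz.size
    if m < 1:
        raise ValueError("m must be >= 1")
    if m == 1 or nz.size == 1:
        return 0.0
    f = nz / total
    h = -np.sum(f * np.log(f))
    return float(h / math.log(m))


def family_entropy(
    stats: DomainFamilyStats,
    axis: EntropyAxis = "gene",
    normalization: Literal["active", "all"] = "active",
) -> float:
    """Entropy of a family's in-domain mutations along a chosen axis.

    axis="gene" (default): distribution over member genes, quantifying
    whether recurrence is spread across genes or driven by one gene.
    axis="patient": distribution over patients; axis="position":
    distribution over residue positions (per gene+position category).
    normalization="active" uses m = categories carrying mass, "all" uses
    m = all member genes (gene axis only).
    """
    hits = stats.in_domain_mutations
    if hits is None or hits.empty:
        return float("nan")
    if axis == "gene":
        counts = hits.groupby("gene").size().to_numpy()
        m = stats.n_genes if normalization == "all" else None
    elif axis == "patient":
        counts = hits.groupby("patient_id").size().to_numpy()
        m = None
    elif axis == "position":
        counts = hits.groupby(["gene", "protein_pos"]).size().to_numpy()
        m = None
    else:
        raise ValueError(f"unknown entropy axis {axis!r}")
    return normalized_entropy(counts, m=m)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def annotate(
    stats_list: Sequence[DomainFamilyStats],
    cohort_size: int,
    *,
    entropy_axis: EntropyAxis = "gene",
    entropy_normalization: Literal["active", "all"] = "active",
) -> list[DomainFamilyStats]:
    """Fill genome_fraction, entropy and BH q-values in place."""
    for st in stats_list:
        st.genome_fraction = st.genomes_hit / cohort_size
        st.entropy = family_entropy(st, axis=entropy_axis,
                                    normalization=entropy_normalization)
    ps = np.array([st.p_value for st in stats_list], dtype=float)
    if np.all(np.isfinite(ps)) and ps.size:
        qs = bh_fdr(ps)
        for st, q in zip(stats_list, qs):
            st.q_value = float(q)
    return list(stats_list)


def screen_families(
    stats_list: Sequence[DomainFamilyStats],
    thresholds: ScreenThresholds,
    cohort_size: int,
) -> list[DomainFamilyStats]:
    """Apply the three-part screen; return passing families sorted by
    ascending p-value (ties broken by family accession).

    A family passes iff genomes_hit >= genome cutoff, p_value < p_max and
    entropy >= entropy_min; if ``fdr_q`` is set, q_value <= fdr_q is also
    required.
    """
    cutoff = thresholds.genome_cutoff(cohort_size)
    passing = []
    for st in stats_list:
        if st.genomes_hit < cutoff:
            continue
        if not (st.p_value < thresholds.p_max):
            continue
        if not (st.entropy >= thresholds.entropy_min):
            continue
        if thresholds.fdr_q is not None and not (st.q_value <= thresholds.fdr_q):
            continue
        passing.append(st)
    return sorted(passing, key=lambda s: (s.p_value, s.family_acc))
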