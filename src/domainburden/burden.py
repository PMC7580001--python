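"""Domain-burden statistic: exact Poisson-binomial tail test.

The model: a somatic mutation in a gene is assumed (i) uniformly
distributed along the protein and (ii) independent of every other mutation.
A gene of protein length L carrying a domain family whose instance spans
cover S residues therefore contributes, for each of its n_i eligible
mutations, one Bernoulli trial with success probability p_i = S / L
("success" = the mutation falls inside the domain-coding region).  Summed
over the family's member genes, the number N of in-domain mutations follows
a Poisson-binomial distribution; the burden p-value is its exact upper
tail at the observed count, computed by dynamic programming rather than by
permutation, which keeps deep tails (below 1e-7) accurate.

The DP recurrence is the prefix convolution
``f_j(k) = f_{j-1}(k) (1-p_j) + f_{j-1}(k-1) p_j``.
All terms are non-negative, so double-precision round-off stays relative
(no cancellation); a log-space variant is available for tails that
underflow doubles entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import VariantClass

logger = logging.getLogger(__name__)

__all__ = [
    "GeneDomainProfile",
    "DomainFamilyStats",
    "span_union_length",
    "domain_hit_probability",
    "poisson_binomial_pmf",
    "poisson_binomial_logpmf",
    "poisson_binomial_tail",
    "tally_family",
    "tally_all_families",
    "family_test",
    "DEFAULT_ELIGIBLE_CLASSES",
]

#: Only missense mutations enter the burden test by default; indels and
#: truncating events have different positional models.
DEFAULT_ELIGIBLE_CLASSES: frozenset[VariantClass] = frozenset({VariantClass.MISSENSE})


@dataclass
class GeneDomainProfile:
    """Per-gene trial summary for one domain family.

    ``p`` is the per-mutation probability S/L of hitting the family's
    (union of) spans; ``n`` the eligible mutation count in the gene;
    ``k`` the number of those inside the spans.
    """

    gene: str
    protein_length: int
    family_span: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n):
            raise ValueError(f"need 0 <= k <= n, got k={self.k}, n={self.n}")
        if not (0 < self.family_span <= self.protein_length):
            raise ValueError("family_span must be in (0, protein_length]")

    @property
    def p(self) -> float:
        return self.family_span / self.protein_length


@dataclass
class DomainFamilyStats:
    """Aggregated burden statistics for one domain family."""

    family_acc: str
    family_name: str
    member_profiles: list[GeneDomainProfile] = field(default_factory=list)
    n_obs: int = 0
    genomes_hit: int = 0
    genome_fraction: float = float("nan")
    entropy: float = float("nan")
    p_value: float = float("nan")
    q_value: float = float("nan")
    #: in-domain eligible mutations (patient_id, gene, protein_pos) kept for
    #: entropy axes and genome counting
    in_domain_mutations: Optional[pd.DataFrame] = None

    @property
    def n_genes(self) -> int:
        return len(self.member_profiles)

    @property
    def trial_probs(self) -> np.ndarray:
        """One Bernoulli probability per eligible mutation, concatenated
        over member genes."""
        return np.concatenate(
            [np.full(pr.n, pr.p) for pr in self.member_profiles]
        ) if self.member_profiles else np.empty(0)

    def to_row(self) -> dict:
        return {
            "family_acc": self.family_acc,
            "family_name": self.family_name,
            "n_genes": self.n_genes,
            "n_obs": self.n_obs,
            "genomes_hit": self.genomes_hit,
            "genome_fraction": self.genome_fraction,
            "entropy": self.entropy,
            "p_value": self.p_value,
            "q_value": self.q_value,
        }


def span_union_length(spans: Iterable[tuple[int, int]]) -> int:
    """Length of the union of 1-based inclusive intervals."""
    ordered = sorted(spans)
    if not ordered:
        return 0
    total = 0
    cur_start, cur_end = ordered[0]
    for s, e in ordered[1:]:
        if s <= cur_end + 1:
            cur_end = max(cur_end, e)
        else:
            total += cur_end - cur_start + 1
            cur_start, cur_end = s, e
    total += cur_end - cur_start + 1
    return total


def domain_hit_probability(instances, protein_length: Optional[int] = None) -> float:
    """Probability that a uniformly placed mutation hits the family's
    domain-coding region: |union of instance spans| / protein length.

    Overlapping instances of the same family are not double-counted.
    """
    insts = list(instances)
    if not insts:
        raise ValueError("need at least one domain instance")
    lengths = {i.protein_length for i in insts}
    if protein_length is None:
        if len(lengths) != 1:
            raise ValueError("instances disagree on protein_length")
        protein_length = lengths.pop()
    union = span_union_length((i.start, i.end) for i in insts)
    if union > protein_length:
        raise ValueError("span union exceeds protein length")
    return union / protein_length


def _validate_probs(probs) -> np.ndarray:
    p = np.asarray(probs, dtype=float).ravel()
    if p.size and (np.min(p) < 0.0 or np.max(p) > 1.0):
        raise ValueError("all probabilities must lie in [0, 1]")
    return p


def poisson_binomial_pmf(probs) -> np.ndarray:
    """Exact pmf of the sum of independent Bernoulli(p_j) trials.

    Returns a vector over k = 0..n computed by the DP prefix convolution;
    the vector sums to 1 to within ~1e-12 for n up to several thousand.
    """
    p = _validate_probs(probs)
    n = p.size
    f = np.zeros(n + 1)
    f[0] = 1.0
    for j, pj in enumerate(p, start=1):
        # one convolution step; slice ops keep this O(n) per trial
        f[1 : j + 1] = f[1 : j + 1] * (1.0 - pj) + f[0:j] * pj
        f[0] *= 1.0 - pj
    return f


def poisson_binomial_logpmf(probs) -> np.ndarray:
    """Log-space DP for regimes where pmf entries underflow doubles."""
    p = _validate_probs(probs)
    n = p.size
    with np.errstate(divide="ignore"):
        logp = np.log(p)
        log1mp = np.log1p(-p)
    f = np.full(n + 1, -np.inf)
    f[0] = 0.0
    for j in range(1, n + 1):
        stay = f[1 : j + 1] + log1mp[j - 1]
        move = f[0:j] + logp[j - 1]
        f[1 : j + 1] = np.logaddexp(stay, move)
        f[0] += log1mp[j - 1]
    return f


def poisson_binomial_tail(
    probs,
    k_obs: int,
    *,
    inclusive: bool = True,
    return_log: bool = False,
) -> float:
    """Exact upper-tail probability of a Poisson-binomial count.

    ``inclusive=True`` (default) returns P(N >= k_obs), the standard
    one-sided exact p-value; ``inclusive=False`` returns the strict
    P(N > k_obs).  When the double-precision tail underflows to zero the
    computation is redone in log space; with ``return_log=True`` the
    natural log of the tail is returned instead.
    """
    p = _validate_probs(probs)
    n = p.size
    if not (0 <= k_obs <= n):
        raise ValueError(f"k_obs must lie in [0, {n}], got {k_obs}")
    k0 = k_obs if inclusive else k_obs + 1
    if k0 > n:
        return -np.inf if return_log else 0.0
    pmf = poisson_binomial_pmf(p)
    # sum smallest-first for accuracy in deep tails
    tail = float(np.sum(pmf[k0:][::-1]))
    if tail == 0.0 or return_log:
        logpmf = poisson_binomial_logpmf(p)
        from scipy.special import logsumexp

        logtail = float(logsumexp(logpmf[k0:]))
        if return_log:
            return logtail
        return float(np.exp(logtail))
    return min(tail, 1.0)


def _eligible(mutations: pd.DataFrame, eligible_classes) -> pd.DataFrame:
    classes = {VariantClass(c).value for c in eligible_classes}
    mask = mutations["variant_class"].isin(classes) & mutations["protein_pos"].notna()
    return mutations.loc[mask]


def tally_family(
    mutations: pd.DataFrame,
    domains: pd.DataFrame,
    family_acc: str,
    *,
    eligible_classes=DEFAULT_ELIGIBLE_CLASSES,
    cohort_size: Optional[int] = None,
) -> DomainFamilyStats:
    """Tally eligible mutations inside/outside one family's domain spans.

    For each member gene (a gene with a retained instance of the family),
    ``n`` counts eligible mutations with a known protein position and
    ``k`` those falling inside the union of the family's instance spans
    (1-based inclusive on both ends).  ``genomes_hit`` counts distinct
    patients among in-domain mutations.
    """
    if not eligible_classes:
        raise ValueError("eligible_classes must be non-empty")
    fam = domains.loc[domains["family_acc"] == family_acc]
    if fam.empty:
        raise KeyError(f"family {family_acc!r} absent from the domain table")
    family_name = str(fam["family_name"].iloc[0])
    elig = _eligible(mutations, eligible_classes)
    stats = DomainFamilyStats(family_acc=family_acc, family_name=family_name)
    hits = []
    for gene, inst in fam.groupby("gene", sort=True):
        L = int(inst["protein_length"].iloc[0])
        spans = list(zip(inst["start"].astype(int), inst["end"].astype(int)))
        S = span_union_length(spans)
        gmut = elig.loc[elig["gene"] == gene]
        pos = gmut["protein_pos"].astype(int)
        in_dom = np.zeros(len(gmut), dtype=bool)
        for s, e in spans:
            in_dom |= (pos.values >= s) & (pos.values <= e)
        prof = GeneDomainProfile(
            gene=gene, protein_length=L, family_span=S,
            n=len(gmut), k=int(in_dom.sum()),
        )
        stats.member_profiles.append(prof)
        if in_dom.any():
            hits.append(gmut.loc[in_dom, ["patient_id", "gene", "protein_pos"]])
    stats.in_domain_mutations = (
        pd.concat(hits, ignore_index=True)
        if hits
        else pd.DataFrame(columns=["patient_id", "gene", "protein_pos"])
    )
    stats.n_obs = int(sum(pr.k for pr in stats.member_profiles))
    stats.genomes_hit = int(stats.in_domain_mutations["patient_id"].nunique())
    if cohort_size:
        stats.genome_fraction = stats.genomes_hit / cohort_size
    return stats


def tally_all_families(
    mutations: pd.DataFrame,
    domains: pd.DataFrame,
    *,
    eligible_classes=DEFAULT_ELIGIBLE_CLASSES,
    cohort_size: Optional[int] = None,
) -> list[DomainFamilyStats]:
    """Vectorised tally across every family in the domain table.

    Equivalent to calling :func:`tally_family` per family but built on a
    single mutations x instances join, which matters for cohorts with
    thousands of families.
    """
    if not eligible_classes:
        raise ValueError("eligible_classes must be non-empty")
    elig = _eligible(mutations, eligible_classes).copy()
    elig["protein_pos"] = elig["protein_pos"].astype(int)

    # per (family, gene): span union length and protein length
    fam_gene = []
    for (acc, name, gene), inst in domains.groupby(
        ["family_acc", "family_name", "gene"], sort=True
    ):
        fam_gene.append(
            {
                "family_acc": acc,
                "family_name": name,
                "gene": gene,
                "protein_length": int(inst["protein_length"].iloc[0]),
                "family_span": span_union_length(
                    zip(inst["start"].astype(int), inst["end"].astype(int))
                ),
            }
        )
    fg = pd.DataFrame(fam_gene)

    # eligible mutation count per gene
    n_per_gene = elig.groupby("gene").size()

    # in-domain hits: join mutations to instances on gene, test span
    joined = elig.merge(
        domains[["gene", "family_acc", "start", "end"]], on="gene", how="inner"
    )
    inside = joined.loc[
        (joined["protein_pos"] >= joined["start"])
        & (joined["protein_pos"] <= joined["end"])
    ]
    # a mutation inside two overlapping instances of one family counts once
    inside = inside.drop_duplicates(
        subset=["family_acc", "gene", "patient_id", "protein_pos"]
    )

    k_per = inside.groupby(["family_acc", "gene"]).size()
    hits_by_family = dict(tuple(inside.groupby("family_acc")))

    out: list[DomainFamilyStats] = []
    for (acc, name), grp in fg.groupby(["family_acc", "family_name"], sort=True):
        st = DomainFamilyStats(family_acc=acc, family_name=name)
        for r in grp.itertuples(index=False):
            st.member_profiles.append(
                GeneDomainProfile(
                    gene=r.gene,
                    protein_length=r.protein_length,
                    family_span=r.family_span,
                    n=int(n_per_gene.get(r.gene, 0)),
                    k=int(k_per.get((acc, r.gene), 0)),
                )
            )
        hits = hits_by_family.get(acc)
        st.in_domain_mutations = (
            hits[["patient_id", "gene", "protein_pos"]].reset_index(drop=True)
            if hits is not None
            else pd.DataFrame(columns=["patient_id", "gene", "protein_pos"])
        )
        st.n_obs = int(sum(pr.k for pr in st.member_profiles))
        st.genomes_hit = int(st.in_domain_mutations["patient_id"].nunique())
        if cohort_size:
            st.genome_fraction = st.genomes_hit / cohort_size
        out.append(st)
    return out


def family_test(
    stats: DomainFamilyStats,
    *,
    inclusive: bool = True,
) -> DomainFamilyStats:
    """Fill ``p_value`` with the exact Poisson-binomial upper tail at the
    observed in-domain count.

    Each of a member gene's n eligible mutations contributes one trial
    with that gene's hit probability p = S/L.  A family with zero trials
    is assigned p = 1 (nothing observable).
    """
    probs = stats.trial_probs
    if probs.size == 0:
        logger.info("family %s has zero trials; p_value = 1", stats.family_acc)
        stats.p_value = 1.0
        return stats
    stats.p_value = poisson_binomial_tail(probs, stats.n_obs, inclusive=inclusive)
    return stats
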