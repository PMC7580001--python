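"""Per-gene cohort statistics: mutation coverage, stage enrichment and the
subsample-consensus harness.

Mutation coverage (MC) of a gene in a patient group is the fraction of
group patients carrying at least one eligible mutation in the gene (a
patient with several mutations counts once).  Stage enrichment compares
carrier counts in one stage against the rest of the cohort with a
one-sided Fisher exact test.  The consensus harness re-runs any per-gene
significance function on seeded patient subsamples and intersects the
resulting gene lists, damping the sensitivity of such tests to individual
patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import Stage

__all__ = [
    "mutation_coverage",
    "coverage_table",
    "fisher_2x2",
    "stage_enrichment",
    "ConsensusResult",
    "subsample_consensus",
    "binomial_coverage_gene_test",
]


def _carriers(mutations: pd.DataFrame, gene: str,
              eligible_classes=None) -> set[str]:
    sub = mutations.loc[mutations["gene"] == gene]
    if eligible_classes is not None:
        classes = {getattr(c, "value", c) for c in eligible_classes}
        sub = sub.loc[sub["variant_class"].isin(classes)]
    return set(sub["patient_id"].astype(str))


def mutation_coverage(
    mutations: pd.DataFrame,
    cohort_patients: Iterable[str],
    gene: str,
    group: Optional[Iterable[str]] = None,
    *,
    eligible_classes=None,
) -> float:
    """Fraction of group patients carrying >= 1 eligible mutation in
    ``gene``.  ``group`` defaults to the whole cohort and must be a subset
    of it.  All variant classes are eligible by default (coverage counts
    any mutation, not only missense)."""
    cohort = set(map(str, cohort_patients))
    grp = cohort if group is None else set(map(str, group))
    if not grp:
        raise ValueError("patient group must be non-empty")
    if not grp <= cohort:
        raise ValueError("group must be a subset of the cohort")
    carriers = _carriers(mutations, gene, eligible_classes) & grp
    return len(carriers) / len(grp)


def fisher_2x2(
    a: int, b: int, c: int, d: int,
    sided: Literal["two-sided", "greater", "less"] = "two-sided",
) -> float:
    """Fisher exact p-value of the 2x2 table [[a, b], [c, d]].

    One-sided tails are exact hypergeometric tails; the two-sided value
    sums tables no more likely than the observed one.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError("all margins must be positive")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative=sided)[1])


def stage_enrichment(
    mutations: pd.DataFrame,
    clinical: pd.DataFrame,
    gene: str,
    stage: str | Stage,
    *,
    direction: Literal["enrichment", "depletion"] = "enrichment",
    eligible_classes=None,
) -> float:
    """One-sided Fisher exact p-value that carriers of ``gene`` are
    enriched (or depleted) in the given stage versus the rest of the
    cohort."""
    stage = Stage(stage).value
    in_stage = set(clinical.loc[clinical["stage"] == stage, "patient_id"].astype(str))
    rest = set(clinical["patient_id"].astype(str)) - in_stage
    if not in_stage:
        raise ValueError(f"no patients in stage {stage}")
    carriers = _carriers(mutations, gene, eligible_classes)
    a = len(carriers & in_stage)
    b = len(in_stage) - a
    c = len(carriers & rest)
    d = len(rest) - c
    sided = "greater" if direction == "enrichment" else "less"
    return fisher_2x2(a, b, c, d, sided=sided)


def coverage_table(
    mutations: pd.DataFrame,
    clinical: pd.DataFrame,
    genes: Optional[Sequence[str]] = None,
    *,
    eligible_classes=None,
) -> pd.DataFrame:
    """Per-gene MC overall, MC and carrier count per stage, and the
    one-sided stage-enrichment p-value for each stage."""
    cohort = set(clinical["patient_id"].astype(str))
    if genes is None:
        genes = sorted(mutations["gene"].unique())
    stage_groups = {
        s.value: set(
            clinical.loc[clinical["stage"] == s.value, "patient_id"].astype(str)
        )
        for s in Stage
    }
    rows = []
    for gene in genes:
        carriers = _carriers(mutations, gene, eligible_classes) & cohort
        row = {"gene": gene, "mc_overall": len(carriers) / len(cohort)}
        for s, grp in stage_groups.items():
            row[f"carriers_{s}"] = len(carriers & grp)
            row[f"mc_{s}"] = len(carriers & grp) / len(grp) if grp else float("nan")
            if grp and len(grp) < len(cohort):
                row[f"enrich_p_{s}"] = stage_enrichment(
                    mutations, clinical, gene, s,
                    eligible_classes=eligible_classes,
                )
            else:
                row[f"enrich_p_{s}"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


GeneTest = Callable[[pd.DataFrame, Sequence[str]], set[str]]


@dataclass
class ConsensusResult:
    consensus: set[str]
    per_run: dict[str, set[str]] = field(default_factory=dict)


def subsample_consensus(
    gene_test: GeneTest,
    mutations: pd.DataFrame,
    cohort_patients: Sequence[str],
    sizes: Sequence[int],
    seed: int,
    *,
    mode: Literal["intersection", "union", "majority"] = "intersection",
) -> ConsensusResult:
    """Run ``gene_test`` on the full cohort and on one seeded
    without-replacement subsample per size; combine the per-run gene sets.

    ``gene_test(mutations_subset, patients_subset) -> set of genes`` must
    be deterministic given its input.  The default combination is the
    intersection over all runs (the conservative consensus); union and
    majority (> half of runs) are selectable.  Per-run sets are retained
    for audit.
    """
    patients = [str(p) for p in cohort_patients]
    for s in sizes:
        if s > len(patients):
            raise ValueError(f"subsample size {s} exceeds cohort size {len(patients)}")
    runs: dict[str, set[str]] = {}
    runs["full"] = set(gene_test(mutations, patients))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(sizes))
    for size, child in zip(sizes, children):
        rng = np.random.default_rng(child)
        chosen = list(rng.choice(patients, size=size, replace=False))
        sub = mutations.loc[mutations["patient_id"].astype(str).isin(set(chosen))]
        runs[f"n{size}"] = set(gene_test(sub, chosen))
    sets = list(runs.values())
    if mode == "intersection":
        consensus = set.intersection(*sets)
    elif mode == "union":
        consensus = set.union(*sets)
    elif mode == "majority":
        from collections import Counter

        counts = Counter(g for s in sets for g in s)
        consensus = {g for g, c in counts.items() if c > len(sets) / 2}
    else:
        raise ValueError(f"unknown consensus mode {mode!r}")
    return ConsensusResult(consensus=consensus, per_run=runs)


def binomial_coverage_gene_test(
    *,
    q_max: float = 0.1,
    min_carriers: int = 3,
    eligible_classes=None,
) -> GeneTest:
    """Built-in per-gene significance function for the consensus harness.

    Tests each gene's carrier count against the cohort-wide median MC with
    a one-sided binomial test and keeps genes with BH q <= ``q_max``.
    This is a deliberately simple stand-in for covariate-aware
    significance callers; the harness accepts any such callable.
    """
    from statsmodels.stats.multitest import multipletests

    def _test(mutations: pd.DataFrame, patients: Sequence[str]) -> set[str]:
        cohort = [str(p) for p in patients]
        n = len(cohort)
        sub = mutations.loc[mutations["patient_id"].astype(str).isin(set(cohort))]
        if eligible_classes is not None:
            classes = {getattr(c, "value", c) for c in eligible_classes}
            sub = sub.loc[sub["variant_class"].isin(classes)]
        carriers = sub.groupby("gene")["patient_id"].nunique().sort_index()
        if carriers.empty:
            return set()
        baseline = max(float(np.median(carriers / n)), 1.0 / n)
        genes, ps = [], []
        for gene, k in carriers.items():
            if k < min_carriers:
                continue
            genes.append(gene)
            ps.append(sps.binomtest(int(k), n, baseline, alternative="greater").pvalue)
        if not genes:
            return set()
        q = multipletests(ps, method="fdr_bh")[1]
        return {g for g, qv in zip(genes, q) if qv <= q_max}

    return _test
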