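"""Synthetic tumor-cohort generator.

Generates (mutations, domains, clinical) bundles with exactly the
statistical structure the burden test assumes, so every downstream stage
can be exercised and calibrated without patient data:

* per-gene missense counts are Poisson with mean
  ``background_mutation_rate * n_patients``, and each missense mutation is
  placed uniformly over the protein — so under no enrichment the
  in-domain indicator is Bernoulli with probability exactly
  span / protein_length;
* planted enrichment multiplies the within-domain *odds* of the hit
  probability by a factor lambda >= 1 for selected families (lambda = 1
  recovers the null exactly);
* stages are multinomial; survival is exponential with the hazard
  multiplied by a configurable hazard ratio for patients carrying >= 1
  in-domain missense mutation in an enriched family, with independent
  uniform censoring.

A single master seed drives named child seeds per stage (genes,
mutations, clinical, survival) through numpy's SeedSequence spawning, so
identical configs give byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["CohortConfig", "CohortBundle", "generate_cohort", "null_cohort",
           "two_arm_exponential", "write_bundle"]

# Default stage mix (I, II, III) of a surgically staged 468-patient breast
# cohort: 89, 287 and 92 cases after merging stage IV into III.
_DEFAULT_STAGE_PROBS = (89 / 468, 287 / 468, 92 / 468)

# Variant-class mix for the non-missense background (descriptive only;
# the burden test consumes missense).
_OTHER_CLASSES = ("silent", "nonsense", "frameshift_indel",
                  "inframe_indel", "splice", "other")
_OTHER_CLASS_PROBS = (0.45, 0.12, 0.15, 0.05, 0.13, 0.10)
_VARIANT_TYPES = ("SNP", "DNP", "INS", "DEL")
_VARIANT_TYPE_PROBS = (0.93, 0.02, 0.02, 0.03)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate a 468-patient exome cohort in the regime the
    recurrence screen targets: large domain families (tens of member
    genes), ~0.005 expected missense mutations per gene per patient, and
    domains covering ~30% of their proteins.
    """

    n_patients: int = 468
    n_families: int = 200
    genes_per_family: int = 30
    protein_length_range: tuple[int, int] = (200, 800)
    domain_span_fraction: float = 0.3
    background_mutation_rate: float = 0.005
    #: family accession -> odds multiplier lambda (>= 1)
    enriched_families: dict[str, float] = field(default_factory=dict)
    other_class_rate_ratio: float = 0.6  # non-missense load relative to missense
    stage_probs: tuple[float, float, float] = _DEFAULT_STAGE_PROBS
    ilbc_fraction: float = 0.0
    baseline_hazard: float = 5e-4  # events per day; median ~1386 days
    hazard_ratio_domain_mut: float = 1.0
    censor_time: float = 3000.0  # uniform censoring on [0, censor_time] days
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_patients, self.n_families, self.genes_per_family) < 1:
            raise ValueError("all counts must be positive")
        lo, hi = self.protein_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid protein_length_range")
        if not (0.0 < self.domain_span_fraction < 1.0):
            raise ValueError("domain_span_fraction must lie in (0, 1)")
        if self.domain_span_fraction * lo < 1:
            raise ValueError(
                "domain span would be empty for the shortest protein"
            )
        if self.background_mutation_rate <= 0:
            raise ValueError("background_mutation_rate must be positive")
        if abs(sum(self.stage_probs) - 1.0) > 1e-12:
            raise ValueError("stage_probs must sum to 1")
        for acc, lam in self.enriched_families.items():
            if lam < 1.0:
                raise ValueError(f"enrichment multiplier for {acc} must be >= 1")
        if self.hazard_ratio_domain_mut <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")

    def family_accessions(self) -> list[str]:
        return [f"FAM{i:04d}" for i in range(1, self.n_families + 1)]


@dataclass
class CohortBundle:
    mutations: pd.DataFrame
    domains: pd.DataFrame
    clinical: pd.DataFrame
    manifest: dict


def _child_rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(c) for name, c in zip(names, children)}


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a (mutations, domains, clinical) bundle.

    Deterministic given the config (including its seed): two calls with
    the same config produce identical tables.
    """
    config.validate()
    unknown = set(config.enriched_families) - set(config.family_accessions())
    if unknown:
        raise ValueError(f"enriched families not in cohort: {sorted(unknown)}")
    rngs = _child_rngs(config.seed, ("genes", "mutations", "clinical", "survival"))

    # --- genes and their single-family domain instances -------------------
    n_genes = config.n_families * config.genes_per_family
    accs = np.repeat(config.family_accessions(), config.genes_per_family)
    genes = np.array([f"G{i:05d}" for i in range(1, n_genes + 1)])
    lo, hi = config.protein_length_range
    L = rngs["genes"].integers(lo, hi + 1, size=n_genes)
    S = np.maximum(1, np.rint(config.domain_span_fraction * L).astype(int))
    start = 1 + rngs["genes"].integers(0, L - S + 1, size=n_genes)
    end = start + S - 1
    domains = pd.DataFrame(
        {
            "gene": genes,
            "protein_length": L,
            "family_acc": accs,
            "family_name": [a.replace("FAM", "fam_") for a in accs],
            "start": start,
            "end": end,
            "e_value": np.full(n_genes, 1e-10),
        }
    )

    lam = np.array(
        [config.enriched_families.get(a, 1.0) for a in accs], dtype=float
    )
    p_null = S / L
    # odds multiplier on the in-domain hit probability, exact null at lambda=1
    p_hit = np.clip(lam * p_null / (1.0 - p_null + lam * p_null), 0.0, 1.0)

    # --- mutations --------------------------------------------------------
    rng = rngs["mutations"]
    patients = np.array([f"P{i:04d}" for i in range(1, config.n_patients + 1)])
    mis_counts = rng.poisson(
        config.background_mutation_rate * config.n_patients, size=n_genes
    )
    gi = np.repeat(np.arange(n_genes), mis_counts)  # gene index per missense
    m = gi.size
    pat_idx = rng.integers(0, config.n_patients, size=m)
    in_dom = rng.random(m) < p_hit[gi]
    u = rng.random(m)
    pos = np.empty(m, dtype=int)
    # inside: uniform over the span; outside: uniform over its complement
    pos[in_dom] = start[gi[in_dom]] + np.floor(u[in_dom] * S[gi[in_dom]]).astype(int)
    out_idx = np.floor(u[~in_dom] * (L[gi[~in_dom]] - S[gi[~in_dom]])).astype(int)
    before = out_idx + 1 < start[gi[~in_dom]]
    pos[~in_dom] = np.where(before, out_idx + 1, out_idx + 1 + S[gi[~in_dom]])
    ref = rng.integers(0, len(_AA), size=m)
    alt = rng.integers(0, len(_AA), size=m)
    mis = pd.DataFrame(
        {
            "patient_id": patients[pat_idx],
            "gene": genes[gi],
            "variant_class": "missense",
            "variant_type": rng.choice(_VARIANT_TYPES, size=m, p=_VARIANT_TYPE_PROBS),
            "protein_pos": pos,
            "aa_change": [
                f"p.{_AA[r]}{p_}{_AA[a]}" for r, p_, a in zip(ref, pos, alt)
            ],
        }
    )

    # non-missense background (descriptive; splice variants lack positions)
    oth_counts = rng.poisson(
        config.other_class_rate_ratio
        * config.background_mutation_rate
        * config.n_patients,
        size=n_genes,
    )
    go = np.repeat(np.arange(n_genes), oth_counts)
    mo = go.size
    oclass = rng.choice(_OTHER_CLASSES, size=mo, p=_OTHER_CLASS_PROBS)
    opos = (1 + np.floor(rng.random(mo) * L[go])).astype(float)
    opos[oclass == "splice"] = np.nan
    oth = pd.DataFrame(
        {
            "patient_id": patients[rng.integers(0, config.n_patients, size=mo)],
            "gene": genes[go],
            "variant_class": oclass,
            "variant_type": rng.choice(_VARIANT_TYPES, size=mo, p=_VARIANT_TYPE_PROBS),
            "protein_pos": opos,
            "aa_change": None,
        }
    )
    mutations = pd.concat([mis, oth], ignore_index=True)
    mutations["protein_pos"] = mutations["protein_pos"].astype("Int64")
    mutations = mutations.sort_values(
        ["patient_id", "gene", "protein_pos"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)

    # --- clinical ---------------------------------------------------------
    crng = rngs["clinical"]
    stage = crng.choice(["I", "II", "III"], size=config.n_patients,
                        p=np.asarray(config.stage_probs))
    hist = np.where(
        crng.random(config.n_patients) < config.ilbc_fraction, "ILBC", "IDBC"
    )

    # carriers: >= 1 in-domain missense mutation in an enriched family
    enriched_gene = np.isin(accs, list(config.enriched_families))
    carrier_pat = set(mis.loc[in_dom & enriched_gene[gi], "patient_id"])
    is_carrier = np.array([p in carrier_pat for p in patients])

    srng = rngs["survival"]
    hazard = config.baseline_hazard * np.where(
        is_carrier, config.hazard_ratio_domain_mut, 1.0
    )
    t_event = srng.exponential(1.0 / hazard)
    t_cens = srng.uniform(0.0, config.censor_time, size=config.n_patients)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "histology": hist,
            "stage": stage,
            "survival_time": np.round(time, 3),
            "event": event.astype(int),
            "subtype": None,
        }
    )

    manifest = {
        "config": dataclasses.asdict(config),
        "n_genes": int(n_genes),
        "n_mutations": int(len(mutations)),
        "n_missense": int(m),
        "n_carriers": int(is_carrier.sum()),
        "all_lambda_one": not config.enriched_families,
    }
    return CohortBundle(mutations=mutations, domains=domains,
                        clinical=clinical, manifest=manifest)


def null_cohort(config: CohortConfig) -> CohortBundle:
    """The same cohort with all enrichment and survival effects disabled
    (every lambda = 1, hazard ratio = 1); for type-I-error studies."""
    null_cfg = dataclasses.replace(
        config, enriched_families={}, hazard_ratio_domain_mut=1.0
    )
    return generate_cohort(null_cfg)


def two_arm_exponential(
    n_per_arm: int,
    hazard: float,
    hazard_ratio: float,
    censor_time: float,
    seed: int,
) -> pd.DataFrame:
    """Two-arm exponential survival with uniform censoring, for hazard-
    ratio recovery studies: arm 0 at ``hazard``, arm 1 at
    ``hazard * hazard_ratio``."""
    rng = np.random.default_rng(seed)
    group = np.repeat([0, 1], n_per_arm)
    h = hazard * np.where(group == 1, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / h)
    t_cens = rng.uniform(0.0, censor_time, size=2 * n_per_arm)
    return pd.DataFrame(
        {
            "group": group,
            "time": np.minimum(t_event, t_cens),
            "event": (t_event <= t_cens).astype(int),
        }
    )


def write_bundle(bundle: CohortBundle, outdir) -> dict[str, Path]:
    """Write the bundle as the three TSVs the readers consume, plus a
    JSON manifest recording the config and seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": out / "mutations.tsv",
        "domains": out / "domains.tsv",
        "clinical": out / "clinical.tsv",
        "manifest": out / "manifest.json",
    }
    bundle.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    bundle.domains.to_csv(paths["domains"], sep="\t", index=False)
    bundle.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)
    return paths
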