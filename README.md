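# domainburden

Somatic mutations in tumor cohorts concentrate in a handful of frequently
mutated genes, while thousands of genes are each hit in only a few
patients.  Aggregating those infrequent mutations over the genes that
share a **protein domain family** can reveal recurrently altered
functional units — kinase, phosphatase or SH2 domains, for example — that
no gene-by-gene test detects.  `domainburden` implements this
domain-centric analysis as a tested Python library and command-line
pipeline for anyone working with MAF-style somatic mutation tables,
Pfam-style domain annotations and clinical follow-up.

## The statistic

Under the null model, a mutation in a gene is (i) placed uniformly along
the protein and (ii) independent of all other mutations.  A gene *i* of
protein length *L<sub>i</sub>* whose instances of a domain family cover
*S<sub>i</sub>* residues (union of spans) then contributes, for each of
its *n<sub>i</sub>* eligible (by default missense) mutations, a Bernoulli
trial with success probability

&nbsp;&nbsp;&nbsp;&nbsp;*p<sub>i</sub> = S<sub>i</sub> / L<sub>i</sub>*.

Summing over the family's member genes, the in-domain mutation count *N*
follows a **Poisson-binomial distribution**; the burden p-value is the
exact upper tail *P(N ≥ N<sub>obs</sub>)* computed by the dynamic-
programming convolution

&nbsp;&nbsp;&nbsp;&nbsp;*f<sub>j</sub>(k) = f<sub>j−1</sub>(k)(1−p<sub>j</sub>) + f<sub>j−1</sub>(k−1)p<sub>j</sub>*,

which stays accurate deep into the tail (relative error ~10<sup>−15</sup>
for tails below 10<sup>−7</sup>, where sampling-based p-values fail).  A
family makes the final list only if it additionally has in-domain
mutations in enough genomes (default: 6.4% of the cohort, i.e. 30 of 468
patients) and spreads them evenly across member genes (normalized Shannon
entropy ≥ 0.71) — so recurrence, not one hypermutated gene, drives the
call.  Around this core the package provides per-gene mutation coverage
and Fisher stage-enrichment tests, a subsample-consensus harness for any
per-gene significance function, projection of mutations onto family
alignment columns, Kaplan–Meier / log-rank / Cox-PH survival
stratification by carrier status, and a synthetic-cohort generator that
reproduces the null model exactly and can plant known enrichment and
survival effects.

## Worked example

Simulate a 468-patient cohort of 50 domain families (30 member genes
each), with one family planted at 8× within-domain odds and a survival
hazard ratio of 2 for its carriers, then run the whole pipeline:

```python
from domainburden import RunConfig, CohortConfig, run_pipeline

cfg = RunConfig(
    output_dir="demo",
    synthetic=CohortConfig(
        n_patients=468, n_families=50,
        enriched_families={"FAM0007": 8.0},
        hazard_ratio_domain_mut=2.0, seed=42,
    ),
)
res = run_pipeline(cfg)
```

`demo/screened_domains.tsv` then contains:

```
family_acc  n_genes  n_obs  genomes_hit  genome_fraction  entropy      p_value
FAM0007          30     67           64         0.136752 0.965265 1.264251e-22
FAM0044          30     30           30         0.064103 0.959644 3.443317e-02
```

The planted family is recovered decisively: 67 in-domain missense
mutations across 64 of 468 genomes where ~20 were expected, an exact tail
p of 1.3×10⁻²², and entropy 0.97 showing the hits are spread over the
member genes.  (FAM0044 is a borderline null family that clears the
screen at p = 0.034 — exactly the kind of marginal call the q-value
column, 0.34 here, flags.)  `demo/survival_screened.tsv` reports the
carrier-vs-non-carrier comparison:

```
family_acc  n_carriers  logrank_stat  logrank_p        hr   wald_p
FAM0007             64     24.476341  7.52e-07   2.290661 0.000001
FAM0044             30      1.434154  0.231      0.702208 0.233516
```

The Cox-PH hazard ratio for the planted family is 2.29 (95% CI
1.63–3.21), consistent with the simulated truth of 2.0; the null family
shows no survival effect.  The same stages are available from the shell:

```bash
domainburden simulate --n-patients 468 --n-families 50 \
    --enrich FAM0007=8.0 --hazard-ratio 2.0 --seed 42 --outdir demo_tsv
domainburden domain-burden --mutations demo_tsv/mutations.tsv \
    --domains demo_tsv/domains.tsv --clinical demo_tsv/clinical.tsv \
    --out burden.tsv
domainburden screen --burden-table burden.tsv --cohort-size 468 \
    --out screened.tsv
```

plus `coverage`, `stage-enrich`, `consensus`, `positional`, `survival`
and `run-all` (YAML config) subcommands.

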