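# Methods

## Model and test

The burden test asks whether a domain family accumulates more mutations
in its domain-coding regions, summed over all member genes, than uniform
placement would predict.  Its two assumptions are: (i) each mutation is
uniformly distributed along its protein, so it hits the family's region
with probability equal to the ratio of domain span to protein length, and
(ii) mutations occur independently.  Each eligible mutation in member
gene *i* is then a Bernoulli trial with probability
p_i = S_i / L_i, where S_i is the length of the **union** of the family's
instance spans in that protein (multiple or overlapping instances are
never double-counted) and L_i the protein length.  The in-domain count N
is Poisson-binomial over the concatenated trial list, and the reported
p-value is the exact upper tail at the observed count.

Conventions, all recorded in the run manifest:

* **Coordinates** are 1-based and inclusive on both ends (Pfam
  convention): a mutation at `start` or `end` is in-domain; `end + 1` is
  out.
* **Tail**: the default is the inclusive tail P(N ≥ N_obs), the standard
  exact one-sided p-value.  The strict tail P(N > N_obs) is exposed
  (`inclusive=False`) because the event is sometimes written that way;
  the strict version is 0 whenever N_obs = n and is not used by default.
* **Eligible classes** default to missense only: missense substitutions
  are the class for which per-residue uniform placement is a meaningful
  null.  Indels and truncating variants enter the descriptive spectra and
  the coverage statistics but not the burden p-value.  The trial count
  n_i includes only mutations with a known protein position, keeping
  numerator and denominator on the same support.

## Numerics

The pmf is computed by the prefix-convolution DP
f_j(k) = f_j−1(k)(1−p_j) + f_j−1(k−1)p_j in double precision.  All terms
are non-negative — there is no cancellation — so round-off accumulates
relatively, at ~n·ε; tails of order 1e−20 at n = 200 are still accurate
to ~1e−15 relative (verified against an exact integer-arithmetic DP in
the acceptance script).  Tail sums are accumulated smallest-term-first.
When a tail underflows double precision entirely the computation is
repeated in log space (logaddexp recurrence), and `return_log=True`
returns log-tails directly; pmf normalization holds to 1e−12 up to
n = 5000.  The DP is O(n²), which is negligible at cohort scale
(n = trials per family, typically < 10³).

## Recurrence screen

A family passes the screen iff

1. `genomes_hit ≥ cutoff`, with cutoff = `ceil(fraction × cohort)` —
   ceiling because "at least 6.4% of 468" must mean 30 whole genomes — or
   an absolute `min_genomes`;
2. `p_value < p_max` (strict, default 0.05, on the raw p-value; BH
   q-values are always reported, and an optional `fdr_q` threshold can be
   added, but the default pass/fail uses raw p);
3. normalized Shannon entropy `H ≥ entropy_min` (non-strict, default
   0.71).

**Entropy axis.**  H = −Σ f_i ln f_i / ln m is computed, by default, over
the distribution of in-domain mutations across member *genes*: the screen
exists to keep families whose recurrence is spread over many genes rather
than driven by one, and the gene axis operationalizes exactly that.  The
normalization constant m defaults to the number of genes actually
carrying in-domain mutations ("active"), so a two-gene family can reach
H = 1; m = all member genes is selectable, as are patient- and
position-axis entropies.  The axis and normalization were a genuinely
open design choice; both are configurable and echoed in the manifest so
no run is ambiguous.  Output ordering is deterministic: ascending
p-value, ties broken lexicographically by accession.

## Cohort statistics

Mutation coverage (MC) of a gene in a patient group is the fraction of
group patients with ≥ 1 mutation in the gene (all variant classes by
default; a patient counts once however many mutations they carry).
Stage enrichment/depletion uses the one-sided Fisher exact test on the
carriers × (stage vs rest) 2×2 table — the natural exact test for
comparing carrier proportions; scipy's hypergeometric implementation is
used and is checked in the tests against explicit enumeration of all
tables.  The subsample-consensus harness re-runs an arbitrary
deterministic per-gene significance function on the full cohort plus one
without-replacement subsample per requested size (default ladder
410…460 under a 468-patient cohort), each drawn from a child seed of the
master seed, and returns the intersection (or union/majority) of the
per-run gene sets along with every per-run list for audit.  The built-in
gene test — a one-sided binomial test of each gene's carrier count
against the cohort-median MC with BH correction — is a deliberately
simple coverage-based stand-in; covariate-aware mutation-significance
callers are outside this package's scope and plug in as callables.

## Positional mapping

Aligned domain instances carry the protein position of their first
residue; residue r of an instance maps to alignment column
`column_map[r]`, where the column map indexes the non-gap columns of the
instance's alignment row.  Tallies count mutations and deduplicated
contributing genes per column; mutations in aligned genes that fall
outside every instance are reported in an explicit unmapped bucket so
mapped + unmapped always equals the candidate count.  A per-column
binomial test against uniform expectation is provided as a clearly
labelled extension; the core analysis only tallies.

## Survival

Carrier status is ≥ 1 eligible mutation in the chosen gene set, or inside
the chosen family's domain spans.  Kaplan–Meier curves, the log-rank
test and the Cox proportional-hazards fit (binary carrier covariate;
hazard ratio = exp(coef), Wald p) are delegated to lifelines; the
product-limit values, the O−E/V log-rank statistic and the HR recovery
are verified against hand computations and simulation truth in the test
suite.  Ties are handled by the Efron approximation (the lifelines
default and the only tie scheme it implements).

## Synthetic cohorts

The generator emulates the statistical regime the screen targets, not a
full tumor genome:

* `n_patients = 468`, stage probabilities (89, 287, 92)/468 — a
  surgically staged breast-cancer-sized cohort with stage IV merged into
  III;
* `background_mutation_rate = 0.005` expected missense mutations per
  gene per patient (the order of magnitude implied by ~31k mutations over
  ~12k genes in 468 exomes), per-gene counts Poisson with mean
  rate × n_patients;
* `genes_per_family = 30` member genes and `domain_span_fraction = 0.3`:
  domain families large enough that genuine recurrent enrichment can
  clear a 30-genome cutoff, as the large kinase/fibronectin-type families
  do in real cohorts (e.g. 374 mutations across 186 kinase-domain genes);
* placement is uniform over codons, so under λ = 1 the in-domain
  indicator is Bernoulli(S/L) **exactly** — the null of the burden test
  holds by construction;
* planted enrichment multiplies the within-domain *odds* by λ ≥ 1
  (p′ = λp/(1−p+λp)), which reduces to the null exactly at λ = 1;
* non-missense classes are generated at 0.6× the missense load with a
  fixed class mix (splice variants get no protein position), purely to
  exercise parsing, class filtering and coverage statistics;
* survival is exponential with baseline hazard 5e−4/day (median ≈ 3.8
  years) times a configurable hazard ratio for patients carrying ≥ 1
  in-domain missense mutation in an enriched family, censored by an
  independent Uniform(0, 3000 days) time.

One master seed spawns named child streams (genes, mutations, clinical,
survival) via `numpy.random.SeedSequence`, making bundles byte-identical
across runs of the same config.

What the generator does **not** model — trinucleotide signatures,
per-gene background-rate covariates, copy number, subclonality,
gene-length–correlated mutation rates, genes in several families —
bounds what passing tests show: they demonstrate calibration and power of
the statistic under its own null, not robustness to covariate-driven
background variation in real cohorts (which is the job of the pluggable
gene test, not the domain statistic).

## Problem sizes

The calibration and recovery studies run at: 2,000 null families for the
type-I-error check; 50 cohort seeds of 200 families (5 planted at λ = 8)
for the recovery study; every 2×2 table with total ≤ 40 for the Fisher
cross-check; 100 seeds × 400 patients/arm for hazard-ratio recovery;
500 random vectors (n ≤ 15) for pmf enumeration equivalence and a
200-trial vector for deep-tail accuracy.  These sizes give the binomial
success-rate checks ~3σ headroom at their thresholds while keeping the
whole acceptance run to a few minutes on one CPU.

## Known limitations

* The burden test inherits its null from assumption (i); genes with
  strongly non-uniform missense placement (mutational hotspots unrelated
  to domains) can inflate family p-values.
* Genome-fraction cutoffs below 1/cohort and families whose genes carry
  no eligible mutations degenerate gracefully (p = 1) but are not
  informative.
* The consensus harness treats its gene test as a black box; it cannot
  repair a miscalibrated test, only damp its sensitivity to individual
  patients.
* Domain coordinates must be pre-annotated in protein space; no
  transcript lifting or consequence prediction is performed.
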