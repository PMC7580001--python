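"""Coverage, Fisher/stage enrichment and the subsample-consensus harness."""

import itertools

import numpy as np
import pandas as pd
import pytest

import helpers
from domainburden.cohort_stats import (
    binomial_coverage_gene_test,
    coverage_table,
    fisher_2x2,
    mutation_coverage,
    stage_enrichment,
    subsample_consensus,
)


def _muts(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "gene", "variant_class",
                                     "variant_type", "protein_pos"])
    df["protein_pos"] = df["protein_pos"].astype("Int64")
    return df


class TestMutationCoverage:
    def test_simple_fraction(self):
        m = _muts([(f"P{i}", "TP53", "missense", "SNP", 10) for i in (1, 2, 3)])
        cohort = [f"P{i}" for i in range(1, 11)]
        assert mutation_coverage(m, cohort, "TP53") == pytest.approx(0.3)

    def test_multiple_mutations_count_once(self):
        m = _muts([("P1", "TP53", "missense", "SNP", p) for p in (10, 20, 30, 40)])
        cohort = ["P1", "P2"]
        assert mutation_coverage(m, cohort, "TP53") == pytest.approx(0.5)

    def test_duplicate_rows_do_not_change_mc(self):
        rows = [("P1", "TP53", "missense", "SNP", 10)]
        assert mutation_coverage(_muts(rows * 3), ["P1", "P2"], "TP53") == (
            mutation_coverage(_muts(rows), ["P1", "P2"], "TP53")
        )

    def test_group_must_be_nonempty_subset(self):
        m = _muts([("P1", "TP53", "missense", "SNP", 10)])
        with pytest.raises(ValueError):
            mutation_coverage(m, ["P1"], "TP53", group=[])
        with pytest.raises(ValueError):
            mutation_coverage(m, ["P1"], "TP53", group=["P9"])

    def test_by_stage_matches_hand_tally(self, toy_clinical):
        # carriers of GX: P1 (stage I), P3, P4 (stage II)
        m = _muts([("P1", "GX", "missense", "SNP", 1),
                   ("P3", "GX", "missense", "SNP", 2),
                   ("P4", "GX", "nonsense", "SNP", 3)])
        tab = coverage_table(m, toy_clinical, ["GX"]).iloc[0]
        assert tab["mc_overall"] == pytest.approx(0.3)
        assert tab["carriers_I"] == 1 and tab["mc_I"] == pytest.approx(1 / 3)
        assert tab["carriers_II"] == 2 and tab["mc_II"] == pytest.approx(2 / 5)
        assert tab["carriers_III"] == 0 and tab["mc_III"] == 0.0


class TestFisher:
    def test_two_sided_enumeration_value(self):
        assert fisher_2x2(3, 1, 1, 3) == pytest.approx(0.4857, abs=1e-4)

    def test_identical_rows_give_one(self):
        assert fisher_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_one_sided_never_exceeds_two_sided_plus_other_side(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 10, size=4)
            two = fisher_2x2(a, b, c, d)
            assert fisher_2x2(a, b, c, d, "greater") <= two + 1e-12 or (
                fisher_2x2(a, b, c, d, "less") <= two + 1e-12
            )

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2(-1, 2, 3, 4)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2(0, 0, 3, 4)

    @pytest.mark.parametrize("sided", ["two-sided", "greater", "less"])
    def test_matches_hypergeometric_enumeration_small_tables(self, sided):
        for a, b, c, d in itertools.product(range(4), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            assert fisher_2x2(a, b, c, d, sided) == pytest.approx(
                helpers.fisher_oracle(a, b, c, d, sided), abs=1e-12
            ), (a, b, c, d)


class TestStageEnrichment:
    def test_gene_only_in_stage_one_matches_enumeration(self, toy_clinical):
        # carriers: exactly the three stage-I patients P1, P2, P10
        m = _muts([(p, "GX", "missense", "SNP", 1) for p in ("P1", "P2", "P10")])
        p = stage_enrichment(m, toy_clinical, "GX", "I")
        # 3 carriers all among 3 stage-I patients of 10
        assert p == pytest.approx(helpers.fisher_oracle(3, 0, 0, 7, "greater"))

    def test_proportional_carriers_near_one(self):
        clinical = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(40)],
            "histology": ["IDBC"] * 40,
            "stage": ["I"] * 10 + ["II"] * 20 + ["III"] * 10,
            "survival_time": 1000.0,
            "event": 0,
        })
        carriers = ["P0", "P1", "P10", "P11", "P12", "P13", "P30", "P31"]
        m = _muts([(p, "GX", "missense", "SNP", 1) for p in carriers])
        assert stage_enrichment(m, clinical, "GX", "I") > 0.3

    def test_enrichment_and_depletion_overlap(self, toy_clinical):
        m = _muts([("P1", "GX", "missense", "SNP", 1),
                   ("P3", "GX", "missense", "SNP", 1)])
        pe = stage_enrichment(m, toy_clinical, "GX", "I")
        pd_ = stage_enrichment(m, toy_clinical, "GX", "I", direction="depletion")
        assert pe + pd_ >= 1.0  # both tails include the observed table

    def test_empty_stage_errors(self, toy_clinical):
        clin = toy_clinical.loc[toy_clinical["stage"] != "III"]
        m = _muts([("P1", "GX", "missense", "SNP", 1)])
        with pytest.raises(ValueError):
            stage_enrichment(m, clin, "GX", "III")


class TestSubsampleConsensus:
    def _cohort(self, n=20):
        return [f"P{i:02d}" for i in range(n)]

    def test_constant_gene_test(self):
        m = _muts([("P00", "G1", "missense", "SNP", 1)])
        res = subsample_consensus(lambda mu, pa: {"G1", "G2"}, m,
                                  self._cohort(), [10, 15], seed=0)
        assert res.consensus == {"G1", "G2"}
        assert set(res.per_run) == {"full", "n10", "n15"}

    def test_patient_dependent_gene_drops_from_intersection(self):
        # gene G is called significant only when patient P00 is present
        m = _muts([("P00", "G", "missense", "SNP", 1)])

        def gene_test(mu, patients):
            return {"G"} if "P00" in set(map(str, patients)) else set()

        # subsample of 19 of 20 excludes P00 in at least one run over seeds
        dropped = False
        for seed in range(10):
            res = subsample_consensus(gene_test, m, self._cohort(), [19, 19, 19],
                                      seed=seed)
            if res.consensus == set():
                dropped = True
                assert any(run == set() for run in res.per_run.values())
        assert dropped

    def test_intersection_is_subset_of_every_run(self):
        rng = np.random.default_rng(5)
        m = _muts([(f"P{rng.integers(20):02d}", f"G{rng.integers(5)}",
                    "missense", "SNP", 1) for _ in range(60)])
        res = subsample_consensus(binomial_coverage_gene_test(min_carriers=1),
                                  m, self._cohort(), [12, 15, 18], seed=3)
        for run in res.per_run.values():
            assert res.consensus <= run

    def test_union_and_majority_modes(self):
        m = _muts([("P00", "G", "missense", "SNP", 1)])
        calls = iter([{"A"}, {"A", "B"}, {"B"}])
        res = subsample_consensus(lambda mu, pa: next(calls), m,
                                  self._cohort(), [10, 10], seed=0, mode="union")
        assert res.consensus == {"A", "B"}

    def test_oversized_subsample_errors(self):
        m = _muts([("P00", "G", "missense", "SNP", 1)])
        with pytest.raises(ValueError):
            subsample_consensus(lambda mu, pa: set(), m, self._cohort(), [25], 0)

    def test_default_sizes_for_468_cohort(self):
        # the conventional ladder below a 468-patient cohort
        sizes = (410, 420, 430, 440, 450, 460)
        assert all(s < 468 for s in sizes)
        m = _muts([("P0000", "G", "missense", "SNP", 1)])
        cohort = [f"P{i:04d}" for i in range(468)]
        res = subsample_consensus(lambda mu, pa: {"G"} if len(pa) else set(),
                                  m, cohort, list(sizes), seed=1)
        assert set(res.per_run) == {"full"} | {f"n{s}" for s in sizes}
        assert res.consensus == {"G"}

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        m = _muts([(f"P{rng.integers(20):02d}", f"G{rng.integers(5)}",
                    "missense", "SNP", 1) for _ in range(40)])
        test = binomial_coverage_gene_test(min_carriers=1)
        r1 = subsample_consensus(test, m, self._cohort(), [12, 16], seed=7)
        r2 = subsample_consensus(test, m, self._cohort(), [12, 16], seed=7)
        assert r1.consensus == r2.consensus and r1.per_run == r2.per_run
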