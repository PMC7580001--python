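import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def toy_domains() -> pd.DataFrame:
    """Three genes sharing family FAMX plus one gene of family FAMY."""
    rows = [
        # gene, L, acc, name, start, end, e
        ("GA", 100, "FAMX", "famx", 11, 40, 1e-9),   # span 30, p = 0.3
        ("GB", 200, "FAMX", "famx", 51, 100, 1e-8),  # span 50, p = 0.25
        ("GC", 150, "FAMX", "famx", 1, 30, 1e-7),    # span 30, p = 0.2
        ("GD", 300, "FAMY", "famy", 101, 160, 1e-9),
    ]
    return pd.DataFrame(
        rows,
        columns=["gene", "protein_length", "family_acc", "family_name",
                 "start", "end", "e_value"],
    )


@pytest.fixture
def toy_mutations() -> pd.DataFrame:
    """Hand-placed mutations: FAMX in-domain hits are GA:15 (P1), GA:40
    (P2) and GC:30 (P1) -> k = (2, 0, 1), N = 3, genomes = {P1, P2}."""
    rows = [
        ("P1", "GA", "missense", "SNP", 15),   # in  [11,40]
        ("P2", "GA", "missense", "SNP", 40),   # in  (boundary: = end)
        ("P3", "GA", "missense", "SNP", 41),   # out (= end + 1)
        ("P1", "GB", "missense", "SNP", 50),   # out (= start - 1)
        ("P2", "GB", "missense", "SNP", 101),  # out
        ("P1", "GC", "missense", "SNP", 30),   # in  [1,30]
        ("P4", "GC", "silent", "SNP", 10),     # ineligible class
        ("P4", "GA", "missense", "SNP", None), # no position -> not a trial
        ("P5", "GD", "missense", "SNP", 120),  # other family
    ]
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "gene", "variant_class", "variant_type",
                 "protein_pos"],
    )
    df["protein_pos"] = df["protein_pos"].astype("Int64")
    df["aa_change"] = None
    return df


@pytest.fixture
def toy_clinical() -> pd.DataFrame:
    rng = np.random.default_rng(42)
    n = 10
    patients = [f"P{i}" for i in range(1, n + 1)]
    return pd.DataFrame(
        {
            "patient_id": patients,
            "histology": ["IDBC"] * 8 + ["ILBC"] * 2,
            "stage": ["I", "I", "II", "II", "II", "II", "III", "III", "II", "I"],
            "survival_time": rng.uniform(100, 2000, n).round(1),
            "event": [1, 0, 1, 1, 0, 0, 1, 0, 1, 0],
            "subtype": [None] * n,
        }
    )
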