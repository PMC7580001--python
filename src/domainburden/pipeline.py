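"""End-to-end pipeline: one config in, a result bundle plus manifest out.

A run either reads the three input tables from disk or generates a
synthetic cohort, then: tallies every domain family, computes exact
burden p-values, annotates entropy and BH q-values, applies the
recurrence screen, writes per-gene coverage/stage-enrichment tables, and
(optionally) survival statistics for each screened family.  Every
threshold and convention used is echoed into ``manifest.json`` so a run
can be reproduced from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import burden, cohort_stats, screen, simulate, survival
from .io import read_clinical_table, read_domain_table, read_mutation_table
from .records import (
    VariantClass,
    clinical_to_frame,
    domains_to_frame,
    mutations_to_frame,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "load_config"]

#: identity column map for tables written by this package
INTERNAL_COLUMN_MAP = {
    "patient_id": "patient_id",
    "gene": "gene",
    "variant_class": "variant_class",
    "variant_type": "variant_type",
    "protein_pos": "protein_pos",
    "aa_change": "aa_change",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of (``mutations_path``/``domains_path``/``clinical_path``)
    or ``synthetic`` must be given.
    """

    output_dir: str = "results"
    mutations_path: Optional[str] = None
    domains_path: Optional[str] = None
    clinical_path: Optional[str] = None
    column_map: Optional[dict] = None
    synthetic: Optional[simulate.CohortConfig] = None
    thresholds: screen.ScreenThresholds = field(default_factory=screen.ScreenThresholds)
    eligible_classes: tuple[str, ...] = ("missense",)
    e_value_max: float = 1e-5
    inclusive_tail: bool = True
    entropy_axis: str = "gene"
    entropy_normalization: str = "active"
    run_survival: bool = True
    seed: int = 0
    log_level: str = "INFO"


def validate_config(config: RunConfig) -> list[str]:
    """Return every violation found (empty list = valid)."""
    errors: list[str] = []
    real = [config.mutations_path, config.domains_path, config.clinical_path]
    has_real = any(p is not None for p in real)
    if has_real and config.synthetic is not None:
        errors.append("give either real input paths or a synthetic config, not both")
    if not has_real and config.synthetic is None:
        errors.append("no inputs: give input paths or a synthetic config")
    if has_real and not all(p is not None for p in real):
        errors.append("real inputs need all of mutations/domains/clinical paths")
    try:
        _ = dataclasses.replace(config.thresholds)
    except ValueError as exc:
        errors.append(str(exc))
    if config.e_value_max <= 0:
        errors.append("e_value_max must be positive")
    for c in config.eligible_classes:
        try:
            VariantClass(c)
        except ValueError:
            errors.append(f"unknown variant class {c!r}")
    if config.entropy_axis not in ("gene", "patient", "position"):
        errors.append(f"unknown entropy axis {config.entropy_axis!r}")
    if config.synthetic is not None:
        try:
            config.synthetic.validate()
        except ValueError as exc:
            errors.append(str(exc))
    return errors


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        bundle = simulate.generate_cohort(config.synthetic)
        return bundle.mutations, bundle.domains, bundle.clinical, bundle.manifest
    muts, report = read_mutation_table(
        config.mutations_path,
        column_map=config.column_map or INTERNAL_COLUMN_MAP,
    )
    doms = read_domain_table(config.domains_path, e_value_max=config.e_value_max)
    clin = read_clinical_table(config.clinical_path)
    meta = {"parse_report": {"n_rows": report.n_rows, "n_skipped": report.n_skipped}}
    return (
        mutations_to_frame(muts),
        domains_to_frame(doms),
        clinical_to_frame(clin),
        meta,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of output paths and summaries."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    stage = "load inputs"
    try:
        mutations, domains, clinical, input_meta = _load_inputs(config)
        cohort_size = int(clinical["patient_id"].nunique())
        eligible = frozenset(VariantClass(c) for c in config.eligible_classes)

        stage = "domain burden"
        stats_list = burden.tally_all_families(
            mutations, domains, eligible_classes=eligible, cohort_size=cohort_size
        )
        for st in stats_list:
            burden.family_test(st, inclusive=config.inclusive_tail)
        screen.annotate(
            stats_list,
            cohort_size,
            entropy_axis=config.entropy_axis,
            entropy_normalization=config.entropy_normalization,
        )
        burden_df = pd.DataFrame([st.to_row() for st in stats_list]).sort_values(
            ["p_value", "family_acc"]
        )
        burden_path = outdir / "domain_burden.tsv"
        burden_df.to_csv(burden_path, sep="\t", index=False)

        stage = "recurrence screen"
        passed = screen.screen_families(stats_list, config.thresholds, cohort_size)
        screened_df = pd.DataFrame([st.to_row() for st in passed])
        screened_path = outdir / "screened_domains.tsv"
        screened_df.to_csv(screened_path, sep="\t", index=False)

        stage = "gene coverage"
        top_genes = (
            mutations.groupby("gene")["patient_id"].nunique().nlargest(100).index
        )
        coverage_df = cohort_stats.coverage_table(mutations, clinical, list(top_genes))
        coverage_path = outdir / "gene_coverage.tsv"
        coverage_df.to_csv(coverage_path, sep="\t", index=False)

        surv_path = None
        if config.run_survival and passed:
            stage = "survival"
            rows = []
            for st in passed:
                try:
                    non, car = survival.stratify_by_carrier(
                        clinical, mutations, domains=domains,
                        family_acc=st.family_acc, eligible_classes=eligible,
                    )
                    lr_stat, lr_p = survival.logrank_test(non, car)
                    hr = survival.hazard_ratio(non, car)
                    rows.append(
                        {
                            "family_acc": st.family_acc,
                            "n_carriers": car.n,
                            "logrank_stat": lr_stat,
                            "logrank_p": lr_p,
                            "hr": hr.hr,
                            "hr_ci_low": hr.ci_low,
                            "hr_ci_high": hr.ci_high,
                            "wald_p": hr.wald_p,
                        }
                    )
                except (ValueError, RuntimeError) as exc:
                    logger.warning("survival skipped for %s: %s", st.family_acc, exc)
            surv_path = outdir / "survival_screened.tsv"
            pd.DataFrame(rows).to_csv(surv_path, sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest = {
        "config": _config_dict(config),
        "inputs": input_meta,
        "cohort_size": cohort_size,
        "genome_cutoff": config.thresholds.genome_cutoff(cohort_size),
        "n_families": len(stats_list),
        "n_screened": len(passed),
        "conventions": {
            "tail": "inclusive P(N >= k)" if config.inclusive_tail else "strict P(N > k)",
            "entropy_axis": config.entropy_axis,
            "entropy_normalization": config.entropy_normalization,
            "coordinates": "1-based inclusive protein coordinates",
        },
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {
        "burden": burden_path,
        "screened": screened_path,
        "coverage": coverage_path,
        "survival": surv_path,
        "manifest": manifest_path,
        "n_screened": len(passed),
    }


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML; nested ``synthetic`` and ``thresholds``
    blocks become their dataclasses."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "synthetic" in raw and raw["synthetic"] is not None:
        syn = dict(raw["synthetic"])
        if "protein_length_range" in syn:
            syn["protein_length_range"] = tuple(syn["protein_length_range"])
        if "stage_probs" in syn:
            syn["stage_probs"] = tuple(syn["stage_probs"])
        raw["synthetic"] = simulate.CohortConfig(**syn)
    if "thresholds" in raw and raw["thresholds"] is not None:
        raw["thresholds"] = screen.ScreenThresholds(**raw["thresholds"])
    if "eligible_classes" in raw:
        raw["eligible_classes"] = tuple(raw["eligible_classes"])
    return RunConfig(**raw)
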