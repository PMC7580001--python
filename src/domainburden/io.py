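"""Readers and writers for the pipeline's tab-separated tables and alignments.

The mutation reader is a configurable-column TSV reader with MAF column
names as defaults, not a full MAF parser: only the five fields the analysis
consumes are read.  Parsing is lenient by default (malformed rows are
logged and skipped, with bookkeeping so parsed + skipped always equals the
input row count); a strict mode turns every skip into a hard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

from .records import (
    ClinicalRecord,
    DomainInstance,
    Histology,
    MutationRecord,
    Stage,
    VariantClass,
    VariantType,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MAF_COLUMN_MAP",
    "VARIANT_CLASS_MAP",
    "DEFAULT_STAGE_MERGE",
    "ParseReport",
    "read_mutation_table",
    "read_domain_table",
    "read_clinical_table",
    "write_results_table",
    "read_domain_alignment",
]

#: Default column map: record field -> column name in the input table.
#: MAF/VEP-style names are the defaults because TCGA-era mutation tables
#: use them; any mapping can be passed instead.
MAF_COLUMN_MAP: dict[str, str] = {
    "patient_id": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "variant_class": "Variant_Classification",
    "variant_type": "Variant_Type",
    "protein_pos": "Protein_position",
    "aa_change": "HGVSp_Short",
}

#: Normalisation of MAF Variant_Classification strings onto the internal
#: enum; unmapped values fall through to "other".
VARIANT_CLASS_MAP: dict[str, VariantClass] = {
    "Missense_Mutation": VariantClass.MISSENSE,
    "Nonsense_Mutation": VariantClass.NONSENSE,
    "Nonstop_Mutation": VariantClass.OTHER,
    "Frame_Shift_Del": VariantClass.FRAMESHIFT_INDEL,
    "Frame_Shift_Ins": VariantClass.FRAMESHIFT_INDEL,
    "In_Frame_Del": VariantClass.INFRAME_INDEL,
    "In_Frame_Ins": VariantClass.INFRAME_INDEL,
    "Splice_Site": VariantClass.SPLICE,
    "Splice_Region": VariantClass.SPLICE,
    "Silent": VariantClass.SILENT,
    # already-normalised values pass through
    **{v.value: v for v in VariantClass},
}

#: Stage IV is merged into Stage III by default (few Stage IV patients in a
#: typical surgical cohort); any merge map can be given.
DEFAULT_STAGE_MERGE: dict[str, str] = {"IV": "III"}


@dataclass
class ParseReport:
    """Bookkeeping for a lenient parse: n_rows == n_parsed + n_skipped."""

    n_rows: int = 0
    n_parsed: int = 0
    n_skipped: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def skip(self, row: int, reason: str) -> None:
        self.n_skipped += 1
        self.skipped.append((row, reason))
        logger.warning("row %d skipped: %s", row, reason)


def _parse_protein_pos(raw: object) -> Optional[int]:
    """Parse a protein position cell; VEP-style '123/456' is accepted.

    Returns None for empty / '-' / '.' cells; raises ValueError otherwise.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    s = str(raw).strip()
    if s in ("", "-", ".", "NA", "nan"):
        return None
    if "/" in s:  # VEP prints position/length
        s = s.split("/", 1)[0]
    if "-" in s:  # interval consequence: take the first residue
        s = s.split("-", 1)[0]
    pos = int(s)
    if pos < 1:
        raise ValueError(f"protein position must be >= 1, got {pos}")
    return pos


def read_mutation_table(
    path: Union[str, Path],
    *,
    column_map: Optional[Mapping[str, str]] = None,
    class_map: Optional[Mapping[str, VariantClass]] = None,
    strict: bool = False,
) -> tuple[list[MutationRecord], ParseReport]:
    """Read a mutation TSV into validated records.

    Parameters
    ----------
    path : file path of a header-bearing TSV.
    column_map : record field -> column name; defaults to MAF names.
        ``variant_type`` and ``aa_change`` columns are optional.
    class_map : raw variant-class string -> :class:`VariantClass`;
        unmapped values become ``other``.
    strict : if True any malformed row is a hard error; otherwise the row
        is logged and skipped.

    Returns
    -------
    (records, report) where ``report`` satisfies
    ``report.n_rows == report.n_parsed + report.n_skipped``.
    """
    cmap = dict(MAF_COLUMN_MAP if column_map is None else column_map)
    klass = dict(VARIANT_CLASS_MAP if class_map is None else class_map)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for fieldname in ("patient_id", "gene", "variant_class"):
        col = cmap.get(fieldname)
        if col is None or col not in df.columns:
            raise ValueError(
                f"required column for field '{fieldname}' "
                f"({col!r}) missing from {path}"
            )
    report = ParseReport(n_rows=len(df))
    records: list[MutationRecord] = []
    type_col = cmap.get("variant_type")
    aa_col = cmap.get("aa_change")
    pos_col = cmap.get("protein_pos")
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        d = dict(zip(df.columns, row))
        try:
            vclass = klass.get(str(d[cmap["variant_class"]]), VariantClass.OTHER)
            vtype = VariantType.SNP
            if type_col and type_col in df.columns and not pd.isna(d[type_col]):
                vtype = VariantType(str(d[type_col]))
            pos = None
            if pos_col and pos_col in df.columns:
                pos = _parse_protein_pos(d[pos_col])
            aa = None
            if aa_col and aa_col in df.columns and not pd.isna(d[aa_col]):
                aa = str(d[aa_col])
            records.append(
                MutationRecord(
                    patient_id=str(d[cmap["patient_id"]]),
                    gene=str(d[cmap["gene"]]),
                    variant_class=vclass,
                    variant_type=vtype,
                    protein_pos=pos,
                    aa_change=aa,
                )
            )
            report.n_parsed += 1
        except (ValueError, KeyError) as exc:
            if strict:
                raise ValueError(f"{path} line {i}: {exc}") from exc
            report.skip(i, str(exc))
    return records, report


def read_domain_table(
    path: Union[str, Path],
    e_value_max: float = 1e-5,
) -> list[DomainInstance]:
    """Read a domain-annotation TSV, keeping instances with E-value below
    ``e_value_max`` (default 1e-5, the usual confident-match cutoff for
    Pfam scans).

    Expected columns: gene, protein_length, family_acc, family_name,
    start, end, e_value.  Span violations are hard errors reported with
    their line number.
    """
    if e_value_max <= 0:
        raise ValueError("e_value_max must be positive")
    df = pd.read_csv(path, sep="\t")
    out: list[DomainInstance] = []
    for i, r in enumerate(df.itertuples(index=False), start=2):
        try:
            inst = DomainInstance(
                gene=str(r.gene),
                protein_length=int(r.protein_length),
                family_acc=str(r.family_acc),
                family_name=str(r.family_name),
                start=int(r.start),
                end=int(r.end),
                e_value=float(r.e_value),
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
        if inst.e_value < e_value_max:
            out.append(inst)
    return out


def read_clinical_table(
    path: Union[str, Path],
    *,
    stage_merge: Optional[Mapping[str, str]] = None,
) -> list[ClinicalRecord]:
    """Read the clinical TSV (patient_id, histology, stage, survival_time,
    event[, subtype]).

    ``stage_merge`` maps out-of-enum stage labels onto the three-level
    scale; the default merges IV into III.  An unknown, unmapped stage
    label is a hard error.
    """
    merge = DEFAULT_STAGE_MERGE if stage_merge is None else dict(stage_merge)
    df = pd.read_csv(path, sep="\t")
    out: list[ClinicalRecord] = []
    for i, r in enumerate(df.itertuples(index=False), start=2):
        raw_stage = str(r.stage).strip()
        stage = merge.get(raw_stage, raw_stage)
        try:
            out.append(
                ClinicalRecord(
                    patient_id=str(r.patient_id),
                    histology=Histology(str(r.histology)),
                    stage=Stage(stage),
                    survival_time=float(r.survival_time),
                    event=bool(int(r.event)),
                    subtype=(
                        None
                        if not hasattr(r, "subtype") or pd.isna(r.subtype)
                        else str(r.subtype)
                    ),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
    return out


def write_results_table(records, path: Union[str, Path]) -> None:
    """Write records (a DataFrame, or an iterable of dataclasses) as a
    header-bearing TSV; writing then reading reproduces values exactly."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        from dataclasses import asdict
        from enum import Enum

        rows = [asdict(r) for r in records]
        df = pd.DataFrame(rows)
        for col in df.columns:
            df[col] = df[col].map(lambda v: v.value if isinstance(v, Enum) else v)
    df.to_csv(path, sep="\t", index=False)


def read_domain_alignment(path: Union[str, Path]) -> MultipleSeqAlignment:
    """Read an aligned FASTA of domain instances.

    All gapped sequences must have the same length; a ragged file is a
    hard error (raised by the alignment parser).
    """
    aln = AlignIO.read(str(path), "fasta")
    return aln
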