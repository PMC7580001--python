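"""Row-level record types shared across the pipeline.

The pipeline operates on three tabular inputs — somatic mutations, protein
domain annotations and clinical follow-up — plus an optional multiple
alignment of domain instances.  Each table row is validated into one of the
frozen dataclasses below before analysis; converters to/from pandas frames
are provided because the statistical layers work on frames.

Coordinate convention: protein positions and domain spans are 1-based and
inclusive on both ends, following Pfam.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "VariantClass",
    "VariantType",
    "Histology",
    "Stage",
    "MutationRecord",
    "DomainInstance",
    "ClinicalRecord",
    "mutations_to_frame",
    "domains_to_frame",
    "clinical_to_frame",
    "frame_to_mutations",
    "frame_to_domains",
    "frame_to_clinical",
]


class VariantClass(str, Enum):
    """Normalised consequence classes of a somatic variant."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"
    SILENT = "silent"
    OTHER = "other"


class VariantType(str, Enum):
    """Nucleotide-level variant type (SNP / DNP / insertion / deletion)."""

    SNP = "SNP"
    DNP = "DNP"
    INS = "INS"
    DEL = "DEL"


class Histology(str, Enum):
    IDBC = "IDBC"
    ILBC = "ILBC"


class Stage(str, Enum):
    """Tumor stage on the merged three-level scale (IV is merged into III)."""

    I = "I"
    II = "II"
    III = "III"


@dataclass(frozen=True, slots=True)
class MutationRecord:
    """One somatic mutation in one patient.

    ``protein_pos`` is the 1-based amino-acid index of the altered residue;
    it is ``None`` for consequences without a protein coordinate (e.g.
    splice-site variants).
    """

    patient_id: str
    gene: str
    variant_class: VariantClass
    variant_type: VariantType = VariantType.SNP
    protein_pos: Optional[int] = None
    aa_change: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not self.gene:
            raise ValueError("gene must be non-empty")
        object.__setattr__(self, "variant_class", VariantClass(self.variant_class))
        object.__setattr__(self, "variant_type", VariantType(self.variant_type))
        if self.protein_pos is not None:
            pos = int(self.protein_pos)
            if pos < 1:
                raise ValueError(f"protein_pos must be >= 1, got {pos}")
            object.__setattr__(self, "protein_pos", pos)


@dataclass(frozen=True, slots=True)
class DomainInstance:
    """One occurrence of a domain family in one protein.

    ``start``/``end`` are 1-based inclusive amino-acid coordinates; the span
    length is ``end - start + 1``.  ``e_value`` is the match E-value from the
    domain scan used to annotate the protein.
    """

    gene: str
    protein_length: int
    family_acc: str
    family_name: str
    start: int
    end: int
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene must be non-empty")
        if self.protein_length < 1:
            raise ValueError("protein_length must be positive")
        if not (1 <= self.start <= self.end <= self.protein_length):
            raise ValueError(
                f"invalid span [{self.start}, {self.end}] for protein of "
                f"length {self.protein_length} ({self.gene}/{self.family_acc})"
            )
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, slots=True)
class ClinicalRecord:
    """Per-patient clinical annotation: histology, stage and follow-up."""

    patient_id: str
    histology: Histology
    stage: Stage
    survival_time: float
    event: bool
    subtype: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        object.__setattr__(self, "histology", Histology(self.histology))
        object.__setattr__(self, "stage", Stage(self.stage))
        if self.survival_time < 0:
            raise ValueError("survival_time must be non-negative")
        object.__setattr__(self, "event", bool(self.event))


def _records_to_frame(records: Iterable, enum_fields: Sequence[str]) -> pd.DataFrame:
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows)
    for col in enum_fields:
        if col in df.columns:
            df[col] = df[col].map(lambda v: v.value if isinstance(v, Enum) else v)
    return df


def mutations_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    df = _records_to_frame(records, ("variant_class", "variant_type"))
    if df.empty:
        df = pd.DataFrame(
            columns=[f.name for f in fields(MutationRecord)]
        )
    df["protein_pos"] = df["protein_pos"].astype("Int64")
    return df


def domains_to_frame(records: Iterable[DomainInstance]) -> pd.DataFrame:
    df = _records_to_frame(records, ())
    if df.empty:
        df = pd.DataFrame(columns=[f.name for f in fields(DomainInstance)])
    return df


def clinical_to_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    df = _records_to_frame(records, ("histology", "stage"))
    if df.empty:
        df = pd.DataFrame(columns=[f.name for f in fields(ClinicalRecord)])
    return df


def frame_to_mutations(df: pd.DataFrame) -> list[MutationRecord]:
    out = []
    for row in df.itertuples(index=False):
        pos = getattr(row, "protein_pos", None)
        if pd.isna(pos):
            pos = None
        else:
            pos = int(pos)
        out.append(
            MutationRecord(
                patient_id=str(row.patient_id),
                gene=str(row.gene),
                variant_class=VariantClass(row.variant_class),
                variant_type=VariantType(row.variant_type),
                protein_pos=pos,
                aa_change=None if pd.isna(getattr(row, "aa_change", None)) else str(row.aa_change),
            )
        )
    return out


def frame_to_domains(df: pd.DataFrame) -> list[DomainInstance]:
    return [
        DomainInstance(
            gene=str(r.gene),
            protein_length=int(r.protein_length),
            family_acc=str(r.family_acc),
            family_name=str(r.family_name),
            start=int(r.start),
            end=int(r.end),
            e_value=float(r.e_value),
        )
        for r in df.itertuples(index=False)
    ]


def frame_to_clinical(df: pd.DataFrame) -> list[ClinicalRecord]:
    return [
        ClinicalRecord(
            patient_id=str(r.patient_id),
            histology=Histology(r.histology),
            stage=Stage(r.stage),
            survival_time=float(r.survival_time),
            event=bool(r.event),
            subtype=None if pd.isna(getattr(r, "subtype", None)) else str(r.subtype),
        )
        for r in df.itertuples(index=False)
    ]
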