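"""Positional recurrence across a domain family's multiple alignment.

Mutations from different member proteins are projected through the
family alignment onto shared columns, so that recurrence at homologous
residues (e.g. the phosphotyrosine-binding arginines of SH2 domains)
becomes visible even when every individual gene is mutated only once.

Columns are 1-based over the alignment; protein positions are 1-based
over the (ungapped) protein.  Each aligned instance carries the protein
position of its first residue, so residue r of the instance corresponds
to protein position ``start + r - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from scipy import stats as sps

from .records import VariantClass
from .burden import DEFAULT_ELIGIBLE_CLASSES

__all__ = [
    "AlignedInstance",
    "instances_from_alignment",
    "map_to_column",
    "column_tally",
    "column_uniformity_test",
]

GAP_CHARS = frozenset("-.")


@dataclass
class AlignedInstance:
    """One aligned domain instance: gene, start offset in the protein and
    the gapped row of the family alignment."""

    gene: str
    start: int
    gapped_seq: str
    #: 1-based alignment column of each ungapped residue, in order
    column_map: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("start must be >= 1")
        if not self.column_map:
            self.column_map = [
                i + 1 for i, ch in enumerate(self.gapped_seq) if ch not in GAP_CHARS
            ]
        if len(self.column_map) != self.ungapped_length:
            raise ValueError("column map length must equal ungapped length")
        if any(b <= a for a, b in zip(self.column_map, self.column_map[1:])):
            raise ValueError("column map must be strictly increasing")

    @property
    def ungapped_length(self) -> int:
        return sum(1 for ch in self.gapped_seq if ch not in GAP_CHARS)

    @property
    def end(self) -> int:
        """Protein position of the instance's last residue (inclusive)."""
        return self.start + self.ungapped_length - 1


def instances_from_alignment(
    alignment: MultipleSeqAlignment,
    offsets: Mapping[str, int],
) -> list[AlignedInstance]:
    """Build aligned instances from an alignment whose record ids name the
    genes, plus a gene -> start-offset map (the protein position of each
    instance's first aligned residue)."""
    out = []
    for rec in alignment:
        gene = rec.id
        if gene not in offsets:
            raise KeyError(f"no start offset given for aligned gene {gene!r}")
        out.append(
            AlignedInstance(gene=gene, start=int(offsets[gene]), gapped_seq=str(rec.seq))
        )
    return out


def map_to_column(instance: AlignedInstance, protein_pos: int) -> Optional[int]:
    """Alignment column of the residue at ``protein_pos``, or None when the
    position falls outside the instance.  Gap columns are never returned."""
    if protein_pos < 1:
        raise ValueError("protein_pos must be >= 1")
    offset = protein_pos - instance.start  # 0-based residue index
    if offset < 0 or offset >= instance.ungapped_length:
        return None
    return instance.column_map[offset]


def column_tally(
    mutations: pd.DataFrame,
    instances: Sequence[AlignedInstance],
    *,
    eligible_classes=DEFAULT_ELIGIBLE_CLASSES,
) -> tuple[pd.DataFrame, int]:
    """Tally eligible mutations of the instances' genes per alignment
    column.

    Returns (tally, n_unmapped): ``tally`` has one row per hit column with
    the mutation count and the deduplicated contributing-gene count;
    mapped + unmapped equals the number of candidate mutations (eligible
    mutations with a protein position, in genes with an aligned instance).
    """
    classes = {getattr(c, "value", c) for c in eligible_classes}
    by_gene: dict[str, list[AlignedInstance]] = {}
    for inst in instances:
        by_gene.setdefault(inst.gene, []).append(inst)
    cand = mutations.loc[
        mutations["gene"].isin(by_gene)
        & mutations["variant_class"].isin(classes)
        & mutations["protein_pos"].notna()
    ]
    col_counts: dict[int, int] = {}
    col_genes: dict[int, set[str]] = {}
    n_unmapped = 0
    for row in cand.itertuples(index=False):
        pos = int(row.protein_pos)
        col = None
        for inst in by_gene[row.gene]:
            col = map_to_column(inst, pos)
            if col is not None:
                break
        if col is None:
            n_unmapped += 1
            continue
        col_counts[col] = col_counts.get(col, 0) + 1
        col_genes.setdefault(col, set()).add(row.gene)
    tally = pd.DataFrame(
        [
            {
                "column": col,
                "n_mutations": col_counts[col],
                "n_genes": len(col_genes[col]),
                "genes": ",".join(sorted(col_genes[col])),
            }
            for col in sorted(col_counts)
        ],
        columns=["column", "n_mutations", "n_genes", "genes"],
    )
    return tally, n_unmapped


def column_uniformity_test(tally: pd.DataFrame, n_columns: int) -> pd.DataFrame:
    """Optional extension (not part of the core tally): per-column binomial
    test of the mutation count against a uniform expectation over
    ``n_columns`` columns."""
    total = int(tally["n_mutations"].sum())
    out = tally.copy()
    out["uniform_p"] = [
        sps.binomtest(int(k), total, 1.0 / n_columns, alternative="greater").pvalue
        for k in out["n_mutations"]
    ]
    return out
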