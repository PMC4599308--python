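"""Core domain types shared across the pipeline.

The pipeline compares two labelled groups of homologous protein chains:
an *interacting* subgroup of homodimers (H) and a *non-interacting*
subgroup of monomers (M).  Per-residue structural annotations of the
query homodimer (accessible and buried surface areas) provide the
ground-truth interface labels against which sequence-level predictions
are evaluated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

# The 20 canonical amino acids, in the fixed order used by every
# frequency vector in the package.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Letters accepted in an unaligned sequence: the canonical 20 plus X
#: (unknown).  X is excluded from all composition counts.
VALID_RESIDUES: frozenset[str] = frozenset(AMINO_ACIDS + "X")

GAP = "-"


class InteractionClass(str, enum.Enum):
    """Interaction label of a chain: obligate self-interacting or not."""

    HOMODIMER = "homodimer"
    MONOMER = "monomer"


class PositionClass(str, enum.Enum):
    """Structural class of a residue, from ASA/BSA of the complex."""

    INTERFACE = "interface"
    SURFACE = "surface"
    BURIED = "buried"


class GroupScheme(str, enum.Enum):
    """Rule used to delimit the two subgroups on the ranked hit lists."""

    FIRST_CROSS = "first_cross"
    LOWER_OF_TWO = "lower_of_two"
    FIXED_EVALUE = "fixed_evalue"
    MIXED20 = "mixed20"


@dataclass(frozen=True)
class SequenceRecord:
    """One protein chain with its interaction-class label."""

    seq_id: str
    interaction_class: InteractionClass
    residues: str

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"{self.seq_id}: empty sequence")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.seq_id}: invalid residue letter(s) {sorted(bad)}; "
                "only the 20 canonical amino acids and X are accepted"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RankedHit:
    """One homology hit from a ranked (tabular) search result."""

    query_id: str
    subject_id: str
    percent_identity: float
    hsp_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.hsp_length < 1:
            raise ValueError(f"{self.query_id}->{self.subject_id}: hsp_length < 1")
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}->{self.subject_id}: negative evalue")


@dataclass
class AlignedGroup:
    """A labelled multiple sequence alignment of one pair group.

    ``rows`` holds ``(seq_id, interaction_class, gapped_sequence)``
    triples; ``query_id`` names the homodimer whose structure provides
    the residue labels.
    """

    rows: list[tuple[str, InteractionClass, str]]
    query_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(seq) for _, _, seq in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        ids = [sid for sid, _, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate seq_id in alignment")
        if self.query_id not in ids:
            raise ValueError(f"query {self.query_id!r} not among alignment rows")
        classes = {cls for _, cls, _ in self.rows}
        for cls in (InteractionClass.HOMODIMER, InteractionClass.MONOMER):
            if cls not in classes:
                raise ValueError(f"alignment has no {cls.value} rows")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][2])

    @property
    def query_row(self) -> str:
        for sid, _, seq in self.rows:
            if sid == self.query_id:
                return seq
        raise AssertionError("unreachable")

    def rows_of(self, cls: InteractionClass) -> list[str]:
        return [seq for _, c, seq in self.rows if c is cls]


@dataclass
class ResidueAnnotation:
    """Per-residue surface areas of the query homodimer.

    ``asa`` is the solvent-accessible surface area of the residue before
    association; ``bsa`` is the part of that area buried when the
    interface forms (both in squared angstroms).
    """

    residue_index: int  # 1-based
    amino_acid: str
    asa: float
    bsa: float
    position_class: PositionClass | None = None

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue_index must be 1-based (>= 1)")
        if self.asa < 0 or self.bsa < 0:
            raise ValueError(
                f"residue {self.residue_index}: negative surface area"
            )


@dataclass
class PairGroup:
    """One interacting subgroup plus one non-interacting subgroup.

    The interacting subgroup (H) contains the query homodimer and its
    homodimer homologs; the non-interacting subgroup (M) is seeded by
    the query's nearest monomer homolog (the *anchor*).
    """

    query_id: str
    interacting_ids: list[str]
    noninteracting_ids: list[str]
    anchor_monomer_id: str
    hsp_len_query_to_anchor: int
    evalue_cut_H: float
    evalue_cut_M: float
    scheme: GroupScheme = GroupScheme.FIRST_CROSS

    def __post_init__(self) -> None:
        overlap = set(self.interacting_ids) & set(self.noninteracting_ids)
        if overlap:
            raise ValueError(f"subgroups overlap: {sorted(overlap)}")

    @property
    def n_interacting(self) -> int:
        return len(self.interacting_ids)

    @property
    def n_noninteracting(self) -> int:
        return len(self.noninteracting_ids)


@dataclass
class ConfusionCounts:
    """Two-state interface-prediction confusion counts."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class EvalReport:
    """Per-pair-group evaluation summary."""

    group_id: str
    counts: ConfusionCounts
    recall: float | None
    fpr: float | None
    precision: float | None
    auc: float | None
    n_evaluated: int
    class_means: dict[str, dict[str, float]] = field(default_factory=dict)
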