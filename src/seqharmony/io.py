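"""Readers and writers for every on-disk format the pipeline touches.

All formats are plain text: FASTA (sequences), aligned FASTA (MSAs),
12-column tabular homology hits (the classic ``outfmt 6`` layout), TSV
(residue annotations, per-column scores) and JSON (metrics).  Writers
are deterministic — fixed column order, floats at six significant
digits — so a read of a write reproduces the values to that precision
and repeated runs produce byte-identical files.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .types import (
    AlignedGroup,
    ConfusionCounts,
    EvalReport,
    InteractionClass,
    RankedHit,
    ResidueAnnotation,
    SequenceRecord,
)

SCORE_COLUMNS = [
    "column_index",
    "query_residue_index",
    "query_aa",
    "n_H",
    "n_M",
    "entropy_H",
    "entropy_M",
    "sh",
]

ANNOTATION_HEADER = ["residue_index", "amino_acid", "asa", "bsa"]


class ParseError(ValueError):
    """A file did not conform to its expected format."""


def _check_fasta_shape(path: Path) -> None:
    """Reject files whose first non-blank line is not a FASTA header."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header '>', "
                    f"got {line.strip()[:30]!r}"
                )
            return


def read_fasta(path: str | Path, class_label: InteractionClass) -> list[SequenceRecord]:
    """Read unaligned FASTA, labelling every entry with one class.

    The header token before the first whitespace becomes ``seq_id``;
    sequences are uppercased.  Duplicate ids and letters outside the
    20 canonical amino acids plus X are rejected.
    """
    path = Path(path)
    _check_fasta_shape(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ParseError(f"{path}: duplicate seq_id {entry.id!r}")
        seen.add(entry.id)
        try:
            records.append(
                SequenceRecord(entry.id, class_label, str(entry.seq).upper())
            )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return records


def read_fasta_with_classes(
    path: str | Path, class_of: Mapping[str, InteractionClass]
) -> list[SequenceRecord]:
    """Read FASTA whose entries are labelled through a class map."""
    path = Path(path)
    _check_fasta_shape(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ParseError(f"{path}: duplicate seq_id {entry.id!r}")
        seen.add(entry.id)
        if entry.id not in class_of:
            raise ParseError(f"{path}: seq_id {entry.id!r} has no class label")
        records.append(
            SequenceRecord(
                entry.id,
                InteractionClass(class_of[entry.id]),
                str(entry.seq).upper(),
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n{rec.residues}\n")


def read_blast_tabular(path: str | Path) -> list[RankedHit]:
    """Read 12-column tabular hits (query, subject, %id, aln length,
    mismatches, gap opens, qstart, qend, sstart, send, evalue, bitscore).

    Rows are preserved in file order; ``hsp_length`` is the
    alignment-length column.  Lines starting with ``#`` are skipped.
    """
    path = Path(path)
    hits: list[RankedHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.strip() == "" or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                hits.append(
                    RankedHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        hsp_length=int(fields[3]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_blast_tabular(hits: Iterable[RankedHit], path: str | Path) -> None:
    """Write hits back to the 12-column layout (unknown columns zeroed)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{_fmt(h.percent_identity)}\t"
                f"{h.hsp_length}\t0\t0\t1\t{h.hsp_length}\t1\t{h.hsp_length}\t"
                f"{_fmt(h.evalue)}\t{_fmt(h.bitscore)}\n"
            )


def read_aligned_fasta(
    path: str | Path,
    class_of: Mapping[str, InteractionClass],
    query_id: str,
) -> AlignedGroup:
    """Read an aligned FASTA into a labelled :class:`AlignedGroup`."""
    path = Path(path)
    _check_fasta_shape(path)
    rows: list[tuple[str, InteractionClass, str]] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id not in class_of:
            raise ParseError(f"{path}: seq_id {entry.id!r} has no class label")
        rows.append((entry.id, InteractionClass(class_of[entry.id]), str(entry.seq).upper()))
    try:
        return AlignedGroup(rows=rows, query_id=query_id)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_aligned_fasta(group: AlignedGroup, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, _, seq in group.rows:
            fh.write(f">{sid}\n{seq}\n")


def read_classes_tsv(path: str | Path) -> dict[str, InteractionClass]:
    """Read a two-column ``seq_id <tab> class`` table."""
    path = Path(path)
    out: dict[str, InteractionClass] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.strip() == "" or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            sid, cls = fields
            if sid == "seq_id":  # optional header
                continue
            if sid in out:
                raise ParseError(f"{path}: line {lineno}: duplicate seq_id {sid!r}")
            try:
                out[sid] = InteractionClass(cls)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: unknown class {cls!r}") from exc
    return out


def write_classes_tsv(classes: Mapping[str, InteractionClass], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tclass\n")
        for sid, cls in classes.items():
            fh.write(f"{sid}\t{cls.value}\n")


def read_residue_annotations(path: str | Path) -> list[ResidueAnnotation]:
    """Read the per-residue annotation TSV.

    Columns: ``residue_index  amino_acid  asa  bsa`` with a header line.
    Residue indices must be strictly increasing and 1-based; gaps in the
    numbering are allowed (unresolved residues may be absent).
    """
    path = Path(path)
    annotations: list[ResidueAnnotation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != ANNOTATION_HEADER:
            raise ParseError(
                f"{path}: bad header {header!r}; expected "
                + "\\t".join(ANNOTATION_HEADER)
            )
        prev = 0
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if line.strip() == "":
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns")
            try:
                idx = int(fields[0])
                ann = ResidueAnnotation(
                    residue_index=idx,
                    amino_acid=fields[1],
                    asa=float(fields[2]),
                    bsa=float(fields[3]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if idx <= prev:
                raise ParseError(
                    f"{path}: line {lineno}: residue_index {idx} not "
                    f"strictly increasing (previous {prev})"
                )
            prev = idx
            annotations.append(ann)
    return annotations


def write_residue_annotations(
    annotations: Iterable[ResidueAnnotation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_HEADER) + "\n")
        for a in annotations:
            fh.write(
                f"{a.residue_index}\t{a.amino_acid}\t{_fmt(a.asa)}\t{_fmt(a.bsa)}\n"
            )


def _fmt(x: float) -> str:
    """Six-significant-digit representation, stable across runs."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    if isinstance(x, float) and x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.6g}"


def write_scores_tsv(scores: pd.DataFrame, path: str | Path) -> None:
    """Write the per-column score table in fixed column order.

    Missing values (query gap, undefined SH) are written as ``NA``.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(SCORE_COLUMNS) + "\n")
        for _, row in scores.iterrows():
            cells = []
            for col in SCORE_COLUMNS:
                v = row[col]
                if col in ("column_index", "n_H", "n_M"):
                    cells.append(str(int(v)))
                elif col == "query_residue_index":
                    cells.append("NA" if pd.isna(v) else str(int(v)))
                elif col == "query_aa":
                    cells.append(str(v))
                else:
                    cells.append(_fmt(v if not pd.isna(v) else float("nan")))
            fh.write("\t".join(cells) + "\n")


def read_scores_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        na_values=["NA"],
        dtype={"column_index": int, "n_H": int, "n_M": int},
    )
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing score columns {sorted(missing)}")
    return df[SCORE_COLUMNS]


def write_metrics_json(report: EvalReport, path: str | Path) -> None:
    """Serialise an evaluation report; deterministic key order."""
    payload = {
        "group_id": report.group_id,
        "counts": {
            "tp": report.counts.tp,
            "fp": report.counts.fp,
            "tn": report.counts.tn,
            "fn": report.counts.fn,
        },
        "recall": _round6(report.recall),
        "fpr": _round6(report.fpr),
        "precision": _round6(report.precision),
        "auc": _round6(report.auc),
        "n_evaluated": report.n_evaluated,
        "class_means": {
            cls: {k: _round6(v) for k, v in means.items()}
            for cls, means in sorted(report.class_means.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _round6(x: float | None) -> float | None:
    if x is None:
        return None
    return float(f"{x:.6g}")


def read_metrics_json(path: str | Path) -> EvalReport:
    with open(path) as fh:
        payload = json.load(fh)
    return EvalReport(
        group_id=payload["group_id"],
        counts=ConfusionCounts(**payload["counts"]),
        recall=payload["recall"],
        fpr=payload["fpr"],
        precision=payload["precision"],
        auc=payload["auc"],
        n_evaluated=payload["n_evaluated"],
        class_means=payload.get("class_means", {}),
    )


def classify_annotations_inplace(annotations: list[ResidueAnnotation]) -> None:
    """Fill ``position_class`` on each annotation (convenience hook;
    the rule itself lives in :mod:`seqharmony.dataset`)."""
    from .dataset import classify_residue

    for a in annotations:
        a.position_class = classify_residue(a.asa, a.bsa)


__all__ = [
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_blast_tabular",
    "write_blast_tabular",
    "read_aligned_fasta",
    "write_aligned_fasta",
    "read_classes_tsv",
    "write_classes_tsv",
    "read_residue_annotations",
    "write_residue_annotations",
    "read_scores_tsv",
    "write_scores_tsv",
    "read_metrics_json",
    "write_metrics_json",
    "classify_annotations_inplace",
    "SCORE_COLUMNS",
]
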