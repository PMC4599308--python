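"""Sequence-level filters and structural residue classification.

Residues of the query homodimer are divided into three classes from
their accessible (ASA) and buried (BSA) surface areas:

* interface — ASA > 0 and BSA > 0 (area is lost on association)
* surface   — ASA > 0 and BSA = 0 (solvent-accessible, not interface)
* buried    — ASA = 0 and BSA = 0 (inaccessible core)

Sequence sets are cleaned by a minimum-length filter, exact-duplicate
removal within each interaction class, and greedy longest-first identity
clustering (the CD-HIT scheme) that keeps the longest representative of
every cluster above the identity threshold.
"""

from __future__ import annotations

import re
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .types import PositionClass, SequenceRecord

#: Identity-threshold presets (percent) used across dataset selections.
IDENTITY_PRESETS: tuple[int, ...] = (40, 50, 60, 70, 80, 90, 95, 98, 99, 100)


def classify_residue(asa: float, bsa: float) -> PositionClass:
    """Classify one residue from its ASA and BSA (squared angstroms).

    Raises if ``asa == 0 < bsa``: buried area cannot exceed the area
    that was accessible in the first place.
    """
    if asa < 0 or bsa < 0:
        raise ValueError("surface areas must be non-negative")
    if asa == 0 and bsa > 0:
        raise ValueError(
            f"invalid annotation: ASA=0 with BSA={bsa} (buried area "
            "cannot exceed accessible area)"
        )
    if asa > 0 and bsa > 0:
        return PositionClass.INTERFACE
    if asa > 0:
        return PositionClass.SURFACE
    return PositionClass.BURIED


def filter_min_length(
    records: list[SequenceRecord], min_len: int = 50
) -> list[SequenceRecord]:
    """Keep sequences of at least ``min_len`` residues (inclusive)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [r for r in records if r.length >= min_len]


def dedupe_identical(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Drop exact-string duplicates within each interaction class.

    The first occurrence is kept.  Identical sequences in *different*
    classes are both retained — the uniqueness rule applies per group.
    """
    seen: set[tuple[str, str]] = set()
    out: list[SequenceRecord] = []
    for r in records:
        key = (r.interaction_class.value, r.residues)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Percent identity between two sequences.

    Identical positions of an optimal global alignment, divided by the
    length of the shorter sequence (the CD-HIT convention), times 100.
    """
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    identical = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            if a[i] == b[j]:
                identical += 1
    return 100.0 * identical / min(len(a), len(b))


def identity_cluster(
    records: list[SequenceRecord], max_pct_id: float
) -> list[SequenceRecord]:
    """Greedy longest-first identity clustering; returns representatives.

    Records are visited longest first (ties by ``seq_id``).  A record
    joins the first existing cluster whose representative it matches at
    ``>= max_pct_id`` percent identity, otherwise it founds a new
    cluster.  Only representatives — the longest member of each cluster
    — are returned, in input order.
    """
    if max_pct_id <= 0:
        raise ValueError("max_pct_id must be positive")
    if not records:
        return []
    aligner = _make_aligner()
    ordered = sorted(records, key=lambda r: (-r.length, r.seq_id))
    representatives: list[SequenceRecord] = []
    for rec in ordered:
        joined = False
        for rep in representatives:
            if pairwise_identity(rec.residues, rep.residues, aligner) >= max_pct_id:
                joined = True
                break
        if not joined:
            representatives.append(rec)
    kept = {r.seq_id for r in representatives}
    return [r for r in records if r.seq_id in kept]


_CLSTR_ENTRY = re.compile(r">(\S+?)(?:\.\.\.)?\s+(\*|at)")


def read_cdhit_clusters(path: str | Path) -> dict[str, list[str]]:
    """Import a CD-HIT ``.clstr`` file as representative -> members.

    Lets a published clustering be injected in place of
    :func:`identity_cluster`.
    """
    clusters: list[tuple[str | None, list[str]]] = []
    rep: str | None = None
    members: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">Cluster"):
                if members:
                    clusters.append((rep, members))
                rep, members = None, []
                continue
            m = _CLSTR_ENTRY.search(line)
            if not m:
                raise ValueError(f"{path}: line {lineno}: unparseable entry")
            sid, marker = m.groups()
            members.append(sid)
            if marker == "*":
                rep = sid
    if members:
        clusters.append((rep, members))
    out: dict[str, list[str]] = {}
    for rep, members in clusters:
        if rep is None:
            raise ValueError(f"{path}: cluster without a representative")
        out[rep] = members
    return out


def apply_clusters(
    records: list[SequenceRecord], clusters: dict[str, list[str]]
) -> list[SequenceRecord]:
    """Keep only cluster representatives, preserving input order."""
    kept = set(clusters)
    return [r for r in records if r.seq_id in kept]
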