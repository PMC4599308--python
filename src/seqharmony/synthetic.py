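"""Seeded synthetic pair groups with planted interface specificity.

The generator emulates the four pipeline inputs — labelled sequences,
ranked homology hits, a labelled alignment and per-residue ASA/BSA
annotations — for one pair group whose columns follow the compositional
patterns the method exploits:

* buried columns: one dominant residue shared by both groups (high
  conservation, low entropy);
* surface columns: a shared moderately diverse residue pool in both
  groups (compositional overlap, SH near 1);
* interface columns: with probability ``specificity`` the two groups
  draw from *disjoint* residue alphabets (planted specificity, SH = 0),
  otherwise they behave like surface columns.

Columns are generated independently — no phylogeny — so closed-form
expectations are checkable.  Ranked hits are laid out so that the
first-cross rule reconstructs the simulated membership exactly, and the
simulated query-anchor HSP length grows monotonically with the planted
specificity, making HSP filtering the generator's analogue of selecting
more informative (more divergent) homolog pairs.

Everything is driven by one integer seed; the same seed gives
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as sh_io
from .types import (
    AMINO_ACIDS,
    AlignedGroup,
    InteractionClass,
    RankedHit,
    ResidueAnnotation,
    SequenceRecord,
)

H, M = InteractionClass.HOMODIMER, InteractionClass.MONOMER


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated pair group.

    Defaults mirror a typical pair group in the kind of homodimer /
    monomer corpus this pipeline targets: 25 interacting and 14
    non-interacting homologs, a 120-residue chain with roughly 15%
    interface, 50% other-surface and 35% buried positions.
    """

    n_H: int = 25
    n_M: int = 14
    n_columns: int = 120
    interface_columns: frozenset[int] = frozenset()
    surface_columns: frozenset[int] = frozenset()
    buried_columns: frozenset[int] = frozenset()
    specificity: float = 0.6
    conservation_buried: float = 0.9
    substitution_rate: float = 0.05
    interface_alphabet_size: int = 3
    surface_pool_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_H < 5 or self.n_M < 5:
            raise ValueError("each subgroup needs at least five members")
        cols = (
            set(self.interface_columns)
            | set(self.surface_columns)
            | set(self.buried_columns)
        )
        n_listed = (
            len(self.interface_columns)
            + len(self.surface_columns)
            + len(self.buried_columns)
        )
        if len(cols) != n_listed or cols != set(range(self.n_columns)):
            raise ValueError(
                "interface/surface/buried column sets must be disjoint and "
                "cover all columns"
            )
        if not 0 <= self.specificity <= 1:
            raise ValueError("specificity must be in [0, 1]")
        if self.interface_alphabet_size < 1 or (
            self.specificity > 0
            and 2 * self.interface_alphabet_size > len(AMINO_ACIDS)
        ):
            raise ValueError(
                "disjoint group alphabets need "
                f"2 x {self.interface_alphabet_size} <= {len(AMINO_ACIDS)} letters"
            )
        if not 2 <= self.surface_pool_size <= len(AMINO_ACIDS):
            raise ValueError("surface_pool_size out of range")


def default_spec(
    seed: int = 0,
    n_columns: int = 120,
    frac_interface: float = 0.15,
    frac_buried: float = 0.35,
    **overrides,
) -> SimSpec:
    """A SimSpec with a random (seeded) column-class layout."""
    rng = np.random.default_rng(seed)
    cols = rng.permutation(n_columns)
    n_if = max(1, round(frac_interface * n_columns))
    n_bu = max(1, round(frac_buried * n_columns))
    return SimSpec(
        n_columns=n_columns,
        interface_columns=frozenset(int(c) for c in cols[:n_if]),
        buried_columns=frozenset(int(c) for c in cols[n_if : n_if + n_bu]),
        surface_columns=frozenset(int(c) for c in cols[n_if + n_bu :]),
        seed=seed,
        **overrides,
    )


@dataclass
class SimResult:
    """One simulated pair group, ready for the whole pipeline."""

    group: AlignedGroup
    records: list[SequenceRecord]
    classes: dict[str, InteractionClass]
    annotations: list[ResidueAnnotation]
    hits: list[RankedHit]
    truth: dict = field(default_factory=dict)


@dataclass(frozen=True)
class _ColumnModel:
    kind: str  # interface / surface / buried
    disjoint: bool
    pool_H: tuple[int, ...]
    weights_H: tuple[float, ...]
    pool_M: tuple[int, ...]
    weights_M: tuple[float, ...]


def _build_column_models(spec: SimSpec, rng: np.random.Generator) -> list[_ColumnModel]:
    n_aa = len(AMINO_ACIDS)
    k = spec.interface_alphabet_size
    models: list[_ColumnModel] = []
    for col in range(spec.n_columns):
        if col in spec.buried_columns:
            pool = tuple(int(x) for x in rng.choice(n_aa, size=3, replace=False))
            dom = pool[0]
            rest = 1.0 - spec.conservation_buried
            w = (spec.conservation_buried + rest / 3, rest / 3, rest / 3)
            models.append(_ColumnModel("buried", False, pool, w, pool, w))
            continue
        kind = "interface" if col in spec.interface_columns else "surface"
        disjoint = kind == "interface" and rng.random() < spec.specificity
        if disjoint:
            letters = rng.choice(n_aa, size=2 * k, replace=False)
            pool_H = tuple(int(x) for x in letters[:k])
            pool_M = tuple(int(x) for x in letters[k:])
            w_H = tuple(rng.dirichlet(np.full(k, 1.5)))
            w_M = tuple(rng.dirichlet(np.full(k, 1.5)))
            models.append(_ColumnModel(kind, True, pool_H, w_H, pool_M, w_M))
        else:
            pool = tuple(
                int(x)
                for x in rng.choice(n_aa, size=spec.surface_pool_size, replace=False)
            )
            w = tuple(rng.dirichlet(np.full(spec.surface_pool_size, 1.5)))
            models.append(_ColumnModel(kind, False, pool, w, pool, w))
    return models


def _draw_residue(
    model: _ColumnModel,
    true_class: InteractionClass,
    spec: SimSpec,
    rng: np.random.Generator,
) -> str:
    pool = model.pool_H if true_class is H else model.pool_M
    weights = model.weights_H if true_class is H else model.weights_M
    if rng.random() < spec.substitution_rate:
        # noise stays within the group's allowed pool, so planted
        # disjointness between the groups is never violated
        idx = pool[int(rng.integers(len(pool)))]
    else:
        idx = pool[int(rng.choice(len(pool), p=np.asarray(weights)))]
    return AMINO_ACIDS[idx]


def _simulate(
    spec: SimSpec,
    true_class_H_block: list[InteractionClass],
    true_class_M_block: list[InteractionClass],
) -> SimResult:
    rng = np.random.default_rng(spec.seed)
    models = _build_column_models(spec, rng)

    ids_H = [f"H{i:03d}" for i in range(spec.n_H)]
    ids_M = [f"M{i:03d}" for i in range(spec.n_M)]
    assigned = dict(zip(ids_H, [H] * spec.n_H)) | dict(zip(ids_M, [M] * spec.n_M))
    true_of = dict(zip(ids_H, true_class_H_block)) | dict(
        zip(ids_M, true_class_M_block)
    )

    seqs: dict[str, str] = {}
    for sid in ids_H + ids_M:
        seqs[sid] = "".join(
            _draw_residue(models[c], true_of[sid], spec, rng)
            for c in range(spec.n_columns)
        )

    query_id = ids_H[0]
    group = AlignedGroup(
        rows=[(sid, assigned[sid], seqs[sid]) for sid in ids_H + ids_M],
        query_id=query_id,
    )
    records = [SequenceRecord(sid, assigned[sid], seqs[sid]) for sid in ids_H + ids_M]

    annotations = _make_annotations(spec, seqs[query_id], rng)
    hits = _make_hits(spec, ids_H, ids_M)

    truth = {
        "query_id": query_id,
        "interacting_ids": ids_H,
        "noninteracting_ids": ids_M,
        "true_class": {sid: cls.value for sid, cls in true_of.items()},
        "assigned_class": {sid: cls.value for sid, cls in assigned.items()},
        "interface_columns": sorted(spec.interface_columns),
        "surface_columns": sorted(spec.surface_columns),
        "buried_columns": sorted(spec.buried_columns),
        "disjoint_columns": sorted(
            c for c, m in enumerate(models) if m.disjoint
        ),
        "seed": spec.seed,
        "specificity": spec.specificity,
    }
    return SimResult(group, records, dict(assigned), annotations, hits, truth)


def _make_annotations(
    spec: SimSpec, query_seq: str, rng: np.random.Generator
) -> list[ResidueAnnotation]:
    annotations = []
    for col in range(spec.n_columns):
        aa = query_seq[col]
        if col in spec.buried_columns:
            asa, bsa = 0.0, 0.0
        elif col in spec.surface_columns:
            asa, bsa = round(float(rng.uniform(20, 120)), 1), 0.0
        else:
            asa = round(float(rng.uniform(20, 120)), 1)
            bsa = round(float(rng.uniform(5, 0.8 * asa)), 1)
        annotations.append(ResidueAnnotation(col + 1, aa, asa, bsa))
    return annotations


def _sim_hsp_length(spec: SimSpec) -> int:
    # longer HSP <-> stronger planted divergence signal
    return max(1, round(spec.n_columns * (0.3 + 0.7 * spec.specificity)))


def _make_hits(spec: SimSpec, ids_H: list[str], ids_M: list[str]) -> list[RankedHit]:
    """Ranked hits from which first-cross recovers the membership.

    The query's list carries its homodimer co-members first (ascending
    e-values), then the anchor monomer, then decoy monomers; the
    anchor's list symmetrically.  All e-values are strictly increasing.
    """
    query, anchor = ids_H[0], ids_M[0]
    hsp = _sim_hsp_length(spec)
    hits: list[RankedHit] = []

    def add(qid: str, sid: str, rank: int) -> None:
        hits.append(
            RankedHit(
                query_id=qid,
                subject_id=sid,
                percent_identity=max(20.0, 95.0 - 2.0 * rank),
                hsp_length=hsp,
                evalue=1e-60 * 10.0 ** rank,
                bitscore=400.0 - 5.0 * rank,
            )
        )

    rank = 0
    for sid in ids_H[1:]:
        add(query, sid, rank)
        rank += 1
    add(query, anchor, rank)  # the first cross
    rank += 1
    for sid in ids_M[1:3]:  # decoys beyond the cross
        add(query, sid, rank)
        rank += 1

    rank = 0
    for sid in ids_M[1:]:
        add(anchor, sid, rank)
        rank += 1
    add(anchor, query, rank)  # anchor's first homodimer hit
    rank += 1
    for sid in ids_H[1:3]:
        add(anchor, sid, rank)
        rank += 1
    return hits


def simulate_pair_group(spec: SimSpec) -> SimResult:
    """Simulate one clean pair group (all labels correct)."""
    return _simulate(spec, [H] * spec.n_H, [M] * spec.n_M)


def simulate_mixed_labels(spec: SimSpec, mix_fraction: float) -> SimResult:
    """Simulate a pair group with label pollution.

    ``floor(mix_fraction * n)`` members of each subgroup are drawn from
    the *other* class's column distributions while keeping their
    subgroup assignment — emulating a relaxed selection threshold that
    lets opposite-class sequences into each subgroup.  The truth table
    records both the true and the assigned class of every member.  With
    ``mix_fraction = 0`` the output is identical to
    :func:`simulate_pair_group`.
    """
    if not 0 <= mix_fraction <= 0.5:
        raise ValueError("mix_fraction must be in [0, 0.5]")
    k_H = int(mix_fraction * spec.n_H)
    k_M = int(mix_fraction * spec.n_M)
    # query (first H row) always keeps its true class
    true_H = [H] * (spec.n_H - k_H) + [M] * k_H
    true_M = [M] * (spec.n_M - k_M) + [H] * k_M
    return _simulate(spec, true_H, true_M)


def write_simulation(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated pair group as pipeline-ready text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sequences": outdir / "sequences.fasta",
        "alignment": outdir / "alignment.afa",
        "classes": outdir / "classes.tsv",
        "hits": outdir / "hits.tsv",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "truth.json",
    }
    sh_io.write_fasta(result.records, paths["sequences"])
    sh_io.write_aligned_fasta(result.group, paths["alignment"])
    sh_io.write_classes_tsv(result.classes, paths["classes"])
    sh_io.write_blast_tabular(result.hits, paths["hits"])
    sh_io.write_residue_annotations(result.annotations, paths["annotations"])
    with open(paths["truth"], "w") as fh:
        json.dump(result.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def spec_with_seed(spec: SimSpec, seed: int) -> SimSpec:
    """The same simulation conditions under a different seed."""
    return replace(spec, seed=seed)
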