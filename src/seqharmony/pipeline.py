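"""End-to-end orchestration: filter -> pair groups -> score -> evaluate.

The pipeline consumes files only (every stage can be re-run on its own
outputs) and writes a run directory containing per-group score tables
and metrics, an aggregate summary, a log, and a manifest recording the
configuration, input checksums and package version.  Re-running with
the same inputs and configuration reproduces all numeric outputs
byte-identically.

Multiple sequence alignment is an import boundary: the pipeline reads
aligned FASTA produced externally (e.g. by MUSCLE or MAFFT with default
parameters) rather than shelling out to an aligner.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import dataset, evaluation, io as sh_io, pairgroup, scoring
from .types import AlignedGroup, GroupScheme, InteractionClass


@dataclass
class RunConfig:
    """Configuration of one pipeline run; serialised into the manifest."""

    sequences: str
    classes: str
    hits: str
    alignments: str  # file (single group) or directory of <query_id>.afa
    annotations: str  # file (single group) or directory of <query_id>.tsv
    outdir: str
    min_len: int = 50
    identity_threshold: float = 100.0
    min_hsp: int = 0
    min_query_len: int = 0
    min_subgroup: int = pairgroup.MIN_SUBGROUP
    scheme: str = GroupScheme.FIRST_CROSS.value
    fixed_evalue: float = 1e-10
    mix_fraction: float = 0.20
    sh_cutoff: float = evaluation.SH_CUTOFF_DEFAULT
    universe: str = "all_classified"
    unique_groups: bool = False
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _resolve(base: str | Path, query_id: str, suffix: str) -> Path | None:
    base = Path(base)
    if base.is_file():
        return base
    candidate = base / f"{query_id}{suffix}"
    return candidate if candidate.exists() else None


def _group_alignment(
    path: Path, group: pairgroup.PairGroup
) -> AlignedGroup:
    """Load a group's alignment, keeping member rows only and labelling
    rows by subgroup membership (the scoring groups)."""
    membership = {sid: InteractionClass.HOMODIMER for sid in group.interacting_ids}
    membership |= {sid: InteractionClass.MONOMER for sid in group.noninteracting_ids}
    from Bio import SeqIO

    rows = []
    for entry in SeqIO.parse(str(path), "fasta"):
        cls = membership.get(entry.id)
        if cls is None:
            continue
        rows.append((entry.id, cls, str(entry.seq).upper()))
    return AlignedGroup(rows=rows, query_id=group.query_id)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full pipeline and return the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t0 = time.perf_counter()

    def log(msg: str) -> None:
        log_lines.append(f"[{time.perf_counter() - t0:8.2f}s] {msg}")

    # --- stage: load + sequence filters -------------------------------
    try:
        class_of = sh_io.read_classes_tsv(config.classes)
        records = sh_io.read_fasta_with_classes(config.sequences, class_of)
    except Exception as exc:
        raise RuntimeError(f"stage load: {exc}") from exc
    log(f"load: {len(records)} sequences")

    try:
        records = dataset.filter_min_length(records, config.min_len)
        records = dataset.dedupe_identical(records)
        if config.identity_threshold < 100 and records:
            records = dataset.identity_cluster(records, config.identity_threshold)
    except Exception as exc:
        raise RuntimeError(f"stage filter: {exc}") from exc
    by_id = {r.seq_id: r for r in records}
    log(f"filter: {len(records)} sequences kept")

    # --- stage: pair groups -------------------------------------------
    try:
        hits = [
            h
            for h in sh_io.read_blast_tabular(config.hits)
            if h.query_id in by_id and h.subject_id in by_id
        ]
        hits_of = pairgroup.rank_hits(hits)
        groups = []
        for rec in records:
            if rec.interaction_class is not InteractionClass.HOMODIMER:
                continue
            g = pairgroup.build_pair_group(
                rec,
                hits_of,
                {r.seq_id: r.interaction_class for r in records},
                scheme=GroupScheme(config.scheme),
                fixed_evalue=config.fixed_evalue,
                mix_fraction=config.mix_fraction,
                min_subgroup=config.min_subgroup,
            )
            if g is not None:
                groups.append(g)
        groups = pairgroup.filter_pair_groups(
            groups, by_id, config.min_hsp, config.min_query_len
        )
        if config.unique_groups:
            groups = pairgroup.unique_groups(groups)
    except Exception as exc:
        raise RuntimeError(f"stage pairgroup: {exc}") from exc
    log(f"pairgroup: {len(groups)} pair groups")

    # --- stage: score + evaluate per group ----------------------------
    groups_dir = outdir / "groups"
    groups_dir.mkdir(exist_ok=True)
    reports = []
    skipped = []
    for group in groups:
        aln_path = _resolve(config.alignments, group.query_id, ".afa")
        ann_path = _resolve(config.annotations, group.query_id, ".tsv")
        if aln_path is None or ann_path is None:
            skipped.append(group.query_id)
            continue
        try:
            aligned = _group_alignment(aln_path, group)
            scores = scoring.score_group(aligned)
            annotations = sh_io.read_residue_annotations(ann_path)
            sh_io.classify_annotations_inplace(annotations)
            report = evaluation.evaluate_group(
                group.query_id,
                scores,
                annotations,
                cutoff=config.sh_cutoff,
                universe=config.universe,  # type: ignore[arg-type]
            )
        except Exception as exc:
            raise RuntimeError(f"stage score/evaluate [{group.query_id}]: {exc}") from exc
        gdir = groups_dir / group.query_id
        gdir.mkdir(exist_ok=True)
        sh_io.write_scores_tsv(scores, gdir / "scores.tsv")
        sh_io.write_metrics_json(report, gdir / "metrics.json")
        reports.append(report)
    log(f"score/evaluate: {len(reports)} groups scored, {len(skipped)} skipped")

    # --- stage: aggregate ---------------------------------------------
    if reports:
        summary = evaluation.aggregate(reports)
    else:
        summary = {
            "n_groups": 0,
            "n_auc_undefined": 0,
            "mean_auc": None,
            "class_means": {},
        }
    summary["n_groups_skipped_no_files"] = len(skipped)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log("aggregate: summary written")

    manifest = {
        "tool": "seqharmony",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {
            name: _sha256(Path(p))
            for name, p in (
                ("sequences", config.sequences),
                ("classes", config.classes),
                ("hits", config.hits),
            )
            if Path(p).is_file()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return outdir
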