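"""Construction of interacting / non-interacting pair groups.

Starting from ranked homology hits of a homodimer query, the
*first-cross* rule takes every homodimer hit ranked strictly above the
query's first monomer hit as the interacting subgroup H (the query
included), and symmetrically seeds the non-interacting subgroup M from
that first monomer (the *anchor*): every monomer hit of the anchor
ranked strictly above the anchor's first homodimer hit.  Both subgroups
must reach a minimum size (five by default) for the pair group to be
usable.

Three threshold variants probe the robustness of the selection:

* ``lower_of_two`` — both subgroups truncated at the lower of the two
  first-cross e-value cut-offs (a stricter selection);
* ``fixed_evalue`` — both subgroups cut at one fixed e-value
  (default 1e-10), for the case where no interaction annotation exists;
* ``mixed20`` — thresholds relaxed past the first cross until a set
  fraction (default 20%) of the other class pollutes each subgroup.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Sequence

from .types import (
    GroupScheme,
    InteractionClass,
    PairGroup,
    RankedHit,
    SequenceRecord,
)

MIN_SUBGROUP = 5

_HitKey = tuple[float, float, str]


def _rank_key(h: RankedHit) -> _HitKey:
    # ascending e-value; ties: descending bitscore, then subject id
    return (h.evalue, -h.bitscore, h.subject_id)


def rank_hits(
    hits: Sequence[RankedHit], drop_self: bool = True
) -> dict[str, list[RankedHit]]:
    """Group hits by query, collapse multi-HSP pairs, sort for ranking.

    Only the first tabular line per query–subject pair (the best HSP) is
    kept; self-hits are dropped; each list is sorted by ascending
    e-value with ties broken by descending bitscore then subject id.
    """
    per_query: dict[str, list[RankedHit]] = defaultdict(list)
    seen: set[tuple[str, str]] = set()
    for h in hits:
        if drop_self and h.query_id == h.subject_id:
            continue
        key = (h.query_id, h.subject_id)
        if key in seen:
            continue
        seen.add(key)
        per_query[h.query_id].append(h)
    return {q: sorted(hl, key=_rank_key) for q, hl in per_query.items()}


def _check_sorted(hits: Sequence[RankedHit], query_id: str) -> None:
    keys = [_rank_key(h) for h in hits]
    if keys != sorted(keys):
        raise ValueError(f"hit list of {query_id!r} is not ranked")


def _first_cross_prefix(
    hits: Sequence[RankedHit],
    own_class: InteractionClass,
    class_of: Mapping[str, InteractionClass],
) -> tuple[list[RankedHit], RankedHit | None]:
    """Same-class hits ranked strictly above the first opposite hit."""
    prefix: list[RankedHit] = []
    for h in hits:
        if class_of[h.subject_id] is own_class:
            prefix.append(h)
        else:
            return prefix, h
    return prefix, None


def _mixed_prefix(
    hits: Sequence[RankedHit],
    own_class: InteractionClass,
    class_of: Mapping[str, InteractionClass],
    mix_fraction: float,
    skip: str | None = None,
    n_seed: int = 1,
) -> list[RankedHit]:
    """Relax the rank threshold until pollution would exceed the bound.

    Hits of either class are taken in rank order; an opposite-class hit
    is admitted only while the opposite-class fraction of the subgroup
    (seed members included) stays at or below ``mix_fraction``.  The
    first opposite-class hit that would break the bound terminates the
    prefix — the threshold is a rank cut, not a per-hit skip.  ``skip``
    names one subject (the seed of the other subgroup): it must pass
    the pollution bound for the walk to continue past it, but it joins
    the other subgroup, not this one.
    """
    taken: list[RankedHit] = []
    n_other = 0
    for h in hits:
        if class_of[h.subject_id] is own_class:
            taken.append(h)
            continue
        if (n_other + 1) / (n_seed + len(taken) + 1) > mix_fraction:
            break
        if h.subject_id != skip:
            n_other += 1
            taken.append(h)
    return taken


def build_pair_group(
    query: SequenceRecord,
    hits_of: Mapping[str, Sequence[RankedHit]],
    class_of: Mapping[str, InteractionClass],
    scheme: GroupScheme = GroupScheme.FIRST_CROSS,
    fixed_evalue: float = 1e-10,
    mix_fraction: float = 0.20,
    min_subgroup: int = MIN_SUBGROUP,
) -> PairGroup | None:
    """Build one pair group for a homodimer query, or ``None``.

    ``hits_of`` maps each sequence id to its ranked hit list (ascending
    e-value, ties by descending bitscore then subject id; self-hits
    excluded — see :func:`rank_hits`).  Returns ``None`` when either
    subgroup ends up smaller than ``min_subgroup`` or the query has no
    monomer hit at all.
    """
    if query.interaction_class is not InteractionClass.HOMODIMER:
        raise ValueError(f"query {query.seq_id!r} is not a homodimer")
    scheme = GroupScheme(scheme)

    q_hits = list(hits_of.get(query.seq_id, ()))
    _check_sorted(q_hits, query.seq_id)

    h_prefix, anchor_hit = _first_cross_prefix(
        q_hits, InteractionClass.HOMODIMER, class_of
    )
    if anchor_hit is None:
        return None  # no monomer homolog found
    anchor_id = anchor_hit.subject_id

    a_hits = list(hits_of.get(anchor_id, ()))
    _check_sorted(a_hits, anchor_id)
    m_prefix, m_cross = _first_cross_prefix(
        a_hits, InteractionClass.MONOMER, class_of
    )

    evalue_cut_H = anchor_hit.evalue
    evalue_cut_M = m_cross.evalue if m_cross is not None else float("inf")

    if scheme is GroupScheme.FIRST_CROSS:
        h_sel, m_sel = h_prefix, m_prefix
    elif scheme is GroupScheme.LOWER_OF_TWO:
        cut = min(evalue_cut_H, evalue_cut_M)
        h_sel = [h for h in h_prefix if h.evalue < cut]
        m_sel = [h for h in m_prefix if h.evalue < cut]
        evalue_cut_H = evalue_cut_M = cut
    elif scheme is GroupScheme.FIXED_EVALUE:
        h_sel = [
            h
            for h in q_hits
            if class_of[h.subject_id] is InteractionClass.HOMODIMER
            and h.evalue <= fixed_evalue
        ]
        m_sel = [
            h
            for h in a_hits
            if class_of[h.subject_id] is InteractionClass.MONOMER
            and h.evalue <= fixed_evalue
        ]
        evalue_cut_H = evalue_cut_M = fixed_evalue
    elif scheme is GroupScheme.MIXED20:
        if not 0 <= mix_fraction <= 0.5:
            raise ValueError("mix_fraction must be in [0, 0.5]")
        # the anchor seeds M and the query seeds H: neither pollutes
        # the other subgroup
        h_sel = _mixed_prefix(
            q_hits, InteractionClass.HOMODIMER, class_of, mix_fraction,
            skip=anchor_id,
        )
        m_sel = _mixed_prefix(
            a_hits, InteractionClass.MONOMER, class_of, mix_fraction,
            skip=query.seq_id,
        )
    else:  # pragma: no cover
        raise ValueError(f"unknown scheme {scheme}")

    interacting = [query.seq_id] + [h.subject_id for h in h_sel]
    noninteracting = [anchor_id] + [h.subject_id for h in m_sel]
    # A sequence cannot sit in both subgroups; drop later duplicates
    # from M (possible only under the mixed scheme).
    h_set = set(interacting)
    noninteracting = [s for s in noninteracting if s not in h_set]

    if len(interacting) < min_subgroup or len(noninteracting) < min_subgroup:
        return None

    return PairGroup(
        query_id=query.seq_id,
        interacting_ids=interacting,
        noninteracting_ids=noninteracting,
        anchor_monomer_id=anchor_id,
        hsp_len_query_to_anchor=anchor_hit.hsp_length,
        evalue_cut_H=evalue_cut_H,
        evalue_cut_M=evalue_cut_M,
        scheme=scheme,
    )


def filter_pair_groups(
    groups: list[PairGroup],
    records: Mapping[str, SequenceRecord],
    min_hsp: int = 0,
    min_query_len: int = 0,
) -> list[PairGroup]:
    """Keep groups passing the HSP-length and query-length cut-offs.

    Both bounds are inclusive; raising either can only remove groups.
    """
    if min_hsp < 0 or min_query_len < 0:
        raise ValueError("cut-offs must be non-negative")
    return [
        g
        for g in groups
        if g.hsp_len_query_to_anchor >= min_hsp
        and records[g.query_id].length >= min_query_len
    ]


def unique_groups(groups: list[PairGroup]) -> list[PairGroup]:
    """Collapse groups with identical member sets (first kept)."""
    seen: set[tuple[frozenset[str], frozenset[str]]] = set()
    out: list[PairGroup] = []
    for g in groups:
        key = (frozenset(g.interacting_ids), frozenset(g.noninteracting_ids))
        if key in seen:
            continue
        seen.add(key)
        out.append(g)
    return out
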