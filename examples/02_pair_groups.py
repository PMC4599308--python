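"""Build a pair group from ranked homology hits with the first-cross rule.

Constructs a toy ranked hit list for one homodimer query: the query's
homodimer homologs rank above its first monomer hit (the anchor), and
the anchor's monomer homologs rank above its first homodimer hit.
"""

from seqharmony import InteractionClass, RankedHit, SequenceRecord, build_pair_group, rank_hits

H, M = InteractionClass.HOMODIMER, InteractionClass.MONOMER


def hit(q, s, rank):
    return RankedHit(q, s, 90.0 - rank, 150, 1e-40 * 10**rank, 300.0 - rank)


class_of = {"Q": H, "h1": H, "h2": H, "h3": H, "h4": H,
            "a": M, "m1": M, "m2": M, "m3": M, "m4": M, "far": M}

hits = (
    # query's ranked list: four homodimers, then the first monomer "a"
    [hit("Q", s, i) for i, s in enumerate(["h1", "h2", "h3", "h4", "a", "far"])]
    # anchor's ranked list: four monomers, then a homodimer
    + [hit("a", s, i) for i, s in enumerate(["m1", "m2", "m3", "m4", "h1"])]
)

query = SequenceRecord("Q", H, "M" * 200)
group = build_pair_group(query, rank_hits(hits), class_of)

print(f"query:            {group.query_id}")
print(f"anchor monomer:   {group.anchor_monomer_id}")
print(f"interacting (H):  {group.interacting_ids}")
print(f"non-interacting:  {group.noninteracting_ids}")
print(f"HSP query-anchor: {group.hsp_len_query_to_anchor} aa")
print()
print(
    "Both subgroups reach the minimum of five members: the query plus\n"
    "every homodimer ranked above its first monomer hit, and the anchor\n"
    "plus every monomer ranked above the anchor's first homodimer hit.\n"
    "The hit 'far' ranks below the cross and is excluded."
)
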