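from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seqharmony.types import AA_INDEX, AlignedGroup, InteractionClass

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def freq(composition: dict[str, float]) -> np.ndarray:
    """A 20-vector amino-acid composition from a letter->fraction map."""
    v = np.zeros(20)
    for aa, p in composition.items():
        v[AA_INDEX[aa]] = p
    return v


def make_group(
    h_rows: dict[str, str],
    m_rows: dict[str, str],
    query_id: str | None = None,
) -> AlignedGroup:
    """A labelled alignment from per-id gapped sequences."""
    rows = [
        (sid, InteractionClass.HOMODIMER, seq) for sid, seq in h_rows.items()
    ] + [(sid, InteractionClass.MONOMER, seq) for sid, seq in m_rows.items()]
    return AlignedGroup(rows=rows, query_id=query_id or next(iter(h_rows)))


@pytest.fixture
def small_alignment() -> AlignedGroup:
    """Three planted column types: shared-conserved, group-disjoint,
    shared-diverse; the query row carries a gap at column 3."""
    return make_group(
        h_rows={
            "Q": "MAAC-K",
            "H1": "MAVCWK",
            "H2": "MAVCWK",
            "H3": "MACCWK",
            "H4": "MAACWK",
        },
        m_rows={
            "M0": "MWACWE",
            "M1": "MWVCWE",
            "M2": "MWCCWE",
            "M3": "MWACWE",
            "M4": "MWVCWE",
        },
        query_id="Q",
    )
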