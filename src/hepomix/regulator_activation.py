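"""Regulator-network overlap testing and activation-state calling.

For each knowledge-base regulator, the overlap of its direct targets with
the differential set is scored by a right-tailed Fisher test over the
analysis universe, and the coherence of target directions with edge signs by
an activation z-score

    z = sum over differential direction-resolved targets of
        edge_sign * target_direction_sign / sqrt(m)

so |z| <= sqrt(m). A regulator is called activated when z >= z_min and
p < alpha, inhibited when z <= -z_min and p < alpha, otherwise no call. The
call never requires the regulator itself to be differential — a regulator
may act purely post-translationally while its targets shift.

Regulator analysis additionally requires tissue (liver) evidence on the
edges: ``tissue_filter`` drops unevidenced edges first, and regulators left
without outgoing edges drop out of the candidate set.
"""

from __future__ import annotations

import math
from typing import Mapping

import pandas as pd

from .kb_model import Edge, KnowledgeBase, ValidationError
from .integration_enrichment import AnalysisSet, fisher_right_tail, _DIR_SIGN

__all__ = [
    "STATE_ACTIVATED",
    "STATE_INHIBITED",
    "STATE_NONE",
    "tissue_filter",
    "activation_z",
    "call_networks",
]

STATE_ACTIVATED = "activated"
STATE_INHIBITED = "inhibited"
STATE_NONE = "none"


def tissue_filter(kb: KnowledgeBase) -> KnowledgeBase:
    """Keep only tissue-evidenced edges; drop regulators left without edges."""
    edges = [e for e in kb.edges if e.tissue_evidence]
    sources = {e.source for e in edges}
    return KnowledgeBase(
        pathways=dict(kb.pathways),
        edges=edges,
        regulators=kb.regulators & sources,
        mirna_targets=list(kb.mirna_targets),
    )


def activation_z(
    edges: list[Edge],
    directions: Mapping[str, str],
    exclude: set[str] | None = None,
) -> tuple[float, int]:
    """Sign-consistency activation score over a regulator's edges.

    ``directions`` maps differential molecules to "up"/"down" (or the
    exclusive labels); targets in ``exclude`` (direction conflicts) are left
    out. Returns (z, m); m = 0 yields (nan, 0) meaning no call is possible.
    """
    exclude = exclude or set()
    total = 0
    m = 0
    for e in edges:
        if e.target in exclude or e.target not in directions:
            continue
        total += e.sign * _DIR_SIGN[directions[e.target]]
        m += 1
    if m == 0:
        return math.nan, 0
    return total / math.sqrt(m), m


def call_networks(
    analysis_set: AnalysisSet,
    kb: KnowledgeBase,
    alpha: float = 0.05,
    z_min: float = 2.0,
    require_tissue_evidence: bool = True,
) -> pd.DataFrame:
    """Overlap p-value, activation z and state for every candidate regulator.

    Columns: regulator, K (direct targets in universe), k (differential
    direct targets), m (direction-resolved targets entering z), n, N,
    p_value, z, state. Regulators whose targets are all absent from the
    universe are omitted. Sorted ascending by p-value.
    """
    if z_min <= 0:
        raise ValidationError("z_min must be positive")
    base = tissue_filter(kb) if require_tissue_evidence else kb
    N = len(analysis_set.universe)
    n = len(analysis_set.differential)
    rows = []
    for reg in sorted(base.regulators):
        edges = [e for e in base.regulator_edges(reg) if e.relation == "regulates"]
        in_universe = [e for e in edges if e.target in analysis_set.universe]
        K = len({e.target for e in in_universe})
        if K == 0:
            continue
        diff_targets = {
            e.target for e in in_universe if e.target in analysis_set.differential
        }
        k = len(diff_targets)
        p = fisher_right_tail(k, K, n, N)
        z, m = activation_z(
            in_universe, analysis_set.direction_of, exclude=analysis_set.conflicts
        )
        state = STATE_NONE
        if m >= 1 and p < alpha and not math.isnan(z):
            if z >= z_min:
                state = STATE_ACTIVATED
            elif z <= -z_min:
                state = STATE_INHIBITED
        rows.append((reg, K, k, m, n, N, p, z, state))
    out = pd.DataFrame(rows, columns=[
        "regulator", "K", "k", "m", "n", "N", "p_value", "z", "state",
    ])
    out = out.sort_values(["p_value", "regulator"], kind="stable").reset_index(drop=True)
    out.attrs["label"] = analysis_set.label
    return out
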