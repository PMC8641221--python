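"""Inverse-expression miRNA-target pairing and merging into enriched sets.

A pair is a differential miRNA and a differential gene/protein target with
strictly opposite directions, connected by a targeting edge whose evidence is
experimentally validated or highly predicted (low-confidence predictions are
excluded). Pairs annotate — but never re-score — significantly enriched
pathways and regulator networks: the miRNA layer adds molecules and putative
regulatory arrows without entering the Fisher test.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .kb_model import KnowledgeBase, ValidationError
from .differential_abundance import DifferentialTable
from .integration_enrichment import AnalysisSet, _DIR_SIGN

__all__ = [
    "ALLOWED_EVIDENCE",
    "find_inverse_pairs",
    "merge_pairs",
    "pair_count_summary",
]

ALLOWED_EVIDENCE = ("validated", "high_predicted")

PAIR_COLUMNS = [
    "mirna", "target", "target_layers", "mirna_direction",
    "target_direction", "evidence",
]


def find_inverse_pairs(
    mirna_table: DifferentialTable,
    analysis_set: AnalysisSet,
    kb: KnowledgeBase,
) -> pd.DataFrame:
    """All strictly inverse, evidence-passing (miRNA, target) pairs.

    Both ends must be differential; the target's direction comes from the
    analysis set (protein precedence over transcript), conflicted targets
    are skipped since their direction is undefined. Deduplicated on
    (miRNA, target); a target differential in both gene-level layers yields
    one pair annotated with both layers.
    """
    mir_dir = {
        row["id"]: row["direction"]
        for _, row in mirna_table.table[mirna_table.table["differential"]].iterrows()
    }
    rows = []
    seen: set[tuple[str, str]] = set()
    for mt in kb.mirna_targets:
        if mt.evidence not in ALLOWED_EVIDENCE:
            continue
        if mt.mirna not in mir_dir:
            continue
        if mt.target not in analysis_set.differential:
            continue
        if mt.target in analysis_set.conflicts:
            continue
        tgt_dir = analysis_set.direction_of[mt.target]
        if _DIR_SIGN[mir_dir[mt.mirna]] == _DIR_SIGN[tgt_dir]:
            continue
        key = (mt.mirna, mt.target)
        if key in seen:
            continue
        seen.add(key)
        layers = "+".join(sorted(analysis_set.layers_of.get(mt.target, set())))
        rows.append((mt.mirna, mt.target, layers,
                     mir_dir[mt.mirna], tgt_dir, mt.evidence))
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return df.sort_values(["mirna", "target"], kind="stable").reset_index(drop=True)


def merge_pairs(
    pairs: pd.DataFrame,
    enrichment: pd.DataFrame,
    calls: pd.DataFrame,
    kb: KnowledgeBase,
) -> dict[str, pd.DataFrame]:
    """Attach inverse pairs to significant pathways and called networks.

    A pair attaches to every significant pathway whose counted molecules
    include its target, and to every called regulator network containing the
    target among its differential direct targets; one miRNA targeting members
    of several sets attaches to each. No p-value is recomputed — the pairing
    is annotation only. Returns {"pathways": ..., "networks": ...,
    "unassigned": ...} with molecule counts reported with and without
    miRNAs.
    """
    if pairs.empty:
        empty = pd.DataFrame(columns=["set_id", "n_molecules", "n_with_mirnas",
                                      "mirna", "target"])
        return {"pathways": empty, "networks": empty.copy(),
                "unassigned": pairs.copy()}

    path_rows = []
    assigned: set[int] = set()
    sig = enrichment[enrichment["significant"]]
    for _, prow in sig.iterrows():
        members = {m.split("(")[0] for m in str(prow["members"]).split(";") if m}
        hit = pairs[pairs["target"].isin(members)]
        mirnas = set(hit["mirna"])
        path_rows.append({
            "set_id": prow["pathway_id"],
            "n_molecules": int(prow["k"]),
            "n_with_mirnas": int(prow["k"]) + len(mirnas),
            "pairs": hit.reset_index(drop=True),
        })
        assigned |= set(hit.index)

    net_rows = []
    called = calls[calls["state"] != "none"]
    for _, crow in called.iterrows():
        targets = {e.target for e in kb.regulator_edges(str(crow["regulator"]))}
        hit = pairs[pairs["target"].isin(targets)]
        mirnas = set(hit["mirna"])
        net_rows.append({
            "set_id": crow["regulator"],
            "n_molecules": int(crow["k"]),
            "n_with_mirnas": int(crow["k"]) + len(mirnas),
            "pairs": hit.reset_index(drop=True),
        })
        assigned |= set(hit.index)

    def _flatten(rows) -> pd.DataFrame:
        flat = []
        for r in rows:
            for _, prow in r["pairs"].iterrows():
                flat.append((r["set_id"], r["n_molecules"], r["n_with_mirnas"],
                             prow["mirna"], prow["target"]))
            if r["pairs"].empty:
                flat.append((r["set_id"], r["n_molecules"], r["n_with_mirnas"],
                             pd.NA, pd.NA))
        return pd.DataFrame(flat, columns=["set_id", "n_molecules",
                                           "n_with_mirnas", "mirna", "target"])

    unassigned = pairs.loc[sorted(set(pairs.index) - assigned)].reset_index(drop=True)
    return {
        "pathways": _flatten(path_rows),
        "networks": _flatten(net_rows),
        "unassigned": unassigned,
    }


def pair_count_summary(pairs: pd.DataFrame) -> tuple[int, int, int]:
    """(number of pairs, distinct miRNAs, distinct targets)."""
    if pairs.empty:
        return 0, 0, 0
    return len(pairs), pairs["mirna"].nunique(), pairs["target"].nunique()


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs[PAIR_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")
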