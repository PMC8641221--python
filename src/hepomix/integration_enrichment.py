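"""Pathway over-representation analysis for single and combined omics layers.

A right-tailed Fisher (hypergeometric) test scores each pathway: with a
universe of N quality-passing molecules, n of them differential, K pathway
members in the universe and k differential pathway members that survive the
direct-connection requirement, the p-value is P(X >= k) for
X ~ Hypergeometric(N, K, n).

Combining layers merges their quality-passing molecule lists into one
universe and their differential lists into one differential set (a molecule
counts once however many layers flag it). This is the integration mechanism:
adding a layer whose differential molecules do not map to a pathway grows n
(the test's denominator population) without growing k, so that pathway's
p-value rises, while pathways gaining connected molecules from the new layer
gain significance.

The direct-connection requirement keeps, before overlap counting, only
differential molecules with at least one knowledge-base edge to another
differential molecule — globally by default, or restricted to within-pathway
partners with ``connection_scope="pathway"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .kb_model import KnowledgeBase, LayerKind, ValidationError
from .differential_abundance import (
    DIRECTION_DOWN,
    DIRECTION_UP,
    EXCLUSIVE_CONTROL,
    EXCLUSIVE_TREATMENT,
    DifferentialTable,
)

__all__ = [
    "AnalysisSet",
    "build_analysis_set",
    "restrict_to_connected",
    "fisher_right_tail",
    "enrich",
    "compare_combinations",
]

# precedence when the same symbol is differential in several layers: protein
# evidence wins over transcript; metabolites/miRNAs have private id spaces
_LAYER_PRECEDENCE = {
    LayerKind.PROTEIN: 3,
    LayerKind.METABOLITE: 2,
    LayerKind.MIRNA: 2,
    LayerKind.TRANSCRIPT: 1,
}

_DIR_SIGN = {
    DIRECTION_UP: 1,
    DIRECTION_DOWN: -1,
    EXCLUSIVE_TREATMENT: 1,
    EXCLUSIVE_CONTROL: -1,
}


@dataclass
class AnalysisSet:
    """The harmonized multi-layer universe and differential set.

    ``universe`` is the union of quality-passing molecule ids across the
    included layers (gene symbols shared between transcript and protein
    layers collapse to one molecule); ``differential`` the union of
    differential ids; ``direction_of`` maps each differential molecule to
    "up"/"down" with protein direction taking precedence over transcript on
    disagreement, the disagreeing molecules being recorded in ``conflicts``.
    """

    label: str
    universe: set[str]
    differential: set[str]
    direction_of: dict[str, str] = field(default_factory=dict)
    conflicts: set[str] = field(default_factory=set)
    layers_of: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValidationError("analysis set universe is empty")
        if not self.differential <= self.universe:
            raise ValidationError("differential set must be within the universe")


def build_analysis_set(
    tables: Sequence[DifferentialTable], label: str
) -> AnalysisSet:
    """Merge per-layer differential tables into one analysis set."""
    if not tables:
        raise ValidationError("at least one differential table is required")
    universe: set[str] = set()
    differential: set[str] = set()
    direction: dict[str, str] = {}
    precedence: dict[str, int] = {}
    conflicts: set[str] = set()
    layers_of: dict[str, set[str]] = {}

    for tab in tables:
        universe |= tab.universe_ids
        for mol in tab.universe_ids:
            layers_of.setdefault(mol, set()).add(tab.layer_kind.value)
        prec = _LAYER_PRECEDENCE[tab.layer_kind]
        diff_rows = tab.table[tab.table["differential"]]
        for mol, direc in zip(diff_rows["id"], diff_rows["direction"]):
            differential.add(mol)
            sign = _DIR_SIGN[direc]
            new = DIRECTION_UP if sign > 0 else DIRECTION_DOWN
            if mol not in direction:
                direction[mol], precedence[mol] = new, prec
                continue
            if direction[mol] != new:
                conflicts.add(mol)
                if prec > precedence[mol]:
                    direction[mol], precedence[mol] = new, prec
            elif prec > precedence[mol]:
                precedence[mol] = prec
    return AnalysisSet(
        label=label,
        universe=universe,
        differential=differential,
        direction_of=direction,
        conflicts=conflicts,
        layers_of=layers_of,
    )


def restrict_to_connected(
    differential: Iterable[str],
    kb: KnowledgeBase,
    within: set[str] | None = None,
) -> set[str]:
    """Differential molecules with a direct edge to another differential one.

    ``within`` optionally confines both endpoints to a molecule set (the
    within-pathway reading of the direct-connection requirement).
    """
    diff = set(differential)
    if within is not None:
        diff = diff & within
    keep: set[str] = set()
    for e in kb.edges:
        if e.source in diff and e.target in diff:
            keep.add(e.source)
            keep.add(e.target)
    return keep


def fisher_right_tail(k: int, K: int, n: int, N: int) -> float:
    """Right-tail hypergeometric probability P(X >= k), X ~ Hyp(N, K, n).

    Summed from log-gamma log-pmfs for numerical stability; p = 1 for k <= 0.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v < 0 or v != int(v):
            raise ValidationError(f"{name} must be a non-negative integer, got {v}")
    if K > N or n > N:
        raise ValidationError(f"K and n must not exceed N (K={K}, n={n}, N={N})")
    if k > min(K, n):
        raise ValidationError(f"k must not exceed min(K, n) (k={k}, K={K}, n={n})")
    hi = min(K, n)
    lo = max(0, n - (N - K))
    if k <= lo:
        return 1.0  # the tail spans the entire support

    def _log_comb(a: int, b: int) -> float:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    js = np.arange(max(k, lo), hi + 1)
    if js.size == 0:
        return 0.0
    log_terms = (
        _log_comb(K, js) + _log_comb(N - K, n - js) - _log_comb(N, n)
    )
    m = log_terms.max()
    p = float(np.exp(m) * np.exp(log_terms - m).sum())
    return min(p, 1.0)


def enrich(
    analysis_set: AnalysisSet,
    kb: KnowledgeBase,
    pathways: Mapping[str, set[str]] | None = None,
    alpha: float = 0.05,
    strict_alpha: float = 0.01,
    connection_scope: str = "global",
) -> pd.DataFrame:
    """Per-pathway over-representation results for one analysis set.

    Columns: pathway_id, K (pathway molecules in the universe), k
    (differential, connection-passing pathway molecules), n (differential
    set size), N (universe size), p_value, significant (p < alpha),
    significant_strict (p < strict_alpha), members (the k molecules with
    layer provenance). Pathways with K = 0 are skipped with a note column in
    the attribute ``enrich.skipped``. Results sort ascending by p-value.
    """
    if connection_scope not in ("global", "pathway"):
        raise ValidationError(f"unknown connection scope '{connection_scope}'")
    pathway_map = kb.pathways if pathways is None else dict(pathways)
    N = len(analysis_set.universe)
    n = len(analysis_set.differential)
    if connection_scope == "global":
        connected = restrict_to_connected(analysis_set.differential, kb)

    rows = []
    skipped: list[str] = []
    for pid in sorted(pathway_map):
        members = pathway_map[pid]
        in_universe = members & analysis_set.universe
        K = len(in_universe)
        if K == 0:
            skipped.append(pid)
            continue
        if connection_scope == "pathway":
            conn = restrict_to_connected(
                analysis_set.differential, kb, within=set(members)
            )
        else:
            conn = connected
        hits = sorted(in_universe & conn)
        k = len(hits)
        p = fisher_right_tail(k, K, n, N)
        member_str = ";".join(
            f"{m}({'+'.join(sorted(analysis_set.layers_of.get(m, set())))})"
            for m in hits
        )
        rows.append((pid, K, k, n, N, p, p < alpha, p < strict_alpha, member_str))

    out = pd.DataFrame(rows, columns=[
        "pathway_id", "K", "k", "n", "N", "p_value",
        "significant", "significant_strict", "members",
    ])
    out = out.sort_values(["p_value", "pathway_id"], kind="stable").reset_index(drop=True)
    out.attrs["label"] = analysis_set.label
    out.attrs["skipped"] = skipped
    return out


def compare_combinations(
    results: Mapping[str, pd.DataFrame], plot_path=None
) -> pd.DataFrame:
    """Long-format comparison of enrichment across layer combinations.

    One row per (pathway, label) with p-value and overlap count k; pathways
    absent from a label appear with missing markers rather than being
    dropped. Optionally renders the dot plot (pathway x -log10 p, dot size
    ~ k) to ``plot_path``.
    """
    labels = list(results)
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate combination labels")
    if len(labels) < 2:
        raise ValidationError("need at least two labeled result sets")
    all_pathways = sorted({
        pid for df in results.values() for pid in df["pathway_id"]
    })
    rows = []
    for label in labels:
        df = results[label].set_index("pathway_id")
        for pid in all_pathways:
            if pid in df.index:
                rows.append((pid, label, float(df.loc[pid, "p_value"]),
                             int(df.loc[pid, "k"])))
            else:
                rows.append((pid, label, math.nan, pd.NA))
    table = pd.DataFrame(rows, columns=["pathway", "label", "p", "k"])
    if plot_path is not None:
        _dot_plot(table, labels, all_pathways, plot_path)
    return table


def _dot_plot(table: pd.DataFrame, labels, pathways, path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.8 + 1.2 * len(labels)),
                 max(3.0, 0.25 * len(pathways) + 1.0)),
    )
    y_of = {p: i for i, p in enumerate(pathways)}
    x_of = {l: i for i, l in enumerate(labels)}
    for _, row in table.dropna(subset=["p"]).iterrows():
        size = 20.0 + 12.0 * float(row["k"] if pd.notna(row["k"]) else 0)
        neglog = -math.log10(max(float(row["p"]), 1e-300))
        ax.scatter(x_of[row["label"]], y_of[row["pathway"]], s=size,
                   c=[neglog], cmap="viridis", vmin=0.0,
                   vmax=max(1.0, -math.log10(1e-12)))
    ax.set_xticks(range(len(labels)), labels, rotation=30, ha="right")
    ax.set_yticks(range(len(pathways)), pathways, fontsize=7)
    ax.set_xlabel("layer combination")
    ax.set_title("pathway enrichment across layer combinations")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
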