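"""Cross-omics set comparisons, trait overlap and the end-to-end pipeline.

``run_pipeline`` drives the full analysis on a study (synthetic via a
SimConfig, or loaded from a fixture directory): per-layer differential
testing, analysis-set construction for each single layer, the
transcript+protein pair and the transcript+protein+metabolite triple,
pathway enrichment per combination, regulator-network activation calls,
inverse miRNA pairing merged into the significant sets, and trait-gene
overlap. Every reported count is re-derivable from the attached tables; a
self-consistency audit runs automatically.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import __version__
from .kb_model import (
    KnowledgeBase,
    LayerKind,
    OmicsLayer,
    ValidationError,
    load_knowledge_base,
    read_groups,
    read_layer,
    read_traits,
)
from .differential_abundance import DifferentialTable, run_layer
from .integration_enrichment import (
    AnalysisSet,
    _DIR_SIGN,
    build_analysis_set,
    compare_combinations,
    enrich,
)
from .mirna_pairing import find_inverse_pairs, merge_pairs, pair_count_summary, write_pairs
from .regulator_activation import call_networks
from .synthetic_data import SimConfig, make_knowledge_base, make_traits, simulate_layers

__all__ = [
    "StudyData",
    "RunReport",
    "venn_compare",
    "gwas_overlap",
    "study_from_config",
    "study_from_dir",
    "run_pipeline",
]

_LAYER_FILES = {
    LayerKind.TRANSCRIPT: "transcripts.tsv",
    LayerKind.PROTEIN: "proteins.tsv",
    LayerKind.METABOLITE: "metabolites.tsv",
    LayerKind.MIRNA: "mirnas.tsv",
}

_COMBINATIONS = (
    ("transcript", (LayerKind.TRANSCRIPT,)),
    ("protein", (LayerKind.PROTEIN,)),
    ("metabolite", (LayerKind.METABOLITE,)),
    ("transcript+protein", (LayerKind.TRANSCRIPT, LayerKind.PROTEIN)),
    ("transcript+protein+metabolite",
     (LayerKind.TRANSCRIPT, LayerKind.PROTEIN, LayerKind.METABOLITE)),
)


@dataclass
class StudyData:
    """Input bundle: four layers, knowledge base, trait table, config echo."""

    kb: KnowledgeBase
    layers: dict[LayerKind, OmicsLayer]
    traits: pd.DataFrame
    config_echo: dict = field(default_factory=dict)
    seed: int | None = None


def study_from_config(config: SimConfig) -> StudyData:
    kb = make_knowledge_base(config)
    return StudyData(
        kb=kb,
        layers=simulate_layers(config, kb),
        traits=make_traits(config, kb),
        config_echo=config.to_dict(),
        seed=config.seed,
    )


def study_from_dir(path) -> StudyData:
    """Load a fixture directory as written by write_fixture_set."""
    groups = read_groups(os.path.join(path, "groups.tsv"))
    layers = {
        kind: read_layer(os.path.join(path, fname), kind, groups)
        for kind, fname in _LAYER_FILES.items()
    }
    kb = load_knowledge_base(
        os.path.join(path, "pathways.gmt"),
        os.path.join(path, "edges.tsv"),
        os.path.join(path, "mirna_targets.tsv"),
    )
    traits = read_traits(os.path.join(path, "traits.tsv"))
    config_echo: dict = {}
    cfg_path = os.path.join(path, "config.yaml")
    if os.path.exists(cfg_path):
        config_echo = SimConfig.from_yaml(cfg_path).to_dict()
    return StudyData(kb=kb, layers=layers, traits=traits,
                     config_echo=config_echo, seed=config_echo.get("seed"))


# ---------------------------------------------------------------------------
# comparisons and overlaps
# ---------------------------------------------------------------------------

def venn_compare(
    table_a: DifferentialTable,
    table_b: DifferentialTable,
    mode: str = "differential",
) -> tuple[pd.DataFrame, set[str], set[str]]:
    """Set comparison of two layers keyed by shared symbols.

    ``mode="expressed"`` compares quality-passing ids, ``"differential"``
    the differential ids. Returns (common table with per-layer directions
    and a concordant flag from the sign of the abundance ratio, only-in-a
    ids, only-in-b ids).
    """
    if mode not in ("expressed", "differential"):
        raise ValidationError(f"unknown venn mode '{mode}'")
    ids_a = table_a.universe_ids if mode == "expressed" else table_a.differential_ids
    ids_b = table_b.universe_ids if mode == "expressed" else table_b.differential_ids
    common = sorted(ids_a & ids_b)
    dir_a = table_a.table.set_index("id")["direction"]
    dir_b = table_b.table.set_index("id")["direction"]
    rows = []
    for mol in common:
        da, db = dir_a.get(mol), dir_b.get(mol)
        concordant = (
            pd.notna(da) and pd.notna(db)
            and _DIR_SIGN.get(da) == _DIR_SIGN.get(db)
        )
        rows.append((mol, da, db, concordant))
    common_df = pd.DataFrame(
        rows, columns=["id", "direction_a", "direction_b", "concordant"]
    )
    return common_df, ids_a - ids_b, ids_b - ids_a


def gwas_overlap(
    differential: set[str],
    traits: pd.DataFrame,
    scope: str = "all",
    significant_sets: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Differential molecules with trait associations.

    One row per gene with traits and variants aggregated; with
    ``scope="enriched_only"`` the gene must additionally belong to at least
    one significantly enriched pathway/called network (``significant_sets``
    maps set id -> member molecules), reported in a ``sets`` column.
    """
    if scope not in ("all", "enriched_only"):
        raise ValidationError(f"unknown scope '{scope}'")
    if traits.empty:
        return pd.DataFrame(columns=["gene", "traits", "variants", "sets"])
    hit = traits[traits["gene"].isin(differential)]
    rows = []
    for gene, grp in hit.groupby("gene"):
        containing = []
        if significant_sets:
            containing = sorted(
                sid for sid, members in significant_sets.items() if gene in members
            )
        if scope == "enriched_only" and not containing:
            continue
        rows.append((
            gene,
            ";".join(sorted(set(grp["trait"]))),
            ";".join(sorted(set(grp["variant"]))),
            ";".join(containing),
        ))
    return pd.DataFrame(rows, columns=["gene", "traits", "variants", "sets"])


# ---------------------------------------------------------------------------
# run report and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    config_echo: dict
    seed: int | None
    version: str
    diff_tables: dict[LayerKind, DifferentialTable]
    layer_counts: pd.DataFrame
    analysis_sets: dict[str, AnalysisSet]
    enrichments: dict[str, pd.DataFrame]
    comparison: pd.DataFrame
    network_calls: dict[str, pd.DataFrame]
    pairs: pd.DataFrame
    merged: dict[str, pd.DataFrame]
    trait_overlap_all: pd.DataFrame
    trait_overlap_enriched: pd.DataFrame

    def audit(self) -> None:
        """Re-derive every reported count from the attached tables."""
        for kind, tab in self.diff_tables.items():
            row = self.layer_counts.loc[self.layer_counts["layer"] == kind.value]
            if int(row["n_universe"].iloc[0]) != len(tab.universe_ids):
                raise AssertionError(f"universe count mismatch for {kind.value}")
            if int(row["n_differential"].iloc[0]) != len(tab.differential_ids):
                raise AssertionError(f"differential count mismatch for {kind.value}")
        for label, aset in self.analysis_sets.items():
            df = self.enrichments[label]
            if not df.empty:
                if not (df["N"] == len(aset.universe)).all():
                    raise AssertionError(f"universe size mismatch in '{label}'")
                if not (df["n"] == len(aset.differential)).all():
                    raise AssertionError(f"differential size mismatch in '{label}'")
                k_recount = df["members"].map(
                    lambda s: 0 if not s else len(str(s).split(";"))
                )
                if not (df["k"] == k_recount).all():
                    raise AssertionError(f"k vs member list mismatch in '{label}'")
        n_pairs, n_mirnas, n_targets = pair_count_summary(self.pairs)
        if n_pairs != len(self.pairs):
            raise AssertionError("pair count mismatch")

    def summary_lines(self) -> list[str]:
        lines = [f"hepomix {self.version} (seed={self.seed})"]
        for _, row in self.layer_counts.iterrows():
            lines.append(
                f"layer {row['layer']}: {row['n_universe']} quality molecules, "
                f"{row['n_differential']} differential"
            )
        for label, df in self.enrichments.items():
            lines.append(
                f"enrichment [{label}]: {int(df['significant'].sum())} "
                f"significant pathways of {len(df)} "
                f"(n={int(df['n'].iloc[0]) if len(df) else 0}, "
                f"N={int(df['N'].iloc[0]) if len(df) else 0})"
            )
        for label, calls in self.network_calls.items():
            called = calls[calls["state"] != "none"]
            lines.append(
                f"networks [{label}]: {len(called)} called "
                f"({', '.join(called['regulator'] + ':' + called['state'])})"
            )
        n_pairs, n_mirnas, n_targets = pair_count_summary(self.pairs)
        lines.append(
            f"inverse miRNA pairs: {n_pairs} pairs, {n_mirnas} miRNAs, "
            f"{n_targets} targets"
        )
        lines.append(
            f"trait overlap: {len(self.trait_overlap_all)} differential genes "
            f"with trait associations; {len(self.trait_overlap_enriched)} in "
            f"enriched sets"
        )
        return lines


def run_pipeline(
    study: StudyData | SimConfig,
    out_dir=None,
    alpha: float = 0.05,
    z_min: float = 2.0,
    connection_scope: str = "global",
) -> RunReport:
    """Execute the full analysis; optionally write all intermediates."""
    if isinstance(study, SimConfig):
        study = study_from_config(study)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    diff_tables = {
        kind: _stage(f"diff:{kind.value}", run_layer, layer, alpha)
        for kind, layer in study.layers.items()
    }
    layer_counts = pd.DataFrame([
        {
            "layer": kind.value,
            "n_universe": len(tab.universe_ids),
            "n_differential": len(tab.differential_ids),
        }
        for kind, tab in diff_tables.items()
    ])

    analysis_sets = {
        label: _stage(
            f"analysis_set:{label}", build_analysis_set,
            [diff_tables[k] for k in kinds], label,
        )
        for label, kinds in _COMBINATIONS
    }
    enrichments = {
        label: _stage(f"enrich:{label}", enrich, aset, study.kb,
                      alpha=alpha, connection_scope=connection_scope)
        for label, aset in analysis_sets.items()
    }
    plot_path = os.path.join(out_dir, "enrichment_comparison.svg") if out_dir else None
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
    comparison = _stage("compare", compare_combinations, enrichments, plot_path)

    network_calls = {
        label: _stage(f"networks:{label}", call_networks, aset, study.kb,
                      alpha=alpha, z_min=z_min)
        for label, aset in analysis_sets.items()
    }

    triple = "transcript+protein+metabolite"
    pairs = _stage(
        "mirna_pairs", find_inverse_pairs,
        diff_tables[LayerKind.MIRNA], analysis_sets[triple], study.kb,
    )
    merged = _stage(
        "merge_pairs", merge_pairs,
        pairs, enrichments[triple], network_calls[triple], study.kb,
    )

    gene_diff = (
        diff_tables[LayerKind.TRANSCRIPT].differential_ids
        | diff_tables[LayerKind.PROTEIN].differential_ids
        | diff_tables[LayerKind.MIRNA].differential_ids
    )
    sig_sets: dict[str, set[str]] = {}
    sig = enrichments[triple][enrichments[triple]["significant"]]
    for _, row in sig.iterrows():
        sig_sets[str(row["pathway_id"])] = {
            m.split("(")[0] for m in str(row["members"]).split(";") if m
        }
    called = network_calls[triple][network_calls[triple]["state"] != "none"]
    for _, row in called.iterrows():
        sig_sets[str(row["regulator"])] = {
            e.target for e in study.kb.regulator_edges(str(row["regulator"]))
        }
    overlap_all = _stage("traits:all", gwas_overlap, gene_diff, study.traits,
                         "all", sig_sets)
    overlap_enr = _stage("traits:enriched", gwas_overlap, gene_diff,
                         study.traits, "enriched_only", sig_sets)

    report = RunReport(
        config_echo=dict(study.config_echo),
        seed=study.seed,
        version=__version__,
        diff_tables=diff_tables,
        layer_counts=layer_counts,
        analysis_sets=analysis_sets,
        enrichments=enrichments,
        comparison=comparison,
        network_calls=network_calls,
        pairs=pairs,
        merged=merged,
        trait_overlap_all=overlap_all,
        trait_overlap_enriched=overlap_enr,
    )
    report.audit()
    if out_dir:
        _write_report(report, out_dir)
    return report


def _write_report(report: RunReport, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)

    def _tsv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(os.path.join(out_dir, name), sep="\t", index=False,
                  lineterminator="\n")

    for kind, tab in report.diff_tables.items():
        tab.to_tsv(os.path.join(out_dir, f"diff_{kind.value}.tsv"))
    _tsv(report.layer_counts, "layer_counts.tsv")
    for label, df in report.enrichments.items():
        _tsv(df, f"enrichment_{label.replace('+', '_')}.tsv")
    _tsv(report.comparison, "enrichment_comparison.tsv")
    for label, df in report.network_calls.items():
        _tsv(df, f"networks_{label.replace('+', '_')}.tsv")
    write_pairs(report.pairs, os.path.join(out_dir, "mirna_pairs.tsv"))
    for name, df in report.merged.items():
        _tsv(df, f"merged_{name}.tsv")
    _tsv(report.trait_overlap_all, "trait_overlap_all.tsv")
    _tsv(report.trait_overlap_enriched, "trait_overlap_enriched.tsv")
    with open(os.path.join(out_dir, "report.txt"), "w", encoding="utf-8",
              newline="\n") as fh:
        fh.write("\n".join(report.summary_lines()) + "\n")
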