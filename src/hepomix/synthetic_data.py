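"""Synthetic two-group multi-omics study generator.

Generates a knowledge base (pathways, signed regulator edges with tissue
evidence, miRNA targeting) and four abundance layers for a control-vs-
treatment design (default n = 5 per group), with planted signals:

* pathway-concentrated differential abundance — a configurable fraction of a
  planted pathway's members is shifted by a log2 effect in the treatment
  group, across every layer that measures the molecule;
* regulator activation — a planted regulator's direct targets are shifted by
  ``edge_sign * activation * effect``, so a sign-consistency score should
  recover the planted activation state;
* inverse miRNA-target expression — planted miRNAs are shifted opposite to
  their differential targets for a configurable fraction of miRNAs;
* protein missingness — missing-at-random masking plus group-exclusive
  proteins (observed in every sample of one group, in none of the other).

Counts (transcripts, miRNAs) are negative-binomial around lognormal
baselines with per-sample depth variation; intensities (proteins,
metabolites) are lognormal. Everything is deterministic given the seed: one
global seed spawns fixed per-purpose substreams.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .kb_model import (
    GROUP_CONTROL,
    GROUP_TREATMENT,
    Edge,
    KnowledgeBase,
    LayerKind,
    MirnaTarget,
    OmicsLayer,
    ValidationError,
    write_edges,
    write_gmt,
    write_groups,
    write_layer,
    write_mirna_targets,
    write_traits,
)

__all__ = [
    "PlantedPathway",
    "PlantedRegulator",
    "SimConfig",
    "make_knowledge_base",
    "planted_effects",
    "simulate_layers",
    "make_traits",
    "write_fixture_set",
    "null_config",
]

_TRAIT_NAMES = [
    "body mass index",
    "triglycerides",
    "total cholesterol",
    "low density lipoprotein cholesterol",
    "type II diabetes",
    "insulin resistance",
    "non-alcoholic fatty liver disease",
    "alkaline phosphatase",
    "aspartate aminotransferase",
    "fat body mass",
]


@dataclass
class PlantedPathway:
    pathway_id: str
    effect_size: float = 1.5  # log2 fold change, treatment vs control
    affected_fraction: float = 0.6


@dataclass
class PlantedRegulator:
    """Planted activation state for the i-th generated regulator.

    ``activation`` is +1 (activated) or -1 (inhibited); each direct target is
    shifted by ``edge_sign * activation * effect_size`` log2 units.
    """

    regulator_index: int
    activation: int = 1
    effect_size: float = 1.5


@dataclass
class SimConfig:
    seed: int = 0
    n_per_group: int = 5
    n_transcripts: int = 2672
    n_proteins: int = 1000
    n_metabolites: int = 471
    n_mirnas: int = 576
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 40)
    pathway_metabolite_fraction: float = 0.15
    n_regulators: int = 5
    targets_per_regulator: int = 15
    targets_per_mirna: int = 5
    tissue_evidence_rate: float = 0.7
    planted_pathways: list[PlantedPathway] = field(
        default_factory=lambda: [
            PlantedPathway("PW01", 1.5, 0.6),
            PlantedPathway("PW02", -1.5, 0.6),
        ]
    )
    planted_regulators: list[PlantedRegulator] = field(
        default_factory=lambda: [
            PlantedRegulator(0, +1, 1.5),
            PlantedRegulator(1, -1, 1.5),
        ]
    )
    n_planted_mirnas: int = 12
    mirna_effect_size: float = 1.5
    mirna_inverse_fraction: float = 0.8
    protein_missing_rate: float = 0.05
    n_exclusive_proteins: int = 24
    count_dispersion: float = 0.2
    intensity_sigma: float = 0.4
    depth_sigma: float = 0.1

    def __post_init__(self) -> None:
        self.pathway_size_range = tuple(self.pathway_size_range)  # type: ignore[assignment]
        self.planted_pathways = [
            p if isinstance(p, PlantedPathway) else PlantedPathway(**p)
            for p in self.planted_pathways
        ]
        self.planted_regulators = [
            r if isinstance(r, PlantedRegulator) else PlantedRegulator(**r)
            for r in self.planted_regulators
        ]
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_per_group": self.n_per_group,
            "n_transcripts": self.n_transcripts,
            "n_proteins": self.n_proteins,
            "n_metabolites": self.n_metabolites,
            "n_mirnas": self.n_mirnas,
            "n_pathways": self.n_pathways,
            "n_regulators": self.n_regulators,
            "targets_per_regulator": self.targets_per_regulator,
            "targets_per_mirna": self.targets_per_mirna,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValidationError(f"{name} must be >= 1, got {v}")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ValidationError(f"invalid pathway_size_range {self.pathway_size_range}")
        for name, p in (
            ("tissue_evidence_rate", self.tissue_evidence_rate),
            ("mirna_inverse_fraction", self.mirna_inverse_fraction),
            ("protein_missing_rate", self.protein_missing_rate),
            ("pathway_metabolite_fraction", self.pathway_metabolite_fraction),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        if self.count_dispersion <= 0:
            raise ValidationError("count_dispersion must be positive")
        for pp in self.planted_pathways:
            if not np.isfinite(pp.effect_size):
                raise ValidationError("planted effect sizes must be finite")
            if not 0.0 <= pp.affected_fraction <= 1.0:
                raise ValidationError("affected_fraction must be in [0, 1]")
        for pr in self.planted_regulators:
            if pr.activation not in (1, -1):
                raise ValidationError("planted regulator activation must be +1 or -1")
            if not 0 <= pr.regulator_index < self.n_regulators:
                raise ValidationError(
                    f"regulator_index {pr.regulator_index} out of range"
                )
        if self.n_proteins > self.n_transcripts:
            raise ValidationError("protein universe must be a subset of the gene universe")
        if self.n_exclusive_proteins > self.n_proteins:
            raise ValidationError("n_exclusive_proteins exceeds n_proteins")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pathway_size_range"] = list(self.pathway_size_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        return cls(**dict(d))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A configuration with every planted effect removed (null study)."""
    cfg = SimConfig(
        seed=seed,
        planted_pathways=[],
        planted_regulators=[],
        n_planted_mirnas=0,
        **overrides,
    )
    return cfg


# ---------------------------------------------------------------------------
# universe and knowledge base
# ---------------------------------------------------------------------------

def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(config.seed), stream)))


def gene_ids(config: SimConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(1, config.n_transcripts + 1)]


def metabolite_ids(config: SimConfig) -> list[str]:
    return [f"MET{i:04d}" for i in range(1, config.n_metabolites + 1)]


def mirna_ids(config: SimConfig) -> list[str]:
    return [f"miR-{i:04d}" for i in range(1, config.n_mirnas + 1)]


def protein_ids(config: SimConfig, kb_rng: np.random.Generator) -> list[str]:
    genes = gene_ids(config)
    picked = kb_rng.choice(len(genes), size=config.n_proteins, replace=False)
    return [genes[i] for i in sorted(picked)]


def make_knowledge_base(config: SimConfig) -> KnowledgeBase:
    """Draw pathways, regulator/interaction edges and miRNA targeting.

    Pathway members mix gene symbols and metabolite names; members of one
    pathway are wired with interaction edges (a random spanning path plus
    extras) so the direct-connection requirement is satisfiable within a
    pathway. Regulators are genes with signed ``regulates`` edges; a
    configurable share of edges carries tissue (liver) evidence.
    """
    rng = _rng(config, 0)
    genes = gene_ids(config)
    mets = metabolite_ids(config)
    mirnas = mirna_ids(config)
    lo, hi = config.pathway_size_range
    if hi > len(genes) + len(mets):
        raise ValidationError(
            f"molecule universe too small for pathway size up to {hi}"
        )

    pathways: dict[str, set[str]] = {}
    for i in range(1, config.n_pathways + 1):
        size = int(rng.integers(lo, hi + 1))
        n_met = min(int(round(size * config.pathway_metabolite_fraction)), len(mets))
        n_gene = size - n_met
        if n_gene > len(genes):
            raise ValidationError("gene universe too small for requested pathway size")
        members = set(rng.choice(genes, size=n_gene, replace=False))
        if n_met:
            members |= set(rng.choice(mets, size=n_met, replace=False))
        pathways[f"PW{i:02d}"] = members

    edges: list[Edge] = []
    seen: set[tuple[str, str]] = set()

    def _add(src: str, tgt: str, sign: int, relation: str, tev: bool) -> None:
        if src == tgt or (src, tgt) in seen or (tgt, src) in seen:
            return
        seen.add((src, tgt))
        edges.append(Edge(src, tgt, sign, relation, tev))

    # intra-pathway interaction wiring: spanning path + size//2 extra edges
    for pid in sorted(pathways):
        members = sorted(pathways[pid])
        order = rng.permutation(len(members))
        for a, b in zip(order[:-1], order[1:]):
            _add(members[a], members[b],
                 int(rng.choice([1, -1])), "interacts",
                 bool(rng.random() < config.tissue_evidence_rate))
        for _ in range(len(members) // 2):
            a, b = rng.choice(len(members), size=2, replace=False)
            _add(members[a], members[b],
                 int(rng.choice([1, -1])), "interacts",
                 bool(rng.random() < config.tissue_evidence_rate))

    # regulators: genes with signed directed edges to gene targets
    reg_pool = rng.choice(genes, size=config.n_regulators, replace=False)
    regulators = sorted(str(r) for r in reg_pool)
    for reg in regulators:
        candidates = [g for g in genes if g != reg]
        targets = rng.choice(candidates, size=config.targets_per_regulator,
                             replace=False)
        for tgt in sorted(str(t) for t in targets):
            _add(reg, tgt, int(rng.choice([1, -1])), "regulates",
                 bool(rng.random() < config.tissue_evidence_rate))

    mirna_targets: list[MirnaTarget] = []
    ev_levels = np.array(["validated", "high_predicted", "low_predicted"])
    for mi in mirnas:
        tgts = rng.choice(genes, size=config.targets_per_mirna, replace=False)
        evs = rng.choice(ev_levels, size=config.targets_per_mirna,
                         p=[0.3, 0.4, 0.3])
        for tgt, ev in sorted(zip((str(t) for t in tgts), evs)):
            mirna_targets.append(MirnaTarget(mi, tgt, str(ev)))

    return KnowledgeBase(
        pathways=pathways,
        edges=edges,
        regulators=set(regulators),
        mirna_targets=mirna_targets,
    )


# ---------------------------------------------------------------------------
# planted truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedTruth:
    """Ground-truth planted structure, recomputable from (config, kb)."""

    lfc: dict[str, float]  # molecule -> log2 FC (treatment vs control)
    mirna_lfc: dict[str, float]  # planted miRNA -> log2 FC
    inverse_mirnas: set[str]  # planted miRNAs given the inverse direction
    exclusive_treatment: set[str]  # proteins present only in treatment
    exclusive_control: set[str]
    regulator_of: dict[str, int]  # regulator id -> planted activation sign

    @property
    def planted_molecules(self) -> set[str]:
        return {m for m, v in self.lfc.items() if v != 0.0}


def planted_effects(config: SimConfig, kb: KnowledgeBase) -> PlantedTruth:
    """Deterministically assign planted effects given the config and KB."""
    rng = _rng(config, 1)
    lfc: dict[str, float] = {}

    for pp in config.planted_pathways:
        if pp.pathway_id not in kb.pathways:
            raise ValidationError(f"planted pathway '{pp.pathway_id}' not in KB")
        members = sorted(kb.pathways[pp.pathway_id])
        n_aff = int(round(pp.affected_fraction * len(members)))
        affected = rng.choice(members, size=n_aff, replace=False)
        for m in affected:
            lfc[str(m)] = lfc.get(str(m), 0.0) + pp.effect_size

    regulators = sorted(kb.regulators)
    regulator_of: dict[str, int] = {}
    for pr in config.planted_regulators:
        reg = regulators[pr.regulator_index]
        regulator_of[reg] = pr.activation
        for e in kb.regulator_edges(reg):
            lfc[e.target] = lfc.get(e.target, 0.0) + e.sign * pr.activation * pr.effect_size

    # planted miRNAs: miRNAs targeting planted genes, shifted opposite to the
    # majority direction of their planted targets for the inverse fraction
    target_map: dict[str, list[str]] = {}
    for mt in kb.mirna_targets:
        target_map.setdefault(mt.mirna, []).append(mt.target)
    candidates = sorted(
        mi for mi, tgts in target_map.items()
        if any(lfc.get(t, 0.0) != 0.0 for t in tgts)
    )
    n_pl = min(config.n_planted_mirnas, len(candidates))
    mirna_lfc: dict[str, float] = {}
    inverse: set[str] = set()
    if n_pl:
        chosen = rng.choice(candidates, size=n_pl, replace=False)
        for mi in sorted(str(m) for m in chosen):
            tgt_sign = np.sign(sum(
                np.sign(lfc.get(t, 0.0)) for t in target_map[mi]
            )) or 1.0
            if rng.random() < config.mirna_inverse_fraction:
                mirna_lfc[mi] = -float(tgt_sign) * config.mirna_effect_size
                inverse.add(mi)
            else:
                mirna_lfc[mi] = float(tgt_sign) * config.mirna_effect_size

    # group-exclusive proteins
    prots = protein_ids(config, _rng(config, 0))
    excl_t: set[str] = set()
    excl_c: set[str] = set()
    if config.n_exclusive_proteins:
        excl = rng.choice(prots, size=config.n_exclusive_proteins, replace=False)
        excl = sorted(str(p) for p in excl)
        half = len(excl) // 2
        excl_t = set(excl[:half])
        excl_c = set(excl[half:])

    return PlantedTruth(
        lfc=lfc,
        mirna_lfc=mirna_lfc,
        inverse_mirnas=inverse,
        exclusive_treatment=excl_t,
        exclusive_control=excl_c,
        regulator_of=regulator_of,
    )


# ---------------------------------------------------------------------------
# layer simulation
# ---------------------------------------------------------------------------

def _sample_ids(config: SimConfig) -> tuple[list[str], dict[str, str]]:
    ctrl = [f"C{i}" for i in range(1, config.n_per_group + 1)]
    trt = [f"T{i}" for i in range(1, config.n_per_group + 1)]
    groups = {s: GROUP_CONTROL for s in ctrl}
    groups.update({s: GROUP_TREATMENT for s in trt})
    return ctrl + trt, groups


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture; var = mu + phi*mu^2."""
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam).astype(float)


def _count_layer(
    rng: np.random.Generator,
    kind: LayerKind,
    feature_lfc: pd.Series,
    samples: list[str],
    groups: dict[str, str],
    config: SimConfig,
) -> OmicsLayer:
    n_feat = len(feature_lfc)
    base = np.exp(rng.normal(np.log(150.0), 1.2, size=n_feat))
    depth = np.exp(rng.normal(0.0, config.depth_sigma, size=len(samples)))
    lfc = feature_lfc.to_numpy()
    mu = np.empty((n_feat, len(samples)))
    for j, s in enumerate(samples):
        shift = 2.0 ** lfc if groups[s] == GROUP_TREATMENT else 1.0
        mu[:, j] = base * shift * depth[j]
    counts = _nb_counts(rng, mu, config.count_dispersion)
    values = pd.DataFrame(counts, index=feature_lfc.index, columns=samples)
    return OmicsLayer(kind, values, groups)


def _intensity_matrix(
    rng: np.random.Generator,
    feature_lfc: pd.Series,
    samples: list[str],
    groups: dict[str, str],
    config: SimConfig,
) -> pd.DataFrame:
    n_feat = len(feature_lfc)
    base_log = rng.normal(np.log(1e6), 1.0, size=n_feat)
    lfc = feature_lfc.to_numpy()
    out = np.empty((n_feat, len(samples)))
    for j, s in enumerate(samples):
        shift = lfc * np.log(2.0) if groups[s] == GROUP_TREATMENT else 0.0
        out[:, j] = np.exp(
            base_log + shift + rng.normal(0.0, config.intensity_sigma, size=n_feat)
        )
    return pd.DataFrame(out, index=feature_lfc.index, columns=samples)


def simulate_layers(
    config: SimConfig, kb: KnowledgeBase
) -> dict[LayerKind, OmicsLayer]:
    """Simulate the four abundance layers with the planted truth applied."""
    truth = planted_effects(config, kb)
    samples, groups = _sample_ids(config)
    ctrl = [s for s in samples if groups[s] == GROUP_CONTROL]
    trt = [s for s in samples if groups[s] == GROUP_TREATMENT]

    genes = gene_ids(config)
    gene_lfc = pd.Series({g: truth.lfc.get(g, 0.0) for g in genes})
    transcripts = _count_layer(
        _rng(config, 2), LayerKind.TRANSCRIPT, gene_lfc, samples, groups, config
    )

    prots = protein_ids(config, _rng(config, 0))
    prot_lfc = pd.Series({p: truth.lfc.get(p, 0.0) for p in prots})
    prng = _rng(config, 3)
    prot_values = _intensity_matrix(prng, prot_lfc, samples, groups, config)
    if config.protein_missing_rate > 0:
        mask = prng.random(prot_values.shape) < config.protein_missing_rate
        prot_values = prot_values.mask(pd.DataFrame(
            mask, index=prot_values.index, columns=prot_values.columns
        ))
    for p in truth.exclusive_treatment:
        prot_values.loc[p, ctrl] = np.nan
        prot_values.loc[p, trt] = prot_values.loc[p, trt].fillna(
            float(np.exp(prng.normal(np.log(1e6), 1.0)))
        )
    for p in truth.exclusive_control:
        prot_values.loc[p, trt] = np.nan
        prot_values.loc[p, ctrl] = prot_values.loc[p, ctrl].fillna(
            float(np.exp(prng.normal(np.log(1e6), 1.0)))
        )
    proteins = OmicsLayer(LayerKind.PROTEIN, prot_values, groups)

    mets = metabolite_ids(config)
    met_lfc = pd.Series({m: truth.lfc.get(m, 0.0) for m in mets})
    metabolites = OmicsLayer(
        LayerKind.METABOLITE,
        _intensity_matrix(_rng(config, 4), met_lfc, samples, groups, config),
        groups,
    )

    mirnas = mirna_ids(config)
    mirna_lfc = pd.Series({m: truth.mirna_lfc.get(m, 0.0) for m in mirnas})
    mirna_layer = _count_layer(
        _rng(config, 5), LayerKind.MIRNA, mirna_lfc, samples, groups, config
    )

    return {
        LayerKind.TRANSCRIPT: transcripts,
        LayerKind.PROTEIN: proteins,
        LayerKind.METABOLITE: metabolites,
        LayerKind.MIRNA: mirna_layer,
    }


def make_traits(config: SimConfig, kb: KnowledgeBase) -> pd.DataFrame:
    """Synthetic trait-gene association table over the gene universe.

    Half the annotated genes are drawn from pathway members so that
    trait-overlap reporting has content under planted configurations.
    """
    rng = _rng(config, 6)
    genes = gene_ids(config)
    pathway_genes = sorted(
        {m for members in kb.pathways.values() for m in members if m in set(genes)}
    )
    n_assoc = min(50, len(genes))
    n_pw = min(n_assoc // 2, len(pathway_genes))
    chosen = set(rng.choice(pathway_genes, size=n_pw, replace=False))
    rest = [g for g in genes if g not in chosen]
    chosen |= set(rng.choice(rest, size=n_assoc - len(chosen), replace=False))
    rows = []
    for g in sorted(chosen):
        for _ in range(int(rng.integers(1, 3))):
            trait = str(rng.choice(_TRAIT_NAMES))
            variant = f"rs{int(rng.integers(10_000, 10_000_000))}"
            rows.append((g, trait, variant))
    df = pd.DataFrame(rows, columns=["gene", "trait", "variant"])
    return df.drop_duplicates().reset_index(drop=True)


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------

_LAYER_FILES = {
    LayerKind.TRANSCRIPT: "transcripts.tsv",
    LayerKind.PROTEIN: "proteins.tsv",
    LayerKind.METABOLITE: "metabolites.tsv",
    LayerKind.MIRNA: "mirnas.tsv",
}


def write_fixture_set(config: SimConfig, out_dir) -> list[str]:
    """Emit the full synthetic study as plain-text files; returns the manifest."""
    os.makedirs(out_dir, exist_ok=True)
    kb = make_knowledge_base(config)
    layers = simulate_layers(config, kb)
    traits = make_traits(config, kb)
    manifest: list[str] = []

    def _emit(name: str, writer) -> None:
        path = os.path.join(out_dir, name)
        writer(path)
        manifest.append(path)

    for kind, fname in _LAYER_FILES.items():
        _emit(fname, lambda p, k=kind: write_layer(layers[k], p))
    _emit("pathways.gmt", lambda p: write_gmt(kb.pathways, p))
    _emit("edges.tsv", lambda p: write_edges(kb.edges, p))
    _emit("mirna_targets.tsv", lambda p: write_mirna_targets(kb.mirna_targets, p))
    _emit("traits.tsv", lambda p: write_traits(traits, p))
    _emit("groups.tsv", lambda p: write_groups(layers[LayerKind.TRANSCRIPT].groups, p))
    _emit("config.yaml", lambda p: config.to_yaml(p))
    return manifest
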