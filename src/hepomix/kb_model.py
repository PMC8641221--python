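"""Domain types and text-format I/O for omics tables and the knowledge base.

The analysis operates on four abundance layers (transcript and miRNA counts,
protein and metabolite intensities) from a two-group design, a knowledge base
of pathway membership sets plus signed molecular edges, and a trait-gene
association table. Molecule identity is the bare symbol string, case
sensitive, shared across gene-level layers; metabolites are identified by
name.

Formats are deliberately plain text:

* pathways — GMT (tab separated: set id, description, member ids);
* edges / miRNA targets / traits — TSV with fixed headers;
* abundance layers — TSV, first column the feature id, header row the
  sample ids, empty cell = missing (allowed only for protein/metabolite).

All writers emit UTF-8 with LF line endings.
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "LayerKind",
    "GROUP_CONTROL",
    "GROUP_TREATMENT",
    "OmicsLayer",
    "Edge",
    "MirnaTarget",
    "KnowledgeBase",
    "ParseError",
    "ValidationError",
    "load_knowledge_base",
    "read_gmt",
    "write_gmt",
    "read_edges",
    "write_edges",
    "read_mirna_targets",
    "write_mirna_targets",
    "read_traits",
    "write_traits",
    "read_groups",
    "write_groups",
    "read_layer",
    "write_layer",
]


class LayerKind(str, enum.Enum):
    TRANSCRIPT = "transcript"
    PROTEIN = "protein"
    METABOLITE = "metabolite"
    MIRNA = "mirna"

    @property
    def is_count(self) -> bool:
        return self in (LayerKind.TRANSCRIPT, LayerKind.MIRNA)

    @property
    def allows_missing(self) -> bool:
        return self in (LayerKind.PROTEIN, LayerKind.METABOLITE)

    @property
    def is_gene_level(self) -> bool:
        """Layers whose feature ids live in the shared gene-symbol space."""
        return self in (LayerKind.TRANSCRIPT, LayerKind.PROTEIN)


GROUP_CONTROL = "control"
GROUP_TREATMENT = "treatment"
_GROUPS = (GROUP_CONTROL, GROUP_TREATMENT)


class ParseError(ValueError):
    """A malformed input file; the message names the offending location."""


class ValidationError(ValueError):
    """A structurally valid input violating a domain invariant."""


@dataclass
class OmicsLayer:
    """One layer's feature-by-sample abundance matrix with group labels.

    ``values`` is a features x samples DataFrame (float; NaN = missing).
    ``groups`` maps every sample id to ``"control"`` or ``"treatment"``.
    """

    kind: LayerKind
    values: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        self.kind = LayerKind(self.kind)
        self.validate()

    def validate(self) -> None:
        cols = list(self.values.columns)
        missing_groups = [s for s in cols if s not in self.groups]
        if missing_groups:
            raise ValidationError(
                f"samples without group assignment: {missing_groups}"
            )
        bad = {s: g for s, g in self.groups.items() if g not in _GROUPS}
        if bad:
            raise ValidationError(f"unknown group labels: {bad}")
        for g in _GROUPS:
            if not any(self.groups[s] == g for s in cols):
                raise ValidationError(f"group '{g}' has no samples")
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not self.kind.allows_missing and np.isnan(arr).any():
            raise ValidationError(
                f"missing values are not allowed in a {self.kind.value} layer"
            )
        finite = arr[~np.isnan(arr)]
        if (finite < 0).any():
            raise ValidationError("abundances must be non-negative")
        if self.kind.is_count and not np.allclose(finite, np.round(finite)):
            raise ValidationError(
                f"{self.kind.value} layer must contain integer counts"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    @property
    def control_samples(self) -> list[str]:
        return self.samples_in(GROUP_CONTROL)

    @property
    def treatment_samples(self) -> list[str]:
        return self.samples_in(GROUP_TREATMENT)

    def subset(self, feature_ids: Sequence[str]) -> "OmicsLayer":
        return OmicsLayer(self.kind, self.values.loc[list(feature_ids)], dict(self.groups))

    def equals(self, other: "OmicsLayer") -> bool:
        if self.kind != other.kind:
            return False
        if set(self.feature_ids) != set(other.feature_ids):
            return False
        if set(self.sample_ids) != set(other.sample_ids):
            return False
        if {k: v for k, v in self.groups.items()} != {k: v for k, v in other.groups.items()}:
            return False
        a = self.values.sort_index()
        b = other.values.loc[a.index, a.columns]
        return bool(np.allclose(a.to_numpy(), b.to_numpy(), equal_nan=True))


class Edge(NamedTuple):
    source: str
    target: str
    sign: int  # +1 activating, -1 inhibiting
    relation: str  # "regulates" or "interacts"
    tissue_evidence: bool


class MirnaTarget(NamedTuple):
    mirna: str
    target: str
    evidence: str  # validated | high_predicted | low_predicted


_EVIDENCE_LEVELS = ("validated", "high_predicted", "low_predicted")
_RELATIONS = ("regulates", "interacts")


@dataclass
class KnowledgeBase:
    """Pathway sets, signed molecular edges, regulators and miRNA targeting.

    The edge list implies an undirected molecule graph used for the
    direct-connection requirement; regulator edges are additionally
    interpreted as directed regulator -> target relations.
    """

    pathways: dict[str, set[str]]
    edges: list[Edge] = field(default_factory=list)
    regulators: set[str] = field(default_factory=set)
    mirna_targets: list[MirnaTarget] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for pid, members in self.pathways.items():
            if not members:
                raise ValidationError(f"pathway '{pid}' is empty")
        seen: set[tuple[str, str, str]] = set()
        for e in self.edges:
            if e.source == e.target:
                raise ValidationError(f"self-edge on '{e.source}'")
            if e.sign not in (1, -1):
                raise ValidationError(f"edge sign must be +1/-1, got {e.sign!r}")
            if e.relation not in _RELATIONS:
                raise ValidationError(f"unknown relation '{e.relation}'")
            key = (e.source, e.target, e.relation)
            if key in seen:
                raise ValidationError(f"duplicate edge {key}")
            seen.add(key)
        out_sources = {e.source for e in self.edges}
        orphans = self.regulators - out_sources
        if orphans:
            raise ValidationError(
                f"regulators without outgoing edges: {sorted(orphans)[:5]}"
            )
        for mt in self.mirna_targets:
            if mt.evidence not in _EVIDENCE_LEVELS:
                raise ValidationError(f"unknown evidence level '{mt.evidence}'")

    @property
    def molecules(self) -> set[str]:
        out: set[str] = set()
        for members in self.pathways.values():
            out |= members
        for e in self.edges:
            out.add(e.source)
            out.add(e.target)
        for mt in self.mirna_targets:
            out.add(mt.mirna)
            out.add(mt.target)
        return out

    def graph(self) -> nx.Graph:
        """Undirected molecule graph over all signed edges."""
        g = nx.Graph()
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign, relation=e.relation,
                       tissue_evidence=e.tissue_evidence)
        return g

    def regulator_edges(self, regulator: str) -> list[Edge]:
        return [e for e in self.edges if e.source == regulator]

    def equals(self, other: "KnowledgeBase") -> bool:
        return (
            self.pathways == other.pathways
            and set(self.edges) == set(other.edges)
            and self.regulators == other.regulators
            and set(self.mirna_targets) == set(other.mirna_targets)
        )


def load_knowledge_base(pathways_path, edges_path, mirna_targets_path=None) -> KnowledgeBase:
    """Assemble a KnowledgeBase from its on-disk parts.

    Regulators are the sources of ``regulates`` edges; there is no separate
    regulator file.
    """
    pathways = read_gmt(pathways_path)
    edges = read_edges(edges_path)
    mirna_targets = read_mirna_targets(mirna_targets_path) if mirna_targets_path else []
    regulators = {e.source for e in edges if e.relation == "regulates"}
    return KnowledgeBase(pathways, edges, regulators, mirna_targets)


# ---------------------------------------------------------------------------
# GMT pathway sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file into {pathway id: member set}.

    Duplicate member tokens within a line collapse by set semantics.
    """
    pathways: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT needs >=3 tab-separated "
                    f"fields (id, description, members), got {len(fields)}"
                )
            pid = fields[0]
            if pid in pathways:
                raise ParseError(f"{path}: line {lineno}: duplicate set id '{pid}'")
            members = {m for m in fields[2:] if m}
            if not members:
                raise ParseError(f"{path}: line {lineno}: set '{pid}' has no members")
            pathways[pid] = members
    return pathways


def write_gmt(pathways: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for pid in sorted(pathways):
            members = sorted(set(pathways[pid]))
            fh.write("\t".join([pid, pid] + members) + "\n")


# ---------------------------------------------------------------------------
# Edge / miRNA-target / trait TSVs
# ---------------------------------------------------------------------------

_EDGE_HEADER = ["source", "target", "sign", "relation", "tissue_evidence"]
_MIRNA_HEADER = ["mirna", "target", "evidence"]
_TRAIT_HEADER = ["gene", "trait", "variant"]

_SIGN_TOKENS = {"+1": 1, "1": 1, "+": 1, "-1": -1, "−1": -1, "-": -1}
_BOOL_TOKENS = {"true": True, "false": False, "1": True, "0": False}


def _check_header(fields: list[str], expected: list[str], path) -> None:
    if fields != expected:
        raise ParseError(
            f"{path}: expected header {expected}, got {fields}"
        )


def read_edges(path) -> list[Edge]:
    edges: list[Edge] = []
    seen: set[tuple[str, str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        _check_header(header, _EDGE_HEADER, path)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 fields")
            src, tgt, sign_s, relation, tev_s = fields
            if sign_s not in _SIGN_TOKENS:
                raise ParseError(
                    f"{path}: line {lineno}: sign must be +1 or -1, got '{sign_s}'"
                )
            if tev_s.lower() not in _BOOL_TOKENS:
                raise ParseError(
                    f"{path}: line {lineno}: tissue_evidence must be boolean, got '{tev_s}'"
                )
            key = (src, tgt, relation)
            if key in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate edge {key}")
            seen.add(key)
            edges.append(
                Edge(src, tgt, _SIGN_TOKENS[sign_s], relation,
                     _BOOL_TOKENS[tev_s.lower()])
            )
    return edges


def write_edges(edges: Sequence[Edge], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_EDGE_HEADER) + "\n")
        for e in sorted(edges):
            sign = "+1" if e.sign > 0 else "-1"
            tev = "true" if e.tissue_evidence else "false"
            fh.write(f"{e.source}\t{e.target}\t{sign}\t{e.relation}\t{tev}\n")


def read_mirna_targets(path) -> list[MirnaTarget]:
    out: list[MirnaTarget] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        _check_header(header, _MIRNA_HEADER, path)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 fields")
            mirna, target, evidence = fields
            if evidence not in _EVIDENCE_LEVELS:
                raise ParseError(
                    f"{path}: line {lineno}: unknown evidence level '{evidence}'"
                )
            if (mirna, target) in seen:
                raise ParseError(
                    f"{path}: line {lineno}: duplicate pair ({mirna}, {target})"
                )
            seen.add((mirna, target))
            out.append(MirnaTarget(mirna, target, evidence))
    return out


def write_mirna_targets(targets: Sequence[MirnaTarget], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_MIRNA_HEADER) + "\n")
        for t in sorted(targets):
            fh.write(f"{t.mirna}\t{t.target}\t{t.evidence}\n")


def read_traits(path) -> pd.DataFrame:
    """Trait-gene association rows (gene, trait, variant); duplicates rejected."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != _TRAIT_HEADER:
        raise ParseError(f"{path}: expected header {_TRAIT_HEADER}, got {list(df.columns)}")
    dup = df.duplicated()
    if dup.any():
        row = df[dup].iloc[0]
        raise ParseError(
            f"{path}: duplicate trait row ({row['gene']}, {row['trait']}, {row['variant']})"
        )
    return df.reset_index(drop=True)


def write_traits(traits: pd.DataFrame, path) -> None:
    traits = traits[_TRAIT_HEADER].sort_values(_TRAIT_HEADER)
    traits.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Group maps and abundance layers
# ---------------------------------------------------------------------------

def read_groups(path) -> dict[str, str]:
    groups: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        _check_header(header, ["sample", "group"], path)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields")
            sample, group = fields
            if group not in _GROUPS:
                raise ParseError(f"{path}: line {lineno}: unknown group '{group}'")
            if sample in groups:
                raise ParseError(f"{path}: line {lineno}: duplicate sample '{sample}'")
            groups[sample] = group
    return groups


def write_groups(groups: Mapping[str, str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample\tgroup\n")
        for sample in sorted(groups):
            fh.write(f"{sample}\t{groups[sample]}\n")


def read_layer(path, kind: LayerKind, groups: Mapping[str, str]) -> OmicsLayer:
    """Read a feature x sample abundance table into an OmicsLayer.

    Blank cells become missing values; OmicsLayer validation rejects them
    for count layers and enforces all other invariants.
    """
    kind = LayerKind(kind)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    values = df.where(df != "", other=np.nan).astype(float)
    absent = [s for s in values.columns if s not in groups]
    if absent:
        raise ValidationError(
            f"{path}: sample columns absent from the group map: {absent}"
        )
    return OmicsLayer(kind, values, {s: groups[s] for s in values.columns})


def write_layer(layer: OmicsLayer, path) -> None:
    df = layer.values.copy()
    if layer.kind.is_count:
        df = df.astype(int)
    out = df.astype(object).where(df.notna(), "")

    def _fmt(v):
        if isinstance(v, float) and not math.isnan(v):
            return format(v, ".10g")
        return v

    out = out.map(_fmt)
    buf = io.StringIO()
    out.to_csv(buf, sep="\t", index_label="feature", lineterminator="\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())
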