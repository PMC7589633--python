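"""Data model and I/O for the mixed TF-miRNA-gene regulatory network.

The network mixes four regulation classes over three node classes:

========== ======== ========
edge class source   target
========== ======== ========
tf_gene    TF       gene (or a TF's gene)
tf_mirna   TF       miRNA
mirna_gene miRNA    gene
mirna_tf   miRNA    TF
========== ======== ========

Node classes are derived from the edge classes and must be consistent: an
identifier carries exactly one node class everywhere.  A TF that is itself
a regulation target stays a TF — a miRNA targeting it must use the
``mirna_tf`` edge class, and a TF regulating its gene uses ``tf_gene``.
Conflicting evidence (e.g. the same id used as a TF source and as a
``mirna_gene`` target) raises :class:`NodeClassConflictError` rather than
silently reclassifying, because motif typing depends on the classes.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

EDGE_CLASSES = ("tf_gene", "tf_mirna", "mirna_gene", "mirna_tf")
NODE_CLASSES = ("TF", "miRNA", "gene")

#: node class of the source / target implied by each edge class.  A
#: ``tf_gene`` target is recorded as weak gene evidence: it may turn out to
#: be a TF (a TF regulating another TF's gene), which is accepted.
_SOURCE_CLASS = {"tf_gene": "TF", "tf_mirna": "TF", "mirna_gene": "miRNA", "mirna_tf": "miRNA"}
_TARGET_CLASS = {"tf_gene": "gene", "tf_mirna": "miRNA", "mirna_gene": "gene", "mirna_tf": "TF"}


class NetworkError(ValueError):
    """Malformed regulatory-network input."""


class NodeClassConflictError(NetworkError):
    """An identifier is used with two incompatible node classes."""


@dataclass(frozen=True)
class Regulation:
    """One directed regulation, typed by its edge class."""

    source: str
    target: str
    edge_class: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.edge_class not in EDGE_CLASSES:
            raise NetworkError(f"unknown edge class {self.edge_class!r}")


@dataclass
class RegulatoryNetwork:
    """Deduplicated, self-loop-free union of typed regulations.

    Attributes
    ----------
    nodes
        Mapping node id -> node class (``TF`` / ``miRNA`` / ``gene``).
    edges
        Deduplicated regulations; duplicates across provenance files are
        collapsed with their provenance labels concatenated by ``;``.
    n_self_loops_removed
        Count of input regulations dropped because source == target.
    """

    nodes: dict[str, str]
    edges: list[Regulation]
    n_self_loops_removed: int = 0
    _edge_index: dict[tuple[str, str, str], Regulation] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._edge_index = {(e.source, e.target, e.edge_class): e for e in self.edges}

    def has_edge(self, source: str, target: str, edge_class: str) -> bool:
        return (source, target, edge_class) in self._edge_index

    def nodes_of_class(self, node_class: str) -> list[str]:
        return sorted(n for n, c in self.nodes.items() if c == node_class)

    def node_counts(self) -> dict[str, int]:
        counts = Counter(self.nodes.values())
        return {c: counts.get(c, 0) for c in NODE_CLASSES}

    def edge_counts(self) -> dict[str, int]:
        counts = Counter(e.edge_class for e in self.edges)
        return {c: counts.get(c, 0) for c in EDGE_CLASSES}

    def successors(self, edge_class: str) -> dict[str, set[str]]:
        """source -> set of targets, restricted to one edge class."""
        out: dict[str, set[str]] = defaultdict(set)
        for e in self.edges:
            if e.edge_class == edge_class:
                out[e.source].add(e.target)
        return dict(out)


def read_regulations(path: str | Path, edge_class: str, provenance: str | None = None) -> list[Regulation]:
    """Read a 2+-column TSV edge list, stamping every row with ``edge_class``.

    Blank lines and ``#`` comment lines are skipped.  An optional header
    line is tolerated: a first row whose two cells are ``source``/``target``
    (case-insensitive) is dropped.
    """
    if edge_class not in EDGE_CLASSES:
        raise NetworkError(f"unknown edge class {edge_class!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    prov = provenance if provenance is not None else path.name
    regs: list[Regulation] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate whitespace-delimited toys
                fields = line.split()
            if len(fields) < 2:
                raise NetworkError(f"{path}:{lineno}: expected >=2 fields, got {len(fields)}")
            src, tgt = fields[0].strip(), fields[1].strip()
            if lineno == 1 and src.lower() == "source" and tgt.lower() == "target":
                continue
            if not src or not tgt:
                raise NetworkError(f"{path}:{lineno}: empty identifier")
            regs.append(Regulation(src, tgt, edge_class, prov))
    return regs


def _resolve_node_classes(regulations: Iterable[Regulation]) -> dict[str, str]:
    evidence: dict[str, set[str]] = defaultdict(set)  # node -> evidence tags
    for r in regulations:
        evidence[r.source].add("src:" + r.edge_class)
        evidence[r.target].add("tgt:" + r.edge_class)
    classes: dict[str, str] = {}
    conflicts: list[str] = []
    for node, tags in evidence.items():
        is_tf = any(t in tags for t in ("src:tf_gene", "src:tf_mirna", "tgt:mirna_tf"))
        is_mirna = any(t in tags for t in ("src:mirna_gene", "src:mirna_tf", "tgt:tf_mirna"))
        gene_strong = "tgt:mirna_gene" in tags
        gene_weak = "tgt:tf_gene" in tags
        if is_tf and is_mirna:
            conflicts.append(f"{node}: TF and miRNA")
        elif is_tf and gene_strong:
            conflicts.append(f"{node}: TF and mirna_gene target (use mirna_tf)")
        elif is_mirna and (gene_strong or gene_weak):
            conflicts.append(f"{node}: miRNA and gene target (use *_mirna classes)")
        elif is_tf:
            classes[node] = "TF"  # tf_gene target that is a TF is accepted
        elif is_mirna:
            classes[node] = "miRNA"
        else:
            classes[node] = "gene"
    if conflicts:
        raise NodeClassConflictError("node class conflicts: " + "; ".join(sorted(conflicts)))
    return classes


def build_network(regulations: Iterable[Regulation]) -> RegulatoryNetwork:
    """Union the regulations into a network: dedup, drop self-loops, type nodes."""
    regulations = list(regulations)
    n_loops = sum(1 for r in regulations if r.source == r.target)
    kept = [r for r in regulations if r.source != r.target]
    merged: dict[tuple[str, str, str], Regulation] = {}
    for r in kept:
        key = (r.source, r.target, r.edge_class)
        if key in merged:
            prev = merged[key]
            provs = [p for p in prev.provenance.split(";") if p]
            if r.provenance and r.provenance not in provs:
                merged[key] = replace(prev, provenance=";".join(provs + [r.provenance]))
        else:
            merged[key] = r
    edges = [merged[k] for k in sorted(merged)]
    nodes = _resolve_node_classes(edges)
    return RegulatoryNetwork(nodes=nodes, edges=edges, n_self_loops_removed=n_loops)


@dataclass
class PowerLawFit:
    """Least-squares fit of log10(frequency) on log10(degree)."""

    slope: float
    intercept: float
    r_squared: float
    degenerate: bool = False


def degree_distribution(network: RegulatoryNetwork) -> tuple[pd.DataFrame, PowerLawFit]:
    """Per-node total degree (in + out over all edge classes) and a log-log fit.

    The fit regresses log10 frequency on log10 degree over the observed
    degree values (zero-frequency bins never appear).  With fewer than two
    distinct degrees the fit is undefined and flagged ``degenerate``.
    """
    deg: Counter[str] = Counter()
    for node in network.nodes:
        deg[node] = 0
    for e in network.edges:
        deg[e.source] += 1
        deg[e.target] += 1
    table = pd.DataFrame(
        {
            "node": list(deg.keys()),
            "node_class": [network.nodes[n] for n in deg],
            "degree": list(deg.values()),
        }
    ).sort_values(["degree", "node"], ascending=[False, True], ignore_index=True)

    freq = Counter(d for d in deg.values() if d > 0)
    if len(freq) < 2:
        return table, PowerLawFit(np.nan, np.nan, np.nan, degenerate=True)
    x = np.log10(sorted(freq))
    y = np.log10([freq[k] for k in sorted(freq)])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return table, PowerLawFit(float(slope), float(intercept), r2)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), optionally with an explicit universe."""

    sets: dict[str, set[str]]
    universe: set[str] | None = None
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise NetworkError(f"gene set {name!r} is empty")

    def members_union(self) -> set[str]:
        return set(itertools.chain.from_iterable(self.sets.values()))


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise NetworkError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            name = fields[0]
            if name in sets:
                raise NetworkError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise NetworkError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = fields[1]
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(collection.sets[name])]) + "\n")


def write_network(network: RegulatoryNetwork, path: str | Path, format: str = "TSV") -> None:
    """Export the network.  ``TSV`` round-trips; ``SIF``/``GraphML`` are for viewers.

    * TSV: ``source  target  edge_class  provenance`` with a header.
    * SIF: ``source  edge_class  target``.
    * GraphML: via networkx, node class and provenance as attributes.
    """
    path = Path(path)
    fmt = format.upper()
    if fmt == "TSV":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tedge_class\tprovenance\n")
            for e in network.edges:
                fh.write(f"{e.source}\t{e.target}\t{e.edge_class}\t{e.provenance}\n")
    elif fmt == "SIF":
        with path.open("w", encoding="utf-8") as fh:
            for e in network.edges:
                fh.write(f"{e.source}\t{e.edge_class}\t{e.target}\n")
    elif fmt == "GRAPHML":
        g = nx.MultiDiGraph()
        for node, cls in sorted(network.nodes.items()):
            g.add_node(node, node_class=cls)
        for e in network.edges:
            g.add_edge(e.source, e.target, edge_class=e.edge_class, provenance=e.provenance)
        nx.write_graphml(g, path)
    else:
        raise NetworkError(f"unknown format {format!r} (expected SIF, GraphML or TSV)")


def read_network(path: str | Path) -> RegulatoryNetwork:
    """Read a network written by :func:`write_network` in TSV format."""
    path = Path(path)
    regs: list[Regulation] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "source":
                continue
            if len(fields) < 3:
                raise NetworkError(f"{path}:{lineno}: expected source, target, edge_class")
            prov = fields[3] if len(fields) > 3 else ""
            regs.append(Regulation(fields[0], fields[1], fields[2], prov))
    return build_network(regs)


def read_system_map(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column TSV mapping body system -> pathway/set name."""
    path = Path(path)
    out: dict[str, set[str]] = defaultdict(set)
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise NetworkError(f"{path}:{lineno}: expected system, pathway")
            if fields[0] == "system" and fields[1] == "pathway":
                continue
            out[fields[0]].add(fields[1])
    return dict(out)
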