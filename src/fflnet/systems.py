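"""Body-system subnetworks from annotated dysregulated FFLs.

Pathway annotations (a GMT-style :class:`~fflnet.netio.GeneSetCollection`
covering genes, TFs and miRNAs alike) are grouped into body systems by a
user-supplied system map (system -> pathway names).  An FFL belongs to a
system only if *all three* of its nodes participate in at least one
pathway mapped to that system; per-system FFLs are merged into
subnetworks, and FFLs are split into system-specific (exactly one
system) and system-general (at least ``general_min`` systems).

Over-representation of a query set in the annotation pathways is tested
with an upper-tail hypergeometric test, Benjamini-Hochberg corrected
across pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .netio import GeneSetCollection, NetworkError, Regulation, RegulatoryNetwork, build_network
from .fflcore import ffl_edges


@dataclass
class SystemAssignment:
    """Per-FFL system membership and per-system FFL tables."""

    systems: list[str]
    ffl_systems: pd.Series  # index aligned with the FFL table; values: frozenset of systems
    per_system: dict[str, pd.DataFrame] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {s: len(self.per_system[s]) for s in self.systems}


def _node_systems(
    annotations: GeneSetCollection, system_map: dict[str, set[str]]
) -> dict[str, set[str]]:
    """node id -> set of systems whose mapped pathways contain it."""
    missing = {p for paths in system_map.values() for p in paths if p not in annotations.sets}
    if missing:
        raise NetworkError(f"system map references unknown pathways: {sorted(missing)[:5]}")
    out: dict[str, set[str]] = {}
    for system, pathways in system_map.items():
        for p in pathways:
            for member in annotations.sets[p]:
                out.setdefault(member, set()).add(system)
    return out


def assign_system_ffls(
    ffls: pd.DataFrame,
    annotations: GeneSetCollection,
    system_map: dict[str, set[str]],
) -> SystemAssignment:
    """Assign each FFL to every system covering all three of its nodes."""
    node_sys = _node_systems(annotations, system_map)
    systems = sorted(system_map)
    memberships = []
    for _, row in ffls.iterrows():
        sets = [node_sys.get(row[c], set()) for c in ("tf", "mirna", "gene")]
        memberships.append(frozenset(sets[0] & sets[1] & sets[2]))
    ffl_systems = pd.Series(memberships, index=ffls.index)
    per_system = {
        s: ffls.loc[[s in m for m in memberships]].copy() for s in systems
    }
    return SystemAssignment(systems=systems, ffl_systems=ffl_systems, per_system=per_system)


def sharing_analysis(assignment: SystemAssignment, general_min: int = 3) -> dict:
    """Split assigned FFLs into system-specific and system-general.

    specific: in exactly one system; general: in >= ``general_min``
    systems.  Also reports how many assigned FFLs fall in each
    number-of-systems stratum (the strata partition the assigned FFLs).
    """
    if len(assignment.systems) < 2:
        raise NetworkError("sharing analysis needs >= 2 systems")
    n_sys = assignment.ffl_systems.map(len)
    assigned = n_sys > 0
    strata = n_sys[assigned].value_counts().sort_index().to_dict()
    return {
        "specific": assignment.ffl_systems.index[n_sys == 1].tolist(),
        "general": assignment.ffl_systems.index[n_sys >= general_min].tolist(),
        "n_assigned": int(assigned.sum()),
        "strata": strata,
    }


def merge_system_subnetworks(assignment: SystemAssignment) -> dict[str, RegulatoryNetwork]:
    """Union each system's FFLs into a subnetwork (empty systems are omitted)."""
    out: dict[str, RegulatoryNetwork] = {}
    for system, table in assignment.per_system.items():
        if table.empty:
            continue
        regs = [
            Regulation(s, t, c, system)
            for _, row in table.iterrows()
            for s, t, c in ffl_edges(row)
        ]
        out[system] = build_network(regs)
    return out


def subnetwork_overlap(subnetworks: dict[str, RegulatoryNetwork]) -> dict[str, pd.DataFrame]:
    """Pairwise node- and edge-overlap counts between system subnetworks."""
    names = sorted(subnetworks)
    node_sets = {s: set(subnetworks[s].nodes) for s in names}
    edge_sets = {
        s: {(e.source, e.target, e.edge_class) for e in subnetworks[s].edges} for s in names
    }
    node_mat = pd.DataFrame(
        [[len(node_sets[a] & node_sets[b]) for b in names] for a in names],
        index=names,
        columns=names,
    )
    edge_mat = pd.DataFrame(
        [[len(edge_sets[a] & edge_sets[b]) for b in names] for a in names],
        index=names,
        columns=names,
    )
    return {"nodes": node_mat, "edges": edge_mat}


def top_degree_nodes(subnetwork: RegulatoryNetwork, k: int = 10) -> pd.DataFrame:
    """Top-k nodes by total degree; ties broken lexicographically."""
    if k < 1:
        raise NetworkError("k must be >= 1")
    deg = {n: 0 for n in subnetwork.nodes}
    for e in subnetwork.edges:
        deg[e.source] += 1
        deg[e.target] += 1
    table = pd.DataFrame(
        {"node": list(deg), "node_class": [subnetwork.nodes[n] for n in deg], "degree": list(deg.values())}
    ).sort_values(["degree", "node"], ascending=[False, True], ignore_index=True)
    return table.head(k)


def hypergeom_enrichment(
    query: set[str],
    gene_sets: GeneSetCollection,
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    For each set S, with M = |universe|, K = |S ∩ universe|, n = |query|
    and k = |query ∩ S|, p = P(X >= k) under sampling n of M without
    replacement.  BH correction across the tested sets.
    """
    if not query <= universe:
        raise NetworkError("query must be contained in the universe")
    M, n = len(universe), len(query)
    rows = []
    for name in sorted(gene_sets.sets):
        members = gene_sets.sets[name] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if k > 0 else 1.0
        rows.append((name, K, k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p_value"])
    if not out.empty:
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["fdr"] = np.array([], dtype=float)
    return out.sort_values(["p_value", "set"], ignore_index=True)
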