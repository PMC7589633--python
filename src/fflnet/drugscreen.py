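"""Signature-reversal drug screening.

Two complementary screens identify drugs that counteract a perturbation:

* miRNA-inhibitor screen: from a table of experimentally supported
  drug -> miRNA expression effects, rank drugs by how many of a target
  miRNA set they shift in the desired direction (default: inhibit).
* gene-signature reversal: from per-drug gene direction signatures,
  count the perturbation DE genes each drug shifts in the opposite
  direction, and keep drugs reversing at least ``min_reversed`` genes
  (default 3).

Both screens are rank-by-count with lexicographic tie-breaking, so the
output is invariant to input row order.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

DIRECTIONS = ("up", "down")


class DrugScreenError(ValueError):
    """Malformed drug table input."""


def read_drug_mirna_table(path: str | Path) -> pd.DataFrame:
    """Read a drug->miRNA effect TSV: drug, mirna, effect(up|down)[, provenance]."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"drug", "mirna", "effect"}
    if not required <= set(table.columns):
        raise DrugScreenError(f"drug-miRNA table needs columns {sorted(required)}")
    bad = set(table["effect"]) - set(DIRECTIONS)
    if bad:
        raise DrugScreenError(f"unknown effects: {sorted(bad)}")
    if "provenance" not in table.columns:
        table["provenance"] = ""
    return table.drop_duplicates(subset=["drug", "mirna", "effect"], ignore_index=True)


def read_drug_signatures(path: str | Path) -> dict[str, dict[str, str]]:
    """Read drug gene signatures TSV (drug, gene, direction) into nested dicts."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"drug", "gene", "direction"}
    if not required <= set(table.columns):
        raise DrugScreenError(f"signature table needs columns {sorted(required)}")
    bad = set(table["direction"]) - set(DIRECTIONS)
    if bad:
        raise DrugScreenError(f"unknown directions: {sorted(bad)}")
    out: dict[str, dict[str, str]] = {}
    for drug, gene, direction in table[["drug", "gene", "direction"]].itertuples(index=False):
        sig = out.setdefault(drug, {})
        if gene in sig and sig[gene] != direction:
            raise DrugScreenError(f"conflicting directions for {drug!r}/{gene!r}")
        sig[gene] = direction
    return out


def _consistent_effects(table: pd.DataFrame) -> pd.DataFrame:
    """Drop (drug, miRNA) pairs recorded with both up and down effects."""
    dedup = table.drop_duplicates(subset=["drug", "mirna", "effect"])
    n_effects = dedup.groupby(["drug", "mirna"])["effect"].transform("nunique")
    conflicted = dedup.loc[n_effects > 1, ["drug", "mirna"]].drop_duplicates()
    if not conflicted.empty:
        warnings.warn(
            f"{len(conflicted)} drug/miRNA pairs have contradictory effects; excluded from coverage"
        )
    return dedup.loc[n_effects == 1]


def screen_mirna_inhibitors(
    table: pd.DataFrame,
    target_mirnas: set[str],
    target_direction: str = "down",
) -> pd.DataFrame:
    """Rank drugs by how many target miRNAs they shift in ``target_direction``.

    Returns columns ``drug, coverage, covered`` (the covered miRNAs,
    ``;``-joined), descending coverage then lexicographic drug; drugs
    with zero coverage are omitted.
    """
    if not target_mirnas:
        raise DrugScreenError("target miRNA set is empty")
    if target_direction not in DIRECTIONS:
        raise DrugScreenError(f"unknown direction {target_direction!r}")
    usable = _consistent_effects(table)
    hits = usable[(usable["effect"] == target_direction) & usable["mirna"].isin(target_mirnas)]
    rows = []
    for drug, group in hits.groupby("drug"):
        covered = sorted(set(group["mirna"]))
        rows.append({"drug": drug, "coverage": len(covered), "covered": ";".join(covered)})
    out = pd.DataFrame(rows, columns=["drug", "coverage", "covered"])
    return out.sort_values(["coverage", "drug"], ascending=[False, True], ignore_index=True)


def signature_reversal(
    signatures: dict[str, dict[str, str]],
    pert_de: dict[str, set[str]],
    min_reversed: int = 3,
) -> pd.DataFrame:
    """Count per drug the perturbation DE genes it shifts the opposite way.

    A gene is reversed if it is perturbation-up and the drug downs it, or
    perturbation-down and the drug ups it.  Returns all drugs with their
    reversed sets plus a ``passes`` flag at the ``min_reversed`` cutoff,
    ranked by count (descending) then drug id.
    """
    up = pert_de.get("up", set())
    down = pert_de.get("down", set())
    if not (up or down):
        raise DrugScreenError("perturbation DE sets are empty")
    if up & down:
        raise DrugScreenError("perturbation up and down sets overlap")
    rows = []
    for drug in sorted(signatures):
        sig = signatures[drug]
        reversed_genes = sorted(
            {g for g in up if sig.get(g) == "down"} | {g for g in down if sig.get(g) == "up"}
        )
        rows.append(
            {
                "drug": drug,
                "n_reversed": len(reversed_genes),
                "reversed": ";".join(reversed_genes),
                "passes": len(reversed_genes) >= min_reversed,
            }
        )
    out = pd.DataFrame(rows, columns=["drug", "n_reversed", "reversed", "passes"])
    return out.sort_values(["n_reversed", "drug"], ascending=[False, True], ignore_index=True)
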