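"""Clonotype calling, clonal-expansion summaries and V/J gene-usage tables.

Clonotype identity defaults to the *full chain-key set*: two cells belong to
the same clonotype only if their entire sets of distinct chains (α and β,
including secondary chains) are identical.  This is the strictest reading of
clone identity for multi-receptor cells and the only one under which a dual
clone is unambiguous.  A ``beta_only`` definition (identical β chain sets) is
available for comparison with bulk-style β-chain clonotyping.

Clonal expansion is defined as clonotype size ≥ 2 cells, evaluated within a
sample and within a receptor class (single-TCR and dual-TCR cells are
clonotyped separately, so expansion of dual cells is reported in its own
right).

Gene usage is counted per *chain*, not per cell: a dual-α cell contributes
two TRAV observations.  This keeps single-versus-dual usage comparisons well
defined.  Gene names are taken verbatim after allele stripping; no registry
validation is attempted.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .pairing import classify_pairing
from .qc import CellChains, ChainKey

ClonotypeDefinition = Literal["full_set", "beta_only"]

GENE_FAMILIES = ("TRAV", "TRBV", "TRAJ", "TRBJ")


@dataclass(slots=True)
class ClonotypeRecord:
    """A group of same-sample, same-class cells sharing identical chains."""

    clonotype_id: str
    chain_key_set: tuple[ChainKey, ...]
    size: int
    receptor_class: str  # "single" | "dual"
    sample_id: str

    @property
    def expanded(self) -> bool:
        return self.size >= 2


def receptor_class(cell: CellChains) -> str:
    """"single" for one α + one β; "dual" for any multi-receptor class."""
    return "dual" if classify_pairing(cell).is_dual else "single"


def _clone_key(cell: CellChains, definition: ClonotypeDefinition) -> tuple[ChainKey, ...]:
    if definition == "full_set":
        chains = cell.chain_set
    elif definition == "beta_only":
        chains = cell.beta_chains
    else:
        raise ValueError(f"unknown clonotype definition: {definition!r}")
    return tuple(sorted(chains, key=lambda k: (k.locus, k.v_gene, k.j_gene, k.cdr3_nt)))


def call_clonotypes(
    cells: Sequence[CellChains],
    definition: ClonotypeDefinition = "full_set",
) -> list[ClonotypeRecord]:
    """Group cells into clonotypes within (sample, receptor class).

    Returns one record per clonotype, ordered by sample, class, descending
    size, then chain keys — a canonical order invariant under input
    permutation.  Sizes within each (sample, class) partition the cells.
    """
    buckets: dict[tuple[str, str, tuple[ChainKey, ...]], int] = defaultdict(int)
    for cell in cells:
        key = (cell.sample_id, receptor_class(cell), _clone_key(cell, definition))
        buckets[key] += 1
    ordered = sorted(
        buckets.items(), key=lambda kv: (kv[0][0], kv[0][1], -kv[1], kv[0][2])
    )
    records = []
    for i, ((sample_id, rclass, chains), size) in enumerate(ordered, start=1):
        records.append(
            ClonotypeRecord(
                clonotype_id=f"{sample_id or 'sample'}_{rclass}_ct{i}",
                chain_key_set=chains,
                size=size,
                receptor_class=rclass,
                sample_id=sample_id,
            )
        )
    return records


def expansion_summary(clonotypes: Sequence[ClonotypeRecord]) -> pd.DataFrame:
    """Per (sample, receptor class): expansion statistics.

    Columns: sample_id, receptor_class, n_clonotypes, n_cells,
    n_expanded_clonotypes, n_cells_expanded, largest_clone, frac_cells_expanded.
    """
    groups: dict[tuple[str, str], list[ClonotypeRecord]] = defaultdict(list)
    for ct in clonotypes:
        groups[(ct.sample_id, ct.receptor_class)].append(ct)
    rows = []
    for (sample_id, rclass), cts in sorted(groups.items()):
        n_cells = sum(c.size for c in cts)
        expanded = [c for c in cts if c.expanded]
        n_cells_expanded = sum(c.size for c in expanded)
        rows.append(
            {
                "sample_id": sample_id,
                "receptor_class": rclass,
                "n_clonotypes": len(cts),
                "n_cells": n_cells,
                "n_expanded_clonotypes": len(expanded),
                "n_cells_expanded": n_cells_expanded,
                "largest_clone": max(c.size for c in cts),
                "frac_cells_expanded": n_cells_expanded / n_cells if n_cells else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _family_of(gene: str) -> str | None:
    for fam in GENE_FAMILIES:
        if gene.startswith(fam):
            return fam
    return None


def gene_usage(
    cells: Sequence[CellChains],
    family: str,
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Chain-level gene-segment usage of one family, stratified by class/group.

    Parameters
    ----------
    cells
        QC'd, paired cells.
    family
        One of ``TRAV``, ``TRBV``, ``TRAJ``, ``TRBJ``.
    groups
        Optional sample_id → group label map; absent samples stratify under
        the empty group label.

    Returns
    -------
    DataFrame with columns gene, receptor_class, group, chain_count,
    frequency; frequencies normalize to 1 within each non-empty
    (receptor_class, group) stratum.
    """
    if family not in GENE_FAMILIES:
        raise ValueError(f"unknown gene family: {family!r}; expected {GENE_FAMILIES}")
    locus = family[:3]  # TRA or TRB
    use_v = family.endswith("V")
    counts: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for cell in cells:
        rclass = receptor_class(cell)
        group = groups.get(cell.sample_id, "") if groups else ""
        chains = cell.alpha_chains if locus == "TRA" else cell.beta_chains
        for chain in chains:
            gene = chain.v_gene if use_v else chain.j_gene
            if _family_of(gene) == family:
                counts[(rclass, group)][gene] += 1
    rows = []
    for (rclass, group), counter in sorted(counts.items()):
        total = sum(counter.values())
        for gene, n in sorted(counter.items()):
            rows.append(
                {
                    "gene": gene,
                    "receptor_class": rclass,
                    "group": group,
                    "chain_count": n,
                    "frequency": n / total,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene", "receptor_class", "group", "chain_count", "frequency"]
    )


def clonotypes_frame(clonotypes: Iterable[ClonotypeRecord]) -> pd.DataFrame:
    """Flat clonotype table; chains serialized as ``locus:V:J:CDR3`` joined by ';'."""
    rows = [
        {
            "clonotype_id": ct.clonotype_id,
            "sample_id": ct.sample_id,
            "receptor_class": ct.receptor_class,
            "size": ct.size,
            "expanded": ct.expanded,
            "chains": ";".join(
                f"{k.locus}:{k.v_gene}:{k.j_gene}:{k.cdr3_nt}" for k in ct.chain_key_set
            ),
        }
        for ct in clonotypes
    ]
    return pd.DataFrame(
        rows,
        columns=["clonotype_id", "sample_id", "receptor_class", "size", "expanded", "chains"],
    )
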