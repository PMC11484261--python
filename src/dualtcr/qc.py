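"""Contig-level quality control and per-cell chain collapsing.

Four exclusion rules are applied to raw contigs, in order:

1. ``non_cell`` — the barcode was not called a cell (``is_cell`` False);
2. ``low_confidence`` — the contig assembly is not high confidence;
3. ``non_ab_chain`` — the locus is not TRA or TRB (γδ chains, ``Multi``,
   unassigned);
4. ``non_productive`` — the rearrangement is out of frame, contains a stop,
   or could not be classified (``productive`` False or undetermined).

Surviving contigs are collapsed per barcode into distinct functional chains
(:class:`CellChains`); cells lacking either an α or a β chain are then
excluded, because pairing classification requires at least one of each.
Each rule's drop count is reported so denominators are auditable.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .contigs import ContigRecord
from .errors import ContractError

logger = logging.getLogger(__name__)

ChainIdentity = Literal["nt", "aa", "gene"]

FUNCTIONAL_LOCI = ("TRA", "TRB")

#: Exclusion rules in the order they are applied; a contig is charged to the
#: first rule it violates.
DROP_RULES = ("non_cell", "low_confidence", "non_ab_chain", "non_productive")


@dataclass(frozen=True, slots=True, order=True)
class ChainKey:
    """Identity of one distinct functional TCR chain within a cell.

    Equality over (locus, V gene, J gene, CDR3).  The junction field holds the
    nucleotide CDR3 under the default ``nt`` identity, the amino-acid CDR3
    under ``aa``, and the empty string under gene-level identity.
    """

    locus: str
    v_gene: str
    j_gene: str
    cdr3_nt: str


@dataclass(slots=True)
class CellChains:
    """The distinct α and β chains detected in one cell barcode."""

    barcode: str
    sample_id: str
    alpha_chains: frozenset[ChainKey]
    beta_chains: frozenset[ChainKey]
    umis: dict[ChainKey, int] = field(default_factory=dict)

    @property
    def n_alpha(self) -> int:
        return len(self.alpha_chains)

    @property
    def n_beta(self) -> int:
        return len(self.beta_chains)

    @property
    def chain_set(self) -> frozenset[ChainKey]:
        return self.alpha_chains | self.beta_chains

    @property
    def is_paired(self) -> bool:
        return self.n_alpha >= 1 and self.n_beta >= 1


@dataclass(slots=True)
class QCReport:
    """Bookkeeping for one QC pass: per-rule drop counts and survivors."""

    n_input: int = 0
    n_retained: int = 0
    drops: dict[str, int] = field(default_factory=lambda: {r: 0 for r in DROP_RULES})
    n_unkeyable: int = 0  # functional contigs missing v/j/cdr3, cannot form a key
    n_cells_total: int = 0  # barcodes with >=1 functional contig
    n_cells_paired: int = 0
    n_cells_unpaired: int = 0

    def balance_ok(self) -> bool:
        return self.n_input == self.n_retained + sum(self.drops.values())

    def as_dict(self) -> dict:
        return {
            "n_input_contigs": self.n_input,
            "n_retained_contigs": self.n_retained,
            "dropped": dict(self.drops),
            "n_unkeyable_contigs": self.n_unkeyable,
            "n_cells_total": self.n_cells_total,
            "n_cells_paired": self.n_cells_paired,
            "n_cells_unpaired": self.n_cells_unpaired,
        }


def _failing_rule(r: ContigRecord, min_umis: int) -> str | None:
    if not r.is_cell:
        return "non_cell"
    if not r.high_confidence:
        return "low_confidence"
    if r.chain not in FUNCTIONAL_LOCI:
        return "non_ab_chain"
    if r.productive is not True:
        return "non_productive"
    if r.umis < min_umis:
        return "low_umi"
    return None


def filter_functional_contigs(
    records: Sequence[ContigRecord],
    min_umis: int = 0,
    report: QCReport | None = None,
) -> list[ContigRecord]:
    """Keep contigs that are cell-associated, high confidence, TRA/TRB and productive.

    ``min_umis`` adds an optional minimum-UMI rule (off by default: secondary
    chains of genuine dual-receptor cells are often low-UMI, and dropping them
    would defeat the analysis).  Idempotent.  If ``report`` is given its
    counters are filled in; drop counts are also logged.
    """
    if report is None:
        report = QCReport()
    if min_umis > 0 and "low_umi" not in report.drops:
        report.drops["low_umi"] = 0
    report.n_input += len(records)
    kept: list[ContigRecord] = []
    for r in records:
        rule = _failing_rule(r, min_umis)
        if rule is None:
            kept.append(r)
        else:
            report.drops[rule] += 1
    report.n_retained += len(kept)
    logger.info(
        "contig QC: %d in, %d retained, drops=%s",
        len(records),
        len(kept),
        {k: v for k, v in report.drops.items() if v},
    )
    return kept


def make_chain_key(r: ContigRecord, identity: ChainIdentity = "nt") -> ChainKey | None:
    """Build the chain-identity key for one functional contig.

    Returns None when the contig lacks a field the identity level needs.
    The D gene is deliberately excluded: it is uncalled on TRA and unreliable
    on TRB, and the junction sequence already encodes it.
    """
    if not r.v_gene or not r.j_gene:
        return None
    if identity == "nt":
        if not r.cdr3_nt:
            return None
        junction = r.cdr3_nt
    elif identity == "aa":
        if not r.cdr3_aa:
            return None
        junction = r.cdr3_aa
    elif identity == "gene":
        junction = ""
    else:
        raise ValueError(f"unknown chain identity level: {identity!r}")
    return ChainKey(locus=r.chain, v_gene=r.v_gene, j_gene=r.j_gene, cdr3_nt=junction)


def collapse_chains(
    records: Sequence[ContigRecord],
    identity: ChainIdentity = "nt",
    report: QCReport | None = None,
) -> list[CellChains]:
    """Group functional contigs by barcode into distinct chains per cell.

    Contigs with identical chain keys within a barcode collapse to one chain
    with UMIs summed (duplicate contig calls for the same rearrangement);
    chains differing in any identity field stay distinct.  Output order
    follows first appearance of each barcode, and content is invariant under
    input row permutation.

    Records that cannot form a chain key (missing V/J/CDR3 after filtering)
    are counted, dropped and warned about.
    """
    per_cell: dict[tuple[str, str], dict[ChainKey, int]] = defaultdict(dict)
    order: list[tuple[str, str]] = []
    n_unkeyable = 0
    for r in records:
        key = make_chain_key(r, identity)
        if key is None:
            n_unkeyable += 1
            continue
        cell_id = (r.sample_id, r.barcode)
        if cell_id not in per_cell:
            order.append(cell_id)
        chains = per_cell[cell_id]
        chains[key] = chains.get(key, 0) + r.umis
    if n_unkeyable:
        logger.warning(
            "%d functional contig(s) lacked V/J/CDR3 and were dropped", n_unkeyable
        )
    if report is not None:
        report.n_unkeyable += n_unkeyable
        report.n_cells_total += len(order)
    # deterministic output independent of input permutation
    order.sort()
    cells: list[CellChains] = []
    for cell_id in order:
        chains = per_cell[cell_id]
        alpha = frozenset(k for k in chains if k.locus == "TRA")
        beta = frozenset(k for k in chains if k.locus == "TRB")
        cells.append(
            CellChains(
                barcode=cell_id[1],
                sample_id=cell_id[0],
                alpha_chains=alpha,
                beta_chains=beta,
                umis=dict(chains),
            )
        )
    return cells


def require_paired(
    cells: Iterable[CellChains], report: QCReport | None = None
) -> list[CellChains]:
    """Keep cells with at least one α and one β chain.

    The retained count is the sample's paired-cell denominator for every
    downstream proportion.
    """
    cells = list(cells)
    paired = [c for c in cells if c.is_paired]
    if report is not None:
        report.n_cells_paired += len(paired)
        report.n_cells_unpaired += len(cells) - len(paired)
    logger.info("paired-cell filter: %d of %d cells retained", len(paired), len(cells))
    return paired


def run_qc(
    records: Sequence[ContigRecord],
    identity: ChainIdentity = "nt",
    min_umis: int = 0,
) -> tuple[list[CellChains], QCReport]:
    """Full QC: rule filtering, chain collapsing, paired-cell requirement."""
    report = QCReport()
    functional = filter_functional_contigs(records, min_umis=min_umis, report=report)
    cells = collapse_chains(functional, identity=identity, report=report)
    paired = require_paired(cells, report=report)
    if not report.balance_ok():
        raise ContractError("QC bookkeeping does not balance")  # pragma: no cover
    return paired, report
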