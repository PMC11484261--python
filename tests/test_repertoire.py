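"""Clonotype calling, expansion summaries and gene-usage tables."""

import random
from collections import Counter

import numpy as np
import pytest

from dualtcr.pairing import PairingType
from dualtcr.qc import CellChains, run_qc
from dualtcr.repertoire import (
    call_clonotypes,
    expansion_summary,
    gene_usage,
    receptor_class,
)
from dualtcr.simulate import SimConfig, simulate_sample
from conftest import make_cell, make_chain


def _clone_of(cell: CellChains, n: int) -> list[CellChains]:
    """n cells sharing the given cell's exact chain set."""
    return [
        CellChains(
            barcode=f"{cell.barcode}_{i}",
            sample_id=cell.sample_id,
            alpha_chains=cell.alpha_chains,
            beta_chains=cell.beta_chains,
            umis=dict(cell.umis),
        )
        for i in range(n)
    ]


def test_identical_chain_sets_form_one_expanded_clonotype():
    cells = _clone_of(make_cell(1, 2), 3)  # a dual-β clone of size 3
    (ct,) = call_clonotypes(cells)
    assert ct.size == 3 and ct.expanded and ct.receptor_class == "dual"


def test_all_unique_cells_are_singletons():
    cells = [make_cell(1, 1) for _ in range(10)]
    cts = call_clonotypes(cells)
    assert len(cts) == 10
    assert all(ct.size == 1 and not ct.expanded for ct in cts)


def test_beta_only_definition_is_coarser_than_full_set():
    base = make_cell(1, 1)
    other_alpha = CellChains(
        barcode="other-1",
        sample_id=base.sample_id,
        alpha_chains=frozenset({make_chain("TRA", "TRAV9", "TRAJ5", "TGTTTT")}),
        beta_chains=base.beta_chains,
        umis={},
    )
    cells = [base, other_alpha]
    assert len(call_clonotypes(cells, "full_set")) == 2
    assert len(call_clonotypes(cells, "beta_only")) == 1


def test_unknown_definition_rejected():
    with pytest.raises(ValueError):
        call_clonotypes([make_cell(1, 1)], "gamma_only")


def test_single_and_dual_cells_clonotyped_separately():
    # a single cell and a dual cell sharing the single cell's chains must not
    # merge, even under beta_only
    single = make_cell(1, 1)
    dual = CellChains(
        barcode="dual-1",
        sample_id=single.sample_id,
        alpha_chains=single.alpha_chains
        | {make_chain("TRA", "TRAV30", "TRAJ1", "TGTGGG")},
        beta_chains=single.beta_chains,
        umis={},
    )
    cts = call_clonotypes([single, dual], "beta_only")
    assert len(cts) == 2
    assert {ct.receptor_class for ct in cts} == {"single", "dual"}


def test_clonotype_partition_sums_to_cell_counts():
    cells = _clone_of(make_cell(1, 1), 4) + [make_cell(2, 1) for _ in range(5)]
    cts = call_clonotypes(cells)
    by_class = Counter()
    for ct in cts:
        by_class[ct.receptor_class] += ct.size
    assert by_class["single"] == 4
    assert by_class["dual"] == 5


def test_clonotype_calling_invariant_under_permutation():
    cells = _clone_of(make_cell(1, 2), 3) + [make_cell(1, 1) for _ in range(7)]
    base = [(c.size, c.chain_key_set) for c in call_clonotypes(cells)]
    shuffled = cells[:]
    random.Random(3).shuffle(shuffled)
    assert [(c.size, c.chain_key_set) for c in call_clonotypes(shuffled)] == base


def test_expansion_summary_arithmetic():
    cells = _clone_of(make_cell(1, 1), 3) + [make_cell(1, 1), make_cell(1, 1)]
    table = expansion_summary(call_clonotypes(cells))
    row = table.iloc[0]
    assert row.n_expanded_clonotypes == 1
    assert row.n_cells_expanded == 3
    assert row.frac_cells_expanded == pytest.approx(0.6)
    assert row.largest_clone == 3


def test_no_expansion_when_all_singletons():
    table = expansion_summary(call_clonotypes([make_cell(1, 1) for _ in range(5)]))
    assert table.n_expanded_clonotypes.item() == 0


def test_planted_clone_recovered_from_simulation():
    cfg = SimConfig(
        sample_id="S1", n_cells=300, seed=11,
        planted_clones=((PairingType.DUAL_B_A1A2, 5),),
    )
    sim = simulate_sample(cfg)
    cells, _ = run_qc(sim.contigs)
    table = expansion_summary(call_clonotypes(cells))
    dual = table[table.receptor_class == "dual"].iloc[0]
    assert dual.n_expanded_clonotypes >= 1
    assert dual.largest_clone == 5


def test_dual_cell_contributes_both_beta_chains_to_usage():
    cell = CellChains(
        barcode="b-1", sample_id="S1",
        alpha_chains=frozenset({make_chain("TRA", "TRAV1", "TRAJ1", "TGTA")}),
        beta_chains=frozenset({
            make_chain("TRB", "TRBV10", "TRBJ1-1", "TGCA"),
            make_chain("TRB", "TRBV30", "TRBJ1-2", "TGCC"),
        }),
        umis={},
    )
    table = gene_usage([cell], "TRBV")
    assert set(table.gene) == {"TRBV10", "TRBV30"}
    assert (table.chain_count == 1).all()


def test_single_chain_stratum_has_frequency_one():
    table = gene_usage([make_cell(1, 1)], "TRAV")
    assert table.frequency.tolist() == [1.0]


def test_frequencies_sum_to_one_within_strata():
    cells = [make_cell(a, b) for a in (1, 2) for b in (1, 2) for _ in range(5)]
    groups = {"S1": "pre_ivig"}
    for family in ("TRAV", "TRBV", "TRAJ", "TRBJ"):
        table = gene_usage(cells, family, groups)
        sums = table.groupby(["receptor_class", "group"]).frequency.sum()
        assert np.allclose(sums, 1.0)


def test_usage_recovers_generator_pool_weights():
    """With 10⁴ cells, observed TRBV frequencies approach the sampling weights."""
    from dualtcr.simulate import GenePool, default_pools

    pools = default_pools()
    pools["TRBV"] = GenePool(("TRBV5", "TRBV6", "TRBV7"), (0.5, 0.3, 0.2))
    cfg = SimConfig(
        sample_id="S1", n_cells=10_000, seed=5,
        pairing_probs={PairingType.SINGLE_AB: 1.0, PairingType.DUAL_A_B1B2: 0.0,
                       PairingType.DUAL_B_A1A2: 0.0, PairingType.DUAL_A1A2B1B2: 0.0,
                       PairingType.OTHERS: 0.0},
        pools=pools,
    )
    sim = simulate_sample(cfg)
    cells, _ = run_qc(sim.contigs)
    table = gene_usage(cells, "TRBV").set_index("gene")
    for gene, weight in [("TRBV5", 0.5), ("TRBV6", 0.3), ("TRBV7", 0.2)]:
        assert abs(table.loc[gene, "frequency"] - weight) < 0.02


def test_receptor_class_labels():
    assert receptor_class(make_cell(1, 1)) == "single"
    assert receptor_class(make_cell(2, 2)) == "dual"
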