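import itertools

import pytest

from dualtcr.contigs import ContigRecord
from dualtcr.qc import CellChains, ChainKey

_counter = itertools.count()


def make_contig(**overrides) -> ContigRecord:
    """A well-formed contig that passes every QC rule; override fields at will."""
    i = next(_counter)
    defaults = dict(
        barcode=f"AAACCTGAGTACGT{i:02d}-1",
        contig_id=f"contig_{i}",
        is_cell=True,
        high_confidence=True,
        chain="TRA",
        v_gene="TRAV1",
        d_gene=None,
        j_gene="TRAJ33",
        c_gene="TRAC",
        cdr3_aa="CAVRDN",
        cdr3_nt="TGTGCTGTGAGAGATAAC",
        productive=True,
        umis=4,
        reads=120,
        sample_id="S1",
    )
    defaults.update(overrides)
    return ContigRecord(**defaults)


def make_chain(locus="TRA", v="TRAV1", j="TRAJ33", cdr3="TGTGCT") -> ChainKey:
    return ChainKey(locus=locus, v_gene=v, j_gene=j, cdr3_nt=cdr3)


def make_cell(n_alpha=1, n_beta=1, barcode=None, sample_id="S1") -> CellChains:
    """A cell with the requested number of distinct α and β chains."""
    tag = next(_counter)
    if barcode is None:
        barcode = f"CELL{tag:06d}-1"
    # junctions carry a per-cell tag so distinct factory calls give distinct
    # chains (clones are built by copying a cell's chain sets explicitly)
    alphas = frozenset(
        make_chain("TRA", f"TRAV{i + 1}", "TRAJ33", f"TGT{'A' * (i + 3)}X{tag}")
        for i in range(n_alpha)
    )
    betas = frozenset(
        make_chain("TRB", f"TRBV{i + 2}", "TRBJ1-1", f"TGC{'G' * (i + 3)}X{tag}")
        for i in range(n_beta)
    )
    return CellChains(
        barcode=barcode,
        sample_id=sample_id,
        alpha_chains=alphas,
        beta_chains=betas,
        umis={k: 3 for k in alphas | betas},
    )


@pytest.fixture
def contig_factory():
    return make_contig


@pytest.fixture
def cell_factory():
    return make_cell
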