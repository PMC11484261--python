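"""Joining receptor classifications to T-cell subset annotations.

Subset labels (naive/central-memory/effector-memory CD4 and CD8, plus Treg)
come from an external annotation table keyed by (sample_id, barcode) — they
are produced upstream by transcriptome clustering and marker-based
annotation, which this package does not perform.  The join is inner;
unmatched barcodes on either side are counted and reported, and cells
without a subset label remain available for sample-level analyses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import ContractError, SchemaError
from .pairing import PairingType, classify_pairing
from .qc import CellChains

#: The seven recognized T-cell subsets.
SUBSETS = (
    "naive_cd4",
    "naive_cd8",
    "cd4_cm",
    "cd8_cm",
    "cd4_em",
    "cd8_em",
    "treg",
)


@dataclass(slots=True)
class JoinResult:
    """Annotated cells plus join bookkeeping."""

    cells: list[CellChains]
    subsets: list[str]  # parallel to cells
    n_unmatched_cells: int
    n_unmatched_annotations: int

    def __len__(self) -> int:
        return len(self.cells)


def read_subset_annotations(path) -> pd.DataFrame:
    """Read an annotation TSV with columns sample_id, barcode, subset."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "barcode", "subset"} - set(df.columns)
    if missing:
        raise SchemaError(f"annotation table missing column(s): {sorted(missing)}")
    return df


def _validated_annotation_map(annotations: pd.DataFrame) -> dict[tuple[str, str], str]:
    missing = {"sample_id", "barcode", "subset"} - set(annotations.columns)
    if missing:
        raise SchemaError(f"annotation table missing column(s): {sorted(missing)}")
    bad = set(annotations["subset"]) - set(SUBSETS)
    if bad:
        raise ContractError(
            f"unknown subset label(s): {sorted(bad)}; expected one of {SUBSETS}"
        )
    mapping: dict[tuple[str, str], str] = {}
    for row in annotations.itertuples(index=False):
        key = (str(row.sample_id), str(row.barcode))
        if key in mapping:
            raise ContractError(
                f"duplicate annotation for sample {key[0]}, barcode {key[1]}"
            )
        mapping[key] = str(row.subset)
    return mapping


def join_subsets(
    cells: Sequence[CellChains], annotations: pd.DataFrame
) -> JoinResult:
    """Inner-join cells with subset annotations on (sample_id, barcode).

    Lossless modulo bookkeeping: joined + unmatched cells = input cells.
    Duplicate (sample, barcode) annotations are an error; unknown subset
    labels are an error (they usually indicate a manifest typo).
    """
    mapping = _validated_annotation_map(annotations)
    joined_cells: list[CellChains] = []
    joined_subsets: list[str] = []
    matched_keys = set()
    for cell in cells:
        key = (cell.sample_id, cell.barcode)
        subset = mapping.get(key)
        if subset is None:
            continue
        matched_keys.add(key)
        joined_cells.append(cell)
        joined_subsets.append(subset)
    return JoinResult(
        cells=joined_cells,
        subsets=joined_subsets,
        n_unmatched_cells=len(cells) - len(joined_cells),
        n_unmatched_annotations=len(mapping) - len(matched_keys),
    )


def subset_composition(
    joined: JoinResult,
    groups: Mapping[str, str] | None = None,
    by: str = "receptor_class",
) -> pd.DataFrame:
    """Single/dual composition of each subset, per group.

    ``by`` is ``receptor_class`` (single vs dual) or ``pairing_type`` (the
    five classes).  Percentages are of the subset's paired cells within the
    group and sum to 100 per non-empty (group, subset) stratum.  Subsets
    with no cells in a group appear as zero rows.
    """
    if by not in ("receptor_class", "pairing_type"):
        raise ValueError(f"unknown stratification: {by!r}")
    counts: Counter = Counter()
    stratum_totals: Counter = Counter()
    seen_groups = set()
    for cell, subset in zip(joined.cells, joined.subsets):
        group = groups.get(cell.sample_id, "") if groups else ""
        seen_groups.add(group)
        ptype = classify_pairing(cell)
        label = ("dual" if ptype.is_dual else "single") if by == "receptor_class" else ptype.value
        counts[(group, subset, label)] += 1
        stratum_totals[(group, subset)] += 1
    labels = (
        ("single", "dual")
        if by == "receptor_class"
        else tuple(t.value for t in PairingType)
    )
    rows = []
    for group in sorted(seen_groups):
        for subset in SUBSETS:
            total = stratum_totals[(group, subset)]
            for label in labels:
                n = counts[(group, subset, label)]
                rows.append(
                    {
                        "group": group,
                        "subset": subset,
                        "class": label,
                        "cell_count": n,
                        "percent": 100.0 * n / total if total else float("nan"),
                    }
                )
    return pd.DataFrame(rows, columns=["group", "subset", "class", "cell_count", "percent"])


def class_distribution_over_subsets(
    joined: JoinResult, groups: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Transposed view: where do single vs dual cells come from?

    Per (group, receptor class): the distribution over subsets, summing to
    100% per non-empty stratum.  This is the view behind statements like
    "dual-TCR cells originate mainly from Tregs".
    """
    counts: Counter = Counter()
    totals: Counter = Counter()
    seen_groups = set()
    for cell, subset in zip(joined.cells, joined.subsets):
        group = groups.get(cell.sample_id, "") if groups else ""
        seen_groups.add(group)
        rclass = "dual" if classify_pairing(cell).is_dual else "single"
        counts[(group, rclass, subset)] += 1
        totals[(group, rclass)] += 1
    rows = []
    for group in sorted(seen_groups):
        for rclass in ("single", "dual"):
            total = totals[(group, rclass)]
            for subset in SUBSETS:
                n = counts[(group, rclass, subset)]
                rows.append(
                    {
                        "group": group,
                        "receptor_class": rclass,
                        "subset": subset,
                        "cell_count": n,
                        "percent": 100.0 * n / total if total else float("nan"),
                    }
                )
    return pd.DataFrame(
        rows, columns=["group", "receptor_class", "subset", "cell_count", "percent"]
    )
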