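"""Pairing-type classification of paired αβ T cells and per-sample summaries.

A paired cell (≥1 α and ≥1 β chain) falls into exactly one of five classes,
determined purely by its chain counts (a = number of distinct α chains,
b = number of distinct β chains):

====================  ==========  =============================================
class                 (a, b)      biology
====================  ==========  =============================================
``SINGLE_AB``         (1, 1)      conventional single-TCR T cell
``DUAL_A_B1B2``       (1, 2)      dual-β cell — escaped TRB allelic exclusion
``DUAL_B_A1A2``       (2, 1)      dual-α cell — TRA allelic inclusion (the
                                  most common dual class)
``DUAL_A1A2B1B2``     (2, 2)      dual at both loci
``OTHERS``            a≥3 or b≥3  residual multi-chain combinations
====================  ==========  =============================================

``OTHERS`` counts toward the dual total: it is a multi-receptor class, and
per-sample count arithmetic (single + dual = paired) only balances that way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .errors import ContractError, EmptySampleError
from .qc import CellChains


class PairingType(str, Enum):
    SINGLE_AB = "single_ab"
    DUAL_A_B1B2 = "dual_a_b1b2"
    DUAL_B_A1A2 = "dual_b_a1a2"
    DUAL_A1A2B1B2 = "dual_a1a2b1b2"
    OTHERS = "others"

    @property
    def is_dual(self) -> bool:
        return self is not PairingType.SINGLE_AB


DUAL_TYPES = (
    PairingType.DUAL_A_B1B2,
    PairingType.DUAL_B_A1A2,
    PairingType.DUAL_A1A2B1B2,
    PairingType.OTHERS,
)

GROUPS = ("pre_ivig", "post_ivig", "control")


def classify_pairing(cell: CellChains) -> PairingType:
    """Classify one paired cell by its distinct chain counts.

    Raises
    ------
    ContractError
        If the cell is unpaired (lacks an α or a β chain).
    """
    a, b = cell.n_alpha, cell.n_beta
    if a < 1 or b < 1:
        raise ContractError(
            f"cell {cell.barcode} is unpaired (alpha={a}, beta={b}); "
            "pairing classification requires at least one chain per locus"
        )
    if a == 1 and b == 1:
        return PairingType.SINGLE_AB
    if a == 1 and b == 2:
        return PairingType.DUAL_A_B1B2
    if a == 2 and b == 1:
        return PairingType.DUAL_B_A1A2
    if a == 2 and b == 2:
        return PairingType.DUAL_A1A2B1B2
    return PairingType.OTHERS


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (display convention for percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(slots=True)
class SampleSummary:
    """Per-sample counts of single and dual pairing classes.

    Count invariants (checked by :meth:`validate`):
    ``n_single + n_dual_total == n_paired`` and the four dual subtype counts
    sum to ``n_dual_total``.  Unrounded proportions sum to exactly 100.
    """

    sample_id: str
    group: str
    n_paired: int
    n_single: int
    n_dual_a_b1b2: int
    n_dual_b_a1a2: int
    n_dual_a1a2b1b2: int
    n_others: int

    @property
    def n_dual_total(self) -> int:
        return (
            self.n_dual_a_b1b2
            + self.n_dual_b_a1a2
            + self.n_dual_a1a2b1b2
            + self.n_others
        )

    def count(self, ptype: PairingType) -> int:
        return {
            PairingType.SINGLE_AB: self.n_single,
            PairingType.DUAL_A_B1B2: self.n_dual_a_b1b2,
            PairingType.DUAL_B_A1A2: self.n_dual_b_a1a2,
            PairingType.DUAL_A1A2B1B2: self.n_dual_a1a2b1b2,
            PairingType.OTHERS: self.n_others,
        }[ptype]

    def proportion(self, which: str) -> float:
        """Unrounded percentage of paired cells.

        ``which`` is ``single``, ``dual_total`` or a :class:`PairingType`
        value string.
        """
        counts = {
            "single": self.n_single,
            "dual_total": self.n_dual_total,
            PairingType.SINGLE_AB.value: self.n_single,
            PairingType.DUAL_A_B1B2.value: self.n_dual_a_b1b2,
            PairingType.DUAL_B_A1A2.value: self.n_dual_b_a1a2,
            PairingType.DUAL_A1A2B1B2.value: self.n_dual_a1a2b1b2,
            PairingType.OTHERS.value: self.n_others,
        }
        return 100.0 * counts[which] / self.n_paired

    def display_proportion(self, which: str) -> float:
        """Half-up rounded to 2 decimals, the tabular display convention."""
        return round_half_up(self.proportion(which), 2)

    def validate(self) -> None:
        if self.n_paired <= 0:
            raise EmptySampleError(
                f"sample {self.sample_id}: no paired cells, proportions undefined"
            )
        if min(
            self.n_single,
            self.n_dual_a_b1b2,
            self.n_dual_b_a1a2,
            self.n_dual_a1a2b1b2,
            self.n_others,
        ) < 0:
            raise ContractError(f"sample {self.sample_id}: negative class count")
        if self.n_single + self.n_dual_total != self.n_paired:
            raise ContractError(
                f"sample {self.sample_id}: single ({self.n_single}) + dual "
                f"({self.n_dual_total}) != paired ({self.n_paired})"
            )
        total_pct = self.proportion("single") + sum(
            self.proportion(t.value) for t in DUAL_TYPES
        )
        if not math.isclose(total_pct, 100.0, abs_tol=1e-9):
            raise ContractError(
                f"sample {self.sample_id}: unrounded proportions sum to {total_pct}"
            )

    def as_dict(self) -> dict:
        d = {
            "sample_id": self.sample_id,
            "group": self.group,
            "n_paired": self.n_paired,
            "n_single": self.n_single,
            "n_dual_total": self.n_dual_total,
            "n_dual_a_b1b2": self.n_dual_a_b1b2,
            "n_dual_b_a1a2": self.n_dual_b_a1a2,
            "n_dual_a1a2b1b2": self.n_dual_a1a2b1b2,
            "n_others": self.n_others,
            "pct_single": self.display_proportion("single"),
            "pct_dual_total": self.display_proportion("dual_total"),
            "pct_dual_a_b1b2": self.display_proportion(PairingType.DUAL_A_B1B2.value),
            "pct_dual_b_a1a2": self.display_proportion(PairingType.DUAL_B_A1A2.value),
            "pct_dual_a1a2b1b2": self.display_proportion(
                PairingType.DUAL_A1A2B1B2.value
            ),
            "pct_others": self.display_proportion(PairingType.OTHERS.value),
        }
        return d


def summarize_sample(
    cells: Sequence[CellChains], sample_id: str, group: str = ""
) -> SampleSummary:
    """Count pairing classes over one sample's paired cells.

    Every cell must be paired and carry the given ``sample_id`` (when the
    record has one).  Raises :class:`EmptySampleError` on zero cells.
    """
    if not cells:
        raise EmptySampleError(f"sample {sample_id}: no paired cells")
    counts = {t: 0 for t in PairingType}
    for cell in cells:
        if cell.sample_id and cell.sample_id != sample_id:
            raise ContractError(
                f"cell {cell.barcode} belongs to sample {cell.sample_id}, "
                f"not {sample_id}"
            )
        counts[classify_pairing(cell)] += 1
    summary = SampleSummary(
        sample_id=sample_id,
        group=group,
        n_paired=len(cells),
        n_single=counts[PairingType.SINGLE_AB],
        n_dual_a_b1b2=counts[PairingType.DUAL_A_B1B2],
        n_dual_b_a1a2=counts[PairingType.DUAL_B_A1A2],
        n_dual_a1a2b1b2=counts[PairingType.DUAL_A1A2B1B2],
        n_others=counts[PairingType.OTHERS],
    )
    summary.validate()
    return summary


def summaries_frame(summaries: Iterable[SampleSummary]) -> pd.DataFrame:
    """Per-sample summary table (one row per sample, counts and percentages)."""
    return pd.DataFrame([s.as_dict() for s in summaries])


_METRICS = (
    "single",
    "dual_total",
    PairingType.DUAL_A_B1B2.value,
    PairingType.DUAL_B_A1A2.value,
    PairingType.DUAL_A1A2B1B2.value,
    PairingType.OTHERS.value,
)


def aggregate_groups(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    """Group-level mean/SD of each proportion across samples.

    Statistics are computed on unrounded proportions.  Groups with a single
    sample report the mean with SD absent (NaN); empty groups are omitted.
    Columns: group, metric, n_samples, mean_pct, sd_pct.
    """
    rows = []
    groups = sorted({s.group for s in summaries}, key=lambda g: (GROUPS.index(g) if g in GROUPS else 99, g))
    for group in groups:
        members = [s for s in summaries if s.group == group]
        for metric in _METRICS:
            values = [s.proportion(metric) for s in members]
            n = len(values)
            mean = sum(values) / n
            if n > 1:
                sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
            else:
                sd = float("nan")
            rows.append(
                {
                    "group": group,
                    "metric": metric,
                    "n_samples": n,
                    "mean_pct": mean,
                    "sd_pct": sd,
                }
            )
    return pd.DataFrame(rows)


def paired_proportions(
    summaries: Sequence[SampleSummary],
    manifest: pd.DataFrame,
    metric: str = "dual_total",
    before: str = "pre_ivig",
    after: str = "post_ivig",
) -> pd.DataFrame:
    """Align before/after proportions by patient for the paired t-test.

    ``manifest`` needs columns sample_id, patient_id, group.  Patients missing
    either timepoint are dropped.  Columns: patient_id, before, after,
    difference (after − before), on unrounded percentages.
    """
    required = {"sample_id", "patient_id", "group"}
    missing = required - set(manifest.columns)
    if missing:
        raise ContractError(f"manifest missing column(s): {sorted(missing)}")
    by_sample = {s.sample_id: s for s in summaries}
    per_patient: dict[str, dict[str, float]] = {}
    for row in manifest.itertuples(index=False):
        if row.sample_id not in by_sample or row.group not in (before, after):
            continue
        slot = "before" if row.group == before else "after"
        entry = per_patient.setdefault(str(row.patient_id), {})
        if slot in entry:
            raise ContractError(
                f"patient {row.patient_id} has multiple {slot!r} samples"
            )
        entry[slot] = by_sample[row.sample_id].proportion(metric)
    rows = [
        {
            "patient_id": pid,
            "before": e["before"],
            "after": e["after"],
            "difference": e["after"] - e["before"],
        }
        for pid, e in sorted(per_patient.items())
        if "before" in e and "after" in e
    ]
    return pd.DataFrame(rows)


def read_manifest(path) -> pd.DataFrame:
    """Read a sample manifest TSV: sample_id, patient_id, group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "patient_id", "group"} - set(df.columns)
    if missing:
        raise ContractError(f"manifest missing column(s): {sorted(missing)}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ContractError(
            f"manifest has unknown group label(s): {sorted(bad)}; expected {GROUPS}"
        )
    return df
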