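"""One-command orchestration: ingest → QC → classify → repertoire → subsets → compare.

Every stage writes a plain TSV (or JSON for the QC report), so each stage is
independently re-runnable and every number in the report bundle is traceable
to a stage output file.  A MANIFEST file lists the stages that completed;
on failure, partial outputs are retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .contigs import read_contigs
from .errors import DualTCRError
from .pairing import (
    SampleSummary,
    aggregate_groups,
    paired_proportions,
    read_manifest,
    summaries_frame,
    summarize_sample,
)
from .qc import CellChains, QCReport, run_qc
from .repertoire import call_clonotypes, clonotypes_frame, expansion_summary, gene_usage
from .stats import anova_oneway, chi_square, independent_t, paired_t
from .subsets import (
    class_distribution_over_subsets,
    join_subsets,
    read_subset_annotations,
    subset_composition,
)

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class RunConfig:
    """Inputs and knobs for a full pipeline run."""

    contig_paths: dict[str, Path]  # sample_id -> contig file
    manifest_path: Path
    out_dir: Path
    dialect: str = "tenx_csv"
    annotations_path: Path | None = None
    chain_identity: str = "nt"
    clonotype_definition: str = "full_set"
    min_umis: int = 0
    alpha: float = 0.05

    def validate(self) -> None:
        for sid, p in self.contig_paths.items():
            if not Path(p).exists():
                raise DualTCRError(f"contig file for sample {sid} not found: {p}")
        if not Path(self.manifest_path).exists():
            raise DualTCRError(f"manifest not found: {self.manifest_path}")
        if self.annotations_path is not None and not Path(self.annotations_path).exists():
            raise DualTCRError(f"annotation table not found: {self.annotations_path}")


@dataclass(slots=True)
class RunResult:
    summaries: list[SampleSummary]
    qc_reports: dict[str, QCReport]
    tests: pd.DataFrame
    completed_stages: list[str] = field(default_factory=list)


def _compare_groups(
    summaries: Sequence[SampleSummary], manifest: pd.DataFrame, alpha: float
) -> pd.DataFrame:
    """The study's comparison battery on dual-receptor proportions."""
    rows = []
    by_group: dict[str, list[float]] = {}
    for s in summaries:
        by_group.setdefault(s.group, []).append(s.proportion("dual_total"))

    paired = paired_proportions(summaries, manifest, metric="dual_total")
    if len(paired) >= 2:
        res = paired_t(paired["before"], paired["after"], pairing=paired["patient_id"])
        rows.append(
            {
                "comparison": "dual_pct_pre_vs_post_paired",
                **res.as_dict(),
                "significant": res.significant(alpha),
                "mean_after_minus_before": res.group_summaries[
                    "mean_diff_after_minus_before"
                ],
            }
        )
    for grp_a, grp_b in (("pre_ivig", "control"), ("post_ivig", "control")):
        if len(by_group.get(grp_a, [])) >= 2 and len(by_group.get(grp_b, [])) >= 2:
            res = independent_t(by_group[grp_a], by_group[grp_b])
            rows.append(
                {
                    "comparison": f"dual_pct_{grp_a}_vs_{grp_b}",
                    **res.as_dict(),
                    "significant": res.significant(alpha),
                }
            )
    if all(len(by_group.get(g, [])) >= 2 for g in ("pre_ivig", "post_ivig", "control")):
        res = anova_oneway(
            by_group["pre_ivig"], by_group["post_ivig"], by_group["control"]
        )
        rows.append(
            {
                "comparison": "dual_pct_three_groups_anova",
                **res.as_dict(),
                "significant": res.significant(alpha),
            }
        )
    # single/dual counts × group contingency
    groups = sorted({s.group for s in summaries})
    if len(groups) >= 2:
        table = [
            [sum(s.n_single for s in summaries if s.group == g) for g in groups],
            [sum(s.n_dual_total for s in summaries if s.group == g) for g in groups],
        ]
        res = chi_square(table)
        rows.append(
            {
                "comparison": "single_dual_counts_by_group_chisq",
                **res.as_dict(),
                "significant": res.significant(alpha),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis and write the report bundle to ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    manifest = read_manifest(config.manifest_path)
    group_of = dict(zip(manifest["sample_id"], manifest["group"]))

    def finish_stage(name: str) -> None:
        completed.append(name)
        (out / "MANIFEST").write_text("\n".join(completed) + "\n")

    try:
        # ingest + qc + classify, per sample
        all_cells: list[CellChains] = []
        qc_reports: dict[str, QCReport] = {}
        summaries: list[SampleSummary] = []
        for sample_id, path in sorted(config.contig_paths.items()):
            records = read_contigs(path, config.dialect, sample_id)
            cells, report = run_qc(
                records, identity=config.chain_identity, min_umis=config.min_umis
            )
            qc_reports[sample_id] = report
            all_cells.extend(cells)
            summaries.append(
                summarize_sample(cells, sample_id, group_of.get(sample_id, ""))
            )
        finish_stage("ingest")
        with open(out / "qc_report.json", "w") as fh:
            json.dump(
                {sid: r.as_dict() for sid, r in qc_reports.items()}, fh, indent=2
            )
        finish_stage("qc")

        summaries_frame(summaries).to_csv(out / "summary.tsv", sep="\t", index=False)
        aggregate_groups(summaries).to_csv(
            out / "group_summary.tsv", sep="\t", index=False
        )
        finish_stage("classify")

        clonotypes = call_clonotypes(all_cells, config.clonotype_definition)
        clonotypes_frame(clonotypes).to_csv(
            out / "clonotypes.tsv", sep="\t", index=False
        )
        expansion_summary(clonotypes).to_csv(
            out / "expansion.tsv", sep="\t", index=False
        )
        usage = pd.concat(
            [gene_usage(all_cells, fam, group_of) for fam in ("TRAV", "TRBV", "TRAJ", "TRBJ")],
            ignore_index=True,
        )
        usage.to_csv(out / "gene_usage.tsv", sep="\t", index=False)
        finish_stage("repertoire")

        if config.annotations_path is not None:
            annotations = read_subset_annotations(config.annotations_path)
            joined = join_subsets(all_cells, annotations)
            subset_composition(joined, group_of).to_csv(
                out / "subset_composition.tsv", sep="\t", index=False
            )
            class_distribution_over_subsets(joined, group_of).to_csv(
                out / "class_distribution.tsv", sep="\t", index=False
            )
            finish_stage("subsets")

        tests = _compare_groups(summaries, manifest, config.alpha)
        tests.to_csv(out / "tests.tsv", sep="\t", index=False)
        finish_stage("compare")

        with open(out / "run_info.json", "w") as fh:
            json.dump(
                {
                    "dualtcr_version": __version__,
                    "dialect": config.dialect,
                    "chain_identity": config.chain_identity,
                    "clonotype_definition": config.clonotype_definition,
                    "min_umis": config.min_umis,
                    "alpha": config.alpha,
                    "n_samples": len(config.contig_paths),
                    "stages": completed,
                },
                fh,
                indent=2,
            )
        return RunResult(
            summaries=summaries,
            qc_reports=qc_reports,
            tests=tests,
            completed_stages=completed,
        )
    except Exception:
        logger.exception("pipeline failed after stages: %s", completed)
        raise
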