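"""End-to-end run: screen trials, match drugs, filter facilities, report.

The pipeline consumes the five offline inputs (MeSH tree file, drug
catalog, SIF interaction file(s), trial corpus, zip table), applies the
per-gene screen -> drug match -> expansion -> proximity chain, and
writes the two tab-delimited reports plus a run log.  All fatal input
errors abort before any report file is written.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import catalog as catalog_mod
from . import geo, mesh, ppi, report, trials as trials_mod
from .config import ConfigError, RunConfig
from .trials import ScreenDecision

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run."""

    reports: list[report.GeneReport]
    decisions: dict[str, list[ScreenDecision]] = field(default_factory=dict)
    summary_path: Path | None = None
    detail_path: Path | None = None
    log_path: Path | None = None
    log_lines: list[str] = field(default_factory=list)


def run_pipeline(
    config: RunConfig,
    mesh_file: str | Path,
    catalog_file: str | Path,
    sif_files: Sequence[str | Path],
    trials_path: str | Path,
    zip_file: str | Path | None = None,
    out_dir: str | Path = "oncomatch_out",
) -> PipelineResult:
    """Run the full matching pipeline and write both reports.

    Raises a fatal error (ConfigError / ValueError / FileNotFoundError)
    before writing anything if any input fails to parse or the
    configuration is inconsistent with the inputs.
    """
    vocab = mesh.neoplasm_subset(mesh.parse_mesh_tree(mesh_file))
    for condition in config.conditions:
        if condition not in vocab:
            raise ConfigError(
                f"conditions: {condition!r} is not a neoplasm MeSH heading"
            )
    cat = catalog_mod.build_indexes(catalog_mod.parse_drug_catalog(catalog_file), vocab)
    graph = ppi.parse_sif(list(sif_files)) if sif_files else None
    if graph is None and config.gene_level > 0:
        logger.warning("no interaction files supplied; expansion disabled")
    corpus = trials_mod.parse_trials(trials_path)

    zip_table: geo.ZipTable | None = None
    unit = geo.unit_by_name(config.unit)
    if config.max_distance > 0:
        if zip_file is None:
            raise ConfigError("max_distance: a zip table is required for proximity filtering")
        zip_table = geo.load_zip_table(zip_file)
        if config.zip_code not in zip_table:
            raise ConfigError(f"zip_code: {config.zip_code!r} not present in the zip table")

    log_lines: list[str] = []
    decisions: dict[str, list[ScreenDecision]] = {}
    gene_reports: list[report.GeneReport] = []
    report_config = report.ReportConfig(gene_level=config.gene_level)

    for gene in config.genes:
        gene_decisions = [
            trials_mod.screen(t, gene, vocab, config.countries, config.conditions)
            for t in corpus
        ]
        decisions[gene] = gene_decisions
        accepted_pairs = []
        for trial, decision in zip(corpus, gene_decisions):
            if not decision.accepted:
                continue
            kept = list(trial.locations)
            if zip_table is not None:
                kept = geo.facilities_within(
                    kept, config.zip_code, config.max_distance, unit, zip_table
                )
                if not kept:
                    logger.warning(
                        "%s: no facility within %.0f %s of %s; keeping trial with "
                        "zero listed facilities",
                        trial.trial_id, config.max_distance, unit.name, config.zip_code,
                    )
            accepted_pairs.append((trial, kept))

        gene_report = report.build_gene_report(
            gene, accepted_pairs, cat, graph, report_config
        )
        gene_reports.append(gene_report)

        n_accepted = len(accepted_pairs)
        reason_counts = Counter(
            code for d in gene_decisions if not d.accepted for code in d.reasons
        )
        reasons = (
            ", ".join(f"{code}={n}" for code, n in sorted(reason_counts.items()))
            or "none"
        )
        source = "direct" if gene_report.direct_drugs else (
            f"level<={config.gene_level}" if gene_report.expansion else "none"
        )
        line = (
            f"{gene}: accepted {n_accepted}/{len(corpus)} trials; "
            f"rejection reasons: {reasons}; "
            f"drugs: {gene_report.n_distinct_drugs} ({source})"
        )
        logger.info(line)
        log_lines.append(line)

    summary_path, detail_path = report.write_reports(gene_reports, out_dir)
    log_path = Path(out_dir) / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return PipelineResult(
        reports=gene_reports,
        decisions=decisions,
        summary_path=summary_path,
        detail_path=detail_path,
        log_path=log_path,
        log_lines=log_lines,
    )
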