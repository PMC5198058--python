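"""Tab-delimited summary and detailed reports.

Each run emits two reports.  The summary report has seven columns: the
queried gene, the trial accession, its title, its conditions, the drugs
under trial, the number of catalog drugs matched for the gene, and the
number of (post-proximity) facilities.  The detailed report has thirteen
columns (A-M): the trial columns plus, per matched catalog drug, its
accession (G), the targeted gene(s) through which it was matched (H),
its name (I), reference prices (J), SNP effect/adverse notes (K, L) and
the facility contact lines (M).  Catalog columns repeat across a gene's
trials so each row is self-contained.

A gene with trials but no drugs emits trial rows with "-" drug cells; a
gene with drugs but no accepted trials emits drug-only rows; a gene with
neither emits nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .catalog import DrugCatalog, DrugRecord, drugs_targeting
from .ppi import ExpansionResult, InteractionGraph, expand_search
from .trials import TrialLocation, TrialRecord

__all__ = [
    "SUMMARY_COLUMNS",
    "DETAIL_COLUMNS",
    "EMPTY_CELL",
    "GeneReport",
    "build_gene_report",
    "write_reports",
]

SUMMARY_COLUMNS = (
    "gene",
    "trial_id",
    "title",
    "conditions",
    "trial_drugs",
    "n_catalog_drugs",
    "n_locations",
)

DETAIL_COLUMNS = (
    "gene",
    "trial_id",
    "title",
    "phase",
    "conditions",
    "trial_drugs",
    "catalog_drug_id",
    "targeted_genes",
    "drug_name",
    "prices",
    "snp_effects",
    "snp_adverse",
    "locations_contact",
)

EMPTY_CELL = "-"
_JOIN = "; "


def _cell(value: str) -> str:
    """Sanitise one cell: collapse tabs/newlines, dash out emptiness."""
    text = " ".join(str(value).split())
    return text if text else EMPTY_CELL


def _join(values: Sequence[str]) -> str:
    return _JOIN.join(v for v in values if v)


def _format_prices(record: DrugRecord) -> str:
    return _join([f"{p.label} USD {p.amount:.2f}" for p in record.prices])


def _format_location(loc: TrialLocation) -> str:
    parts = [loc.facility, loc.contact, loc.city, loc.state, loc.zip, loc.country]
    return ", ".join(p for p in parts if p)


@dataclass(frozen=True)
class _DrugEntry:
    """One matched drug with the gene(s) through which it was reached."""

    record: DrugRecord
    via_genes: tuple[str, ...]


@dataclass
class GeneReport:
    """Everything reported for one queried gene."""

    gene: str
    #: (accepted trial, proximity-filtered facilities) pairs.
    trials: list[tuple[TrialRecord, list[TrialLocation]]] = field(default_factory=list)
    direct_drugs: list[DrugRecord] = field(default_factory=list)
    expansion: ExpansionResult | None = None
    entries: list[_DrugEntry] = field(default_factory=list)

    @property
    def n_distinct_drugs(self) -> int:
        return len({e.record.drug_id for e in self.entries})

    def summary_rows(self) -> list[tuple[str, ...]]:
        rows = []
        n_drugs = self.n_distinct_drugs
        for trial, kept in self.trials:
            rows.append(
                (
                    self.gene,
                    trial.trial_id,
                    _cell(trial.title),
                    _cell(_join(trial.conditions)),
                    _cell(_join(trial.drug_names)),
                    str(n_drugs),
                    str(len(kept)),
                )
            )
        if not self.trials and self.entries:
            rows.append(
                (self.gene, EMPTY_CELL, EMPTY_CELL, EMPTY_CELL, EMPTY_CELL, str(n_drugs), "0")
            )
        return rows

    def detail_rows(self) -> list[tuple[str, ...]]:
        drug_cells: list[tuple[str, str, str, str, str, str]] = [
            (
                entry.record.drug_id,
                _cell(_join(entry.via_genes)),
                _cell(entry.record.name),
                _cell(_format_prices(entry.record)),
                _cell(entry.record.snp_effects),
                _cell(entry.record.snp_adverse),
            )
            for entry in sorted(
                self.entries, key=lambda e: (e.record.drug_id, e.via_genes)
            )
        ]
        if not drug_cells:
            drug_cells = [(EMPTY_CELL,) * 6]

        rows: list[tuple[str, ...]] = []
        if self.trials:
            for trial, kept in self.trials:
                trial_cells = (
                    trial.trial_id,
                    _cell(trial.title),
                    _cell(trial.phase),
                    _cell(_join(trial.conditions)),
                    _cell(_join(trial.drug_names)),
                )
                contact = _cell(_join([_format_location(l) for l in kept]))
                for cells in drug_cells:
                    rows.append((self.gene, *trial_cells, *cells, contact))
        elif self.entries:
            for cells in drug_cells:
                rows.append(
                    (self.gene, EMPTY_CELL, EMPTY_CELL, EMPTY_CELL, EMPTY_CELL,
                     EMPTY_CELL, *cells, EMPTY_CELL)
                )
        return rows


@dataclass(frozen=True)
class ReportConfig:
    """Knobs that influence report construction (subset of the run config)."""

    gene_level: int = 1


def build_gene_report(
    gene: str,
    accepted_trials: Sequence[tuple[TrialRecord, list[TrialLocation]]],
    catalog: DrugCatalog,
    graph: InteractionGraph | None,
    config: ReportConfig = ReportConfig(),
) -> GeneReport:
    """Integrate one gene's accepted trials with its drug matches.

    Direct catalog hits are matched under the queried gene itself.  When
    there is no direct hit and ``config.gene_level > 0``, the interaction
    graph is expanded upstream; each (interactor, drug) pair becomes one
    drug entry, so a drug reached through two regulators is listed under
    both.
    """
    g = gene.strip().upper()
    report = GeneReport(gene=g, trials=list(accepted_trials))
    report.direct_drugs = drugs_targeting(g, catalog)
    if report.direct_drugs:
        report.entries = [
            _DrugEntry(record=r, via_genes=(g,)) for r in report.direct_drugs
        ]
    elif config.gene_level > 0 and graph is not None:
        expansion = expand_search(g, config.gene_level, graph, catalog)
        report.expansion = expansion
        entries: dict[str, _DrugEntry] = {}
        for level in sorted(k for k in expansion.levels if k >= 1):
            for interactor, records in expansion.levels[level].items():
                for r in records:
                    prev = entries.get(r.drug_id)
                    via = (interactor,) if prev is None else (*prev.via_genes, interactor)
                    entries[r.drug_id] = _DrugEntry(record=r, via_genes=tuple(sorted(set(via))))
        report.entries = [entries[i] for i in sorted(entries)]
    return report


def write_reports(
    reports: Sequence[GeneReport], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write ``summary.tsv`` and ``detailed.tsv`` under *out_dir*.

    Row order is panel order, then trial accession, then drug accession;
    embedded tabs and newlines in free text are collapsed to spaces.
    Returns the two paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_path = out / "summary.tsv"
    detail_path = out / "detailed.tsv"

    with summary_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for report in reports:
            for row in report.summary_rows():
                fh.write("\t".join(row) + "\n")
    with detail_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(DETAIL_COLUMNS) + "\n")
        for report in reports:
            for row in report.detail_rows():
                fh.write("\t".join(row) + "\n")
    return summary_path, detail_path
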