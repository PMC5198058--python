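"""DrugBank-style drug catalog: parsing, cancer-drug tagging, gene search.

The catalog dialect is a headered TSV with one drug per row and
";"-joined multi-valued cells.  A drug is tagged as a *cancer drug* when
its pharmacology indication contains at least one neoplasm MeSH heading;
gene-keyed search only ever returns cancer drugs that also pass the
eligibility rule (no nutraceuticals, over-the-counter products,
withdrawn or illicit drugs).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .mesh import NeoplasmVocabulary, match_neoplasm_terms

logger = logging.getLogger(__name__)

__all__ = [
    "PriceEntry",
    "DrugRecord",
    "DrugCatalog",
    "CATALOG_COLUMNS",
    "EXCLUDED_GROUPS",
    "parse_drug_catalog",
    "classify_cancer_drug",
    "is_eligible",
    "build_indexes",
    "drugs_targeting",
]

CATALOG_COLUMNS = (
    "drug_id",
    "molecule_type",
    "name",
    "brand_names",
    "synonyms",
    "prices",
    "indication",
    "target_genes",
    "snp_effects",
    "snp_adverse",
    "groups",
    "description",
)

#: Drug group labels that make a drug ineligible for reporting.
EXCLUDED_GROUPS = frozenset({"nutraceutical", "over-the-counter", "withdrawn", "illicit"})

_DRUG_ID = re.compile(r"^DB\d+$")
_PRICE = re.compile(r"^(?P<label>.*?)\s*USD\s*(?P<amount>\d+(?:\.\d+)?)$")


@dataclass(frozen=True)
class PriceEntry:
    """One unit price: free-text label (brand + dosage) and USD amount."""

    label: str
    amount: float

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("price amount must be non-negative")


@dataclass(frozen=True)
class DrugRecord:
    """One catalog entry (accession, names, prices, targets, SNP notes)."""

    drug_id: str
    molecule_type: str
    name: str
    brand_names: tuple[str, ...] = ()
    synonyms: tuple[str, ...] = ()
    prices: tuple[PriceEntry, ...] = ()
    indication: str = ""
    target_genes: tuple[str, ...] = ()
    snp_effects: str = ""
    snp_adverse: str = ""
    groups: tuple[str, ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        if not _DRUG_ID.match(self.drug_id):
            raise ValueError(f"drug_id must match 'DB<digits>': {self.drug_id!r}")


@dataclass
class DrugCatalog:
    """Parsed drug records plus (once built) the cancer and gene indexes."""

    records: list[DrugRecord]
    cancer_ids: set[str] = field(default_factory=set)
    gene_index: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.by_id: dict[str, DrugRecord] = {r.drug_id: r for r in self.records}

    @property
    def indexed(self) -> bool:
        return bool(self.gene_index) or bool(self.cancer_ids)


def _split_multi(cell: str) -> tuple[str, ...]:
    return tuple(part.strip() for part in cell.split(";") if part.strip())


def _parse_prices(cell: str, drug_id: str) -> tuple[PriceEntry, ...]:
    entries = []
    for part in _split_multi(cell):
        m = _PRICE.match(part)
        if m is None or not m.group("label"):
            logger.warning("%s: dropping unparseable price entry %r", drug_id, part)
            continue
        entries.append(PriceEntry(label=m.group("label"), amount=float(m.group("amount"))))
    return tuple(entries)


def _dedup_upper(symbols: tuple[str, ...]) -> tuple[str, ...]:
    seen: list[str] = []
    for s in symbols:
        u = s.upper()
        if u not in seen:
            seen.append(u)
    return tuple(seen)


def parse_drug_catalog(file: str | Path) -> DrugCatalog:
    """Parse the catalog TSV into a :class:`DrugCatalog` (indexes unbuilt).

    Raises
    ------
    FileNotFoundError
        If *file* does not exist.
    ValueError
        On a missing required column, an empty catalog, or a duplicate
        drug accession.  Unparseable price entries are dropped with a
        warning instead.
    """
    path = Path(file)
    if not path.is_file():
        raise FileNotFoundError(f"drug catalog not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty drug catalog: {path}") from None
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise ValueError(f"empty drug catalog: {path}")

    records: list[DrugRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        drug_id = row.drug_id.strip()
        if drug_id in seen:
            raise ValueError(f"{path}: duplicate drug_id {drug_id}")
        seen.add(drug_id)
        records.append(
            DrugRecord(
                drug_id=drug_id,
                molecule_type=row.molecule_type.strip(),
                name=row.name.strip(),
                brand_names=_split_multi(row.brand_names),
                synonyms=_split_multi(row.synonyms),
                prices=_parse_prices(row.prices, drug_id),
                indication=row.indication.strip(),
                target_genes=_dedup_upper(_split_multi(row.target_genes)),
                snp_effects=row.snp_effects.strip(),
                snp_adverse=row.snp_adverse.strip(),
                groups=_split_multi(row.groups),
                description=row.description.strip(),
            )
        )
    return DrugCatalog(records=records)


def classify_cancer_drug(record: DrugRecord, vocab: NeoplasmVocabulary) -> bool:
    """True iff the pharmacology indication contains a neoplasm heading."""
    return bool(match_neoplasm_terms(record.indication, vocab))


def is_eligible(record: DrugRecord) -> bool:
    """False iff the drug carries an excluded group label.

    Nutraceuticals, over-the-counter products, withdrawn drugs and
    illicit drugs are never reported, regardless of other labels.
    """
    return not any(g.lower() in EXCLUDED_GROUPS for g in record.groups)


def build_indexes(catalog: DrugCatalog, vocab: NeoplasmVocabulary) -> DrugCatalog:
    """Populate ``cancer_ids`` and ``gene_index`` in place and return the catalog.

    ``cancer_ids`` holds drugs that are both cancer-tagged and eligible;
    ``gene_index`` maps every (upper-cased) target gene of *all* records
    to the sorted accessions targeting it.
    """
    catalog.cancer_ids = {
        r.drug_id
        for r in catalog.records
        if is_eligible(r) and classify_cancer_drug(r, vocab)
    }
    index: dict[str, list[str]] = {}
    for r in catalog.records:
        for gene in r.target_genes:
            index.setdefault(gene, []).append(r.drug_id)
    catalog.gene_index = {g: sorted(ids) for g, ids in index.items()}
    return catalog


def drugs_targeting(gene: str, catalog: DrugCatalog) -> list[DrugRecord]:
    """Eligible cancer drugs whose target list contains *gene*.

    Symbol comparison is exact after upper-casing both sides; results are
    sorted by accession.  Requires :func:`build_indexes` to have run.
    """
    ids = catalog.gene_index.get(gene.strip().upper(), [])
    return [catalog.by_id[i] for i in ids if i in catalog.cancer_ids]
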