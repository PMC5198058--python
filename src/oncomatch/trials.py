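"""Clinical-trial records and the four-predicate screening filter.

Registry keyword search is noisy: a gene-symbol query returns surgery
trials, dietary-supplement trials, device trials and trials that are not
recruiting.  Screening keeps a trial only when it

1. mentions the queried gene symbol (whole token, any textual field),
2. studies a cancer condition (>= 1 neoplasm MeSH heading among its
   tagged MeSH terms or condition strings),
3. has a drug intervention, and
4. is actively recruiting, in one of the requested countries if any
   were requested.

Every failing predicate is recorded as a reason code, so a rejection is
always explainable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from lxml import etree

from .mesh import NeoplasmVocabulary, match_neoplasm_terms, normalize_text

__all__ = [
    "TrialLocation",
    "TrialRecord",
    "ScreenDecision",
    "REASON_CODES",
    "parse_trials",
    "mentions_gene",
    "is_cancer_trial",
    "has_drug_intervention",
    "is_recruiting_status",
    "has_recruiting_location_in",
    "is_recruiting_in",
    "screen",
]

#: Reason codes, in the order they are evaluated and reported.
REASON_CODES = (
    "NO_GENE_MENTION",
    "NOT_CANCER",
    "NO_DRUG",
    "NOT_RECRUITING",
    "NO_LOCATION_IN_COUNTRY",
)

_RECRUITING = "recruiting"


@dataclass(frozen=True)
class TrialLocation:
    """One facility conducting a trial."""

    facility: str = ""
    city: str = ""
    state: str = ""
    zip: str = ""
    country: str = ""
    contact: str = ""
    recruiting: bool = True

    def __post_init__(self) -> None:
        if not self.country.strip():
            raise ValueError("trial location must carry a country")


@dataclass(frozen=True)
class TrialRecord:
    """One registry record, with the searchable text derived on demand."""

    trial_id: str
    title: str = ""
    conditions: tuple[str, ...] = ()
    status: str = ""
    phase: str = ""
    interventions: tuple[tuple[str, str], ...] = ()
    mesh_terms: tuple[str, ...] = ()
    locations: tuple[TrialLocation, ...] = ()
    summary: str = ""

    def __post_init__(self) -> None:
        if not self.trial_id.startswith("NCT"):
            raise ValueError(f"trial id must carry the NCT prefix: {self.trial_id!r}")

    @property
    def full_text(self) -> str:
        """Concatenation of the textual fields, regenerated on every access."""
        parts = [self.trial_id, self.title, *self.conditions, *self.mesh_terms]
        parts.extend(f"{itype} {name}" for itype, name in self.interventions)
        parts.append(self.summary)
        return "\n".join(p for p in parts if p)

    @property
    def drug_names(self) -> tuple[str, ...]:
        return tuple(
            name
            for itype, name in self.interventions
            if itype.strip().lower() == "drug" and name.strip()
        )


@dataclass(frozen=True)
class ScreenDecision:
    """Accept/reject verdict for one trial under one gene query."""

    trial_id: str
    accepted: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.accepted != (len(self.reasons) == 0):
            raise ValueError("accepted must hold exactly when no reason is recorded")


def _text(element: etree._Element, tag: str) -> str:
    child = element.find(tag)
    return (child.text or "").strip() if child is not None else ""


def _parse_location(element: etree._Element, trial_recruiting: bool) -> TrialLocation:
    attr = element.get("recruiting")
    recruiting = trial_recruiting if attr is None else attr.strip().lower() == "true"
    return TrialLocation(
        facility=_text(element, "facility"),
        city=_text(element, "city"),
        state=_text(element, "state"),
        zip=_text(element, "zip"),
        country=_text(element, "country"),
        contact=_text(element, "contact"),
        recruiting=recruiting,
    )


def parse_trials(path: str | Path) -> list[TrialRecord]:
    """Parse trial records from an XML file or a directory of ``*.xml``.

    Dialect: root ``<trials>`` holding ``<trial>`` elements with children
    ``<id>``, ``<title>``, ``<status>``, ``<phase>``, ``<condition>*``,
    ``<mesh_term>*``, ``<intervention type="...">name</intervention>*``,
    ``<summary>`` and ``<location recruiting="true|false">*``.  Missing
    optional fields default to empty; a location without a recruiting
    attribute inherits the trial-level status.

    Raises
    ------
    ValueError
        On malformed XML (named by file), a duplicate trial id, or zero
        records overall.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(p.glob("*.xml"))
    elif p.is_file():
        files = [p]
    else:
        raise FileNotFoundError(f"trial corpus not found: {p}")

    records: list[TrialRecord] = []
    seen: set[str] = set()
    for file in files:
        try:
            root = etree.parse(str(file)).getroot()
        except etree.XMLSyntaxError as exc:
            raise ValueError(f"malformed trial XML in {file}: {exc}") from exc
        for trial in root.findall("trial"):
            status = _text(trial, "status")
            trial_recruiting = status.strip().casefold() == _RECRUITING
            record = TrialRecord(
                trial_id=_text(trial, "id"),
                title=_text(trial, "title"),
                conditions=tuple(
                    (c.text or "").strip() for c in trial.findall("condition")
                ),
                status=status,
                phase=_text(trial, "phase"),
                interventions=tuple(
                    (i.get("type", "").strip(), (i.text or "").strip())
                    for i in trial.findall("intervention")
                ),
                mesh_terms=tuple(
                    (m.text or "").strip() for m in trial.findall("mesh_term")
                ),
                locations=tuple(
                    _parse_location(loc, trial_recruiting)
                    for loc in trial.findall("location")
                ),
                summary=_text(trial, "summary"),
            )
            if record.trial_id in seen:
                raise ValueError(f"duplicate trial id {record.trial_id} in {file}")
            seen.add(record.trial_id)
            records.append(record)
    if not records:
        raise ValueError(f"no trial records found under {p}")
    return records


def mentions_gene(trial: TrialRecord, gene: str) -> bool:
    """Whole-token, case-insensitive occurrence of *gene* in the trial text.

    Word-boundary matching prevents e.g. ATM from matching "treATMent".
    """
    pattern = re.compile(rf"\b{re.escape(gene.strip())}\b", re.IGNORECASE)
    return bool(pattern.search(trial.full_text))


def is_cancer_trial(trial: TrialRecord, vocab: NeoplasmVocabulary) -> bool:
    """True iff any tagged MeSH term or condition string matches the vocabulary."""
    return any(
        match_neoplasm_terms(text, vocab)
        for text in (*trial.mesh_terms, *trial.conditions)
    )


def has_drug_intervention(trial: TrialRecord) -> bool:
    """True iff at least one intervention is a named drug compound."""
    return len(trial.drug_names) > 0


def is_recruiting_status(trial: TrialRecord) -> bool:
    """Exactly "Recruiting" after trimming and case-folding.

    "Not yet recruiting", "Enrolling by invitation" and "Active, not
    recruiting" all fail.
    """
    return trial.status.strip().casefold() == _RECRUITING


def has_recruiting_location_in(trial: TrialRecord, countries: Sequence[str]) -> bool:
    """True iff no country filter, or >= 1 actively recruiting facility there."""
    if not countries:
        return True
    wanted = {c.strip().casefold() for c in countries}
    return any(
        loc.recruiting and loc.country.strip().casefold() in wanted
        for loc in trial.locations
    )


def is_recruiting_in(trial: TrialRecord, countries: Sequence[str]) -> bool:
    """Recruiting status plus, when requested, a recruiting facility in-country."""
    return is_recruiting_status(trial) and has_recruiting_location_in(trial, countries)


def _matches_user_conditions(
    trial: TrialRecord, user_conditions: Sequence[str]
) -> bool:
    """Containment of any requested cancer type in the trial's condition text."""
    if not user_conditions:
        return True
    haystack = f" {normalize_text(' ; '.join((*trial.conditions, *trial.mesh_terms)))} "
    return any(f" {normalize_text(c)} " in haystack for c in user_conditions if c.strip())


def screen(
    trial: TrialRecord,
    gene: str,
    vocab: NeoplasmVocabulary,
    countries: Sequence[str] = (),
    user_conditions: Sequence[str] = (),
) -> ScreenDecision:
    """Apply all four predicates (no short-circuit) and record every failure.

    When *user_conditions* is non-empty the trial must additionally name
    one of the requested cancer types among its conditions or MeSH
    terms; failure is reported as NOT_CANCER since the restriction
    narrows the cancer type.
    """
    reasons: list[str] = []
    if not mentions_gene(trial, gene):
        reasons.append("NO_GENE_MENTION")
    if not (
        is_cancer_trial(trial, vocab) and _matches_user_conditions(trial, user_conditions)
    ):
        reasons.append("NOT_CANCER")
    if not has_drug_intervention(trial):
        reasons.append("NO_DRUG")
    if not is_recruiting_status(trial):
        reasons.append("NOT_RECRUITING")
    if not has_recruiting_location_in(trial, countries):
        reasons.append("NO_LOCATION_IN_COUNTRY")
    return ScreenDecision(
        trial_id=trial.trial_id, accepted=not reasons, reasons=tuple(reasons)
    )
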