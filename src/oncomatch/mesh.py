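"""Neoplasm vocabulary derived from MeSH tree numbers.

The Medical Subject Headings (MeSH) thesaurus arranges headings in a
hierarchy encoded by dot-separated *tree numbers*.  The subtree rooted at
``C04`` holds every neoplasm heading: ``C04`` itself is "Neoplasms",
``C04.182`` is "Cysts", ``C04.182.044`` is "Bone Cysts", and so on.  A
heading may carry several tree numbers (one per position in the
hierarchy), so a heading is cancer-related as soon as *any* of its tree
numbers starts with ``C04``.

This module parses a simple two-column tree file, extracts the neoplasm
subset, and matches vocabulary headings against free text.  The matcher
is deliberately conservative: case-insensitive, punctuation-normalised,
whole-phrase containment, with extra variants for inverted headings such
as "Carcinoma, Non-Small-Cell Lung" (see :func:`heading_variants`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

__all__ = [
    "MeshEntry",
    "NeoplasmVocabulary",
    "NEOPLASM_PREFIX",
    "normalize_text",
    "heading_variants",
    "parse_mesh_tree",
    "neoplasm_subset",
    "match_neoplasm_terms",
]

#: Root tree number of the neoplasm subtree.
NEOPLASM_PREFIX = "C04"

#: Headings shorter than this after normalisation are never matched as
#: phrases (guards against degenerate vocabulary entries).
MIN_HEADING_CHARS = 4

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalize_text(text: str) -> str:
    """Lower-case *text* and collapse every punctuation run to one space.

    Commas, semicolons and hyphens (and any other non-alphanumeric
    character) become word separators, so "Non-Small-Cell" and
    "non small cell" normalise identically.
    """
    return _NON_ALNUM.sub(" ", text.lower()).strip()


@dataclass(frozen=True)
class MeshEntry:
    """One (heading, tree number) pair from a MeSH tree file."""

    heading: str
    tree_number: str

    def __post_init__(self) -> None:
        if not self.heading.strip():
            raise ValueError("MeSH heading must be non-empty")
        if not self.tree_number or not all(self.tree_number.split(".")):
            raise ValueError(f"malformed tree number: {self.tree_number!r}")

    @property
    def is_neoplasm(self) -> bool:
        """Whether the tree number lies in the ``C04`` subtree."""
        return self.tree_number == NEOPLASM_PREFIX or self.tree_number.startswith(
            NEOPLASM_PREFIX + "."
        )


def heading_variants(heading: str) -> frozenset[str]:
    """Normalised phrase variants under which *heading* may occur in text.

    MeSH headings are frequently *inverted* — "Carcinoma, Non-Small-Cell
    Lung" reads naturally as "non-small-cell lung carcinoma".  Besides the
    heading itself, two families of variants are generated from the
    comma-separated segments:

    * every cyclic rotation of the segment list (covers the common
      two-segment inversion), and
    * every reversed prefix of the segment list, i.e. progressive
      un-inversion: "Leukemia, Lymphocytic, Chronic, B-Cell" yields
      "lymphocytic leukemia", "chronic lymphocytic leukemia" and
      "b cell chronic lymphocytic leukemia".

    Variants shorter than ``MIN_HEADING_CHARS`` are dropped.
    """
    segments = [s.strip() for s in heading.split(",") if s.strip()]
    variants = {normalize_text(heading)}
    if len(segments) >= 2:
        for k in range(1, len(segments)):
            variants.add(normalize_text(" ".join(segments[k:] + segments[:k])))
        for k in range(2, len(segments) + 1):
            variants.add(normalize_text(" ".join(reversed(segments[:k]))))
    return frozenset(v for v in variants if len(v) >= MIN_HEADING_CHARS)


@dataclass(frozen=True)
class NeoplasmVocabulary:
    """Deduplicated set of MeSH headings from the neoplasm subtree.

    Lookup is case-insensitive.  Iteration and matching are in sorted
    heading order for reproducibility.
    """

    headings: frozenset[str]
    _variants: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )
    _casefolded: frozenset[str] = field(
        default_factory=frozenset, repr=False, compare=False
    )

    @classmethod
    def from_headings(cls, headings: Iterable[str]) -> "NeoplasmVocabulary":
        unique = frozenset(h.strip() for h in headings if h.strip())
        variants = {h: heading_variants(h) for h in unique}
        return cls(
            headings=unique,
            _variants=variants,
            _casefolded=frozenset(h.casefold() for h in unique),
        )

    @property
    def size(self) -> int:
        return len(self.headings)

    def __len__(self) -> int:
        return len(self.headings)

    def __iter__(self):
        return iter(sorted(self.headings))

    def __contains__(self, heading: object) -> bool:
        return isinstance(heading, str) and heading.strip().casefold() in self._casefolded

    def variants_of(self, heading: str) -> frozenset[str]:
        return self._variants[heading]

    def dump(self, file: str | Path) -> Path:
        """Write the vocabulary, one heading per line, for auditing."""
        path = Path(file)
        path.write_text("".join(f"{h}\n" for h in sorted(self.headings)), encoding="utf-8")
        return path


def parse_mesh_tree(file: str | Path) -> list[MeshEntry]:
    """Parse a two-column, semicolon-delimited MeSH tree file.

    Each data line carries ``heading;tree_number``; ``#`` lines are
    comments.  Malformed lines are skipped with a logged warning.

    Raises
    ------
    FileNotFoundError
        If *file* does not exist.
    ValueError
        If the file contains zero parseable lines.
    """
    path = Path(file)
    if not path.is_file():
        raise FileNotFoundError(f"MeSH tree file not found: {path}")
    entries: list[MeshEntry] = []
    skipped = 0
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        head, sep, tree = line.partition(";")
        if not sep or not head.strip() or not tree.strip() or ";" in tree:
            skipped += 1
            logger.warning("%s:%d: skipping malformed MeSH line: %r", path, lineno, raw)
            continue
        entries.append(MeshEntry(heading=head.strip(), tree_number=tree.strip()))
    if not entries:
        raise ValueError(f"no parseable MeSH entries in {path}")
    if skipped:
        logger.warning("%s: skipped %d malformed line(s)", path, skipped)
    return entries


def neoplasm_subset(entries: Iterable[MeshEntry]) -> NeoplasmVocabulary:
    """Headings of entries whose tree number lies under ``C04``.

    A heading listed under both a ``C04`` and a non-``C04`` tree number is
    included; duplicates collapse to a single vocabulary member.  An empty
    vocabulary is allowed but logged as a warning.
    """
    vocab = NeoplasmVocabulary.from_headings(
        e.heading for e in entries if e.is_neoplasm
    )
    if not vocab.headings:
        logger.warning("neoplasm vocabulary is empty: no C04 tree numbers found")
    return vocab


def match_neoplasm_terms(text: str, vocab: NeoplasmVocabulary) -> list[str]:
    """Vocabulary headings occurring in *text*, in sorted heading order.

    A heading matches when any of its :func:`heading_variants` is
    contained in the normalised text at word boundaries.  Returns an
    empty list for empty text or an empty vocabulary.
    """
    if not text or not vocab.headings:
        return []
    padded = f" {normalize_text(text)} "
    return [
        heading
        for heading in sorted(vocab.headings)
        if any(f" {v} " in padded for v in vocab.variants_of(heading))
    ]
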