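"""Run configuration: the user-controllable knobs of a pipeline run."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["ConfigError", "RunConfig", "parse_gene_panel", "parse_config", "load_config"]

VALID_UNITS = ("miles", "km")


class ConfigError(ValueError):
    """A fatal configuration problem, named after the offending parameter."""


def parse_gene_panel(text: str) -> tuple[str, ...]:
    """Whitespace-tokenised gene symbols, upper-cased, first-occurrence dedup.

    Symbols may be separated by any whitespace and may span lines.
    """
    seen: list[str] = []
    for token in text.split():
        symbol = token.upper()
        if symbol not in seen:
            seen.append(symbol)
    return tuple(seen)


def _parse_conditions(value: Any) -> tuple[str, ...]:
    if value is None:
        return ()
    if isinstance(value, str):
        return tuple(c.strip() for c in value.split(",") if c.strip())
    return tuple(str(c).strip() for c in value if str(c).strip())


def _parse_countries(value: Any) -> tuple[str, ...]:
    if value is None:
        return ()
    if isinstance(value, str):
        return tuple(c.strip() for c in value.split(",") if c.strip())
    return tuple(str(c).strip() for c in value if str(c).strip())


@dataclass(frozen=True)
class RunConfig:
    """Validated user parameters for one pipeline run.

    ``gene_level`` bounds the upstream network expansion (0 disables it);
    ``max_distance == 0`` disables proximity filtering.  Proximity
    filtering requires a zip code and the United States among the
    requested countries, since only US facilities carry usable zips.
    """

    genes: tuple[str, ...]
    conditions: tuple[str, ...] = ()
    gene_level: int = 1
    zip_code: str = ""
    countries: tuple[str, ...] = ()
    max_distance: float = 0.0
    unit: str = "miles"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ConfigError("genes: at least one gene symbol is required")
        if self.gene_level < 0:
            raise ConfigError("gene_level: must be a non-negative integer")
        if self.max_distance < 0:
            raise ConfigError("max_distance: must be non-negative (0 disables)")
        if self.unit not in VALID_UNITS:
            raise ConfigError(f"unit: must be one of {VALID_UNITS}, got {self.unit!r}")
        if self.max_distance > 0:
            if not self.zip_code.strip():
                raise ConfigError("zip_code: required when max_distance > 0")
            if not any(c.strip().casefold() == "united states" for c in self.countries):
                raise ConfigError(
                    "countries: must include 'United States' when max_distance > 0"
                )


def parse_config(mapping: Mapping[str, Any]) -> RunConfig:
    """Build a :class:`RunConfig` from a raw key-value mapping.

    ``genes`` may be a whitespace-separated string (possibly multi-line)
    or a list; ``conditions`` and ``countries`` may be comma-separated
    strings or lists.
    """
    raw_genes = mapping.get("genes", "")
    if isinstance(raw_genes, str):
        genes = parse_gene_panel(raw_genes)
    else:
        genes = parse_gene_panel(" ".join(str(g) for g in raw_genes))
    try:
        gene_level = int(mapping.get("gene_level", 1))
    except (TypeError, ValueError):
        raise ConfigError("gene_level: must be a non-negative integer") from None
    try:
        max_distance = float(mapping.get("max_distance", 0) or 0)
    except (TypeError, ValueError):
        raise ConfigError("max_distance: must be a number") from None
    return RunConfig(
        genes=genes,
        conditions=_parse_conditions(mapping.get("conditions")),
        gene_level=gene_level,
        zip_code=str(mapping.get("zip_code", "") or "").strip(),
        countries=_parse_countries(mapping.get("countries")),
        max_distance=max_distance,
        unit=str(mapping.get("unit", "miles") or "miles").strip().lower(),
    )


def load_config(file: str | Path) -> RunConfig:
    """Load a YAML (or plain ``key: value``) configuration file."""
    path = Path(file)
    if not path.is_file():
        raise ConfigError(f"configuration file not found: {path}")
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(data, Mapping):
        raise ConfigError(f"configuration file {path} must hold key-value pairs")
    return parse_config(data)
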