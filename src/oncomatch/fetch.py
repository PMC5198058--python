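"""Optional live-registry fetch adapter (network plumbing, not exercised offline).

The offline pipeline consumes a trial corpus file; this adapter can
materialise such a corpus from a live registry query.  The query carries
the standard five parameters: the gene symbol as the search term,
recruiting status, interventional study type, drug intervention, and the
disease condition.  Only the emitted dialect is contract-tested; the
network path is best-effort plumbing.
"""

from __future__ import annotations

import urllib.parse
import urllib.request
from pathlib import Path
from typing import Sequence

from lxml import etree

__all__ = ["build_query_url", "fetch_corpus"]

DEFAULT_ENDPOINT = "https://clinicaltrials.gov/api/query/full_studies"


def build_query_url(
    gene: str, condition: str = "neoplasms", endpoint: str = DEFAULT_ENDPOINT
) -> str:
    """Registry query URL for one gene symbol."""
    params = {
        "expr": (
            f"{gene} AND AREA[OverallStatus]Recruiting "
            f"AND AREA[StudyType]Interventional "
            f"AND AREA[InterventionType]Drug "
            f"AND AREA[Condition]{condition}"
        ),
        "fmt": "xml",
    }
    return f"{endpoint}?{urllib.parse.urlencode(params)}"


def fetch_corpus(
    genes: Sequence[str],
    condition: str,
    out_file: str | Path,
    endpoint: str = DEFAULT_ENDPOINT,
    timeout: float = 30.0,
) -> Path:
    """Query the registry per gene and write a corpus in the trial dialect.

    Mapping a live registry payload onto the offline dialect is
    registry-specific; this adapter emits a ``<trials>`` root and leaves
    per-record transformation to the payload structure at hand, raising
    if the response cannot be interpreted.
    """
    root = etree.Element("trials")
    for gene in genes:
        url = build_query_url(gene, condition, endpoint)
        with urllib.request.urlopen(url, timeout=timeout) as response:  # noqa: S310
            payload = response.read()
        try:
            remote = etree.fromstring(payload)
        except etree.XMLSyntaxError as exc:
            raise OSError(f"unparseable registry response for {gene}: {exc}") from exc
        for trial in remote.iter("trial"):
            root.append(trial)
    out = Path(out_file)
    out.write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    )
    return out
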