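"""Match panel genes to eligible cancer drugs in the catalog.

A drug is matched when the queried symbol appears in its target-gene
field, its indication carries a neoplasm MeSH heading, and it is not a
nutraceutical / over-the-counter / withdrawn / illicit product.
"""

import tempfile
from pathlib import Path

from oncomatch import (
    build_indexes,
    drugs_targeting,
    neoplasm_subset,
    parse_drug_catalog,
    parse_mesh_tree,
)
from oncomatch.fixtures import make_catalog, make_mesh_file

with tempfile.TemporaryDirectory() as tmp:
    work = Path(tmp)
    vocab = neoplasm_subset(parse_mesh_tree(make_mesh_file(work / "mesh.txt")))
    catalog = build_indexes(parse_drug_catalog(make_catalog(work / "drugs.tsv")), vocab)

    for gene in ("EPCAM", "CHEK2", "ABL1", "ATM"):
        hits = drugs_targeting(gene, catalog)
        names = ", ".join(f"{r.name} ({r.drug_id})" for r in hits) or "none"
        print(f"{gene:6s} -> {names}")

    gefitinib = catalog.by_id["DB00317"]
    print("\nGefitinib reference prices:")
    for price in gefitinib.prices:
        print(f"  {price.label}: USD {price.amount:.2f}")

# EPCAM matches its two antibody drugs and CHEK2 its checkpoint-kinase
# inhibitor; ABL1 matches the approved BCR-ABL inhibitors plus the
# experimental XL228, while the nutraceutical ATP is excluded.  ATM has
# no direct cancer drug (caffeine targets it but is not a cancer drug) —
# see the network-expansion example.  Prices aggregate per-brand dosages.
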