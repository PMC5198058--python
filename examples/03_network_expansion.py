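"""Repurpose drugs through upstream interaction-network expansion.

When no drug directly targets a queried gene, the search regresses one
gene level up the protein-protein-interaction network: drugs hitting the
gene's regulators or complex partners are candidate antagonists of the
same pathway.
"""

import tempfile
from pathlib import Path

from oncomatch import (
    build_indexes,
    expand_search,
    neoplasm_subset,
    parse_drug_catalog,
    parse_mesh_tree,
    parse_sif,
    upstream_interactors,
)
from oncomatch.fixtures import make_catalog, make_mesh_file, make_sif_file

with tempfile.TemporaryDirectory() as tmp:
    work = Path(tmp)
    vocab = neoplasm_subset(parse_mesh_tree(make_mesh_file(work / "mesh.txt")))
    catalog = build_indexes(parse_drug_catalog(make_catalog(work / "drugs.tsv")), vocab)
    graph = parse_sif(make_sif_file(work / "ppi.sif"))

    for gene in ("BRCA1", "ATM"):
        print(f"{gene}: upstream = {sorted(upstream_interactors(gene, graph))}")
        result = expand_search(gene, max_level=1, graph=graph, catalog=catalog)
        for drug in result.all_drugs():
            via = ", ".join(result.interactors_of(drug.drug_id))
            print(f"  {drug.name} ({drug.drug_id}) via {via}")
        print()

# BRCA1 has no direct cancer drug, but one level of expansion reaches
# eight unique drugs through its regulators (e.g. flavopiridol via CDK7
# and CDK9).  ATM reaches three drugs through six interacting genes.
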