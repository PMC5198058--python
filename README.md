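# oncomatch

Match a cancer gene panel against clinical trials and targeted cancer
drugs, offline.

Targeted cancer therapy starts from a panel of genes whose mutations
drive a patient's tumor (e.g. the breast/ovarian panel *ATM*, *BRCA1*,
*BRCA2*, *CHEK2*, *EPCAM*, *PTEN*, ...). Finding treatment options for
such a panel means combing two noisy sources: registry keyword search
over clinical-trial records, which returns surgery, supplement and
device trials alongside the relevant ones, and a drug catalog in which
most entries are not cancer drugs. `oncomatch` is a library (plus a thin
CLI) for clinicians-facing tooling and for reproducible analysis of this
matching problem. It:

- **screens trial records** with four precision predicates — a trial must
  (1) mention the queried gene symbol as a whole token in any textual
  field, (2) carry at least one neoplasm MeSH heading among its disease
  conditions, (3) have a named drug intervention, and (4) be actively
  recruiting in a requested country. Every rejection carries machine-
  readable reason codes;
- **matches genes to drugs** in a DrugBank-style catalog: a drug
  qualifies when the gene is in its target list, its pharmacology
  indication contains a neoplasm MeSH heading, and it is not a
  nutraceutical, over-the-counter, withdrawn or illicit product;
- **expands the search upstream** when no drug targets the gene
  directly: bounded breadth-first regression over a protein–protein
  interaction network (SIF files) finds drugs hitting the gene's
  regulators or complex partners — the drug-repurposing step;
- **filters trial facilities by proximity** to a US zip code using the
  haversine great-circle distance
  `d = 2r·asin(√(sin²(Δθ/2) + cosθ₁·cosθ₂·sin²(Δλ/2)))` with
  r = 3959 miles or 6371 km;
- **writes two tab-delimited reports**: a 7-column summary (one row per
  accepted gene–trial pair) and a 13-column detailed report in which
  catalog columns repeat per trial so each row is self-contained.

The neoplasm vocabulary is derived from a MeSH tree file: every heading
whose tree number starts with `C04` (the neoplasms subtree) is a cancer
term. Free-text matching is case-insensitive whole-phrase containment
with segment reordering for inverted headings ("Carcinoma, Non-Small-Cell
Lung" matches "non-small cell lung carcinoma").

## Worked example

Every input format has a deterministic synthetic generator in
`oncomatch.fixtures`, so the whole pipeline runs without any external
data. `python examples/03_network_expansion.py` prints:

```
BRCA1: upstream = ['AURKA', 'CDK2', 'CDK7', 'CDK9', 'CHEK1', 'CHEK2', 'POLE', 'POLE2', 'SRC']
  Cladribine (DB00242) via POLE, POLE2
  Flavopiridol (DB03496) via CDK7, CDK9
  XL844 (DB05149) via CHEK1, CHEK2
  Bosutinib (DB06616) via SRC
  AT7519 (DB90002) via CDK2
  AT9283 (DB90003) via AURKA
  CYC116 (DB90004) via AURKA
  MLN8237 (DB90005) via AURKA
```

No cancer drug targets *BRCA1* directly, but one level of network
regression reaches eight unique cancer drugs through nine upstream
genes — e.g. the pan-CDK inhibitor flavopiridol is suggested because it
inhibits CDK7 and CDK9, which control *BRCA1* expression. Screening a
19-record breast-cancer corpus containing one non-recruiting, one
non-cancer and one non-drug trial (`examples/01_screen_trials.py`)
accepts 16 and names each rejection's failing predicate. The other
examples demonstrate drug matching with prices
(`02_match_drugs.py`), proximity filtering — the Easton→Philadelphia
centroid pair prints 50.5 miles = 81.3 km, and a trial spread over five
states keeps only its New York and Pennsylvania facilities within 50
miles of zip 18042 (`04_proximity_filter.py`) — and the full pipeline
with its run log (`05_full_pipeline.py`).

The same pipeline is available from a shell:

```sh
oncomatch make-fixtures --out-dir demo --seed 1
oncomatch run --genes "BRCA1 EPCAM" --mesh demo/mesh_tree.txt \
  --catalog demo/drug_catalog.tsv --sif demo/reactome.sif --sif demo/pid.sif \
  --trials demo/trials.xml --zips demo/zipcodes.csv \
  --countries "United States" --zip-code 18042 --max-distance 50 --out-dir out
```

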