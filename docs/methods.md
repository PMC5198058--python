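# Methods

## Problem and pipeline

`oncomatch` integrates three offline sources around a panel of cancer
genes: a corpus of clinical-trial records, a DrugBank-style drug
catalog, and a protein–protein-interaction (PPI) network, with a MeSH
neoplasm vocabulary acting as the cancer classifier for both trials and
drugs, and a zip-code gazetteer supporting facility proximity
filtering. For each panel gene the pipeline (i) screens every trial
record, (ii) searches the catalog for drugs targeting the gene,
(iii) regresses up the PPI network when the direct search is empty, and
(iv) joins accepted trials with matched drugs into a summary and a
detailed tab-delimited report.

## Neoplasm vocabulary

MeSH tree numbers encode hierarchy by dotted prefixes; the subtree
rooted at `C04` holds the neoplasm headings. A heading belongs to the
vocabulary when any of its tree numbers is `C04` or starts with `C04.`
(plain string-prefix tests on whole segments, so `C044.1` does not
qualify). Headings are deduplicated; lookup is case-insensitive.

**Text matching.** Registry and catalog text is free text, not
canonical headings, so matching is deliberately simple and auditable:
both sides are lower-cased, every punctuation run becomes a single
space, and a heading matches when one of its phrase variants occurs in
the text between word boundaries. Variants handle MeSH inversion
("Carcinoma, Non-Small-Cell Lung" ≈ "non-small-cell lung carcinoma"):
for a heading with comma segments `s1, …, sn` we generate every cyclic
rotation of the segment list and every reversed prefix
(`sk sk-1 … s1` for k = 2…n). The reversed prefixes progressively
un-invert the heading, so "Leukemia, Lymphocytic, Chronic, B-Cell"
also matches the common clinical phrase "chronic lymphocytic
leukemia". Variants shorter than 4 characters are discarded to guard
against degenerate entries. This containment scheme cannot bridge
genuine synonymy (e.g. free text using "cancer" where the heading says
"carcinoma", or phrases that drop a modifier entirely); such cases
require a thesaurus lookup and are out of scope.

## Drug catalog

The catalog dialect is a headered TSV mirroring the classic DrugBank
fields (accession, molecule type, name, brands, synonyms, prices,
pharmacology indication, target genes, SNP effect/adverse notes, group
labels, description) with `;`-joined multi-valued cells. Two
classifiers gate gene-keyed search:

- *cancer drug*: the indication contains ≥ 1 neoplasm heading under the
  matcher above;
- *eligible*: the group labels do not include nutraceutical,
  over-the-counter, withdrawn or illicit (case-insensitive).

`drugs_targeting(gene)` returns exactly the eligible cancer drugs whose
(upper-cased, deduplicated) target list contains the symbol, sorted by
accession. Gene symbols are compared verbatim after upper-casing; alias
or HGNC-history resolution is out of scope. Price cells must end in
`USD <amount>`; entries that do not parse are dropped with a warning
rather than aborting, since a malformed price should not hide a drug.

## Interaction network and gene-level regression

SIF rows are typed directed edges drawn from the closed twelve-label
Pathway-Commons vocabulary; unknown labels are skipped with a warning,
and triples are deduplicated across files. The "upstream or complex
partner" policy is centralised in one table:

- qualifying into-the-gene labels: controls-expression-of,
  controls-state-change-of, controls-phosphorylation-of,
  controls-transport-of, controls-production-of, chemical-affects,
  catalysis-precedes;
- `consumption-controlled-by` qualifies with reversed orientation;
- `in-complex-with` is undirected;
- reacts-with, used-to-produce and controls-transport-of-chemical never
  qualify (they describe chemistry, not regulation).

Expansion triggers only when the direct search is empty. It is a
breadth-first traversal over the upstream relation: level k holds the
genes first reached at distance k, each annotated with its own direct
drug hits; visited genes are never re-expanded and hits accumulate at
every level up to the bound (accumulation is deterministic and strictly
more informative than stopping at the first productive level). Frontier
and output ordering is lexicographic. With the visited-set guard each
edge is examined at most once per level, so work is bounded by
`|edges| × max_level` even though the number of *reachable* paths grows
much faster with depth — deep regression remains scientifically
questionable (each level dilutes the mechanistic rationale) and the
default bound is 1.

## Trial screening

The four predicates are evaluated independently (no short-circuit) so a
decision lists every failing predicate:

| code | predicate |
| --- | --- |
| NO_GENE_MENTION | whole-token, case-insensitive symbol occurrence in the concatenated textual fields (title, conditions, interventions, MeSH terms, summary) |
| NOT_CANCER | no neoplasm heading among tagged MeSH terms *or* condition strings (both are checked because records vary in which they populate) |
| NO_DRUG | no intervention of type "drug" with a non-empty name |
| NOT_RECRUITING | status ≠ "Recruiting" after trimming/case-folding ("Not yet recruiting", "Enrolling by invitation", "Active, not recruiting" all fail) |
| NO_LOCATION_IN_COUNTRY | a country filter was given and no actively recruiting facility lies in one of the countries |

A per-location recruiting flag omitted in the record inherits the
trial-level status. An optional user condition list (a cancer-type
restriction such as "Ovarian Neoplasms") must consist of vocabulary
headings — anything else is a fatal configuration error — and is applied
as phrase containment against conditions + MeSH terms; its failure is
reported as NOT_CANCER because it narrows the same axis.

## Proximity filtering

Distances use the haversine formula on a spherical Earth with the
conventional radii 3959 miles / 6371 km; coordinates are stored in
degrees and converted at computation time. `max_distance = 0` is the
documented "filtering off" sentinel. Filtering applies to facilities in
the United States only; non-US facilities pass through, as do US
facilities whose zip is empty or not in the gazetteer (an unknown
location should be surfaced, not silently discarded). Zips are
normalised by keeping digits, truncating ZIP+4 to five, and
zero-padding. When no facility of an accepted trial survives, the trial
is kept with zero listed facilities and a warning — proximity reduces
facility lists, it does not re-reject trials.

## Reports

The summary report has one row per accepted (gene, trial) pair plus one
drug-only row per gene that matched drugs but no trial; its drug count
is the number of distinct accessions in the gene's detail rows. The
detailed report crosses accepted trials with drug entries; a drug
reached through several interactors carries them all in the
targeted-genes column ("CDK7; CDK9"), the drug-accession and drug-name
columns are separate, empty cells render as `-`, multi-valued cells join
with `"; "`, and embedded tabs/newlines are collapsed to spaces so the
files re-parse cleanly with tab as the only delimiter. Row order is
panel order, then trial accession, then drug accession, making reruns
byte-identical.

## Synthetic data

`oncomatch.fixtures` generates all six inputs deterministically (same
seed → byte-identical files). The defaults are not arbitrary: they
reconstruct the worked examples the package is validated against — the
gefitinib four-price list, the two EPCAM antibodies, XL844 for
CHEK1/CHEK2, the six approved BCR-ABL inhibitors plus experimental
XL228 for ABL1 (with the nutraceutical ATP and unannotated early-stage
chemicals as exclusion distractors), a PPI file whose BRCA1 in-edges
yield exactly eight repurposing drugs at level 1 and whose ATM in-edges
yield cladribine/flavopiridol/XL844 through six interactors, and a zip
table in which the Easton/Philadelphia pair carries the published
Census centroids (all other coordinates are synthetic, placed so the
five-state facility example reduces to NY + PA within 50 miles).
Accessions not fixed by the worked examples use a synthetic `DB9xxxx`
range.

Trial corpora are built from a `ScenarioSpec`: n records, all
mentioning the scenario gene (mentions are confined to the templated
summary field so no accidental token matches occur), with a defect plan
assigning each flagged record exactly one predicate violation
(NOT_RECRUITING, NOT_CANCER, NO_DRUG, DEVICE_ONLY, NO_US_LOCATION).
Screening therefore accepts exactly `n − Σ defects` — the invariant the
count-reconstruction scenarios rely on. The NO_US_LOCATION defect is a
defect only under a United-States country filter.

What the synthetic data does **not** emulate: realistic trial prose,
registry query-engine behaviour, real DrugBank/MeSH/Pathway-Commons
release contents, or their version-dependent totals (live counts such
as a specific number of cancer drugs or of BRCA1 interactors vary by
release and are deliberately not reproduced — the test suite covers the
governing invariants instead: screening monotonicity and reason-code
completeness, expansion monotonicity in the level bound and level-0
equivalence with direct search against a brute-force oracle, haversine
symmetry/identity/unit-ratio, report conservation laws, and
byte-identical reruns). Passing tests demonstrate the mechanics and
the published worked examples, not retrieval quality on live data.

## Numerical and degenerate-input choices

- Haversine clamps the intermediate at 1.0 before `asin` to absorb
  floating-point overshoot on near-antipodal points.
- Ties and orderings are everywhere lexicographic (vocabulary-sorted
  match lists, accession-sorted drug lists, BFS frontiers) for
  reproducibility.
- Fatal-vs-warning policy: structurally broken inputs (missing file,
  empty corpus/catalog/vocabulary-file, duplicate accessions, malformed
  XML, unknown origin zip, invalid configuration) abort before any
  report is written; locally malformed content (a bad MeSH line, an
  unknown SIF label, an unparseable price) is skipped with a logged
  warning.
- The live-registry fetch adapter is plumbing for convenience only; it
  needs network access and is excluded from the validated surface.

## Acceptance script

`scripts/acceptance.py --seed N --out results/acceptance.json`
regenerates the fixture inputs and recomputes: the Easton→Philadelphia
haversine distance in miles and km (each rounded to the nearest ten, the
precision at which such distances are conventionally quoted), and the
accepted-trial counts of the 19/9/6-record screening scenarios with
their fixed defect plans. The seed feeds the corpus generators; the
resulting counts are structural (defect arithmetic), so they are stable
across seeds by design.
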