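"""Deterministic synthetic inputs for every file format the pipeline reads.

Everything here is synthetic test/demo data.  The default data sets
reconstruct the published worked examples this package is exercised
against: the gefitinib price list, the EPCAM/CHEK2/ABL1 drug matches,
the BRCA1 and ATM upstream-expansion stories, the five-state facility
spread, and trial corpora whose screening outcome is fixed by an
explicit defect plan.  DrugBank accessions are real where the worked
examples print them and synthetic (DB9xxxx) otherwise; zip-code
centroids are synthetic except the Easton/Philadelphia pair.

All generators are pure functions of their arguments: the same seed
yields byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

from .catalog import CATALOG_COLUMNS

__all__ = [
    "DEFECT_CODES",
    "ScenarioSpec",
    "make_trial_corpus",
    "make_catalog",
    "make_mesh_file",
    "make_sif_file",
    "make_zip_table",
    "make_all",
    "DEFAULT_CATALOG_ENTRIES",
    "DEFAULT_MESH_ENTRIES",
    "DEFAULT_SIF_EDGES",
    "DEFAULT_ZIP_TABLE",
]

#: Injectable defect codes; each breaks exactly one screening predicate
#: (NO_US_LOCATION assumes the screen runs with countries=["United States"]).
DEFECT_CODES = (
    "NOT_RECRUITING",
    "NOT_CANCER",
    "NO_DRUG",
    "NO_US_LOCATION",
    "DEVICE_ONLY",
)

# Facility roster.  Zips refer to DEFAULT_ZIP_TABLE; the first five mirror
# the five-state spread (CA, MA, NY, PA, TX) of the proximity worked example.
US_SITES = (
    ("Stanford University Medical Center", "Stanford", "California", "94305"),
    ("Massachusetts General Hospital", "Boston", "Massachusetts", "02114"),
    ("Hudson Valley Oncology Center", "Newburgh", "New York", "12550"),
    ("Lehigh Valley Cancer Institute", "Bethlehem", "Pennsylvania", "18015"),
    ("MD Anderson Cancer Center", "Houston", "Texas", "77030"),
    ("Memorial Sloan Kettering Cancer Center", "New York", "New York", "10065"),
    ("Community Oncology Clinic", "Easton", "Pennsylvania", ""),
)

NON_US_SITES = (
    ("Princess Margaret Cancer Centre", "Toronto", "Ontario", "", "Canada"),
    ("National Cancer Center Hospital", "Tokyo", "", "", "Japan"),
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Plan for one synthetic trial corpus.

    ``defects`` lists (count, code) pairs; each flagged record violates
    exactly the named predicate and every unflagged record passes all
    four predicates by construction, so screening accepts
    ``n_trials - sum(counts)`` records.
    """

    seed: int
    n_trials: int
    defects: tuple[tuple[int, str], ...] = ()
    gene: str = "BRCA1"
    condition: str = "Breast Neoplasms"

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        for count, code in self.defects:
            if code not in DEFECT_CODES:
                raise ValueError(f"unknown defect code {code!r}")
            if count < 0:
                raise ValueError("defect counts must be non-negative")
        if sum(c for c, _ in self.defects) > self.n_trials:
            raise ValueError("defect plan exceeds the number of trials")

    @property
    def n_clean(self) -> int:
        return self.n_trials - sum(c for c, _ in self.defects)


def _sub(parent: etree._Element, tag: str, text: str = "", **attrib: str) -> etree._Element:
    el = etree.SubElement(parent, tag, **attrib)
    if text:
        el.text = text
    return el


def make_trial_corpus(spec: ScenarioSpec, path: str | Path) -> Path:
    """Write a trial-XML corpus realising *spec*; returns the path.

    Gene mentions are confined to the templated ``<summary>`` element so
    a record mentions exactly the genes it is planned to mention.
    """
    rng = random.Random(spec.seed)
    codes: list[str | None] = []
    for count, code in spec.defects:
        codes.extend([code] * count)
    codes.extend([None] * (spec.n_trials - len(codes)))
    rng.shuffle(codes)

    base_id = rng.randrange(10_000_000, 90_000_000)
    root = etree.Element("trials")
    clean_seen = 0
    for i, code in enumerate(codes):
        trial = etree.SubElement(root, "trial")
        compound = f"ONC-{rng.randrange(100, 1000)}{i:02d}"
        condition = spec.condition
        mesh_terms = [spec.condition]
        status = "Recruiting"
        interventions = [("drug", compound)]
        sites: Sequence[tuple[str, ...]] = ()
        title_topic = spec.condition

        if code == "NOT_RECRUITING":
            status = "Not yet recruiting"
        elif code == "NOT_CANCER":
            condition = "Breast Reconstruction"
            mesh_terms = ["Pain, Postoperative", "Breast Diseases"]
            title_topic = "Breast Reconstruction"
        elif code == "NO_DRUG":
            interventions = [("dietary supplement", "High-fiber dietary regimen")]
        elif code == "DEVICE_ONLY":
            interventions = [("device", "Intraoperative imaging system")]
        elif code == "NO_US_LOCATION":
            sites = NON_US_SITES

        if not sites:
            if code is None and clean_seen == 0:
                us = list(US_SITES[:5])  # the five-state facility spread
            else:
                us = rng.sample(US_SITES[:5], k=rng.randrange(1, 4))
            sites = tuple((*s, "United States") for s in us)
        if code is None:
            clean_seen += 1

        _sub(trial, "id", f"NCT{base_id + i:08d}")
        _sub(trial, "title", f"A Phase 2 Study of {compound} in {title_topic}")
        _sub(trial, "status", status)
        _sub(trial, "phase", "Phase 2")
        _sub(trial, "condition", condition)
        for term in mesh_terms:
            _sub(trial, "mesh_term", term)
        for itype, name in interventions:
            _sub(trial, "intervention", name, type=itype)
        _sub(
            trial,
            "summary",
            f"Open-label study enrolling patients whose tumors carry germline "
            f"or somatic {spec.gene} mutations.",
        )
        for facility, city, state, zip_code, country in sites:
            loc = _sub(trial, "location", recruiting="true")
            _sub(loc, "facility", facility)
            _sub(loc, "city", city)
            _sub(loc, "state", state)
            _sub(loc, "zip", zip_code)
            _sub(loc, "country", country)
            _sub(loc, "contact", f"{facility} Research Office, +1-555-0{i:03d}")

    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    )
    return out


def _price(label: str, amount: float) -> str:
    return f"{label} USD {amount}"


# One dict per drug; keys are the catalog TSV columns.  Multi-valued
# cells are ";"-joined.  Ids printed by the worked examples are real;
# DB9xxxx ids and the distractor drugs are synthetic.
DEFAULT_CATALOG_ENTRIES: tuple[dict[str, str], ...] = (
    dict(
        drug_id="DB00317", molecule_type="small molecule", name="Gefitinib",
        brand_names="Iressa;Tarceva",
        synonyms="Iressa; gefitinib; ZD 1839",
        prices=";".join(
            [
                _price("Tarceva 25 mg tablet", 52.78),
                _price("Iressa 250 mg tablet", 68.08),
                _price("Tarceva 100 mg tablet", 144.98),
                _price("Tarceva 150 mg tablet", 163.98),
            ]
        ),
        indication="Metastatic non-small cell lung carcinoma with activating EGFR mutations",
        target_genes="EGFR",
        snp_effects="G719A/C variation in EGFR associated with increased response",
        snp_adverse="-",
        groups="approved;investigational",
        description="EGFR tyrosine kinase inhibitor.",
    ),
    dict(
        drug_id="DB00242", molecule_type="small molecule", name="Cladribine",
        brand_names="Leustatin", synonyms="2-CdA", prices="",
        indication="Hairy cell leukemia and B-cell chronic lymphocytic leukemia",
        target_genes="POLE;POLE2", snp_effects="-", snp_adverse="-",
        groups="approved;investigational",
        description="Purine analog incorporated by DNA polymerases.",
    ),
    dict(
        drug_id="DB03496", molecule_type="small molecule", name="Flavopiridol",
        brand_names="", synonyms="Alvocidib", prices="",
        indication="Investigated for esophageal neoplasms, lung neoplasms and lymphoid leukemia",
        target_genes="CDK7;CDK9", snp_effects="-", snp_adverse="-",
        groups="experimental;investigational",
        description="Pan-CDK inhibitor.",
    ),
    dict(
        drug_id="DB05149", molecule_type="small molecule", name="XL844",
        brand_names="", synonyms="", prices="",
        indication="Chronic lymphocytic leukemia and advanced solid neoplasms",
        target_genes="CHEK1;CHEK2", snp_effects="-", snp_adverse="-",
        groups="experimental",
        description="Checkpoint kinase inhibitor.",
    ),
    dict(
        drug_id="DB05319", molecule_type="biotech", name="Oportuzumab monatox",
        brand_names="", synonyms="VB4-845", prices="",
        indication="Urinary bladder neoplasms",
        target_genes="EPCAM", snp_effects="-", snp_adverse="-",
        groups="investigational",
        description="Anti-EpCAM immunotoxin.",
    ),
    dict(
        drug_id="DB05831", molecule_type="biotech", name="ING-1",
        brand_names="", synonyms="", prices="",
        indication="Adenocarcinoma expressing epithelial cell adhesion molecule",
        target_genes="EPCAM", snp_effects="-", snp_adverse="-",
        groups="investigational",
        description="High-affinity anti-EpCAM antibody.",
    ),
    dict(
        drug_id="DB06616", molecule_type="small molecule", name="Bosutinib",
        brand_names="Bosulif", synonyms="SKI-606", prices="",
        indication="Chronic myelogenous leukemia",
        target_genes="ABL1;SRC", snp_effects="-", snp_adverse="-",
        groups="approved",
        description="Dual SRC/ABL kinase inhibitor.",
    ),
    dict(
        drug_id="DB01254", molecule_type="small molecule", name="Dasatinib",
        brand_names="Sprycel", synonyms="BMS-354825", prices="",
        indication="Chronic myelogenous leukemia with resistance to prior therapy",
        target_genes="ABL1", snp_effects="-", snp_adverse="-",
        groups="approved;investigational",
        description="Second-generation BCR-ABL inhibitor.",
    ),
    dict(
        drug_id="DB00619", molecule_type="small molecule", name="Imatinib",
        brand_names="Gleevec", synonyms="STI-571", prices="",
        indication="Chronic myelogenous leukemia and gastrointestinal stromal tumors",
        target_genes="ABL1;KIT", snp_effects="-", snp_adverse="-",
        groups="approved",
        description="Prototype BCR-ABL inhibitor.",
    ),
    dict(
        drug_id="DB04868", molecule_type="small molecule", name="Nilotinib",
        brand_names="Tasigna", synonyms="AMN107", prices="",
        indication="Chronic myelogenous leukemia",
        target_genes="ABL1", snp_effects="-",
        snp_adverse="UGT1A1*28 allele associated with hyperbilirubinemia",
        groups="approved",
        description="Second-generation BCR-ABL inhibitor.",
    ),
    dict(
        drug_id="DB08901", molecule_type="small molecule", name="Ponatinib",
        brand_names="Iclusig", synonyms="AP24534", prices="",
        indication="Chronic myelogenous leukemia and Philadelphia chromosome positive acute lymphoblastic leukemia",
        target_genes="ABL1", snp_effects="-", snp_adverse="-",
        groups="approved",
        description="Pan-BCR-ABL inhibitor active against T315I.",
    ),
    dict(
        drug_id="DB08896", molecule_type="small molecule", name="Regorafenib",
        brand_names="Stivarga", synonyms="BAY 73-4506", prices="",
        indication="Metastatic colorectal neoplasms and gastrointestinal stromal tumors",
        target_genes="ABL1;KDR", snp_effects="-", snp_adverse="-",
        groups="approved",
        description="Multi-kinase inhibitor.",
    ),
    dict(
        drug_id="DB90001", molecule_type="small molecule", name="XL228",
        brand_names="", synonyms="", prices="",
        indication="Acute lymphocytic leukemia",
        target_genes="ABL1;IGF1R", snp_effects="-", snp_adverse="-",
        groups="experimental",
        description="Multi-target kinase inhibitor (synthetic accession).",
    ),
    dict(
        drug_id="DB90002", molecule_type="small molecule", name="AT7519",
        brand_names="", synonyms="", prices="",
        indication="Refractory solid neoplasms and multiple myeloma",
        target_genes="CDK2", snp_effects="-", snp_adverse="-",
        groups="experimental",
        description="CDK inhibitor (synthetic accession).",
    ),
    dict(
        drug_id="DB90003", molecule_type="small molecule", name="AT9283",
        brand_names="", synonyms="", prices="",
        indication="Advanced solid neoplasms and leukemia",
        target_genes="AURKA;AURKB", snp_effects="-", snp_adverse="-",
        groups="experimental",
        description="Aurora kinase inhibitor (synthetic accession).",
    ),
    dict(
        drug_id="DB90004", molecule_type="small molecule", name="CYC116",
        brand_names="", synonyms="", prices="",
        indication="Advanced solid neoplasms",
        target_genes="AURKA", snp_effects="-", snp_adverse="-",
        groups="experimental",
        description="Aurora kinase inhibitor (synthetic accession).",
    ),
    dict(
        drug_id="DB90005", molecule_type="small molecule", name="MLN8237",
        brand_names="", synonyms="Alisertib", prices="",
        indication="Neoplasms including lymphoma and neuroblastoma",
        target_genes="AURKA", snp_effects="-", snp_adverse="-",
        groups="investigational",
        description="Selective aurora A inhibitor (synthetic accession).",
    ),
    dict(
        drug_id="DB01268", molecule_type="small molecule", name="Sunitinib",
        brand_names="Sutent", synonyms="SU11248", prices="",
        indication="Renal cell carcinoma and imatinib-resistant gastrointestinal stromal tumors",
        target_genes="FLT3;KIT;PDGFRA", snp_effects="-", snp_adverse="-",
        groups="approved;investigational",
        description="Multi-target receptor tyrosine kinase inhibitor.",
    ),
    # Distractors: not cancer drugs, or ineligible groups.
    dict(
        drug_id="DB00201", molecule_type="small molecule", name="Caffeine",
        brand_names="", synonyms="1,3,7-trimethylxanthine", prices="",
        indication="Central nervous system stimulation for fatigue and drowsiness",
        target_genes="ATM;ADORA2A", snp_effects="-", snp_adverse="-",
        groups="approved",
        description="Methylxanthine stimulant; not a cancer drug.",
    ),
    dict(
        drug_id="DB00171", molecule_type="small molecule", name="Adenosine triphosphate",
        brand_names="", synonyms="ATP", prices="",
        indication="Nutritional supplementation in metabolic disorders",
        target_genes=";".join(["ABL1"] + [f"PKX{j}" for j in range(1, 33)]),
        snp_effects="-", snp_adverse="-",
        groups="nutraceutical",
        description="Ubiquitous cofactor; 33 annotated targets.",
    ),
    dict(
        drug_id="DB08043", molecule_type="small molecule",
        name="1-[4-(PYRIDIN-4-YLOXY)PHENYL]-3-[3-(TRIFLUOROMETHYL)PHENYL]UREA",
        brand_names="", synonyms="", prices="",
        indication="",
        target_genes="ABL1", snp_effects="-", snp_adverse="-",
        groups="experimental",
        description="Early-stage chemical; no annotated indication.",
    ),
    dict(
        drug_id="DB07831", molecule_type="small molecule",
        name="2-{[(6-OXO-1,6-DIHYDROPYRIDIN-3-YL)METHYL]AMINO}-N-[4-PROPYL-3-(TRIFLUOROMETHYL)PHENYL]BENZAMIDE",
        brand_names="", synonyms="", prices="",
        indication="",
        target_genes="ABL1", snp_effects="-", snp_adverse="-",
        groups="experimental",
        description="Early-stage chemical; no annotated indication.",
    ),
    dict(
        drug_id="DB90006", molecule_type="small molecule", name="Oncoban",
        brand_names="", synonyms="", prices="",
        indication="Breast neoplasms",
        target_genes="EGFR", snp_effects="-", snp_adverse="-",
        groups="approved;withdrawn",
        description="Synthetic distractor: cancer-indicated but withdrawn.",
    ),
    dict(
        drug_id="DB90007", molecule_type="small molecule", name="Paintrex",
        brand_names="", synonyms="", prices="",
        indication="Relief of minor aches and pain",
        target_genes="PTGS2", snp_effects="-", snp_adverse="-",
        groups="approved;over-the-counter",
        description="Synthetic distractor: over-the-counter analgesic.",
    ),
)


def make_catalog(
    path: str | Path,
    entries: Iterable[Mapping[str, str]] = DEFAULT_CATALOG_ENTRIES,
) -> Path:
    """Write a drug-catalog TSV; defaults to the worked-example entry set."""
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    lines = ["\t".join(CATALOG_COLUMNS)]
    for entry in entries:
        lines.append("\t".join(str(entry.get(col, "")) for col in CATALOG_COLUMNS))
    out.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out


# (heading, tree_number) pairs; C04 rows form the neoplasm vocabulary,
# the rest are non-cancer distractors.  Tree numbers are illustrative.
DEFAULT_MESH_ENTRIES: tuple[tuple[str, str], ...] = (
    ("Neoplasms", "C04"),
    ("Cysts", "C04.182"),
    ("Cysts", "C23.300.306"),
    ("Bone Cysts", "C04.182.044"),
    ("Breast Neoplasms", "C04.588.180"),
    ("Triple Negative Breast Neoplasms", "C04.588.180.438"),
    ("Ovarian Neoplasms", "C04.588.322.455"),
    ("Carcinoma", "C04.557.470"),
    ("Adenocarcinoma", "C04.557.470.035"),
    ("Carcinoma, Non-Small-Cell Lung", "C04.588.894.797.520.109"),
    ("Carcinoma, Renal Cell", "C04.588.945.947.535.160"),
    ("Lung Neoplasms", "C04.588.894.797.520"),
    ("Esophageal Neoplasms", "C04.588.274.476.205"),
    ("Colorectal Neoplasms", "C04.588.274.476.411"),
    ("Urinary Bladder Neoplasms", "C04.588.945.947.960"),
    ("Leukemia", "C04.557.337"),
    ("Leukemia, Lymphocytic, Chronic, B-Cell", "C04.557.337.428.080"),
    ("Leukemia, Myelogenous, Chronic, BCR-ABL Positive", "C04.557.337.539.250"),
    ("Leukemia, Hairy Cell", "C04.557.337.428.580"),
    ("Precursor Cell Lymphoblastic Leukemia-Lymphoma", "C04.557.337.428.600"),
    ("Multiple Myeloma", "C04.557.595.500"),
    ("Lymphoma", "C04.557.386"),
    ("Neuroblastoma", "C04.557.580.625.600"),
    ("Gastrointestinal Stromal Tumors", "C04.557.450.565.590.340"),
    # Non-neoplasm distractors (tree numbers outside C04).
    ("Heart Diseases", "C14.280"),
    ("Pain, Postoperative", "C23.888.592.612.944"),
    ("Breast Diseases", "C17.800.090"),
    ("Ataxia Telangiectasia", "C10.228.140.252.190"),
    ("Obesity", "C18.654.726.500"),
)


def make_mesh_file(
    path: str | Path,
    entries: Iterable[tuple[str, str]] = DEFAULT_MESH_ENTRIES,
) -> Path:
    """Write a two-column MeSH tree file (heading;tree_number)."""
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    lines = ["# heading;tree_number"]
    lines.extend(f"{heading};{tree}" for heading, tree in entries)
    out.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out


# Default interaction edges.  The BRCA1 in-edges reconstruct the
# CDK2/CDK7/CDK9 regulator story plus the extra upstream genes needed to
# reach the eight repurposing drugs; the ATM in-edges reconstruct the
# POLE/POLE2/CDK7/CDK9/CHEK1/CHEK2 row.  The last two edges are a
# downstream-direction distractor and a non-qualifying interaction type.
DEFAULT_SIF_EDGES: tuple[tuple[str, str, str], ...] = (
    ("CDK2", "controls-state-change-of", "BRCA1"),
    ("CDK7", "controls-expression-of", "BRCA1"),
    ("CDK9", "controls-expression-of", "BRCA1"),
    ("POLE", "in-complex-with", "BRCA1"),
    ("POLE2", "in-complex-with", "BRCA1"),
    ("CHEK1", "controls-phosphorylation-of", "BRCA1"),
    ("CHEK2", "controls-phosphorylation-of", "BRCA1"),
    ("AURKA", "controls-phosphorylation-of", "BRCA1"),
    ("SRC", "controls-phosphorylation-of", "BRCA1"),
    ("POLE", "controls-state-change-of", "ATM"),
    ("POLE2", "controls-state-change-of", "ATM"),
    ("CDK7", "controls-state-change-of", "ATM"),
    ("CDK9", "controls-state-change-of", "ATM"),
    ("CHEK1", "controls-phosphorylation-of", "ATM"),
    ("CHEK2", "controls-phosphorylation-of", "ATM"),
    ("BRCA1", "controls-expression-of", "TP53"),
    ("PLK1", "reacts-with", "BRCA1"),
)


def make_sif_file(
    path: str | Path,
    edges: Iterable[tuple[str, str, str]] = DEFAULT_SIF_EDGES,
) -> Path:
    """Write a 3-column SIF file."""
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(
        "".join(f"{s}\t{t}\t{o}\n" for s, t, o in edges), encoding="utf-8"
    )
    return out


# zip -> (latitude, longitude).  18042/19019 carry the printed Census
# centroids; all other coordinates are synthetic, placed so that only the
# NY and PA facilities fall within 50 miles of 18042.
DEFAULT_ZIP_TABLE: tuple[tuple[str, float, float], ...] = (
    ("18042", 40.68, -75.22),
    ("19019", 39.95, -75.16),
    ("94305", 37.42, -122.17),
    ("02114", 42.36, -71.07),
    ("12550", 41.15, -75.05),
    ("18015", 40.62, -75.38),
    ("77030", 29.70, -95.40),
    ("10065", 40.76, -73.96),
)


def make_zip_table(
    path: str | Path,
    rows: Iterable[tuple[str, float, float]] = DEFAULT_ZIP_TABLE,
) -> Path:
    """Write a headered zip,latitude,longitude CSV."""
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    lines = ["zip,latitude,longitude"]
    lines.extend(f"{z},{lat},{lon}" for z, lat, lon in rows)
    out.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out


def make_all(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Materialise a complete demo workspace under *out_dir*.

    Writes every input the pipeline needs: MeSH tree file, drug catalog,
    two SIF files (split so one edge is duplicated across both, which the
    merge deduplicates), zip table, a 19-record trial corpus with the
    classic three-defect plan, a gene panel and a run configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["mesh"] = make_mesh_file(out / "mesh_tree.txt")
    paths["catalog"] = make_catalog(out / "drug_catalog.tsv")
    brca1_edges = [e for e in DEFAULT_SIF_EDGES if e[2] == "BRCA1" or e[0] == "BRCA1"]
    other_edges = [e for e in DEFAULT_SIF_EDGES if e not in brca1_edges]
    paths["sif_reactome"] = make_sif_file(out / "reactome.sif", brca1_edges)
    paths["sif_pid"] = make_sif_file(
        out / "pid.sif", other_edges + [("CDK7", "controls-expression-of", "BRCA1")]
    )
    paths["zips"] = make_zip_table(out / "zipcodes.csv")
    spec = ScenarioSpec(
        seed=seed,
        n_trials=19,
        defects=((1, "NOT_RECRUITING"), (1, "NOT_CANCER"), (1, "NO_DRUG")),
        gene="BRCA1",
        condition="Breast Neoplasms",
    )
    paths["trials"] = make_trial_corpus(spec, out / "trials.xml")
    panel = out / "gene_panel.txt"
    panel.write_text("BRCA1 CHEK2 EPCAM\nATM ABL1\n", encoding="utf-8")
    paths["panel"] = panel
    config = out / "config.yaml"
    config.write_text(
        "genes: BRCA1 CHEK2 EPCAM ATM ABL1\n"
        "conditions: ''\n"
        "gene_level: 1\n"
        "zip_code: '18042'\n"
        "countries: United States\n"
        "max_distance: 50\n"
        "unit: miles\n",
        encoding="utf-8",
    )
    paths["config"] = config
    return paths
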