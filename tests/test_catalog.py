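"""Drug catalog: TSV parsing, cancer tagging, eligibility, gene search."""

import pytest

from oncomatch.catalog import (
    CATALOG_COLUMNS,
    DrugRecord,
    build_indexes,
    classify_cancer_drug,
    drugs_targeting,
    is_eligible,
    parse_drug_catalog,
)
from oncomatch.mesh import NeoplasmVocabulary


def write_catalog(tmp_path, rows, columns=CATALOG_COLUMNS):
    path = tmp_path / "catalog.tsv"
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(row.get(c, "") for c in columns))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


GEFITINIB = dict(
    drug_id="DB00317",
    molecule_type="small molecule",
    name="Gefitinib",
    brand_names="Iressa;Tarceva",
    prices="Tarceva 25 mg tablet USD 52.78; Iressa 250 mg tablet USD 68.08",
    indication="Metastatic non-small cell lung carcinoma",
    target_genes="EGFR;egfr",
    groups="approved",
)


class TestParseDrugCatalog:
    def test_example_row_fields_are_split_and_trimmed(self, tmp_path):
        cat = parse_drug_catalog(write_catalog(tmp_path, [GEFITINIB]))
        (record,) = cat.records
        assert record.drug_id == "DB00317"
        assert record.brand_names == ("Iressa", "Tarceva")
        assert record.target_genes == ("EGFR",)  # upper-cased, deduplicated
        assert [(p.label, p.amount) for p in record.prices] == [
            ("Tarceva 25 mg tablet", 52.78),
            ("Iressa 250 mg tablet", 68.08),
        ]

    def test_unparseable_price_is_dropped_with_warning(self, tmp_path, caplog):
        row = dict(GEFITINIB, prices="no amount here; Iressa 250 mg tablet USD 68.08")
        with caplog.at_level("WARNING"):
            cat = parse_drug_catalog(write_catalog(tmp_path, [row]))
        assert [p.amount for p in cat.records[0].prices] == [68.08]
        assert "price" in caplog.text

    def test_duplicate_drug_id_is_fatal(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate drug_id"):
            parse_drug_catalog(write_catalog(tmp_path, [GEFITINIB, GEFITINIB]))

    def test_missing_required_column_is_fatal(self, tmp_path):
        columns = tuple(c for c in CATALOG_COLUMNS if c != "indication")
        with pytest.raises(ValueError, match="indication"):
            parse_drug_catalog(write_catalog(tmp_path, [], columns=columns))

    def test_empty_catalog_is_fatal(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            parse_drug_catalog(write_catalog(tmp_path, []))


class TestCancerClassification:
    vocab = NeoplasmVocabulary.from_headings(
        ["Carcinoma, Non-Small-Cell Lung", "Leukemia, Lymphocytic, Chronic, B-Cell"]
    )

    def test_indication_with_inverted_heading_is_cancer(self):
        record = DrugRecord(
            drug_id="DB00317", molecule_type="small molecule", name="Gefitinib",
            indication="Metastatic non-small cell lung carcinoma",
        )
        assert classify_cancer_drug(record, self.vocab)

    def test_empty_indication_is_not_cancer(self):
        record = DrugRecord(drug_id="DB00001", molecule_type="biotech", name="X")
        assert not classify_cancer_drug(record, self.vocab)

    def test_comma_rotation_oracle_on_cll_indication(self):
        # Oracle: exhaustively check every reordered variant by hand.
        from oncomatch.mesh import heading_variants, normalize_text

        text = normalize_text("chronic lymphocytic leukemia (CLL)")
        variants = heading_variants("Leukemia, Lymphocytic, Chronic, B-Cell")
        oracle = any(f" {v} " in f" {text} " for v in variants)
        record = DrugRecord(
            drug_id="DB05149", molecule_type="small molecule", name="XL844",
            indication="chronic lymphocytic leukemia (CLL)",
        )
        assert classify_cancer_drug(record, self.vocab) == oracle is True


class TestEligibility:
    @pytest.mark.parametrize(
        "groups,expected",
        [
            (("approved", "nutraceutical"), False),
            (("experimental",), True),
            ((), True),
            (("Over-The-Counter",), False),
            (("withdrawn",), False),
            (("illicit",), False),
        ],
    )
    def test_excluded_group_labels(self, groups, expected):
        record = DrugRecord(
            drug_id="DB00001", molecule_type="small molecule", name="X", groups=groups
        )
        assert is_eligible(record) is expected


class TestDrugsTargeting:
    def test_worked_examples_epcam_and_chek2(self, catalog):
        assert [r.drug_id for r in drugs_targeting("EPCAM", catalog)] == [
            "DB05319",
            "DB05831",
        ]
        assert "XL844" in [r.name for r in drugs_targeting("CHEK2", catalog)]

    def test_unknown_gene_yields_empty_list(self, catalog):
        assert drugs_targeting("NOSUCHGENE", catalog) == []

    def test_lookup_is_case_insensitive_and_sorted(self, catalog):
        records = drugs_targeting("abl1", catalog)
        ids = [r.drug_id for r in records]
        assert ids == sorted(ids) and len(ids) > 0

    def test_only_eligible_cancer_drugs_are_returned(self, catalog, vocab):
        for gene, ids in catalog.gene_index.items():
            for record in drugs_targeting(gene, catalog):
                assert is_eligible(record)
                assert classify_cancer_drug(record, vocab)

    def test_noncancer_and_ineligible_targeters_are_excluded(self, catalog):
        abl1 = {r.name for r in drugs_targeting("ABL1", catalog)}
        assert "Adenosine triphosphate" not in abl1  # nutraceutical
        assert not drugs_targeting("ATM", catalog)  # caffeine is not a cancer drug
        assert not drugs_targeting("PTGS2", catalog)  # over-the-counter distractor

    def test_multi_target_record_appears_under_each_target(self, catalog):
        atp = next(r for r in catalog.records if r.drug_id == "DB00171")
        assert len(atp.target_genes) == 33
        for gene in atp.target_genes:
            assert "DB00171" in catalog.gene_index[gene]

    def test_rebuilding_indexes_is_deterministic(self, workspace, vocab):
        a = build_indexes(parse_drug_catalog(workspace["catalog"]), vocab)
        b = build_indexes(parse_drug_catalog(workspace["catalog"]), vocab)
        assert a.cancer_ids == b.cancer_ids and a.gene_index == b.gene_index
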