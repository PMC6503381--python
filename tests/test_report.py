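"""Duplicate collapsing, run summary reconciliation and report output."""

import pandas as pd

from chemcurate import report as rp
from chemcurate import scoring
from chemcurate.pipeline import InputRecord, run_pipeline


def entry(cas, name, smiles):
    return [("CAS", cas, smiles), ("NAME", name, smiles)]


def merge(*table_sets):
    out = {}
    for tables in table_sets:
        for source, rows in tables.items():
            out.setdefault(source, []).extend(rows)
    return out


def concordant(cas, name, smiles):
    return {s: entry(cas, name, smiles) for s in ("cir", "comptox")}


def run_records(gateway_factory, specs, synonyms=None):
    tables = merge(*(concordant(*spec[1:]) for spec in specs))
    gateway = gateway_factory(tables, synonyms)
    records = [InputRecord(rid, name, cas) for rid, cas, name, _ in specs]
    return run_pipeline(records, gateway)


class TestCollapseDuplicates:
    def test_enantiomer_records_collapse_to_one(self, gateway_factory):
        run = run_records(
            gateway_factory,
            [
                ("R1", "56-41-7", "L-alanine", "C[C@H](N)C(=O)O"),
                ("R2", "338-69-2", "D-alanine", "C[C@@H](N)C(=O)O"),
            ],
        )
        curated = rp.collapse_duplicates(run.maintained)
        assert len(curated) == 1
        assert curated[0].duplicate_count == 2
        assert dict(curated[0].names_with_occurrences) == {
            "L-alanine": 1, "D-alanine": 1,
        }

    def test_representative_prefers_high_reliability(self, gateway_factory):
        # R1 concordant in one source only (promoted medium via secondary),
        # R2 fully concordant (high): R2 must represent the merged record.
        tables = merge(
            {"cir": entry("64-17-5", "ethanol", "CCO"),
             "pubchem": [("CAS", "64-17-5", "CCO")]},
            concordant("1234-56-6", "ethyl alcohol", "CCO"),
        )
        gateway = gateway_factory(tables)
        run = run_pipeline(
            [InputRecord("R1", "ethanol", "64-17-5"),
             InputRecord("R2", "ethyl alcohol", "1234-56-6")],
            gateway,
        )
        assert [r.reliability for r in run.maintained] == [
            scoring.RELIABILITY_MEDIUM, scoring.RELIABILITY_HIGH
        ]
        curated = rp.collapse_duplicates(run.maintained)
        assert len(curated) == 1
        assert curated[0].reliability == scoring.RELIABILITY_HIGH
        assert curated[0].member_ids[0] == "R2"

    def test_salt_counterion_differences_flagged(self, gateway_factory):
        run = run_records(
            gateway_factory,
            [
                ("R1", "127-09-3", "sodium acetate", "CC(=O)[O-].[Na+]"),
                ("R2", "127-08-2", "potassium acetate", "CC(=O)[O-].[K+]"),
            ],
        )
        curated = rp.collapse_duplicates(run.maintained)
        assert len(curated) == 1
        assert "counterion_difference" in curated[0].warnings

    def test_idempotent_and_order_insensitive(self, gateway_factory):
        run = run_records(
            gateway_factory,
            [
                ("R1", "64-17-5", "ethanol", "CCO"),
                ("R2", "67-56-1", "methanol", "CO"),
                ("R3", "1234-56-6", "ethyl alcohol", "CCO"),
            ],
        )
        curated = rp.collapse_duplicates(run.maintained)
        again = rp.collapse_duplicates(run.maintained)
        assert [(c.dedup_key, c.duplicate_count) for c in curated] == [
            (c.dedup_key, c.duplicate_count) for c in again
        ]
        reversed_curated = rp.collapse_duplicates(run.maintained[::-1])
        assert {c.dedup_key for c in curated} == {
            c.dedup_key for c in reversed_curated
        }

    def test_progressive_ids_assigned_in_input_order(self, gateway_factory):
        run = run_records(
            gateway_factory,
            [
                ("R1", "67-56-1", "methanol", "CO"),
                ("R2", "64-17-5", "ethanol", "CCO"),
            ],
        )
        curated = rp.collapse_duplicates(run.maintained)
        assert [c.new_id for c in curated] == [1, 2]
        assert curated[0].member_ids == ["R1"]


class TestSummary:
    def test_conservation_identity(self, gateway_factory):
        specs = [
            ("R1", "64-17-5", "ethanol", "CCO"),
            ("R2", "67-56-1", "methanol mixture", "CO"),  # rejected: keyword
            ("R3", "98-80-6", "phenylboronic acid", "OB(O)c1ccccc1"),  # element
        ]
        run = run_records(gateway_factory, specs)
        curated = rp.collapse_duplicates(run.maintained)
        summary = rp.summarize(run, curated)
        assert summary.reconciles()
        assert summary.total_input == 3
        assert summary.rejected_by_reason == {
            "mixture_or_unresolvable_name": 1,
            "inorganic_or_unusual_element": 1,
        }

    def test_zero_noise_full_maintain(self, gateway_factory):
        specs = [
            ("R1", "64-17-5", "ethanol", "CCO"),
            ("R2", "67-56-1", "methanol", "CO"),
        ]
        run = run_records(gateway_factory, specs)
        curated = rp.collapse_duplicates(run.maintained)
        summary = rp.summarize(run, curated)
        assert summary.maintained_with_duplicates == summary.total_input
        assert summary.maintained_unique_high == 2


class TestWriteReport:
    def test_sheets_and_csv_mirror_identical(self, gateway_factory, tmp_path):
        specs = [
            ("R1", "64-17-5", "ethanol", "CCO"),
            ("R2", "67-56-1", "methanol mixture", "CO"),
        ]
        run = run_records(gateway_factory, specs)
        curated = rp.collapse_duplicates(run.maintained)
        summary = rp.summarize(run, curated)
        out = tmp_path / "report.xlsx"
        rp.write_report(run, curated, summary, run.worksheet(), out)
        assert out.exists()
        csv_dir = tmp_path / "report_csv"
        for sheet in rp.SHEET_NAMES:
            from_xlsx = pd.read_excel(out, sheet_name=sheet, dtype=str).fillna("")
            from_csv = pd.read_csv(
                csv_dir / (sheet.replace(" ", "_") + ".csv"), dtype=str
            ).fillna("")
            pd.testing.assert_frame_equal(from_xlsx, from_csv)

    def test_empty_manual_check_sheet_still_present(
        self, gateway_factory, tmp_path
    ):
        run = run_records(
            gateway_factory, [("R1", "64-17-5", "ethanol", "CCO")]
        )
        out = tmp_path / "report.xlsx"
        curated = rp.collapse_duplicates(run.maintained)
        rp.write_report(run, curated, rp.summarize(run, curated),
                        run.worksheet(), out)
        manual = pd.read_excel(out, sheet_name="Manual Check")
        assert manual.empty

    def test_rejected_sheet_carries_reason_warnings(
        self, gateway_factory, tmp_path
    ):
        run = run_records(
            gateway_factory, [("R1", "67-56-1", "methanol mixture", "CO")]
        )
        curated = rp.collapse_duplicates(run.maintained)
        out = tmp_path / "report.xlsx"
        rp.write_report(run, curated, rp.summarize(run, curated),
                        run.worksheet(), out)
        rejected = pd.read_excel(out, sheet_name="Rejected")
        assert "mixture_or_unresolvable_name" in rejected.loc[0, "WARNINGS"]
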