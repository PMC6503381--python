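"""Duplicate collapsing, run summary and the multi-sheet output document.

Maintained records are grouped on the three-layer identifier key, so two
records whose structures differ only below that depth (typically stripped
stereoisomers, or salt vs free form after neutralization) collapse into one
curated entry.  The report is an .xlsx workbook with fixed sheet names plus a
cell-identical CSV mirror directory for diff-friendly testing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import scoring
from .pipeline import PipelineRun, RecordResult
from .resolvers import PRIMARY_SLOTS, SECONDARY_SLOTS

__all__ = [
    "CuratedRecord",
    "RunSummary",
    "collapse_duplicates",
    "summarize",
    "write_report",
    "SHEET_NAMES",
]

_RELIABILITY_RANK = {scoring.RELIABILITY_HIGH: 0, scoring.RELIABILITY_MEDIUM: 1}


@dataclass
class CuratedRecord:
    new_id: int
    dedup_key: str
    smiles_original: str
    smiles_neutralized: str
    smiles_canonical_kekulized: str
    duplicate_count: int
    names_with_occurrences: list
    cas_with_occurrences: list
    reliability: str
    warnings: list = field(default_factory=list)
    member_ids: list = field(default_factory=list)


def _counterion_profile(result: RecordResult):
    """Counterion tuples seen across a record's retrieved structures."""
    profiles = set()
    for s in result.standardized.values():
        if s is not None and s.usable:
            profiles.add(tuple(sorted(s.counterions)))
    return profiles


def collapse_duplicates(maintained) -> list:
    """Group maintained records on the three-layer dedup key.

    One representative per group: highest reliability, then lowest input row
    index.  Name/CAS occurrence lists aggregate over the group; differing
    counterions across group members (or across one record's sources) are
    flagged.  Progressive IDs are assigned after deduplication, in input
    order of the representatives.
    """
    groups: dict = {}
    for result in maintained:
        rep = result.representative
        key = rep.dedup_key if rep is not None else f"__nokey__{result.index}"
        groups.setdefault(key, []).append(result)

    curated = []
    for key, members in groups.items():
        members.sort(
            key=lambda r: (_RELIABILITY_RANK.get(r.reliability, 9), r.index)
        )
        head = members[0]
        rep = head.representative
        names = Counter(m.record.name for m in members)
        cas_numbers = Counter(m.cas.normalized for m in members)
        warnings = []
        seen = [w for m in members for w in m.warnings]
        if seen:
            warnings.extend(dict.fromkeys(seen))
        ion_profiles = set()
        for m in members:
            ion_profiles |= _counterion_profile(m)
        if len(ion_profiles) > 1:
            warnings.append("counterion_difference")
        curated.append(
            CuratedRecord(
                new_id=0,  # assigned below
                dedup_key=key,
                smiles_original=rep.smiles_original if rep else "",
                smiles_neutralized=rep.neutralized if rep else "",
                smiles_canonical_kekulized=rep.canonical_kekulized if rep else "",
                duplicate_count=len(members),
                names_with_occurrences=sorted(names.items()),
                cas_with_occurrences=sorted(cas_numbers.items()),
                reliability=head.reliability,
                warnings=warnings,
                member_ids=[m.record.record_id for m in members],
            )
        )
    curated.sort(key=lambda c: min(m for m in _member_indices(c, maintained)))
    for new_id, record in enumerate(curated, start=1):
        record.new_id = new_id
    return curated


def _member_indices(curated: CuratedRecord, maintained):
    by_id = {r.record.record_id: r.index for r in maintained}
    return [by_id[m] for m in curated.member_ids]


@dataclass
class RunSummary:
    total_input: int
    maintained_with_duplicates: int
    maintained_unique: int
    maintained_unique_high: int
    maintained_unique_medium: int
    manual_check_pending: int
    rejected_total: int
    rejected_by_reason: dict

    def reconciles(self) -> bool:
        return (
            self.maintained_with_duplicates
            + self.rejected_total
            + self.manual_check_pending
            == self.total_input
        )

    def as_rows(self):
        rows = [
            ("Total input records", self.total_input),
            ("Maintained (with duplicates)", self.maintained_with_duplicates),
            ("Maintained (without duplicates)", self.maintained_unique),
            ("Maintained (w/o duplicates, high reliability)",
             self.maintained_unique_high),
            ("Maintained (w/o duplicates, medium reliability)",
             self.maintained_unique_medium),
            ("Manual check pending", self.manual_check_pending),
            ("Rejected (total)", self.rejected_total),
        ]
        for reason, count in sorted(self.rejected_by_reason.items()):
            rows.append((f"Rejected ({reason})", count))
        return rows


def summarize(run: PipelineRun, curated) -> RunSummary:
    rejected = run.rejected
    by_reason: dict = {}
    for r in rejected:
        by_reason[r.reject_reason] = by_reason.get(r.reject_reason, 0) + 1
    return RunSummary(
        total_input=len(run.records),
        maintained_with_duplicates=len(run.maintained),
        maintained_unique=len(curated),
        maintained_unique_high=sum(
            1 for c in curated if c.reliability == scoring.RELIABILITY_HIGH
        ),
        maintained_unique_medium=sum(
            1 for c in curated if c.reliability == scoring.RELIABILITY_MEDIUM
        ),
        manual_check_pending=len(run.pending),
        rejected_total=len(rejected),
        rejected_by_reason=by_reason,
    )


# --------------------------------------------------------------------------
# sheet assembly

SHEET_NAMES = (
    "Maintained",
    "Rejected",
    "Manual Check",
    "Full output",
    "Neutralized and Counterions",
    "PubChem_ChemID_check",
    "Summary",
    "Counterions_CIR_NAME",
    "Counterions_CIR_CAS",
    "Counterions_COMPTOX_NAME",
    "Counterions_COMPTOX_CAS",
)


def _maintained_frame(curated) -> pd.DataFrame:
    rows = [
        {
            "NEW_ID": c.new_id,
            "ORIGINAL_SMILES": c.smiles_original,
            "NEUTRALIZED_SMILES": c.smiles_neutralized,
            "CANONICAL_KEKULIZED_SMILES": c.smiles_canonical_kekulized,
            "DUPLICATES": c.duplicate_count,
            "NAMES (OCCURRENCES)": "; ".join(
                f"{n} ({k})" for n, k in c.names_with_occurrences
            ),
            "CAS (OCCURRENCES)": "; ".join(
                f"{n} ({k})" for n, k in c.cas_with_occurrences
            ),
            "RELIABILITY": c.reliability,
            "WARNINGS": "; ".join(c.warnings),
        }
        for c in curated
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "NEW_ID", "ORIGINAL_SMILES", "NEUTRALIZED_SMILES",
            "CANONICAL_KEKULIZED_SMILES", "DUPLICATES", "NAMES (OCCURRENCES)",
            "CAS (OCCURRENCES)", "RELIABILITY", "WARNINGS",
        ],
    )


def _rejected_frame(run: PipelineRun) -> pd.DataFrame:
    rows = [
        {
            "ID": r.record.record_id,
            "NAME": r.record.name,
            "CAS": r.cas.normalized,
            "WARNINGS": "; ".join([f"rejected: {r.reject_reason}"] + r.warnings),
        }
        for r in run.rejected
    ]
    return pd.DataFrame(rows, columns=["ID", "NAME", "CAS", "WARNINGS"])


def _full_frame(run: PipelineRun) -> pd.DataFrame:
    rows = []
    for r in run.records:
        rep = r.representative
        rows.append(
            {
                "ID": r.record.record_id,
                "NAME": r.record.name,
                "CAS": r.cas.normalized,
                "E": r.profile.E if r.profile else "",
                "D": r.profile.D if r.profile else "",
                "M": r.profile.M if r.profile else "",
                "RAW_SCORE": f"{r.score.raw_score:.1f}" if r.score else "",
                "FINAL_SCORE": f"{r.score.final_score:.1f}" if r.score else "",
                "CATEGORY": r.category,
                "RELIABILITY": r.reliability,
                "CHECK_REASON": r.check_reason,
                "NEUTRALIZED_SMILES": rep.neutralized if rep else "",
                "WARNINGS": "; ".join(r.warnings),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ID", "NAME", "CAS", "E", "D", "M", "RAW_SCORE", "FINAL_SCORE",
            "CATEGORY", "RELIABILITY", "CHECK_REASON", "NEUTRALIZED_SMILES",
            "WARNINGS",
        ],
    )


_ION_COLUMNS = [
    "ID", "CAS", "SLOT", "ORIGINAL_SMILES", "MAIN_FRAGMENT",
    "NEUTRALIZED_SMILES", "COUNTERIONS", "WARNINGS",
]


def _ions_frame(run: PipelineRun, slots) -> pd.DataFrame:
    rows = []
    for r in run.records:
        source = r.standardized if slots is PRIMARY_SLOTS else r.secondary_standardized
        for slot in slots:
            s = source.get(slot)
            if s is None:
                continue
            rows.append(
                {
                    "ID": r.record.record_id,
                    "CAS": r.cas.normalized,
                    "SLOT": str(slot),
                    "ORIGINAL_SMILES": s.smiles_original,
                    "MAIN_FRAGMENT": s.main_fragment,
                    "NEUTRALIZED_SMILES": s.neutralized,
                    "COUNTERIONS": "; ".join(s.counterions),
                    "WARNINGS": "; ".join(sorted(s.flags)),
                }
            )
    return pd.DataFrame(rows, columns=_ION_COLUMNS)


def _slot_ions_frame(run: PipelineRun, slot) -> pd.DataFrame:
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    columns = [
        "ID", "ORIGINAL_SMILES", "STRIPPED_SMILES", "NEUTRALIZED_SMILES",
        "COUNTERIONS", "MW_MAIN", "MW_COUNTERIONS", "NEUTRALIZATION_WARNINGS",
    ]
    rows = []
    for r in run.records:
        s = r.standardized.get(slot)
        if s is None or not s.main_fragment:
            continue
        main_mol = Chem.MolFromSmiles(s.main_fragment)
        ion_mws = []
        for ion in s.counterions:
            mol = Chem.MolFromSmiles(ion)
            ion_mws.append(round(Descriptors.MolWt(mol), 2) if mol else "")
        rows.append(
            {
                "ID": r.record.record_id,
                "ORIGINAL_SMILES": s.smiles_original,
                "STRIPPED_SMILES": s.main_fragment,
                "NEUTRALIZED_SMILES": s.neutralized,
                "COUNTERIONS": "; ".join(s.counterions),
                "MW_MAIN": round(Descriptors.MolWt(main_mol), 2) if main_mol else "",
                "MW_COUNTERIONS": "; ".join(str(m) for m in ion_mws),
                "NEUTRALIZATION_WARNINGS": (
                    "neutralization_failed" if "neutralization_failed" in s.flags
                    else ""
                ),
            }
        )
    return pd.DataFrame(rows, columns=columns)


def build_sheets(run: PipelineRun, curated, summary: RunSummary,
                 worksheet: pd.DataFrame) -> dict:
    """Assemble every output sheet as a DataFrame, keyed by sheet name."""
    sheets = {
        "Maintained": _maintained_frame(curated),
        "Rejected": _rejected_frame(run),
        "Manual Check": worksheet,
        "Full output": _full_frame(run),
        "Neutralized and Counterions": _ions_frame(run, PRIMARY_SLOTS),
        "PubChem_ChemID_check": _ions_frame(run, SECONDARY_SLOTS),
        "Summary": pd.DataFrame(summary.as_rows(), columns=["ITEM", "COUNT"]),
    }
    for slot in PRIMARY_SLOTS:
        sheets[f"Counterions_{slot.source.value}_{slot.identifier_kind.value}"] = (
            _slot_ions_frame(run, slot)
        )
    return sheets


def write_report(run: PipelineRun, curated, summary: RunSummary,
                 worksheet: pd.DataFrame, path: str | Path) -> Path:
    """Write the .xlsx workbook and its CSV mirror directory.

    The mirror directory sits next to the workbook (``<stem>_csv/``) and is
    cell-for-cell identical to the sheets.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sheets = build_sheets(run, curated, summary, worksheet)
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for name in SHEET_NAMES:
            sheets[name].to_excel(writer, sheet_name=name, index=False)
    csv_dir = path.with_name(path.stem + "_csv")
    csv_dir.mkdir(exist_ok=True)
    for name in SHEET_NAMES:
        fname = name.replace(" ", "_") + ".csv"
        sheets[name].to_csv(csv_dir / fname, index=False)
    return path
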