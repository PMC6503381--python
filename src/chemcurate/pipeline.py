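"""End-to-end orchestration: input table -> scored, curated, reported run.

First pass: normalize/validate identifiers, resolve the four primary slots
(CIR and CompTox by name and CAS), standardize every retrieved SMILES, tally
concordance, score and route.  Structure-level rejections (mixture keywords,
unusual elements, inorganics) override any score.  Check records then go
through the automated confirmation round (synonym match, PubChem/ChemIDplus
retrievals); what remains lands on the manual worksheet.

Resume pass: the user-edited worksheet is reloaded, confirmation counts are
applied, and former Check records are moved to Maintain or Reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import confirm, scoring
from .identifiers import (
    CasNumber,
    DISPOSITION_MANUAL,
    DISPOSITION_REMOVE,
    KeywordRules,
    normalize_cas,
    triage_name,
)
from .resolvers import IdentifierKind, ResolverGateway
from .structures import (
    INORGANIC,
    UNUSUAL_ELEMENT,
    StandardizedStructure,
    standardize,
)

__all__ = [
    "InputRecord",
    "RecordResult",
    "PipelineConfig",
    "read_input_table",
    "run_pipeline",
    "apply_worksheet",
    "REJECT_MIXTURE",
    "REJECT_INORGANIC",
    "REJECT_MISSING",
    "REJECT_MANUAL",
]

REJECT_MIXTURE = "mixture_or_unresolvable_name"
REJECT_INORGANIC = "inorganic_or_unusual_element"
REJECT_MISSING = "missing_or_ambiguous_structure"
REJECT_MANUAL = "manual_check_failed"


@dataclass(frozen=True)
class InputRecord:
    record_id: str
    name: str
    cas_raw: str


@dataclass
class PipelineConfig:
    id_column: str = "ID"
    name_column: str = "NAME"
    cas_column: str = "CAS"
    delimiter: str = ","
    keyword_rules: KeywordRules | None = None


@dataclass
class RecordResult:
    """Everything the pipeline knows about one input record."""

    index: int
    record: InputRecord
    cas: CasNumber
    triage: object
    resolved: dict = field(default_factory=dict)
    standardized: dict = field(default_factory=dict)
    secondary_resolved: dict = field(default_factory=dict)
    secondary_standardized: dict = field(default_factory=dict)
    profile: object = None
    score: object = None
    category: str = ""
    reliability: str = scoring.RELIABILITY_NONE
    check_reason: str = scoring.REASON_NONE
    reject_reason: str = ""
    confirmation: object = None
    synonyms: tuple = ()
    warnings: list = field(default_factory=list)

    @property
    def representative(self) -> StandardizedStructure | None:
        """Standardized structure of the concordant class, CAS slot preferred."""
        if self.profile is None or self.profile.majority_key is None:
            return None
        candidates = [
            (slot, s)
            for slot, s in self.standardized.items()
            if s is not None and s.comparison_key == self.profile.majority_key
        ]
        if not candidates:
            return None
        candidates.sort(
            key=lambda item: (item[0].identifier_kind != IdentifierKind.CAS,
                              str(item[0]))
        )
        return candidates[0][1]


def read_input_table(path: str | Path, config: PipelineConfig | None = None
                     ) -> list:
    """Read the user's substance table (CSV/TSV) into InputRecords."""
    config = config or PipelineConfig()
    df = pd.read_csv(path, sep=config.delimiter, dtype=str).fillna("")
    records = []
    seen = set()
    for _, row in df.iterrows():
        rid = str(row[config.id_column])
        if rid in seen:
            raise ValueError(f"duplicate record id {rid!r}")
        seen.add(rid)
        records.append(
            InputRecord(
                record_id=rid,
                name=str(row[config.name_column]),
                cas_raw=str(row[config.cas_column]),
            )
        )
    return records


def _first_pass(record: InputRecord, index: int, gateway: ResolverGateway,
                config: PipelineConfig) -> RecordResult:
    cas = normalize_cas(record.cas_raw)
    triage = triage_name(record.name, config.keyword_rules)
    result = RecordResult(index=index, record=record, cas=cas, triage=triage)

    if cas.anomaly_flags:
        result.warnings.extend(f"CAS: {f}" for f in sorted(cas.anomaly_flags))
    if not cas.malformed and not cas.checksum_valid:
        result.warnings.append("CAS: checksum_invalid")
    if triage.keywords_hit:
        result.warnings.append(
            "name keywords: " + ", ".join(sorted(triage.keywords_hit))
        )

    cas_query = "" if cas.malformed else cas.normalized
    result.resolved = gateway.resolve_primary(record.name, cas_query)
    for slot, res in result.resolved.items():
        result.standardized[slot] = (
            standardize(res.smiles_raw) if res.found else None
        )
        if res.status == "error":
            result.warnings.append(f"{slot}: backend error ({res.message})")

    slot_keys = {
        slot: (s.comparison_key if s is not None and s.usable else None)
        for slot, s in result.standardized.items()
    }
    for slot, s in result.standardized.items():
        if s is not None and not s.usable:
            result.warnings.append(f"{slot}: unusable structure (parse failure)")

    result.profile, result.score = scoring.score_slots(slot_keys)
    result.category = result.score.category
    result.reliability = result.score.reliability
    result.check_reason = result.score.check_reason

    # structure- and name-level overrides (never promoted, only demoted)
    if triage.disposition == DISPOSITION_REMOVE:
        result.category = scoring.REJECT
        result.reject_reason = REJECT_MIXTURE
        result.reliability = scoring.RELIABILITY_NONE
        return result

    rep = result.representative
    if rep is not None and ({UNUSUAL_ELEMENT, INORGANIC} & rep.flags):
        result.category = scoring.REJECT
        result.reject_reason = REJECT_INORGANIC
        result.reliability = scoring.RELIABILITY_NONE
        return result

    if result.category == scoring.REJECT:
        result.reject_reason = REJECT_MISSING
        return result

    if result.category == scoring.MAINTAIN:
        demote = None
        if triage.disposition == DISPOSITION_MANUAL:
            demote = scoring.REASON_VERIFY_NAME
            result.warnings.append("maintained score demoted: name keyword")
        elif not cas.malformed and not cas.checksum_valid:
            demote = scoring.REASON_VERIFY_CAS_NEED_ONE
            result.warnings.append("maintained score demoted: CAS checksum invalid")
        elif cas.malformed and result.record.cas_raw.strip():
            demote = scoring.REASON_VERIFY_CAS_NEED_ONE
            result.warnings.append("maintained score demoted: malformed CAS")
        if demote is not None:
            result.category = scoring.CHECK
            result.check_reason = demote
            result.reliability = scoring.RELIABILITY_NONE
    return result


def _confirmation_round(result: RecordResult, gateway: ResolverGateway) -> None:
    """Automated second pass for one Check record (mutates ``result``)."""
    reason = result.check_reason
    state = confirm.ConfirmationState(
        record_id=result.record.record_id,
        check_reason=reason,
        confirmations_required=confirm.required_confirmations(reason),
        cas_checksum_valid=result.cas.checksum_valid,
    )

    if reason in (scoring.REASON_VERIFY_NAME, scoring.REASON_VERIFY_CAS_NEED_ONE):
        synonyms = gateway.fetch_synonyms(result.cas)
        result.synonyms = synonyms.synonyms
        match = confirm.verify_name(result.record.name, synonyms)
        state = confirm.ConfirmationState(
            record_id=state.record_id,
            check_reason=state.check_reason,
            confirmations_required=state.confirmations_required,
            synonym_match=match,
            cas_checksum_valid=state.cas_checksum_valid,
        )
        if reason == scoring.REASON_VERIFY_NAME and match == confirm.SYN_MATCHED:
            result.confirmation = state
            result.category = scoring.MAINTAIN
            result.reliability = scoring.RELIABILITY_MEDIUM
            result.warnings.append("promoted: name matched a known synonym")
            return

    if reason != scoring.REASON_VERIFY_NAME:
        cas_query = "" if result.cas.malformed else result.cas.normalized
        result.secondary_resolved = gateway.resolve_secondary(
            result.record.name, cas_query
        )
        result.secondary_standardized = {
            slot: (standardize(res.smiles_raw) if res.found else None)
            for slot, res in result.secondary_resolved.items()
        }
        majority = result.profile.majority_key if result.profile else None
        state = confirm.confirm_with_secondary(
            state, majority, result.secondary_standardized
        )
        result.warnings.extend(state.warnings)
        if state.resolved_category == scoring.MAINTAIN:
            result.confirmation = state
            result.category = scoring.MAINTAIN
            result.reliability = scoring.RELIABILITY_MEDIUM
            result.warnings.append(
                f"promoted: {state.confirmations_found} secondary confirmation(s)"
            )
            return

    result.confirmation = state


@dataclass
class PipelineRun:
    records: list
    gateway: ResolverGateway
    config: PipelineConfig

    @property
    def maintained(self):
        return [r for r in self.records if r.category == scoring.MAINTAIN]

    @property
    def pending(self):
        return [r for r in self.records if r.category == scoring.CHECK]

    @property
    def rejected(self):
        return [r for r in self.records if r.category == scoring.REJECT]

    def worksheet(self) -> pd.DataFrame:
        rows = []
        for r in self.pending:
            rep = r.representative
            state = r.confirmation
            rows.append(
                {
                    "ID": r.record.record_id,
                    "NAME": r.record.name,
                    "CAS": r.cas.normalized,
                    "NEUTRALIZED_SMILES": rep.neutralized if rep else "",
                    "E": r.profile.E,
                    "D": r.profile.D,
                    "M": r.profile.M,
                    "INSTRUCTION": scoring.CHECK_INSTRUCTIONS[r.check_reason],
                    "SYNONYMS": "; ".join(r.synonyms),
                    "CONFIRMATIONS_REQUIRED": (
                        state.confirmations_required if state else 1
                    ),
                    "CONFIRMATIONS_FOUND": (
                        state.confirmations_found if state else 0
                    ),
                }
            )
        return confirm.emit_manual_worksheet(rows)


def run_pipeline(records, gateway: ResolverGateway,
                 config: PipelineConfig | None = None,
                 confirmation: bool = True) -> PipelineRun:
    """Run the first pass (and optionally the automated confirmation round)."""
    config = config or PipelineConfig()
    results = []
    for index, record in enumerate(records):
        result = _first_pass(record, index, gateway, config)
        results.append(result)
    if confirmation:
        for result in results:
            if result.category == scoring.CHECK:
                _confirmation_round(result, gateway)
    return PipelineRun(records=results, gateway=gateway, config=config)


def apply_worksheet(run: PipelineRun, worksheet: pd.DataFrame) -> PipelineRun:
    """Resume step: fold user-filled confirmation counts back into the run."""
    states = [r.confirmation for r in run.pending if r.confirmation is not None]
    updated = confirm.reload_and_rescore(worksheet, states)
    by_id = {r.record.record_id: r for r in run.records}
    for record_id, state in updated.items():
        result = by_id.get(record_id)
        if result is None or result.category != scoring.CHECK:
            continue
        result.confirmation = state
        if state.resolved_category == scoring.MAINTAIN:
            result.category = scoring.MAINTAIN
            result.reliability = scoring.RELIABILITY_MEDIUM
            result.warnings.append("promoted after manual check")
        elif state.resolved_category == scoring.REJECT:
            result.category = scoring.REJECT
            result.reject_reason = REJECT_MANUAL
            result.warnings.append("rejected: manual check failed")
        # records with malformed counts stay pending, warning already attached
    return run
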