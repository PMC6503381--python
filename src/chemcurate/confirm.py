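"""Second-pass confirmation of doubtful (Check) records.

Three automated escape routes exist before a human is involved:

* name verification — the record's CAS number is used to pull the synonym
  list from PubChem; a normalized match between the input name and any
  synonym confirms name/CAS consistency and promotes the record;
* secondary-source confirmation — PubChem and ChemIDplus are queried by name
  and CAS, their structures standardized, and each *source* that reproduces
  the primary majority key counts as one confirmation (a source agreeing via
  both its name and CAS slots still counts once);
* CAS verification — the checksum must hold in addition to one confirmation.

Whatever remains pending is written to a manual worksheet; after the user
fills the confirmation counts the worksheet is reloaded and records are
moved to Maintain (medium reliability) or Reject — nothing stays pending.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd

from . import scoring
from .resolvers import SynonymList

__all__ = [
    "ConfirmationState",
    "required_confirmations",
    "verify_name",
    "normalize_name",
    "confirm_with_secondary",
    "emit_manual_worksheet",
    "reload_and_rescore",
    "WORKSHEET_COLUMNS",
]

SYN_MATCHED = "matched"
SYN_UNMATCHED = "unmatched"
SYN_NOT_APPLICABLE = "not_applicable"

PENDING = "pending_manual"


@dataclass(frozen=True)
class ConfirmationState:
    record_id: str
    check_reason: str
    confirmations_found: int = 0
    confirmations_required: int = 0
    synonym_match: str = SYN_NOT_APPLICABLE
    resolved_category: str = PENDING
    cas_checksum_valid: bool = True
    warnings: tuple = field(default_factory=tuple)


def required_confirmations(check_reason: str) -> int:
    """Confirmations needed to promote a Check record to Maintain.

    Name-verification records need one manual confirmation only if the
    automated synonym match fails.
    """
    return {
        scoring.REASON_VERIFY_NAME: 1,
        scoring.REASON_NEED_ONE: 1,
        scoring.REASON_VERIFY_CAS_NEED_ONE: 1,
        scoring.REASON_NEED_TWO: 2,
    }.get(check_reason, 1)


_EDGE_PUNCT = re.compile(r"^[\s\.\,\;\:\-\'\"\(\)\[\]]+|[\s\.\,\;\:\-\'\"\(\)\[\]]+$")


def normalize_name(name: str) -> str:
    """Case-fold, collapse internal whitespace, strip edge punctuation."""
    text = re.sub(r"\s+", " ", (name or "").casefold())
    return _EDGE_PUNCT.sub("", text)


def verify_name(name: str, synonyms: SynonymList) -> str:
    """Compare the input name against the synonym list (normalized equality)."""
    target = normalize_name(name)
    if not target:
        return SYN_UNMATCHED
    for syn in synonyms.synonyms:
        if normalize_name(syn) == target:
            return SYN_MATCHED
    return SYN_UNMATCHED


def confirm_with_secondary(state: ConfirmationState, majority_key: str | None,
                           secondary_structures) -> ConfirmationState:
    """Count source-level confirmations from standardized secondary retrievals.

    ``secondary_structures`` maps secondary slots to StandardizedStructure.
    A source confirms when at least one of its slots yields the majority
    comparison key; a source contradicting the majority key is recorded as a
    warning, never as a confirmation.
    """
    if majority_key is None:
        return state
    agreeing = set()
    warnings = list(state.warnings)
    for slot, structure in secondary_structures.items():
        if structure is None or not structure.usable:
            continue
        if structure.comparison_key == majority_key:
            agreeing.add(slot.source)
        else:
            warnings.append(
                f"discordant secondary structure from {slot}"
            )
    found = max(state.confirmations_found, len(agreeing))
    new_state = replace(
        state, confirmations_found=found, warnings=tuple(warnings)
    )
    if found >= state.confirmations_required and _extra_conditions_met(new_state):
        new_state = replace(new_state, resolved_category=scoring.MAINTAIN)
    return new_state


def _extra_conditions_met(state: ConfirmationState) -> bool:
    if state.check_reason == scoring.REASON_VERIFY_CAS_NEED_ONE:
        return state.cas_checksum_valid
    return True


WORKSHEET_COLUMNS = [
    "ID",
    "NAME",
    "CAS",
    "NEUTRALIZED_SMILES",
    "E",
    "D",
    "M",
    "INSTRUCTION",
    "SYNONYMS",
    "CONFIRMATIONS_REQUIRED",
    "CONFIRMATIONS_FOUND",
    "USER_CONFIRMATIONS",
]


def emit_manual_worksheet(pending_rows) -> pd.DataFrame:
    """Build the manual-check worksheet for records the automation left open.

    Each row carries the identifiers, the neutralized primary structure, the
    evidence counts, the instruction for the user, the synonym list pulled
    for name verification and an empty USER_CONFIRMATIONS cell to fill.
    """
    frame = pd.DataFrame(list(pending_rows), columns=WORKSHEET_COLUMNS)
    frame["USER_CONFIRMATIONS"] = ""
    return frame


def reload_and_rescore(worksheet: pd.DataFrame, states) -> dict:
    """Apply user-entered confirmation counts to pending records.

    Blank cells count as zero.  Records reaching their requirement move to
    Maintain (medium reliability); the rest are rejected.  Malformed counts
    (non-integer or negative) leave the record pending with a row error.
    Returns {record_id: updated ConfirmationState}.
    """
    by_id = {state.record_id: state for state in states}
    out = {}
    for _, row in worksheet.iterrows():
        record_id = str(row["ID"])
        state = by_id.get(record_id)
        if state is None:
            continue
        raw = row.get("USER_CONFIRMATIONS", "")
        text = "" if raw is None or (isinstance(raw, float) and pd.isna(raw)) else str(raw).strip()
        if text in ("", "nan"):
            count = 0
        else:
            try:
                count = int(float(text)) if float(text).is_integer() else None
            except ValueError:
                count = None
            if count is None or count < 0:
                out[record_id] = replace(
                    state,
                    warnings=state.warnings
                    + (f"invalid confirmation count {text!r}",),
                )
                continue
        total = state.confirmations_found + count
        if total >= state.confirmations_required and _extra_conditions_met(state):
            category = scoring.MAINTAIN
        else:
            category = scoring.REJECT
        out[record_id] = replace(
            state, confirmations_found=total, resolved_category=category
        )
    return out
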