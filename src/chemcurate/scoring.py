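"""Cross-source concordance scoring and Maintain/Check/Reject routing.

For each record, up to four structures are retrieved (CIR and CompTox, each
queried by chemical name and by CAS number).  Their tautomer-insensitive
comparison keys are tallied into an evidence profile of

* E — concordant structures: the largest group of slots sharing one key,
  counted only when it has at least two members or is the sole retrieval
  (a single uncontradicted structure is weak but consistent evidence);
* D — retrieved structures outside that group;
* M — missing or unusable slots,

with E + D + M = 4.  The raw score is

    score = E - 0.2 * D

and is forced to zero when (a) D >= E with at least one discordance, (b) the
two CAS-derived structures disagree (the CAS number is the more reliable
identifier, so a CAS-level conflict is disqualifying), or (c) nothing
concordant was retrieved.  Routing: score >= 3 -> Maintain (4.0 = high
reliability, 3.0 = medium), score = 0 -> Reject, otherwise Check with a
reason that tells the confirmation round what to do.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .resolvers import PRIMARY_SLOTS, IdentifierKind

__all__ = [
    "EvidenceProfile",
    "ScoreResult",
    "count_evidence",
    "raw_score",
    "apply_forcing",
    "classify",
    "score_slots",
    "enumerate_decision_matrix",
    "DISCORDANCE_PENALTY",
]

DISCORDANCE_PENALTY = 0.2

# cas_pair states
CAS_AGREE = "agree"
CAS_DISAGREE = "disagree"
CAS_INCOMPARABLE = "incomparable"

# categories
MAINTAIN = "Maintain"
CHECK = "Check"
REJECT = "Reject"

# reliability grades
RELIABILITY_HIGH = "high"
RELIABILITY_MEDIUM = "medium"
RELIABILITY_NONE = "none"

# check reasons
REASON_VERIFY_NAME = "verify_name"
REASON_NEED_ONE = "need_one_confirmation"
REASON_NEED_TWO = "need_two_confirmations"
REASON_VERIFY_CAS_NEED_ONE = "verify_cas_and_need_one"
REASON_NONE = "none"

CHECK_INSTRUCTIONS = {
    REASON_VERIFY_NAME: "Verify name",
    REASON_NEED_ONE: "Search for at least one confirmation",
    REASON_NEED_TWO: "Search for at least two confirmations",
    REASON_VERIFY_CAS_NEED_ONE: (
        "Verify correctness of CAS; search for at least one confirmation"
    ),
    REASON_NONE: "",
}


@dataclass(frozen=True)
class EvidenceProfile:
    E: int
    D: int
    M: int
    cas_pair: str
    missing_slots: frozenset
    majority_key: str | None

    def __post_init__(self):
        if self.E + self.D + self.M != 4:
            raise ValueError("E + D + M must equal 4 for the primary round")


@dataclass(frozen=True)
class ScoreResult:
    raw_score: float
    final_score: float
    category: str
    reliability: str
    check_reason: str


def count_evidence(slot_keys) -> EvidenceProfile:
    """Tally comparison keys of the four primary slots into (E, D, M).

    ``slot_keys`` maps each primary slot to a comparison key, or None/empty
    for a missing or unusable retrieval.  The concordant class is the largest
    group of slots sharing a key; ties are broken toward the class holding
    more CAS-derived slots (then the lexicographically smallest key).  A
    lone class of size one counts as concordant only when it is the single
    retrieved structure; otherwise every retrieved key is mutually
    discordant and E = 0.
    """
    if set(slot_keys) != set(PRIMARY_SLOTS):
        raise ValueError("exactly the four primary slots are required")
    present = {slot: key for slot, key in slot_keys.items() if key}
    missing = frozenset(slot for slot in PRIMARY_SLOTS if slot not in present)
    m_count = len(missing)

    cas_slots = [s for s in PRIMARY_SLOTS if s.identifier_kind == IdentifierKind.CAS]
    cas_keys = [slot_keys.get(s) or None for s in cas_slots]
    if None in cas_keys:
        cas_pair = CAS_INCOMPARABLE
    elif cas_keys[0] == cas_keys[1]:
        cas_pair = CAS_AGREE
    else:
        cas_pair = CAS_DISAGREE

    if not present:
        return EvidenceProfile(0, 0, 4, cas_pair, missing, None)

    groups: dict = {}
    for slot, key in present.items():
        groups.setdefault(key, []).append(slot)

    def rank(item):
        key, slots = item
        n_cas = sum(1 for s in slots if s.identifier_kind == IdentifierKind.CAS)
        return (-len(slots), -n_cas, key)

    best_key, best_slots = sorted(groups.items(), key=rank)[0]
    if len(best_slots) >= 2 or len(present) == 1:
        e_count = len(best_slots)
        majority = best_key
    else:
        e_count = 0
        majority = None
    d_count = len(present) - e_count
    return EvidenceProfile(e_count, d_count, m_count, cas_pair, missing, majority)


def raw_score(e_count: int, d_count: int,
              penalty: float = DISCORDANCE_PENALTY) -> float:
    """Concordance score: E minus a penalty per discordant structure."""
    if e_count < 0 or d_count < 0 or e_count + d_count > 4:
        raise ValueError("counts must be non-negative with E + D <= 4")
    return e_count - d_count * penalty


def apply_forcing(raw: float, profile: EvidenceProfile) -> float:
    """Force the score to zero on disqualifying evidence patterns."""
    if profile.E == 0:
        return 0.0
    if profile.D >= profile.E and profile.D > 0:
        return 0.0
    if profile.cas_pair == CAS_DISAGREE:
        return 0.0
    return raw


def classify(final: float, profile: EvidenceProfile) -> ScoreResult:
    """Route a scored record to Maintain / Check / Reject.

    Check records get a reason for the confirmation round, driven by which
    slots are missing and whether the CAS pair agrees.
    """
    raw = raw_score(profile.E, profile.D)
    if final >= 3:
        reliability = RELIABILITY_HIGH if final >= 4 else RELIABILITY_MEDIUM
        return ScoreResult(raw, final, MAINTAIN, reliability, REASON_NONE)
    if final == 0:
        return ScoreResult(raw, final, REJECT, RELIABILITY_NONE, REASON_NONE)

    reason = _check_reason(profile)
    return ScoreResult(raw, final, CHECK, RELIABILITY_NONE, reason)


def _check_reason(profile: EvidenceProfile) -> str:
    name_slots = frozenset(
        s for s in PRIMARY_SLOTS if s.identifier_kind == IdentifierKind.NAME
    )
    cas_slots = frozenset(
        s for s in PRIMARY_SLOTS if s.identifier_kind == IdentifierKind.CAS
    )
    if profile.D == 0 and profile.M == 2:
        if profile.missing_slots == name_slots:
            return REASON_VERIFY_NAME
        if profile.missing_slots == cas_slots:
            return REASON_VERIFY_CAS_NEED_ONE
        return REASON_NEED_ONE
    if profile.E == 1 and profile.M == 3:
        return REASON_NEED_TWO
    if profile.D == 1:
        # E=3,M=0 (one discordant name) or E=2,M=1; CAS agreement means the
        # doubt concerns the name, otherwise one more retrieval must decide.
        if profile.cas_pair == CAS_AGREE:
            return REASON_VERIFY_NAME
        return REASON_NEED_ONE
    return REASON_NEED_ONE


def score_slots(slot_keys) -> tuple:
    """Convenience: slot keys -> (EvidenceProfile, ScoreResult)."""
    profile = count_evidence(slot_keys)
    raw = raw_score(profile.E, profile.D)
    final = apply_forcing(raw, profile)
    return profile, classify(final, profile)


# --------------------------------------------------------------------------
# exhaustive enumeration of the decision matrix

_OUTCOMES = ("correct", "wrong", "missing")


def _slot_key_assignments():
    """Yield every distinguishable assignment of the four primary slots.

    Each slot is either concordant with the truth key ("T"), discordant with
    everything else (a unique key per slot), or missing.  This spans every
    reachable (E, D, M, cas_pair, missing-subset) combination.
    """
    for combo in product(_OUTCOMES, repeat=4):
        keys = {}
        for i, (slot, outcome) in enumerate(zip(PRIMARY_SLOTS, combo)):
            if outcome == "correct":
                keys[slot] = "T"
            elif outcome == "wrong":
                keys[slot] = f"W{i}"
            else:
                keys[slot] = None
        yield combo, keys


def enumerate_decision_matrix():
    """Classify every reachable evidence pattern of the four primary slots.

    Returns a list of dicts (one per distinguishable slot assignment) with
    the profile, scores, category and check reason — a machine-readable
    superset of the published decision table.
    """
    rows = []
    for combo, keys in _slot_key_assignments():
        profile, result = score_slots(keys)
        rows.append(
            {
                "slots": tuple(
                    f"{slot}:{outcome}"
                    for slot, outcome in zip(PRIMARY_SLOTS, combo)
                ),
                "E": profile.E,
                "D": profile.D,
                "M": profile.M,
                "cas_pair": profile.cas_pair,
                "missing_slots": tuple(sorted(str(s) for s in profile.missing_slots)),
                "raw_score": result.raw_score,
                "final_score": result.final_score,
                "category": result.category,
                "reliability": result.reliability,
                "check_reason": result.check_reason,
            }
        )
    return rows


def decision_matrix_table():
    """Distinct (E, D, M, cas_pair, reason) rows as a pandas DataFrame."""
    import pandas as pd

    rows = enumerate_decision_matrix()
    df = pd.DataFrame(rows).drop(columns=["slots", "missing_slots"])
    df = (
        df.drop_duplicates()
        .sort_values(["E", "D", "M", "cas_pair", "check_reason"],
                     ascending=[False, True, True, True, True])
        .reset_index(drop=True)
    )
    return df
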