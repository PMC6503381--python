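"""CAS registry number normalization/validation and chemical-name triage.

A CAS registry number has the form ``N{2,7}-NN-N``; the final digit is a
weighted-sum checksum over the first two digit groups.  User-supplied CAS
strings are normalized (leading zeros stripped from the first group, stray
characters removed) with every anomaly recorded as a flag rather than an
error, so that downstream routing — not parsing — decides a record's fate.

Chemical names are screened for keywords that mark substances without a
single defined structure (mixtures, polymers, UVCBs, reaction masses, ...).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "CasNumber",
    "NameTriage",
    "cas_check_digit",
    "normalize_cas",
    "validate_cas",
    "triage_name",
    "KeywordRules",
    "load_keyword_rules",
]

_CAS_PATTERN = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")

# anomaly flags
LEADING_ZEROS_REMOVED = "leading_zeros_removed"
UNEXPECTED_CHARACTERS = "unexpected_characters"
MALFORMED = "malformed"


@dataclass(frozen=True)
class CasNumber:
    """A normalized CAS registry number with validation state."""

    body: str  # digits of the first two hyphen-separated groups
    check_digit: str  # single digit, empty if malformed
    normalized: str  # canonical "group1-group2-check" string
    checksum_valid: bool
    anomaly_flags: frozenset = field(default_factory=frozenset)

    @property
    def malformed(self) -> bool:
        return MALFORMED in self.anomaly_flags

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.normalized


def cas_check_digit(body: str) -> int:
    """Weighted-sum check digit for a CAS body (groups one and two, no hyphens).

    Digits are weighted 1, 2, 3, ... counting from the rightmost digit of the
    body leftwards; the check digit is the weighted sum modulo 10.
    """
    if not body.isdigit() or not (4 <= len(body) <= 9):
        raise ValueError(f"CAS body must be 4-9 digits, got {body!r}")
    return sum(int(d) * w for w, d in enumerate(reversed(body), start=1)) % 10


def normalize_cas(cas_raw: str) -> CasNumber:
    """Normalize a free-text CAS string, flagging every anomaly found.

    Leading zeros are removed from the first digit group; characters other
    than digits and hyphens are stripped and flagged; strings that cannot be
    coerced to the registry pattern are flagged ``malformed``.  No exception
    is ever raised: the flags let the scoring stage route the record.
    """
    flags = set()
    text = (cas_raw or "").strip()
    cleaned = re.sub(r"[^0-9\-]", "", text)
    if cleaned != text:
        flags.add(UNEXPECTED_CHARACTERS)

    groups = [g for g in cleaned.split("-") if g != ""]
    if len(groups) != 3 or not all(g.isdigit() for g in groups):
        flags.add(MALFORMED)
        return CasNumber(
            body="",
            check_digit="",
            normalized=cleaned,
            checksum_valid=False,
            anomaly_flags=frozenset(flags),
        )

    g1, g2, g3 = groups
    stripped = g1.lstrip("0") or "0"
    if stripped != g1:
        flags.add(LEADING_ZEROS_REMOVED)
    g1 = stripped

    normalized = f"{g1}-{g2}-{g3}"
    if not _CAS_PATTERN.match(normalized):
        flags.add(MALFORMED)
        return CasNumber(
            body="",
            check_digit="",
            normalized=normalized,
            checksum_valid=False,
            anomaly_flags=frozenset(flags),
        )

    body = g1 + g2
    valid = cas_check_digit(body) == int(g3)
    return CasNumber(
        body=body,
        check_digit=g3,
        normalized=normalized,
        checksum_valid=valid,
        anomaly_flags=frozenset(flags),
    )


def validate_cas(cas: CasNumber) -> bool:
    """True iff the stored check digit equals the recomputed one."""
    if cas.malformed:
        return False
    return cas_check_digit(cas.body) == int(cas.check_digit)


# --------------------------------------------------------------------------
# name triage

DISPOSITION_CLEAN = "clean"
DISPOSITION_REMOVE = "remove"
DISPOSITION_MANUAL = "manual_check"
DISPOSITION_KEEP_FLAGGED = "keep_flagged"


@dataclass(frozen=True)
class NameTriage:
    keywords_hit: frozenset
    disposition: str


@dataclass(frozen=True)
class KeywordRules:
    """Keyword table driving name triage.

    Each entry is (keyword, word_boundary).  ``remove`` keywords mark
    substances with no single structure; ``manual`` keywords mark names that
    need a human look; an ``isomer`` hit combined with a ``remove``-class
    "mixture" hit is kept (stereochemistry is stripped upstream, so isomeric
    mixtures collapse to one structure).
    """

    remove: tuple
    manual: tuple
    isomer: tuple


_DEFAULT_RULES_FILE = "keywords.txt"


def load_keyword_rules(path: str | Path | None = None) -> KeywordRules:
    """Load triage keywords from a plain-text config file.

    Format: one rule per line, ``category<TAB>keyword<TAB>word_boundary``
    where category is remove/manual/isomer and word_boundary is 0 or 1.
    Blank lines and ``#`` comments are ignored.
    """
    if path is None:
        text = (
            resources.files("chemcurate")
            .joinpath("data", _DEFAULT_RULES_FILE)
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    buckets = {"remove": [], "manual": [], "isomer": []}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        category, keyword, boundary = line.split("\t")
        buckets[category].append((keyword.casefold(), boundary == "1"))
    return KeywordRules(
        remove=tuple(buckets["remove"]),
        manual=tuple(buckets["manual"]),
        isomer=tuple(buckets["isomer"]),
    )


_DEFAULT_RULES: KeywordRules | None = None


def _default_rules() -> KeywordRules:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_keyword_rules()
    return _DEFAULT_RULES


def _match(name: str, keyword: str, boundary: bool) -> bool:
    if boundary:
        return re.search(rf"\b{re.escape(keyword)}\b", name) is not None
    return keyword in name


def triage_name(name: str, rules: KeywordRules | None = None) -> NameTriage:
    """Screen a chemical name for problem keywords.

    Matching is case-insensitive and substring-based on a
    whitespace-normalized name; "product(s)" and "isomer(s)" are anchored at
    word boundaries so they do not fire inside longer words.
    """
    rules = rules or _default_rules()
    folded = re.sub(r"\s+", " ", (name or "").casefold()).strip()

    hits = set()
    remove_hit = manual_hit = isomer_hit = False
    for kw, boundary in rules.remove:
        if _match(folded, kw, boundary):
            hits.add(kw)
            remove_hit = True
    for kw, boundary in rules.manual:
        if _match(folded, kw, boundary):
            hits.add(kw)
            manual_hit = True
    for kw, boundary in rules.isomer:
        if _match(folded, kw, boundary):
            hits.add(kw)
            isomer_hit = True

    if isomer_hit:
        disposition = DISPOSITION_KEEP_FLAGGED
    elif remove_hit:
        disposition = DISPOSITION_REMOVE
    elif manual_hit:
        disposition = DISPOSITION_MANUAL
    else:
        disposition = DISPOSITION_CLEAN
    return NameTriage(keywords_hit=frozenset(hits), disposition=disposition)
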