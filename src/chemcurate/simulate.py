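"""Synthetic multi-source registries with controlled error structure.

Public chemical registries disagree through random compilation errors: a
source may hold no entry for an identifier, hold a structurally wrong entry,
or hold the right structure under a corrupted name key.  The generator
reproduces exactly that phenomenology so the whole pipeline can run offline:

* a truth set of drug-like molecules (from a curated template library) with
  valid-by-construction CAS numbers and unique names; configurable fractions
  of the records are salts, stereo-labelled structures, alternative tautomer
  spellings, mixtures-by-name and organometallics;
* four source tables (CIR, CompTox, PubChem, ChemIDplus) derived from the
  truth set under a :class:`NoiseModel` — per (record, slot) a structure is
  independently missing with ``p_missing`` or replaced by a different
  molecule with ``p_wrong_structure``; per (record, source) the stored name
  key is corrupted with ``p_name_typo`` (so name lookups miss);
* an exact routing oracle: because wrong structures are drawn distinct per
  record (and never share the victim's comparison key), the Maintain/Check/
  Reject probabilities follow from enumerating the 3^4 per-slot outcomes.

Default rates emulate a well-documented pharmaceutical dataset: small error
and missingness rates, no mixtures or organometallics.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from rdkit import Chem

from .identifiers import CasNumber, cas_check_digit, normalize_cas
from .resolvers import Source, IdentifierKind
from .scoring import (
    CHECK,
    MAINTAIN,
    REJECT,
    apply_forcing,
    classify,
    count_evidence,
    raw_score,
)
from .resolvers import PRIMARY_SLOTS
from .structures import standardize

__all__ = [
    "TruthEntry",
    "NoiseModel",
    "load_templates",
    "generate_truth_set",
    "generate_registry",
    "expected_routing_fractions",
    "DEFAULT_COMPOSITION",
]

DEFAULT_COMPOSITION = {
    "salt": 0.15,
    "stereo": 0.15,
    "tautomer": 0.05,
    "mixture": 0.0,
    "organometallic": 0.0,
}


@dataclass(frozen=True)
class TruthEntry:
    name: str
    cas: CasNumber
    smiles: str
    alt_smiles: str  # alternative spelling (tautomer) or "" when none
    kind: str  # plain | salt | stereo | tautomer | mixture | organometallic
    comparison_key: str


@dataclass(frozen=True)
class NoiseModel:
    """Per-slot corruption rates of the synthetic registries."""

    p_wrong_structure: float = 0.05
    p_missing: float = 0.10
    p_name_typo: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("p_wrong_structure", "p_missing", "p_name_typo"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class _Template:
    name: str
    cls: str
    smiles: str
    alt_smiles: str = ""


def load_templates():
    text = (
        resources.files("chemcurate")
        .joinpath("data", "templates.smi")
        .read_text(encoding="utf-8")
    )
    templates = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        name, cls, smiles = parts[:3]
        alt = parts[3] if len(parts) > 3 else ""
        templates.append(_Template(name, cls, smiles, alt))
    return templates


def _random_cas(rng: random.Random, taken: set) -> CasNumber:
    while True:
        g1 = str(rng.randint(10, 9_999_999))
        g2 = f"{rng.randint(0, 99):02d}"
        body = g1 + g2
        check = cas_check_digit(body)
        normalized = f"{g1}-{g2}-{check}"
        if normalized not in taken:
            taken.add(normalized)
            return normalize_cas(normalized)


def _sodium_salt(smiles: str) -> str | None:
    """Deprotonate the first carboxylic acid and pair it with Na+."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    match = mol.GetSubstructMatches(Chem.MolFromSmarts("C(=O)[OX2H1]"))
    if not match:
        return None
    rw = Chem.RWMol(mol)
    o_atom = rw.GetAtomWithIdx(match[0][2])
    o_atom.SetFormalCharge(-1)
    o_atom.SetNumExplicitHs(0)
    Chem.SanitizeMol(rw)
    return Chem.MolToSmiles(rw) + ".[Na+]"


def generate_truth_set(n: int, composition: dict | None = None,
                       seed: int = 0):
    """Deterministically build ``n`` truth entries for a given seed.

    Composition fractions select how many records are salts, stereo-labelled
    structures, tautomer-spelling pairs, mixtures-by-name or organometallics;
    the remainder are plain organics.  CAS check digits are computed, never
    guessed, so the whole truth set passes checksum validation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    composition = dict(DEFAULT_COMPOSITION, **(composition or {}))
    if sum(composition.values()) > 1.0 + 1e-9:
        raise ValueError("composition fractions must sum to at most 1")
    rng = random.Random(seed)
    templates = load_templates()
    by_class: dict = {}
    for t in templates:
        by_class.setdefault(t.cls, []).append(t)
    acids = by_class.get("acid", [])
    bases = by_class.get("base", [])
    stereo = by_class.get("stereo", [])
    tautomer = by_class.get("tautomer", [])
    organometallic = by_class.get("organometallic", [])
    organics = (
        by_class.get("organic", []) + acids + bases
    )

    counts = {k: int(round(composition[k] * n)) for k in composition}
    kinds = (
        ["salt"] * counts["salt"]
        + ["stereo"] * counts["stereo"]
        + ["tautomer"] * counts["tautomer"]
        + ["mixture"] * counts["mixture"]
        + ["organometallic"] * counts["organometallic"]
    )
    kinds += ["plain"] * (n - len(kinds))
    rng.shuffle(kinds)

    taken_cas: set = set()
    entries = []
    key_cache: dict = {}

    def key_of(smiles: str) -> str:
        if smiles not in key_cache:
            key_cache[smiles] = standardize(smiles).comparison_key
        return key_cache[smiles]

    for i, kind in enumerate(kinds):
        alt = ""
        if kind == "salt":
            template = rng.choice(acids + bases)
            if template in acids:
                smiles = _sodium_salt(template.smiles) or template.smiles + ".Cl"
            else:
                smiles = template.smiles + ".Cl"
            name = f"{template.name} sodium salt-{i:05d}" if template in acids else (
                f"{template.name} hydrochloride-{i:05d}"
            )
        elif kind == "stereo":
            template = rng.choice(stereo)
            smiles = template.smiles
            name = f"{template.name}-{i:05d}"
        elif kind == "tautomer":
            template = rng.choice(tautomer)
            smiles, alt = template.smiles, template.alt_smiles
            name = f"{template.name}-{i:05d}"
        elif kind == "mixture":
            a, b = rng.sample(organics, 2)
            smiles = f"{a.smiles}.{b.smiles}"
            name = f"mixture of {a.name} and {b.name}-{i:05d}"
        elif kind == "organometallic":
            template = rng.choice(organometallic + by_class.get("inorganic", []))
            smiles = template.smiles
            name = f"{template.name}-{i:05d}"
        else:
            template = rng.choice(organics)
            smiles = template.smiles
            name = f"{template.name}-{i:05d}"
        entries.append(
            TruthEntry(
                name=name,
                cas=_random_cas(rng, taken_cas),
                smiles=smiles,
                alt_smiles=alt,
                kind=kind,
                comparison_key=key_of(smiles),
            )
        )
    return entries


_SOURCES = (Source.CIR, Source.COMPTOX, Source.PUBCHEM, Source.CHEMID)
_FILENAMES = {
    Source.CIR: "cir.tsv",
    Source.COMPTOX: "comptox.tsv",
    Source.PUBCHEM: "pubchem.tsv",
    Source.CHEMID: "chemid.tsv",
}
# Sources holding the alternative tautomer spelling when one exists.
_ALT_SPELLING_SOURCES = (Source.COMPTOX, Source.CHEMID)


def _spelling(entry: TruthEntry, source: Source) -> str:
    if entry.alt_smiles and source in _ALT_SPELLING_SOURCES:
        return entry.alt_smiles
    return entry.smiles


def generate_registry(truth, noise: NoiseModel, directory: str | Path,
                      slot_mask=None) -> Path:
    """Write noisy fixture registries (4 source TSVs + synonym table).

    Per (record, slot) the entry is independently missing with ``p_missing``,
    else wrong with ``p_wrong_structure``; wrong structures are drawn from
    other truth entries with a *different* comparison key and are distinct
    across the record's slots, so every wrong retrieval is discordant with
    every other slot.  Per (record, source) the stored name key is corrupted
    with ``p_name_typo``.  ``slot_mask`` (optional set of (Source,
    IdentifierKind)) restricts the noise to selected slots; unmasked slots
    are error-free.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = random.Random(noise.seed)
    rows = {source: [] for source in _SOURCES}
    synonym_rows = []

    distinct_keys: dict = {}
    for entry in truth:
        distinct_keys.setdefault(entry.comparison_key, entry)

    def wrong_pool(entry: TruthEntry):
        pool = [e for k, e in sorted(distinct_keys.items()) if k != entry.comparison_key]
        rng.shuffle(pool)
        return pool

    for entry in truth:
        pool = wrong_pool(entry)
        wrong_iter = iter(pool)
        for source in _SOURCES:
            name_key = entry.name
            if rng.random() < noise.p_name_typo:
                name_key = entry.name + "~typo"
            for kind in (IdentifierKind.NAME, IdentifierKind.CAS):
                masked = slot_mask is None or (source, kind) in slot_mask
                u_missing = rng.random()
                u_wrong = rng.random()
                if masked and u_missing < noise.p_missing:
                    continue
                if masked and u_wrong < noise.p_wrong_structure:
                    try:
                        other = next(wrong_iter)
                    except StopIteration:  # tiny truth sets: reuse the pool
                        wrong_iter = iter(wrong_pool(entry))
                        other = next(wrong_iter)
                    smiles = other.smiles
                else:
                    smiles = _spelling(entry, source)
                identifier = (
                    name_key if kind == IdentifierKind.NAME else entry.cas.normalized
                )
                rows[source].append((kind.value, identifier, smiles))
        synonym_rows.append((entry.cas.normalized, entry.name))
        synonym_rows.append((entry.cas.normalized, entry.name.upper()))

    for source in _SOURCES:
        path = directory / _FILENAMES[source]
        with path.open("w", encoding="utf-8") as fh:
            fh.write("IDENTIFIER_KIND\tIDENTIFIER\tSMILES\n")
            for kind, identifier, smiles in rows[source]:
                fh.write(f"{kind}\t{identifier}\t{smiles}\n")
    with (directory / "synonyms.tsv").open("w", encoding="utf-8") as fh:
        fh.write("CAS\tSYNONYM\n")
        for cas, synonym in synonym_rows:
            fh.write(f"{cas}\t{synonym}\n")
    return directory


def expected_routing_fractions(noise: NoiseModel, slot_mask=None) -> dict:
    """Exact first-pass routing probabilities under a noise model.

    Enumerates the 3^4 per-slot outcome combinations (correct / wrong /
    missing), maps each through the real evidence-counting and scoring
    functions (correct slots share the truth key, wrong slots carry unique
    keys, matching the generator's guarantees) and weights by probability.
    Name slots miss additionally through name-key typos.
    """
    from itertools import product

    def slot_probs(slot):
        masked = slot_mask is None or (slot.source, slot.identifier_kind) in slot_mask
        p_missing = noise.p_missing if masked else 0.0
        p_wrong = noise.p_wrong_structure if masked else 0.0
        if slot.identifier_kind == IdentifierKind.NAME:
            p_missing = p_missing + (1.0 - p_missing) * noise.p_name_typo
        p_miss_total = p_missing
        p_wrong_total = (1.0 - p_miss_total) * p_wrong
        p_correct = 1.0 - p_miss_total - p_wrong_total
        return {"correct": p_correct, "wrong": p_wrong_total, "missing": p_miss_total}

    probs = {slot: slot_probs(slot) for slot in PRIMARY_SLOTS}
    totals = {MAINTAIN: 0.0, CHECK: 0.0, REJECT: 0.0}
    for combo in product(("correct", "wrong", "missing"), repeat=4):
        weight = 1.0
        keys = {}
        for i, (slot, outcome) in enumerate(zip(PRIMARY_SLOTS, combo)):
            weight *= probs[slot][outcome]
            keys[slot] = {"correct": "T", "wrong": f"W{i}", "missing": None}[outcome]
        if weight == 0.0:
            continue
        profile = count_evidence(keys)
        final = apply_forcing(raw_score(profile.E, profile.D), profile)
        totals[classify(final, profile).category] += weight
    return totals
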