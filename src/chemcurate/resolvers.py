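"""Identifier-to-structure resolution against pluggable backends.

Four public services are modeled: CIR (CACTUS), the CompTox dashboard,
PubChem and ChemIDplus, each queried by chemical name and by CAS number.
CIR and CompTox form the primary round (four slots per record); PubChem and
ChemIDplus are the secondary round used to confirm doubtful records.

The test suite and offline runs use a fixture backend reading plain TSV
registries; live HTTP adapters (stdlib urllib, conservative throttling) share
the same contract and are exercised only when explicitly configured.
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .identifiers import CasNumber

__all__ = [
    "Source",
    "IdentifierKind",
    "SourceSlot",
    "ResolvedStructure",
    "SynonymList",
    "PRIMARY_SLOTS",
    "SECONDARY_SLOTS",
    "FixtureBackend",
    "LiveBackend",
    "ResolverGateway",
    "BackendError",
]


class Source(str, Enum):
    CIR = "CIR"
    COMPTOX = "COMPTOX"
    PUBCHEM = "PUBCHEM"
    CHEMID = "CHEMID"


class IdentifierKind(str, Enum):
    NAME = "NAME"
    CAS = "CAS"


@dataclass(frozen=True)
class SourceSlot:
    source: Source
    identifier_kind: IdentifierKind

    def __str__(self) -> str:
        return f"{self.source.value}_{self.identifier_kind.value}"


PRIMARY_SLOTS = (
    SourceSlot(Source.CIR, IdentifierKind.NAME),
    SourceSlot(Source.CIR, IdentifierKind.CAS),
    SourceSlot(Source.COMPTOX, IdentifierKind.NAME),
    SourceSlot(Source.COMPTOX, IdentifierKind.CAS),
)

SECONDARY_SLOTS = (
    SourceSlot(Source.PUBCHEM, IdentifierKind.NAME),
    SourceSlot(Source.PUBCHEM, IdentifierKind.CAS),
    SourceSlot(Source.CHEMID, IdentifierKind.NAME),
    SourceSlot(Source.CHEMID, IdentifierKind.CAS),
)

STATUS_FOUND = "found"
STATUS_MISSING = "missing"
STATUS_ERROR = "error"


@dataclass(frozen=True)
class ResolvedStructure:
    slot: SourceSlot
    query: str
    smiles_raw: str | None
    status: str
    message: str = ""

    @property
    def found(self) -> bool:
        return self.status == STATUS_FOUND


@dataclass(frozen=True)
class SynonymList:
    cas: CasNumber
    synonyms: tuple


class BackendError(RuntimeError):
    """Raised by backends on infrastructure failure (mapped to status=error)."""


class FixtureBackend:
    """Offline registry backend reading one TSV per source.

    ``<dir>/{cir,comptox,pubchem,chemid}.tsv`` with columns
    IDENTIFIER_KIND, IDENTIFIER, SMILES, and ``<dir>/synonyms.tsv`` with
    columns CAS, SYNONYM.  Name keys are matched case-insensitively; lookups
    are pure (no hidden state).
    """

    _FILES = {
        Source.CIR: "cir.tsv",
        Source.COMPTOX: "comptox.tsv",
        Source.PUBCHEM: "pubchem.tsv",
        Source.CHEMID: "chemid.tsv",
    }

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self._tables: dict = {}
        self._synonyms: dict = {}
        for source, fname in self._FILES.items():
            table = {}
            path = self.directory / fname
            if path.exists():
                with path.open(newline="", encoding="utf-8") as fh:
                    for row in csv.DictReader(fh, delimiter="\t"):
                        kind = IdentifierKind(row["IDENTIFIER_KIND"])
                        key = self._norm(kind, row["IDENTIFIER"])
                        table[(kind, key)] = row["SMILES"]
            self._tables[source] = table
        syn_path = self.directory / "synonyms.tsv"
        if syn_path.exists():
            with syn_path.open(newline="", encoding="utf-8") as fh:
                for row in csv.DictReader(fh, delimiter="\t"):
                    self._synonyms.setdefault(row["CAS"], []).append(row["SYNONYM"])

    @staticmethod
    def _norm(kind: IdentifierKind, identifier: str) -> str:
        ident = identifier.strip()
        return ident.casefold() if kind == IdentifierKind.NAME else ident

    def lookup(self, source: Source, kind: IdentifierKind, identifier: str):
        return self._tables[source].get((kind, self._norm(kind, identifier)))

    def synonyms(self, cas_normalized: str):
        return list(self._synonyms.get(cas_normalized, []))


class LiveBackend:  # pragma: no cover - requires network, not used in tests
    """Thin HTTP adapter for the four public REST services.

    Endpoint templates are configurable; a fixed delay between calls keeps
    request rates conservative.  Shares the FixtureBackend contract.
    """

    DEFAULT_ENDPOINTS = {
        (Source.CIR, IdentifierKind.NAME): (
            "https://cactus.nci.nih.gov/chemical/structure/{query}/smiles"
        ),
        (Source.CIR, IdentifierKind.CAS): (
            "https://cactus.nci.nih.gov/chemical/structure/{query}/smiles"
        ),
        (Source.PUBCHEM, IdentifierKind.NAME): (
            "https://pubchem.ncbi.nlm.nih.gov/rest/pug/compound/name/"
            "{query}/property/CanonicalSMILES/TXT"
        ),
        (Source.PUBCHEM, IdentifierKind.CAS): (
            "https://pubchem.ncbi.nlm.nih.gov/rest/pug/compound/name/"
            "{query}/property/CanonicalSMILES/TXT"
        ),
    }

    def __init__(self, endpoints=None, timeout: float = 15.0, delay: float = 1.0,
                 retries: int = 2):
        self.endpoints = dict(self.DEFAULT_ENDPOINTS)
        if endpoints:
            self.endpoints.update(endpoints)
        self.timeout = timeout
        self.delay = delay
        self.retries = retries

    def lookup(self, source: Source, kind: IdentifierKind, identifier: str):
        import urllib.error
        import urllib.parse
        import urllib.request

        template = self.endpoints.get((source, kind))
        if template is None:
            raise BackendError(f"no endpoint configured for {source}/{kind}")
        url = template.format(query=urllib.parse.quote(identifier))
        last_err = None
        for _ in range(self.retries + 1):
            time.sleep(self.delay)
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    text = resp.read().decode("utf-8").strip()
                return text.splitlines()[0] if text else None
            except urllib.error.HTTPError as err:
                if err.code == 404:
                    return None
                last_err = err
            except Exception as err:  # noqa: BLE001 - mapped to status=error
                last_err = err
        raise BackendError(str(last_err))

    def synonyms(self, cas_normalized: str):
        import json
        import urllib.parse
        import urllib.request

        url = (
            "https://pubchem.ncbi.nlm.nih.gov/rest/pug/compound/name/"
            f"{urllib.parse.quote(cas_normalized)}/synonyms/JSON"
        )
        time.sleep(self.delay)
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                payload = json.load(resp)
            info = payload["InformationList"]["Information"][0]
            return list(info.get("Synonym", []))
        except Exception as err:  # noqa: BLE001
            raise BackendError(str(err)) from err


@dataclass
class ResolverGateway:
    """Resolution front-end with a per-run (slot, identifier) cache."""

    backend: object
    _cache: dict = field(default_factory=dict)
    calls_attempted: int = 0

    def resolve(self, slot: SourceSlot, identifier: str) -> ResolvedStructure:
        """Resolve one identifier through one (source, kind) slot.

        Backend failures map to status=error; absent entries to
        status=missing.  Results are cached per run.
        """
        key = (slot, identifier)
        if key in self._cache:
            return self._cache[key]
        self.calls_attempted += 1
        try:
            smiles = self.backend.lookup(slot.source, slot.identifier_kind, identifier)
        except BackendError as err:
            result = ResolvedStructure(slot, identifier, None, STATUS_ERROR, str(err))
        else:
            if smiles:
                result = ResolvedStructure(slot, identifier, smiles, STATUS_FOUND)
            else:
                result = ResolvedStructure(slot, identifier, None, STATUS_MISSING)
        self._cache[key] = result
        return result

    def _resolve_slots(self, slots, name: str, cas_normalized: str):
        out = {}
        for slot in slots:
            identifier = (
                name if slot.identifier_kind == IdentifierKind.NAME else cas_normalized
            )
            if not identifier:
                out[slot] = ResolvedStructure(slot, "", None, STATUS_MISSING)
            else:
                out[slot] = self.resolve(slot, identifier)
        return out

    def resolve_primary(self, name: str, cas_normalized: str):
        """The four primary slots: CIR and CompTox, each by name and CAS.

        Empty identifiers yield status=missing without a backend call.
        Checksum-invalid CAS strings are still queried (the warning is
        carried by the record and enforced at scoring time).
        """
        return self._resolve_slots(PRIMARY_SLOTS, name, cas_normalized)

    def resolve_secondary(self, name: str, cas_normalized: str):
        """The four secondary confirmation slots: PubChem and ChemIDplus."""
        return self._resolve_slots(SECONDARY_SLOTS, name, cas_normalized)

    def fetch_synonyms(self, cas: CasNumber) -> SynonymList:
        """Verbatim synonym list for a CAS number; empty on miss or error."""
        if cas.malformed:
            return SynonymList(cas=cas, synonyms=())
        try:
            syns = self.backend.synonyms(cas.normalized)
        except BackendError:
            syns = []
        return SynonymList(cas=cas, synonyms=tuple(syns))
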