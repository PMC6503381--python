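"""Structure cleaning and standardization of retrieved SMILES.

Every SMILES coming back from a resolver is put through a fixed pipeline:

1. fragment splitting — the main molecule is the fragment of highest
   molecular weight, everything else is a counterion (kept, never discarded);
2. neutralization — protonation-state adjustment only (O/N/S anions gain a
   proton, protonated amines lose one); permanently charged centers such as
   quaternary ammonium stay charged and are flagged;
3. stereochemistry stripping — tetrahedral and double-bond descriptors are
   cleared on the molecular graph (2D QSAR descriptors ignore them);
4. element filter — only H, C, N, O, F, Br, I, Cl, P, S are allowed;
   carbon-free structures are additionally flagged inorganic;
5. key generation — layered InChI identifiers truncated at different depths
   give a tautomer-insensitive comparison key and a coarser deduplication
   key;
6. canonical kekulized serialization for the QSAR-ready output.

All functions are pure string -> value; parse failures are encoded as flags,
never raised, so a bad SMILES degrades to "missing evidence" downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "StandardizedStructure",
    "LayeredIdentifier",
    "split_fragments",
    "neutralize",
    "strip_stereo",
    "element_filter",
    "layered_identifier",
    "comparison_key",
    "dedup_key",
    "canonicalize_kekulized",
    "standardize",
    "ALLOWED_ELEMENTS",
]

# flags
PARSE_ERROR = "parse_error"
NEUTRALIZATION_FAILED = "neutralization_failed"
METALLIC_COUNTERION = "metallic_counterion"
ORGANIC_COUNTERION = "organic_counterion"
DIMER = "dimer"
STEREO_STRIPPED = "stereo_stripped"
UNUSUAL_ELEMENT = "unusual_element"
INORGANIC = "inorganic"
MW_TIE = "mw_tie"
KEKULIZE_FAILED = "kekulize_failed"

ALLOWED_ELEMENTS = frozenset(["H", "C", "N", "O", "F", "Br", "I", "Cl", "P", "S"])

# Atomic numbers considered non-metallic; anything else (metals and
# metalloids such as B, Si, As) marks a counterion as metallic.
_NONMETALS = frozenset([1, 2, 6, 7, 8, 9, 10, 15, 16, 17, 18, 34, 35, 36, 53, 54, 86])


@dataclass
class LayeredIdentifier:
    """A layered canonical structure identifier (standard InChI string)."""

    full: str
    layers: list

    @classmethod
    def from_string(cls, inchi: str) -> "LayeredIdentifier":
        return cls(full=inchi, layers=inchi.split("/"))


@dataclass
class StandardizedStructure:
    """Result of the full cleaning pipeline on one retrieved SMILES."""

    smiles_original: str
    main_fragment: str = ""
    candidate_mains: list = field(default_factory=list)
    neutralized: str = ""
    counterions: list = field(default_factory=list)
    flags: set = field(default_factory=set)
    comparison_key: str = ""
    dedup_key: str = ""
    canonical_kekulized: str = ""

    @property
    def usable(self) -> bool:
        """Usable as structural evidence (parsed and keyed)."""
        return PARSE_ERROR not in self.flags and bool(self.comparison_key)


def _parse(smiles: str):
    if not smiles:
        return None
    return Chem.MolFromSmiles(smiles)


def split_fragments(smiles: str):
    """Split a multi-fragment SMILES into (main, counterions, flags).

    The main molecule is the fragment with the highest molecular weight.  A
    counterion identical to the main fragment marks the record a dimer; a tie
    in molecular weight between non-identical fragments is flagged for manual
    review (the lexicographically smallest canonical SMILES is kept as main
    so the pipeline stays deterministic).
    """
    flags = set()
    mol = _parse(smiles)
    if mol is None:
        return "", [], {PARSE_ERROR}
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return Chem.MolToSmiles(frags[0]), [], flags

    weighted = sorted(
        ((round(Descriptors.MolWt(f), 4), Chem.MolToSmiles(f)) for f in frags),
        key=lambda t: (-t[0], t[1]),
    )
    top_mw = weighted[0][0]
    candidates = sorted({smi for mw, smi in weighted if mw == top_mw})
    main = candidates[0]
    if len(candidates) > 1:
        flags.add(MW_TIE)

    counterions = []
    main_taken = False
    for _, smi in weighted:
        if smi == main and not main_taken:
            main_taken = True
            continue
        counterions.append(smi)

    main_mol = Chem.MolFromSmiles(main)
    for ion in counterions:
        ion_mol = Chem.MolFromSmiles(ion)
        if ion == main:
            flags.add(DIMER)
        if ion_mol is None:
            continue
        atoms = {a.GetAtomicNum() for a in ion_mol.GetAtoms()}
        if any(z not in _NONMETALS for z in atoms):
            flags.add(METALLIC_COUNTERION)
        if 6 in atoms:
            flags.add(ORGANIC_COUNTERION)
    return main, counterions, flags


_NEG_NOS = Chem.MolFromSmarts("[#7,#8,#16;-1;!$([*]~[+1,+2,+3,+4])]")
_POS_NH = Chem.MolFromSmarts("[#7;+1;!h0;!$([*]~[-1,-2,-3,-4])]")


def neutralize(smiles: str):
    """Neutralize a single-fragment SMILES by protonation-state change only.

    O-, S- and N- anions gain a hydrogen; N+ centers carrying a hydrogen
    lose one.  Charge-separated ylides and permanently charged centers
    (quaternary N, charged carbon/phosphorus) are left untouched; success is
    True iff the result has zero net formal charge.
    """
    mol = _parse(smiles)
    if mol is None:
        return "", False
    mol = Chem.RWMol(mol)
    for match in mol.GetSubstructMatches(_NEG_NOS):
        atom = mol.GetAtomWithIdx(match[0])
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
        atom.UpdatePropertyCache()
    for match in mol.GetSubstructMatches(_POS_NH):
        atom = mol.GetAtomWithIdx(match[0])
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(max(atom.GetTotalNumHs() - 1, 0))
        atom.UpdatePropertyCache()
    Chem.SanitizeMol(mol)
    out = Chem.MolToSmiles(mol)
    net_charge = sum(a.GetFormalCharge() for a in mol.GetAtoms())
    return out, net_charge == 0


def strip_stereo(smiles: str):
    """Remove stereochemistry from the molecular graph.

    Operates on the parsed structure (clearing chiral tags and bond stereo)
    and re-serializes; returns (flat SMILES, had_stereo).
    """
    mol = _parse(smiles)
    if mol is None:
        return "", False
    had = any(
        a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED for a in mol.GetAtoms()
    ) or any(
        b.GetStereo() != Chem.BondStereo.STEREONONE
        or b.GetBondDir()
        in (Chem.BondDir.ENDUPRIGHT, Chem.BondDir.ENDDOWNRIGHT)
        for b in mol.GetBonds()
    )
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol), had


def element_filter(smiles: str):
    """Check the ten-element whitelist; returns (passed, flags).

    Structures containing any element outside {H,C,N,O,F,Br,I,Cl,P,S} fail
    with an ``unusual_element`` flag; carbon-free structures are flagged
    ``inorganic`` and also fail.
    """
    mol = _parse(smiles)
    if mol is None:
        return False, {PARSE_ERROR}
    flags = set()
    symbols = {a.GetSymbol() for a in mol.GetAtoms()}
    if symbols - ALLOWED_ELEMENTS:
        flags.add(UNUSUAL_ELEMENT)
    if not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
        flags.add(INORGANIC)
    return not flags, flags


def layered_identifier(smiles: str) -> LayeredIdentifier | None:
    """Standard layered identifier (InChI) for a SMILES, or None on failure."""
    mol = _parse(smiles)
    if mol is None:
        return None
    inchi = Chem.MolToInchi(mol)
    if not inchi:
        return None
    return LayeredIdentifier.from_string(inchi)


# Layer prefixes that terminate the connectivity-only comparison key: the
# hydrogen layer (mobile/fixed H positions) and everything after it encode
# tautomeric, charge and stereo detail that must not break concordance.
_TERMINAL_PREFIXES = ("h", "q", "p", "b", "t", "m", "s", "i")


def comparison_key(smiles: str) -> str:
    """Tautomer-insensitive comparison key: version + formula + connectivity.

    The layered identifier is truncated before its hydrogen layer, so two
    spellings of one compound that differ only in tautomeric hydrogen
    placement (or protonation detail) share a key.  Empty string on parse
    failure (treated as missing evidence by the caller).
    """
    ident = layered_identifier(smiles)
    if ident is None:
        return ""
    kept = ident.layers[:2]
    for layer in ident.layers[2:]:
        if layer[:1] in _TERMINAL_PREFIXES:
            break
        kept.append(layer)
    return "/".join(kept)


def dedup_key(smiles: str) -> str:
    """Deduplication key: the first three slash-delimited identifier layers."""
    ident = layered_identifier(smiles)
    if ident is None:
        return ""
    return "/".join(ident.layers[:3])


def canonicalize_kekulized(smiles: str) -> str:
    """Deterministic canonical SMILES with explicit (kekulized) aromaticity.

    Idempotent; falls back to the canonical aromatic form when a ring system
    cannot be kekulized.
    """
    mol = _parse(smiles)
    if mol is None:
        return ""
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
        return Chem.MolToSmiles(mol, kekuleSmiles=True)
    except Chem.KekulizeException:
        return Chem.MolToSmiles(mol)


def standardize(smiles: str) -> StandardizedStructure:
    """Run the full cleaning pipeline on one retrieved SMILES.

    Order: split fragments -> neutralize -> strip stereo -> element filter ->
    comparison/dedup keys -> canonical kekulized form.  Original, neutralized
    and counterion forms are all retained; flags accumulate across stages.
    """
    result = StandardizedStructure(smiles_original=smiles or "")
    main, counterions, flags = split_fragments(smiles)
    result.flags |= flags
    result.counterions = counterions
    if PARSE_ERROR in result.flags:
        return result
    result.main_fragment = main
    if MW_TIE in flags:
        main_mw = round(Descriptors.MolWt(Chem.MolFromSmiles(main)), 4)
        ties = {
            c
            for c in counterions
            if Chem.MolFromSmiles(c) is not None
            and round(Descriptors.MolWt(Chem.MolFromSmiles(c)), 4) == main_mw
        }
        result.candidate_mains = sorted({main, *ties})
    else:
        result.candidate_mains = [main]

    neutral, ok = neutralize(main)
    if not neutral:
        result.flags.add(PARSE_ERROR)
        return result
    if not ok:
        result.flags.add(NEUTRALIZATION_FAILED)
    result.neutralized = neutral

    flat, had_stereo = strip_stereo(neutral)
    if had_stereo:
        result.flags.add(STEREO_STRIPPED)
    result.neutralized = flat

    _, ef_flags = element_filter(flat)
    result.flags |= ef_flags

    result.comparison_key = comparison_key(flat)
    result.dedup_key = dedup_key(flat)
    result.canonical_kekulized = canonicalize_kekulized(flat)
    if not result.comparison_key:
        result.flags.add(PARSE_ERROR)
    return result
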