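# chemcurate

Semi-automated retrieval, cross-source quality checking and standardization
of chemical structures, producing QSAR-ready datasets with per-record
reliability grades.

QSAR models are only as good as the structures they are trained on, and the
identifiers found in legacy datasets — free-text chemical names and CAS
registry numbers — are ambiguous and error-prone. `chemcurate` resolves each
(name, CAS) pair to structures from independent public registries, measures
how well the retrievals agree, and routes every record to **Maintain**,
**Check** or **Reject**, so that manual inspection is reserved for the small
fraction of records the automation cannot settle.

## The method

For each input record, four structures are requested in a first round: the
Chemical Identifier Resolver (CIR/CACTUS) and the EPA CompTox dashboard, each
queried by chemical name and by CAS number. Every retrieved SMILES is

1. split into fragments — the highest-molecular-weight fragment is the main
   molecule, the rest are counterions (kept as attributes, with flags for
   metallic/organic counterions and dimers);
2. neutralized by protonation-state change only (permanently charged centers
   such as quaternary N are flagged, never altered);
3. stripped of stereochemistry (classical 2D QSAR ignores it);
4. screened against a ten-element whitelist (H, C, N, O, F, Br, I, Cl, P, S);
   carbon-free structures are flagged inorganic;
5. reduced to a tautomer-insensitive **comparison key**: the layered InChI
   identifier truncated before its hydrogen layer, so spellings that differ
   only in mobile-hydrogen placement compare equal.

The four comparison keys are tallied into counts of equal (E), different (D)
and missing (M) retrievals, E + D + M = 4, and scored:

    score = E − 0.2·D

forced to zero when D ≥ E (with D > 0), when the two CAS-derived structures
disagree, or when nothing concordant was retrieved. Routing:

| final score | category | reliability |
|---|---|---|
| 4.0 | Maintain | high |
| 3.0 | Maintain | medium |
| 0 < score < 3 | Check | — (reason attached) |
| 0.0 | Reject | — |

Check records enter an automated confirmation round: name/CAS consistency is
verified against the PubChem synonym list, and PubChem + ChemIDplus are
queried as secondary sources (each *source* contributes at most one
confirmation). Whatever remains pending is written to a manual worksheet;
after the user fills in confirmation counts the worksheet is reloaded and
every record ends up Maintained (medium reliability) or Rejected. Maintained
structures are kekulized to canonical SMILES with explicit aromaticity and
deduplicated on the first three InChI layers.

Names are also screened for keywords (mixture, reaction mass/product, UVCB,
polymer → removed; metabolite, formulation, degradate, product, derivative →
manual check; isomeric-mixture wording → kept, since stereochemistry is
stripped anyway), and records whose consensus structure contains unusual
elements or no carbon are rejected regardless of score.

## Worked example

The package ships a synthetic-registry generator that emulates the error
phenomenology of public registries (missing entries, structurally wrong
entries, corrupted name keys), so the whole workflow runs offline:

```bash
chemcurate simulate --n 50 --seed 7 --p-missing 0.15 --p-wrong 0.05 --out fixtures
chemcurate run fixtures/input.csv --resolvers fixture:fixtures --out report.xlsx
```

prints

```
Total input records: 50
Maintained (with duplicates): 48
Maintained (without duplicates): 29
Maintained (w/o duplicates, high reliability): 17
Maintained (w/o duplicates, medium reliability): 12
Manual check pending: 0
Rejected (total): 2
Rejected (missing_or_ambiguous_structure): 2
report written to report.xlsx
```

48 of 50 records had enough concordant evidence to keep (several after the
automated confirmation round, hence the medium-reliability entries); they
collapse to 29 unique structures because the generator deliberately reuses
template molecules (e.g. enantiomer spellings that merge once stereochemistry
is stripped). Two records were rejected for discordant or missing retrievals.
The workbook's `Maintained` sheet holds the QSAR-ready structures:

```
 NEW_ID    CANONICAL_KEKULIZED_SMILES  DUPLICATES RELIABILITY
      1                   C1=CN=CC=N1           2      medium
      2 CCN(CC)CC(=O)NC1=C(C)C=CC=C1C           3        high
      3                   CC(N)C(=O)O           1      medium
      4             CN(C)C(=N)NC(=N)N           2        high
```

plus sheets for rejected records (with reasons), the manual-check worksheet,
counterion bookkeeping per source/identifier slot, and a summary. A CSV
mirror directory (`report_csv/`) with identical cell content is always
written alongside. If the worksheet needs manual input, fill the
`USER_CONFIRMATIONS` column and finish with:

```bash
chemcurate resume fixtures/input.csv worksheet.csv --resolvers fixture:fixtures --out final.xlsx
```

Live adapters for the four public services can be selected with
`--resolvers live` (network access and patience required); the test suite
runs entirely against fixture registries.

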