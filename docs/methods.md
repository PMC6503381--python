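# Methods

## Scope and model

`chemcurate` curates the *structural* identity of substance records: it does
not touch endpoint/bioactivity values, does not canonicalize tautomers (it
only compares tautomer-insensitively), and does not attempt nomenclature
parsing — chemical names are lookup keys and keyword-triage inputs only.

The underlying model of data quality is redundancy across orthogonal
registries: if the same structure is recovered from independent sources
through two independent identifiers (name and CAS number), a real match
between structure and identifiers is highly plausible; disagreement signals
a compilation error in at least one source. The workflow quantifies this
with the concordance score and treats the CAS number as the more trustworthy
identifier (it is less exposed to typos and synonym drift than free-text
names), which motivates the CAS-disagreement forcing rule and the
CAS-preferring tie-break described below.

## Evidence counting

Retrieved structures are compared on a **comparison key**: the standard
layered identifier (InChI) of the cleaned main fragment, truncated before
its hydrogen layer. Everything from the hydrogen layer on (mobile-H,
charge/protonation, stereo, isotope layers) is excluded, because those
layers encode exactly the distinctions — tautomeric hydrogen placement,
protonation detail — that must not break concordance between sources. Note
the standard identifier already unifies many mobile-H tautomer pairs (e.g.
2-hydroxypyridine/2-pyridone) at the full-string level; the truncation
additionally covers fixed-H spellings and protonation-state leftovers.

The four primary slots are tallied as:

* the largest class of slots sharing a key counts as **E** when it has at
  least two members, or when it is the only retrieval (a single
  uncontradicted structure is consistent, if weak, evidence — it routes to
  "search for at least two confirmations", never to Maintain);
* retrieved slots outside that class count as **D**; when every retrieved
  key is distinct and there is more than one, all of them are mutually
  discordant and E = 0;
* absent or unusable (unparseable) retrievals count as **M**.

When two classes tie in size, the class holding both CAS-derived slots wins,
then the class holding more CAS-derived slots, then the lexicographically
smallest key — deterministic, and biased toward the more reliable
identifier. Tie situations are forced to zero by the D ≥ E rule anyway, so
the tie-break only affects which structure is displayed as representative.

`score = E − 0.2·D` is forced to zero when D ≥ E with D > 0 (the published
decision table routes the 2-2-0 profile to Reject, so ties force zero too),
when the two CAS retrievals disagree, or when E = 0. The penalty 0.2 is a
named constant (`DISCORDANCE_PENALTY`).

One profile is not covered by the published table: E=2, D=1, M=1 with one
CAS slot missing (the table prints only the CAS-agree and CAS-disagree
subrows). It is routed to Check with "search for at least one confirmation",
the closest published rule; with the CAS pair incomparable, name
verification alone would not be convincing.

Records promoted out of Check (by synonym match, secondary-source
confirmation or manual confirmation) are graded **medium** reliability:
their evidence never reached the four-concordant standard of a high grade.

## Standardization pipeline

Fixed stage order: fragment split → neutralize → strip stereo → element
filter → keys → canonical kekulized form. Choices worth recording:

* **Stereo stripping** operates on the parsed molecule (clearing chiral tags
  and bond stereo) and re-serializes. Deleting the characters `@ \ /` from
  the SMILES string would corrupt ring-closure and charge tokens; the graph
  operation achieves the intended outcome robustly.
* **Neutralization scope**: add a proton at O⁻/S⁻/N⁻, remove one from N⁺
  carrying a hydrogen; atoms adjacent to an opposite charge (ylides,
  zwitterionic push-pull systems like nitro groups written charge-separated)
  are excluded so bonds are never rewritten. Success is defined as zero net
  formal charge afterwards; failures are flagged, never dropped.
* **Counterion classing**: a counterion is *metallic* if it contains any
  atom that is not a nonmetal (metals and metalloids — B, Si, As, … — count
  as metallic), *organic* if it contains carbon. A counterion identical to
  the main fragment marks a dimer. A molecular-weight tie between
  non-identical fragments keeps all tied fragments as candidate mains,
  flags the record and lets the deterministic lexicographic choice stand in
  for display.
* **Dedup key**: literally the first three slash-delimited segments of the
  identifier (version, formula, connectivity for typical organics). For
  molecules without a connectivity layer (e.g. methane) the third segment is
  the hydrogen layer; at that size the key is still unambiguous.
* **Kekulization** uses the toolkit's canonical kekulized serialization and
  is verified idempotent; aromatic systems that cannot be kekulized fall
  back to the canonical aromatic form with a warning.

## Pipeline-level rules

* Checksum-invalid or malformed (but non-empty) CAS numbers are still sent
  to the resolvers — registries tolerate some anomalies — but a record that
  would be Maintained with such a CAS is demoted to Check ("verify
  correctness of CAS; search for at least one confirmation").
* Name-keyword hits of the manual class (metabolite, formulation, degradate,
  product, derivative) demote a would-be Maintain to Check through the name
  verification path, with the keyword recorded as a warning.
* Removal keywords (mixture, reaction mass/product, UVCB, polymer) and a
  consensus structure failing the element filter reject the record
  regardless of score. "Isomer(s)" wording is kept-but-flagged, because
  stereochemistry has already been stripped. Keyword matching is
  case-insensitive substring matching on whitespace-normalized names, with
  word-boundary anchoring for "product(s)" and "isomer(s)" to avoid hits
  inside longer words.
* Synonym matching in name verification is normalized equality: case-fold,
  collapse internal whitespace, strip edge punctuation. Fuzzier matching is
  deliberately out of scope — a near-miss (e.g. a positional-isomer name)
  must reach a human.
* Confirmations are counted per *source*: PubChem agreeing through both its
  name and CAS slots is one confirmation, because two slots of one registry
  are not independent evidence.
* On the reloaded manual worksheet, blank confirmation cells mean zero (the
  terminal step rejects unconfirmed records); non-integer or negative
  entries are row-level errors that leave the record pending with a warning.

## Synthetic registries and what they show

The generator emulates the error phenomenology of public registries —
random, independent compilation errors — not their content:

* **Truth set**: drug-like template molecules (ten-element organics, with
  stereo-labelled, tautomer-spelling, salt, mixture-by-name and
  organometallic variants) with unique names and valid-by-construction CAS
  check digits. Default composition: 15% salts, 15% stereo, 5% tautomer
  spellings, no mixtures or organometallics — the profile of a
  well-documented pharmaceutical dataset; industrial-style fractions are
  configurable.
* **Noise model**: per (record, slot), missing with `p_missing = 0.10`, else
  structurally wrong with `p_wrong_structure = 0.05`; per (record, source),
  the stored name key is corrupted with `p_name_typo = 0.02` (name lookups
  then miss). Defaults chosen once as plausible small error rates for
  curated public sources.
* Wrong structures are drawn from other truth entries with a *different*
  comparison key and are distinct across a record's slots. This makes the
  routing oracle exact: Maintain/Check/Reject probabilities follow from
  enumerating the 3⁴ per-slot outcomes through the real counting and
  scoring functions, and Monte-Carlo runs must match within binomial noise
  (tested at n = 2000 against 3σ bounds).

What passing these tests does **not** show about real data: real registry
errors are correlated (sources copy from each other), wrong structures are
often near-misses sharing scaffold and formula with the truth, names are
messier than the generator's controlled typos, and the template library is
tiny compared to real chemical space. The synthetic runs validate the
routing arithmetic and the plumbing, not the field error rates.

## Problem sizes and numerics

Default test problem sizes: exhaustive enumerations are 3⁴ = 81 slot
assignments (instantaneous); end-to-end property tests run at 80–300
records; the Monte-Carlo check at 2000 records. Score comparisons use exact
arithmetic at one decimal (E and D are small integers, 0.2·D is exact at
that precision); the forcing comparisons are integer comparisons on E and D,
so no floating-point tolerance is involved in routing. Molecular-weight ties
in fragment splitting are detected after rounding to 4 decimals.

## Known limitations

* Live HTTP adapters are optional plumbing (stdlib urllib, fixed polite
  delay, small retry budget) and are not exercised by the test suite; the
  fixture backend defines the contract.
* The "first three layers" dedup key merges protonation states and — by
  design — stereoisomers; users modeling endpoints where the counterion or
  stereochemistry matters should consult the counterion sheets and warnings
  instead of the deduplicated list.
* Reliability has two grades only; no per-source trust weighting is
  attempted — all four primary slots weigh equally.
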