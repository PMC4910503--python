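# Methods

## The verification model

A catalogue name is a query against a provider checklist.  Verification is
two-step and strictly ordered:

1. *Exact search.*  Lookup by the canonical name (no authority), case
   insensitive.  One hit → the provider's status, mapped into the
   harmonized vocabulary; more than one hit → *Ambiguous* (homonyms:
   identical spellings under different authorship).
2. *Relaxed search*, attempted **only** when step 1 returns nothing.  All
   records at the next higher rank are enumerated — congeners for a
   species-rank query, all names under the binomial for an infraspecific
   query, hybrids treated at species rank within their genus — and screened
   with unit-cost Levenshtein distance, keeping candidates at distance
   1–2 (the "< 3" bound).  Exactly one candidate spelling → that spelling
   becomes the *alternative name* and contributes its status; several
   spellings → verified with status *Ambiguous* (no nearest-distance
   tie-break); none → unverified (NA).

Distance is computed on the full canonical string, case-insensitively,
via `edlib` (global alignment); the test suite checks it against an
independent dynamic-programming oracle and for metric properties.

Decisions on points the two-step scheme leaves open:

* a relaxed match on a single spelling backed by several records (homonym
  twins) adopts their common harmonized status, or *Ambiguous* when the
  records disagree;
* EOL-dialect results never carry a status (the provider does not return
  one); a verified EOL hit has status NA with `verified=true`;
* for dialects whose name field may embed the authority (EOL), an exact
  match also accepts a record whose name field begins with the query at a
  word boundary.

## Status harmonization and reconciliation

COL's three statuses are adapted to TPL's four: "Accepted name" and
"Provisionally accepted name" → Accepted; "Synonym" → Synonym.  *Ambiguous*
is a derived status (multiple matches), not a provider vocabulary item.
Reconciliation compares harmonized TPL and COL statuses per unique name,
counting only names with a status from both providers; identical → one
agreement, different → one discrepancy record, tallied in an off-diagonal
cross-tabulation.

## Annotation with alternative-name fallback

Each verified unique name is queried against four annotation domains.  The
original name is always tried first; only on a complete miss are the
*alternative names* — the accepted name, then the synonyms in alphabetical
order, both resolved from the TPL-like store — queried in turn, the first
hit winning.  Provenance labels record which variant hit: for the Red List
`RL` (primary name), `RLsynonym` (red-list-internal synonym, checked before
TPL expansion), `TPLaccepted`, `TPLsynonym`; for GISIN the TPL status of
the name that hit (`Accepted`/`Synonym`/`Unresolved`); for BOLD
`original`/`TPLaccepted`/`TPLsynonym`.  DAISIE is plain membership of the
canonical name (alien list plus worst-invaders sublist; worst ⇒ alien is
enforced at load).  GISIN classing: any occurrence record flagged exotic
*and* harmful ⇒ Invasive; any exotic ⇒ Exotic; else Neither
(order-independent).  If two alternatives would hit with different
categories the first in query order wins and the conflict is logged.
Accepted-before-synonyms is a deterministic choice; nothing in the domain
fixes the order.

An audit object counts, per domain, hits via the original name, hits via
alternatives and misses; the three always partition the annotated name
list, and every alternative-provenance hit implies (and is re-checked in
the tests to imply) that the original name misses the store.

## The synthetic world

The generator emulates the statistical structure the pipeline assumes,
not real floras:

* **Name material** is pseudo-Latin built from syllable templates.  Genera
  are ≥ 3 edits apart; within a genus all epithets (accepted and synonym)
  are ≥ 7 edits apart.  This separation is what makes corruption outcomes
  provable: a 1–2-edit typo is within the bound of exactly its source
  name (every other congener stays ≥ 5 away), and a 3–4-edit corruption is
  ≥ 3 from everything, so the expected outcome of every planted corruption
  is deterministic.
* **Master taxonomy**: `n_accepted` accepted taxa (default 500 — large
  enough for stable rate estimates, small enough that the whole pipeline
  runs in seconds), Poisson-distributed synonyms (mean 1.5 per taxon,
  giving ≈ 2.5 names per taxon as in large plant checklists), homonym
  twins at rate 0.05 (a second record of the same spelling, different
  authority, status Unresolved, TPL only — mirroring that homonym
  detection is essentially a TPL feature).
* **Provider snapshots** subsample the master at per-provider coverage
  (defaults 0.92/0.88/0.91, the per-provider verification success of large
  seed-catalogue name sets); COL statuses are translated into the COL
  vocabulary (10 % of accepted records rendered "Provisionally accepted
  name") and flipped Accepted↔Synonym at `status_disagreement_rate`
  (default 0.13); 30 % of EOL records embed the authority in the name
  field.
* **Annotation stores** cover configured fractions of taxa (defaults: Red
  List 0.076 with an LC-heavy category mix and a thin extinct tail, GISIN
  classes 0.013/0.027/0.003, DAISIE 0.196 with a small worst sublist,
  BOLD 0.576 with Poisson(2) public-record counts so that ≈ 13 % of found
  taxa have zero records).  A controlled fraction of covered taxa is keyed
  only under a synonym (Red List 0.176, GISIN 0.122, BOLD 0.102), which is
  what the alternative-name fallback recovers.
* **Catalogues** sample accepted names (75 %) and synonyms (25 % — gardens
  mostly list current names), render half the lines with an authority, add
  two non-name decoy lines per catalogue, and corrupt the epithet at
  `typo_rate` (default 0.05) within edit distance 1–2 plus an
  `unrecoverable_rate` (0.01) of ≥ 3-edit corruptions.  Corruptions touch
  only the epithet so genus routing stays intact.

Alongside the data the generator emits a **ground-truth table**: per
generated catalogue line, the source taxon, the injected edit distance,
and the expected match type, status, alternative name and annotation
outcome/provenance per provider and domain, derived from the generator's
own record bookkeeping (with its own DP edit distance, not the package's).
`truth_check` scores a pipeline run against this table: per-provider match
and status accuracy, exact/relaxed/unrecoverable recovery rates,
false-ambiguity count, the observed disagreement rate over eligible names
(clean, exactly matched by both TPL and COL, not homonym-ambiguous — over
these, a discrepancy occurs exactly when a COL flip was planted), the
synonym-only red-list keying rate over eligible accepted-name queries, and
per-domain provenance accuracy.

What passing on synthetic worlds does **not** show: robustness to OCR
noise, vernacular or misapplied names, authority-string variation beyond
token differences, infraspecific-rank interactions in the master taxonomy
(the generator emits species-rank names; infraspecific sibling routing is
covered by unit tests), or realistic phylogenetic/abundance structure.

## Numerical conventions and degenerate inputs

* Percentages are 100·part/total rounded **half-up** to one decimal
  (`Decimal`, not float rounding).
* The uniqueness key of the UNL is canonical text (case-folded) plus rank
  marker; authorities never enter any matching key.
* The hybrid sign is rendered as a single fixed symbol, so "Genus x
  species" and "Genus × species" collapse to one entry.
* Unparseable catalogue lines are skipped and logged with their line
  number; undecodable bytes are a hard error naming the offset.
* Checklist rows with a status outside the dialect vocabulary, or synonym
  rows without an accepted-name link, are rejected row-by-row with a log;
  duplicate record ids abort the load.
* Impossible world configurations (probabilities outside [0, 1], homonyms
  with fewer than two taxa, typo distances outside 1–2) are rejected
  before generation.

## Known limitations

* Relaxed search does not rank candidates by distance; any plurality of
  spellings is Ambiguous even when one candidate is strictly nearer.
* Alternative-name expansion resolves a homonym spelling to its first
  record; a warning is logged, but the second reading is not pursued.
* The reconciliation cross-tab covers exactly two providers (TPL- and
  COL-style); EOL contributes to verification only.
* Status flips in the synthetic COL snapshot may produce dangling
  accepted-name links (a snapshot-truncation artifact the loader
  tolerates by design).
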