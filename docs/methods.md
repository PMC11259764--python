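# Methods

This note records the models, rules and design choices behind `fedkg`, and
what the synthetic test bed does and does not establish.

## Chronicity rule

Chronic kidney disease requires kidney dysfunction sustained over at least
three months. The package operationalizes this as:

> criteria met ⇔ there exist two abnormal kidney findings whose dates are
> **≥ 90 days** apart (inclusive at exactly 90) with **no normal
> kidney-function observation strictly between them**.

`first_met_date` is the earliest closing date over all qualifying pairs,
and one supporting pair is returned for explanation. The intervening-normal
clause is the *recovery reset*: post-surgical or treatment-related dips in
kidney function recover, and a normal result between two abnormal ones
breaks the chain rather than letting the pair straddle it. A normal result
on the same day as an endpoint abnormal does not block the pair (it is not
strictly between). The linear-scan implementation is checked against an
independent O(n²) enumeration on hundreds of random timelines, including
the 89/90-day boundary.

Abnormality thresholds follow the screening criteria: eGFR strictly below
60 mL/min, ACR strictly above 30 mg/g (values reported in mg/mmol are
converted at 8.84 mg/g per mg/mmol), serum creatinine above 115 µmol/L.
Only the two criterion analytes (eGFR, ACR) emit *negative* observations
("kidney function normal") that act as recovery markers; an incidental
normal creatinine does not reset a chain established by eGFR results. The
default treats any abnormal-kidney finding concept as qualifying for a
pair, regardless of analyte; whether both abnormalities must come from the
same analyte is genuinely open, and the choice is configurable through the
rule set.

## Vocabulary and hypernym abstraction

The vocabulary is a DAG of concepts with an `is_hypernym` flag marking the
expressions cleared for export. Hypernym designation itself is expert
curation — data, not computation — so the flag ships in the vocabulary
rather than being discovered. What the package computes is the *mapping*
from each leaf finding to the hypernym that represents it:

* candidate set: all hypernym ancestors of the leaf (the leaf itself when
  flagged);
* cohesion score per candidate: mean pairwise cosine similarity of its
  descendant leaves' embedding vectors (1.0 for a single leaf);
* chosen: the **deepest** candidate with cohesion ≥ threshold
  (default 0.7; ties break to the smallest concept id);
* fallback when none qualifies: the **most general** hypernym ancestor,
  with a low-cohesion warning. Falling back toward the root rather than
  toward the leaf keeps the map monotone — raising the threshold can only
  generalize a leaf's expression, never specialize it — and errs on the
  privacy side when cohesion is poor;
* leaves with no hypernym ancestor are reported unmapped and are **never
  exported** (dropped with a warning at abstraction time): the privacy
  contract dominates completeness.

The 0.7 threshold is a package default, not an empirical constant; the
shipped embeddings are synthetic unit vectors clustered per hypernym (no
embedding training is performed, as the embedding method is an input to
the system, not part of it).

## Privacy model

Three structural guarantees, each enforced in code and swept by tests:

1. **Intermediate findings** carry only (hashed identity, date, hypernym,
   positive/negative label) — no value, unit, provenance, raw identity or
   leaf concept field exists on the type.
2. **Online subgraphs** are canonical JSON with a closed schema; the
   deserializer rejects any payload containing an unexpected field (e.g.
   an injected `value`) or a non-whitelisted concept.
3. Everything that crosses a node boundary passes through the ledger, so
   a single byte-scan of all ledger payloads checks the whole exchange:
   no raw identity string, no decimal-formatted source measurement value,
   no non-hypernym concept id, no department name.

Identity digests are SHA-256 over a consortium-shared salt prepended to
the normalized identity (trimmed, uppercased, whitespace/hyphens removed).
The salt travels out of band via configuration and blunts dictionary
attacks on low-entropy citizen IDs; digest equality across sites is the
entire alignment mechanism, so fuzzy linkage on non-unique identifiers is
out of scope. Digest collisions between distinct local identities are
flagged and withheld, never merged.

## The collaborative protocol

Five steps, one shared ledger, one sponsor per process series:

1. every node screens patients locally (eligible ⇔ ≥1 kidney-function
   test, no nephrology visit, no kidney-disease diagnosis) and broadcasts
   eligible patients' kidney findings as initiation subgraphs; patients
   failing the exclusion clauses are announced as digest + reason code
   only, and a patient excluded by *any* node is excluded consortium-wide
   (ineligible patients' clinical data never leave their node);
2. the sponsor groups subgraphs by digest (alignment);
3. the sponsor runs the chronicity rule on each merged timeline and
   designates the ROI as [first abnormal finding date, last abnormal
   finding date] — an operationalization chosen here, as no closed ROI
   formula exists; patients without a qualifying pair get no ROI;
4. each node re-derives findings restricted to the ROI and exports them;
   the node's visit-date pathway is exported alongside (dates only —
   exactly what the online-subgraph ontology permits), because the
   transferred-group classification needs post-ROI visit dates while
   clinical events outside the ROI must never be processed for export;
5. the sponsor merges all rounds (idempotently, deduplicating virtual
   nodes on origin + date + concept + label) and classifies: if some
   single hospital's findings alone satisfy the criteria and the patient
   later visited a different hospital, the patient is *transferred* (the
   transfer date is the first such later visit); if no single hospital
   suffices but the union does, *multicenter-data*; otherwise
   *single-center*. These labels are mutually exclusive and exhaustive
   over detected patients.

The ledger is a single-sequencer hash chain (block hash over
index ‖ previous hash ‖ payload hash) with synchronous broadcast and
per-node receipts; consensus, peer-to-peer networking and payload
encryption of the deployed system are infrastructure outside this
package's contribution, but the contract they provide — ordered,
tamper-evident, traceable delivery — is preserved and tested (any
single-byte mutation is detected and localized). Access control is a
per-message recipient allow-list at delivery time. The secure two-value
comparison is an interface with a plaintext trusted-evaluator reference
implementation; a garbled-circuit backend could be substituted without
changing callers.

## Evaluation quantities

* **Lead time**: multicenter group `t_diagnosis − t_CDS`; transferred
  group `t_diagnosis − t_transfer`. On synthetic data `t_diagnosis` comes
  from ground truth (planted 90–700 days after objective onset); the
  study's clinician-assessed values are not reproduction targets.
* **Risk coverage**: |risks from collaborative reasoning within the
  3-month window anchored at the ROI end| / |risks from the sponsor's own
  store over its latest 3 months|, in percent. Anchoring at the ROI end
  reflects reviewing the most recent evidence; the anchor is a package
  choice. The equation's source rendering is not available in closed
  form, so the set-cardinality ratio described in prose is implemented;
  per-patient mean is the default aggregate, pooled counts available by
  flag.
* **Duplicate-exam reduction**: kidney-function tests at non-sponsor
  hospitals inside the ROI with no sponsor-side kidney test within ±14
  days (the mirroring window is configurable; no canonical value exists).
* **Detection metrics**: sensitivity / specificity / PPV / group-label
  accuracy against the generator's ground truth, with recovery
  confounders reported separately as the false-positive mechanism of
  interest.

## Synthetic cohort: what it emulates, and what it does not

Per patient: a shared 18-character citizen-ID-like identity across 2–3
hospitals (distinct local person ids), an active period of roughly 0.5–2.5
years inside a 2016–2020 study window, background visits at ~3/patient-year
across ten non-nephrology departments, comorbidity diagnoses (diabetes,
hypertension, cardiovascular disease, hyperlipidemia) and laboratory
chemistry (potassium, glucose, urea nitrogen, uric acid, creatinine) drawn
from distributions matching the study population's reported means and
spreads. Phenotypes are planted constructively:

* *multicenter*: abnormal kidney results at ≥2 hospitals, within-hospital
  pairs < 90 days apart, cross-hospital pair ≥ 90 days — only the union
  satisfies the rule;
* *transferred*: two abnormal results ≥ 90 days apart at one hospital,
  then visits to another hospital that holds no kidney tests;
* *recovery confounder*: abnormal → normal → abnormal with the normal
  blocking every qualifying pair;
* *control*: all kidney values normal;
* *decoy*: an alarming abnormal pair **plus** a nephrology visit or
  kidney-disease diagnosis, so only the exclusion path keeps it silent.

The generator re-verifies every emitted patient against the chronicity
oracle before returning, and is a pure function of the seed.

Because phenotypes are planted to be exactly recoverable, perfect
detection on this test bed demonstrates *correctness of the machinery*
(rule evaluation, abstraction, merging, classification, exclusion), not
expected clinical performance: real data add missingness, coding
variation, non-unique identifiers, measurement error around thresholds
and genuinely ambiguous trajectories that the generator deliberately does
not model. Lead-time and coverage magnitudes on synthetic data follow
from the planting distributions and should be read the same way.

## Numerical and determinism choices

Dates are day-granular ISO-8601, intervals closed on both ends; 90 days
stands for three months, compared inclusively. Multi-day admissions
collapse to their start date (the exchanged structure carries visit dates
only). Visit ordering ties break by visit id, event ties by event id,
equally deep hypernym candidates by concept id. All cross-boundary
serialization is canonical JSON (sorted keys, sorted node lists), the
triple projection serializes to sorted N-Triples lines, and a full run is
a pure function of (stores, vocabulary, rules, salt, seed) — verified by
byte-identical repeat runs. Default problem sizes (1200-patient
acceptance consortium, 150-patient determinism check, 500 oracle
timelines, 50-block tamper sweep) keep a full from-scratch reproduction
in the tens of seconds on one CPU.

## Known limitations

Single sponsor per process; alignment requires unique identifiers; the
rule engine ships only the kidney-disease application content (though
rules, vocabulary and thresholds are all data); no streaming operation;
no real consensus layer or cryptographic comparison backend; eGFR values
are taken as recorded, never recomputed from creatinine.
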