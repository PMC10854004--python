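# Methods

## Model and assumptions

`lynchvus` assesses one germline MMR VUS at a time against a fixed,
conservative rule set. The guiding assumption is mechanistic: if the
queried variant is a true Lynch allele, the tumor should show the complete
molecular fingerprint of biallelic inactivation of that gene — a somatic
second hit at the locus (presumed in trans), MSI-high phenotype, and an IHC
loss pattern explained by the MLH1–PMS2 / MSH2–MSH6 heterodimer biology —
in a patient whose clinical presentation independently suggests Lynch
syndrome. Anything less is deliberately *not* called POSITIVE: missing
evidence renders INCONCLUSIVE with one flag code per absent item, and
complete-but-unusual presentations render NEUTRAL. The asymmetry is
intentional; the tree trades sensitivity for a high degree of confidence in
its POSITIVE calls, and it never attempts variant re-classification.

Assessment is two-staged. **Structural gates** check evidence *presence*:
single-VUS status, clinical criteria, second hit, MSI, and an assessable
IHC panel with ≥ 1 protein lost. All failing gates are reported, not just
the first. **Gene stage** then routes on the sporadic-etiology work-up and
the canonical IHC pattern. The sporadic work-up is handled per gene rather
than as a gate because its interpretation is gene-dependent: for an *MLH1*
VUS a positive or unavailable work-up leaves a complete-but-uninterpretable
picture (NEUTRAL), while for the other genes it removes a precondition of
assessment (INCONCLUSIVE with the corresponding flag code). For a *PMS2*
VUS with MLH1+PMS2 co-loss the verdict is NEUTRAL regardless of the
work-up, since the pattern itself already points at *MLH1*.

A positive methylation result always vetoes POSITIVE, for every gene and
tumor type. For colorectal tumors a negative BRAF p.V600E result in the
absence of methylation testing is accepted as excluding sporadic etiology;
BRAF is never consulted for endometrial tumors.

## Parameters

| Parameter | Default | Unit | Rationale |
|---|---|---|---|
| `premm5_threshold` | 2.5 (inclusive) | % carrier probability | the published PREMM5 testing threshold for CRC/EC patients; configurable via `--config` |
| LS cancer label set | colorectal, endometrial, small bowel, ureter, renal pelvis | — | the tumor types admissible under Amsterdam II; configurable per call |
| `include_proband` | true | — | the proband counts among the "three relatives" of Amsterdam II; configurable |

The PREMM5 score itself is an input (computed externally); only the
threshold comparison happens here.

## Amsterdam II conventions

The checker searches exhaustively over subsets of affected members
(pedigrees are small; no pruning): it requires a subset of ≥ 3 affected, one
of whom is a first-degree relative of two others, generations containing
two values differing by exactly 1 ("successive"), at least one qualifying
diagnosis strictly before age 50, and FAP excluded whenever a qualifying
diagnosis is colorectal. Relationship degree is the shortest path through
parent links, with full siblings joined directly (degree 1) and
half-siblings at degree 2 — the standard genetic-relationship convention.
A consequence of the path rule is that in-laws connected only through a
shared descendant get a finite degree rather than UNRELATED; only members
in disconnected pedigree components are UNRELATED.

## Evidence codes

Family-I codes flag absent/adverse key evidence; families II–V are the
per-gene scenario codes (II = MLH1, III = PMS2, IV = MSH2, V = MSH6). The
EC registry has one fewer family-I code than CRC because BRAF is not an EC
criterion. Sub-indices inside families II–V are assigned from explicit
per-family branch tables over (sporadic-test configuration × IHC pattern);
the tables are printed by `lynchvus list-codes`. Category and code family
are the load-bearing outputs; sub-indices are a stable labeling of
branches, useful for audit trails.

## Questionnaire and answer space

The questionnaire asks exactly the evidence classes the tree consumes:
11 radio-button questions for CRC, 10 for EC (the difference being BRAF).
PREMM5 is a yes/no at this layer; the batch format takes the numeric score.
The full answer space is finite — 114,048 CRC and 38,016 EC combinations —
and the engine's invariants are checked by exhaustive enumeration over all
of it, not by sampling: totality (every combination yields exactly one
verdict, no internal errors), the conjunction property (flipping any single
required evidence to its absent/adverse value breaks every POSITIVE), the
methylation-positive veto, EC invariance to BRAF, and monotonicity of
ignorance.

Monotonicity of ignorance is defined over *supportive* results: hiding a
negative sporadic test, MSI-high status, the IHC panel, the PREMM score, or
the second hit never converts a non-POSITIVE verdict into POSITIVE. Hiding
an *adverse* result is excluded from the property by design: a colorectal
case with positive BRAF and negative methylation is NEUTRAL, while the same
case with BRAF untested is legitimately POSITIVE, because a negative
methylation (or BRAF) result alone is an accepted sporadic-etiology
exclusion. "Less information can only demote" therefore holds for
supportive evidence, and cannot hold — under this rule set — for adverse
evidence.

## Control cohort and what passing shows

The packaged table transcribes 52 positive-control subjects: patients with
Lynch-related CRC (subjects 1–29) or EC (subjects 30–52) and a known
pathogenic MMR alteration, assessed as if the alteration were the queried
VUS. Expected classes derive from the provenance code printed for each
subject (families II–V ⇒ POSITIVE). The harness reproduces 23 POSITIVE and
29 flagged non-POSITIVE with zero mismatches, and additionally matches the
printed scenario code of all 23 POSITIVE subjects.

Transcription conventions worth noting: report spellings are normalized
("MSI-S" → MSS, "Neg"/"N/A", "hypermethylation" → positive); the combined
"BRAF, methylation" column is split, with "Neg, NA" meaning BRAF negative
and methylation untested; a PREMM score printed as an inequality (">50%")
is taken at its bound; and the per-event `inactivating` flags are the
reporting laboratory's assertions, which cannot be derived from the HGVS
description alone (one subject's somatic missense was asserted
inactivating while another's was not). Scores in brackets are taken at
face value.

What passing does *not* show: the controls all carry pathogenic variants,
so the cohort measures sensitivity-style behavior and flag correctness, not
specificity against benign variants; and cohort-scale screening statistics
(thousands of tumor-sequencing cases) require institutional patient-level
data and are out of scope. The synthetic random-case generator exists to
fuzz validity and totality, not to emulate the joint distribution of real
clinico-genomic evidence — its evidence-presence weights are plausible
round numbers, and passing on it shows robustness, not calibration.

## Numerical and degenerate-input choices

All comparisons are exact or threshold-based; there is no floating-point
fitting. Degenerate inputs are handled explicitly: an absent PREMM score
never meets the threshold; an empty somatic list with no questionnaire
override means "second hit undocumented"; any equivocal/partial/unstained
IHC entry makes the whole panel NOT_ASSESSABLE (gate failure); unknown
vocabulary labels raise at parse time rather than propagating. Validation
returns the complete list of violations instead of stopping at the first.
`validate_case` and the engine are pure functions; batch and export outputs
are byte-reproducible given a fixed date and version string.

## Known limitations

* Only CRC and EC tumors are in scope; other Lynch-associated tumors are
  rejected at the type level.
* HGVS strings are opaque identifiers — no normalization or transcript
  mapping, so the same variant written two ways is two variants.
* The count-based single-VUS gate does not distinguish multiple VUS in the
  same gene from VUS in different genes.
* Cis/trans phase of the second hit is not modeled; a qualifying somatic
  event is presumed in trans.
* The ClinVar exporter writes the paper-trail spreadsheet only; it does not
  submit to any API.
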