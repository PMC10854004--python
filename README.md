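# lynchvus

Integrated germline–tumor evidence assessment of mismatch-repair (MMR)
variants of uncertain significance (VUS) in suspected Lynch syndrome.

## The problem

Lynch syndrome is diagnosed by finding a pathogenic germline alteration in
one of the MMR genes *MLH1*, *MSH2*, *MSH6*, or *PMS2* (or an *EPCAM* 3′
deletion). Germline panels, however, frequently return VUS, which standard
germline-only classification (ACMG) cannot resolve — yet the patient's
*tumor* carries rich, routinely collected evidence about whether the variant
is behaving like a Lynch allele: microsatellite instability (MSI), MMR
protein immunohistochemistry (IHC), somatic second hits at the MMR locus,
and sporadic-etiology markers (*MLH1* promoter methylation; *BRAF* p.V600E
in colorectal cancer).

`lynchvus` implements a conservative, rule-based decision tree that
integrates these evidence classes for a single queried variant in a
Lynch-related colorectal (CRC) or endometrial (EC) tumor and returns one of
four categories with machine-readable evidence codes:

| Category       | Meaning |
|----------------|---------|
| `POSITIVE`     | every required evidence item is present and concordant with a pathogenic allele of the queried gene |
| `NEUTRAL`      | all evidence present, but the pattern is unusual or rare; significance remains uncertain |
| `INCONCLUSIVE` | one or more key evidence items absent or adverse (each flagged with a family-I code) |
| `OUT_OF_SCOPE` | the combination is not enumerated by the decision tree |

The tool does **not** re-classify variants or score ACMG criteria; it is a
companion for clinical-genetics professionals that collates the evidence,
renders the category, and exports a ClinVar-ready evidence synopsis.

## The decision model

A verdict for queried gene *g* requires, conjunctively:

1. exactly one germline MMR VUS, no other pathogenic MMR germline
   alteration, no *EPCAM* 3′ deletion;
2. clinical criteria: PREMM5 score ≥ 2.5 % (inclusive) **or** Amsterdam II
   met (a pedigree checker for the full Amsterdam II clause list is
   included);
3. a documented somatic inactivating event (SNV/indel, copy loss, …) in *g*
   — the presumed-in-trans second hit;
4. MSI-high tumor phenotype;
5. an assessable four-protein IHC panel with loss of ≥ 1 MMR protein;
6. sporadic etiology excluded: *MLH1* promoter methylation negative, or (CRC
   only) *BRAF* p.V600E negative; a positive result on either test vetoes a
   POSITIVE for every gene;
7. an IHC loss pattern concordant with *g* under MMR heterodimer biology
   (MLH1–PMS2 and MSH2–MSH6): e.g. MLH1+PMS2 loss or isolated PMS2 loss for
   an *MLH1* variant; MSH2+MSH6 loss or isolated MSH6 loss for *MSH2*;
   isolated loss of the respective protein for *PMS2* and *MSH6*.

Discordant-but-recognized patterns (isolated MLH1 loss, all-four loss,
MSH2+MSH6 loss with an *MSH6* variant, …) yield NEUTRAL.

## Worked example

```sh
lynchvus assess --cancer-type CRC --gene MSH2 --cdna "c.226C>T" \
    --premm5 6.7 --braf NEGATIVE --methylation NEGATIVE --msi MSI_HIGH \
    --second-hit yes --ihc-mlh1 INTACT --ihc-msh2 LOST \
    --ihc-msh6 LOST --ihc-pms2 INTACT
```

prints

```
Category: POSITIVE
Codes:    CRC IV-I
Comment:  MSH2 c.226C>T: POSITIVE. Loss of MSH2 and MSH6 is compatible with
biallelic MSH2 inactivation and degradation of its dimerization partner
MSH6. [CRC IV-I] MSH2 VUS; loss of MSH2 and MSH6; sporadic etiology excluded.
```

Every required item is present: PREMM5 6.7 % ≥ 2.5 %, a somatic second hit
in *MSH2*, MSI-high, BRAF/methylation negative, and the canonical MSH2+MSH6
loss pattern — so the variant is behaving like a pathogenic *MSH2* allele
and the case earns the scenario code `CRC IV-I`. Dropping `--premm5` (or
lowering it to 1.0) flips the verdict to `INCONCLUSIVE` with flag code
`CRC I-II` (clinical criteria not met).

Other entry points: `lynchvus batch <tsv>` (column dictionary via
`lynchvus columns`), `lynchvus schema --cancer-type crc` (the 11-question
CRC questionnaire; EC has 10 — no BRAF question), `lynchvus list-codes`,
`lynchvus export-clinvar`, and `lynchvus evaluate-controls`. The same
operations are available as library functions (`lynchvus.assess_case`,
`lynchvus.evaluate_controls`, …).

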