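"""The integrated germline-tumor decision tree.

Assessment of a germline MMR VUS proceeds in two stages:

1. **Structural gates** — evidence that must simply be *present and
   supportive*: exactly one germline MMR VUS (and no other pathogenic MMR
   alteration or EPCAM 3' deletion), qualifying clinical criteria (PREMM5 or
   Amsterdam II), a documented somatic second hit in the queried gene,
   MSI-high tumor phenotype, and an assessable MMR IHC panel showing loss of
   at least one protein.  Any failing gate renders INCONCLUSIVE, carrying
   one family-I evidence code per absent item.

2. **Gene stage** — with all gates satisfied, the verdict depends on the
   queried gene, the sporadic-etiology work-up (MLH1 promoter methylation,
   and BRAF p.V600E for colorectal tumors only) and the canonical IHC loss
   pattern.  Concordant patterns with sporadic etiology excluded are
   POSITIVE; complete-but-unusual presentations are NEUTRAL; combinations
   the tree does not enumerate are OUT_OF_SCOPE.

The biology behind the pattern rules: MLH1-PMS2 and MSH2-MSH6 act as
heterodimers.  Biallelic MLH1 inactivation typically removes both MLH1 and
PMS2 from tumor nuclei (isolated PMS2 loss is also compatible, since
nonfunctional MLH1 can retain antigenicity); biallelic MSH2 inactivation
removes MSH2 and MSH6 (or MSH6 alone); biallelic PMS2 or MSH6 inactivation
removes only the respective protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .model import (
    CancerType,
    Category,
    EvidenceCase,
    IHCPanel,
    IHCStatus,
    MMRGene,
    MSIStatus,
    SomaticKind,
    TernaryResult,
    TumorProfile,
    Verdict,
    validate_case,
)
from .criteria import PREMM5_THRESHOLD, clinical_criteria_met

log = logging.getLogger(__name__)


class IHCPattern(Enum):
    """Canonical label for a four-protein MMR IHC panel."""

    NO_LOSS = "no loss of any MMR protein"
    MLH1_PMS2_LOSS = "loss of MLH1 and PMS2"
    ISOLATED_MLH1 = "isolated loss of MLH1"
    ISOLATED_PMS2 = "isolated loss of PMS2"
    MSH2_MSH6_LOSS = "loss of MSH2 and MSH6"
    ISOLATED_MSH2 = "isolated loss of MSH2"
    ISOLATED_MSH6 = "isolated loss of MSH6"
    MSH6_MLH1_PMS2_LOSS = "loss of MLH1, PMS2, and MSH6"
    ALL_FOUR_LOSS = "loss of all four MMR proteins"
    OTHER_COMBINATION = "other combination of losses"
    NOT_ASSESSABLE = "partial, equivocal, or incomplete IHC"


class SporadicCheck(Enum):
    """Outcome of the sporadic-etiology work-up."""

    EXCLUDED = "EXCLUDED"
    POSITIVE_METHYLATION = "POSITIVE_METHYLATION"
    POSITIVE_BRAF = "POSITIVE_BRAF"
    UNTESTED = "UNTESTED"


@dataclass(frozen=True)
class EvidenceCode:
    """One registry entry, e.g. ``CRC I-II``.

    Family I codes flag absent or adverse key evidence (INCONCLUSIVE);
    families II-V are the per-gene POSITIVE/NEUTRAL scenario codes
    (II = MLH1, III = PMS2, IV = MSH2, V = MSH6).
    """

    cancer_type: CancerType
    family: str
    index: str
    meaning: str

    @property
    def id(self) -> str:
        return f"{self.cancer_type.name} {self.family}-{self.index}"


def _build_registry() -> dict[str, EvidenceCode]:
    entries = [
        # --- colorectal, family I: absent/adverse key evidence ---
        ("CRC", "I", "I", "not exactly one germline MMR VUS, or another pathogenic "
                          "MMR germline alteration or EPCAM 3' deletion is present"),
        ("CRC", "I", "II", "clinical criteria (PREMM5 >= threshold or Amsterdam II) not met"),
        ("CRC", "I", "III", "tumor BRAF p.V600E positive or untested without a "
                            "negative MLH1 promoter methylation result"),
        ("CRC", "I", "IV", "MLH1 promoter methylation positive or untested without "
                           "a negative BRAF p.V600E result"),
        ("CRC", "I", "V", "somatic second-allele inactivation of the queried gene "
                          "not documented"),
        ("CRC", "I", "VI", "tumor is not MSI-high (stable or untested)"),
        ("CRC", "I", "VII", "IHC shows no loss of any MMR protein, or the panel is "
                            "partial, equivocal, or incomplete"),
        # --- colorectal, families II-V: per-gene scenarios ---
        ("CRC", "II", "I", "MLH1 VUS; loss of MLH1 and PMS2; BRAF negative, "
                           "methylation untested"),
        ("CRC", "II", "II", "MLH1 VUS; loss of MLH1 and PMS2; methylation negative, "
                            "BRAF untested"),
        ("CRC", "II", "III", "MLH1 VUS; loss of MLH1 and PMS2; both BRAF and "
                             "methylation negative"),
        ("CRC", "II", "IV", "MLH1 VUS; compatible variant pattern (isolated PMS2 "
                            "loss, or MLH1/PMS2 loss with secondary MSH6 loss)"),
        ("CRC", "II", "V", "MLH1 VUS; MLH1 promoter methylation positive"),
        ("CRC", "II", "VI", "MLH1 VUS; BRAF p.V600E positive"),
        ("CRC", "II", "VII", "MLH1 VUS; both methylation and BRAF results unavailable"),
        ("CRC", "II", "VIII", "MLH1 VUS; unusual isolated loss of MLH1"),
        ("CRC", "III", "I", "PMS2 VUS; isolated loss of PMS2; both BRAF and "
                            "methylation negative"),
        ("CRC", "III", "II", "PMS2 VUS; isolated loss of PMS2; methylation negative, "
                             "BRAF untested"),
        ("CRC", "III", "III", "PMS2 VUS; isolated loss of PMS2; BRAF negative, "
                              "methylation untested"),
        ("CRC", "III", "IV", "PMS2 VUS; loss of MLH1 and PMS2 (suggests MLH1 "
                             "alteration); sporadic etiology excluded"),
        ("CRC", "III", "V", "PMS2 VUS; loss of MLH1 and PMS2; methylation positive"),
        ("CRC", "III", "VI", "PMS2 VUS; loss of MLH1 and PMS2; BRAF positive"),
        ("CRC", "III", "VII", "PMS2 VUS; loss of MLH1 and PMS2; methylation and "
                              "BRAF unavailable"),
        ("CRC", "IV", "I", "MSH2 VUS; loss of MSH2 and MSH6; sporadic etiology excluded"),
        ("CRC", "IV", "II", "MSH2 VUS; isolated loss of MSH6; sporadic etiology excluded"),
        ("CRC", "IV", "III", "MSH2 VUS; unusual pattern (isolated MSH2 loss, or all "
                             "four proteins lost)"),
        ("CRC", "V", "I", "MSH6 VUS; isolated loss of MSH6; sporadic etiology excluded"),
        ("CRC", "V", "II", "MSH6 VUS; loss of MSH2 and MSH6 (suggests MSH2 alteration)"),
        ("CRC", "V", "III", "MSH6 VUS; loss of MLH1, PMS2, and MSH6 (suggests "
                            "secondary MSH6 loss)"),
        # --- endometrial, family I (no BRAF criterion) ---
        ("EC", "I", "I", "not exactly one germline MMR VUS, or another pathogenic "
                         "MMR germline alteration or EPCAM 3' deletion is present"),
        ("EC", "I", "II", "clinical criteria (PREMM5 >= threshold or Amsterdam II) not met"),
        ("EC", "I", "III", "MLH1 promoter methylation positive or untested"),
        ("EC", "I", "IV", "somatic second-allele inactivation of the queried gene "
                          "not documented"),
        ("EC", "I", "V", "tumor is not MSI-high (stable or untested)"),
        ("EC", "I", "VI", "IHC shows no loss of any MMR protein, or the panel is "
                          "partial, equivocal, or incomplete"),
        # --- endometrial, families II-V ---
        ("EC", "II", "I", "MLH1 VUS; loss of MLH1 and PMS2; methylation negative"),
        ("EC", "II", "II", "MLH1 VUS; compatible variant pattern (isolated PMS2 "
                           "loss, or MLH1/PMS2 loss with secondary MSH6 loss)"),
        ("EC", "II", "III", "MLH1 VUS; MLH1 promoter methylation positive"),
        ("EC", "II", "IV", "MLH1 VUS; methylation result unavailable"),
        ("EC", "II", "V", "MLH1 VUS; unusual isolated loss of MLH1"),
        ("EC", "III", "I", "PMS2 VUS; isolated loss of PMS2; methylation negative"),
        ("EC", "III", "II", "PMS2 VUS; loss of MLH1 and PMS2 (suggests MLH1 "
                            "alteration); methylation negative"),
        ("EC", "III", "III", "PMS2 VUS; loss of MLH1 and PMS2; methylation positive "
                             "or unavailable"),
        ("EC", "IV", "I", "MSH2 VUS; loss of MSH2 and MSH6; methylation negative"),
        ("EC", "IV", "II", "MSH2 VUS; isolated loss of MSH6; methylation negative"),
        ("EC", "IV", "III", "MSH2 VUS; unusual pattern (isolated MSH2 loss, or all "
                            "four proteins lost)"),
        ("EC", "V", "I", "MSH6 VUS; isolated loss of MSH6; methylation negative"),
        ("EC", "V", "II", "MSH6 VUS; loss of MSH2 and MSH6 (suggests MSH2 alteration)"),
        ("EC", "V", "III", "MSH6 VUS; loss of MLH1, PMS2, and MSH6 (suggests "
                           "secondary MSH6 loss)"),
    ]
    registry: dict[str, EvidenceCode] = {}
    for cancer, family, index, meaning in entries:
        code = EvidenceCode(CancerType[cancer], family, index, meaning)
        if code.id in registry:
            raise ValueError(f"duplicate evidence code {code.id}")
        registry[code.id] = code
    return registry


#: the full evidence-code registry keyed by id, e.g. ``"CRC I-II"``
CODE_REGISTRY: dict[str, EvidenceCode] = _build_registry()


def code(cancer_type: CancerType, family: str, index: str) -> EvidenceCode:
    return CODE_REGISTRY[f"{cancer_type.name} {family}-{index}"]


_PATTERN_BY_LOSS_SET = {
    frozenset(): IHCPattern.NO_LOSS,
    frozenset({"MLH1", "PMS2"}): IHCPattern.MLH1_PMS2_LOSS,
    frozenset({"MLH1"}): IHCPattern.ISOLATED_MLH1,
    frozenset({"PMS2"}): IHCPattern.ISOLATED_PMS2,
    frozenset({"MSH2", "MSH6"}): IHCPattern.MSH2_MSH6_LOSS,
    frozenset({"MSH2"}): IHCPattern.ISOLATED_MSH2,
    frozenset({"MSH6"}): IHCPattern.ISOLATED_MSH6,
    frozenset({"MLH1", "PMS2", "MSH6"}): IHCPattern.MSH6_MLH1_PMS2_LOSS,
    frozenset({"MLH1", "MSH2", "MSH6", "PMS2"}): IHCPattern.ALL_FOUR_LOSS,
}


def canonical_ihc_pattern(panel: IHCPanel) -> IHCPattern:
    """Reduce a four-protein panel to its canonical loss-pattern label.

    Any equivocal, partial-loss, or unperformed stain makes the panel
    NOT_ASSESSABLE (such patterns are not incorporated in the assessment).
    """
    statuses = panel.as_dict()
    if any(s in (IHCStatus.EQUIVOCAL, IHCStatus.PARTIAL_LOSS, IHCStatus.NOT_PERFORMED)
           for s in statuses.values()):
        return IHCPattern.NOT_ASSESSABLE
    lost = frozenset(name for name, s in statuses.items() if s is IHCStatus.LOST)
    return _PATTERN_BY_LOSS_SET.get(lost, IHCPattern.OTHER_COMBINATION)


def biallelic_documented(queried_gene: MMRGene, tumor: TumorProfile) -> bool:
    """Is somatic inactivation of the second allele of ``queried_gene``
    documented?

    True when the questionnaire override asserts it, or when some somatic
    event in the queried gene is annotated inactivating.  Copy losses count
    as inactivating regardless of the annotation flag.
    """
    if tumor.biallelic_documented_override is True:
        return True
    return any(
        ev.gene is queried_gene
        and (ev.inactivating or ev.kind is SomaticKind.COPY_LOSS)
        for ev in tumor.somatic_events
    )


def sporadic_etiology_excluded(cancer_type: CancerType,
                               tumor: TumorProfile) -> SporadicCheck:
    """Sporadic-etiology work-up outcome.

    MLH1 promoter methylation identifies sporadic MMR-deficient tumors in
    both tumor types; BRAF p.V600E does so only in colorectal cancer and is
    never consulted for endometrial cases.  For colorectal tumors a negative
    BRAF result in the absence of methylation testing is acceptable.
    """
    meth = tumor.mlh1_promoter_methylation
    if meth is TernaryResult.POSITIVE:
        return SporadicCheck.POSITIVE_METHYLATION
    if cancer_type is CancerType.CRC and tumor.braf_v600e is TernaryResult.POSITIVE:
        return SporadicCheck.POSITIVE_BRAF
    if meth is TernaryResult.NEGATIVE:
        return SporadicCheck.EXCLUDED
    if cancer_type is CancerType.CRC and tumor.braf_v600e is TernaryResult.NEGATIVE:
        return SporadicCheck.EXCLUDED
    return SporadicCheck.UNTESTED


def _gate_code(case: EvidenceCase, slot: str) -> EvidenceCode:
    crc = case.cancer_type is CancerType.CRC
    index = {
        "single_vus": "I",
        "clinical": "II",
        "biallelic": "V" if crc else "IV",
        "msi": "VI" if crc else "V",
        "ihc": "VII" if crc else "VI",
    }[slot]
    return code(case.cancer_type, "I", index)


def structural_gate_codes(case: EvidenceCase,
                          threshold: float = PREMM5_THRESHOLD) -> list[EvidenceCode]:
    """All failing structural gates, as family-I evidence codes.

    Gates are evaluated exhaustively (every absent item is reported, not
    just the first).  The sporadic-etiology work-up is not a gate; it is
    routed per gene in :func:`gene_stage_assess`.
    """
    failing: list[EvidenceCode] = []
    if (case.germline_vus_count != 1 or case.other_pathogenic_mmr_germline
            or case.epcam_3prime_deletion):
        failing.append(_gate_code(case, "single_vus"))
    if not clinical_criteria_met(case.clinical, threshold):
        failing.append(_gate_code(case, "clinical"))
    if not biallelic_documented(case.queried_variant.gene, case.tumor):
        failing.append(_gate_code(case, "biallelic"))
    if case.tumor.msi is not MSIStatus.MSI_HIGH:
        failing.append(_gate_code(case, "msi"))
    if canonical_ihc_pattern(case.ihc) in (IHCPattern.NO_LOSS,
                                           IHCPattern.NOT_ASSESSABLE):
        failing.append(_gate_code(case, "ihc"))
    if failing and log.isEnabledFor(logging.DEBUG):
        log.debug("structural gates failing: %s", [c.id for c in failing])
    return failing


def _sporadic_gate_codes(case: EvidenceCase,
                         check: SporadicCheck) -> tuple[EvidenceCode, ...]:
    """Family-I code(s) carried by an INCONCLUSIVE verdict caused by a
    non-excluded sporadic work-up (non-MLH1 genes)."""
    crc = case.cancer_type is CancerType.CRC
    if check is SporadicCheck.POSITIVE_METHYLATION:
        return (code(case.cancer_type, "I", "IV" if crc else "III"),)
    if check is SporadicCheck.POSITIVE_BRAF:
        return (code(case.cancer_type, "I", "III"),)
    # UNTESTED: every consulted sporadic test is unavailable
    if crc:
        return (code(case.cancer_type, "I", "III"),
                code(case.cancer_type, "I", "IV"))
    return (code(case.cancer_type, "I", "III"),)


def _sporadic_config(case: EvidenceCase) -> str:
    """Classify the sporadic-test result configuration for sub-code lookup."""
    meth = case.tumor.mlh1_promoter_methylation
    braf = case.tumor.braf_v600e
    if case.cancer_type is CancerType.CRC:
        if meth is TernaryResult.NEGATIVE and braf is TernaryResult.NEGATIVE:
            return "both_neg"
        if meth is TernaryResult.NEGATIVE:
            return "meth_neg_only"
        if braf is TernaryResult.NEGATIVE:
            return "braf_neg_only"
        return "untested"
    return "meth_neg" if meth is TernaryResult.NEGATIVE else "untested"


_Fragment = tuple[Category, tuple[EvidenceCode, ...], str]


def _fragment(category: Category, codes: tuple[EvidenceCode, ...],
              comment: str) -> _Fragment:
    return category, codes, comment


def _assess_mlh1(case: EvidenceCase, check: SporadicCheck,
                 pattern: IHCPattern) -> _Fragment:
    ct = case.cancer_type
    crc = ct is CancerType.CRC
    if check is SporadicCheck.POSITIVE_METHYLATION:
        return _fragment(Category.NEUTRAL, (code(ct, "II", "V" if crc else "III"),),
                         "The significance of the MLH1 VUS remains uncertain: "
                         "MLH1 promoter methylation is positive, which marks a "
                         "likely sporadic etiology.")
    if check is SporadicCheck.POSITIVE_BRAF:
        return _fragment(Category.NEUTRAL, (code(ct, "II", "VI"),),
                         "The significance of the MLH1 VUS remains uncertain: "
                         "BRAF p.V600E is positive, which marks a likely "
                         "sporadic etiology in colorectal cancer.")
    if check is SporadicCheck.UNTESTED:
        return _fragment(Category.NEUTRAL, (code(ct, "II", "VII" if crc else "IV"),),
                         "The significance of the MLH1 VUS remains uncertain: "
                         "results of the sporadic-etiology work-up "
                         "(methylation" + ("/BRAF" if crc else "") +
                         ") are unavailable.")
    # sporadic etiology excluded
    if pattern is IHCPattern.MLH1_PMS2_LOSS:
        sub = {"braf_neg_only": "I", "meth_neg_only": "II",
               "both_neg": "III"}[_sporadic_config(case)] if crc else "I"
        return _fragment(Category.POSITIVE, (code(ct, "II", sub),),
                         "Loss of MLH1 and PMS2 with sporadic etiology excluded "
                         "is compatible with biallelic MLH1 inactivation.")
    if pattern in (IHCPattern.ISOLATED_PMS2, IHCPattern.MSH6_MLH1_PMS2_LOSS):
        return _fragment(Category.POSITIVE,
                         (code(ct, "II", "IV" if crc else "II"),),
                         "The IHC pattern is a recognized variant compatible "
                         "with biallelic MLH1 inactivation.")
    if pattern is IHCPattern.ISOLATED_MLH1:
        return _fragment(Category.NEUTRAL,
                         (code(ct, "II", "VIII" if crc else "V"),),
                         "Isolated loss of MLH1 is unusual; a review of the IHC "
                         "findings (and potentially repeat IHC) is warranted.")
    return _out_of_scope(case)


def _assess_pms2(case: EvidenceCase, check: SporadicCheck,
                 pattern: IHCPattern) -> _Fragment:
    ct = case.cancer_type
    crc = ct is CancerType.CRC
    if pattern is IHCPattern.MLH1_PMS2_LOSS:
        # neutral regardless of methylation/BRAF results
        if crc:
            sub = {"both_neg": "IV", "meth_neg_only": "IV", "braf_neg_only": "IV"}.get(
                _sporadic_config(case))
            if sub is None:
                sub = {"POSITIVE_METHYLATION": "V", "POSITIVE_BRAF": "VI",
                       "UNTESTED": "VII"}[check.name]
        else:
            sub = "II" if check is SporadicCheck.EXCLUDED else "III"
        return _fragment(Category.NEUTRAL, (code(ct, "III", sub),),
                         "Loss of both MLH1 and PMS2 suggests an MLH1 alteration "
                         "rather than biallelic PMS2 inactivation; the "
                         "significance of the PMS2 VUS remains uncertain.")
    if pattern is IHCPattern.ISOLATED_PMS2:
        if check is SporadicCheck.EXCLUDED:
            sub = {"both_neg": "I", "meth_neg_only": "II",
                   "braf_neg_only": "III"}[_sporadic_config(case)] if crc else "I"
            return _fragment(Category.POSITIVE, (code(ct, "III", sub),),
                             "Isolated loss of PMS2 with sporadic etiology "
                             "excluded supports biallelic PMS2 inactivation.")
        return _fragment(Category.INCONCLUSIVE, _sporadic_gate_codes(case, check),
                         "The sporadic-etiology work-up (methylation"
                         + ("/BRAF" if crc else "")
                         + ") is positive or unavailable; assessment of the "
                           "PMS2 VUS is excluded.")
    return _out_of_scope(case)


def _assess_msh2(case: EvidenceCase, check: SporadicCheck,
                 pattern: IHCPattern) -> _Fragment:
    ct = case.cancer_type
    if check is not SporadicCheck.EXCLUDED:
        return _fragment(Category.INCONCLUSIVE, _sporadic_gate_codes(case, check),
                         "The sporadic-etiology work-up (methylation"
                         + ("/BRAF" if ct is CancerType.CRC else "")
                         + ") is positive or unavailable; assessment of the "
                           "MSH2 VUS is excluded.")
    if pattern is IHCPattern.MSH2_MSH6_LOSS:
        return _fragment(Category.POSITIVE, (code(ct, "IV", "I"),),
                         "Loss of MSH2 and MSH6 is compatible with biallelic "
                         "MSH2 inactivation and degradation of its "
                         "dimerization partner MSH6.")
    if pattern is IHCPattern.ISOLATED_MSH6:
        return _fragment(Category.POSITIVE, (code(ct, "IV", "II"),),
                         "Isolated loss of MSH6 is a recognized variant "
                         "pattern of biallelic MSH2 inactivation with "
                         "retained nonfunctional MSH2.")
    if pattern is IHCPattern.ISOLATED_MSH2:
        return _fragment(Category.NEUTRAL, (code(ct, "IV", "III"),),
                         "Isolated loss of MSH2 is unusual (MSH6 is normally "
                         "co-lost); a review of the IHC findings is "
                         "recommended. The significance of the MSH2 VUS "
                         "remains uncertain.")
    if pattern is IHCPattern.ALL_FOUR_LOSS:
        return _fragment(Category.NEUTRAL, (code(ct, "IV", "III"),),
                         "All four MMR proteins are lost; the MLH1/PMS2 loss "
                         "could be subclonal and a detailed IHC review is "
                         "recommended. The significance of the MSH2 VUS "
                         "remains uncertain.")
    return _out_of_scope(case)


def _assess_msh6(case: EvidenceCase, check: SporadicCheck,
                 pattern: IHCPattern) -> _Fragment:
    ct = case.cancer_type
    if check is not SporadicCheck.EXCLUDED:
        return _fragment(Category.INCONCLUSIVE, _sporadic_gate_codes(case, check),
                         "The sporadic-etiology work-up (methylation"
                         + ("/BRAF" if ct is CancerType.CRC else "")
                         + ") is positive or unavailable; assessment of the "
                           "MSH6 VUS is excluded.")
    if pattern is IHCPattern.ISOLATED_MSH6:
        return _fragment(Category.POSITIVE, (code(ct, "V", "I"),),
                         "Isolated loss of MSH6 with sporadic etiology excluded "
                         "supports biallelic MSH6 inactivation.")
    if pattern is IHCPattern.MSH2_MSH6_LOSS:
        return _fragment(Category.NEUTRAL, (code(ct, "V", "II"),),
                         "Loss of both MSH2 and MSH6 suggests a likely MSH2 "
                         "alteration; the significance of the MSH6 VUS "
                         "remains uncertain.")
    if pattern is IHCPattern.MSH6_MLH1_PMS2_LOSS:
        return _fragment(Category.NEUTRAL, (code(ct, "V", "III"),),
                         "Loss of MSH6 together with MLH1 and PMS2 suggests a "
                         "secondary loss of MSH6; the significance of the "
                         "MSH6 VUS remains uncertain.")
    return _out_of_scope(case)


def _out_of_scope(case: EvidenceCase) -> _Fragment:
    return _fragment(
        Category.OUT_OF_SCOPE, (),
        f"The combination of evidence entered for this {case.queried_variant.gene.name} "
        "variant falls outside of the current parameters of the algorithm.")


_GENE_STAGE = {
    MMRGene.MLH1: _assess_mlh1,
    MMRGene.PMS2: _assess_pms2,
    MMRGene.MSH2: _assess_msh2,
    MMRGene.MSH6: _assess_msh6,
}


def gene_stage_assess(case: EvidenceCase,
                      threshold: float = PREMM5_THRESHOLD) -> _Fragment:
    """Per-gene verdict fragment; requires all structural gates satisfied."""
    if structural_gate_codes(case, threshold):
        raise ValueError("gene_stage_assess requires all structural gates satisfied")
    check = sporadic_etiology_excluded(case.cancer_type, case.tumor)
    pattern = canonical_ihc_pattern(case.ihc)
    log.debug("gene stage: gene=%s sporadic=%s pattern=%s",
              case.queried_variant.gene.name, check.name, pattern.name)
    return _GENE_STAGE[case.queried_variant.gene](case, check, pattern)


def verdict_comment(category: Category, codes: tuple[EvidenceCode, ...],
                    case: EvidenceCase, detail: str = "") -> str:
    """Explanatory comment naming the gene, the category, and each code."""
    gene = case.queried_variant.gene.name
    cdna = case.queried_variant.cdna
    head = f"{gene} {cdna}: {category.name}."
    if category is Category.OUT_OF_SCOPE:
        body = detail or (f"The combination of evidence entered for this {gene} "
                          "variant falls outside of the current parameters of "
                          "the algorithm.")
        return f"{head} {body}"
    parts = [head]
    if detail:
        parts.append(detail)
    if category is Category.INCONCLUSIVE:
        parts.append("Absent or adverse key evidence: "
                     + "; ".join(f"{c.id}: {c.meaning}" for c in codes) + ".")
    else:
        parts.extend(f"[{c.id}] {c.meaning}." for c in codes)
    return " ".join(parts)


def assess_case(case: EvidenceCase, threshold: float = PREMM5_THRESHOLD,
                with_synopsis: bool = True) -> Verdict:
    """Run the full decision tree on a validated case.

    Deterministic and total over valid inputs.  ``with_synopsis=False``
    skips building the question/answer synopsis (useful for bulk runs).
    """
    violations = validate_case(case)
    if violations:
        raise ValueError("invalid case: " + "; ".join(violations))
    gate_codes = structural_gate_codes(case, threshold)
    if gate_codes:
        category: Category = Category.INCONCLUSIVE
        codes = tuple(gate_codes)
        detail = ("One or more key evidence items are absent; the VUS "
                  "cannot be assessed.")
    else:
        category, codes, detail = gene_stage_assess(case, threshold)
    comment = verdict_comment(category, codes, case, detail)
    synopsis: tuple[tuple[str, str], ...] = ()
    if with_synopsis:
        from .questionnaire import case_synopsis
        synopsis = case_synopsis(case, threshold)
    return Verdict(category=category, codes=tuple(c.id for c in codes),
                   comment=comment, synopsis=synopsis)
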