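"""Question schemas, answer validation, and the answers->case mapping.

The colorectal schema carries 11 radio-button questions; the endometrial
schema is identical minus the BRAF question (BRAF p.V600E is not a criterion
in endometrial cancer), giving 10.  Every question is required.  The PREMM5
score is asked as a threshold yes/no at this layer (radio-button constraint);
the batch layer accepts the numeric score directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .criteria import PREMM5_THRESHOLD, premm5_meets_threshold
from .engine import IHCPattern, biallelic_documented, canonical_ihc_pattern
from .model import (
    CancerType,
    ClinicalEvidence,
    EvidenceCase,
    GermlineFinding,
    IHCPanel,
    IHCStatus,
    MMRGene,
    MSIStatus,
    Ternary,
    TernaryResult,
    TumorProfile,
)

YES_NO = ("Yes", "No")
TERNARY_RESULT = ("Positive", "Negative", "Not tested")

#: questionnaire answer label for each canonical IHC pattern
IHC_ANSWER_BY_PATTERN = {
    IHCPattern.NO_LOSS: "No loss of any MMR protein",
    IHCPattern.MLH1_PMS2_LOSS: "Loss of MLH1 and PMS2",
    IHCPattern.ISOLATED_MLH1: "Isolated loss of MLH1",
    IHCPattern.ISOLATED_PMS2: "Isolated loss of PMS2",
    IHCPattern.MSH2_MSH6_LOSS: "Loss of MSH2 and MSH6",
    IHCPattern.ISOLATED_MSH2: "Isolated loss of MSH2",
    IHCPattern.ISOLATED_MSH6: "Isolated loss of MSH6",
    IHCPattern.MSH6_MLH1_PMS2_LOSS: "Loss of MLH1, PMS2, and MSH6",
    IHCPattern.ALL_FOUR_LOSS: "Loss of all four MMR proteins",
    IHCPattern.OTHER_COMBINATION: "Other combination of losses",
    IHCPattern.NOT_ASSESSABLE: "Not all four proteins stained, or partial/equivocal",
}
_PATTERN_BY_IHC_ANSWER = {v: k for k, v in IHC_ANSWER_BY_PATTERN.items()}

#: a representative panel realizing each pattern (used by answers_to_case)
_PANEL_BY_PATTERN = {
    IHCPattern.NO_LOSS: IHCPanel.all_intact(),
    IHCPattern.MLH1_PMS2_LOSS: IHCPanel.with_lost("MLH1", "PMS2"),
    IHCPattern.ISOLATED_MLH1: IHCPanel.with_lost("MLH1"),
    IHCPattern.ISOLATED_PMS2: IHCPanel.with_lost("PMS2"),
    IHCPattern.MSH2_MSH6_LOSS: IHCPanel.with_lost("MSH2", "MSH6"),
    IHCPattern.ISOLATED_MSH2: IHCPanel.with_lost("MSH2"),
    IHCPattern.ISOLATED_MSH6: IHCPanel.with_lost("MSH6"),
    IHCPattern.MSH6_MLH1_PMS2_LOSS: IHCPanel.with_lost("MLH1", "PMS2", "MSH6"),
    IHCPattern.ALL_FOUR_LOSS: IHCPanel.with_lost("MLH1", "MSH2", "MSH6", "PMS2"),
    IHCPattern.OTHER_COMBINATION: IHCPanel.with_lost("MLH1", "MSH2"),
    IHCPattern.NOT_ASSESSABLE: IHCPanel(*(IHCStatus.NOT_PERFORMED,) * 4),
}


@dataclass(frozen=True)
class Question:
    key: str
    prompt: str
    answers: tuple[str, ...]
    applies_to: frozenset[CancerType] = frozenset({CancerType.CRC, CancerType.EC})

    def __post_init__(self):
        if len(self.answers) < 2:
            raise ValueError(f"question {self.key!r} needs >= 2 answers")


_BOTH = frozenset({CancerType.CRC, CancerType.EC})
_CRC_ONLY = frozenset({CancerType.CRC})

_QUESTIONS: tuple[Question, ...] = (
    Question("vus_count",
             "How many germline variants of uncertain significance were "
             "reported in MMR genes?", ("One", "More than one"), _BOTH),
    Question("gene", "In which MMR gene is the variant under assessment?",
             ("MLH1", "MSH2", "MSH6", "PMS2"), _BOTH),
    Question("other_pathogenic",
             "Is another pathogenic or likely pathogenic germline MMR "
             "alteration present?", YES_NO, _BOTH),
    Question("epcam", "Is a germline EPCAM 3' deletion present?", YES_NO, _BOTH),
    Question("premm5",
             f"Is the PREMM5 risk score at or above {PREMM5_THRESHOLD}%?",
             YES_NO, _BOTH),
    Question("amsterdam", "Are Amsterdam II criteria met?",
             ("Yes", "No", "Unknown"), _BOTH),
    Question("braf", "Tumor BRAF p.V600E result?", TERNARY_RESULT, _CRC_ONLY),
    Question("methylation", "Tumor MLH1 promoter methylation result?",
             TERNARY_RESULT, _BOTH),
    Question("second_hit",
             "Is somatic inactivation of the second allele of the queried "
             "gene documented in the tumor?", YES_NO, _BOTH),
    Question("msi", "Tumor microsatellite instability status?",
             ("MSI-High", "MSS", "Not tested"), _BOTH),
    Question("ihc", "MMR protein IHC result?",
             tuple(IHC_ANSWER_BY_PATTERN[p] for p in IHCPattern), _BOTH),
)


def schema_for(cancer_type: CancerType) -> tuple[Question, ...]:
    """The ordered question schema for a tumor type (11 CRC / 10 EC)."""
    return tuple(q for q in _QUESTIONS if cancer_type in q.applies_to)


def schema_as_dicts(cancer_type: CancerType) -> list[dict]:
    """Machine-readable schema description for UI builders."""
    return [{"key": q.key, "prompt": q.prompt, "answers": list(q.answers)}
            for q in schema_for(cancer_type)]


@dataclass(frozen=True)
class AnswerSet:
    """One complete set of radio-button selections plus the variant fields."""

    cancer_type: CancerType
    answers: dict[str, str] = field(default_factory=dict)
    cdna: str = ""
    protein: str | None = None


def validate_answers(answers: AnswerSet) -> list[str]:
    """All violations: missing questions, out-of-vocabulary labels, empty cDNA."""
    violations: list[str] = []
    schema = schema_for(answers.cancer_type)
    keys = {q.key for q in schema}
    for q in schema:
        chosen = answers.answers.get(q.key)
        if chosen is None:
            violations.append(f"question {q.key!r} ({q.prompt}) not answered")
        elif chosen not in q.answers:
            violations.append(
                f"question {q.key!r}: answer {chosen!r} is not one of {q.answers}")
    for key in answers.answers:
        if key not in keys:
            violations.append(f"unknown question key {key!r}")
    if not answers.cdna.strip():
        violations.append("cdna: the variant's cDNA designation is required")
    return violations


def answers_to_case(answers: AnswerSet,
                    threshold: float = PREMM5_THRESHOLD) -> EvidenceCase:
    """Deterministic mapping from a valid answer set to an evidence case.

    Round-trips: ``case_to_answers(answers_to_case(a)) == a``.
    """
    violations = validate_answers(answers)
    if violations:
        raise ValueError("invalid answers: " + "; ".join(violations))
    a = answers.answers
    crc = answers.cancer_type is CancerType.CRC
    pattern = _PATTERN_BY_IHC_ANSWER[a["ihc"]]
    return EvidenceCase(
        cancer_type=answers.cancer_type,
        germline_vus_count=1 if a["vus_count"] == "One" else 2,
        queried_variant=GermlineFinding(
            gene=MMRGene.parse(a["gene"]), cdna=answers.cdna,
            protein=answers.protein),
        other_pathogenic_mmr_germline=a["other_pathogenic"] == "Yes",
        epcam_3prime_deletion=a["epcam"] == "Yes",
        clinical=ClinicalEvidence(
            premm5_percent=threshold if a["premm5"] == "Yes" else None,
            amsterdam_ii_met=Ternary.parse(a["amsterdam"])),
        tumor=TumorProfile(
            braf_v600e=TernaryResult.parse(a["braf"]) if crc
                else TernaryResult.NOT_TESTED,
            mlh1_promoter_methylation=TernaryResult.parse(a["methylation"]),
            msi=MSIStatus.parse(a["msi"]),
            somatic_events=(),
            biallelic_documented_override=a["second_hit"] == "Yes"),
        ihc=_PANEL_BY_PATTERN[pattern],
    )


def case_to_answers(case: EvidenceCase,
                    threshold: float = PREMM5_THRESHOLD) -> AnswerSet:
    """Project an evidence case onto the questionnaire's answer labels."""
    t = case.tumor
    mapping = {
        "vus_count": "One" if case.germline_vus_count == 1 else "More than one",
        "gene": case.queried_variant.gene.name,
        "other_pathogenic": "Yes" if case.other_pathogenic_mmr_germline else "No",
        "epcam": "Yes" if case.epcam_3prime_deletion else "No",
        "premm5": "Yes" if premm5_meets_threshold(
            case.clinical.premm5_percent, threshold) else "No",
        "amsterdam": {Ternary.TRUE: "Yes", Ternary.FALSE: "No",
                      Ternary.UNKNOWN: "Unknown"}[case.clinical.amsterdam_ii_met],
        "braf": {TernaryResult.POSITIVE: "Positive",
                 TernaryResult.NEGATIVE: "Negative",
                 TernaryResult.NOT_TESTED: "Not tested"}[t.braf_v600e],
        "methylation": {TernaryResult.POSITIVE: "Positive",
                        TernaryResult.NEGATIVE: "Negative",
                        TernaryResult.NOT_TESTED: "Not tested"}[
                            t.mlh1_promoter_methylation],
        "second_hit": "Yes" if biallelic_documented(
            case.queried_variant.gene, t) else "No",
        "msi": {MSIStatus.MSI_HIGH: "MSI-High", MSIStatus.MSS: "MSS",
                MSIStatus.NOT_TESTED: "Not tested"}[t.msi],
        "ihc": IHC_ANSWER_BY_PATTERN[canonical_ihc_pattern(case.ihc)],
    }
    applicable = {q.key for q in schema_for(case.cancer_type)}
    return AnswerSet(
        cancer_type=case.cancer_type,
        answers={k: v for k, v in mapping.items() if k in applicable},
        cdna=case.queried_variant.cdna,
        protein=case.queried_variant.protein,
    )


def case_synopsis(case: EvidenceCase,
                  threshold: float = PREMM5_THRESHOLD) -> tuple[tuple[str, str], ...]:
    """Ordered (question, answer) pairs summarizing a case for the synopsis."""
    answers = case_to_answers(case, threshold)
    return tuple((q.prompt, answers.answers[q.key])
                 for q in schema_for(case.cancer_type))
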