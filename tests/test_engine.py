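"""Decision-tree unit tests: IHC canonicalization, sporadic-etiology routing,
structural gates, and per-gene verdicts."""

import dataclasses

import pytest

from lynchvus import (
    CancerType,
    Category,
    IHCPanel,
    IHCPattern,
    IHCStatus,
    MMRGene,
    SomaticEvent,
    SomaticKind,
    SporadicCheck,
    TernaryResult,
    TumorProfile,
    assess_case,
    biallelic_documented,
    canonical_ihc_pattern,
    gene_stage_assess,
    sporadic_etiology_excluded,
    structural_gate_codes,
    verdict_comment,
)
from lynchvus.engine import CODE_REGISTRY


@pytest.mark.parametrize("panel, expected", [
    (IHCPanel.with_lost("MSH2", "MSH6"), IHCPattern.MSH2_MSH6_LOSS),
    (IHCPanel.all_intact(), IHCPattern.NO_LOSS),
    (IHCPanel(mlh1=IHCStatus.INTACT, msh2=IHCStatus.INTACT,
              msh6=IHCStatus.PARTIAL_LOSS, pms2=IHCStatus.LOST),
     IHCPattern.NOT_ASSESSABLE),
    (IHCPanel(mlh1=IHCStatus.INTACT, msh2=IHCStatus.LOST,
              msh6=IHCStatus.EQUIVOCAL, pms2=IHCStatus.INTACT),
     IHCPattern.NOT_ASSESSABLE),
    (IHCPanel.with_lost("MLH1", "PMS2"), IHCPattern.MLH1_PMS2_LOSS),
    (IHCPanel.with_lost("MLH1", "PMS2", "MSH6"), IHCPattern.MSH6_MLH1_PMS2_LOSS),
    (IHCPanel.with_lost("MLH1", "MSH2", "MSH6", "PMS2"), IHCPattern.ALL_FOUR_LOSS),
    (IHCPanel.with_lost("MSH6"), IHCPattern.ISOLATED_MSH6),
    (IHCPanel.with_lost("MLH1", "MSH2"), IHCPattern.OTHER_COMBINATION),
])
def test_canonical_ihc_pattern(panel, expected):
    assert canonical_ihc_pattern(panel) is expected


def _tumor(events=(), override=None, **kwargs):
    return TumorProfile(somatic_events=tuple(events),
                        biallelic_documented_override=override, **kwargs)


class TestBiallelicDocumented:
    def test_copy_loss_counts_regardless_of_flag(self):
        tumor = _tumor([SomaticEvent(MMRGene.PMS2, "PMS2 one copy loss",
                                     SomaticKind.COPY_LOSS, inactivating=False)])
        assert biallelic_documented(MMRGene.PMS2, tumor)

    def test_no_events_and_no_override_is_undocumented(self):
        assert not biallelic_documented(MMRGene.MSH6, _tumor())

    def test_event_in_other_gene_does_not_count(self):
        tumor = _tumor([SomaticEvent(MMRGene.MSH2, "MSH2 p.R711*",
                                     inactivating=True)])
        assert not biallelic_documented(MMRGene.MSH6, tumor)

    def test_non_inactivating_event_does_not_count(self):
        tumor = _tumor([SomaticEvent(MMRGene.PMS2, "PMS2 p.L135P",
                                     inactivating=False)])
        assert not biallelic_documented(MMRGene.PMS2, tumor)

    def test_questionnaire_override(self):
        assert biallelic_documented(MMRGene.MLH1, _tumor(override=True))


NEG, POS, NT = (TernaryResult.NEGATIVE, TernaryResult.POSITIVE,
                TernaryResult.NOT_TESTED)


@pytest.mark.parametrize("cancer, braf, meth, expected", [
    ("CRC", NEG, NT, SporadicCheck.EXCLUDED),   # BRAF-negative alone suffices
    ("CRC", NT, NEG, SporadicCheck.EXCLUDED),
    ("CRC", NEG, NEG, SporadicCheck.EXCLUDED),
    ("CRC", POS, NEG, SporadicCheck.POSITIVE_BRAF),
    ("CRC", NEG, POS, SporadicCheck.POSITIVE_METHYLATION),
    ("CRC", NT, NT, SporadicCheck.UNTESTED),
    ("EC", NT, NT, SporadicCheck.UNTESTED),     # EC requires methylation
    ("EC", NEG, NT, SporadicCheck.UNTESTED),    # BRAF never consulted for EC
    ("EC", POS, NEG, SporadicCheck.EXCLUDED),
    ("EC", NT, POS, SporadicCheck.POSITIVE_METHYLATION),
])
def test_sporadic_etiology_check(cancer, braf, meth, expected):
    tumor = _tumor(braf_v600e=braf, mlh1_promoter_methylation=meth)
    assert sporadic_etiology_excluded(CancerType.parse(cancer), tumor) is expected


class TestStructuralGates:
    def test_all_gates_satisfied(self, make_case):
        assert structural_gate_codes(make_case()) == []

    def test_low_premm_and_missing_second_hit(self, make_case):
        case = make_case(cancer_type="EC", gene="PMS2", premm5=2.0,
                         braf="NOT_TESTED", lost=("PMS2",), somatic=())
        codes = [c.id for c in structural_gate_codes(case)]
        assert codes == ["EC I-II", "EC I-IV"]

    def test_normal_ihc(self, make_case):
        case = make_case(gene="MLH1", premm5=27.5, lost=())
        assert [c.id for c in structural_gate_codes(case)] == ["CRC I-VII"]

    def test_multiple_vus_and_epcam(self, make_case):
        case = make_case(germline_vus_count=2)
        assert [c.id for c in structural_gate_codes(case)] == ["CRC I-I"]
        case = make_case(epcam_3prime_deletion=True)
        assert [c.id for c in structural_gate_codes(case)] == ["CRC I-I"]

    def test_msi_gate_uses_cancer_specific_index(self, make_case):
        crc = make_case(msi="MSS")
        ec = make_case(cancer_type="EC", msi="MSS", braf="NOT_TESTED")
        assert [c.id for c in structural_gate_codes(crc)] == ["CRC I-VI"]
        assert [c.id for c in structural_gate_codes(ec)] == ["EC I-V"]


class TestGeneStage:
    def test_requires_gates_satisfied(self, make_case):
        with pytest.raises(ValueError, match="gates"):
            gene_stage_assess(make_case(premm5=1.0))

    def test_msh6_isolated_loss_is_positive(self, make_case):
        case = make_case(gene="MSH6", cdna="c.3436C>T", premm5=4.2,
                         lost=("MSH6",))
        category, codes, _ = gene_stage_assess(case)
        assert category is Category.POSITIVE
        assert codes[0].id == "CRC V-I"

    def test_mlh1_dimer_loss_with_copy_loss_hit_is_positive(self, make_case):
        case = make_case(gene="MLH1", premm5=5.7, lost=("MLH1", "PMS2"),
                         somatic=(SomaticEvent(MMRGene.MLH1,
                                               "MLH1 single-copy loss",
                                               SomaticKind.COPY_LOSS),))
        category, codes, _ = gene_stage_assess(case)
        assert category is Category.POSITIVE
        assert codes[0].family == "II"

    def test_unenumerated_combination_is_out_of_scope(self, make_case):
        # MSH6 VUS in an EC tumor with isolated PMS2 loss: no branch covers it
        case = make_case(cancer_type="EC", gene="MSH6", braf="NOT_TESTED",
                         lost=("PMS2",))
        category, codes, _ = gene_stage_assess(case)
        assert category is Category.OUT_OF_SCOPE
        assert codes == ()

    def test_pms2_dimer_loss_neutral_even_with_positive_methylation(self, make_case):
        case = make_case(gene="PMS2", methylation="POSITIVE",
                         lost=("MLH1", "PMS2"))
        category, codes, _ = gene_stage_assess(case)
        assert category is Category.NEUTRAL
        assert codes[0].family == "III"

    def test_msh2_untested_sporadic_is_inconclusive_with_gate_codes(self, make_case):
        case = make_case(braf="NOT_TESTED", methylation="NOT_TESTED")
        category, codes, _ = gene_stage_assess(case)
        assert category is Category.INCONCLUSIVE
        assert {c.id for c in codes} == {"CRC I-III", "CRC I-IV"}

    def test_mlh1_untested_sporadic_is_neutral(self, make_case):
        case = make_case(gene="MLH1", braf="NOT_TESTED",
                         methylation="NOT_TESTED", lost=("MLH1", "PMS2"))
        category, codes, _ = gene_stage_assess(case)
        assert category is Category.NEUTRAL
        assert codes[0].id == "CRC II-VII"


class TestAssessCase:
    def test_full_concordant_msh2_case_is_positive(self, make_case):
        verdict = assess_case(make_case(premm5=6.7))
        assert verdict.category is Category.POSITIVE
        assert verdict.codes == ("CRC IV-I",)
        assert len(verdict.synopsis) == 11

    def test_missing_second_hit_is_inconclusive(self, make_case):
        case = make_case(gene="MLH1", premm5=20.3, lost=("MLH1", "PMS2"),
                         somatic=())
        verdict = assess_case(case)
        assert verdict.category is Category.INCONCLUSIVE
        assert verdict.codes == ("CRC I-V",)

    def test_everything_absent_carries_several_codes(self, make_case):
        case = make_case(premm5=None, braf="NOT_TESTED",
                         methylation="NOT_TESTED", msi="NOT_TESTED",
                         somatic=(), lost=())
        verdict = assess_case(case)
        assert verdict.category is Category.INCONCLUSIVE
        assert len(verdict.codes) >= 3

    def test_invalid_case_raises_listing_violations(self, make_case):
        with pytest.raises(ValueError, match="premm5_percent"):
            assess_case(make_case(premm5=130.0))

    def test_deterministic(self, make_case):
        case = make_case()
        assert assess_case(case) == assess_case(case)

    def test_positive_and_neutral_carry_exactly_one_scenario_code(self, make_case):
        for verdict in (assess_case(make_case()),
                        assess_case(make_case(gene="MSH6",
                                              lost=("MSH2", "MSH6")))):
            assert verdict.category in (Category.POSITIVE, Category.NEUTRAL)
            assert len(verdict.codes) == 1
            family = verdict.codes[0].split()[1].split("-")[0]
            assert family in ("II", "III", "IV", "V")


class TestVerdictComment:
    def test_inconclusive_comment_names_absent_evidence(self, make_case):
        case = make_case(gene="MLH1", lost=())
        code = CODE_REGISTRY["CRC I-VII"]
        text = verdict_comment(Category.INCONCLUSIVE, (code,), case)
        assert "IHC" in text and "MLH1" in text

    def test_positive_comment_names_gene(self, make_case):
        code = CODE_REGISTRY["CRC IV-I"]
        text = verdict_comment(Category.POSITIVE, (code,), make_case())
        assert "MSH2" in text and "POSITIVE" in text

    def test_out_of_scope_phrase(self, make_case):
        text = verdict_comment(Category.OUT_OF_SCOPE, (), make_case())
        assert "falls outside of the current parameters of the algorithm" in text


def test_code_registry_ids_unique_and_cancer_typed():
    ids = list(CODE_REGISTRY)
    assert len(ids) == len(set(ids))
    assert all(code.id == key for key, code in CODE_REGISTRY.items())
    crc = [c for c in CODE_REGISTRY.values() if c.cancer_type is CancerType.CRC]
    ec = [c for c in CODE_REGISTRY.values() if c.cancer_type is CancerType.EC]
    # EC has one fewer family-I code (no BRAF criterion)
    assert len([c for c in crc if c.family == "I"]) == 7
    assert len([c for c in ec if c.family == "I"]) == 6


def test_ec_verdicts_ignore_braf(make_case):
    base = make_case(cancer_type="EC", braf="NOT_TESTED")
    for braf in (NEG, POS, NT):
        alt = dataclasses.replace(
            base, tumor=dataclasses.replace(base.tumor, braf_v600e=braf))
        assert assess_case(alt, with_synopsis=False).codes == \
            assess_case(base, with_synopsis=False).codes
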