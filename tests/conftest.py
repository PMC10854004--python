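import pytest

from lynchvus import (
    CancerType,
    ClinicalEvidence,
    EvidenceCase,
    GermlineFinding,
    IHCPanel,
    MMRGene,
    MSIStatus,
    SomaticEvent,
    SomaticKind,
    Ternary,
    TernaryResult,
    TumorProfile,
)


@pytest.fixture
def make_case():
    """Factory for a fully concordant case (POSITIVE unless overridden)."""

    def build(cancer_type="CRC", gene="MSH2", cdna="c.226C>T", premm5=6.7,
              amsterdam=Ternary.UNKNOWN, braf="NEGATIVE", methylation="NEGATIVE",
              msi="MSI_HIGH", lost=("MSH2", "MSH6"), somatic=None, **kwargs):
        gene = MMRGene.parse(gene)
        if somatic is None:
            somatic = (SomaticEvent(gene=gene, description="somatic hit",
                                    kind=SomaticKind.SNV_INDEL,
                                    inactivating=True),)
        return EvidenceCase(
            cancer_type=CancerType.parse(cancer_type),
            queried_variant=GermlineFinding(gene=gene, cdna=cdna),
            clinical=ClinicalEvidence(premm5_percent=premm5,
                                      amsterdam_ii_met=amsterdam),
            tumor=TumorProfile(
                braf_v600e=TernaryResult.parse(braf),
                mlh1_promoter_methylation=TernaryResult.parse(methylation),
                msi=MSIStatus.parse(msi),
                somatic_events=tuple(somatic)),
            ihc=IHCPanel.with_lost(*lost),
            **kwargs,
        )

    return build
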