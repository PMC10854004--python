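"""Domain types and case-level validation.

The decision tree consumes one :class:`EvidenceCase` per patient/tumor: the
queried germline mismatch-repair (MMR) variant, clinical criteria (PREMM5
score, Amsterdam II status), the tumor molecular profile (sporadic-etiology
tests, microsatellite instability, somatic second-hit events) and the
four-protein MMR immunohistochemistry (IHC) panel.

Controlled vocabularies are small fixed enums.  Each enum carries a
``parse`` classmethod that also accepts the loosely spelled strings found in
clinical report transcriptions ("MSI-S", "Neg", "N/A", "hypermethylation",
blank cells) and normalizes them to the canonical label; anything outside
the vocabulary raises ``ValueError``.

HGVS cDNA/protein strings are opaque identifiers here: they are checked for
non-emptiness only, never parsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class _Vocab(Enum):
    """Enum base with lenient string normalization."""

    #: per-subclass map of lowercase aliases -> member name
    @classmethod
    def _aliases(cls) -> dict[str, str]:
        return {}

    @classmethod
    def parse(cls, value):
        if isinstance(value, cls):
            return value
        text = str(value).strip()
        key = text.lower()
        aliases = cls._aliases()
        if key in aliases:
            return cls[aliases[key]]
        for member in cls:
            if key == member.name.lower() or key == str(member.value).lower():
                return member
        raise ValueError(f"{cls.__name__}: unrecognized label {text!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


class MMRGene(_Vocab):
    """The four mismatch-repair genes assessed."""

    MLH1 = "MLH1"
    MSH2 = "MSH2"
    MSH6 = "MSH6"
    PMS2 = "PMS2"


class CancerType(_Vocab):
    """Tumor types in scope: colorectal (CRC) and endometrial (EC)."""

    CRC = "CRC"
    EC = "EC"

    @classmethod
    def _aliases(cls):
        return {
            "colorectal": "CRC",
            "colorectal cancer": "CRC",
            "endometrial": "EC",
            "endometrial cancer": "EC",
        }


class TernaryResult(_Vocab):
    """Result of a yes/no tumor assay (BRAF p.V600E, MLH1 promoter methylation)."""

    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    NOT_TESTED = "NOT_TESTED"

    @classmethod
    def _aliases(cls):
        return {
            "neg": "NEGATIVE",
            "negative": "NEGATIVE",
            "unmethylated": "NEGATIVE",
            "unmethylated mlh1 promoter": "NEGATIVE",
            "pos": "POSITIVE",
            "positive": "POSITIVE",
            "hypermethylation": "POSITIVE",
            "mlh1 promoter hyper methylation": "POSITIVE",
            "mlh1 promoter hypermethylation": "POSITIVE",
            "na": "NOT_TESTED",
            "n/a": "NOT_TESTED",
            "none": "NOT_TESTED",
            "not tested": "NOT_TESTED",
            "": "NOT_TESTED",
        }


class MSIStatus(_Vocab):
    """Microsatellite instability phenotype of the tumor."""

    MSI_HIGH = "MSI_HIGH"
    MSS = "MSS"
    NOT_TESTED = "NOT_TESTED"

    @classmethod
    def _aliases(cls):
        return {
            "msi-high": "MSI_HIGH",
            "msi-h": "MSI_HIGH",
            "msi high": "MSI_HIGH",
            "msi-s": "MSS",
            "stable": "MSS",
            "microsatellite stable": "MSS",
            "none": "NOT_TESTED",
            "n/a": "NOT_TESTED",
            "na": "NOT_TESTED",
            "not tested": "NOT_TESTED",
            "": "NOT_TESTED",
        }


class IHCStatus(_Vocab):
    """Nuclear staining call for one MMR protein."""

    LOST = "LOST"
    INTACT = "INTACT"
    EQUIVOCAL = "EQUIVOCAL"
    PARTIAL_LOSS = "PARTIAL_LOSS"
    NOT_PERFORMED = "NOT_PERFORMED"

    @classmethod
    def _aliases(cls):
        return {
            "loss": "LOST",
            "lost": "LOST",
            "absent": "LOST",
            "intact": "INTACT",
            "normal": "INTACT",
            "retained": "INTACT",
            "equivocal": "EQUIVOCAL",
            "partial": "PARTIAL_LOSS",
            "partial loss": "PARTIAL_LOSS",
            "not performed": "NOT_PERFORMED",
            "n/a": "NOT_PERFORMED",
            "": "NOT_PERFORMED",
        }


class GermlineClass(_Vocab):
    """Classification of the queried germline finding."""

    VUS = "VUS"
    PATHOGENIC_OR_LP = "PATHOGENIC_OR_LP"


class SomaticKind(_Vocab):
    """Mechanistic class of a somatic event at an MMR locus."""

    SNV_INDEL = "SNV_INDEL"
    COPY_LOSS = "COPY_LOSS"
    COPY_GAIN = "COPY_GAIN"
    STRUCTURAL = "STRUCTURAL"


class Ternary(_Vocab):
    """Three-valued flag (Amsterdam II status and similar)."""

    TRUE = "TRUE"
    FALSE = "FALSE"
    UNKNOWN = "UNKNOWN"

    @classmethod
    def _aliases(cls):
        return {"yes": "TRUE", "no": "FALSE", "": "UNKNOWN"}


class Category(_Vocab):
    """Verdict categories rendered by the decision tree."""

    POSITIVE = "POSITIVE"
    NEUTRAL = "NEUTRAL"
    INCONCLUSIVE = "INCONCLUSIVE"
    OUT_OF_SCOPE = "OUT_OF_SCOPE"


@dataclass(frozen=True)
class IHCPanel:
    """Per-protein staining status for the four MMR proteins."""

    mlh1: IHCStatus
    msh2: IHCStatus
    msh6: IHCStatus
    pms2: IHCStatus

    def as_dict(self) -> dict[str, IHCStatus]:
        return {"MLH1": self.mlh1, "MSH2": self.msh2,
                "MSH6": self.msh6, "PMS2": self.pms2}

    @classmethod
    def all_intact(cls) -> "IHCPanel":
        return cls(*(IHCStatus.INTACT,) * 4)

    @classmethod
    def with_lost(cls, *genes: str) -> "IHCPanel":
        """Panel with the named proteins LOST and the rest INTACT."""
        lost = {g.upper() for g in genes}
        return cls(**{
            name.lower(): IHCStatus.LOST if name in lost else IHCStatus.INTACT
            for name in ("MLH1", "MSH2", "MSH6", "PMS2")
        })


@dataclass(frozen=True)
class GermlineFinding:
    """One germline MMR finding; the variant under assessment."""

    gene: MMRGene
    cdna: str
    protein: str | None = None
    classification: GermlineClass = GermlineClass.VUS


@dataclass(frozen=True)
class SomaticEvent:
    """A somatic alteration observed in the tumor at an MMR locus.

    ``inactivating`` is an assertion supplied by the annotator (e.g. the
    reporting laboratory); it is NOT inferred from the description.  Copy
    losses are always treated as inactivating by the engine.
    """

    gene: MMRGene
    description: str
    kind: SomaticKind = SomaticKind.SNV_INDEL
    inactivating: bool = False


@dataclass(frozen=True)
class ClinicalEvidence:
    """Clinical criteria inputs: PREMM5 percent risk and Amsterdam II flag."""

    premm5_percent: float | None = None
    amsterdam_ii_met: Ternary = Ternary.UNKNOWN


@dataclass(frozen=True)
class TumorProfile:
    """Tumor molecular profile.

    ``braf_v600e`` is carried for endometrial cases but never consulted by
    the decision tree (BRAF is a colorectal-only criterion).
    ``biallelic_documented_override`` lets questionnaire users answer the
    second-hit question directly instead of listing events.
    """

    braf_v600e: TernaryResult = TernaryResult.NOT_TESTED
    mlh1_promoter_methylation: TernaryResult = TernaryResult.NOT_TESTED
    msi: MSIStatus = MSIStatus.NOT_TESTED
    somatic_events: tuple[SomaticEvent, ...] = ()
    biallelic_documented_override: bool | None = None


@dataclass(frozen=True)
class EvidenceCase:
    """One patient/tumor evidence bundle submitted for assessment."""

    cancer_type: CancerType
    queried_variant: GermlineFinding
    germline_vus_count: int = 1
    other_pathogenic_mmr_germline: bool = False
    epcam_3prime_deletion: bool = False
    clinical: ClinicalEvidence = field(default_factory=ClinicalEvidence)
    tumor: TumorProfile = field(default_factory=TumorProfile)
    ihc: IHCPanel = field(default_factory=IHCPanel.all_intact)


@dataclass(frozen=True)
class Verdict:
    """Decision-tree output: category, evidence codes, comment, synopsis."""

    category: Category
    codes: tuple[str, ...]
    comment: str
    synopsis: tuple[tuple[str, str], ...] = ()


def _check(violations: list[str], ok: bool, message: str) -> None:
    if not ok:
        violations.append(message)


def validate_case(case: EvidenceCase) -> list[str]:
    """Return all invariant violations of ``case`` (empty list = valid).

    Violations are returned, never raised; each message names the offending
    field. The function is pure.
    """
    v: list[str] = []
    _check(v, isinstance(case.cancer_type, CancerType),
           "cancer_type: not a CancerType label")
    g = case.queried_variant
    _check(v, isinstance(g, GermlineFinding), "queried_variant: missing")
    if isinstance(g, GermlineFinding):
        _check(v, isinstance(g.gene, MMRGene),
               "queried_variant.gene: not an MMR gene label")
        _check(v, isinstance(g.cdna, str) and g.cdna.strip() != "",
               "queried_variant.cdna: must be non-empty")
        _check(v, isinstance(g.classification, GermlineClass),
               "queried_variant.classification: not a recognized label")
    _check(v, isinstance(case.germline_vus_count, int)
           and case.germline_vus_count >= 0,
           "germline_vus_count: must be a non-negative integer")
    if isinstance(case.germline_vus_count, int) and isinstance(g, GermlineFinding):
        _check(v, case.germline_vus_count >= 1,
               "germline_vus_count: must be >= 1 when a queried variant is present")
    c = case.clinical
    if c.premm5_percent is not None:
        _check(v, isinstance(c.premm5_percent, (int, float))
               and 0.0 <= float(c.premm5_percent) <= 100.0,
               "clinical.premm5_percent: must lie in [0, 100]")
    _check(v, isinstance(c.amsterdam_ii_met, Ternary),
           "clinical.amsterdam_ii_met: not a TRUE/FALSE/UNKNOWN label")
    t = case.tumor
    _check(v, isinstance(t.braf_v600e, TernaryResult),
           "tumor.braf_v600e: not a POSITIVE/NEGATIVE/NOT_TESTED label")
    _check(v, isinstance(t.mlh1_promoter_methylation, TernaryResult),
           "tumor.mlh1_promoter_methylation: not a POSITIVE/NEGATIVE/NOT_TESTED label")
    _check(v, isinstance(t.msi, MSIStatus), "tumor.msi: not an MSI label")
    for i, ev in enumerate(t.somatic_events):
        _check(v, isinstance(ev.gene, MMRGene),
               f"tumor.somatic_events[{i}].gene: not an MMR gene label")
        _check(v, isinstance(ev.description, str) and ev.description.strip() != "",
               f"tumor.somatic_events[{i}].description: must be non-empty")
        _check(v, isinstance(ev.kind, SomaticKind),
               f"tumor.somatic_events[{i}].kind: not a recognized label")
    for name, status in case.ihc.as_dict().items():
        _check(v, isinstance(status, IHCStatus),
               f"ihc.{name.lower()}: not an IHC staining label")
    return v


# ---------------------------------------------------------------------------
# Flat key:value (de)serialization for batch files
# ---------------------------------------------------------------------------

#: column order of the flat representation; names are field paths
FLAT_COLUMNS = (
    "cancer_type",
    "germline_vus_count",
    "queried_variant.gene",
    "queried_variant.cdna",
    "queried_variant.protein",
    "queried_variant.classification",
    "other_pathogenic_mmr_germline",
    "epcam_3prime_deletion",
    "clinical.premm5_percent",
    "clinical.amsterdam_ii_met",
    "tumor.braf_v600e",
    "tumor.mlh1_promoter_methylation",
    "tumor.msi",
    "tumor.somatic_events",
    "tumor.biallelic_documented_override",
    "ihc.mlh1",
    "ihc.msh2",
    "ihc.msh6",
    "ihc.pms2",
)


def _encode_events(events: tuple[SomaticEvent, ...]) -> str:
    return ";".join(
        "|".join([e.gene.name, e.description, e.kind.name,
                  "yes" if e.inactivating else "no"])
        for e in events
    )


def _decode_events(text: str) -> tuple[SomaticEvent, ...]:
    text = text.strip()
    if not text:
        return ()
    events = []
    for chunk in text.split(";"):
        parts = chunk.split("|")
        if len(parts) != 4:
            raise ValueError(
                f"tumor.somatic_events: expected gene|description|kind|yes-no, got {chunk!r}")
        gene, desc, kind, inact = (p.strip() for p in parts)
        events.append(SomaticEvent(
            gene=MMRGene.parse(gene), description=desc,
            kind=SomaticKind.parse(kind),
            inactivating=inact.lower() in ("yes", "true", "1")))
    return tuple(events)


def case_to_flat(case: EvidenceCase) -> dict[str, str]:
    """Serialize a case to the flat column dictionary used by batch files."""
    t, c, g = case.tumor, case.clinical, case.queried_variant
    override = t.biallelic_documented_override
    return {
        "cancer_type": case.cancer_type.name,
        "germline_vus_count": str(case.germline_vus_count),
        "queried_variant.gene": g.gene.name,
        "queried_variant.cdna": g.cdna,
        "queried_variant.protein": g.protein or "",
        "queried_variant.classification": g.classification.name,
        "other_pathogenic_mmr_germline": "yes" if case.other_pathogenic_mmr_germline else "no",
        "epcam_3prime_deletion": "yes" if case.epcam_3prime_deletion else "no",
        "clinical.premm5_percent": "" if c.premm5_percent is None else repr(float(c.premm5_percent)),
        "clinical.amsterdam_ii_met": c.amsterdam_ii_met.name,
        "tumor.braf_v600e": t.braf_v600e.name,
        "tumor.mlh1_promoter_methylation": t.mlh1_promoter_methylation.name,
        "tumor.msi": t.msi.name,
        "tumor.somatic_events": _encode_events(t.somatic_events),
        "tumor.biallelic_documented_override":
            "" if override is None else ("yes" if override else "no"),
        "ihc.mlh1": case.ihc.mlh1.name,
        "ihc.msh2": case.ihc.msh2.name,
        "ihc.msh6": case.ihc.msh6.name,
        "ihc.pms2": case.ihc.pms2.name,
    }


def case_from_flat(row: dict[str, str]) -> EvidenceCase:
    """Build a case from a flat column dictionary (inverse of case_to_flat)."""
    def get(key: str, default: str = "") -> str:
        value = row.get(key, default)
        return "" if value is None else str(value).strip()

    premm_raw = get("clinical.premm5_percent")
    override_raw = get("tumor.biallelic_documented_override")
    protein = get("queried_variant.protein")
    return EvidenceCase(
        cancer_type=CancerType.parse(get("cancer_type")),
        germline_vus_count=int(get("germline_vus_count", "1") or 1),
        queried_variant=GermlineFinding(
            gene=MMRGene.parse(get("queried_variant.gene")),
            cdna=get("queried_variant.cdna"),
            protein=protein or None,
            classification=GermlineClass.parse(
                get("queried_variant.classification", "VUS") or "VUS"),
        ),
        other_pathogenic_mmr_germline=get("other_pathogenic_mmr_germline", "no").lower()
            in ("yes", "true", "1"),
        epcam_3prime_deletion=get("epcam_3prime_deletion", "no").lower()
            in ("yes", "true", "1"),
        clinical=ClinicalEvidence(
            premm5_percent=float(premm_raw) if premm_raw else None,
            amsterdam_ii_met=Ternary.parse(get("clinical.amsterdam_ii_met", "UNKNOWN")),
        ),
        tumor=TumorProfile(
            braf_v600e=TernaryResult.parse(get("tumor.braf_v600e")),
            mlh1_promoter_methylation=TernaryResult.parse(
                get("tumor.mlh1_promoter_methylation")),
            msi=MSIStatus.parse(get("tumor.msi")),
            somatic_events=_decode_events(get("tumor.somatic_events")),
            biallelic_documented_override=None if not override_raw
                else override_raw.lower() in ("yes", "true", "1"),
        ),
        ihc=IHCPanel(
            mlh1=IHCStatus.parse(get("ihc.mlh1", "NOT_PERFORMED")),
            msh2=IHCStatus.parse(get("ihc.msh2", "NOT_PERFORMED")),
            msh6=IHCStatus.parse(get("ihc.msh6", "NOT_PERFORMED")),
            pms2=IHCStatus.parse(get("ihc.pms2", "NOT_PERFORMED")),
        ),
    )
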