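"""Packaged control cohort, evaluation harness, and case generators.

The packaged table (``data/controls.tsv``) transcribes 52 positive-control
patients: suspected-Lynch-syndrome cases with a known pathogenic germline
MMR alteration and the tumor evidence recorded for each.  Running the
decision tree over them, treating each pathogenic alteration as if it were
the queried VUS, measures whether the tree recovers the expected outcome:
POSITIVE whenever every evidence item is present and concordant, and a
flagged non-POSITIVE verdict otherwise.

Also provided: an exhaustive enumerator over the questionnaire answer space
(the oracle substrate for the engine's property tests) and a seeded random
case generator.
"""

from __future__ import annotations

import itertools
import random
import re
from dataclasses import dataclass, field
from importlib import resources

from .criteria import PREMM5_THRESHOLD
from .engine import assess_case
from .model import (
    CancerType,
    Category,
    ClinicalEvidence,
    EvidenceCase,
    GermlineClass,
    GermlineFinding,
    IHCPanel,
    IHCStatus,
    MMRGene,
    MSIStatus,
    SomaticEvent,
    SomaticKind,
    Ternary,
    TernaryResult,
    TumorProfile,
)
from .questionnaire import AnswerSet, schema_for

_PROTEINS = ("MLH1", "MSH2", "MSH6", "PMS2")


@dataclass(frozen=True)
class ControlRecord:
    """One transcribed control row; ``printed_code`` is provenance only."""

    subject_id: int
    cancer_type: CancerType
    premm5_percent: float
    germline: GermlineFinding
    braf: TernaryResult
    methylation: TernaryResult
    msi: MSIStatus
    ihc: IHCPanel
    somatic_events: tuple[SomaticEvent, ...]
    printed_code: str
    expected_class: str  # POSITIVE | NON_POSITIVE
    reported_organ: str = ""


def _parse_premm(text: str, subject: int) -> float:
    cleaned = text.strip().strip("[]").lstrip(">").rstrip("%").strip()
    try:
        value = float(cleaned)
    except ValueError as exc:
        raise ValueError(f"subject {subject}: unreadable PREMM score {text!r}") from exc
    if not 0 <= value <= 100:
        raise ValueError(f"subject {subject}: PREMM score {value} outside [0,100]")
    return value


def _parse_ihc(text: str, subject: int) -> IHCPanel:
    """Parse a free-text staining summary, e.g. 'Loss of MSH2 and equivocal
    MSH6**', into a four-protein panel (unmentioned proteins are INTACT)."""
    cleaned = text.replace("**", "").strip()
    if cleaned.lower() in ("normal ihc", "normal"):
        return IHCPanel.all_intact()
    m = re.match(r"(?i)^loss of\s+(.*)$", cleaned)
    if not m:
        raise ValueError(f"subject {subject}: unreadable IHC summary {text!r}")
    statuses = {p: IHCStatus.INTACT for p in _PROTEINS}
    chunks = re.split(r",\s*|\s+and\s+", m.group(1))
    for chunk in chunks:
        chunk = re.sub(r"(?i)^and\s+", "", chunk.strip())
        if not chunk:
            continue
        status = IHCStatus.LOST
        lowered = chunk.lower()
        if lowered.startswith("equivocal"):
            status, chunk = IHCStatus.EQUIVOCAL, chunk.split(None, 1)[1]
        elif lowered.startswith("partial loss"):
            status, chunk = IHCStatus.PARTIAL_LOSS, chunk.split(None, 2)[2]
        protein = chunk.strip().upper()
        if protein not in statuses:
            raise ValueError(f"subject {subject}: unknown MMR protein {chunk!r}")
        statuses[protein] = status
    return IHCPanel(**{p.lower(): s for p, s in statuses.items()})


def _somatic_kind(description: str) -> SomaticKind:
    lowered = description.lower()
    if "copy loss" in lowered or "copy-loss" in lowered:
        return SomaticKind.COPY_LOSS
    if "copy gain" in lowered:
        return SomaticKind.COPY_GAIN
    if re.search(r"(?i)(^|[:_\s])(5'?utr|ex(on)?\d)", description) \
            and ":c." not in description:
        return SomaticKind.STRUCTURAL
    return SomaticKind.SNV_INDEL


def _parse_somatic(text: str, flags: str, subject: int) -> tuple[SomaticEvent, ...]:
    text = text.strip()
    if not text or text.lower() == "none detected":
        return ()
    descriptions = [c.strip() for c in text.split(";") if c.strip()]
    flag_list = [f.strip().lower() for f in flags.split(";")] if flags.strip() else []
    if len(flag_list) != len(descriptions):
        raise ValueError(
            f"subject {subject}: {len(descriptions)} somatic events but "
            f"{len(flag_list)} inactivating flags")
    events = []
    for desc, flag in zip(descriptions, flag_list):
        gene_token = re.split(r"[:\s]", desc, maxsplit=1)[0].upper()
        if gene_token not in _PROTEINS:
            raise ValueError(f"subject {subject}: somatic event {desc!r} "
                             "does not name an MMR gene")
        events.append(SomaticEvent(
            gene=MMRGene[gene_token], description=desc,
            kind=_somatic_kind(desc), inactivating=flag in ("yes", "true", "1")))
    return tuple(events)


def packaged_control_path():
    """Path-like handle on the packaged control table."""
    return resources.files("lynchvus").joinpath("data/controls.tsv")


def load_control_table(path=None) -> list[ControlRecord]:
    """Load and normalize the control table (the packaged one by default)."""
    source = packaged_control_path() if path is None else path
    text = (source.read_text(encoding="utf-8") if hasattr(source, "read_text")
            else open(source, encoding="utf-8").read())
    lines = [ln for ln in text.split("\n") if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    records: list[ControlRecord] = []
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        subject = int(row["subject_id"])
        combined = row["braf_methylation"].strip()
        if "," in combined:
            braf_raw, meth_raw = (p.strip() for p in combined.split(",", 1))
        else:
            braf_raw, meth_raw = "", combined
        printed = row["printed_code"].strip()
        expected = row["expected_class"].strip()
        positive_printed = bool(re.match(r"^(II|III|IV|V)-", printed))
        if (expected == "POSITIVE") != positive_printed:
            raise ValueError(
                f"subject {subject}: expected_class {expected!r} inconsistent "
                f"with printed code {printed!r}")
        records.append(ControlRecord(
            subject_id=subject,
            cancer_type=CancerType.parse(row["cancer_type"]),
            premm5_percent=_parse_premm(row["premm5"], subject),
            germline=GermlineFinding(
                gene=MMRGene.parse(row["gene"]),
                cdna=row["cdna"].strip(),
                protein=row["protein"].strip() or None,
                classification=GermlineClass.PATHOGENIC_OR_LP),
            braf=TernaryResult.parse(braf_raw),
            methylation=TernaryResult.parse(meth_raw),
            msi=MSIStatus.parse(row["msi"]),
            ihc=_parse_ihc(row["ihc"], subject),
            somatic_events=_parse_somatic(row["somatic"],
                                          row.get("somatic_inactivating", ""),
                                          subject),
            printed_code=printed,
            expected_class=expected,
            reported_organ=row.get("reported_organ", "").strip(),
        ))
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in control table")
    return records


def control_to_case(record: ControlRecord) -> EvidenceCase:
    """Treat a control's pathogenic alteration as the queried VUS.

    Exactly one germline finding, no other pathogenic alteration or EPCAM
    deletion; Amsterdam II is UNKNOWN (the table records only PREMM scores).
    """
    return EvidenceCase(
        cancer_type=record.cancer_type,
        germline_vus_count=1,
        queried_variant=record.germline,
        other_pathogenic_mmr_germline=False,
        epcam_3prime_deletion=False,
        clinical=ClinicalEvidence(premm5_percent=record.premm5_percent,
                                  amsterdam_ii_met=Ternary.UNKNOWN),
        tumor=TumorProfile(
            braf_v600e=record.braf,
            mlh1_promoter_methylation=record.methylation,
            msi=record.msi,
            somatic_events=record.somatic_events),
        ihc=record.ihc,
    )


@dataclass
class EvaluationSummary:
    total: int = 0
    positive: int = 0
    non_positive: int = 0
    per_code_family: dict[str, int] = field(default_factory=dict)
    gate_code_tally: dict[str, int] = field(default_factory=dict)
    mismatches: list[tuple[int, str, str]] = field(default_factory=list)
    results: list[tuple[int, str, tuple[str, ...]]] = field(default_factory=list)

    def to_frame(self):
        """Per-subject results as a pandas DataFrame (for display/export)."""
        import pandas as pd

        return pd.DataFrame(self.results,
                            columns=["subject_id", "category", "codes"])


def evaluate_controls(records: list[ControlRecord],
                      threshold: float = PREMM5_THRESHOLD) -> EvaluationSummary:
    """Assess every control and compare categories against expected classes.

    ``per_code_family`` tallies the family of each verdict's leading code
    (family I for flagged cases); ``gate_code_tally`` counts every family-I
    code emitted, i.e. the reasons cases were flagged.
    """
    summary = EvaluationSummary()
    for record in records:
        verdict = assess_case(control_to_case(record), threshold,
                              with_synopsis=False)
        got = ("POSITIVE" if verdict.category is Category.POSITIVE
               else "NON_POSITIVE")
        summary.total += 1
        if got == "POSITIVE":
            summary.positive += 1
        else:
            summary.non_positive += 1
        if verdict.codes:
            family = verdict.codes[0].split()[1].split("-")[0]
            summary.per_code_family[family] = \
                summary.per_code_family.get(family, 0) + 1
        for code_id in verdict.codes:
            if code_id.split()[1].startswith("I-"):
                summary.gate_code_tally[code_id] = \
                    summary.gate_code_tally.get(code_id, 0) + 1
        if got != record.expected_class:
            summary.mismatches.append((record.subject_id,
                                       record.expected_class, got))
        summary.results.append((record.subject_id, verdict.category.name,
                                verdict.codes))
    return summary


def enumerate_answer_space(cancer_type: CancerType,
                           cdna: str = "c.1A>G"):
    """Yield every possible complete answer set, in deterministic order.

    The cartesian product of all radio-button answer sets for the tumor
    type's schema, with a fixed placeholder cDNA.
    """
    schema = schema_for(cancer_type)
    keys = [q.key for q in schema]
    for combo in itertools.product(*(q.answers for q in schema)):
        yield AnswerSet(cancer_type=cancer_type,
                        answers=dict(zip(keys, combo)), cdna=cdna)


def answer_space_size(cancer_type: CancerType) -> int:
    size = 1
    for q in schema_for(cancer_type):
        size *= len(q.answers)
    return size


DEFAULT_WEIGHTS = {
    "premm_present": 0.8,
    "amsterdam_known": 0.5,
    "braf_tested": 0.6,
    "methylation_tested": 0.5,
    "msi_tested": 0.9,
    "second_hit_present": 0.5,
    "ihc_assessable": 0.9,
}


def generate_random_cases(n: int, seed: int,
                          weights: dict[str, float] | None = None
                          ) -> list[EvidenceCase]:
    """Reproducible random evidence cases for fuzzing the engine.

    ``weights`` bias the probability that each evidence class is present
    (keys as in :data:`DEFAULT_WEIGHTS`; all must lie in [0, 1]).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    merged = dict(DEFAULT_WEIGHTS)
    if weights:
        unknown = set(weights) - set(DEFAULT_WEIGHTS)
        if unknown:
            raise ValueError(f"unknown weight keys: {sorted(unknown)}")
        merged.update(weights)
    for key, p in merged.items():
        if not (isinstance(p, (int, float)) and 0.0 <= p <= 1.0):
            raise ValueError(f"weight {key!r} must lie in [0, 1], got {p!r}")
    rng = random.Random(seed)
    cases = []
    for i in range(n):
        gene = rng.choice(list(MMRGene))
        cancer = rng.choice(list(CancerType))
        premm = round(rng.uniform(0.2, 45.0), 1) \
            if rng.random() < merged["premm_present"] else None
        amsterdam = rng.choice([Ternary.TRUE, Ternary.FALSE]) \
            if rng.random() < merged["amsterdam_known"] else Ternary.UNKNOWN
        braf = rng.choices([TernaryResult.NEGATIVE, TernaryResult.POSITIVE],
                           [0.85, 0.15])[0] \
            if rng.random() < merged["braf_tested"] else TernaryResult.NOT_TESTED
        meth = rng.choices([TernaryResult.NEGATIVE, TernaryResult.POSITIVE],
                           [0.8, 0.2])[0] \
            if rng.random() < merged["methylation_tested"] else TernaryResult.NOT_TESTED
        msi = rng.choices([MSIStatus.MSI_HIGH, MSIStatus.MSS], [0.7, 0.3])[0] \
            if rng.random() < merged["msi_tested"] else MSIStatus.NOT_TESTED
        events: tuple[SomaticEvent, ...] = ()
        if rng.random() < merged["second_hit_present"]:
            kind = rng.choice([SomaticKind.SNV_INDEL, SomaticKind.COPY_LOSS])
            events = (SomaticEvent(
                gene=gene if rng.random() < 0.8 else rng.choice(list(MMRGene)),
                description=f"synthetic somatic event {i}",
                kind=kind, inactivating=rng.random() < 0.9),)
        if rng.random() < merged["ihc_assessable"]:
            lost = rng.sample(_PROTEINS, k=rng.randint(0, 4))
            panel = IHCPanel.with_lost(*lost)
        else:
            panel = IHCPanel(IHCStatus.NOT_PERFORMED, IHCStatus.INTACT,
                             IHCStatus.INTACT, IHCStatus.INTACT)
        cases.append(EvidenceCase(
            cancer_type=cancer,
            germline_vus_count=1 if rng.random() < 0.95 else 2,
            queried_variant=GermlineFinding(gene=gene, cdna=f"c.{100 + i}A>G"),
            other_pathogenic_mmr_germline=rng.random() < 0.03,
            epcam_3prime_deletion=rng.random() < 0.02,
            clinical=ClinicalEvidence(premm5_percent=premm,
                                      amsterdam_ii_met=amsterdam),
            tumor=TumorProfile(braf_v600e=braf,
                               mlh1_promoter_methylation=meth,
                               msi=msi, somatic_events=events),
            ihc=panel,
        ))
    return cases
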