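"""Evidence-synopsis export for ClinVar submission.

POSITIVE and NEUTRAL assessments can be exported as a tab-delimited,
spreadsheet-openable file carrying the ClinVar-prompted fields (Assertion
Method, Assertion Method Citation, Citation URL, Comment on Clinical
Significance) plus the download date and algorithm version, followed by the
question/answer synopsis block.  INCONCLUSIVE and OUT_OF_SCOPE assessments
are refused.  Everything happens locally; nothing is transmitted anywhere.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass

from .model import Category, EvidenceCase, MMRGene, Verdict

DEFAULT_ASSERTION_METHOD = "Integrated germline-tumor MMR VUS decision tree"
DEFAULT_CITATION = "see package documentation"
DEFAULT_CITATION_URL = "https://example.invalid/lynchvus"

_EXPORTABLE = (Category.POSITIVE, Category.NEUTRAL)


class ExportRefused(ValueError):
    """Raised when a verdict is not eligible for ClinVar export."""


@dataclass(frozen=True)
class SubmissionRecord:
    assertion_method: str
    assertion_method_citation: str
    citation_url: str
    comment_on_clinical_significance: str
    download_date: _dt.date
    algorithm_version: str
    gene: MMRGene
    cdna: str
    protein: str | None
    synopsis: tuple[tuple[str, str], ...]
    category: Category

    def __post_init__(self):
        if self.category not in _EXPORTABLE:
            raise ExportRefused(
                "export only for POSITIVE and NEUTRAL assessments; "
                f"got {self.category.name}")
        for name in ("assertion_method", "assertion_method_citation",
                     "citation_url", "comment_on_clinical_significance",
                     "algorithm_version", "cdna"):
            if not str(getattr(self, name)).strip():
                raise ValueError(f"{name}: required field is empty")


def build_submission(case: EvidenceCase, verdict: Verdict, version: str,
                     date: _dt.date,
                     assertion_method: str = DEFAULT_ASSERTION_METHOD,
                     citation: str = DEFAULT_CITATION,
                     citation_url: str = DEFAULT_CITATION_URL) -> SubmissionRecord:
    """Assemble a submission record from an assessed case.

    Refuses INCONCLUSIVE and OUT_OF_SCOPE verdicts.
    """
    category = Category.parse(verdict.category)
    if category not in _EXPORTABLE:
        raise ExportRefused(
            "export only for POSITIVE and NEUTRAL assessments; "
            f"got {category.name}")
    return SubmissionRecord(
        assertion_method=assertion_method,
        assertion_method_citation=citation,
        citation_url=citation_url,
        comment_on_clinical_significance=verdict.comment,
        download_date=date,
        algorithm_version=version,
        gene=case.queried_variant.gene,
        cdna=case.queried_variant.cdna,
        protein=case.queried_variant.protein,
        synopsis=tuple(verdict.synopsis),
        category=category,
    )


def submission_filename(record: SubmissionRecord) -> str:
    """File-name tag ``<gene>_<cdna>[_<protein>].tsv`` with unsafe characters
    replaced by underscores."""
    parts = [record.gene.name, record.cdna]
    if record.protein:
        parts.append(record.protein)
    tag = "_".join(re.sub(r"[^A-Za-z0-9.+-]", "_", p) for p in parts)
    return f"{tag}.tsv"


_HEADER = (
    "Assertion Method",
    "Assertion Method Citation",
    "Citation URL",
    "Comment on Clinical Significance",
    "Date of Download",
    "Algorithm Version",
    "Gene",
    "cDNA",
    "Protein",
    "Category",
)


def write_submission(record: SubmissionRecord, path) -> None:
    """Write a record as UTF-8, tab-delimited, LF-terminated text.

    Layout: one header row, one value row, a blank line, then the
    question/answer synopsis block (one Q&A pair per row).  Writing the same
    record twice yields byte-identical files.
    """
    values = (
        record.assertion_method,
        record.assertion_method_citation,
        record.citation_url,
        record.comment_on_clinical_significance,
        record.download_date.isoformat(),
        record.algorithm_version,
        record.gene.name,
        record.cdna,
        record.protein or "",
        record.category.name,
    )
    lines = ["\t".join(_HEADER), "\t".join(values), ""]
    lines += [f"{question}\t{answer}" for question, answer in record.synopsis]
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\n".join(lines) + "\n")


def read_submission(path) -> SubmissionRecord:
    """Parse a written submission file back into a record (round trip)."""
    with open(path, encoding="utf-8") as handle:
        lines = handle.read().split("\n")
    header = lines[0].split("\t")
    if tuple(header) != _HEADER:
        raise ValueError(f"unexpected submission header: {header!r}")
    values = dict(zip(header, lines[1].split("\t")))
    synopsis = tuple(
        tuple(line.split("\t", 1))
        for line in lines[3:] if line.strip()
    )
    return SubmissionRecord(
        assertion_method=values["Assertion Method"],
        assertion_method_citation=values["Assertion Method Citation"],
        citation_url=values["Citation URL"],
        comment_on_clinical_significance=values["Comment on Clinical Significance"],
        download_date=_dt.date.fromisoformat(values["Date of Download"]),
        algorithm_version=values["Algorithm Version"],
        gene=MMRGene.parse(values["Gene"]),
        cdna=values["cDNA"],
        protein=values["Protein"] or None,
        synopsis=synopsis,  # type: ignore[arg-type]
        category=Category.parse(values["Category"]),
    )
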