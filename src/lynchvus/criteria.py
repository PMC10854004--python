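"""Clinical-criteria evaluators.

Two criteria qualify a family for the decision tree, as a disjunction:

* a PREMM5 risk score at or above the testing threshold (default 2.5%,
  inclusive), or
* Amsterdam II criteria met on the pedigree: at least three relatives with a
  Lynch-syndrome-associated cancer, one of them a first-degree relative of
  the other two, at least two successive generations affected, at least one
  diagnosis before age 50, and — when any qualifying diagnosis is colorectal
  — familial adenomatous polyposis (FAP) excluded.

The pedigree checker is exhaustive over affected-member subsets; clinical
pedigrees are small, so no pruning is attempted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .model import ClinicalEvidence, Ternary

#: Lynch-syndrome-associated tumors considered by the Amsterdam II checker.
DEFAULT_LS_CANCERS = frozenset(
    {"colorectal", "endometrial", "small bowel", "ureter", "renal pelvis"}
)

#: sentinel returned by relationship_degree for disconnected pairs
UNRELATED = "UNRELATED"

PREMM5_THRESHOLD = 2.5


def premm5_meets_threshold(premm5_percent: float | None,
                           threshold: float = PREMM5_THRESHOLD) -> bool:
    """True iff a PREMM5 score is present and >= ``threshold`` (inclusive).

    An absent score never satisfies the criterion.
    """
    if not 0.0 < threshold <= 100.0:
        raise ValueError("threshold must lie in (0, 100]")
    if premm5_percent is None:
        return False
    return float(premm5_percent) >= threshold


def clinical_criteria_met(clinical: ClinicalEvidence,
                          threshold: float = PREMM5_THRESHOLD) -> bool:
    """PREMM5-over-threshold OR Amsterdam II flagged TRUE."""
    return (premm5_meets_threshold(clinical.premm5_percent, threshold)
            or clinical.amsterdam_ii_met is Ternary.TRUE)


@dataclass(frozen=True)
class Relative:
    """One pedigree member.

    ``generation`` counts from the proband: 0 = proband's generation,
    -1 = parents, +1 = children.  ``diagnoses`` is a tuple of
    (cancer_label, age_at_diagnosis) pairs.
    """

    id: str
    mother_id: str | None = None
    father_id: str | None = None
    generation: int = 0
    diagnoses: tuple[tuple[str, int], ...] = ()


@dataclass(frozen=True)
class Pedigree:
    proband_id: str
    members: tuple[Relative, ...] = ()
    fap_excluded: bool = False

    def __post_init__(self):
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("pedigree: duplicate member ids")
        known = set(ids)
        if self.proband_id not in known:
            raise ValueError(f"pedigree: proband {self.proband_id!r} not among members")
        for m in self.members:
            for pid in (m.mother_id, m.father_id):
                if pid is not None and pid not in known:
                    raise ValueError(f"pedigree: unknown parent id {pid!r} of {m.id!r}")
        # reject cyclic parent links
        dag = nx.DiGraph()
        dag.add_nodes_from(known)
        for m in self.members:
            for pid in (m.mother_id, m.father_id):
                if pid is not None:
                    dag.add_edge(m.id, pid)
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("pedigree: cyclic parent links")

    def member(self, label: str) -> Relative:
        for m in self.members:
            if m.id == label:
                return m
        raise KeyError(f"pedigree: no member named {label!r}")


def _kinship_graph(pedigree: Pedigree) -> nx.Graph:
    """Undirected parent-link graph with unit edges; full siblings get a
    direct unit edge (first-degree by convention; half-siblings stay at 2)."""
    g = nx.Graph()
    g.add_nodes_from(m.id for m in pedigree.members)
    for m in pedigree.members:
        for pid in (m.mother_id, m.father_id):
            if pid is not None:
                g.add_edge(m.id, pid)
    for a, b in itertools.combinations(pedigree.members, 2):
        if (a.mother_id is not None and a.father_id is not None
                and a.mother_id == b.mother_id and a.father_id == b.father_id):
            g.add_edge(a.id, b.id)
    return g


def relationship_degree(pedigree: Pedigree, a: str, b: str) -> int | str:
    """Degree of relationship between two members.

    Parent-child and full siblings are degree 1; otherwise the shortest path
    through parent links (grandparent 2, half-sibling 2, ...).  Returns
    :data:`UNRELATED` when no path exists; 0 for a member and itself.
    """
    for label in (a, b):
        pedigree.member(label)  # raises KeyError naming the unknown label
    graph = _kinship_graph(pedigree)
    try:
        return nx.shortest_path_length(graph, a, b)
    except nx.NetworkXNoPath:
        return UNRELATED


@dataclass
class AmsterdamResult:
    met: bool
    reasons: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.met


def _ls_diagnoses(member: Relative, ls_cancers: frozenset[str]):
    return [(label, age) for label, age in member.diagnoses
            if label.strip().lower() in ls_cancers]


def amsterdam_ii_met(pedigree: Pedigree,
                     ls_cancer_labels: frozenset[str] = DEFAULT_LS_CANCERS,
                     include_proband: bool = True) -> AmsterdamResult:
    """Evaluate Amsterdam II on a pedigree.

    Searches exhaustively for a subset of >= 3 affected members in which one
    member is a first-degree relative of (at least) two others, the subset's
    generations include two successive values, and at least one qualifying
    diagnosis is before age 50.  If any qualifying diagnosis in the subset
    is colorectal, ``fap_excluded`` must additionally be true.

    The proband counts among the "relatives" by default (``include_proband``).
    Returns the decision plus the clauses that failed when unmet.
    """
    ls_cancers = frozenset(c.lower() for c in ls_cancer_labels)
    members = [m for m in pedigree.members
               if include_proband or m.id != pedigree.proband_id]
    affected = [m for m in members if _ls_diagnoses(m, ls_cancers)]

    if len(affected) < 3:
        return AmsterdamResult(False, ["fewer than three affected relatives "
                                       "with a Lynch-associated cancer"])

    graph = _kinship_graph(pedigree)
    failures: set[str] = set()
    for size in range(3, len(affected) + 1):
        for subset in itertools.combinations(affected, size):
            ids = [m.id for m in subset]
            first_degree_ok = any(
                sum(1 for other in ids
                    if other != anchor and graph.has_edge(anchor, other)) >= 2
                for anchor in ids)
            if not first_degree_ok:
                failures.add("no affected member is a first-degree relative "
                             "of two other affected members")
                continue
            generations = {m.generation for m in subset}
            if not any(g + 1 in generations for g in generations):
                failures.add("affected members do not span two successive generations")
                continue
            dx = [d for m in subset for d in _ls_diagnoses(m, ls_cancers)]
            if not any(age < 50 for _, age in dx):
                failures.add("no diagnosis before age 50")
                continue
            if any(label.lower() == "colorectal" for label, _ in dx) \
                    and not pedigree.fap_excluded:
                failures.add("familial adenomatous polyposis not excluded "
                             "despite colorectal diagnoses")
                continue
            return AmsterdamResult(True, [])
    return AmsterdamResult(False, sorted(failures) or
                           ["no qualifying set of three affected relatives"])


def read_pedigree(path) -> Pedigree:
    """Read a pedigree from a tab-delimited file.

    Header flag lines of the form ``#key=value`` precede the column header
    (``fap_excluded`` and ``proband`` are recognized).  Columns: ``id``,
    ``mother_id``, ``father_id``, ``generation``, ``diagnoses`` with
    diagnoses written ``cancer@age`` and separated by semicolons.
    """
    flags: dict[str, str] = {}
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                flags[key.strip().lower()] = value.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                continue
            rows.append(dict(zip(header, fields)))
    members = []
    for row in rows:
        dx = []
        for chunk in (row.get("diagnoses") or "").split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            label, _, age = chunk.partition("@")
            dx.append((label.strip(), int(age)))
        members.append(Relative(
            id=row["id"].strip(),
            mother_id=(row.get("mother_id") or "").strip() or None,
            father_id=(row.get("father_id") or "").strip() or None,
            generation=int(row.get("generation") or 0),
            diagnoses=tuple(dx),
        ))
    proband = flags.get("proband") or (members[0].id if members else "")
    fap = flags.get("fap_excluded", "false").lower() in ("yes", "true", "1")
    return Pedigree(proband_id=proband, members=tuple(members), fap_excluded=fap)
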