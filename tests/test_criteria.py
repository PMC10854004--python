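"""PREMM5 threshold rule and the Amsterdam II pedigree checker."""

import itertools

import pytest

from lynchvus import (
    ClinicalEvidence,
    Pedigree,
    Relative,
    Ternary,
    UNRELATED,
    amsterdam_ii_met,
    clinical_criteria_met,
    premm5_meets_threshold,
    read_pedigree,
    relationship_degree,
)


@pytest.mark.parametrize("score, expected", [
    (2.5, True),      # inclusive bound
    (2.4, False),
    (None, False),    # absent evidence never satisfies a threshold
    (100.0, True),
])
def test_premm5_threshold_is_inclusive(score, expected):
    assert premm5_meets_threshold(score) is expected


def test_premm5_rejects_invalid_threshold():
    with pytest.raises(ValueError):
        premm5_meets_threshold(5.0, threshold=0.0)


@pytest.mark.parametrize("premm5, amsterdam, expected", [
    (6.7, Ternary.UNKNOWN, True),
    (None, Ternary.TRUE, True),     # disjunction: Amsterdam alone suffices
    (1.3, Ternary.FALSE, False),
    (1.3, Ternary.TRUE, True),
])
def test_clinical_criteria_disjunction(premm5, amsterdam, expected):
    clinical = ClinicalEvidence(premm5_percent=premm5, amsterdam_ii_met=amsterdam)
    assert clinical_criteria_met(clinical) is expected


def test_clinical_criteria_monotone_in_premm5():
    last = False
    for score in (0.0, 1.0, 2.4, 2.5, 10.0, 99.0):
        met = clinical_criteria_met(ClinicalEvidence(premm5_percent=score))
        assert met >= last
        last = met


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

def _pedigree(members, proband="p", fap=True):
    return Pedigree(proband_id=proband, members=tuple(members), fap_excluded=fap)


THREE_GEN = _pedigree([
    Relative("gm", generation=-2),
    Relative("gf", generation=-2),
    Relative("mom", mother_id="gm", father_id="gf", generation=-1,
             diagnoses=(("colorectal", 45),)),
    Relative("dad", generation=-1),
    Relative("p", mother_id="mom", father_id="dad", generation=0,
             diagnoses=(("endometrial", 52),)),
    Relative("sib", mother_id="mom", father_id="dad", generation=0,
             diagnoses=(("colorectal", 55),)),
    Relative("half", mother_id="mom", generation=0),
    Relative("stranger", generation=0),
])


def _bfs_degree(pedigree, a, b):
    """Independent oracle: breadth-first shortest path over parent links,
    with a direct edge between full siblings."""
    adjacency = {m.id: set() for m in pedigree.members}
    for m in pedigree.members:
        for pid in (m.mother_id, m.father_id):
            if pid:
                adjacency[m.id].add(pid)
                adjacency[pid].add(m.id)
    for x, y in itertools.combinations(pedigree.members, 2):
        if x.mother_id and x.father_id and (x.mother_id, x.father_id) == \
                (y.mother_id, y.father_id):
            adjacency[x.id].add(y.id)
            adjacency[y.id].add(x.id)
    frontier, seen, depth = {a}, {a}, 0
    while frontier:
        if b in frontier:
            return depth
        frontier = {n for f in frontier for n in adjacency[f]} - seen
        seen |= frontier
        depth += 1
    return UNRELATED


@pytest.mark.parametrize("a, b, expected", [
    ("mom", "p", 1),      # parent-child
    ("p", "sib", 1),      # full siblings
    ("p", "half", 2),     # half-siblings share one parent
    ("gm", "p", 2),       # grandparent-grandchild
    ("dad", "gm", 3),     # in-laws connect only through the shared child
    ("p", "stranger", UNRELATED),
    ("p", "p", 0),
])
def test_relationship_degree(a, b, expected):
    assert relationship_degree(THREE_GEN, a, b) == expected
    assert relationship_degree(THREE_GEN, a, b) == _bfs_degree(THREE_GEN, a, b)


def test_relationship_degree_symmetric():
    ids = [m.id for m in THREE_GEN.members]
    for a, b in itertools.combinations(ids, 2):
        assert relationship_degree(THREE_GEN, a, b) == \
            relationship_degree(THREE_GEN, b, a)


def test_relationship_degree_names_unknown_member():
    with pytest.raises(KeyError, match="ghost"):
        relationship_degree(THREE_GEN, "p", "ghost")


def test_pedigree_rejects_unknown_parent_and_cycles():
    with pytest.raises(ValueError, match="unknown parent"):
        _pedigree([Relative("p", mother_id="nobody")])
    with pytest.raises(ValueError, match="cyclic"):
        _pedigree([Relative("p", mother_id="q"), Relative("q", mother_id="p")])


def _family(*diagnosed, fap=True):
    """Parent + two children; ``diagnosed`` lists (id, cancer, age)."""
    dx = {i: (c, a) for i, c, a in diagnosed}

    def d(i):
        return (dx[i],) if i in dx else ()

    return _pedigree([
        Relative("mom", generation=-1, diagnoses=d("mom")),
        Relative("dad", generation=-1, diagnoses=d("dad")),
        Relative("p", mother_id="mom", father_id="dad", generation=0,
                 diagnoses=d("p")),
        Relative("sib", mother_id="mom", father_id="dad", generation=0,
                 diagnoses=d("sib")),
    ], fap=fap)


def test_amsterdam_met_on_textbook_family():
    # parent CRC at 45 + two children (EC 52, CRC 55), FAP excluded
    ped = _family(("mom", "colorectal", 45), ("p", "endometrial", 52),
                  ("sib", "colorectal", 55))
    assert amsterdam_ii_met(ped).met


def test_amsterdam_fails_with_two_affected():
    ped = _family(("mom", "colorectal", 45), ("p", "endometrial", 52))
    result = amsterdam_ii_met(ped)
    assert not result.met
    assert any("fewer than three" in r for r in result.reasons)


def test_amsterdam_age_clause_is_strict():
    # all diagnoses at >= 50, including one exactly at the boundary
    ped = _family(("mom", "colorectal", 50), ("p", "endometrial", 52),
                  ("sib", "colorectal", 55))
    result = amsterdam_ii_met(ped)
    assert not result.met
    assert any("age 50" in r for r in result.reasons)


def test_amsterdam_requires_successive_generations():
    # three affected full siblings: first-degree structure holds but all
    # diagnoses sit in a single generation
    ped = _pedigree([
        Relative("mom", generation=-1),
        Relative("dad", generation=-1),
        Relative("p", mother_id="mom", father_id="dad", generation=0,
                 diagnoses=(("colorectal", 48),)),
        Relative("sib", mother_id="mom", father_id="dad", generation=0,
                 diagnoses=(("endometrial", 60),)),
        Relative("sib2", mother_id="mom", father_id="dad", generation=0,
                 diagnoses=(("colorectal", 61),)),
    ])
    result = amsterdam_ii_met(ped)
    assert not result.met
    assert any("successive generations" in r for r in result.reasons)


def test_amsterdam_fap_clause_applies_to_colorectal_only():
    crc = _family(("mom", "colorectal", 45), ("p", "endometrial", 52),
                  ("sib", "colorectal", 55), fap=False)
    assert not amsterdam_ii_met(crc).met
    no_crc = _family(("mom", "endometrial", 45), ("p", "endometrial", 52),
                     ("sib", "ureter", 55), fap=False)
    assert amsterdam_ii_met(no_crc).met


def test_amsterdam_ignores_non_lynch_tumors():
    ped = _family(("mom", "breast", 45), ("p", "endometrial", 52),
                  ("sib", "colorectal", 48))
    assert not amsterdam_ii_met(ped).met


def test_amsterdam_monotone_in_affected_relatives():
    base = _family(("mom", "colorectal", 45), ("p", "endometrial", 52),
                   ("sib", "colorectal", 55))
    assert amsterdam_ii_met(base).met
    extended = Pedigree(
        proband_id="p",
        members=base.members + (
            Relative("child", mother_id="p", generation=1,
                     diagnoses=(("colorectal", 30),)),),
        fap_excluded=True)
    assert amsterdam_ii_met(extended).met


def test_read_pedigree_round_trip(tmp_path):
    path = tmp_path / "family.ped.tsv"
    path.write_text(
        "#fap_excluded=true\n#proband=p\n"
        "id\tmother_id\tfather_id\tgeneration\tdiagnoses\n"
        "mom\t\t\t-1\tcolorectal@45\n"
        "dad\t\t\t-1\t\n"
        "p\tmom\tdad\t0\tendometrial@52\n"
        "sib\tmom\tdad\t0\tcolorectal@55\n",
        encoding="utf-8")
    ped = read_pedigree(path)
    assert ped.proband_id == "p"
    assert ped.fap_excluded
    assert ped.member("mom").diagnoses == (("colorectal", 45),)
    assert amsterdam_ii_met(ped).met
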