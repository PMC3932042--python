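"""LINKAGE-format IO, structural validation and Mendelian checking."""

import numpy as np
import pytest

from linkld import (
    MarkerMap,
    Pedigree,
    PedigreeError,
    PedigreeSet,
    check_mendelian,
    check_mendelian_all,
    preset_model,
    read_mapfile,
    read_pedfile,
    simulate_dataset,
    write_pedfile,
)
from linkld.pedigree_io import FEMALE, MALE, UNKNOWN
from linkld.simulator import SimulationDesign

from conftest import make_individual, make_trio

PED_3ROWS = """\
F1 1 0 0 1 1 1 2
F1 2 0 0 2 2 1 1
F1 3 1 2 1 2 1 1
"""


def test_read_pedfile_trio_structure(tmp_path):
    p = tmp_path / "trio.ped"
    p.write_text(PED_3ROWS)
    data = read_pedfile(p, n_markers=1)
    assert len(data) == 1
    ped = data.pedigrees[0]
    assert len(ped) == 3
    assert {m.indiv_id for m in ped.founders} == {"1", "2"}
    assert [m.indiv_id for m in ped.nonfounders] == ["3"]
    assert ped["3"].father_id == "1" and ped["3"].mother_id == "2"
    assert ped["1"].genotype(0) == (1, 2)


def test_half_missing_genotype_is_fully_missing(tmp_path):
    p = tmp_path / "m.ped"
    p.write_text("F1 1 0 0 1 0 0 0\nF2 1 0 0 1 0 5 0\n")
    data = read_pedfile(p, n_markers=1)
    for ped in data:
        assert ped.members[0].genotype(0) is None


def test_dangling_parent_reference_names_family_and_individual(tmp_path):
    p = tmp_path / "bad.ped"
    p.write_text("F7 1 0 0 2 1 1 1\nF7 3 99 1 1 2 1 2\n")
    with pytest.raises(PedigreeError, match=r"F7.*3.*99"):
        read_pedfile(p, n_markers=1)


def test_parent_sex_inconsistency_rejected(tmp_path):
    p = tmp_path / "sex.ped"
    # father reference points at a female individual
    p.write_text("F1 1 0 0 2 1 1 1\nF1 2 0 0 2 1 1 1\nF1 3 1 2 1 1 1 1\n")
    with pytest.raises(PedigreeError, match="sex"):
        read_pedfile(p, n_markers=1)


def test_duplicate_individual_rejected(tmp_path):
    p = tmp_path / "dup.ped"
    p.write_text("F1 1 0 0 1 1 1 1\nF1 1 0 0 1 1 1 1\n")
    with pytest.raises(PedigreeError, match="duplicate"):
        read_pedfile(p, n_markers=1)


def test_column_count_mismatch(tmp_path):
    p = tmp_path / "cols.ped"
    p.write_text("F1 1 0 0 1 1 1\n")
    with pytest.raises(PedigreeError, match="columns"):
        read_pedfile(p, n_markers=1)


def test_post_makeped_columns_ignored_with_warning(tmp_path, caplog):
    p = tmp_path / "post.ped"
    # fam id fa mo firstchild nextpatsib nextmatsib sex proband alleles...
    p.write_text("F1 1 0 0 3 0 0 1 1 1 2\nF1 2 0 0 3 0 0 2 0 1 1\n"
                 "F1 3 1 2 0 0 0 1 0 1 1\n")
    with caplog.at_level("WARNING"):
        data = read_pedfile(p, n_markers=1)
    assert "post-makeped" in caplog.text
    ped = data.pedigrees[0]
    assert ped["1"].genotype(0) == (1, 2)
    assert ped["3"].father_id == "1"


def test_roundtrip_preserves_tokens(tmp_path):
    src = tmp_path / "in.ped"
    src.write_text(PED_3ROWS)
    data = read_pedfile(src, n_markers=1)
    out = tmp_path / "out.ped"
    write_pedfile(data, out)
    orig = [line.split() for line in PED_3ROWS.strip().splitlines()]
    new = [line.split() for line in out.read_text().strip().splitlines()]
    assert orig == new


# --- map files ---------------------------------------------------------------


def test_plink4col_map(tmp_path):
    p = tmp_path / "a.map"
    p.write_text("22 rs1 0 123\n22 rs2 0 456\n")
    mm = read_mapfile(p, "plink4col")
    assert mm.markers[0] == ("rs1", "22", 123.0)
    assert mm.names == ["rs1", "rs2"]


def test_wrong_dialect_column_error(tmp_path):
    p = tmp_path / "a.map"
    p.write_text("22 rs1 0 123\n")
    with pytest.raises(ValueError, match="columns"):
        read_mapfile(p, "simple3col")


def test_unknown_dialect(tmp_path):
    p = tmp_path / "a.map"
    p.write_text("22 rs1 0 123\n")
    with pytest.raises(ValueError, match="dialect"):
        read_mapfile(p, "bogus")


def test_empty_map_warns(tmp_path, caplog):
    p = tmp_path / "empty.map"
    p.write_text("")
    with caplog.at_level("WARNING"):
        mm = read_mapfile(p, "simple3col")
    assert len(mm) == 0
    assert "empty" in caplog.text


def test_duplicate_marker_names_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        MarkerMap([("rs1", "1", 0.0), ("rs1", "2", 5.0)])


def test_non_numeric_position(tmp_path):
    p = tmp_path / "a.map"
    p.write_text("1 rs1 abc\n")
    with pytest.raises(ValueError, match="position"):
        read_mapfile(p, "simple3col")


# --- Mendelian checking ------------------------------------------------------


@pytest.mark.parametrize(
    "gf,gm,gc,expect_violation",
    [
        ((1, 1), (1, 1), (1, 2), True),   # allele 2 from nowhere
        ((1, 2), (1, 2), (1, 1), False),  # possible transmission
        ((0, 0), (0, 0), (3, 4), False),  # untyped parents compatible
        ((1, 1), (2, 2), (1, 1), True),   # child must be heterozygous
        ((1, 2), (3, 4), (1, 3), False),
    ],
)
def test_check_mendelian_nuclear(gf, gm, gc, expect_violation):
    ped = make_trio(gf, gm, gc)
    violations = check_mendelian(ped, 0)
    assert bool(violations) == expect_violation
    if violations:
        v = violations[0]
        assert v.family_id == "T1" and v.marker_index == 0


def test_untyped_parent_two_children_supply_limit():
    # an untyped parent has only two alleles: three children needing three
    # distinct alleles from them are inconsistent even without typing
    fam = "F9"
    members = [
        make_individual(fam, "1", sex=MALE, genotypes=((0, 0),)),
        make_individual(fam, "2", sex=FEMALE, genotypes=((5, 5),)),
        make_individual(fam, "3", "1", "2", genotypes=((1, 5),)),
        make_individual(fam, "4", "1", "2", genotypes=((2, 5),)),
        make_individual(fam, "5", "1", "2", genotypes=((3, 5),)),
    ]
    assert check_mendelian(Pedigree(fam, members), 0)


def test_masking_genotype_never_creates_violation():
    rng = np.random.default_rng(7)
    for _ in range(200):
        genos = [tuple(rng.integers(1, 4, size=2)) for _ in range(3)]
        ped = make_trio(*genos)
        before = bool(check_mendelian(ped, 0))
        mask = int(rng.integers(3))
        genos2 = list(genos)
        genos2[mask] = (0, 0)
        after = bool(check_mendelian(make_trio(*genos2), 0))
        if not before:
            assert not after, (genos, mask)


def test_simulated_data_are_mendelian_consistent():
    model = preset_model("extreme_dominant", 0.01)
    design = SimulationDesign(
        counts={"sibpair": 20, "triad": 10, "extended": 5},
        theta=0.1,
        model=model,
        marker_freqs=(0.4, 0.6),
        seed=3,
    )
    data, _ = simulate_dataset(design)
    assert check_mendelian_all(data, 0) == []


# --- loops -------------------------------------------------------------------


def test_loop_detection():
    fam = "L1"
    # full-sib mating: parents A,B; sibs C,D; child E of C x D
    members = [
        make_individual(fam, "A", sex=MALE),
        make_individual(fam, "B", sex=FEMALE),
        make_individual(fam, "C", "A", "B", sex=MALE),
        make_individual(fam, "D", "A", "B", sex=FEMALE),
        make_individual(fam, "E", "C", "D", sex=MALE),
    ]
    assert Pedigree(fam, members).has_loops
    assert not make_trio((0, 0), (0, 0), (0, 0)).has_loops


def test_pedigree_set_rejects_duplicate_pairs():
    a = make_trio((0, 0), (0, 0), (0, 0), fam="X")
    with pytest.raises(PedigreeError, match="duplicate"):
        PedigreeSet([a, make_trio((1, 1), (1, 1), (1, 1), fam="X")])
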