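"""Shared fixtures: pedigree builders, random loop-free pedigrees with
gene-dropped data, and the expensive session-scoped simulation batteries
(null calibration, parameter recovery, optimizer comparison) that several
test modules consume."""

from __future__ import annotations

import numpy as np
import pytest

from linkld import (
    Individual,
    ModelSpec,
    OptimizerOptions,
    Pedigree,
    SimulationDesign,
    preset_model,
    pseudomarker_tests,
    simulate_dataset,
)
from linkld.pedigree_io import FEMALE, MALE, UNKNOWN
from linkld.trait_model import INFEASIBLE

# ---------------------------------------------------------------------------
# Small deterministic pedigrees
# ---------------------------------------------------------------------------


def make_individual(
    fam="F1",
    iid="1",
    father=None,
    mother=None,
    sex=MALE,
    phenotype=UNKNOWN,
    genotypes=((0, 0),),
):
    return Individual(
        family_id=fam,
        indiv_id=iid,
        father_id=father,
        mother_id=mother,
        sex=sex,
        phenotype=phenotype,
        genotypes=list(genotypes),
    )


def make_trio(g_father, g_mother, g_child, p_father=UNKNOWN, p_mother=UNKNOWN,
              p_child=UNKNOWN, fam="T1"):
    """Father, mother, one child; genotypes are single-marker allele pairs."""
    return Pedigree(
        fam,
        [
            make_individual(fam, "1", sex=MALE, phenotype=p_father,
                            genotypes=(g_father,)),
            make_individual(fam, "2", sex=FEMALE, phenotype=p_mother,
                            genotypes=(g_mother,)),
            make_individual(fam, "3", "1", "2", sex=MALE, phenotype=p_child,
                            genotypes=(g_child,)),
        ],
    )


@pytest.fixture
def dominant_model():
    return preset_model("extreme_dominant", 0.01)


# ---------------------------------------------------------------------------
# Random loop-free pedigrees with gene-dropped genotypes (package generators)
# ---------------------------------------------------------------------------

from linkld.simulator import (  # noqa: E402
    random_dropped_pedigree,
    random_parameters,
    random_structure,
)


def random_params(rng: np.random.Generator, spec: ModelSpec):
    """Feasible random parameters; asserts feasibility for test use."""
    pv = random_parameters(rng, spec)
    assert pv is not INFEASIBLE
    assert len(list(getattr(pv, "marker_freqs", ()) or ())) in (0, spec.k)
    return pv


ALL_SPECS = [
    (False, False),
    (True, False),
    (False, True),
    (True, True),
]


# ---------------------------------------------------------------------------
# Session-scoped simulation batteries (shared by property + acceptance tests)
# ---------------------------------------------------------------------------

N_NULL_REPLICATES = 500


@pytest.fixture(scope="session")
def null_battery():
    """LR tests on replicated null data: theta=0.5, linkage equilibrium,
    100 affected-sib-pair families + 100 cases + 100 controls per replicate,
    fully penetrant dominant trait with disease allele frequency 0.01.

    Returns per-test arrays of statistics and p-values across replicates.
    """
    model = preset_model("extreme_dominant", 0.01)
    out: dict[str, dict[str, list[float]]] = {}
    for rep in range(N_NULL_REPLICATES):
        design = SimulationDesign(
            counts={"sibpair": 100, "case": 100, "control": 100},
            theta=0.5,
            model=model,
            marker_freqs=(0.5, 0.5),
            seed=20000 + rep,
        )
        data, _ = simulate_dataset(design)
        results = pseudomarker_tests(
            data, 0, model, options=OptimizerOptions(seed=1)
        )
        for r in results:
            d = out.setdefault(r.name, {"stat": [], "p": [], "df": r.df})
            d["stat"].append(r.statistic)
            d["p"].append(r.p_value)
    return {
        name: {
            "stat": np.asarray(d["stat"]),
            "p": np.asarray(d["p"]),
            "df": d["df"],
        }
        for name, d in out.items()
    }


@pytest.fixture(scope="session")
def recovery_battery():
    """Joint tests on strong-signal data: theta=0.05, complete LD
    (disease allele always on marker allele 1), 200 ASP families,
    10 seeded replicates.  Returns the TestResult list per replicate."""
    model = preset_model("extreme_dominant", 0.01)
    runs = []
    for rep in range(10):
        design = SimulationDesign(
            counts={"sibpair": 200},
            theta=0.05,
            model=model,
            freqs_given_D=(1.0, 0.0),
            freqs_given_d=(0.3, 0.7),
            seed=1000 + rep,
        )
        data, _ = simulate_dataset(design)
        (joint,) = pseudomarker_tests(
            data, 0, model, options=OptimizerOptions(seed=1),
            tests=("joint_linkage_ld",),
        )
        runs.append(joint)
    return runs
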