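"""Two-locus pedigree likelihood: scalar factors, peeling, and the
brute-force enumeration oracle."""

import itertools

import numpy as np
import pytest

from linkld import (
    Haplotype,
    LoopedPedigreeError,
    ModelSpec,
    OrderedGenotype,
    Pedigree,
    PedigreeSet,
    StateCapError,
    dataset_loglik,
    enumerate_loglik,
    peel_loglik,
    penetrance_prob,
    preset_model,
    transmission_prob,
    unpack,
)
from linkld.likelihood_engine import DatasetLikelihood
from linkld.pedigree_io import AFFECTED, FEMALE, MALE, UNAFFECTED, UNKNOWN
from linkld.trait_model import InheritanceModel, founder_haplotype_priors

from conftest import (
    ALL_SPECS,
    make_individual,
    make_trio,
    random_dropped_pedigree,
    random_params,
)

D, d = 0, 1


# --- scalar factor definitions ----------------------------------------------


def test_penetrance_prob_extreme_dominant():
    model = preset_model("extreme_dominant", 0.01)
    geno_Dd = OrderedGenotype(Haplotype(D, 1), Haplotype(d, 1))
    aff = make_individual(phenotype=AFFECTED, genotypes=((0, 0),))
    unaff = make_individual(phenotype=UNAFFECTED, genotypes=((0, 0),))
    assert penetrance_prob(aff, geno_Dd, model) == 1.0
    assert penetrance_prob(unaff, geno_Dd, model) == 0.0


def test_penetrance_prob_marker_match_only_for_unknown_phenotype():
    model = preset_model("extreme_dominant", 0.01)
    ind = make_individual(phenotype=UNKNOWN, genotypes=((1, 2),))
    match = OrderedGenotype(Haplotype(D, 2), Haplotype(d, 1))
    mismatch = OrderedGenotype(Haplotype(D, 1), Haplotype(d, 1))
    assert penetrance_prob(ind, match, model) == 1.0
    assert penetrance_prob(ind, mismatch, model) == 0.0


@pytest.mark.parametrize(
    "theta,expected",
    [
        (0.5, {(D, 1): 0.25, (D, 2): 0.25, (d, 1): 0.25, (d, 2): 0.25}),
        (0.0, {(D, 1): 0.5, (D, 2): 0.0, (d, 1): 0.0, (d, 2): 0.5}),
        (0.1, {(D, 1): 0.45, (D, 2): 0.05, (d, 1): 0.05, (d, 2): 0.45}),
    ],
)
def test_transmission_prob_values(theta, expected):
    parent = OrderedGenotype(Haplotype(D, 1), Haplotype(d, 2))
    for (a, m), p in expected.items():
        assert transmission_prob(parent, Haplotype(a, m), theta) == pytest.approx(p)


def test_transmission_probs_sum_to_one():
    rng = np.random.default_rng(0)
    for _ in range(20):
        k = int(rng.integers(2, 5))
        parent = OrderedGenotype(
            Haplotype(int(rng.integers(2)), int(rng.integers(1, k + 1))),
            Haplotype(int(rng.integers(2)), int(rng.integers(1, k + 1))),
        )
        theta = float(rng.uniform(0, 0.5))
        total = sum(
            transmission_prob(parent, Haplotype(a, m), theta)
            for a in (D, d)
            for m in range(1, k + 1)
        )
        assert total == pytest.approx(1.0)


def test_transmission_theta_out_of_range():
    parent = OrderedGenotype(Haplotype(D, 1), Haplotype(d, 2))
    with pytest.raises(ValueError):
        transmission_prob(parent, Haplotype(D, 1), 0.7)


# --- independent reference: explicit python enumeration ----------------------


def reference_loglik(ped, params, model, spec):
    """Plain-python enumeration over ordered genotypes, written directly
    from the probability model (independent of the package's numerics)."""
    k = spec.k
    haps = [(a, m) for a in (D, d) for m in range(1, k + 1)]
    genos = list(itertools.product(haps, haps))
    prior = founder_haplotype_priors(params, model, spec)
    theta = params.effective_theta

    def hap_prior(h):
        return prior[h[0], h[1] - 1]

    def trans(parent, h):
        (pa, pm), (ma, mm) = parent
        p = 0.0
        for hap, prob in (
            ((pa, pm), (1 - theta) / 2),
            ((ma, mm), (1 - theta) / 2),
            ((pa, mm), theta / 2),
            ((ma, pm), theta / 2),
        ):
            if hap == h:
                p += prob
        return p

    def pen(ind, g):
        (pa, pm), (ma, mm) = g
        ncopies = (pa == D) + (ma == D)
        f = model.penetrances[ncopies]
        if ind.phenotype == AFFECTED:
            w = f
        elif ind.phenotype == UNAFFECTED:
            w = 1 - f
        else:
            w = 1.0
        obs = ind.genotype(0)
        if obs is not None and obs != tuple(sorted((pm, mm))):
            return 0.0
        return w

    members = ped.members
    total = 0.0
    for assign in itertools.product(genos, repeat=len(members)):
        byid = {m.indiv_id: g for m, g in zip(members, assign)}
        term = 1.0
        for m, g in zip(members, assign):
            term *= pen(m, g)
            if m.is_founder:
                term *= hap_prior(g[0]) * hap_prior(g[1])
            else:
                term *= trans(byid[m.father_id], g[0])
                term *= trans(byid[m.mother_id], g[1])
            if term == 0.0:
                break
        total += term
    return np.log(total) if total > 0 else -np.inf


# --- closed-form singletons ---------------------------------------------------


def test_singleton_hardy_weinberg():
    model = preset_model("extreme_dominant", 0.01)
    spec = ModelSpec(True, False, 2)
    pv = unpack([0.1, 0.3], spec)
    s = Pedigree("S", [make_individual("S", "1", genotypes=((1, 2),))])
    r = peel_loglik(s, 0, pv, model, spec)
    assert np.exp(r.loglik) == pytest.approx(2 * 0.3 * 0.7)


def test_untyped_unknown_singleton_probability_one():
    model = preset_model("extreme_dominant", 0.01)
    spec = ModelSpec(False, False, 2)
    pv = unpack([0.3], spec)
    s = Pedigree("S", [make_individual("S", "1", genotypes=((0, 0),))])
    assert peel_loglik(s, 0, pv, model, spec).loglik == pytest.approx(0.0, abs=1e-12)


# --- triads against the independent reference --------------------------------


@pytest.mark.parametrize("linkage,ld", ALL_SPECS)
def test_trio_matches_reference_enumeration(linkage, ld):
    model = InheritanceModel(0.2, (0.05, 0.6, 0.95))
    spec = ModelSpec(linkage, ld, 2)
    rng = np.random.default_rng(11)
    pv = random_params(rng, spec)
    trio = make_trio((1, 2), (1, 1), (1, 2), AFFECTED, UNAFFECTED, AFFECTED)
    ref = reference_loglik(trio, pv, model, spec)
    assert peel_loglik(trio, 0, pv, model, spec).loglik == pytest.approx(
        ref, rel=1e-9
    )
    assert enumerate_loglik(trio, 0, pv, model, spec).loglik == pytest.approx(
        ref, rel=1e-9
    )


def test_impossible_data_minus_inf():
    model = preset_model("extreme_dominant", 0.01)
    spec = ModelSpec(False, False, 3)
    pv = unpack([0.4, 0.3], spec)
    bad = make_trio((1, 1), (1, 1), (3, 3))
    r = enumerate_loglik(bad, 0, pv, model, spec)
    assert r.loglik == -np.inf and r.impossible
    assert peel_loglik(bad, 0, pv, model, spec).loglik == -np.inf


# --- peeling vs package oracle on random pedigrees ---------------------------


@pytest.mark.parametrize("linkage,ld", ALL_SPECS)
def test_peel_equals_enumerate_random_pedigrees(linkage, ld, dominant_model):
    rng = np.random.default_rng(100 * linkage + 10 * ld + 5)
    for i in range(8):
        k = int(rng.choice([2, 2, 3, 4]))
        spec = ModelSpec(linkage, ld, k)
        ped = random_dropped_pedigree(rng, k, f"R{i}", dominant_model)
        pv = random_params(rng, spec)
        a = peel_loglik(ped, 0, pv, dominant_model, spec).loglik
        b = enumerate_loglik(ped, 0, pv, dominant_model, spec).loglik
        if np.isfinite(b):
            assert a == pytest.approx(b, rel=1e-9), (i, k, len(ped))
        else:
            assert a == -np.inf


# --- total probability --------------------------------------------------------


def test_trio_total_probability_over_all_observations():
    """Summing the likelihood over every fully-typed genotype/phenotype
    observation of a triad must give exactly 1."""
    model = InheritanceModel(0.3, (0.05, 0.6, 0.9))
    spec = ModelSpec(True, False, 2)
    pv = unpack([0.2, 0.3], spec)
    genos = [(1, 1), (1, 2), (2, 2)]
    phenos = [AFFECTED, UNAFFECTED]
    total = 0.0
    for gf, gm, gc in itertools.product(genos, repeat=3):
        for pf, pm, pc in itertools.product(phenos, repeat=3):
            trio = make_trio(gf, gm, gc, pf, pm, pc)
            ll = peel_loglik(trio, 0, pv, model, spec).loglik
            if np.isfinite(ll):
                total += np.exp(ll)
    assert total == pytest.approx(1.0, abs=1e-9)


# --- dataset-level properties -------------------------------------------------


def test_two_identical_singletons_double_loglik(dominant_model):
    spec = ModelSpec(False, False, 2)
    pv = unpack([0.3], spec)
    a = Pedigree("A", [make_individual("A", "1", phenotype=AFFECTED,
                                      genotypes=((1, 2),))])
    b = Pedigree("B", [make_individual("B", "1", phenotype=AFFECTED,
                                      genotypes=((1, 2),))])
    single = peel_loglik(a, 0, pv, dominant_model, spec).loglik
    both = dataset_loglik(PedigreeSet([a, b]), 0, pv, dominant_model, spec).loglik
    assert both == pytest.approx(2 * single, rel=1e-12)


def _strip(data: PedigreeSet, what: str) -> PedigreeSet:
    peds = []
    for ped in data:
        members = []
        for m in ped.members:
            geno = [(0, 0)] if what == "genotypes" else list(m.genotypes)
            phen = UNKNOWN if what == "phenotypes" else m.phenotype
            members.append(
                make_individual(ped.family_id, m.indiv_id, m.father_id,
                                m.mother_id, m.sex, phen, geno)
            )
        peds.append(Pedigree(ped.family_id, members))
    return PedigreeSet(peds)


def test_independence_factorization_at_theta_half(dominant_model):
    """At theta=0.5 under LE the marker and trait factorize: the full
    log-likelihood equals marker-only plus trait-only."""
    from linkld import SimulationDesign, simulate_dataset

    design = SimulationDesign(
        counts={"sibpair": 10, "case": 10, "control": 10},
        theta=0.5,
        model=dominant_model,
        marker_freqs=(0.4, 0.6),
        seed=9,
    )
    data, _ = simulate_dataset(design)
    spec = ModelSpec(True, False, 2)
    pv = unpack([0.5, 0.4], spec)
    full = dataset_loglik(data, 0, pv, dominant_model, spec).loglik
    marker_only = dataset_loglik(
        _strip(data, "phenotypes"), 0, pv, dominant_model, spec
    ).loglik
    trait_only = dataset_loglik(
        _strip(data, "genotypes"), 0, pv, dominant_model, spec
    ).loglik
    assert full == pytest.approx(marker_only + trait_only, rel=1e-9)


def test_pedigree_order_does_not_matter(dominant_model):
    from linkld import SimulationDesign, simulate_dataset

    design = SimulationDesign(
        counts={"sibpair": 5, "case": 5},
        theta=0.2,
        model=dominant_model,
        marker_freqs=(0.4, 0.6),
        seed=10,
    )
    data, _ = simulate_dataset(design)
    spec = ModelSpec(True, False, 2)
    pv = unpack([0.2, 0.4], spec)
    fwd = dataset_loglik(data, 0, pv, dominant_model, spec).loglik
    rev = dataset_loglik(
        PedigreeSet(list(reversed(data.pedigrees))), 0, pv, dominant_model, spec
    ).loglik
    assert fwd == rev


def test_adding_uninformative_child_keeps_likelihood(dominant_model):
    spec = ModelSpec(True, False, 2)
    pv = unpack([0.1, 0.3], spec)
    trio = make_trio((1, 2), (1, 1), (1, 2), AFFECTED, UNAFFECTED, AFFECTED)
    base = peel_loglik(trio, 0, pv, dominant_model, spec).loglik
    extended = Pedigree(
        "T1",
        trio.members
        + [make_individual("T1", "4", "1", "2", FEMALE, UNKNOWN, ((0, 0),))],
    )
    assert peel_loglik(extended, 0, pv, dominant_model, spec).loglik == (
        pytest.approx(base, rel=1e-12)
    )


def test_ld_nesting_and_theta_half_through_full_likelihood(dominant_model):
    trio = make_trio((1, 2), (1, 1), (1, 2), AFFECTED, UNAFFECTED, AFFECTED)
    le_spec = ModelSpec(False, False, 2)
    ld_spec = ModelSpec(True, True, 2)
    base = peel_loglik(trio, 0, unpack([0.3], le_spec), dominant_model, le_spec)
    nested = peel_loglik(
        trio, 0, unpack([0.5, 0.3, 0.3], ld_spec), dominant_model, ld_spec
    )
    assert nested.loglik == pytest.approx(base.loglik, rel=1e-12)


# --- looped pedigrees ---------------------------------------------------------


def _looped_pedigree():
    fam = "L1"
    members = [
        make_individual(fam, "A", sex=MALE, genotypes=((1, 2),)),
        make_individual(fam, "B", sex=FEMALE, genotypes=((1, 1),)),
        make_individual(fam, "C", "A", "B", sex=MALE, genotypes=((1, 2),)),
        make_individual(fam, "D", "A", "B", sex=FEMALE, genotypes=((1, 1),)),
        make_individual(fam, "E", "C", "D", sex=MALE, phenotype=AFFECTED,
                        genotypes=((1, 1),)),
    ]
    return Pedigree(fam, members)


def test_looped_pedigree_peel_raises_enumerate_works(dominant_model):
    ped = _looped_pedigree()
    spec = ModelSpec(True, False, 2)
    pv = unpack([0.1, 0.4], spec)
    with pytest.raises(LoopedPedigreeError):
        peel_loglik(ped, 0, pv, dominant_model, spec)
    ll = enumerate_loglik(ped, 0, pv, dominant_model, spec).loglik
    assert np.isfinite(ll)
    # dataset_loglik transparently falls back to enumeration
    via_dataset = dataset_loglik(
        PedigreeSet([ped]), 0, pv, dominant_model, spec
    ).loglik
    assert via_dataset == pytest.approx(ll, rel=1e-12)


def test_enumerate_state_cap(dominant_model):
    ped = _looped_pedigree()
    spec = ModelSpec(True, False, 2)
    pv = unpack([0.1, 0.4], spec)
    with pytest.raises(StateCapError):
        enumerate_loglik(ped, 0, pv, dominant_model, spec, state_cap=100)


# --- compiled dataset evaluator ----------------------------------------------


@pytest.mark.parametrize("linkage,ld", ALL_SPECS)
def test_dataset_likelihood_matches_per_pedigree_sum(linkage, ld, dominant_model):
    from linkld import SimulationDesign, simulate_dataset

    design = SimulationDesign(
        counts={"sibpair": 15, "triad": 5, "extended": 5, "case": 10,
                "control": 10},
        theta=0.1,
        model=dominant_model,
        marker_freqs=(0.3, 0.7),
        missing_rate={"parent": 0.3},
        seed=12,
    )
    data, _ = simulate_dataset(design)
    spec = ModelSpec(linkage, ld, 2)
    rng = np.random.default_rng(13)
    dl = DatasetLikelihood(data, 0, dominant_model, spec)
    for _ in range(3):
        pv = random_params(rng, spec)
        assert dl.loglik(pv) == pytest.approx(
            dataset_loglik(data, 0, pv, dominant_model, spec).loglik, rel=1e-9
        )
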