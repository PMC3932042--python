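"""Gene-dropping simulator producing LINKAGE-format datasets with known truth.

Founders draw two (trait allele, marker allele) haplotypes from the
population haplotype frequencies; each child receives one haplotype from
each parent, recombinant with probability theta; phenotypes are sampled
from the penetrances given the trait genotype.  Ascertainment rules
("both sibs affected", "case", ...) are applied by rejection sampling with
a per-family attempt cap, which is exact for such simple rules.
Missingness is applied last, per individual class.

Randomness is organised as one root seed with a per-family spawned stream,
so a dataset is bit-reproducible and individual families do not depend on
how many families precede them.
"""

from __future__ import annotations

import dataclasses
import json
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pedigree_io import (
    AFFECTED,
    FEMALE,
    MALE,
    UNAFFECTED,
    Individual,
    MarkerMap,
    Pedigree,
    PedigreeSet,
    write_mapfile,
    write_pedfile,
)
from .trait_model import (
    InheritanceModel,
    ModelSpec,
    ParameterVector,
    founder_haplotype_priors,
)

__all__ = [
    "SimulationDesign",
    "AscertainmentError",
    "gene_drop",
    "simulate_dataset",
    "write_dataset",
    "TEMPLATES",
]


class AscertainmentError(RuntimeError):
    """Rejection sampling exceeded the attempt cap; design infeasible."""


# Template structures: (indiv_id, father_id, mother_id, sex, class) rows.
# Class tags ("parent" / "child" / "singleton") select the missingness rate.
TEMPLATES: dict[str, list[tuple[str, str | None, str | None, int, str]]] = {
    "triad": [
        ("1", None, None, MALE, "parent"),
        ("2", None, None, FEMALE, "parent"),
        ("3", "1", "2", MALE, "child"),
    ],
    "sibpair": [
        ("1", None, None, MALE, "parent"),
        ("2", None, None, FEMALE, "parent"),
        ("3", "1", "2", MALE, "child"),
        ("4", "1", "2", FEMALE, "child"),
    ],
    "extended": [
        # three generations: grandparental couple, one of their children
        # married in, two grandchildren
        ("1", None, None, MALE, "parent"),
        ("2", None, None, FEMALE, "parent"),
        ("3", "1", "2", MALE, "parent"),
        ("4", None, None, FEMALE, "parent"),
        ("5", "3", "4", MALE, "child"),
        ("6", "3", "4", FEMALE, "child"),
    ],
    "case": [("1", None, None, MALE, "singleton")],
    "control": [("1", None, None, FEMALE, "singleton")],
}

#: Default ascertainment per template.
DEFAULT_ASCERTAINMENT = {
    "triad": "all_children_affected",
    "sibpair": "all_children_affected",
    "extended": "at_least_one_affected",
    "case": "affected",
    "control": "unaffected",
}

_RULES = (
    "none",
    "all_children_affected",
    "at_least_one_affected",
    "affected",
    "unaffected",
)


@dataclass
class SimulationDesign:
    """Generating truth of a simulated dataset.

    ``counts`` maps template names to family counts.  Either
    ``marker_freqs`` (linkage equilibrium) or both conditional frequency
    simplices (LD) must be given.  ``missing_rate`` maps individual classes
    (parent/child/singleton) to the probability of dropping the genotype.
    """

    counts: dict[str, int]
    theta: float
    model: InheritanceModel
    marker_freqs: tuple[float, ...] | None = None
    freqs_given_D: tuple[float, ...] | None = None
    freqs_given_d: tuple[float, ...] | None = None
    missing_rate: dict[str, float] = field(default_factory=dict)
    ascertainment: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    max_attempts: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 0.5:
            raise ValueError(f"theta must be in [0, 0.5], got {self.theta}")
        if (self.marker_freqs is None) == (self.freqs_given_D is None):
            raise ValueError(
                "specify exactly one of marker_freqs or conditional frequencies"
            )
        if (self.freqs_given_D is None) != (self.freqs_given_d is None):
            raise ValueError("both conditional simplices are required under LD")
        for name, simplex in (
            ("marker_freqs", self.marker_freqs),
            ("freqs_given_D", self.freqs_given_D),
            ("freqs_given_d", self.freqs_given_d),
        ):
            if simplex is not None:
                arr = np.asarray(simplex)
                if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
                    raise ValueError(f"{name} is not a probability simplex")
        for t, n in self.counts.items():
            if t not in TEMPLATES:
                raise ValueError(f"unknown template {t!r}")
            if n < 0:
                raise ValueError("counts must be >= 0")
        for t, rule in self.ascertainment.items():
            if rule not in _RULES:
                raise ValueError(f"unknown ascertainment rule {rule!r}")

    @property
    def ld(self) -> bool:
        return self.freqs_given_D is not None

    @property
    def k(self) -> int:
        f = self.marker_freqs if self.marker_freqs is not None else self.freqs_given_D
        return len(f)

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(linkage=True, ld=self.ld, n_marker_alleles=self.k)

    @property
    def params(self) -> ParameterVector:
        return ParameterVector(
            theta=self.theta,
            marker_freqs=self.marker_freqs,
            freqs_given_D=self.freqs_given_D,
            freqs_given_d=self.freqs_given_d,
        )

    def rule_for(self, template: str) -> str:
        return self.ascertainment.get(template, DEFAULT_ASCERTAINMENT[template])

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["model"] = {
            "p_disease": self.model.p_disease,
            "penetrances": list(self.model.penetrances),
        }
        return d


def _haplotype_prior(design: SimulationDesign) -> np.ndarray:
    return founder_haplotype_priors(design.params, design.model, design.spec).ravel()


class _Sampler:
    """Precomputed draw tables for one design (rejection loops are hot)."""

    def __init__(self, design: SimulationDesign):
        self.k = design.k
        self.theta = design.theta
        self.pen = design.model.penetrances
        self.cum_prior = list(np.cumsum(_haplotype_prior(design)))
        self.cum_prior[-1] = 1.0  # guard against roundoff

    def founder_hap(self, rng) -> int:
        return bisect_right(self.cum_prior, rng.random())

    def transmit(self, parent: tuple[int, int], rng) -> int:
        """One meiosis: each parental haplotype with prob (1-theta)/2,
        each recombinant with theta/2."""
        hp, hm = parent
        k, theta = self.k, self.theta
        u = rng.random()
        if u < (1.0 - theta) / 2.0:
            return hp
        if u < 1.0 - theta:
            return hm
        if u < 1.0 - theta / 2.0:
            return (hp // k) * k + hm % k
        return (hm // k) * k + hp % k

    def phenotype(self, dose: int, rng) -> int:
        return AFFECTED if rng.random() < self.pen[dose] else UNAFFECTED


def gene_drop(
    structure: list[tuple[str, str | None, str | None, int, str]],
    design: SimulationDesign,
    rng: np.random.Generator,
    sampler: _Sampler | None = None,
) -> tuple[dict[str, tuple[int, int]], dict[str, int], dict[str, int]]:
    """Drop haplotypes through one family structure.

    Returns per-individual marker genotypes (ordered paternal, maternal;
    1-based allele codes), phenotypes, and trait-allele dose (number of D
    alleles, part of the simulation truth).
    """
    s = sampler or _Sampler(design)
    k = s.k
    haps: dict[str, tuple[int, int]] = {}  # haplotype indices h = a*k + m
    for iid, fa, mo, _sex, _cls in structure:
        if fa is None:
            haps[iid] = (s.founder_hap(rng), s.founder_hap(rng))
        else:
            haps[iid] = (s.transmit(haps[fa], rng), s.transmit(haps[mo], rng))
    genotypes = {}
    phenotypes = {}
    doses = {}
    for iid, (h1, h2) in haps.items():
        genotypes[iid] = (h1 % k + 1, h2 % k + 1)
        dose = int(h1 < k) + int(h2 < k)
        doses[iid] = dose
        phenotypes[iid] = s.phenotype(dose, rng)
    return genotypes, phenotypes, doses


def _attempt_children_affected(structure, s: _Sampler, rng):
    """One rejection attempt for the all-children-affected rule, aborting at
    the first unaffected child (children are sampled after their parents)."""
    k = s.k
    haps: dict[str, tuple[int, int]] = {}
    phenotypes: dict[str, int] = {}
    for iid, fa, mo, _sex, _cls in structure:
        if fa is None:
            h = (s.founder_hap(rng), s.founder_hap(rng))
        else:
            h = (s.transmit(haps[fa], rng), s.transmit(haps[mo], rng))
        haps[iid] = h
        if fa is not None:
            dose = int(h[0] < k) + int(h[1] < k)
            phen = s.phenotype(dose, rng)
            if phen != AFFECTED:
                return None
            phenotypes[iid] = phen
    genotypes = {}
    for iid, fa, _mo, _sex, _cls in structure:
        h1, h2 = haps[iid]
        genotypes[iid] = (h1 % k + 1, h2 % k + 1)
        if fa is None:
            dose = int(h1 < k) + int(h2 < k)
            phenotypes[iid] = s.phenotype(dose, rng)
    return genotypes, phenotypes


def _satisfies(rule: str, structure, phenotypes: dict[str, int]) -> bool:
    children = [iid for iid, fa, _mo, _sex, _cls in structure if fa is not None]
    if rule == "none":
        return True
    if rule == "all_children_affected":
        return all(phenotypes[c] == AFFECTED for c in children)
    if rule == "at_least_one_affected":
        return any(p == AFFECTED for p in phenotypes.values())
    if rule == "affected":
        return all(p == AFFECTED for p in phenotypes.values())
    if rule == "unaffected":
        return all(p == UNAFFECTED for p in phenotypes.values())
    raise ValueError(f"unknown rule {rule!r}")  # pragma: no cover


def simulate_dataset(design: SimulationDesign) -> tuple[PedigreeSet, dict]:
    """Simulate the designed mixture of families and singletons.

    Returns the dataset and a truth record of all generating parameters
    (suitable for a JSON sidecar).
    """
    templates = sorted(design.counts)
    n_total = sum(design.counts[t] for t in templates)
    streams = np.random.SeedSequence(design.seed).spawn(n_total)
    sampler = _Sampler(design)
    pedigrees: list[Pedigree] = []
    fam_no = 0
    for template in templates:
        structure = TEMPLATES[template]
        rule = design.rule_for(template)
        for _ in range(design.counts[template]):
            rng = np.random.default_rng(streams[fam_no])
            fam_no += 1
            for attempt in range(design.max_attempts):
                if rule == "all_children_affected":
                    out = _attempt_children_affected(structure, sampler, rng)
                    if out is not None:
                        genotypes, phenotypes = out
                        break
                else:
                    genotypes, phenotypes, _ = gene_drop(
                        structure, design, rng, sampler
                    )
                    if _satisfies(rule, structure, phenotypes):
                        break
            else:
                raise AscertainmentError(
                    f"template {template!r}: rule {rule!r} not met in "
                    f"{design.max_attempts} attempts"
                )
            members = []
            fam_id = f"F{fam_no:05d}"
            for iid, fa, mo, sex, cls in structure:
                geno = genotypes[iid]
                if rng.random() < design.missing_rate.get(cls, 0.0):
                    geno = (0, 0)
                members.append(
                    Individual(
                        family_id=fam_id,
                        indiv_id=iid,
                        father_id=fa,
                        mother_id=mo,
                        sex=sex,
                        phenotype=phenotypes[iid],
                        genotypes=[geno],
                    )
                )
            pedigrees.append(Pedigree(fam_id, members))
    data = PedigreeSet(pedigrees)
    truth = design.to_json()
    truth["n_pedigrees"] = len(data)
    return data, truth


# ---------------------------------------------------------------------------
# Randomized pedigrees (validation fixtures for the likelihood oracle)
# ---------------------------------------------------------------------------

#: member budget keeping brute-force enumeration (4k^2)^n below ~2e7 states
MAX_ENUMERABLE_MEMBERS = {2: 6, 3: 4, 4: 4}


def random_structure(rng: np.random.Generator, k: int):
    """Random loop-free structure: a founder couple plus children; a child
    may marry a fresh founder spouse and open a second generation.  Sizes
    are capped so the pedigree stays brute-force enumerable at k alleles."""
    n_max = MAX_ENUMERABLE_MEMBERS[k]
    rows = [
        ("1", None, None, MALE, "parent"),
        ("2", None, None, FEMALE, "parent"),
    ]
    next_id = 3
    open_couples = [("1", "2")]
    while len(rows) < n_max and open_couples:
        fa, mo = open_couples[0]
        child_sex = MALE if rng.random() < 0.5 else FEMALE
        cid = str(next_id)
        next_id += 1
        rows.append((cid, fa, mo, child_sex, "child"))
        if len(rows) <= n_max - 2 and rng.random() < 0.25:
            sid = str(next_id)
            next_id += 1
            spouse_sex = FEMALE if child_sex == MALE else MALE
            rows.append((sid, None, None, spouse_sex, "parent"))
            couple = (cid, sid) if child_sex == MALE else (sid, cid)
            open_couples.append(couple)
        if rng.random() < 0.4:
            open_couples.pop(0)
    return rows


def random_parameters(rng: np.random.Generator, spec: ModelSpec):
    """Feasible random parameters for a model spec (Dirichlet simplices)."""
    from .trait_model import unpack

    x = []
    if spec.linkage:
        x.append(rng.uniform(0.0, 0.5))
    for _ in range(2 if spec.ld else 1):
        x.extend(rng.dirichlet(np.ones(spec.k))[:-1])
    return unpack(np.asarray(x), spec)


def random_dropped_pedigree(
    rng: np.random.Generator,
    k: int,
    fam_id: str,
    model: InheritanceModel,
    missing_rate: float = 0.2,
) -> Pedigree:
    """Random enumerable structure with gene-dropped data and missingness."""
    structure = random_structure(rng, k)
    design = SimulationDesign(
        counts={"triad": 1},
        theta=float(rng.uniform(0, 0.5)),
        model=model,
        marker_freqs=tuple(rng.dirichlet(np.ones(k))),
        seed=0,
    )
    genotypes, phenotypes, _ = gene_drop(structure, design, rng)
    members = []
    for iid, fa, mo, sex, _cls in structure:
        geno = genotypes[iid]
        if rng.random() < missing_rate:
            geno = (0, 0)
        members.append(Individual(fam_id, iid, fa, mo, sex, phenotypes[iid], [geno]))
    return Pedigree(fam_id, members)


def write_dataset(
    data: PedigreeSet, truth: dict, prefix: str | Path, marker_name: str = "M1"
) -> dict[str, Path]:
    """Write ped + map + JSON truth sidecar; returns the paths."""
    prefix = Path(prefix)
    paths = {
        "ped": prefix.with_suffix(".ped"),
        "map": prefix.with_suffix(".map"),
        "truth": prefix.with_suffix(".truth.json"),
    }
    write_pedfile(data, paths["ped"])
    write_mapfile(MarkerMap([(marker_name, "1", 0.0)], dialect="simple3col"), paths["map"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return paths
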