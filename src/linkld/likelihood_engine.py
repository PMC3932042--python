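"""Exact two-locus pedigree likelihoods by Elston-Stewart peeling.

The likelihood of a pedigree is a sum over every member's *ordered two-locus
genotype*: an ordered pair of (trait allele, marker allele) haplotypes, the
first paternal and the second maternal, giving 4k^2 states per individual
for a k-allele marker.  Each term is a product of

* founder priors — Hardy-Weinberg products of population haplotype
  frequencies (:func:`linkld.trait_model.founder_haplotype_priors`),
* transmission probabilities — a parent passes each of its two haplotypes
  intact with probability (1-theta)/2 and each recombinant with theta/2,
* penetrance factors — probability of the observed phenotype given the
  number of D alleles carried, times an indicator that any typed marker
  genotype matches the state's unordered marker pair.

:func:`peel_loglik` evaluates this sum exactly on loop-free pedigrees by
variable elimination in leaves-upward order (the Elston-Stewart scheme, with
per-step rescaling carried in log space to avoid underflow).
:func:`enumerate_loglik` is a brute-force oracle that materialises the full
joint state tensor and sums it; it is exponential in pedigree size but
independent of the peeling code path, and also handles looped pedigrees
within its state cap.

:class:`DatasetLikelihood` is the evaluator used by model fitting: it groups
pedigrees with identical structure and observed data (simulated datasets
contain many duplicate nuclear-family patterns), precomputes all
parameter-independent factors, and exposes a packed-coordinate objective
with the extreme barrier applied to infeasible points.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .pedigree_io import AFFECTED, UNAFFECTED, Individual, Pedigree, PedigreeSet
from .trait_model import (
    INFEASIBLE,
    InheritanceModel,
    ModelSpec,
    ParameterVector,
    founder_haplotype_priors,
    unpack,
)

__all__ = [
    "Haplotype",
    "OrderedGenotype",
    "LikelihoodResult",
    "LoopedPedigreeError",
    "StateCapError",
    "penetrance_prob",
    "transmission_prob",
    "peel_loglik",
    "enumerate_loglik",
    "dataset_loglik",
    "DatasetLikelihood",
]

D_ALLELE = 0  #: trait allele index for the predisposing allele D
d_ALLELE = 1


class Haplotype(NamedTuple):
    """(trait allele, marker allele); trait 0=D, 1=d; marker 1-based."""

    trait: int
    marker: int


class OrderedGenotype(NamedTuple):
    """Paternal and maternal two-locus haplotypes of one individual."""

    paternal: Haplotype
    maternal: Haplotype

    @property
    def n_disease(self) -> int:
        return int(self.paternal.trait == D_ALLELE) + int(
            self.maternal.trait == D_ALLELE
        )

    @property
    def marker_pair(self) -> tuple[int, int]:
        a, b = self.paternal.marker, self.maternal.marker
        return (a, b) if a <= b else (b, a)


class LoopedPedigreeError(ValueError):
    """Pedigree contains a marriage loop; peeling is not available."""


class StateCapError(ValueError):
    """Brute-force enumeration would exceed the configured state cap."""


@dataclass
class LikelihoodResult:
    """Natural-log likelihood; -inf (impossible=True) if the data have
    probability zero under the parameters."""

    loglik: float
    per_pedigree: dict[str, float] | None = None

    @property
    def impossible(self) -> bool:
        return not np.isfinite(self.loglik)


# ---------------------------------------------------------------------------
# Ordered-genotype state space (cached per marker allele count k)
# ---------------------------------------------------------------------------


class _StateSpace:
    """Index arrays over the 4k^2 ordered two-locus genotypes."""

    def __init__(self, k: int):
        self.k = k
        self.H = H = 2 * k  # haplotypes, index h = trait * k + (marker - 1)
        self.S = S = H * H  # ordered genotypes, index g = h_pat * H + h_mat
        h = np.arange(H)
        self.hap_trait = h // k
        self.hap_marker = h % k  # 0-based marker allele
        g = np.arange(S)
        self.g_hp = g // H
        self.g_hm = g % H
        self.n_disease = (self.hap_trait[self.g_hp] == D_ALLELE).astype(int) + (
            self.hap_trait[self.g_hm] == D_ALLELE
        ).astype(int)
        m1 = self.hap_marker[self.g_hp]
        m2 = self.hap_marker[self.g_hm]
        self.marker_pair_id = np.minimum(m1, m2) * k + np.maximum(m1, m2)
        # recombinant haplotype indices for transmission: paternal trait with
        # maternal marker and vice versa
        self.rec1 = self.hap_trait[self.g_hp] * k + self.hap_marker[self.g_hm]
        self.rec2 = self.hap_trait[self.g_hm] * k + self.hap_marker[self.g_hp]

    def transmission_matrix(self, theta: float) -> np.ndarray:
        """(S, H) matrix of P(transmitted haplotype | parent ordered genotype)."""
        if not 0.0 <= theta <= 0.5:
            raise ValueError(f"theta must be in [0, 0.5], got {theta}")
        S, H = self.S, self.H
        T = np.zeros((S, H))
        rows = np.arange(S)
        np.add.at(T, (rows, self.g_hp), (1.0 - theta) / 2.0)
        np.add.at(T, (rows, self.g_hm), (1.0 - theta) / 2.0)
        np.add.at(T, (rows, self.rec1), theta / 2.0)
        np.add.at(T, (rows, self.rec2), theta / 2.0)
        return T

    def pair_id(self, genotype: tuple[int, int]) -> int:
        a, b = genotype
        lo, hi = (a - 1, b - 1) if a <= b else (b - 1, a - 1)
        if lo < 0 or hi >= self.k:
            raise ValueError(f"allele codes {genotype} outside 1..{self.k}")
        return lo * self.k + hi

    def penetrance_vector(
        self, ind: Individual, marker_index: int, model: InheritanceModel
    ) -> np.ndarray:
        """(S,) phenotype x marker-typing factor for one individual."""
        f = np.asarray(model.penetrances)
        if ind.phenotype == AFFECTED:
            pen = f[self.n_disease]
        elif ind.phenotype == UNAFFECTED:
            pen = 1.0 - f[self.n_disease]
        else:
            pen = np.ones(self.S)
        geno = ind.genotype(marker_index)
        if geno is not None:
            pen = pen * (self.marker_pair_id == self.pair_id(geno))
        return pen


@functools.lru_cache(maxsize=None)
def get_state_space(k: int) -> _StateSpace:
    return _StateSpace(k)


# ---------------------------------------------------------------------------
# Scalar operations (definitions; the vectorised paths above must agree)
# ---------------------------------------------------------------------------


def penetrance_prob(
    ind: Individual,
    geno: OrderedGenotype,
    model: InheritanceModel,
    marker_index: int = 0,
) -> float:
    """P(phenotype and typed marker genotype | ordered genotype).

    Unknown phenotype contributes 1; a typed marker genotype contributes an
    indicator that it equals the state's unordered marker pair.
    """
    if ind.phenotype == AFFECTED:
        p = model.penetrances[geno.n_disease]
    elif ind.phenotype == UNAFFECTED:
        p = 1.0 - model.penetrances[geno.n_disease]
    else:
        p = 1.0
    observed = ind.genotype(marker_index)
    if observed is not None and observed != geno.marker_pair:
        return 0.0
    return p


def transmission_prob(
    parent: OrderedGenotype, transmitted: Haplotype, theta: float
) -> float:
    """P(parent transmits ``transmitted`` | parent genotype, theta)."""
    if not 0.0 <= theta <= 0.5:
        raise ValueError(f"theta must be in [0, 0.5], got {theta}")
    p = 0.0
    hp, hm = parent.paternal, parent.maternal
    for hap, prob in (
        (hp, (1.0 - theta) / 2.0),
        (hm, (1.0 - theta) / 2.0),
        (Haplotype(hp.trait, hm.marker), theta / 2.0),
        (Haplotype(hm.trait, hp.marker), theta / 2.0),
    ):
        if hap == transmitted:
            p += prob
    return p


# ---------------------------------------------------------------------------
# Factor construction shared by peeling and enumeration
# ---------------------------------------------------------------------------


def _founder_prior_g(
    params: ParameterVector, model: InheritanceModel, spec: ModelSpec
) -> np.ndarray:
    """(S,) prior over a founder's ordered genotype: product of independent
    haplotype draws from the population haplotype frequencies."""
    ph = founder_haplotype_priors(params, model, spec).ravel()  # (H,)
    return np.outer(ph, ph).ravel()


def _trans3(space: _StateSpace, T: np.ndarray) -> np.ndarray:
    """(S, S, S) tensor P(child genotype | father, mother genotypes)."""
    H, S = space.H, space.S
    return (T[:, None, :, None] * T[None, :, None, :]).reshape(S, S, S)


def _structure(ped: Pedigree) -> list[tuple[int, int]]:
    """Per-member (father_index, mother_index), (-1, -1) for founders."""
    index = {m.indiv_id: i for i, m in enumerate(ped.members)}
    out = []
    for m in ped.members:
        if m.is_founder:
            out.append((-1, -1))
        else:
            out.append((index[m.father_id], index[m.mother_id]))
    return out


# ---------------------------------------------------------------------------
# Peeling (variable elimination, leaves upward)
# ---------------------------------------------------------------------------


def _peel_from_factors(
    structure: list[tuple[int, int]],
    pens: list[np.ndarray],
    prior_g: np.ndarray,
    T: np.ndarray,
    space: _StateSpace,
) -> float:
    """Eliminate individuals one at a time; returns the log-likelihood.

    Children without descendants are absorbed into a factor over their
    parent couple via two small matrix products (the inner step of
    Elston-Stewart peeling); remaining individuals are eliminated by
    generic sum-product contraction in a min-size order.
    """
    n = len(structure)
    H, S = space.H, space.S
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    for c, (fa, mo) in enumerate(structure):
        if fa >= 0:
            children[fa].append(c)
            children[mo].append(c)

    log_scale = 0.0
    # factors: list of (vars tuple sorted, ndarray); start with per-individual
    factors: list[tuple[tuple[int, ...], np.ndarray]] = []
    vec: dict[int, np.ndarray] = {}
    for i, (fa, mo) in enumerate(structure):
        v = pens[i] * prior_g if fa < 0 else pens[i].copy()
        vec[i] = v

    trans3 = None
    # Pass 1: absorb leaf children (no children of their own) into couples.
    couple: dict[tuple[int, int], np.ndarray] = {}
    remaining = set(range(n))
    for i, (fa, mo) in enumerate(structure):
        if fa >= 0 and not children[i]:
            Vc = vec.pop(i).reshape(H, H)
            msg = T @ Vc @ T.T  # (S fa, S mo)
            key = (fa, mo)
            couple[key] = couple[key] * msg if key in couple else msg
            remaining.discard(i)
    for (fa, mo), arr in couple.items():
        mx = arr.max()
        if mx <= 0.0:
            return -np.inf
        log_scale += np.log(mx)
        factors.append(((fa, mo), arr / mx))
    for i in remaining:
        factors.append(((i,), vec[i]))
    # transmission factors for mid-generation members (children who are
    # themselves parents)
    for c in remaining:
        fa, mo = structure[c]
        if fa >= 0:
            if trans3 is None:
                trans3 = _trans3(space, T)
            factors.append(((fa, mo, c), trans3))

    # Pass 2: generic elimination over the remaining individuals.
    letters = "abcdefghijklmnopqrstuvwxyz"
    while remaining:
        # choose the variable whose elimination builds the smallest factor
        best_var, best_vars = None, None
        for v in remaining:
            union: set[int] = set()
            for vars_, _ in factors:
                if v in vars_:
                    union.update(vars_)
            if best_vars is None or len(union) < len(best_vars):
                best_var, best_vars = v, union
        v = best_var
        involved = [(vars_, arr) for vars_, arr in factors if v in vars_]
        factors = [f for f in factors if v not in f[0]]
        out_vars = tuple(sorted(set(best_vars) - {v}))
        sub = {u: letters[j] for j, u in enumerate(sorted(best_vars))}
        lhs = ",".join("".join(sub[u] for u in vars_) for vars_, _ in involved)
        rhs = "".join(sub[u] for u in out_vars)
        arr = np.einsum(lhs + "->" + rhs, *[a for _, a in involved], optimize=True)
        remaining.discard(v)
        if arr.size == 0 or not np.isfinite(arr).all():
            return -np.inf
        mx = arr.max() if arr.ndim else float(arr)
        if mx <= 0.0:
            return -np.inf
        if arr.ndim:
            log_scale += np.log(mx)
            factors.append((out_vars, arr / mx))
        else:
            log_scale += np.log(mx)
    total = 1.0
    for vars_, arr in factors:
        total *= float(np.asarray(arr).sum()) if vars_ else float(arr)
    if total <= 0.0:
        return -np.inf
    return float(np.log(total) + log_scale)


def _nuclear_loglik(
    prior_g: np.ndarray,
    T: np.ndarray,
    pen_fa: np.ndarray,
    pen_mo: np.ndarray,
    pen_kids: Sequence[np.ndarray],
    H: int,
) -> float:
    """Fast path for a single nuclear family (parents plus leaf children)."""
    M = np.outer(prior_g * pen_fa, prior_g * pen_mo)
    for pen_c in pen_kids:
        M *= T @ pen_c.reshape(H, H) @ T.T
    s = M.sum()
    return float(np.log(s)) if s > 0.0 else -np.inf


def peel_loglik(
    ped: Pedigree,
    marker_index: int,
    params: ParameterVector,
    model: InheritanceModel,
    spec: ModelSpec,
) -> LikelihoodResult:
    """Exact log-likelihood of one loop-free pedigree at one marker."""
    if params is INFEASIBLE:
        raise ValueError("infeasible parameter vector")
    if ped.has_loops:
        raise LoopedPedigreeError(
            f"family {ped.family_id}: marriage loop; use enumerate_loglik"
        )
    space = get_state_space(spec.k)
    prior_g = _founder_prior_g(params, model, spec)
    T = space.transmission_matrix(params.effective_theta)
    pens = [space.penetrance_vector(m, marker_index, model) for m in ped.members]
    ll = _peel_from_factors(_structure(ped), pens, prior_g, T, space)
    return LikelihoodResult(ll)


def enumerate_loglik(
    ped: Pedigree,
    marker_index: int,
    params: ParameterVector,
    model: InheritanceModel,
    spec: ModelSpec,
    state_cap: float = 1e8,
) -> LikelihoodResult:
    """Brute-force oracle: sum the full joint ordered-genotype tensor.

    Exponential in pedigree size ((4k^2)^n states); refuses to run past
    ``state_cap``.  Valid on looped pedigrees, unlike :func:`peel_loglik`.
    """
    if params is INFEASIBLE:
        raise ValueError("infeasible parameter vector")
    space = get_state_space(spec.k)
    n = len(ped)
    S = space.S
    if float(S) ** n > state_cap:
        raise StateCapError(
            f"{S}^{n} ordered-genotype states exceed cap {state_cap:g}"
        )
    prior_g = _founder_prior_g(params, model, spec)
    T = space.transmission_matrix(params.effective_theta)
    structure = _structure(ped)
    arr = np.ones((S,) * n)

    def axis_shape(positions: list[int], factor: np.ndarray) -> np.ndarray:
        order = np.argsort(positions)
        f = np.transpose(factor, order)
        shape = [1] * n
        for p in sorted(positions):
            shape[p] = S
        return f.reshape(shape)

    trans3 = None
    for i, m in enumerate(ped.members):
        pen = space.penetrance_vector(m, marker_index, model)
        fa, mo = structure[i]
        if fa < 0:
            pen = pen * prior_g
        else:
            if trans3 is None:
                trans3 = _trans3(space, T)
            arr *= axis_shape([fa, mo, i], trans3)
        arr *= axis_shape([i], pen.reshape(S))
    total = arr.sum()
    return LikelihoodResult(float(np.log(total)) if total > 0.0 else -np.inf)


def dataset_loglik(
    data: PedigreeSet,
    marker_index: int,
    params: ParameterVector,
    model: InheritanceModel,
    spec: ModelSpec,
) -> LikelihoodResult:
    """Sum of per-pedigree log-likelihoods over a mixed pedigree/singleton set.

    Looped pedigrees fall back to brute-force enumeration within the default
    state cap; errors are annotated with the family id.
    """
    per: dict[str, float] = {}
    total = 0.0
    for ped in data:
        try:
            try:
                r = peel_loglik(ped, marker_index, params, model, spec)
            except LoopedPedigreeError:
                r = enumerate_loglik(ped, marker_index, params, model, spec)
        except (ValueError, KeyError) as exc:
            raise type(exc)(f"family {ped.family_id}: {exc}") from exc
        per[ped.family_id] = r.loglik
        total += r.loglik
    return LikelihoodResult(total, per_pedigree=per)


# ---------------------------------------------------------------------------
# Compiled dataset evaluator for model fitting
# ---------------------------------------------------------------------------


class DatasetLikelihood:
    """Reusable evaluator of the dataset log-likelihood at one marker.

    Pedigrees with identical structure, phenotypes and marker genotypes are
    collapsed into weighted unique patterns, and all parameter-independent
    factors (penetrance vectors) are precomputed, so that each evaluation
    costs a handful of small matrix products per *unique* pattern.  This is
    the objective handed to the optimizers, which evaluate it hundreds of
    times per fit.
    """

    def __init__(
        self,
        data: PedigreeSet,
        marker_index: int,
        model: InheritanceModel,
        spec: ModelSpec,
    ):
        self.marker_index = marker_index
        self.model = model
        self.spec = spec
        self.space = get_state_space(spec.k)
        space = self.space
        groups: dict[tuple, list] = {}
        for ped in data:
            sig = (
                tuple(_structure(ped)),
                tuple(m.phenotype for m in ped.members),
                tuple(m.genotype(marker_index) for m in ped.members),
            )
            if sig in groups:
                groups[sig][0] += 1
            else:
                groups[sig] = [1, ped]
        self._patterns = []
        for count, ped in groups.values():
            structure = _structure(ped)
            pens = [
                space.penetrance_vector(m, marker_index, model) for m in ped.members
            ]
            extra = None
            if len(ped) == 1:
                kind = "singleton"
            elif ped.has_loops:
                kind = "enumerate"
            else:
                fams = ped.nuclear_families()
                index = {m.indiv_id: i for i, m in enumerate(ped.members)}
                parents = {fams[0][0], fams[0][1]} if len(fams) == 1 else set()
                if len(fams) == 1 and len(parents | set(fams[0][2])) == len(ped):
                    kind = "nuclear"
                    fa, mo, kids = fams[0]
                    extra = (index[fa], index[mo], [index[c] for c in kids])
                else:
                    kind = "generic"
            self._patterns.append((count, kind, ped, structure, pens, extra))

    def loglik(self, params: ParameterVector) -> float:
        space = self.space
        prior_g = _founder_prior_g(params, self.model, self.spec)
        T = space.transmission_matrix(params.effective_theta)
        H = space.H
        total = 0.0
        for count, kind, ped, structure, pens, extra in self._patterns:
            if kind == "singleton":
                s = float(prior_g @ pens[0])
                ll = np.log(s) if s > 0.0 else -np.inf
            elif kind == "nuclear":
                fa_i, mo_i, kid_i = extra
                ll = _nuclear_loglik(
                    prior_g, T, pens[fa_i], pens[mo_i], [pens[c] for c in kid_i], H
                )
            elif kind == "generic":
                ll = _peel_from_factors(structure, pens, prior_g, T, space)
            else:  # looped: brute force
                ll = enumerate_loglik(
                    ped, self.marker_index, params, self.model, self.spec
                ).loglik
            if not np.isfinite(ll):
                return -np.inf
            total += count * ll
        return total

    def objective(self, x: np.ndarray):
        """Packed-coordinate objective with the extreme barrier applied."""
        pv = unpack(x, self.spec)
        if pv is INFEASIBLE:
            return INFEASIBLE
        return self.loglik(pv)
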