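"""Model fitting and likelihood-ratio tests for linkage and/or LD.

Four models are fitted per marker, covering every combination of linkage
(free recombination fraction theta) and LD (marker allele frequencies
conditional on the trait allele):

====================  ======  ====  ==================================
model                 theta   LD    free parameters (k-allele marker)
====================  ======  ====  ==================================
null                  0.5     no    k-1
linkage               free    no    k
ld                    0.5     yes   2(k-1)
joint                 free    yes   2(k-1) + 1
====================  ======  ====  ==================================

Five nested comparisons are reported: linkage (linkage vs null), LD given
linkage (joint vs linkage), linkage given LD (joint vs ld), joint linkage
and LD (joint vs null), and LD without linkage (ld vs null).

Every larger model is warm-started from the smaller model's solution,
embedded so its objective value is *exactly* the smaller model's maximum
(theta = 0.5 and/or equal conditional frequencies).  Because the optimizer
never returns a value below its starting point, each LR statistic is
non-negative by construction — a failed maximization can depress power but
can never produce a nonsensical negative statistic.

For the two tests that free *only* theta (linkage, linkage given LD), the
null value theta = 0.5 lies on the boundary of [0, 0.5], the LR statistic
has an atom at zero (theta-hat sits at 0.5 in about half of null
replicates), and the default p-value uses the classical 50:50 mixture of a
point mass at zero and chi-square(1).  The joint test frees theta *and* the
conditional frequencies; its null statistic carries no atom at zero because
the frequency parameters always absorb some deviance, and in null
calibration experiments plain chi-square(df) tracks its distribution well
while mixture corrections are anti-conservative — so the joint test
defaults to plain chi-square.  ``chi2_mode="plain"`` switches every test to
plain chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .likelihood_engine import DatasetLikelihood
from .mads_optimizer import (
    OptimizerOptions,
    OptResult,
    gps_maximize,
    mads_maximize,
)
from .pedigree_io import PedigreeSet
from .trait_model import (
    INFEASIBLE,
    InheritanceModel,
    ModelSpec,
    ParameterVector,
    n_free_params,
    pack,
    param_bounds,
    unpack,
)

__all__ = [
    "ModelFit",
    "TestResult",
    "TEST_NAMES",
    "MonomorphicMarkerError",
    "observed_allele_freqs",
    "fit_model",
    "pseudomarker_tests",
]

TEST_NAMES = (
    "linkage",
    "ld_given_linkage",
    "linkage_given_ld",
    "joint_linkage_ld",
    "ld_no_linkage",
)

#: (null model, alt model) per test; models keyed by (linkage, ld) flags.
_TEST_MODELS = {
    "linkage": ((False, False), (True, False)),
    "ld_given_linkage": ((True, False), (True, True)),
    "linkage_given_ld": ((False, True), (True, True)),
    "joint_linkage_ld": ((False, False), (True, True)),
    "ld_no_linkage": ((False, False), (False, True)),
}

#: Tests whose alternative frees only theta: the null puts theta on the
#: boundary of [0, 0.5] and the statistic has a point mass at zero, so the
#: 50:50 chi2_0 : chi2_1 mixture applies by default.  The joint test is
#: excluded: its statistic has no atom at zero (see module docstring).
_BOUNDARY_TESTS = {"linkage", "linkage_given_ld"}


class MonomorphicMarkerError(ValueError):
    """Marker shows fewer than two alleles; skip it (no test is defined)."""


@dataclass
class ModelFit:
    spec: ModelSpec
    params: ParameterVector
    loglik: float
    n_evals: int
    opt_result: OptResult | None = None


@dataclass
class TestResult:
    name: str
    statistic: float
    df: int
    p_value: float
    boundary_adjusted: bool
    alt: ModelFit
    null: ModelFit


def observed_allele_freqs(data: PedigreeSet, marker_index: int, k: int) -> np.ndarray:
    """Allele proportions among typed individuals (counting both alleles)."""
    counts = np.zeros(k)
    for _, ind in data.individuals():
        g = ind.genotype(marker_index)
        if g is not None:
            counts[g[0] - 1] += 1
            counts[g[1] - 1] += 1
    total = counts.sum()
    if total == 0:
        raise MonomorphicMarkerError("no typed genotypes at this marker")
    return counts / total


def _default_start(spec: ModelSpec, obs_freqs: np.ndarray) -> np.ndarray:
    """Observed frequencies; theta0 = 0.25; LD conditionals both at observed."""
    parts: list[float] = []
    if spec.linkage:
        parts.append(0.25)
    expl = list(obs_freqs[:-1])
    parts.extend(expl * (2 if spec.ld else 1))
    return np.asarray(parts)


def _embed(params: ParameterVector, from_spec: ModelSpec, to_spec: ModelSpec) -> np.ndarray:
    """Pack a smaller model's solution into a larger model's coordinates so
    that the likelihood value is preserved exactly."""
    theta = params.theta if from_spec.linkage else None
    if to_spec.ld:
        if from_spec.ld:
            fD, fd = params.freqs_given_D, params.freqs_given_d
        else:
            fD = fd = params.marker_freqs
        embedded = ParameterVector(theta, None, fD, fd)
    else:
        assert not from_spec.ld
        embedded = ParameterVector(theta, params.marker_freqs, None, None)
    x = pack(embedded, to_spec)
    if to_spec.linkage and not from_spec.linkage:
        x[0] = 0.5
    return x


def fit_model(
    data: PedigreeSet | DatasetLikelihood,
    marker_index: int,
    model: InheritanceModel,
    spec: ModelSpec,
    options: OptimizerOptions | None = None,
    init: np.ndarray | list[np.ndarray] | None = None,
    optimizer: str = "mads",
    obs_freqs: np.ndarray | None = None,
) -> ModelFit:
    """Maximize the dataset log-likelihood over the spec's free parameters.

    The default starting point is the observed allele frequencies (theta0 =
    0.25 under linkage; both conditional simplices at the observed
    frequencies under LD).  ``init`` may supply one or more additional
    candidate starts in packed coordinates (warm starts from nested models'
    solutions); the best-scoring candidate is used, so the fitted maximum
    can never fall below any warm-start value.
    """
    opts = options or OptimizerOptions()
    if isinstance(data, DatasetLikelihood):
        dl = data
        if obs_freqs is None:
            raise ValueError("obs_freqs is required with a prebuilt evaluator")
    else:
        _check_polymorphic(data, marker_index)
        dl = DatasetLikelihood(data, marker_index, model, spec)
        if obs_freqs is None:
            obs_freqs = observed_allele_freqs(data, marker_index, spec.k)
    starts = [_default_start(spec, obs_freqs)]
    if init is not None:
        inits = init if isinstance(init, list) else [init]
        starts.extend(np.asarray(i, dtype=float) for i in inits)
    extra_evals = 0
    vals = []
    for s in starts:
        v = dl.objective(s)
        extra_evals += 1
        vals.append(-np.inf if v is INFEASIBLE or v is None else v)
    x0 = starts[int(np.argmax(vals))]
    maximize = {"mads": mads_maximize, "gps": gps_maximize}[optimizer]
    res = maximize(dl.objective, param_bounds(spec), x0, opts)
    params = unpack(res.x, spec)
    if params is INFEASIBLE:  # cannot happen: optimizer never accepts such
        raise RuntimeError("optimizer returned an infeasible point")
    return ModelFit(
        spec=spec,
        params=params,
        loglik=res.f,
        n_evals=res.n_evals + extra_evals,
        opt_result=res,
    )


def _check_polymorphic(data: PedigreeSet, marker_index: int) -> None:
    seen: set[int] = set()
    for _, ind in data.individuals():
        g = ind.genotype(marker_index)
        if g is not None:
            seen.update(g)
    if len(seen) < 2:
        raise MonomorphicMarkerError(
            f"marker {marker_index} shows {len(seen)} allele(s); "
            "skip monomorphic markers"
        )


def _mixture_p(stat: float, df: int) -> float:
    # 50:50 mixture of chi2_0 (point mass at 0) and chi2_df
    if stat <= 0.0:
        return 1.0
    return 0.5 * float(chi2.sf(stat, df))


def pseudomarker_tests(
    data: PedigreeSet,
    marker_index: int,
    model: InheritanceModel,
    options: OptimizerOptions | None = None,
    tests: tuple[str, ...] = TEST_NAMES,
    chi2_mode: str = "mixture",
    optimizer: str = "mads",
) -> list[TestResult]:
    """Fit the hypothesis models needed for ``tests`` and report LR tests.

    ``chi2_mode`` selects the null distribution for boundary tests:
    ``"mixture"`` (default) the 50:50 chi2_0 : chi2_df mixture, ``"plain"``
    ordinary chi-square.
    """
    unknown = set(tests) - set(TEST_NAMES)
    if unknown:
        raise ValueError(f"unknown test name(s): {sorted(unknown)}")
    if chi2_mode not in ("mixture", "plain"):
        raise ValueError("chi2_mode must be 'mixture' or 'plain'")
    _check_polymorphic(data, marker_index)
    k = data.n_alleles(marker_index)
    obs = observed_allele_freqs(data, marker_index, k)
    specs = {
        flags: ModelSpec(linkage=flags[0], ld=flags[1], n_marker_alleles=k)
        for flags in {f for t in tests for f in _TEST_MODELS[t]} | {(False, False)}
    }
    evaluators = {
        flags: DatasetLikelihood(data, marker_index, model, spec)
        for flags, spec in specs.items()
    }

    def run_fit(flags: tuple[bool, bool], init: np.ndarray | None) -> ModelFit:
        return fit_model(
            evaluators[flags],
            marker_index,
            model,
            specs[flags],
            options=options,
            init=init,
            optimizer=optimizer,
            obs_freqs=obs,
        )

    fits: dict[tuple[bool, bool], ModelFit] = {}
    fits[(False, False)] = run_fit((False, False), None)
    null_fit = fits[(False, False)]
    for flags in ((True, False), (False, True)):
        if flags in specs:
            fits[flags] = run_fit(
                flags, _embed(null_fit.params, specs[(False, False)], specs[flags])
            )
    if (True, True) in specs:
        joint_spec = specs[(True, True)]
        candidates = [
            _embed(fits[f].params, specs[f], joint_spec)
            for f in ((True, False), (False, True), (False, False))
            if f in fits
        ]
        fits[(True, True)] = run_fit((True, True), candidates)

    results = []
    for name in tests:
        nf, af = _TEST_MODELS[name]
        null, alt = fits[nf], fits[af]
        stat = 2.0 * (alt.loglik - null.loglik)
        df = n_free_params(alt.spec) - n_free_params(null.spec)
        boundary = name in _BOUNDARY_TESTS and chi2_mode == "mixture"
        if boundary:
            p = _mixture_p(stat, df)
        else:
            p = 1.0 if stat <= 0.0 else float(chi2.sf(stat, df))
        results.append(
            TestResult(
                name=name,
                statistic=stat,
                df=df,
                p_value=p,
                boundary_adjusted=boundary,
                alt=alt,
                null=null,
            )
        )
    return results
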