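"""Inheritance models, hypothesis model specs, and parameter packing.

The trait locus is modelled with two alleles, D (predisposing) and d, a
fixed population frequency ``p_disease`` for D, and three penetrances
``(f0, f1, f2)`` giving the probability of affection for 0, 1 or 2 copies
of D.  These are model *inputs*; the likelihood's free parameters are only
the marker allele frequencies (or, under LD, the marker allele frequencies
conditional on the trait allele carried on the same haplotype) and, under
linkage, the recombination fraction theta in [0, 0.5].

Each frequency simplex of k marker alleles is packed as k-1 explicit values;
the last allele's frequency is implicit (1 minus the sum).  A packed point
whose implicit entry falls outside [0, 1] is infeasible and is reported with
the :data:`INFEASIBLE` sentinel so optimizers can apply the extreme barrier:
the point is discarded as if it had an infinitely bad objective value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "InheritanceModel",
    "ModelSpec",
    "ParameterVector",
    "INFEASIBLE",
    "preset_model",
    "n_free_params",
    "pack",
    "unpack",
    "param_bounds",
    "founder_haplotype_priors",
]


class _Infeasible:
    """Sentinel for a parameter point violating an implicit-frequency bound."""

    def __repr__(self) -> str:  # pragma: no cover
        return "INFEASIBLE"

    def __bool__(self) -> bool:
        return False


INFEASIBLE = _Infeasible()


@dataclass(frozen=True)
class InheritanceModel:
    """Disease allele frequency and penetrances of a diallelic trait locus."""

    p_disease: float
    penetrances: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not 0.0 < self.p_disease < 1.0:
            raise ValueError(f"p_disease must be in (0,1), got {self.p_disease}")
        if any(not 0.0 <= f <= 1.0 for f in self.penetrances):
            raise ValueError(f"penetrances must be in [0,1]: {self.penetrances}")


#: Default disease-allele frequencies of the extreme model presets.  The
#: recessive default sqrt(0.02) ~ 0.141 gives a ~2% trait prevalence under
#: Hardy-Weinberg; the dominant default 0.01 gives ~2% as well.  Both are
#: configurable through :func:`preset_model`.
PRESET_DISEASE_FREQ = {"extreme_dominant": 0.01, "extreme_recessive": 0.1414213562373095}

_PRESET_PENETRANCES = {
    "extreme_dominant": (0.0, 1.0, 1.0),
    "extreme_recessive": (0.0, 0.0, 1.0),
}


def preset_model(name: str, p_disease: float | None = None) -> InheritanceModel:
    """Fully penetrant dominant or recessive inheritance model.

    ``extreme_dominant`` has penetrances (0, 1, 1); ``extreme_recessive``
    (0, 0, 1).  ``p_disease`` defaults per :data:`PRESET_DISEASE_FREQ`.
    """
    try:
        pen = _PRESET_PENETRANCES[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESET_PENETRANCES)}"
        )
    if p_disease is None:
        p_disease = PRESET_DISEASE_FREQ[name]
    return InheritanceModel(p_disease=p_disease, penetrances=pen)


@dataclass(frozen=True)
class ModelSpec:
    """Which of the four hypothesis models is being fitted.

    The four (linkage, ld) combinations are: neither (null), linkage only,
    LD only, and joint linkage + LD.
    """

    linkage: bool
    ld: bool
    n_marker_alleles: int

    def __post_init__(self) -> None:
        if self.n_marker_alleles < 2:
            raise ValueError("need at least 2 marker alleles")

    @property
    def k(self) -> int:
        return self.n_marker_alleles


@dataclass(frozen=True)
class ParameterVector:
    """Unpacked free parameters of one hypothesis model.

    ``marker_freqs`` holds the full k-simplex (implicit entry restored) when
    the model has no LD; under LD, ``freqs_given_D`` and ``freqs_given_d``
    hold the conditional simplices instead.  ``theta`` is None when linkage
    is not part of the model, in which case it is treated as 0.5.
    """

    theta: float | None
    marker_freqs: tuple[float, ...] | None
    freqs_given_D: tuple[float, ...] | None
    freqs_given_d: tuple[float, ...] | None

    @property
    def effective_theta(self) -> float:
        return 0.5 if self.theta is None else self.theta


def n_free_params(spec: ModelSpec) -> int:
    """k-1 free frequencies (2(k-1) under LD), plus theta under linkage."""
    k = spec.k
    n = 2 * (k - 1) if spec.ld else (k - 1)
    return n + 1 if spec.linkage else n


def _complete_simplex(explicit: np.ndarray) -> tuple[float, ...] | None:
    if np.any(explicit < 0.0) or np.any(explicit > 1.0):
        return None
    implicit = 1.0 - float(explicit.sum())
    # tolerate roundoff at the boundary of the simplex
    if implicit < -1e-12 or implicit > 1.0 + 1e-12:
        return None
    return tuple(explicit) + (min(max(implicit, 0.0), 1.0),)


def unpack(x: Sequence[float], spec: ModelSpec):
    """Reconstruct a :class:`ParameterVector` from packed coordinates.

    Returns :data:`INFEASIBLE` when any implicit simplex entry falls outside
    [0, 1]; callers must then apply the extreme barrier (treat the point as
    infinitely bad) rather than evaluate a likelihood.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (n_free_params(spec),):
        raise ValueError(
            f"expected {n_free_params(spec)} packed parameters, got {x.shape}"
        )
    k = spec.k
    pos = 0
    theta = None
    if spec.linkage:
        theta = float(x[0])
        if not 0.0 <= theta <= 0.5:
            return INFEASIBLE
        pos = 1
    if spec.ld:
        fD = _complete_simplex(x[pos : pos + k - 1])
        fd = _complete_simplex(x[pos + k - 1 : pos + 2 * (k - 1)])
        if fD is None or fd is None:
            return INFEASIBLE
        return ParameterVector(theta, None, fD, fd)
    freqs = _complete_simplex(x[pos : pos + k - 1])
    if freqs is None:
        return INFEASIBLE
    return ParameterVector(theta, freqs, None, None)


def pack(params: ParameterVector, spec: ModelSpec) -> np.ndarray:
    """Inverse of :func:`unpack` on feasible parameter vectors."""
    out: list[float] = []
    if spec.linkage:
        out.append(params.effective_theta)
    if spec.ld:
        assert params.freqs_given_D is not None and params.freqs_given_d is not None
        out.extend(params.freqs_given_D[:-1])
        out.extend(params.freqs_given_d[:-1])
    else:
        assert params.marker_freqs is not None
        out.extend(params.marker_freqs[:-1])
    return np.asarray(out, dtype=float)


def param_bounds(spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Box bounds of the packed parameter space ([0,0.5] for theta, [0,1] else)."""
    n = n_free_params(spec)
    lo = np.zeros(n)
    hi = np.ones(n)
    if spec.linkage:
        hi[0] = 0.5
    return lo, hi


def founder_haplotype_priors(
    params: ParameterVector, model: InheritanceModel, spec: ModelSpec
) -> np.ndarray:
    """Population frequencies of the 2k (trait allele, marker allele) haplotypes.

    Returns a (2, k) array ``P[a, m]`` with row 0 the D-bearing haplotypes
    and row 1 the d-bearing ones.  Without LD the loci are independent,
    ``P(a, m) = p_a * p_m``; with LD the marker frequency is conditional on
    the trait allele, ``P(a, m) = p_a * p(m | a)``.
    """
    k = spec.k
    pD = model.p_disease
    if spec.ld:
        if params.freqs_given_D is None or params.freqs_given_d is None:
            raise ValueError("LD model requires conditional frequencies")
        out = np.vstack(
            [
                pD * np.asarray(params.freqs_given_D),
                (1.0 - pD) * np.asarray(params.freqs_given_d),
            ]
        )
    else:
        if params.marker_freqs is None:
            raise ValueError("LE model requires marginal marker frequencies")
        pm = np.asarray(params.marker_freqs)
        out = np.vstack([pD * pm, (1.0 - pD) * pm])
    if out.shape != (2, k):
        raise ValueError(f"frequency simplices must have length {k}")
    return out
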