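"""Optimizer-efficiency benchmark: MADS vs restarted GPS on a fixed battery
of simulated likelihood maximizations.

Each problem simulates a dataset (sib pairs, triads, extended families,
cases/controls; biallelic and triallelic markers; dominant and recessive
fully penetrant trait models) and maximizes one of the hypothesis-model
likelihoods from the common default start.  The comparison mirrors how the
two optimizers are used for real analyses: MADS is invoked once, GPS with
its restart protocol.
"""

from __future__ import annotations

from .hypothesis_tests import _default_start, observed_allele_freqs
from .likelihood_engine import DatasetLikelihood
from .mads_optimizer import OptimizerOptions, gps_maximize, mads_maximize
from .simulator import SimulationDesign, simulate_dataset
from .trait_model import ModelSpec, param_bounds, preset_model

__all__ = ["efficiency_battery_configs", "run_efficiency_battery"]


def efficiency_battery_configs():
    """Twelve (design kwargs, trait model, (linkage, ld)) problem settings."""
    dom = preset_model("extreme_dominant", 0.01)
    rec = preset_model("extreme_recessive")
    return [
        (dict(counts={"sibpair": 30, "case": 30, "control": 30}, theta=0.5,
              marker_freqs=(0.6, 0.4)), dom, (True, True)),
        (dict(counts={"sibpair": 30, "case": 30, "control": 30}, theta=0.5,
              marker_freqs=(0.6, 0.4)), dom, (True, False)),
        (dict(counts={"sibpair": 40}, theta=0.05, freqs_given_D=(0.9, 0.1),
              freqs_given_d=(0.2, 0.8)), dom, (True, True)),
        (dict(counts={"sibpair": 40}, theta=0.05, freqs_given_D=(0.9, 0.1),
              freqs_given_d=(0.2, 0.8)), dom, (False, True)),
        (dict(counts={"triad": 50, "control": 50}, theta=0.1,
              marker_freqs=(0.3, 0.7)), dom, (True, True)),
        (dict(counts={"triad": 50, "control": 50}, theta=0.1,
              marker_freqs=(0.3, 0.7)), dom, (True, False)),
        (dict(counts={"sibpair": 30, "case": 20, "control": 20}, theta=0.5,
              marker_freqs=(0.4, 0.35, 0.25)), dom, (True, True)),
        (dict(counts={"sibpair": 30, "case": 20, "control": 20}, theta=0.5,
              marker_freqs=(0.4, 0.35, 0.25)), dom, (False, True)),
        (dict(counts={"sibpair": 40, "control": 40}, theta=0.5,
              marker_freqs=(0.5, 0.5)), rec, (True, True)),
        (dict(counts={"sibpair": 40, "control": 40}, theta=0.5,
              marker_freqs=(0.5, 0.5)), rec, (True, False)),
        (dict(counts={"extended": 30}, theta=0.02, freqs_given_D=(1.0, 0.0),
              freqs_given_d=(0.5, 0.5)), dom, (True, True)),
        (dict(counts={"extended": 30}, theta=0.02, freqs_given_D=(1.0, 0.0),
              freqs_given_d=(0.5, 0.5)), dom, (True, False)),
    ]


def run_efficiency_battery(seed_base: int = 7000, opt_seed: int = 1):
    """Run both optimizers on every battery problem.

    Returns per-problem tuples (mads_evals, gps_evals, hit) where ``hit``
    means MADS reached within 1e-4 of the best log-likelihood either
    optimizer found.
    """
    rows = []
    for i, (dkw, model, flags) in enumerate(efficiency_battery_configs()):
        design = SimulationDesign(model=model, seed=seed_base + i, **dkw)
        data, _ = simulate_dataset(design)
        k = data.n_alleles(0)
        spec = ModelSpec(linkage=flags[0], ld=flags[1], n_marker_alleles=k)
        dl = DatasetLikelihood(data, 0, model, spec)
        x0 = _default_start(spec, observed_allele_freqs(data, 0, k))
        opts = OptimizerOptions(seed=opt_seed)
        rm = mads_maximize(dl.objective, param_bounds(spec), x0, opts)
        rg = gps_maximize(dl.objective, param_bounds(spec), x0, opts)
        best = max(rm.f, rg.f)
        rows.append((rm.n_evals, rg.n_evals, (best - rm.f) < 1e-4))
    return rows
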