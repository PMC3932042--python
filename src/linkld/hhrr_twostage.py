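"""Two-stage marker screening: HHRR + cheap linkage scan, then full tests.

The haplotype-based haplotype relative risk (HHRR) statistic compares the
marker alleles that genotyped parents transmitted to affected offspring
with the alleles they did not transmit, as a Pearson chi-square on a
k x 2 (allele x transmitted/untransmitted) table.  Stage one flags a marker
when either the HHRR p-value or a 1-df two-point linkage LR test (no-LD
models only) falls under a loose threshold; stage two runs the full
likelihood-ratio test battery on the flagged markers only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .hypothesis_tests import TestResult, pseudomarker_tests
from .mads_optimizer import OptimizerOptions
from .pedigree_io import AFFECTED, PedigreeSet
from .trait_model import InheritanceModel

__all__ = [
    "HhrrTable",
    "build_hhrr_table",
    "hhrr_statistic",
    "stage_one_screen",
    "two_stage_analysis",
]


@dataclass
class HhrrTable:
    """k x 2 integer counts: column 0 transmitted, column 1 untransmitted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[1] != 2:
            raise ValueError("HHRR table must be k x 2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def _resolved_transmissions(
    parent: tuple[int, int],
    other: tuple[int, int] | None,
    child: tuple[int, int],
) -> tuple[int, int] | None:
    """(transmitted, untransmitted) allele of ``parent``, or None if the
    transmission cannot be resolved unambiguously."""
    outcomes = set()
    c1, c2 = child
    for t_par, u_par in ((parent[0], parent[1]), (parent[1], parent[0])):
        for t_child, rest in ((c1, c2), (c2, c1)):
            if t_par != t_child:
                continue
            if other is not None and rest not in other:
                continue
            outcomes.add((t_par, u_par))
    if len(outcomes) == 1:
        return outcomes.pop()
    return None


def build_hhrr_table(
    data: PedigreeSet, marker_index: int, k: int | None = None
) -> HhrrTable:
    """Count transmitted vs untransmitted parental alleles to affected children.

    Ambiguous transmissions (typically all members identically heterozygous)
    are skipped, keeping the counts integral.  When the data contain no
    resolvable parent-to-affected-child transmission at all (e.g. pure
    case-control data), the fallback is an allele-count table of affected
    singletons (column T) against unaffected singletons (column U).
    """
    if k is None:
        k = data.n_alleles(marker_index)
    counts = np.zeros((k, 2), dtype=int)
    found = False
    for ped in data:
        for m in ped.members:
            if m.is_founder or m.phenotype != AFFECTED:
                continue
            gc = m.genotype(marker_index)
            if gc is None:
                continue
            gf = ped[m.father_id].genotype(marker_index)
            gm = ped[m.mother_id].genotype(marker_index)
            for parent_geno, other_geno in ((gf, gm), (gm, gf)):
                if parent_geno is None:
                    continue
                res = _resolved_transmissions(parent_geno, other_geno, gc)
                if res is None:
                    continue
                t, u = res
                counts[t - 1, 0] += 1
                counts[u - 1, 1] += 1
                found = True
    if not found:
        for ped in data:
            if len(ped) != 1:
                continue
            (m,) = ped.members
            g = m.genotype(marker_index)
            if g is None or m.phenotype == 0:
                continue
            col = 0 if m.phenotype == AFFECTED else 1
            counts[g[0] - 1, col] += 1
            counts[g[1] - 1, col] += 1
    return HhrrTable(counts)


def hhrr_statistic(table: HhrrTable) -> tuple[float, int, float]:
    """Pearson chi-square on the transmitted/untransmitted table.

    Alleles with no observations are dropped; df = (observed alleles) - 1.
    Raises on a degenerate table (a zero column margin or a single allele).
    """
    counts = table.counts
    keep = counts.sum(axis=1) > 0
    counts = counts[keep]
    if counts.shape[0] < 2 or np.any(counts.sum(axis=0) == 0):
        raise ValueError("degenerate HHRR table (zero margin)")
    if np.array_equal(counts[:, 0], counts[:, 1]):
        # identical columns: chi2 exactly 0 (avoid roundoff in the library)
        return 0.0, counts.shape[0] - 1, 1.0
    stat, p, df, _ = chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def stage_one_screen(
    data: PedigreeSet,
    markers: list[int],
    model: InheritanceModel,
    thresholds: tuple[float, float] = (0.05, 0.05),
    options: OptimizerOptions | None = None,
) -> tuple[list[int], pd.DataFrame]:
    """Flag markers with HHRR p <= p_hhrr OR linkage-test p <= p_linkage.

    A permissive OR-combination: the screen should rarely discard a marker
    that full analysis would flag.  Markers whose HHRR table is degenerate
    are screened on the linkage test alone.
    """
    p_hhrr_thr, p_link_thr = thresholds
    if not (0.0 < p_hhrr_thr <= 1.0 and 0.0 < p_link_thr <= 1.0):
        raise ValueError("thresholds must be in (0, 1]")
    rows = []
    passed = []
    for mi in markers:
        try:
            _, _, p_hhrr = hhrr_statistic(build_hhrr_table(data, mi))
        except ValueError:
            p_hhrr = np.nan
        (link,) = pseudomarker_tests(
            data, mi, model, options=options, tests=("linkage",)
        )
        ok = (not np.isnan(p_hhrr) and p_hhrr <= p_hhrr_thr) or (
            link.p_value <= p_link_thr
        )
        rows.append(
            {
                "marker": mi,
                "p_hhrr": p_hhrr,
                "p_linkage": link.p_value,
                "passed": ok,
            }
        )
        if ok:
            passed.append(mi)
    return passed, pd.DataFrame(rows)


def two_stage_analysis(
    data: PedigreeSet,
    markers: list[int],
    model: InheritanceModel,
    thresholds: tuple[float, float] = (0.05, 0.05),
    options: OptimizerOptions | None = None,
    **test_kwargs,
) -> tuple[pd.DataFrame, dict[int, list[TestResult]]]:
    """Stage-one screen, then full LR tests on the surviving markers."""
    passed, report = stage_one_screen(data, markers, model, thresholds, options)
    full = {
        mi: pseudomarker_tests(data, mi, model, options=options, **test_kwargs)
        for mi in passed
    }
    return report, full
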