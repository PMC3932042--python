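"""Reading and writing LINKAGE-format pedigree files and marker maps.

The pedigree dialect is pre-makeped LINKAGE: six fixed columns (family,
individual, father, mother, sex, affection status) followed by one pair of
allele codes per marker.  Post-makeped files (with the three pointer columns
and a proband column inserted by ``makeped``) are recognised by column count
and read with those columns ignored, with a logged warning.

Codings follow the LINKAGE convention: sex 1=male / 2=female; affection
0=unknown, 1=unaffected, 2=affected; allele code 0 = missing.  A genotype
with one missing allele is treated as fully missing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

MALE = 1
FEMALE = 2

UNKNOWN = 0
UNAFFECTED = 1
AFFECTED = 2

#: Parent code meaning "not in the pedigree" (founder).
MISSING_PARENT = "0"


class PedigreeError(ValueError):
    """Structural problem in a pedigree file (dangling parent, bad sex, ...)."""


@dataclass
class Individual:
    """One row of a LINKAGE pedigree file."""

    family_id: str
    indiv_id: str
    father_id: str | None
    mother_id: str | None
    sex: int
    phenotype: int
    genotypes: list[tuple[int, int]] = field(default_factory=list)

    @property
    def is_founder(self) -> bool:
        return self.father_id is None

    def genotype(self, marker_index: int) -> tuple[int, int] | None:
        """Unordered allele pair at ``marker_index``, or None if missing."""
        a, b = self.genotypes[marker_index]
        if a == 0 or b == 0:
            return None
        return (a, b) if a <= b else (b, a)


@dataclass
class Pedigree:
    """One family: an ordered list of individuals with resolved parent links."""

    family_id: str
    members: list[Individual]

    def __post_init__(self) -> None:
        self._by_id = {m.indiv_id: m for m in self.members}
        self._validate()

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, indiv_id: str) -> Individual:
        return self._by_id[indiv_id]

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]

    def nuclear_families(self) -> list[tuple[str, str, list[str]]]:
        """(father_id, mother_id, children_ids) per mating, in file order."""
        fams: dict[tuple[str, str], list[str]] = {}
        for m in self.members:
            if not m.is_founder:
                fams.setdefault((m.father_id, m.mother_id), []).append(m.indiv_id)
        return [(fa, mo, kids) for (fa, mo), kids in fams.items()]

    @property
    def has_loops(self) -> bool:
        """True if the marriage-node graph contains a cycle.

        Nodes are individuals and matings; each spouse and each child is
        joined to the mating node.  A cycle indicates a pedigree loop
        (inbreeding or multiple inter-marriage), for which peeling is not
        implemented here.
        """
        g = nx.Graph()
        for fa, mo, kids in self.nuclear_families():
            mating = ("mating", fa, mo)
            g.add_edge(("i", fa), mating)
            g.add_edge(("i", mo), mating)
            for c in kids:
                g.add_edge(mating, ("i", c))
        return len(nx.cycle_basis(g)) > 0

    def _validate(self) -> None:
        if len(self._by_id) != len(self.members):
            seen: set[str] = set()
            for m in self.members:
                if m.indiv_id in seen:
                    raise PedigreeError(
                        f"family {self.family_id}: duplicate individual id "
                        f"{m.indiv_id!r}"
                    )
                seen.add(m.indiv_id)
        for m in self.members:
            if (m.father_id is None) != (m.mother_id is None):
                raise PedigreeError(
                    f"family {self.family_id}, individual {m.indiv_id}: "
                    "both parents must be present or both missing"
                )
            for pid, want_sex, role in (
                (m.father_id, MALE, "father"),
                (m.mother_id, FEMALE, "mother"),
            ):
                if pid is None:
                    continue
                parent = self._by_id.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"family {self.family_id}, individual {m.indiv_id}: "
                        f"{role} {pid!r} not in pedigree"
                    )
                if parent.sex != want_sex:
                    raise PedigreeError(
                        f"family {self.family_id}, individual {m.indiv_id}: "
                        f"{role} {pid!r} has sex {parent.sex}, expected {want_sex}"
                    )
        dg = nx.DiGraph()
        dg.add_nodes_from(m.indiv_id for m in self.members)
        for m in self.members:
            if not m.is_founder:
                dg.add_edge(m.father_id, m.indiv_id)
                dg.add_edge(m.mother_id, m.indiv_id)
        if not nx.is_directed_acyclic_graph(dg):
            raise PedigreeError(
                f"family {self.family_id}: parent-child graph contains a cycle"
            )


@dataclass
class PedigreeSet:
    """A collection of pedigrees; singletons are one-member pedigrees."""

    pedigrees: list[Pedigree]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for ped in self.pedigrees:
            for m in ped.members:
                key = (ped.family_id, m.indiv_id)
                if key in seen:
                    raise PedigreeError(f"duplicate (family, individual) pair {key}")
                seen.add(key)

    def __len__(self) -> int:
        return len(self.pedigrees)

    def __iter__(self):
        return iter(self.pedigrees)

    @property
    def n_markers(self) -> int:
        if not self.pedigrees:
            return 0
        return len(self.pedigrees[0].members[0].genotypes)

    def n_alleles(self, marker_index: int) -> int:
        """Highest observed allele code at a marker (alleles coded 1..k)."""
        best = 0
        for ped in self.pedigrees:
            for m in ped.members:
                a, b = m.genotypes[marker_index]
                best = max(best, a, b)
        return best

    def individuals(self) -> Iterable[tuple[Pedigree, Individual]]:
        for ped in self.pedigrees:
            for m in ped.members:
                yield ped, m


@dataclass
class MarkerMap:
    """Ordered marker names and genetic/physical positions."""

    markers: list[tuple[str, str, float]]  # (name, chromosome, position)
    dialect: str = "simple3col"

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.markers]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate marker name(s): {dup}")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.markers]


def read_pedfile(path: str | Path, n_markers: int) -> PedigreeSet:
    """Read a whitespace-delimited LINKAGE pedigree file.

    Parameters
    ----------
    path:
        Pedigree file with 6 + 2 * ``n_markers`` columns per row
        (pre-makeped) or 9 + 2 * ``n_markers`` (post-makeped; pointer and
        proband columns are ignored).
    n_markers:
        Number of markers (allele-pair columns) expected per row.
    """
    pre_cols = 6 + 2 * n_markers
    post_cols = 9 + 2 * n_markers
    rows: dict[str, list[Individual]] = {}
    warned_post = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) == pre_cols:
                fixed, alleles = tok[:6], tok[6:]
                fam, iid, fa, mo, sex, aff = fixed
            elif len(tok) == post_cols:
                if not warned_post:
                    logger.warning(
                        "%s: post-makeped column count detected; pointer and "
                        "proband columns ignored",
                        path,
                    )
                    warned_post = True
                fam, iid, fa, mo = tok[0], tok[1], tok[2], tok[3]
                sex, aff = tok[7], tok[8]
                alleles = tok[9:]
            else:
                raise PedigreeError(
                    f"{path}:{lineno}: expected {pre_cols} columns "
                    f"(or {post_cols} post-makeped), found {len(tok)}"
                )
            try:
                geno = [
                    (int(alleles[2 * i]), int(alleles[2 * i + 1]))
                    for i in range(n_markers)
                ]
            except ValueError as exc:
                raise PedigreeError(f"{path}:{lineno}: bad allele code: {exc}")
            if any(a < 0 or b < 0 for a, b in geno):
                raise PedigreeError(f"{path}:{lineno}: negative allele code")
            sex_i, aff_i = int(sex), int(aff)
            if sex_i not in (MALE, FEMALE):
                raise PedigreeError(f"{path}:{lineno}: sex must be 1 or 2, got {sex}")
            if aff_i not in (UNKNOWN, UNAFFECTED, AFFECTED):
                raise PedigreeError(
                    f"{path}:{lineno}: affection must be 0, 1 or 2, got {aff}"
                )
            rows.setdefault(fam, []).append(
                Individual(
                    family_id=fam,
                    indiv_id=iid,
                    father_id=None if fa == MISSING_PARENT else fa,
                    mother_id=None if mo == MISSING_PARENT else mo,
                    sex=sex_i,
                    phenotype=aff_i,
                    genotypes=geno,
                )
            )
    return PedigreeSet([Pedigree(fam, members) for fam, members in rows.items()])


def write_pedfile(data: PedigreeSet, path: str | Path) -> None:
    """Write ``data`` as a pre-makeped LINKAGE pedigree file."""
    with open(path, "w") as fh:
        for ped in data:
            for m in ped.members:
                fields = [
                    ped.family_id,
                    m.indiv_id,
                    m.father_id or MISSING_PARENT,
                    m.mother_id or MISSING_PARENT,
                    str(m.sex),
                    str(m.phenotype),
                ]
                for a, b in m.genotypes:
                    fields += [str(a), str(b)]
                fh.write(" ".join(fields) + "\n")


MAP_DIALECTS = ("plink4col", "simple3col")


def read_mapfile(path: str | Path, dialect: str) -> MarkerMap:
    """Read a marker map.

    ``plink4col`` rows are ``chrom name gdist pos`` (PLINK .map); the
    position stored is the fourth column.  ``simple3col`` rows are
    ``chrom name pos``.
    """
    if dialect not in MAP_DIALECTS:
        raise ValueError(f"unknown map dialect {dialect!r}; choose from {MAP_DIALECTS}")
    want = 4 if dialect == "plink4col" else 3
    markers: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != want:
                raise ValueError(
                    f"{path}:{lineno}: dialect {dialect!r} expects {want} "
                    f"columns, found {len(tok)}"
                )
            chrom, name = tok[0], tok[1]
            try:
                pos = float(tok[-1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric position {tok[-1]!r}")
            markers.append((name, chrom, pos))
    if not markers:
        logger.warning("%s: empty map file", path)
    return MarkerMap(markers, dialect=dialect)


def write_mapfile(mm: MarkerMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, chrom, pos in mm.markers:
            if mm.dialect == "plink4col":
                fh.write(f"{chrom} {name} 0 {pos:g}\n")
            else:
                fh.write(f"{chrom} {name} {pos:g}\n")


@dataclass(frozen=True)
class MendelViolation:
    """A nuclear family whose typed genotypes admit no consistent transmission."""

    family_id: str
    marker_index: int
    father_id: str
    mother_id: str
    children: tuple[str, ...]

    def __str__(self) -> str:
        return (
            f"family {self.family_id}, marker {self.marker_index}: mating "
            f"{self.father_id} x {self.mother_id} inconsistent with children "
            f"{', '.join(self.children)}"
        )


def _parent_genotype_choices(
    geno: tuple[int, int] | None, universe: Sequence[int]
) -> list[tuple[int, int]]:
    if geno is not None:
        return [geno]
    return list(itertools.combinations_with_replacement(universe, 2))


def check_mendelian(ped: Pedigree, marker_index: int) -> list[MendelViolation]:
    """Find nuclear families with impossible genotype transmissions.

    Each nuclear family is checked in isolation: the typed members must
    admit at least one assignment of genotypes consistent with Mendelian
    transmission.  Untyped parents range over pairs of alleles observed in
    the family; this loses no generality, since an allele absent from the
    family's typed members can never be required for a transmission to a
    typed child.  Cross-family inference is not attempted, so some
    multi-generation inconsistencies can go undetected.
    """
    violations = []
    for fa, mo, kids in ped.nuclear_families():
        typed_kids = [
            g for g in (ped[c].genotype(marker_index) for c in kids) if g is not None
        ]
        gf = ped[fa].genotype(marker_index)
        gm = ped[mo].genotype(marker_index)
        if not typed_kids:
            continue
        observed: set[int] = set()
        for g in typed_kids + [g for g in (gf, gm) if g is not None]:
            observed.update(g)
        universe = sorted(observed)
        ok = False
        for pf in _parent_genotype_choices(gf, universe):
            for pm in _parent_genotype_choices(gm, universe):
                if all(
                    (c1 in pf and c2 in pm) or (c2 in pf and c1 in pm)
                    for c1, c2 in typed_kids
                ):
                    ok = True
                    break
            if ok:
                break
        if not ok:
            violations.append(
                MendelViolation(ped.family_id, marker_index, fa, mo, tuple(kids))
            )
    return violations


def check_mendelian_all(data: PedigreeSet, marker_index: int) -> list[MendelViolation]:
    out: list[MendelViolation] = []
    for ped in data:
        out.extend(check_mendelian(ped, marker_index))
    return out
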