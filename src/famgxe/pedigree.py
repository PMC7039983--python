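"""Family structure: pseudo-sibling genotypes, Mendelian checks, designs.

When parents but not the unaffected sister are genotyped, the matched
control genotype is the "pseudo-sister": the hypothetical, equally likely
sibling carrying the parental alleles that were *not* transmitted to the
case.  For an additive dosage g this complement is a linear function,

    g_pseudo = g_father + g_mother - g_case,

per SNP, so no phasing is needed and the pseudo-sibling's PRS equals
PRS_father + PRS_mother - PRS_case exactly.

Families are classified into four disjoint designs by data availability
(case genotype and case exposure are always required):

    case_parents_plus  -- both parents genotyped, sister's exposures known
    case_parents       -- both parents genotyped, no sister exposures
    case_sibling_plus  -- sister genotyped, sister's exposures known
    case_plus          -- only the case genotyped, sister's exposures known
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

import numpy as np

__all__ = [
    "Role",
    "Design",
    "SubjectRecord",
    "FamilyRecord",
    "PseudoSibGenotype",
    "MendelianError",
    "FamilyStructureError",
    "pseudo_sib_genotype",
    "pseudo_sib_dosages",
    "mendelian_check",
    "classify_family",
]


class Role(str, Enum):
    CASE = "case"
    CONTROL_SISTER = "control_sister"
    FATHER = "father"
    MOTHER = "mother"


class Design(str, Enum):
    CASE_PARENTS_PLUS = "case_parents_plus"
    CASE_PARENTS = "case_parents"
    CASE_SIBLING_PLUS = "case_sibling_plus"
    CASE_PLUS = "case_plus"

    @property
    def matching_ratio(self) -> int:
        """Number of non-case members matched to the case (3 or 1)."""
        return 3 if self in (Design.CASE_PARENTS_PLUS, Design.CASE_SIBLING_PLUS) else 1


class MendelianError(ValueError):
    """A hard-call trio genotype is impossible under Mendelian transmission."""


class FamilyStructureError(ValueError):
    """Family does not fit any of the four analyzable designs."""


@dataclass
class SubjectRecord:
    subject_id: str
    family_id: str
    role: Role
    birth_order_rank: int = 1       # 1 = elder sister; parents carry 0
    genotyped: bool = False
    has_exposure: bool = False


@dataclass
class FamilyRecord:
    family_id: str
    members: list[SubjectRecord]
    index_age: Optional[float] = None
    design: Optional[Design] = None
    invasive: Optional[bool] = None
    er_positive: Optional[bool] = None
    ethnicity: Optional[str] = None

    def member(self, role: Role) -> Optional[SubjectRecord]:
        found = [m for m in self.members if m.role == role]
        if len(found) > 1:
            raise FamilyStructureError(
                f"family {self.family_id}: more than one {role.value}"
            )
        return found[0] if found else None

    def validate(self) -> None:
        if self.member(Role.CASE) is None:
            raise FamilyStructureError(f"family {self.family_id}: no case")
        for role in (Role.CONTROL_SISTER, Role.FATHER, Role.MOTHER):
            self.member(role)  # raises on duplicates


@dataclass
class PseudoSibGenotype:
    family_id: str
    dosages: dict[str, float]
    out_of_range_snps: tuple[str, ...] = ()


def _transmissible(g_parent: int) -> set[int]:
    """Risk-allele counts a hard-call parent can transmit (one allele)."""
    return {0: {0}, 1: {0, 1}, 2: {1}}[g_parent]


def _trio_consistent(g_case: int, g_father: int, g_mother: int) -> bool:
    return any(
        tf + tm == g_case
        for tf in _transmissible(g_father)
        for tm in _transmissible(g_mother)
    )


def pseudo_sib_genotype(
    g_case: float, g_father: float, g_mother: float, snp_id: str = "?"
) -> float:
    """Complement-of-transmitted dosage: g_father + g_mother - g_case.

    For hard calls the trio is first checked for Mendelian consistency and a
    MendelianError is raised on impossible configurations.  Fractional
    (imputed) dosages are passed through arithmetically; a result outside
    [0, 2] is possible then and is left to the caller to flag.
    """
    for name, g in (("case", g_case), ("father", g_father), ("mother", g_mother)):
        if not (0.0 <= g <= 2.0):
            raise ValueError(f"{snp_id}: {name} dosage {g} outside [0, 2]")
    if all(float(g).is_integer() for g in (g_case, g_father, g_mother)):
        if not _trio_consistent(int(g_case), int(g_father), int(g_mother)):
            raise MendelianError(
                f"{snp_id}: trio (case={g_case:g}, father={g_father:g}, "
                f"mother={g_mother:g}) is Mendelian-impossible"
            )
    return g_father + g_mother - g_case


def pseudo_sib_dosages(
    family_id: str,
    case: Mapping[str, float],
    father: Mapping[str, float],
    mother: Mapping[str, float],
) -> PseudoSibGenotype:
    """Per-SNP pseudo-sibling dosages for a trio over shared SNPs.

    Hard-call Mendelian violations raise; fractional results that fall
    outside [0, 2] (possible for imputed dosages) are kept as-is but their
    SNP ids are flagged in ``out_of_range_snps``.
    """
    shared = [s for s in case if s in father and s in mother]
    out: dict[str, float] = {}
    flagged: list[str] = []
    for s in shared:
        g = pseudo_sib_genotype(case[s], father[s], mother[s], snp_id=s)
        if not (0.0 <= g <= 2.0):
            flagged.append(s)
        out[s] = g
    return PseudoSibGenotype(family_id, out, tuple(flagged))


@dataclass
class MendelianReport:
    family_id: str
    inconsistent_snps: tuple[str, ...]
    unchecked_snps: tuple[str, ...]

    @property
    def consistent(self) -> bool:
        return not self.inconsistent_snps


def mendelian_check(
    family_id: str,
    case: Mapping[str, float],
    father: Mapping[str, float],
    mother: Mapping[str, float],
    hard_call_threshold: float = 0.1,
) -> MendelianReport:
    """Report every SNP whose trio hard calls are Mendelian-impossible.

    Dosages within ``hard_call_threshold`` of an integer are rounded to that
    integer for checking; SNPs where any member's dosage is not that close
    to an integer are skipped and listed as unchecked.
    """
    inconsistent: list[str] = []
    unchecked: list[str] = []
    for s in case:
        if s not in father or s not in mother:
            continue
        calls = []
        skip = False
        for g in (case[s], father[s], mother[s]):
            r = round(g)
            if abs(g - r) <= hard_call_threshold and 0 <= r <= 2:
                calls.append(int(r))
            else:
                skip = True
                break
        if skip:
            unchecked.append(s)
        elif not _trio_consistent(*calls):
            inconsistent.append(s)
    return MendelianReport(family_id, tuple(inconsistent), tuple(unchecked))


def classify_family(
    case_genotyped: bool,
    sibling_genotyped: bool,
    parents_genotyped: bool,
    sibling_exposure: bool,
    case_exposure: bool = True,
) -> Design:
    """Assign a family to one of the four matched designs.

    ``parents_genotyped`` means *both* parents; single-parent families do
    not fit any design.  When both parents and the sibling are genotyped the
    sibling genotype takes precedence (case_sibling_plus) so the groups stay
    disjoint.  Raises FamilyStructureError with a reason when no design
    matches.
    """
    if not case_genotyped or not case_exposure:
        raise FamilyStructureError("case genotype and exposures are required")
    if sibling_genotyped and sibling_exposure:
        return Design.CASE_SIBLING_PLUS
    if parents_genotyped:
        return Design.CASE_PARENTS_PLUS if sibling_exposure else Design.CASE_PARENTS
    if sibling_exposure:
        return Design.CASE_PLUS
    raise FamilyStructureError(
        "no matched comparison possible: needs both parents genotyped, a "
        "genotyped sister, or sister exposure data"
    )
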