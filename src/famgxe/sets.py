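"""Matched-set (CLR stratum) assembly.

Each family contributes one conditional-logistic stratum built by crossing
genotype sources with exposure sources.  With G = PRS source and E = risk
factor source, c = case, s = (real or pseudo) sister:

    case_parents_plus / case_sibling_plus (1:3):
        (Gc,Ec), (Gs,Es), (Gc,Es), (Gs,Ec)
    case_parents (1:1):  (Gc,Ec), (Gs,Ec)
    case_plus   (1:1):   (Gc,Ec), (Gc,Es)

The (Gc,Ec) member is the case; all others are matched pseudo-observations.
Member order is fixed (case first, then the order above) so serialized sets
are reproducible; the conditional likelihood itself is order-invariant.
The birth-order covariate travels with the *exposure* source: a
pseudo-sibling member inherits the elder/younger rank of whichever sister
supplied its risk factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .exposures import ExposureProfile
from .pedigree import Design, FamilyRecord

__all__ = ["GenotypeSource", "SetMember", "MatchedSet", "build_matched_set",
           "DesignMismatchError"]


class DesignMismatchError(ValueError):
    """Inputs inconsistent with the family's design."""


@dataclass(frozen=True)
class SetMember:
    genotype_source: str        # "case" | "sibling" | "pseudo_sibling"
    exposure_source: str        # "case" | "sibling"
    prs: float                  # centered PRS of the genotype source
    exposure: ExposureProfile   # aligned profile of the exposure source
    is_case_member: bool


@dataclass
class MatchedSet:
    family_id: str
    design: Design
    members: list[SetMember]

    @property
    def size(self) -> int:
        return len(self.members)

    def case_member(self) -> SetMember:
        return next(m for m in self.members if m.is_case_member)


def build_matched_set(
    family: FamilyRecord,
    case_prs: float,
    counterpart_prs: Optional[float],
    case_exposure: ExposureProfile,
    sibling_exposure: Optional[ExposureProfile],
) -> MatchedSet:
    """Assemble the family's CLR stratum for its design.

    ``counterpart_prs`` is the centered PRS of the genotyped sister
    (case_sibling_plus) or of the pseudo-sister derived from the parents
    (case_parents_plus, case_parents); it must be None only for case_plus.
    ``sibling_exposure`` is required for the three designs whose matching
    sets use Es.  Extra inputs not used by the design are ignored.
    """
    design = family.design
    if design is None:
        raise DesignMismatchError(f"family {family.family_id}: no design assigned")

    counterpart_label = (
        "sibling" if design == Design.CASE_SIBLING_PLUS else "pseudo_sibling"
    )
    needs_counterpart = design != Design.CASE_PLUS
    needs_sib_exposure = design != Design.CASE_PARENTS

    if needs_counterpart and counterpart_prs is None:
        raise DesignMismatchError(
            f"family {family.family_id} ({design.value}): "
            f"missing {counterpart_label} PRS"
        )
    if needs_sib_exposure and sibling_exposure is None:
        raise DesignMismatchError(
            f"family {family.family_id} ({design.value}): missing sister exposures"
        )

    def member(gsrc: str, esrc: str) -> SetMember:
        prs = case_prs if gsrc == "case" else counterpart_prs
        exp = case_exposure if esrc == "case" else sibling_exposure
        assert prs is not None and exp is not None
        return SetMember(
            genotype_source=gsrc,
            exposure_source=esrc,
            prs=prs,
            exposure=exp,
            is_case_member=(gsrc == "case" and esrc == "case"),
        )

    g = counterpart_label
    if design in (Design.CASE_PARENTS_PLUS, Design.CASE_SIBLING_PLUS):
        members = [member("case", "case"), member(g, "sibling"),
                   member("case", "sibling"), member(g, "case")]
    elif design == Design.CASE_PARENTS:
        members = [member("case", "case"), member(g, "case")]
    else:  # CASE_PLUS
        members = [member("case", "case"), member("case", "sibling")]

    return MatchedSet(family_id=family.family_id, design=design, members=members)
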