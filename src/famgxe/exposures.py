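"""Risk-factor exposure profiles and index-age alignment.

The matched sibling design evaluates every time-dependent risk factor for
*both* sisters as of the case's age at diagnosis (the "index age"), so that
the two sisters have comparable opportunity for exposure.  This module holds
the per-subject event history, the alignment logic that truncates histories
at the index age, and the registry describing how each of the 14 risk
factors is typed and coded in regression models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

__all__ = [
    "EventHistory",
    "ExposureProfile",
    "Factor",
    "FACTORS",
    "align_exposure",
    "HistoryError",
]

SMOKING_LEVELS = ("never", "former", "current")
ALCOHOL_LEVELS = ("never", "lt1_per_day", "ge1_per_day")
YEARS_HBC_LEVELS = ("lt2", "2to10", "ge10")
PARITY_LEVELS = ("1", "2", "ge3")  # parity models are restricted to parous women
AFB_LEVELS = ("nulliparous", "le20", "20to25", "25to30", "gt30")


class HistoryError(ValueError):
    """Raised when a subject's event history is internally inconsistent."""


@dataclass
class EventHistory:
    """Raw, un-aligned exposure data for one sister.

    Time-fixed attributes are stored as plain values; time-dependent ones as
    event ages so that they can be truncated at any index age.  HBC =
    hormonal birth control.
    """

    subject_id: str
    height: Optional[float] = None          # inches
    bmi_at_30: Optional[float] = None       # kg/m^2, reported for age ~30
    age_menarche: Optional[float] = None    # years
    smoking: Optional[str] = None           # never/former/current
    alcohol: Optional[str] = None           # never/lt1_per_day/ge1_per_day
    birth_ages: tuple[float, ...] = ()      # ages at each live birth, ascending
    hbc_intervals: tuple[tuple[float, float], ...] = ()  # (start_age, stop_age)
    menopause_age: Optional[float] = None   # None = not yet menopausal
    breastfed_any: Optional[bool] = None    # ever breastfed (among parous)
    birth_order_rank: int = 1               # 1 = elder of the two sisters

    def validate(self) -> None:
        if self.smoking is not None and self.smoking not in SMOKING_LEVELS:
            raise HistoryError(f"{self.subject_id}: unknown smoking level {self.smoking!r}")
        if self.alcohol is not None and self.alcohol not in ALCOHOL_LEVELS:
            raise HistoryError(f"{self.subject_id}: unknown alcohol level {self.alcohol!r}")
        ages = list(self.birth_ages)
        if any(a < 0 for a in ages):
            raise HistoryError(f"{self.subject_id}: negative birth age")
        if ages != sorted(ages):
            raise HistoryError(f"{self.subject_id}: birth ages not ascending")
        for start, stop in self.hbc_intervals:
            if start < 0 or stop < start:
                raise HistoryError(
                    f"{self.subject_id}: invalid HBC interval ({start}, {stop})"
                )
        if self.menopause_age is not None and self.menopause_age < 0:
            raise HistoryError(f"{self.subject_id}: negative menopause age")


@dataclass
class ExposureProfile:
    """The 14 risk factors for one sister, evaluated as of an index age."""

    subject_id: str
    index_age: float
    height: Optional[float] = None
    bmi_at_30: Optional[float] = None       # only defined when premenopausal at index
    smoking: Optional[str] = None
    alcohol: Optional[str] = None
    premenopausal: Optional[bool] = None
    age_menarche: Optional[float] = None
    ever_hbc: Optional[bool] = None
    years_hbc: Optional[float] = None       # cumulative years of use before index
    hbc_within_5y: Optional[bool] = None
    parity: Optional[int] = None
    age_first_birth: Optional[float] = None  # None when nulliparous
    last_birth_within_5y: Optional[bool] = None  # among parous
    breastfeeding: Optional[bool] = None     # among parous
    birth_order_rank: int = 1

    @property
    def years_hbc_cat(self) -> Optional[str]:
        if self.years_hbc is None:
            return None
        if self.years_hbc < 2:
            return "lt2"
        if self.years_hbc < 10:
            return "2to10"
        return "ge10"

    @property
    def afb_cat(self) -> Optional[str]:
        if self.parity is None:
            return None
        if self.parity == 0:
            return "nulliparous"
        a = self.age_first_birth
        if a is None:
            return None
        if a <= 20:
            return "le20"
        if a <= 25:
            return "20to25"
        if a <= 30:
            return "25to30"
        return "gt30"

    @property
    def is_elder(self) -> bool:
        return self.birth_order_rank == 1


def align_exposure(history: EventHistory, index_age: float) -> ExposureProfile:
    """Evaluate a sister's risk factors as of ``index_age``.

    All time-dependent quantities reflect status strictly up to the index
    age: births after it do not count toward parity, menopause after it
    leaves the woman premenopausal at index, and the "within 5 years"
    recency windows are evaluated against the index age.  Time-fixed
    factors (height, age at menarche, smoking, alcohol, BMI at 30) pass
    through, except that BMI at 30 is only defined for women premenopausal
    at the index age.
    """
    if index_age <= 0:
        raise ValueError(f"index_age must be positive, got {index_age}")
    history.validate()

    births = [a for a in history.birth_ages if a <= index_age]
    parity = len(births)
    age_first_birth = births[0] if births else None
    last_birth_within_5y: Optional[bool]
    if parity > 0:
        last_birth_within_5y = (index_age - births[-1]) < 5
    else:
        last_birth_within_5y = None

    years_hbc = 0.0
    ever_hbc = False
    hbc_within_5y = False
    for start, stop in history.hbc_intervals:
        overlap = min(stop, index_age) - start
        if overlap > 0:
            ever_hbc = True
            years_hbc += overlap
            if min(stop, index_age) > index_age - 5:
                hbc_within_5y = True

    premenopausal = history.menopause_age is None or history.menopause_age > index_age

    return ExposureProfile(
        subject_id=history.subject_id,
        index_age=index_age,
        height=history.height,
        bmi_at_30=history.bmi_at_30 if premenopausal else None,
        smoking=history.smoking,
        alcohol=history.alcohol,
        premenopausal=premenopausal,
        age_menarche=history.age_menarche,
        ever_hbc=ever_hbc,
        years_hbc=years_hbc,
        hbc_within_5y=hbc_within_5y,
        parity=parity,
        age_first_birth=age_first_birth,
        last_birth_within_5y=last_birth_within_5y,
        breastfeeding=history.breastfed_any if parity > 0 else None,
        birth_order_rank=history.birth_order_rank,
    )


# ---------------------------------------------------------------------------
# Factor registry: how each risk factor is typed and coded in CLR models.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Factor:
    """Typing and coding metadata for one risk factor.

    ``accessor`` returns the model value for a profile: a float for
    continuous factors, a bool for binary ones, a level string for
    categorical ones, or ``None`` when the factor is undefined/ineligible
    for that subject (complete-case handling drops the matched set).
    ``kind`` is one of continuous / binary / ordered / nominal.  Ordered
    factors get integer trend scores 0,1,2,... over ``levels`` in
    interaction terms; nominal factors (smoking only) get one product
    column per non-reference level.
    """

    name: str
    kind: str
    accessor: Callable[[ExposureProfile], object]
    levels: tuple[str, ...] = ()
    confounders: tuple[str, ...] = ()
    center_by_controls: bool = False
    label: str = ""

    def level_score(self, value: str) -> int:
        return self.levels.index(value)


def _parous_guard(fn):
    def accessor(p: ExposureProfile):
        if p.parity is None or p.parity == 0:
            return None
        return fn(p)
    return accessor


def _parity_cat(p: ExposureProfile):
    if p.parity is None or p.parity == 0:
        return None
    return "ge3" if p.parity >= 3 else str(p.parity)


def _afb_cat_all(p: ExposureProfile):
    return p.afb_cat


FACTORS: dict[str, Factor] = {
    f.name: f
    for f in [
        Factor("ever_hbc", "binary", lambda p: p.ever_hbc,
               label="Ever use hormonal birth control"),
        Factor("hbc_within_5y", "binary", lambda p: p.hbc_within_5y,
               label="Hormonal birth control use within 5 years"),
        Factor("last_birth_within_5y", "binary",
               _parous_guard(lambda p: p.last_birth_within_5y),
               label="Last birth within 5 years"),
        Factor("breastfeeding", "binary",
               _parous_guard(lambda p: p.breastfeeding),
               confounders=("parity", "age_first_birth_cont"),
               label="Breastfeeding among parous"),
        Factor("premenopausal", "binary", lambda p: p.premenopausal,
               label="Pre-menopause"),
        Factor("height", "continuous", lambda p: p.height,
               center_by_controls=True, label="Height (inches)"),
        Factor("bmi_at_30", "continuous", lambda p: p.bmi_at_30,
               center_by_controls=True,
               label="BMI at 30s among pre-menopausal"),
        Factor("age_menarche", "continuous", lambda p: p.age_menarche,
               center_by_controls=True, label="Age at menarche"),
        Factor("age_first_birth_cont", "continuous",
               _parous_guard(lambda p: p.age_first_birth),
               center_by_controls=True,
               label="Age at first birth among parous"),
        Factor("smoking", "nominal", lambda p: p.smoking,
               levels=SMOKING_LEVELS, confounders=("alcohol",),
               label="Smoking"),
        Factor("alcohol", "ordered", lambda p: p.alcohol,
               levels=ALCOHOL_LEVELS, confounders=("smoking",),
               label="Alcohol"),
        Factor("years_hbc", "ordered", lambda p: p.years_hbc_cat,
               levels=YEARS_HBC_LEVELS, confounders=("age_menarche",),
               label="Years using hormonal birth control"),
        Factor("parity", "ordered", _parity_cat, levels=PARITY_LEVELS,
               confounders=("age_first_birth_cont",),
               label="Parity among parous"),
        Factor("age_first_birth_cat", "ordered", _afb_cat_all,
               levels=AFB_LEVELS, label="Age at first birth (categorical)"),
    ]
}
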