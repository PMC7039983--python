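"""Synthetic ascertained sister families for end-to-end verification.

No real genotype or interview data is distributable, so every pipeline stage
is exercised against families generated here.  The generator emulates a
family-based study of young-onset breast cancer:

* parents drawn under Hardy-Weinberg equilibrium per panel SNP, two
  daughters by independent Mendelian transmission;
* 14 risk factors per daughter with moderate sister-sister correlation
  (shared-family Gaussian latent, rho = 0.3 by default), with marginal
  distributions matching the case/control characteristics table of the
  study population (control PRS ~ N(5.0, 0.45), ~89% premenopausal at
  index, etc.);
* disease risk from a logistic model
      logit P = alpha + b_prs*(PRS - 5) + sum b_e*E + sum b_ge*(PRS - 5)*E
  evaluated for both sisters at a single family index age T (the eventual
  case's diagnosis age, truncated below 50);
* ascertainment by rejection: keep a family when exactly one daughter is
  affected and the unaffected sister has already aged past T (which makes
  control sisters more often the elder one, the birth-order artifact the
  analysis adjusts for);
* accepted families are assigned to the four designs and the unavailable
  data are masked accordingly.

Defaults follow the study conditions: alpha = logit(0.02) (cumulative
young-onset risk to age 50 of about 2%, which also keeps the rare-disease
approximation behind the pseudo-sibling likelihood accurate), PRS log-OR
ln 2.33 per unit, and an ever-use-of-hormonal-birth-control effect ln 1.31
with interaction log-ROR ln 0.56.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .exposures import (ALCOHOL_LEVELS, SMOKING_LEVELS, EventHistory,
                        ExposureProfile)
from .pedigree import Design, FamilyRecord, Role, SubjectRecord
from .prs import SnpWeight, SnpWeightPanel
from .sets import MatchedSet, build_matched_set

__all__ = [
    "SimConfig",
    "SimFamily",
    "SimulatedDataset",
    "default_panel",
    "simulate_families",
    "calibration_summary",
    "AscertainmentError",
]

PRS_MEAN = 5.0   # population PRS location matched to the control mean
PRS_SD = 0.45    # population PRS scale matched to the control SD

# population exposure parameters (control-sister marginals of the study)
HEIGHT_MEAN, HEIGHT_SD = 65.0, 2.6          # inches
BMI30_MEAN, BMI30_SD = 23.8, 4.4
MENARCHE_MEAN, MENARCHE_SD = 12.8, 1.5
MENOPAUSE_MEAN, MENOPAUSE_SD = 51.8, 4.3    # calibrated: ~89% premenopausal at index
SMOKING_P = (0.65, 0.26, 0.09)
ALCOHOL_P = (0.08, 0.81, 0.11)
EVER_HBC_P = 0.89
YEARS_HBC_P = (0.22, 0.41, 0.37)            # <2 / 2-<10 / >=10 among users
HBC_RECENT_P = 0.30                          # stopped within 5y of index, among users
PARITY_P = (0.25, 0.17, 0.35, 0.23)          # 0 / 1 / 2 / >=3
AFB_MEAN, AFB_SD = 26.7, 5.2                 # age at first birth
BREASTFED_P = 0.83                           # among parous
# diagnosis-age distribution: normal truncated to (28, 50); gives a case
# mean near 44.9 with SD near 3.9
DXAGE_MU, DXAGE_SIGMA, DXAGE_LO, DXAGE_HI = 48.0, 5.5, 28.0, 50.0

DEFAULT_DESIGN_PROPS = {
    Design.CASE_PARENTS_PLUS: 384 / 1152,
    Design.CASE_PARENTS: 32 / 1152,
    Design.CASE_SIBLING_PLUS: 432 / 1152,
    Design.CASE_PLUS: 304 / 1152,
}


class AscertainmentError(RuntimeError):
    """Family acceptance probability fell below the configured floor."""


def default_panel(n_snps: int = 10) -> tuple[SnpWeightPanel, np.ndarray]:
    """A synthetic SNP weight panel calibrated to the target PRS distribution.

    Risk-allele frequencies are spread around a common value and per-allele
    log odds ratios are solved so the population PRS (parents under HWE) has
    mean PRS_MEAN and standard deviation PRS_SD exactly:

        mean = sum_i 2 f_i w_i,   var = sum_i 2 f_i (1 - f_i) w_i^2.

    ``default_panel(77)`` gives the realistic-scale configuration (many
    small weights); the 10-SNP default keeps tests fast.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    spread = np.linspace(-0.06, 0.06, n_snps) if n_snps > 1 else np.zeros(1)
    c = PRS_MEAN / (2 * n_snps)  # f_i * w_i, fixed so the mean is exact

    def var_gap(f0: float) -> float:
        f = np.clip(f0 + spread, 0.01, 0.999)
        return float(2 * np.sum((1 - f) / f) * c**2 - PRS_SD**2)

    f0 = brentq(var_gap, 0.02 - spread.min(), 0.998 - spread.max(), xtol=1e-14)
    freqs = np.clip(f0 + spread, 0.01, 0.999)
    weights = tuple(
        SnpWeight(
            snp_id=f"rs{900000 + i}",
            risk_allele="A",
            per_allele_or=float(np.exp(c / freqs[i])),
        )
        for i in range(n_snps)
    )
    return SnpWeightPanel(weights), freqs


@dataclass
class SimConfig:
    """Generating parameters for one synthetic study.

    ``design_counts`` fixes the exact number of families per design (in the
    order case_parents_plus, case_parents, case_sibling_plus, case_plus) and
    overrides ``n_families``/``design_props`` when given.  Effects in
    ``beta_exposure``/``beta_interaction`` are on the analysis coding scale
    (binary 0/1, ordered factors integer trend scores, continuous factors
    centered at their population means).
    """

    n_families: int = 1000
    panel: Optional[SnpWeightPanel] = None
    allele_freqs: Optional[Sequence[float]] = None
    baseline_logit: float = float(logit(0.02))
    beta_prs: float = math.log(2.33)
    beta_exposure: dict[str, float] = field(
        default_factory=lambda: {"ever_hbc": math.log(1.31)}
    )
    beta_interaction: dict[str, float] = field(
        default_factory=lambda: {"ever_hbc": math.log(0.56)}
    )
    sister_rho: float = 0.3
    # per-factor distribution overrides; recognized keys: ever_hbc_p,
    # hbc_recent_p, breastfed_p, smoking_p, alcohol_p, years_hbc_p, parity_p,
    # menopause_mean, menopause_sd, height_mean, height_sd
    exposure_params: dict = field(default_factory=dict)
    design_props: Optional[dict[Design, float]] = None
    design_counts: Optional[tuple[int, int, int, int]] = None
    p_invasive: float = 0.85
    p_er_positive: float = 0.81
    ethnicity: str = "non_hispanic_white"
    acceptance_floor: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.panel is None:
            self.panel, self.allele_freqs = default_panel()
        if self.allele_freqs is None:
            raise ValueError("allele_freqs must accompany a custom panel")
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        if len(self.allele_freqs) != len(self.panel):
            raise ValueError("allele_freqs length must match panel size")
        if np.any((self.allele_freqs <= 0) | (self.allele_freqs >= 1)):
            raise ValueError("allele frequencies must lie in (0, 1)")
        if not (0 <= self.sister_rho < 1):
            raise ValueError("sister_rho must be in [0, 1)")
        if self.design_counts is not None:
            if any(c < 0 for c in self.design_counts):
                raise ValueError("design_counts must be non-negative")
            self.n_families = int(sum(self.design_counts))
        props = self.design_props or DEFAULT_DESIGN_PROPS
        total = sum(props.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"design proportions sum to {total}, expected 1")
        self.design_props = props

    def truth(self) -> dict:
        return {
            "baseline_logit": self.baseline_logit,
            "beta_prs": self.beta_prs,
            "beta_exposure": dict(self.beta_exposure),
            "beta_interaction": dict(self.beta_interaction),
            "sister_rho": self.sister_rho,
            "prs_mean": PRS_MEAN,
            "prs_sd": PRS_SD,
            "n_families": self.n_families,
            "seed": self.seed,
            "panel_size": len(self.panel),
        }


@dataclass
class SimFamily:
    family_id: str
    design: Design
    index_age: float
    case_profile: ExposureProfile
    sister_profile: ExposureProfile
    case_history: EventHistory
    sister_history: EventHistory
    case_dosages: np.ndarray
    sister_dosages: np.ndarray
    father_dosages: np.ndarray
    mother_dosages: np.ndarray
    case_prs: float
    sister_prs: float
    father_prs: float
    mother_prs: float
    invasive: bool
    er_positive: bool
    ethnicity: str

    @property
    def pseudo_prs(self) -> float:
        return self.father_prs + self.mother_prs - self.case_prs

    def family_record(self) -> FamilyRecord:
        fid = self.family_id
        sib_g = self.design == Design.CASE_SIBLING_PLUS
        par_g = self.design in (Design.CASE_PARENTS_PLUS, Design.CASE_PARENTS)
        sib_e = self.design != Design.CASE_PARENTS
        members = [
            SubjectRecord(f"{fid}_case", fid, Role.CASE,
                          birth_order_rank=self.case_profile.birth_order_rank,
                          genotyped=True, has_exposure=True),
            SubjectRecord(f"{fid}_sis", fid, Role.CONTROL_SISTER,
                          birth_order_rank=self.sister_profile.birth_order_rank,
                          genotyped=sib_g, has_exposure=sib_e),
        ]
        if par_g:
            members += [
                SubjectRecord(f"{fid}_fa", fid, Role.FATHER, 0, True, False),
                SubjectRecord(f"{fid}_mo", fid, Role.MOTHER, 0, True, False),
            ]
        return FamilyRecord(
            family_id=fid, members=members, index_age=self.index_age,
            design=self.design, invasive=self.invasive,
            er_positive=self.er_positive, ethnicity=self.ethnicity,
        )


# ---------------------------------------------------------------------------
# Vectorised draws
# ---------------------------------------------------------------------------

def _corr_normal(rng, n: int, rho: float) -> np.ndarray:
    """(n, 2) standard normals with sister-sister correlation rho."""
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, 2))
    return math.sqrt(rho) * shared + math.sqrt(1 - rho) * own


def _categorical_from_latent(z: np.ndarray, probs: Sequence[float]) -> np.ndarray:
    """Map correlated normals to category indices via cumulative thresholds."""
    from scipy.stats import norm
    cuts = norm.ppf(np.cumsum(probs)[:-1])
    return np.searchsorted(cuts, z).astype(np.int64)


def _disease_value(key: str, aligned: dict[str, np.ndarray]) -> np.ndarray:
    """Analysis-scale coding of one factor for the disease model."""
    coders = {
        "ever_hbc": lambda a: a["ever_hbc"].astype(float),
        "premenopausal": lambda a: a["premenopausal"].astype(float),
        "hbc_within_5y": lambda a: a["hbc_within_5y"].astype(float),
        "last_birth_within_5y": lambda a: a["last_birth_within_5y"].astype(float),
        "breastfeeding": lambda a: a["breastfed"].astype(float),
        "height": lambda a: a["height"] - HEIGHT_MEAN,
        "bmi_at_30": lambda a: a["bmi_at_30"] - BMI30_MEAN,
        "age_menarche": lambda a: a["age_menarche"] - MENARCHE_MEAN,
        "alcohol": lambda a: a["alcohol_idx"].astype(float),
        "smoking": lambda a: a["smoking_idx"].astype(float),
        "years_hbc": lambda a: a["years_hbc_score"].astype(float),
        "parity": lambda a: np.minimum(a["parity"], 3).astype(float),
        "age_first_birth_cont": lambda a: np.where(
            a["parity"] > 0, np.nan_to_num(a["afb"] - AFB_MEAN), 0.0
        ),
    }
    if key not in coders:
        raise KeyError(f"no disease-model coding for factor {key!r}")
    return coders[key](aligned)


def _draw_batch(cfg: SimConfig, rng: np.random.Generator, n: int) -> dict:
    """Draw n candidate families (all arrays; second axis = the two sisters)."""
    m = len(cfg.panel)
    freqs = cfg.allele_freqs
    log_ors = cfg.panel.log_ors
    rho = cfg.sister_rho

    father = (rng.random((n, m)) < freqs).astype(np.int8) + (
        rng.random((n, m)) < freqs
    ).astype(np.int8)
    mother = (rng.random((n, m)) < freqs).astype(np.int8) + (
        rng.random((n, m)) < freqs
    ).astype(np.int8)

    def transmit(parent):
        # one allele per parent: P(risk allele) = dosage / 2
        return (rng.random((n, m, 2)) < (parent / 2.0)[:, :, None]).astype(np.int8)

    daughters = transmit(father) + transmit(mother)   # (n, m, 2)
    prs = np.einsum("nmk,m->nk", daughters.astype(float), log_ors)
    parent_prs = np.stack(
        [father.astype(float) @ log_ors, mother.astype(float) @ log_ors], axis=1
    )

    # family index age (the eventual case's diagnosis age)
    T = np.empty(0)
    while T.size < n:
        draw = rng.normal(DXAGE_MU, DXAGE_SIGMA, size=2 * n)
        draw = draw[(draw > DXAGE_LO) & (draw < DXAGE_HI)]
        T = np.concatenate([T, draw])
    T = T[:n]
    Tcol = T[:, None]

    xp = cfg.exposure_params
    height = (xp.get("height_mean", HEIGHT_MEAN)
              + xp.get("height_sd", HEIGHT_SD) * _corr_normal(rng, n, rho))
    bmi30 = BMI30_MEAN + BMI30_SD * _corr_normal(rng, n, rho)
    menarche = np.clip(MENARCHE_MEAN + MENARCHE_SD * _corr_normal(rng, n, rho), 8, 18)
    menopause = (xp.get("menopause_mean", MENOPAUSE_MEAN)
                 + xp.get("menopause_sd", MENOPAUSE_SD) * _corr_normal(rng, n, rho))
    smoking_idx = _categorical_from_latent(
        _corr_normal(rng, n, rho), xp.get("smoking_p", SMOKING_P))
    alcohol_idx = _categorical_from_latent(
        _corr_normal(rng, n, rho), xp.get("alcohol_p", ALCOHOL_P))

    hbc_user = _corr_normal(rng, n, rho) < _norm_ppf(xp.get("ever_hbc_p", EVER_HBC_P))
    dur_cat = _categorical_from_latent(
        _corr_normal(rng, n, rho), xp.get("years_hbc_p", YEARS_HBC_P))
    u = rng.random((n, 2))
    duration = np.where(
        dur_cat == 0, 0.25 + 1.7 * u,
        np.where(dur_cat == 1, 2.0 + 8.0 * u, 10.0 + 15.0 * u),
    )
    recent = _corr_normal(rng, n, rho) < _norm_ppf(xp.get("hbc_recent_p", HBC_RECENT_P))
    stop = np.where(recent, Tcol - 5.0 * rng.random((n, 2)),
                    Tcol - (5.0 + 15.0 * rng.random((n, 2))))
    start = stop - duration
    shift = np.maximum(14.0 - start, 0.0)   # nobody starts before 14
    start, stop = start + shift, stop + shift

    parity = _categorical_from_latent(
        _corr_normal(rng, n, rho), xp.get("parity_p", PARITY_P))
    afb = np.clip(AFB_MEAN + AFB_SD * _corr_normal(rng, n, rho), 16.0, 42.0)
    gap1 = 2.0 + 1.5 * rng.random((n, 2))
    gap2 = 2.0 + 1.5 * rng.random((n, 2))
    birth2 = afb + gap1
    birth3 = birth2 + gap2
    breastfed = _corr_normal(rng, n, rho) < _norm_ppf(xp.get("breastfed_p", BREASTFED_P))

    # aligned-at-T quantities (the disease model and profiles both use these)
    births = np.stack([afb, birth2, birth3], axis=2)          # (n, 2, 3)
    have = births <= Tcol[:, :, None]
    have &= np.arange(3) < parity[:, :, None]
    parity_T = have.sum(axis=2)
    last_birth = np.where(parity_T > 0,
                          np.max(np.where(have, births, -np.inf), axis=2), np.nan)
    afb_T = np.where(parity_T > 0, afb, np.nan)

    years_hbc = np.where(hbc_user, np.maximum(np.minimum(stop, Tcol) - start, 0.0), 0.0)
    ever_T = years_hbc > 0
    hbc_recent_T = ever_T & (np.minimum(stop, Tcol) > Tcol - 5.0)
    years_score = np.where(years_hbc < 2, 0, np.where(years_hbc < 10, 1, 2))

    aligned = {
        "height": height,
        "bmi_at_30": bmi30,
        "age_menarche": menarche,
        "premenopausal": menopause > Tcol,
        "smoking_idx": smoking_idx,
        "alcohol_idx": alcohol_idx,
        "ever_hbc": ever_T,
        "years_hbc": years_hbc,
        "years_hbc_score": years_score,
        "hbc_within_5y": hbc_recent_T,
        "parity": parity_T,
        "afb": afb_T,
        "last_birth_age": last_birth,
        "last_birth_within_5y": (Tcol - last_birth < 5.0) & (parity_T > 0),
        "breastfed": breastfed & (parity_T > 0),
    }

    eta = cfg.baseline_logit + cfg.beta_prs * (prs - PRS_MEAN)
    for k, b in cfg.beta_exposure.items():
        eta = eta + b * _disease_value(k, aligned)
    for k, b in cfg.beta_interaction.items():
        eta = eta + b * (prs - PRS_MEAN) * _disease_value(k, aligned)
    affected = rng.random((n, 2)) < expit(eta)

    # birth order and the aged-past-index requirement for the control
    elder_slot = rng.integers(0, 2, size=n)          # which sister is elder
    age_gap = 2.0 + rng.exponential(2.0, size=n)
    recruit_lag = 4.0 * rng.random(n)

    return {
        "father": father, "mother": mother, "daughters": daughters,
        "prs": prs, "parent_prs": parent_prs, "T": T,
        "menopause": menopause, "start": start, "stop": stop,
        "births": births, "parity_full": parity, "breastfed_raw": breastfed,
        "aligned": aligned, "affected": affected, "hbc_user": hbc_user,
        "elder_slot": elder_slot, "age_gap": age_gap, "recruit_lag": recruit_lag,
    }


def _norm_ppf(p: float) -> float:
    from scipy.stats import norm
    return float(norm.ppf(p))


def _accept(batch: dict) -> np.ndarray:
    """Ascertainment: exactly one affected sister, control aged past index."""
    affected = batch["affected"]
    one_case = affected.sum(axis=1) == 1
    case_slot = affected.argmax(axis=1)
    control_is_elder = batch["elder_slot"] != case_slot
    control_old_enough = control_is_elder | (batch["age_gap"] <= batch["recruit_lag"])
    return one_case & control_old_enough


def _build_family(cfg: SimConfig, batch: dict, i: int, fid: str,
                  design: Design, rng: np.random.Generator) -> SimFamily:
    affected = batch["affected"][i]
    cs = int(affected.argmax())   # case slot
    ss = 1 - cs
    T = float(batch["T"][i])
    a = batch["aligned"]

    def profile(slot: int, sid: str) -> ExposureProfile:
        parity = int(a["parity"][i, slot])
        pre = bool(a["premenopausal"][i, slot])
        return ExposureProfile(
            subject_id=sid, index_age=T,
            height=round(float(a["height"][i, slot]), 4),
            bmi_at_30=round(float(a["bmi_at_30"][i, slot]), 4) if pre else None,
            smoking=SMOKING_LEVELS[a["smoking_idx"][i, slot]],
            alcohol=ALCOHOL_LEVELS[a["alcohol_idx"][i, slot]],
            premenopausal=pre,
            age_menarche=round(float(a["age_menarche"][i, slot]), 4),
            ever_hbc=bool(a["ever_hbc"][i, slot]),
            years_hbc=float(a["years_hbc"][i, slot]),
            hbc_within_5y=bool(a["hbc_within_5y"][i, slot]),
            parity=parity,
            age_first_birth=(round(float(a["afb"][i, slot]), 4)
                             if parity > 0 else None),
            last_birth_within_5y=(bool(a["last_birth_within_5y"][i, slot])
                                  if parity > 0 else None),
            breastfeeding=(bool(a["breastfed"][i, slot]) if parity > 0 else None),
            birth_order_rank=1 if batch["elder_slot"][i] == slot else 2,
        )

    def history(slot: int, sid: str) -> EventHistory:
        n_births = int(batch["parity_full"][i, slot])
        births = tuple(
            round(float(b), 4) for b in batch["births"][i, slot, :n_births]
        )
        intervals = ()
        if bool(batch["hbc_user"][i, slot]):
            intervals = ((round(float(batch["start"][i, slot]), 4),
                          round(float(batch["stop"][i, slot]), 4)),)
        meno = float(batch["menopause"][i, slot])
        return EventHistory(
            subject_id=sid,
            height=round(float(a["height"][i, slot]), 4),
            bmi_at_30=round(float(a["bmi_at_30"][i, slot]), 4),
            age_menarche=round(float(a["age_menarche"][i, slot]), 4),
            smoking=SMOKING_LEVELS[a["smoking_idx"][i, slot]],
            alcohol=ALCOHOL_LEVELS[a["alcohol_idx"][i, slot]],
            birth_ages=births,
            hbc_intervals=intervals,
            menopause_age=round(meno, 4),
            breastfed_any=bool(batch["breastfed_raw"][i, slot]),
            birth_order_rank=1 if batch["elder_slot"][i] == slot else 2,
        )

    log_ors = cfg.panel.log_ors
    case_d = batch["daughters"][i, :, cs].astype(float)
    sis_d = batch["daughters"][i, :, ss].astype(float)
    fa_d = batch["father"][i].astype(float)
    mo_d = batch["mother"][i].astype(float)

    return SimFamily(
        family_id=fid, design=design, index_age=round(T, 4),
        case_profile=profile(cs, f"{fid}_case"),
        sister_profile=profile(ss, f"{fid}_sis"),
        case_history=history(cs, f"{fid}_case"),
        sister_history=history(ss, f"{fid}_sis"),
        case_dosages=case_d, sister_dosages=sis_d,
        father_dosages=fa_d, mother_dosages=mo_d,
        case_prs=float(case_d @ log_ors),
        sister_prs=float(sis_d @ log_ors),
        father_prs=float(fa_d @ log_ors),
        mother_prs=float(mo_d @ log_ors),
        invasive=bool(rng.random() < cfg.p_invasive),
        er_positive=bool(rng.random() < cfg.p_er_positive),
        ethnicity=cfg.ethnicity,
    )


@dataclass
class SimulatedDataset:
    config: SimConfig
    families: list[SimFamily]

    @property
    def n_families(self) -> int:
        return len(self.families)

    def design_counts(self) -> dict[Design, int]:
        out = {d: 0 for d in Design}
        for f in self.families:
            out[f.design] += 1
        return out

    # -- in-memory analysis path -------------------------------------------
    def matched_sets(self, centered: bool = True) -> list[MatchedSet]:
        """Matched CLR strata straight from the simulated families.

        PRS centering uses the genotyped control sisters (case_sibling_plus
        families); if there are none the raw scores are used unshifted.
        """
        const = self.control_prs_mean() if centered else 0.0
        sets = []
        for fam in self.families:
            rec = fam.family_record()
            if fam.design == Design.CASE_SIBLING_PLUS:
                counterpart = fam.sister_prs - const
            elif fam.design == Design.CASE_PLUS:
                counterpart = None
            else:
                counterpart = fam.pseudo_prs - const
            sib_exp = None if fam.design == Design.CASE_PARENTS else fam.sister_profile
            sets.append(build_matched_set(
                rec, fam.case_prs - const, counterpart,
                fam.case_profile, sib_exp,
            ))
        return sets

    def control_prs_mean(self) -> float:
        vals = [f.sister_prs for f in self.families
                if f.design == Design.CASE_SIBLING_PLUS]
        return float(np.mean(vals)) if vals else 0.0

    # -- file emission ------------------------------------------------------
    def pedigree_frame(self) -> pd.DataFrame:
        rows = []
        for fam in self.families:
            rec = fam.family_record()
            for m in rec.members:
                rows.append({
                    "family_id": m.family_id,
                    "subject_id": m.subject_id,
                    "role": m.role.value,
                    "birth_order_rank": m.birth_order_rank,
                    "genotyped": int(m.genotyped),
                    "exposure": int(m.has_exposure),
                    "index_age": fam.index_age if m.role == Role.CASE else "",
                    "invasive": int(fam.invasive) if m.role == Role.CASE else "",
                    "er_positive": int(fam.er_positive) if m.role == Role.CASE else "",
                    "ethnicity": fam.ethnicity if m.role == Role.CASE else "",
                })
        return pd.DataFrame(rows)

    def dosage_frame(self) -> pd.DataFrame:
        """Wide dosage matrix for genotyped subjects only (masking applied)."""
        snps = list(self.config.panel.snp_ids)
        rows, index = [], []
        for fam in self.families:
            rec = fam.family_record()
            by_role = {
                Role.CASE: fam.case_dosages,
                Role.CONTROL_SISTER: fam.sister_dosages,
                Role.FATHER: fam.father_dosages,
                Role.MOTHER: fam.mother_dosages,
            }
            for m in rec.members:
                if m.genotyped:
                    index.append(m.subject_id)
                    rows.append(by_role[m.role])
        df = pd.DataFrame(np.asarray(rows, dtype=float), columns=snps, index=index)
        df.index.name = "subject_id"
        return df

    def weights_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.config.panel.snp_ids,
            "risk_allele": [w.risk_allele for w in self.config.panel],
            "odds_ratio": [w.per_allele_or for w in self.config.panel],
        })

    def exposure_frame(self) -> pd.DataFrame:
        """Long-format event history CSV for subjects with exposure data."""
        rows = []
        for fam in self.families:
            rec = fam.family_record()
            hists = {f"{fam.family_id}_case": fam.case_history,
                     f"{fam.family_id}_sis": fam.sister_history}
            for m in rec.members:
                if not m.has_exposure:
                    continue
                h = hists[m.subject_id]
                sid = m.subject_id

                def add(factor, value="", age=""):
                    rows.append({"subject_id": sid, "factor": factor,
                                 "value": value, "age_at_event": age})

                add("height", h.height)
                add("bmi_at_30", h.bmi_at_30)
                add("age_menarche", h.age_menarche)
                add("smoking", h.smoking)
                add("alcohol", h.alcohol)
                add("breastfed_any", int(bool(h.breastfed_any)))
                if h.menopause_age is not None:
                    add("menopause", "", h.menopause_age)
                for b in h.birth_ages:
                    add("birth", "", b)
                for start, stop in h.hbc_intervals:
                    add("hbc_use", stop, start)
        return pd.DataFrame(rows,
                            columns=["subject_id", "factor", "value", "age_at_event"])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "weights": outdir / "weights.tsv",
            "dosages": outdir / "dosages.tsv",
            "pedigree": outdir / "pedigree.tsv",
            "exposures": outdir / "exposures.csv",
            "truth": outdir / "truth.json",
        }
        self.weights_frame().to_csv(paths["weights"], sep="\t", index=False)
        self.dosage_frame().to_csv(paths["dosages"], sep="\t",
                                   float_format="%.10g")
        self.pedigree_frame().to_csv(paths["pedigree"], sep="\t", index=False)
        self.exposure_frame().to_csv(paths["exposures"], index=False)
        with open(paths["truth"], "w") as fh:
            json.dump(self.config.truth(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def simulate_families(config: SimConfig) -> SimulatedDataset:
    """Generate an ascertained study of ``config.n_families`` families.

    Rejection-samples candidate families until enough are accepted (exactly
    one affected daughter, control aged past the index age), then assigns
    designs by exact multinomial counts when ``design_counts`` is given and
    by rounded proportions otherwise.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    target = config.n_families
    accepted_idx: list[tuple[dict, int]] = []
    tried = 0
    batch_size = max(2048, int(target / 0.02))
    while len(accepted_idx) < target:
        batch = _draw_batch(config, rng, batch_size)
        keep = np.flatnonzero(_accept(batch))
        tried += batch_size
        for i in keep:
            accepted_idx.append((batch, int(i)))
            if len(accepted_idx) == target:
                break
        if tried >= batch_size and len(accepted_idx) / tried < config.acceptance_floor:
            raise AscertainmentError(
                f"acceptance rate {len(accepted_idx) / tried:.2e} below floor "
                f"{config.acceptance_floor:.0e}; raise baseline_logit or relax "
                "the design"
            )

    if config.design_counts is not None:
        labels = np.repeat(
            np.arange(4), np.asarray(config.design_counts, dtype=int)
        )
        rng.shuffle(labels)
    else:
        props = [config.design_props[d] for d in _DESIGN_ORDER]
        labels = rng.choice(4, size=target, p=np.asarray(props) / np.sum(props))

    families = [
        _build_family(config, batch, i, f"F{k:05d}", _DESIGN_ORDER[labels[k]], rng)
        for k, (batch, i) in enumerate(accepted_idx)
    ]
    return SimulatedDataset(config=config, families=families)


_DESIGN_ORDER = (
    Design.CASE_PARENTS_PLUS,
    Design.CASE_PARENTS,
    Design.CASE_SIBLING_PLUS,
    Design.CASE_PLUS,
)


def calibration_summary(dataset: SimulatedDataset) -> pd.DataFrame:
    """Case/control marginals in the layout of the study's Table of
    participant characteristics (mean (SD) for continuous variables,
    count (proportion) for categorical ones).

    "Controls" are the real unaffected sisters with exposure data; the PRS
    row uses genotyped sisters only, mirroring the study's restriction.
    """
    from .pipeline import summarize_profiles

    cases = [f.case_profile for f in dataset.families]
    controls = [f.sister_profile for f in dataset.families
                if f.design != Design.CASE_PARENTS]
    case_prs = [f.case_prs for f in dataset.families]
    ctrl_prs = [f.sister_prs for f in dataset.families
                if f.design == Design.CASE_SIBLING_PLUS]
    return summarize_profiles(cases, controls, case_prs, ctrl_prs)
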