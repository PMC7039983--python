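"""End-to-end orchestration: inputs -> PRS -> pseudo-sibs -> sets -> models.

``run_analysis`` executes the whole analysis for a configuration: it reads
the weight panel, genotypes, pedigree and exposure histories; computes and
centers the PRS; validates trios and derives pseudo-sibling genotypes;
aligns exposures to each case's diagnosis age; assembles the matched sets;
and fits the requested conditional-logistic models, producing a report with
one row per model (risk-factor OR, PRS OR, interaction ROR, Wald p), a
case/control characteristics summary, and a per-family exclusion log so
that every input family is accounted for exactly once.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as fio
from .clr import (EstimationError, FitResult, ModelSpec, build_design_matrix,
                  default_model_specs, fit_clr, fit_design)
from .exposures import (FACTORS, AFB_LEVELS, EventHistory, ExposureProfile,
                        align_exposure)
from .pedigree import (Design, FamilyRecord, FamilyStructureError,
                       MendelianError, Role, classify_family, mendelian_check,
                       pseudo_sib_dosages)
from .prs import DosageVector, PrsScore, SnpWeightPanel, compute_prs
from .sets import DesignMismatchError, MatchedSet, build_matched_set

logger = logging.getLogger("famgxe")

__all__ = [
    "RunConfig",
    "AnalysisReport",
    "ConfigError",
    "run_analysis",
    "prepare_families",
    "summarize_profiles",
    "export_matched_sets",
    "read_matched_set_tsv",
]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    weights: str
    dosages: str            # .vcf -> VCF reader, otherwise wide dosage TSV
    pedigree: str
    exposures: str
    output_dir: Optional[str] = None
    missing_policy: str = "error"
    centering_scope: str = "actual_controls"   # or "controls_and_pseudo"
    subset: str = "all"                        # all | invasive_only | er_positive_only
    ethnicity: Optional[str] = None            # None = every ethnic group
    models: Optional[list[ModelSpec]] = None
    strict: bool = False
    hard_call_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.models is None:
            self.models = default_model_specs()
        if not self.models:
            raise ConfigError("model list is empty")
        if self.subset not in ("all", "invasive_only", "er_positive_only"):
            raise ConfigError(f"unknown subset filter {self.subset!r}")
        if self.centering_scope not in ("actual_controls", "controls_and_pseudo"):
            raise ConfigError(f"unknown centering scope {self.centering_scope!r}")

    def content_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        models = data.pop("models", None)
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if models:
            cfg.models = [ModelSpec(**m) for m in models]
        return cfg


@dataclass
class PreparedFamily:
    record: FamilyRecord
    case_prs: float                 # centered
    counterpart_prs: Optional[float]
    case_profile: ExposureProfile
    sister_profile: Optional[ExposureProfile]

    def matched_set(self) -> MatchedSet:
        return build_matched_set(self.record, self.case_prs, self.counterpart_prs,
                                 self.case_profile, self.sister_profile)


@dataclass
class AnalysisReport:
    model_rows: pd.DataFrame
    summary: pd.DataFrame
    exclusions: pd.DataFrame
    fits: dict[str, FitResult]
    provenance: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "models": outdir / "models.tsv",
            "summary": outdir / "summary.tsv",
            "exclusions": outdir / "exclusions.tsv",
            "provenance": outdir / "provenance.json",
            "fits": outdir / "fits.json",
        }
        self.model_rows.to_csv(paths["models"], sep="\t", index=False,
                               float_format="%.6g")
        self.summary.to_csv(paths["summary"], sep="\t", index=False)
        self.exclusions.to_csv(paths["exclusions"], sep="\t", index=False)
        with open(paths["provenance"], "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")
        sidecar = {
            name: {
                "params": fit.params,
                "se": fit.se,
                "cov": np.asarray(fit.cov).tolist(),
                "names": fit.names,
                "loglik": fit.loglik,
                "converged": fit.converged,
                "iterations": fit.iterations,
                "separation_flag": fit.separation_flag,
                "unidentifiable": list(fit.unidentifiable),
                "n_sets": fit.n_sets,
                "n_dropped_sets": len(fit.dropped_sets),
            }
            for name, fit in self.fits.items()
        }
        with open(paths["fits"], "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _subject_dosages(dosages: dict[str, DosageVector], subject_id: str,
                     family_id: str) -> DosageVector:
    try:
        return dosages[subject_id]
    except KeyError:
        raise KeyError(
            f"family {family_id}: subject {subject_id} flagged genotyped "
            "but absent from the genotype file"
        ) from None


def prepare_families(
    panel: SnpWeightPanel,
    dosages: dict[str, DosageVector],
    families: list[FamilyRecord],
    histories: dict[str, EventHistory],
    missing_policy: str = "error",
    centering_scope: str = "actual_controls",
    hard_call_threshold: float = 0.1,
    subset: str = "all",
    ethnicity: Optional[str] = None,
    strict: bool = False,
) -> tuple[list[PreparedFamily], list[tuple[str, str]], dict[str, float]]:
    """Classify, score and align every family; returns (prepared, exclusions,
    control_means).

    Exclusion reasons are structured strings ("no_design: ...",
    "mendelian: ...", "filtered: ...", "missing_data: ...").  In strict mode
    data errors raise instead of excluding.
    """
    exclusions: list[tuple[str, str]] = []
    staged = []

    for fam in families:
        try:
            fam.validate()
            case = fam.member(Role.CASE)
            sib = fam.member(Role.CONTROL_SISTER)
            father = fam.member(Role.FATHER)
            mother = fam.member(Role.MOTHER)
            if fam.index_age is None:
                raise FamilyStructureError("case has no index age")
            if subset == "invasive_only" and not fam.invasive:
                exclusions.append((fam.family_id, "filtered: not invasive"))
                continue
            if subset == "er_positive_only" and not fam.er_positive:
                exclusions.append((fam.family_id, "filtered: not ER+"))
                continue
            if ethnicity is not None and fam.ethnicity != ethnicity:
                exclusions.append((fam.family_id, "filtered: ethnicity"))
                continue
            design = classify_family(
                case_genotyped=case.genotyped,
                sibling_genotyped=sib.genotyped if sib else False,
                parents_genotyped=bool(father and mother and father.genotyped
                                       and mother.genotyped),
                sibling_exposure=sib.has_exposure if sib else False,
                case_exposure=case.has_exposure,
            )
            fam.design = design
            case_d = _subject_dosages(dosages, case.subject_id, fam.family_id)
            sib_d = fa_d = mo_d = None
            if design == Design.CASE_SIBLING_PLUS:
                sib_d = _subject_dosages(dosages, sib.subject_id, fam.family_id)
            elif design in (Design.CASE_PARENTS_PLUS, Design.CASE_PARENTS):
                fa_d = _subject_dosages(dosages, father.subject_id, fam.family_id)
                mo_d = _subject_dosages(dosages, mother.subject_id, fam.family_id)
                report = mendelian_check(fam.family_id, case_d.dosages,
                                         fa_d.dosages, mo_d.dosages,
                                         hard_call_threshold)
                if not report.consistent:
                    raise MendelianError(
                        f"inconsistent SNPs: {list(report.inconsistent_snps)}"
                    )
            if case.subject_id not in histories:
                raise FamilyStructureError("case exposure history missing")
            if design != Design.CASE_PARENTS and (
                    sib is None or sib.subject_id not in histories):
                raise FamilyStructureError("sister exposure history missing")
            staged.append((fam, case, sib, case_d, sib_d, fa_d, mo_d))
        except MendelianError as exc:
            if strict:
                raise
            exclusions.append((fam.family_id, f"mendelian: {exc}"))
        except (FamilyStructureError, KeyError) as exc:
            if strict:
                raise
            exclusions.append((fam.family_id, f"no_design: {exc}"))

    # PRS for every scored genotype source
    raw: dict[str, float] = {}
    control_ids: list[str] = []
    pseudo_ids: list[str] = []
    scored = []
    for fam, case, sib, case_d, sib_d, fa_d, mo_d in staged:
        try:
            case_prs = compute_prs(case_d, panel, missing_policy).raw
            counterpart = None
            counterpart_id = None
            if sib_d is not None:
                counterpart = compute_prs(sib_d, panel, missing_policy).raw
                counterpart_id = sib.subject_id
                control_ids.append(sib.subject_id)
            elif fa_d is not None:
                pseudo = pseudo_sib_dosages(
                    fam.family_id, case_d.dosages, fa_d.dosages, mo_d.dosages
                )
                pd_vec = DosageVector.__new__(DosageVector)
                pd_vec.subject_id = f"{fam.family_id}_pseudo"
                pd_vec.dosages = pseudo.dosages   # may hold flagged fractional values
                counterpart = compute_prs(pd_vec, panel, missing_policy).raw
                counterpart_id = pd_vec.subject_id
                pseudo_ids.append(pd_vec.subject_id)
            raw[case.subject_id] = case_prs
            if counterpart_id is not None:
                raw[counterpart_id] = counterpart
            scored.append((fam, case, sib, case_prs, counterpart, counterpart_id))
        except (KeyError, ValueError) as exc:
            if strict:
                raise
            exclusions.append((fam.family_id, f"missing_data: {exc}"))

    centering_ids = list(control_ids)
    if centering_scope == "controls_and_pseudo":
        centering_ids += pseudo_ids
    if centering_ids:
        constant = float(np.mean([raw[i] for i in centering_ids]))
    else:
        constant = 0.0
        logger.warning("no control sisters available for PRS centering; "
                       "scores left uncentered")

    prepared: list[PreparedFamily] = []
    control_profiles: list[ExposureProfile] = []
    for fam, case, sib, case_prs, counterpart, _ in scored:
        try:
            case_hist = histories[case.subject_id]
            case_hist.birth_order_rank = case.birth_order_rank
            case_profile = align_exposure(case_hist, fam.index_age)
            sister_profile = None
            if fam.design != Design.CASE_PARENTS:
                sib_hist = histories[sib.subject_id]
                sib_hist.birth_order_rank = sib.birth_order_rank
                sister_profile = align_exposure(sib_hist, fam.index_age)
                control_profiles.append(sister_profile)
            prepared.append(PreparedFamily(
                record=fam,
                case_prs=case_prs - constant,
                counterpart_prs=(counterpart - constant
                                 if counterpart is not None else None),
                case_profile=case_profile,
                sister_profile=sister_profile,
            ))
        except (ValueError, KeyError) as exc:
            if strict:
                raise
            exclusions.append((fam.family_id, f"missing_data: {exc}"))

    control_means: dict[str, float] = {}
    for name in ("height", "bmi_at_30", "age_menarche", "age_first_birth_cont"):
        factor = FACTORS[name]
        vals = [factor.accessor(p) for p in control_profiles]
        vals = [float(v) for v in vals if v is not None]
        if vals:
            control_means[name] = float(np.mean(vals))
    return prepared, exclusions, control_means


def _or_cells(fit: FitResult, term: str, prefix: str) -> dict:
    try:
        o, lo, hi = fit.odds_ratio(term)
        return {f"{prefix}_or": round(o, 2), f"{prefix}_lo": round(lo, 2),
                f"{prefix}_hi": round(hi, 2), f"{prefix}_p": round(fit.p_value(term), 4)}
    except KeyError:
        return {f"{prefix}_or": None, f"{prefix}_lo": None, f"{prefix}_hi": None,
                f"{prefix}_p": None}


def _model_rows(name: str, factor, rf_fit, present_fit, int_fit) -> list[dict]:
    rows = []
    if factor.kind == "nominal":
        pairs = [(f"{factor.name}[{lv}]", f"prs_x_{factor.name}[{lv}]", lv)
                 for lv in factor.levels[1:]]
    else:
        rf_term = (factor.name if factor.kind in ("continuous", "binary")
                   else f"{factor.name}_trend")
        pairs = [(rf_term, f"prs_x_{factor.name}", "")]
    for rf_term, int_term, level in pairs:
        row = {"model": name, "variable": factor.label or factor.name,
               "level": level, "variable_type": factor.kind,
               "n_sets": int_fit.n_sets if int_fit else None}
        row.update(_or_cells(rf_fit, rf_term, "rf") if rf_fit else {})
        if present_fit is not None:
            row.update(_or_cells(present_fit, rf_term, "int_rf"))
        if int_fit is not None:
            row.update(_or_cells(int_fit, "prs", "prs"))
            row.update(_or_cells(int_fit, int_term, "ror"))
        rows.append(row)
    return rows


def run_analysis(config: RunConfig) -> AnalysisReport:
    """Execute the full pipeline for one configuration (see module docstring).

    Deterministic given the inputs; data problems exclude the affected
    family (strict mode raises instead), configuration problems raise
    ConfigError before any computation.
    """
    panel = fio.read_weights_tsv(config.weights)
    if str(config.dosages).endswith(".vcf") or str(config.dosages).endswith(".vcf.gz"):
        dosages, _ = fio.read_vcf_dosages(config.dosages, panel)
    else:
        dosages = fio.read_dosage_tsv(config.dosages)
    families = fio.read_pedigree_tsv(config.pedigree)
    histories = fio.read_exposure_csv(config.exposures)

    prepared, exclusions, control_means = prepare_families(
        panel, dosages, families, histories,
        missing_policy=config.missing_policy,
        centering_scope=config.centering_scope,
        hard_call_threshold=config.hard_call_threshold,
        subset=config.subset,
        ethnicity=config.ethnicity,
        strict=config.strict,
    )
    sets = [p.matched_set() for p in prepared]

    rows: list[dict] = []
    fits: dict[str, FitResult] = {}
    for spec in config.models:
        factor = spec.factor()
        name = spec.target_factor
        try:
            rf_fit = fit_clr(sets, ModelSpec(
                target_factor=name, interaction=False,
                confounders=spec.resolved_confounders()), control_means=control_means)
            int_fit = fit_clr(sets, spec, control_means=control_means)
            if factor.kind in ("ordered",):
                present_fit = fit_clr(sets, ModelSpec(
                    target_factor=name, interaction=True,
                    confounders=spec.resolved_confounders(),
                    main_effect_coding="trend"), control_means=control_means)
            else:
                present_fit = int_fit
            fits[name] = int_fit
            fits[f"{name}__risk_factor_only"] = rf_fit
            rows.extend(_model_rows(name, factor, rf_fit, present_fit, int_fit))
        except EstimationError as exc:
            logger.warning("model %s failed: %s", name, exc)
            rows.append({"model": name, "variable": factor.label or name,
                         "level": "", "variable_type": factor.kind,
                         "n_sets": 0, "error": str(exc)})

    case_profiles = [p.case_profile for p in prepared]
    ctrl_profiles = [p.sister_profile for p in prepared
                     if p.sister_profile is not None]
    case_prs = [p.case_prs for p in prepared]
    ctrl_prs = [p.counterpart_prs for p in prepared
                if p.record.design == Design.CASE_SIBLING_PLUS
                and p.counterpart_prs is not None]
    summary = summarize_profiles(case_profiles, ctrl_profiles, case_prs, ctrl_prs)

    n_input = len(families)
    n_analyzed = len(prepared)
    provenance = {
        "config_hash": config.content_hash(),
        "n_input_families": n_input,
        "n_analyzed_families": n_analyzed,
        "n_excluded_families": len(exclusions),
        "design_counts": {d.value: sum(1 for p in prepared
                                       if p.record.design == d) for d in Design},
        "prs_centering_scope": config.centering_scope,
        "subset": config.subset,
        "package": "famgxe",
    }
    assert n_analyzed + len(exclusions) == n_input, "family accounting violated"

    report = AnalysisReport(
        model_rows=pd.DataFrame(rows),
        summary=summary,
        exclusions=pd.DataFrame(exclusions, columns=["family_id", "reason"]),
        fits=fits,
        provenance=provenance,
    )
    if config.output_dir:
        report.write(config.output_dir)
    return report


# ---------------------------------------------------------------------------
# Table-2-style summary
# ---------------------------------------------------------------------------

def _cont_row(label, acc, cases, controls):
    def stat(group):
        vals = [acc(p) for p in group]
        vals = [float(v) for v in vals if v is not None]
        if not vals:
            return ""
        return f"{np.mean(vals):.2f} ({np.std(vals, ddof=1):.2f})" if len(vals) > 1 \
            else f"{vals[0]:.2f}"
    return [{"variable": label, "level": "mean (SD)",
             "case": stat(cases), "control": stat(controls)}]


def _cat_row(label, acc, levels, cases, controls):
    rows = []
    case_vals = [acc(p) for p in cases]
    ctrl_vals = [acc(p) for p in controls]
    case_n = sum(v is not None for v in case_vals)
    ctrl_n = sum(v is not None for v in ctrl_vals)
    for lv in levels:
        def cell(vals, n):
            if n == 0:
                return ""
            c = sum(v == lv for v in vals)
            return f"{c} ({c / n:.2f})"
        rows.append({"variable": label, "level": str(lv),
                     "case": cell(case_vals, case_n),
                     "control": cell(ctrl_vals, ctrl_n)})
    return rows


def summarize_profiles(
    cases: Sequence[ExposureProfile],
    controls: Sequence[ExposureProfile],
    case_prs: Sequence[float] = (),
    control_prs: Sequence[float] = (),
) -> pd.DataFrame:
    """Characteristics table: mean (SD) for continuous variables and
    count (proportion) for categorical ones, cases versus control sisters,
    with per-variable denominators reflecting missingness."""
    rows: list[dict] = []

    def prs_stat(vals):
        vals = list(vals)
        if not vals:
            return ""
        sd = np.std(vals, ddof=1) if len(vals) > 1 else 0.0
        return f"{np.mean(vals):.2f} ({sd:.2f})"

    rows.append({"variable": "PRS", "level": "mean (SD)",
                 "case": prs_stat(case_prs), "control": prs_stat(control_prs)})
    rows += _cont_row("Age at diagnosis", lambda p: p.index_age, cases, [])
    rows += _cont_row("Height", lambda p: p.height, cases, controls)
    rows += _cont_row("BMI at 30 among premenopausal", lambda p: p.bmi_at_30,
                      cases, controls)
    rows += _cont_row("Age at menarche", lambda p: p.age_menarche, cases, controls)
    rows += _cont_row("Age at first birth (continuous)",
                      lambda p: p.age_first_birth, cases, controls)
    rows += _cat_row("Smoking", lambda p: p.smoking,
                     ("never", "former", "current"), cases, controls)
    rows += _cat_row("Alcohol", lambda p: p.alcohol,
                     ("never", "lt1_per_day", "ge1_per_day"), cases, controls)
    rows += _cat_row("Premenopausal at index age", lambda p: p.premenopausal,
                     (True, False), cases, controls)
    rows += _cat_row("Ever hormonal birth control", lambda p: p.ever_hbc,
                     (True, False), cases, controls)
    rows += _cat_row("Years using hormonal birth control",
                     lambda p: p.years_hbc_cat, ("lt2", "2to10", "ge10"),
                     cases, controls)
    rows += _cat_row("Hormonal birth control within 5 years",
                     lambda p: p.hbc_within_5y, (True, False), cases, controls)
    rows += _cat_row("Parity at index age",
                     lambda p: (None if p.parity is None
                                else ("ge3" if p.parity >= 3 else str(p.parity))),
                     ("0", "1", "2", "ge3"), cases, controls)
    rows += _cat_row("Age at first birth (categorical)", lambda p: p.afb_cat,
                     AFB_LEVELS, cases, controls)
    rows += _cat_row("Last birth within 5 years", lambda p: p.last_birth_within_5y,
                     (True, False), cases, controls)
    rows += _cat_row("Breastfeeding among parous", lambda p: p.breastfeeding,
                     (True, False), cases, controls)
    return pd.DataFrame(rows, columns=["variable", "level", "case", "control"])


# ---------------------------------------------------------------------------
# Matched-set serialization
# ---------------------------------------------------------------------------

def export_matched_sets(
    sets: Sequence[MatchedSet],
    spec: ModelSpec,
    path: str | Path,
    control_means: Optional[dict[str, float]] = None,
) -> Path:
    """Write the CLR rows of one model to TSV (set_id, member_rank, is_case,
    genotype_source, exposure_source, member_prs, then one column per model
    covariate).  Sets dropped by complete-case handling are omitted."""
    design = build_design_matrix(sets, spec, control_means=control_means)
    by_id = {s.family_id: s for s in sets}
    rows = []
    for si in range(design.n_sets):
        mset = by_id[design.set_ids[si]]
        members = sorted(mset.members, key=lambda m: not m.is_case_member)
        for rank, (member, r) in enumerate(
                zip(members, range(design.starts[si], design.starts[si + 1]))):
            row = {
                "set_id": mset.family_id,
                "member_rank": rank,
                "is_case": int(member.is_case_member),
                "genotype_source": member.genotype_source,
                "exposure_source": member.exposure_source,
                "member_prs": member.prs,
            }
            row.update({n: design.X[r, j] for j, n in enumerate(design.names)})
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return Path(path)


_META_COLS = ("set_id", "member_rank", "is_case", "genotype_source",
              "exposure_source", "member_prs")


def read_matched_set_tsv(path: str | Path):
    """Read an exported matched-set TSV back into (X, starts, names)."""
    df = pd.read_csv(path, sep="\t")
    names = [c for c in df.columns if c not in _META_COLS]
    X_rows, starts = [], [0]
    for _, grp in df.groupby("set_id", sort=False):
        grp = grp.sort_values("is_case", ascending=False, kind="stable")
        X_rows.append(grp[names].to_numpy(dtype=float))
        starts.append(starts[-1] + len(grp))
    X = np.vstack(X_rows)
    return X, np.asarray(starts, dtype=np.intp), names
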