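"""Readers and writers for the pipeline's plain-text input formats.

* weight panel: TSV with columns snp_id, risk_allele, odds_ratio;
* genotypes: wide TSV dosage matrix (rows = subjects, columns = snp_ids,
  already risk-allele oriented) or VCF (dosage from the DS FORMAT field when
  present, else the GT alternate-allele count), with risk-allele flipping
  (dosage -> 2 - dosage) applied when the panel's risk allele is the REF
  allele;
* pedigree: TSV with columns family_id, subject_id, role, birth_order_rank,
  genotyped, exposure, plus case-row attributes index_age, invasive,
  er_positive, ethnicity;
* exposures: long-format event CSV (subject_id, factor, value,
  age_at_event).  The factor vocabulary is: height, bmi_at_30, age_menarche,
  smoking, alcohol, breastfed_any (time-fixed; value column), menopause and
  birth (event ages), and hbc_use (age_at_event = start age, value = stop
  age of a hormonal-birth-control interval).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .exposures import EventHistory, HistoryError
from .pedigree import FamilyRecord, FamilyStructureError, Role, SubjectRecord
from .prs import DosageVector, SnpWeight, SnpWeightPanel

logger = logging.getLogger("famgxe")

__all__ = [
    "read_weights_tsv",
    "read_dosage_tsv",
    "read_vcf_dosages",
    "write_vcf",
    "read_pedigree_tsv",
    "read_exposure_csv",
]


def read_weights_tsv(path: str | Path) -> SnpWeightPanel:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "risk_allele": str})
    required = {"snp_id", "risk_allele", "odds_ratio"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: weight panel needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    return SnpWeightPanel(tuple(
        SnpWeight(str(r.snp_id), str(r.risk_allele), float(r.odds_ratio))
        for r in df.itertuples()
    ))


def read_dosage_tsv(path: str | Path) -> dict[str, DosageVector]:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    out = {}
    for sid, row in df.iterrows():
        vals = {snp: float(v) for snp, v in row.items() if pd.notna(v)}
        out[str(sid)] = DosageVector(subject_id=str(sid), dosages=vals)
    return out


def read_vcf_dosages(
    path: str | Path, panel: SnpWeightPanel
) -> tuple[dict[str, DosageVector], list[str]]:
    """Extract risk-allele dosages for the panel SNPs from a VCF.

    Uses the per-sample DS field when the file has one, otherwise the GT
    alternate-allele count.  When the panel's risk allele is the REF allele
    the dosage is flipped to 2 - dosage; flipped SNP ids are returned (and
    logged).  A panel SNP whose risk allele matches neither REF nor the
    first ALT raises.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    wanted = {w.snp_id: w for w in panel}
    dosages: dict[str, dict[str, float]] = {s: {} for s in samples}
    flipped: list[str] = []

    for variant in vcf:
        w = wanted.get(variant.ID)
        if w is None:
            continue
        alt = variant.ALT[0] if variant.ALT else None
        ds = variant.format("DS")
        if ds is not None:
            values = np.asarray(ds, dtype=float).reshape(len(samples))
        else:
            # gt_types: 0=hom ref, 1=het, 2=hom alt (cyvcf2 gts012=False maps
            # 3 to unknown); use alt allele counts from genotype tuples
            values = np.array(
                [sum(1 for a in g[:2] if a == 1) for g in variant.genotypes],
                dtype=float,
            )
        if w.risk_allele == alt:
            pass
        elif w.risk_allele == variant.REF:
            values = 2.0 - values
            flipped.append(w.snp_id)
            logger.info("flipped dosage orientation for %s (risk allele = REF)",
                        w.snp_id)
        else:
            raise ValueError(
                f"{w.snp_id}: panel risk allele {w.risk_allele!r} matches "
                f"neither REF {variant.REF!r} nor ALT {alt!r}"
            )
        for s, v in zip(samples, values):
            dosages[s][w.snp_id] = float(v)

    return (
        {s: DosageVector(subject_id=s, dosages=d) for s, d in dosages.items()},
        flipped,
    )


def write_vcf(
    dosage_frame: pd.DataFrame,
    panel: SnpWeightPanel,
    path: str | Path,
    ref_allele: str = "G",
) -> Path:
    """Write a minimal single-ALT VCF with per-sample DS dosages.

    The panel risk allele is written as ALT so no flipping is needed on
    re-import.  ``dosage_frame`` is the wide matrix (subjects x snp_ids).
    """
    path = Path(path)
    samples = [str(s) for s in dosage_frame.index]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Risk allele dosage">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for pos, w in enumerate(panel, start=1):
            ref = ref_allele if ref_allele != w.risk_allele else "T"
            vals = dosage_frame[w.snp_id].to_numpy(dtype=float)
            fields = ["1", str(pos), w.snp_id, ref, w.risk_allele, ".", "PASS",
                      ".", "DS"] + [f"{v:.6g}" for v in vals]
            fh.write("\t".join(fields) + "\n")
    return path


def read_pedigree_tsv(path: str | Path) -> list[FamilyRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "subject_id": str})
    required = {"family_id", "subject_id", "role", "birth_order_rank",
                "genotyped", "exposure"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: pedigree needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    valid_roles = {r.value for r in Role}
    families: dict[str, FamilyRecord] = {}
    for r in df.itertuples():
        if r.role not in valid_roles:
            raise FamilyStructureError(
                f"{path}: unknown role {r.role!r} for subject {r.subject_id}"
            )
        fam = families.setdefault(
            str(r.family_id), FamilyRecord(family_id=str(r.family_id), members=[])
        )
        fam.members.append(SubjectRecord(
            subject_id=str(r.subject_id),
            family_id=str(r.family_id),
            role=Role(r.role),
            birth_order_rank=int(r.birth_order_rank),
            genotyped=bool(int(r.genotyped)),
            has_exposure=bool(int(r.exposure)),
        ))
        if r.role == Role.CASE.value:
            if "index_age" in df.columns and pd.notna(r.index_age) and r.index_age != "":
                fam.index_age = float(r.index_age)
            if "invasive" in df.columns and pd.notna(r.invasive) and r.invasive != "":
                fam.invasive = bool(int(float(r.invasive)))
            if ("er_positive" in df.columns and pd.notna(r.er_positive)
                    and r.er_positive != ""):
                fam.er_positive = bool(int(float(r.er_positive)))
            if ("ethnicity" in df.columns and pd.notna(r.ethnicity)
                    and r.ethnicity != ""):
                fam.ethnicity = str(r.ethnicity)
    for fam in families.values():
        fam.validate()
    return list(families.values())


_TIME_FIXED = {"height", "bmi_at_30", "age_menarche", "smoking", "alcohol",
               "breastfed_any"}


def read_exposure_csv(path: str | Path) -> dict[str, EventHistory]:
    """Parse the long-format event CSV into per-subject histories."""
    df = pd.read_csv(path, dtype={"subject_id": str, "factor": str})
    required = {"subject_id", "factor", "value", "age_at_event"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: exposure file needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    out: dict[str, EventHistory] = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        births: list[float] = []
        intervals: list[tuple[float, float]] = []
        fields: dict = {}
        for r in grp.itertuples():
            f = r.factor
            if f in _TIME_FIXED:
                if f in ("smoking", "alcohol"):
                    fields[f] = str(r.value)
                elif f == "breastfed_any":
                    fields[f] = bool(int(float(r.value)))
                else:
                    fields[f] = float(r.value)
            elif f == "menopause":
                fields["menopause_age"] = float(r.age_at_event)
            elif f == "birth":
                births.append(float(r.age_at_event))
            elif f == "hbc_use":
                intervals.append((float(r.age_at_event), float(r.value)))
            else:
                raise HistoryError(f"{sid}: unknown exposure factor {f!r}")
        hist = EventHistory(
            subject_id=str(sid),
            height=fields.get("height"),
            bmi_at_30=fields.get("bmi_at_30"),
            age_menarche=fields.get("age_menarche"),
            smoking=fields.get("smoking"),
            alcohol=fields.get("alcohol"),
            birth_ages=tuple(sorted(births)),
            hbc_intervals=tuple(sorted(intervals)),
            menopause_age=fields.get("menopause_age"),
            breastfed_any=fields.get("breastfed_any"),
        )
        hist.validate()
        out[str(sid)] = hist
    return out
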