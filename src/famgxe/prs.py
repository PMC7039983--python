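"""Multiplicative polygenic risk score (PRS) construction and centering.

The PRS is the natural log of the product of the risk-allele-specific odds
ratios, accumulated over the panel SNPs according to each subject's
risk-allele dosage:

    PRS = sum_i g_i * ln(OR_i),   g_i in [0, 2]

Dosages may be fractional (imputed markers); no rounding to hard calls is
performed anywhere.  Reported PRS odds ratios are "per unit change" on this
natural-log scale.  In interaction models the score is centered by
subtracting the mean PRS of the actual control sisters, so exposure main
effects refer to a woman at the controls' mean genetic risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "SnpWeight",
    "SnpWeightPanel",
    "DosageVector",
    "PrsScore",
    "MissingMarkerError",
    "PanelError",
    "compute_prs",
    "center_scores",
]


class PanelError(ValueError):
    """Invalid SNP weight panel (duplicate ids, non-positive odds ratio)."""


class MissingMarkerError(KeyError):
    """A panel SNP is absent from a dosage vector under policy='error'."""

    def __init__(self, subject_id: str, snp_ids: Sequence[str]):
        self.subject_id = subject_id
        self.snp_ids = tuple(snp_ids)
        super().__init__(
            f"subject {subject_id}: missing dosages for panel SNPs {list(snp_ids)}"
        )


@dataclass(frozen=True)
class SnpWeight:
    snp_id: str
    risk_allele: str
    per_allele_or: float

    def __post_init__(self):
        if not (self.per_allele_or > 0):
            raise PanelError(
                f"{self.snp_id}: per-allele odds ratio must be > 0, "
                f"got {self.per_allele_or}"
            )

    @property
    def log_or(self) -> float:
        return float(np.log(self.per_allele_or))


@dataclass(frozen=True)
class SnpWeightPanel:
    weights: tuple[SnpWeight, ...]

    def __post_init__(self):
        if len(self.weights) == 0:
            raise PanelError("weight panel is empty")
        ids = [w.snp_id for w in self.weights]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate snp_ids in panel: {dupes}")

    def __len__(self) -> int:
        return len(self.weights)

    def __iter__(self):
        return iter(self.weights)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(w.snp_id for w in self.weights)

    @property
    def log_ors(self) -> np.ndarray:
        return np.array([w.log_or for w in self.weights])

    def concat(self, other: "SnpWeightPanel") -> "SnpWeightPanel":
        return SnpWeightPanel(self.weights + other.weights)


@dataclass
class DosageVector:
    """Risk-allele dosages for one subject, keyed by snp_id.

    Values are copies of the risk allele in [0, 2]; fractional values are
    expected for imputed markers.  SNPs absent from ``dosages`` are treated
    as missing.
    """

    subject_id: str
    dosages: dict[str, float]

    def __post_init__(self):
        bad = {k: v for k, v in self.dosages.items() if not (0.0 <= v <= 2.0)}
        if bad:
            raise ValueError(
                f"subject {self.subject_id}: dosages outside [0, 2]: {bad}"
            )


@dataclass
class PrsScore:
    subject_id: str
    raw: float
    centered: Optional[float] = None


def compute_prs(
    dosages: DosageVector,
    panel: SnpWeightPanel,
    missing_policy: str = "error",
    reference_means: Optional[Mapping[str, float]] = None,
) -> PrsScore:
    """Compute the raw PRS = sum_i g_i * ln(OR_i) over the panel.

    missing_policy:
        "error"       -- any panel SNP absent from the dosage vector raises
                         MissingMarkerError listing the offending snp_ids.
        "mean_dosage" -- absent SNPs are filled from ``reference_means``
                         (a per-SNP mean-dosage table, which must cover
                         every missing SNP).
    """
    if missing_policy not in ("error", "mean_dosage"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    missing = [s for s in panel.snp_ids if s not in dosages.dosages]
    if missing:
        if missing_policy == "error":
            raise MissingMarkerError(dosages.subject_id, missing)
        if reference_means is None:
            raise ValueError(
                "missing_policy='mean_dosage' requires a reference_means table"
            )
        uncovered = [s for s in missing if s not in reference_means]
        if uncovered:
            raise MissingMarkerError(dosages.subject_id, uncovered)
    raw = 0.0
    for w in panel:
        g = dosages.dosages.get(w.snp_id)
        if g is None:
            g = float(reference_means[w.snp_id])  # type: ignore[index]
        raw += g * w.log_or
    return PrsScore(subject_id=dosages.subject_id, raw=raw)


def center_scores(
    scores: Iterable[PrsScore],
    centering_ids: Iterable[str],
) -> list[PrsScore]:
    """Shift every score by the mean raw PRS over ``centering_ids``.

    The centering set is normally the actual (not pseudo-) control sisters.
    Returns new PrsScore objects with ``centered`` filled in; the mean of
    centered values over the centering set is zero.
    """
    scores = list(scores)
    ids = set(centering_ids)
    if not ids:
        raise ValueError("centering set is empty")
    by_id = {s.subject_id: s for s in scores}
    unknown = ids - set(by_id)
    if unknown:
        raise ValueError(f"centering ids not among scores: {sorted(unknown)}")
    constant = float(np.mean([by_id[i].raw for i in sorted(ids)]))
    return [
        PrsScore(subject_id=s.subject_id, raw=s.raw, centered=s.raw - constant)
        for s in scores
    ]
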