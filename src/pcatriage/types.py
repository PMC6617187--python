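"""Core domain records shared across the triage pipeline.

The records are deliberately thin: plain dataclasses with eager validation,
so that file readers and generators fail at construction time rather than
deep inside a model fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "PatientProfile",
    "BiopsyRecord",
    "SurvivalRecord",
    "OUTCOME_LABELS",
    "CHARLSON_LEVELS",
    "PV_CATEGORIES",
]

#: biopsy outcome labels, ordered by severity
OUTCOME_LABELS = ("no_pca", "indolent_pca", "cspca")

#: Charlson comorbidity index collapsed to the three strata used throughout
CHARLSON_LEVELS = ("0", "1", "2+")

#: rough prostate-volume estimate categories (cc) assessed during DRE
PV_CATEGORIES = (25, 40, 60)


def normalize_charlson(value) -> str:
    """Map ints/strings onto the canonical '0' | '1' | '2+' strata."""
    s = str(value).strip()
    if s in CHARLSON_LEVELS:
        return s
    try:
        v = int(float(s))
    except ValueError:
        raise ValueError(f"unrecognized Charlson category: {value!r}") from None
    if v < 0:
        raise ValueError(f"Charlson index must be >= 0, got {v}")
    return "2+" if v >= 2 else str(v)


@dataclass(frozen=True)
class PatientProfile:
    """GP-visible covariates for one man.

    Parameters
    ----------
    age : int
        Age in years at assessment (50-80 expected).
    psa : float
        Total serum PSA in ng/mL, strictly positive.
    free_psa_pct : float
        Free-to-total PSA ratio, in (0, 1].
    dre_abnormal : bool, optional
        Abnormal digital rectal examination.
    pv_estimate_cc : int, optional
        Rough prostate-volume estimate during DRE; one of 25, 40, 60 cc.
    family_history : bool, optional
        First-degree family history of prostate cancer.
    ipss : int, optional
        International Prostate Symptom Score, 0-35.
    charlson : str
        Charlson comorbidity stratum: '0', '1' or '2+'.
    """

    age: int
    psa: float
    free_psa_pct: float
    dre_abnormal: Optional[bool] = None
    pv_estimate_cc: Optional[int] = None
    family_history: Optional[bool] = None
    ipss: Optional[int] = None
    charlson: str = "0"

    def __post_init__(self):
        if not self.psa > 0:
            raise ValueError(f"psa must be > 0 ng/mL, got {self.psa}")
        if not (0 < self.free_psa_pct <= 1):
            raise ValueError(
                f"free_psa_pct must be a ratio in (0, 1], got {self.free_psa_pct}"
            )
        if self.pv_estimate_cc is not None and self.pv_estimate_cc not in PV_CATEGORIES:
            raise ValueError(
                f"pv_estimate_cc must be one of {PV_CATEGORIES}, got {self.pv_estimate_cc}"
            )
        if self.ipss is not None and not (0 <= self.ipss <= 35):
            raise ValueError(f"ipss must be in [0, 35], got {self.ipss}")
        object.__setattr__(self, "charlson", normalize_charlson(self.charlson))


@dataclass(frozen=True)
class BiopsyRecord:
    """One biopsied man: his profile plus the histological outcome."""

    profile: PatientProfile
    outcome: str

    def __post_init__(self):
        if self.outcome not in OUTCOME_LABELS:
            raise ValueError(
                f"outcome must be one of {OUTCOME_LABELS}, got {self.outcome!r}"
            )

    @property
    def is_cspca(self) -> bool:
        """True for ISUP grade >= 2 (Gleason >= 3+4) cancer."""
        return self.outcome == "cspca"


@dataclass(frozen=True)
class SurvivalRecord:
    """Follow-up record for the no-csPCa life-expectancy cohort."""

    age_at_entry: float
    charlson: Optional[str]  # None = missing, to be imputed
    follow_up_months: float
    status: str  # 'dead' | 'alive'

    def __post_init__(self):
        if self.follow_up_months < 0:
            raise ValueError("follow_up_months must be >= 0")
        if self.status not in ("dead", "alive"):
            raise ValueError(f"status must be 'dead' or 'alive', got {self.status!r}")
        if self.charlson is not None:
            object.__setattr__(self, "charlson", normalize_charlson(self.charlson))

    @property
    def dead(self) -> bool:
        return self.status == "dead"
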