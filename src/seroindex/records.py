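"""Cohort-level subject records joining net ODs with clinical covariates."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

COHORTS = (
    "risk_ra",
    "lura",
    "eira",
    "predict",
    "sle",
    "other_disease",
    "healthy",
)

TREATMENTS = ("mtx", "etanercept", "other", "none")


@dataclass
class SubjectRecord:
    """One subject: both net ODs plus serology, genetics and clinical labels.

    Missing covariates are ``None`` (never imputed). ``se_copies`` is the
    shared-epitope allele dosage (0, 1 or 2). ``eular_responder_6m`` is
    the 6-month EULAR response label, an input, never derived here.
    """

    subject_id: str
    cohort: str
    cit_net: float
    native_net: float
    rf_igm: Optional[bool] = None
    ccp2: Optional[bool] = None
    se_copies: Optional[int] = None
    lung_parenchymal_change: Optional[bool] = None
    arthritis_progression: Optional[bool] = None
    treatment: Optional[str] = None
    eular_responder_6m: Optional[bool] = None
    pain_vas_6m: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(
                f"unknown cohort {self.cohort!r}; allowed: {', '.join(COHORTS)}"
            )
        if not (math.isfinite(self.cit_net) and math.isfinite(self.native_net)):
            raise ValueError(f"non-finite net OD for subject {self.subject_id!r}")
        if self.se_copies is not None and self.se_copies not in (0, 1, 2):
            raise ValueError(
                f"se_copies must be 0, 1 or 2; got {self.se_copies!r} "
                f"for subject {self.subject_id!r}"
            )
        if self.treatment is not None and self.treatment not in TREATMENTS:
            raise ValueError(
                f"unknown treatment {self.treatment!r}; allowed: {', '.join(TREATMENTS)}"
            )
        if self.pain_vas_6m is not None and not (0.0 <= self.pain_vas_6m <= 100.0):
            raise ValueError("pain_vas_6m must be within 0-100")

    @property
    def delta(self) -> float:
        """Citrullinated-minus-native net OD (the CN-index delta)."""
        return self.cit_net - self.native_net

    @property
    def seropositive(self) -> Optional[bool]:
        """RF-IgM positive or CCP-2 positive; None when both unknown."""
        if self.rf_igm is None and self.ccp2 is None:
            return None
        return bool(self.rf_igm) or bool(self.ccp2)
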