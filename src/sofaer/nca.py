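"""Non-compartmental AUC0-8h and the subject-level exposure summary.

The model consumes exposure only as a scalar steady-state AUC0-8h per
subject: the linear trapezoidal integral of the concentration-time
profile over one 8-hour dosing interval, averaged over the first-dose
and last-dose occasions when both were sampled, with a single-occasion
fallback when one is missing.  No extrapolation beyond the last sample
is performed; integrating a partial interval is flagged, not fatal.

Concentrations below the 0.1 ng/mL assay LLOQ are set to 0 at t=0 and
dropped elsewhere.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ConcentrationProfile

__all__ = [
    "LLOQ",
    "ExposureSummary",
    "InsufficientDataError",
    "auc_0_8",
    "subject_exposure",
    "exposure_table",
    "write_exposures",
]

logger = logging.getLogger(__name__)

#: Lower limit of quantification of the plasma assay, ng/mL.
LLOQ = 0.1


class InsufficientDataError(ValueError):
    """Too few usable samples to compute an exposure metric."""


@dataclass(frozen=True)
class ExposureSummary:
    """Per-subject AUC0-8h summary; ``auc_used`` is the model input."""

    id: str
    auc_first: float | None
    auc_last: float | None
    auc_used: float

    def __post_init__(self) -> None:
        if self.auc_first is None and self.auc_last is None:
            raise InsufficientDataError(f"subject {self.id}: no AUC available on either occasion")


def _apply_lloq(times: np.ndarray, concs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # pre-dose sample: BLQ means effectively zero drug on board.  An exact
    # zero elsewhere is a true (idealised) zero, not a BLQ measurement, and
    # is kept; strictly positive sub-LLOQ values are dropped.
    below = (concs > 0.0) & (concs < LLOQ)
    concs = np.where((concs < LLOQ) & (times == 0.0), 0.0, concs)
    keep = ~(below & (times > 0.0))
    return times[keep], concs[keep]


def auc_0_8(profile: ConcentrationProfile) -> float:
    """Linear trapezoidal AUC over [0, 8] h, in h*ng/mL.

    Requires a sample at t=0 (its concentration may be 0) and at least
    two usable samples in [0, 8].  If no sample falls exactly at 8 h the
    integral runs to the last sample <= 8 h and a warning is logged;
    there is no extrapolation.
    """
    times = profile.times
    concs = profile.concentrations
    if np.any(concs < 0):
        raise ValueError(f"profile {profile.id}: negative concentration")
    times, concs = _apply_lloq(times, concs)
    in_window = times <= 8.0
    times, concs = times[in_window], concs[in_window]
    if times.size < 2:
        raise InsufficientDataError(
            f"profile {profile.id}/{profile.occasion}: need >=2 samples within [0, 8] h, got {times.size}"
        )
    if times[0] != 0.0:
        raise InsufficientDataError(
            f"profile {profile.id}/{profile.occasion}: no t=0 sample"
        )
    if times[-1] < 8.0:
        logger.warning(
            "profile %s/%s: last sample at %.3g h < 8 h; integrating the partial interval",
            profile.id,
            profile.occasion,
            times[-1],
        )
    return float(np.trapezoid(concs, times))


def subject_exposure(
    first: ConcentrationProfile | None,
    last: ConcentrationProfile | None,
) -> ExposureSummary:
    """Combine occasion AUCs into the per-subject exposure.

    The averaged first/last AUC is the exposure measure; when the
    last-dose profile is missing (dropout) the first-dose AUC is used
    alone, and symmetrically for a missing first dose (an extension of
    the trial's rule, flagged in the log).
    """
    if first is None and last is None:
        raise InsufficientDataError("both occasions missing; cannot derive exposure")
    sid = (first or last).id
    auc_first = auc_0_8(first) if first is not None else None
    auc_last = auc_0_8(last) if last is not None else None
    if auc_first is not None and auc_last is not None:
        used = 0.5 * (auc_first + auc_last)
    elif auc_first is not None:
        logger.info("subject %s: last-dose profile missing, using first-dose AUC", sid)
        used = auc_first
    else:
        logger.info("subject %s: first-dose profile missing, using last-dose AUC", sid)
        used = auc_last
    return ExposureSummary(id=sid, auc_first=auc_first, auc_last=auc_last, auc_used=used)


def exposure_table(profiles: Sequence[ConcentrationProfile]) -> pd.DataFrame:
    """Per-subject exposure summary frame (ID, AUC_FIRST, AUC_LAST, AUC_USED)."""
    by_subject: dict[str, dict[str, ConcentrationProfile]] = {}
    for p in profiles:
        by_subject.setdefault(p.id, {})[p.occasion] = p
    rows = []
    for sid, occ in by_subject.items():
        summ = subject_exposure(occ.get("first_dose"), occ.get("last_dose"))
        rows.append((sid, summ.auc_first, summ.auc_last, summ.auc_used))
    return pd.DataFrame(rows, columns=["ID", "AUC_FIRST", "AUC_LAST", "AUC_USED"])


def write_exposures(profiles: Sequence[ConcentrationProfile], path: str | Path) -> None:
    exposure_table(profiles).to_csv(Path(path), index=False, na_rep=".", float_format="%.12g")
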