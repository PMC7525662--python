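"""Residence times (time-integrated activity coefficients) from TACs.

The residence time τ of a source organ is the integral of its
fraction-of-injected-activity curve over all time, in hours
(MBq·h/MBq).  The measured part of the curve is integrated with the
trapezoid rule on frame midpoints; beyond the last frame, activity is
extrapolated by physical decay of the radionuclide alone (no biological
clearance), which integrates in closed form to A_end/λ.

The remainder compartment is any activity in the whole body not assigned
to a source organ: τ_remainder = τ_whole_body − Σ τ_organ.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import NegativeRemainderError, ValidationError
from .tac import MINUTES_PER_HOUR, SubjectScan, TimeActivityCurve, minutes_to_hours

log = logging.getLogger(__name__)

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77

#: Deficit tolerance for a negative remainder, as a fraction of the
#: whole-body τ: below it the remainder clamps to zero (VOI overlap can
#: overcount slightly); above it the input is considered corrupt.
REMAINDER_TOLERANCE = 0.02

#: Slack on the pure-physical-decay bound for whole-body τ, matching the
#: 5% measurement tolerance on whole-body activity.
WHOLE_BODY_BOUND_TOLERANCE = 0.05


@dataclass(frozen=True)
class DecayConstants:
    """Physical decay of the radionuclide (default: fluorine-18)."""

    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.half_life_min <= 0:
            raise ValidationError("half-life must be positive")

    @property
    def lambda_per_min(self) -> float:
        return math.log(2.0) / self.half_life_min

    @property
    def max_residence_h(self) -> float:
        """Residence time of 100 %ID decaying purely physically: 1/λ in hours."""
        return 1.0 / self.lambda_per_min / MINUTES_PER_HOUR


@dataclass
class ResidenceTimeSet:
    """Per-organ residence times (hours) plus whole body and remainder."""

    organs: dict[str, float]
    whole_body: float
    remainder: float
    reconstruction: str
    normalised: bool = False

    def __post_init__(self) -> None:
        for organ, tau in self.organs.items():
            if tau < 0:
                raise ValidationError(f"{organ}: negative residence time {tau}")
        if self.whole_body < 0 or self.remainder < 0:
            raise ValidationError("negative whole-body or remainder residence time")

    def source_taus(self) -> dict[str, float]:
        """Organ τ plus the remainder — the sources entering the dose engine."""
        out = dict(self.organs)
        out["remainder"] = self.remainder
        return out

    def scaled(self, factor: float) -> "ResidenceTimeSet":
        return replace(
            self,
            organs={o: t * factor for o, t in self.organs.items()},
            whole_body=self.whole_body * factor,
            remainder=self.remainder * factor,
        )


def uncorrect_decay(
    tac: TimeActivityCurve, decay: DecayConstants = DecayConstants()
) -> TimeActivityCurve:
    """Re-impose physical decay on a decay-corrected curve.

    Activity at each frame midpoint t is multiplied by exp(−λ t).  If the
    curve is already non-corrected this is a no-op with a warning.
    """
    if not tac.decay_corrected:
        warnings.warn(
            f"{tac.organ}: curve already non-decay-corrected; returning copy",
            stacklevel=2,
        )
        return replace(tac)
    factor = np.exp(-decay.lambda_per_min * tac.midpoints)
    return replace(tac, activity=tac.activity * factor, decay_corrected=False)


def trapezoid_auc(tac: TimeActivityCurve, anchor: float | None = None) -> float:
    """Trapezoid area under a TAC at frame midpoints, in fraction·hours.

    Parameters
    ----------
    tac : TimeActivityCurve
        Non-decay-corrected curve.
    anchor : float, optional
        If given, a (t=0, anchor %ID) point is prepended — 0 for organs
        (intravenous bolus starts outside the organ), 100 for the whole
        body (the bolus is in the body from injection).
    """
    if tac.decay_corrected:
        raise ValidationError(
            f"{tac.organ}: integrate non-decay-corrected activity only"
        )
    t = tac.midpoints
    a = tac.activity
    if anchor is not None:
        if t[0] <= 0:
            raise ValidationError(f"{tac.organ}: cannot anchor, first midpoint ≤ 0")
        t = np.concatenate([[0.0], t])
        a = np.concatenate([[float(anchor)], a])
    if t.size < 2:
        raise ValidationError(f"{tac.organ}: need ≥ 2 time points to integrate")
    return float(np.trapezoid(a / 100.0, minutes_to_hours(t)))


def tail_residence(
    activity_end_pct: float,
    t_end_min: float,
    decay: DecayConstants = DecayConstants(),
) -> float:
    """Residence time (hours) of the physical-decay tail beyond the scan.

    ∫_{t_end}^∞ (A_end/100)·exp(−λ (t − t_end)) dt = (A_end/100)/λ,
    independent of t_end.
    """
    if activity_end_pct < 0:
        raise ValidationError("negative tail activity")
    return activity_end_pct / 100.0 * decay.max_residence_h


def _resolve_remainder(whole_body_tau: float, organ_sum: float) -> float:
    remainder = whole_body_tau - organ_sum
    if remainder < 0:
        deficit = -remainder
        if deficit > REMAINDER_TOLERANCE * whole_body_tau:
            raise NegativeRemainderError(
                f"source organ τ sum {organ_sum:.4g} h exceeds whole-body τ "
                f"{whole_body_tau:.4g} h by more than "
                f"{REMAINDER_TOLERANCE:.0%}"
            )
        log.warning(
            "remainder τ %.4g h negative within tolerance; clamped to 0", remainder
        )
        remainder = 0.0
    return remainder


def curve_residence_time(
    tac: TimeActivityCurve,
    decay: DecayConstants = DecayConstants(),
    anchor: float | None = None,
    tail: bool = True,
) -> float:
    """τ of a single curve: trapezoid over the frames + decay-only tail."""
    tau = trapezoid_auc(tac, anchor=anchor)
    if tail:
        tau += tail_residence(float(tac.activity[-1]), float(tac.midpoints[-1]), decay)
    return tau


def residence_times(
    scan: SubjectScan,
    decay: DecayConstants = DecayConstants(),
    anchor: bool = True,
) -> ResidenceTimeSet:
    """Residence times for every source organ, the whole body and remainder.

    If the scan is decay-corrected, physical decay is re-imposed first
    (logged).  With ``anchor`` (default), a t=0 point is prepended: 0 %ID
    for organs, 100 %ID for the whole body, reflecting an intravenous
    bolus at t=0.  The tail starts at the last frame midpoint with the
    last measured activity.
    """
    if scan.decay_corrected:
        log.info("scan %s: re-imposing physical decay before integration",
                 scan.subject_id)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curves = {o: uncorrect_decay(t, decay) for o, t in scan.tacs.items()}
            whole_body = uncorrect_decay(scan.whole_body, decay)
    else:
        curves = scan.tacs
        whole_body = scan.whole_body

    organ_tau = {
        organ: curve_residence_time(
            tac, decay, anchor=0.0 if anchor else None
        )
        for organ, tac in curves.items()
    }
    wb_tau = curve_residence_time(
        whole_body, decay, anchor=100.0 if anchor else None
    )
    bound = decay.max_residence_h * (1.0 + WHOLE_BODY_BOUND_TOLERANCE)
    if wb_tau > bound:
        raise ValidationError(
            f"whole-body τ {wb_tau:.4g} h exceeds the physical-decay bound "
            f"{decay.max_residence_h:.4g} h beyond tolerance"
        )
    remainder = _resolve_remainder(wb_tau, sum(organ_tau.values()))
    return ResidenceTimeSet(
        organs=organ_tau,
        whole_body=wb_tau,
        remainder=remainder,
        reconstruction=scan.reconstruction,
        normalised=False,
    )
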