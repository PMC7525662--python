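"""Time-activity curve (TAC) data model.

A :class:`TimeActivityCurve` holds one organ's sampled activity over the
scan frames of one subject, expressed as percent of injected dose (%ID)
— the unit exported by upstream VOI quantification.  A
:class:`SubjectScan` bundles the whole-body curve with the delineated
source-organ curves for a single animal and reconstruction method.

Times are minutes in files and in these containers; residence times are
hours.  The minutes→hours conversion is centralised in
:func:`minutes_to_hours` so the unit change happens in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FrameScheduleError, ValidationError
from .organs import WHOLE_BODY

MINUTES_PER_HOUR = 60.0

#: Frame re-binning template of a 240-min rodent whole-body acquisition:
#: 7 x 1 min, 2 x 5 min and 4 x 10 min (57 min), extended with 10-min
#: frames plus a final short frame so the schedule ends exactly at 240 min.
FIRST_PASS_TEMPLATE = [1.0] * 7 + [5.0] * 2 + [10.0] * 4


def minutes_to_hours(t_min):
    """Convert minutes to hours (the only place this conversion lives)."""
    return np.asarray(t_min, dtype=float) / MINUTES_PER_HOUR


def default_frame_schedule(total_min: float = 240.0) -> np.ndarray:
    """Return an (n, 2) array of frame (start, end) minutes.

    The 13-frame first-pass template is extended with 10-min frames; if
    the total does not divide evenly a final shorter frame closes the
    schedule exactly at ``total_min``.
    """
    edges = np.concatenate([[0.0], np.cumsum(FIRST_PASS_TEMPLATE)])
    if edges[-1] > total_min:
        raise ValidationError(f"total_min={total_min} shorter than template")
    t = edges[-1]
    ext = []
    while t + 10.0 <= total_min:
        t += 10.0
        ext.append(t)
    if t < total_min:
        ext.append(total_min)
    edges = np.concatenate([edges, ext])
    return np.column_stack([edges[:-1], edges[1:]])


@dataclass
class TimeActivityCurve:
    """Sampled activity of one organ over the scan frames.

    Parameters
    ----------
    organ : str
        Canonical organ label.
    t_start, t_end : array of float
        Frame boundaries in minutes; ordered and non-overlapping.
    activity : array of float
        Activity per frame as percent of injected dose (%ID), >= 0.
    decay_corrected : bool
        Whether the values have been corrected back to injection time.
        Residence-time integration requires physically decaying (i.e.
        *non*-corrected) activity.
    injected_activity_mbq : float, optional
        Injected activity in MBq; metadata only, activity values are
        already fractions of it.
    """

    organ: str
    t_start: np.ndarray
    t_end: np.ndarray
    activity: np.ndarray
    decay_corrected: bool = False
    injected_activity_mbq: float | None = None

    def __post_init__(self) -> None:
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.t_end = np.asarray(self.t_end, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if not (self.t_start.shape == self.t_end.shape == self.activity.shape):
            raise ValidationError(f"{self.organ}: frame arrays differ in length")
        if self.t_start.size == 0:
            raise ValidationError(f"{self.organ}: empty time-activity curve")
        if np.any(self.t_start >= self.t_end):
            raise FrameScheduleError(f"{self.organ}: frame with t_start >= t_end")
        if np.any(self.t_end[:-1] > self.t_start[1:]):
            raise FrameScheduleError(f"{self.organ}: overlapping frames")
        if np.any(self.activity < 0):
            raise ValidationError(f"{self.organ}: negative activity")
        if (
            self.organ == WHOLE_BODY
            and not self.decay_corrected
            and np.any(self.activity > 105.0)
        ):
            raise ValidationError(
                "whole-body activity exceeds 100 %ID beyond 5% tolerance"
            )

    @property
    def midpoints(self) -> np.ndarray:
        """Frame midpoints in minutes — the integration abscissae."""
        return 0.5 * (self.t_start + self.t_end)

    @property
    def n_frames(self) -> int:
        return self.t_start.size

    def same_schedule(self, other: "TimeActivityCurve") -> bool:
        return self.n_frames == other.n_frames and bool(
            np.allclose(self.t_start, other.t_start)
            and np.allclose(self.t_end, other.t_end)
        )

    def scaled(self, factor: float) -> "TimeActivityCurve":
        """Return a copy with activity multiplied by ``factor``."""
        return replace(self, activity=self.activity * factor)


@dataclass
class SubjectScan:
    """One animal's whole-body scan: whole-body + source-organ TACs.

    All curves share the frame schedule; there is always a whole-body
    curve and at least one source organ.
    """

    subject_id: str
    radiotracer: str
    body_mass_g: float | None
    reconstruction: str  # "FBP" | "iterative"
    whole_body: TimeActivityCurve
    tacs: dict[str, TimeActivityCurve] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reconstruction not in ("FBP", "iterative"):
            raise ValidationError(
                f"reconstruction must be 'FBP' or 'iterative', got "
                f"{self.reconstruction!r}"
            )
        if self.whole_body.organ != WHOLE_BODY:
            raise ValidationError("whole_body curve must be labelled whole_body")
        if not self.tacs:
            raise ValidationError("scan has no source-organ curves")
        for organ, tac in self.tacs.items():
            if organ != tac.organ:
                raise ValidationError(f"key {organ!r} != curve organ {tac.organ!r}")
            if not tac.same_schedule(self.whole_body):
                raise FrameScheduleError(
                    f"{organ}: frame schedule differs from whole-body curve"
                )
            if tac.decay_corrected != self.whole_body.decay_corrected:
                raise ValidationError(
                    f"{organ}: decay_corrected flag differs from whole-body curve"
                )

    @property
    def decay_corrected(self) -> bool:
        return self.whole_body.decay_corrected

    @property
    def organs(self) -> list[str]:
        return sorted(self.tacs)

    def all_curves(self) -> list[TimeActivityCurve]:
        return [self.whole_body] + [self.tacs[o] for o in self.organs]
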