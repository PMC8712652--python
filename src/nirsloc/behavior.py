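"""Behavioral sound-localization scoring.

The pointing task uses a 7-loudspeaker arc from -90 to +90 deg at 30 deg
spacing; five speakers are active but the listener may answer any of the
seven.  Localization performance is the root-mean-square (RMS) angular
error between target and reported speaker, reported per intensity level and
pooled, plus a target x response count matrix for confusion displays.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .core import BehavioralSession, ValidationError

__all__ = ["RmsReport", "rms_error", "rms_report", "response_matrix", "ACTIVE_SPEAKERS"]

#: the five speakers used for presentation (at -90, -30, 0, +30, +90 deg)
ACTIVE_SPEAKERS: tuple[int, ...] = (1, 3, 4, 5, 7)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _errors_deg(session: BehavioralSession, intensity_db: int | None) -> np.ndarray:
    angles = session.speaker_angles_deg
    errs = [
        angles[resp] - angles[tgt]
        for tgt, resp, level in session.trials
        if intensity_db is None or level == intensity_db
    ]
    return np.asarray(errs, dtype=float)


def rms_error(session: BehavioralSession, intensity_db: int | None = None) -> float:
    """RMS angular error (degrees) over the selected trials.

    ``intensity_db=None`` pools both levels.  Correct responses contribute
    zero error; the result is rounded half-up to 2 decimals.
    """
    errs = _errors_deg(session, intensity_db)
    if errs.size == 0:
        raise ValidationError(f"no trials at intensity {intensity_db}")
    return _round2(float(np.sqrt(np.mean(errs**2))))


@dataclass(frozen=True)
class RmsReport:
    """Per-level and pooled RMS errors with an error histogram."""

    rms_low_deg: float
    rms_high_deg: float
    rms_all_deg: float
    n_low: int
    n_high: int
    error_histogram: dict[int, int]

    @property
    def n_all(self) -> int:
        return self.n_low + self.n_high


def rms_report(session: BehavioralSession) -> RmsReport:
    """Score one session: RMS at 48 dB, at 58 dB, and pooled.

    The pooled value satisfies
    ``rms_all = sqrt((n_low*rms_low^2 + n_high*rms_high^2) / n_all)``
    up to the 2-decimal rounding of the reported components.
    """
    low = _errors_deg(session, 48)
    high = _errors_deg(session, 58)
    if low.size == 0 or high.size == 0:
        raise ValidationError("session must contain trials at both levels")
    all_errs = _errors_deg(session, None)
    hist: dict[int, int] = {}
    for e in all_errs:
        hist[int(e)] = hist.get(int(e), 0) + 1
    return RmsReport(
        rms_low_deg=_round2(float(np.sqrt(np.mean(low**2)))),
        rms_high_deg=_round2(float(np.sqrt(np.mean(high**2)))),
        rms_all_deg=_round2(float(np.sqrt(np.mean(all_errs**2)))),
        n_low=low.size,
        n_high=high.size,
        error_histogram=hist,
    )


def response_matrix(session: BehavioralSession) -> np.ndarray:
    """Target x response count matrix (5 active targets x 7 responses).

    Rows follow the active speakers (-90, -30, 0, +30, +90 deg), columns the
    seven response speakers.  Row sums equal the trial count per target.
    """
    row_of = {spk: i for i, spk in enumerate(ACTIVE_SPEAKERS)}
    mat = np.zeros((len(ACTIVE_SPEAKERS), 7), dtype=int)
    for tgt, resp, _ in session.trials:
        if tgt not in row_of:
            raise ValidationError(f"target speaker {tgt} is not an active speaker")
        mat[row_of[tgt], resp - 1] += 1
    return mat
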