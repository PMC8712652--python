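"""Windowed temporal features of epoched hemodynamic responses.

Task-evoked responses peak with a variable 3-8 s delay, so each 10-s epoch
is covered by 14 overlapping analysis windows (seven 2-s, four 3-s and
three 4-s windows) and five temporal statistics — mean, variance, skewness,
kurtosis and slope — are computed per unit and window.  The full candidate
pool is therefore units x 14 x 5 features (700 at ROI level, 1400 at
channel level).

Statistic conventions (centralised here so the alternative population
definitions can be swapped in one place): variance uses n-1; skewness is
the biased moment ratio m3/m2^1.5; kurtosis is excess (m4/m2^2 - 3);
slope is the least-squares linear-fit slope against time in seconds.
Zero-variance windows get skewness = kurtosis = 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import TrialTensor, ValidationError

__all__ = ["WindowGrid", "FeatureDescriptor", "FeatureTable", "STATISTICS",
           "extract_features", "standardize"]

STATISTICS: tuple[str, ...] = ("mean", "variance", "skewness", "kurtosis", "slope")

_DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = (
    (2, 4), (3, 5), (4, 6), (5, 7), (6, 8), (7, 9), (8, 10),
    (4, 7), (5, 8), (6, 9), (7, 10),
    (4, 8), (5, 9), (6, 10),
)


@dataclass(frozen=True)
class WindowGrid:
    """The analysis windows (start_s, end_s) relative to stimulus onset."""

    windows: tuple[tuple[float, float], ...] = _DEFAULT_WINDOWS

    def __post_init__(self) -> None:
        for s, e in self.windows:
            if not 0 <= s < e:
                raise ValidationError(f"bad window ({s}, {e})")

    def __len__(self) -> int:
        return len(self.windows)

    def sample_slices(self, fs_hz: float, n_samples: int) -> list[slice]:
        """Half-open sample ranges [round(start*fs), round(end*fs))."""
        out = []
        for s, e in self.windows:
            lo, hi = int(round(s * fs_hz)), int(round(e * fs_hz))
            if hi > n_samples:
                raise ValidationError(
                    f"window ({s}, {e}) s exceeds the {n_samples}-sample epoch"
                )
            if hi - lo < 3:
                raise ValidationError(
                    f"window ({s}, {e}) s has {hi - lo} samples; need >= 3"
                )
            out.append(slice(lo, hi))
        return out


@dataclass(frozen=True)
class FeatureDescriptor:
    unit_id: int
    window: tuple[float, float]
    statistic: str

    def __str__(self) -> str:  # e.g. "roi3:5-8s:slope"
        s, e = self.window
        return f"{self.unit_id}:{s:g}-{e:g}s:{self.statistic}"


@dataclass
class FeatureTable:
    """trials x features matrix with per-feature descriptors and labels."""

    values: np.ndarray
    descriptors: list[FeatureDescriptor]
    labels: list[tuple[int, int]]
    unit_kind: str = "roi"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("feature values must be 2-D")
        if self.values.shape[1] != len(self.descriptors):
            raise ValidationError(
                f"{len(self.descriptors)} descriptors for {self.values.shape[1]} columns"
            )
        if self.values.shape[0] != len(self.labels):
            raise ValidationError(
                f"{len(self.labels)} labels for {self.values.shape[0]} rows"
            )

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_features(self, cols: Sequence[int]) -> "FeatureTable":
        cols = list(cols)
        return FeatureTable(
            values=self.values[:, cols],
            descriptors=[self.descriptors[c] for c in cols],
            labels=list(self.labels),
            unit_kind=self.unit_kind,
        )

    def select_trials(self, rows: Sequence[int]) -> "FeatureTable":
        rows = list(rows)
        return FeatureTable(
            values=self.values[rows],
            descriptors=list(self.descriptors),
            labels=[self.labels[r] for r in rows],
            unit_kind=self.unit_kind,
        )


def _window_stats(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Five statistics over the last axis; returns (..., 5)."""
    mean = x.mean(axis=-1)
    dev = x - mean[..., None]
    n = x.shape[-1]
    m2 = (dev**2).mean(axis=-1)
    m3 = (dev**3).mean(axis=-1)
    m4 = (dev**4).mean(axis=-1)
    var = m2 * n / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(m2 > 0, m4 / np.where(m2 > 0, m2, 1.0) ** 2 - 3.0, 0.0)
    tc = t - t.mean()
    slope = (x * tc).sum(axis=-1) / (tc**2).sum()
    return np.stack([mean, var, skew, kurt, slope], axis=-1)


def extract_features(tt: TrialTensor, grid: WindowGrid = WindowGrid()) -> FeatureTable:
    """Compute the full candidate-feature pool from an epoched tensor.

    Feature order is deterministic: unit-major, then window (grid order),
    then statistic (mean, variance, skewness, kurtosis, slope).
    """
    slices = grid.sample_slices(tt.fs_hz, tt.n_samples)
    per_window = []
    for sl in slices:
        t = np.arange(sl.start, sl.stop) / tt.fs_hz
        per_window.append(_window_stats(tt.data[:, :, sl], t))
    # (trials, units, windows, 5) -> (trials, units*windows*5)
    stacked = np.stack(per_window, axis=2)
    values = stacked.reshape(tt.n_trials, -1)
    descriptors = [
        FeatureDescriptor(unit_id=uid, window=win, statistic=stat)
        for uid in tt.unit_ids
        for win in grid.windows
        for stat in STATISTICS
    ]
    return FeatureTable(
        values=values,
        descriptors=descriptors,
        labels=list(tt.labels),
        unit_kind=tt.unit_kind,
    )


def standardize(
    ft: FeatureTable, stats_from: Sequence[int] | None = None
) -> FeatureTable:
    """Center/scale each feature using statistics from a trial subset.

    ``stats_from`` selects the rows (training fold) whose mean and standard
    deviation are applied to the whole table; ``None`` uses all trials.
    Zero-variance features map to all-zero columns.
    """
    rows = np.arange(ft.n_trials) if stats_from is None else np.asarray(list(stats_from))
    if rows.size == 0:
        raise ValidationError("stats_from must select at least one trial")
    sub = ft.values[rows]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0)
    out = np.where(sd > 0, (ft.values - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return FeatureTable(
        values=out,
        descriptors=list(ft.descriptors),
        labels=list(ft.labels),
        unit_kind=ft.unit_kind,
    )
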