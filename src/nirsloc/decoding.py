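"""Fisher-criterion feature selection and leave-one-out linear-SVM decoding.

Each binary contrast (e.g. source at -90 deg vs 0 deg at 58 dB SPL) is
decoded per subject with leave-one-out cross-validation: for every held-out
trial, feature standardisation and the Fisher ranking are computed on the
remaining trials only, the top-``dim`` features are selected, and a linear
maximum-margin classifier is trained and applied to the held-out trial.
Accuracy is the fraction of correctly predicted folds, evaluated for
feature-set sizes dim = 1..20; the best dim maximises accuracy (smallest
wins ties).

The Fisher score of feature k is

    FS_k = (mu_1 - mu_2)^2 / (var_1 + var_2)

with class means mu_i and within-class sample variances var_i.  A feature
with both class variances zero but distinct means separates the classes
perfectly and is ranked first (+inf sentinel).

Beyond plain location/level contrasts, the module implements the
interhemispheric comparison (symmetric ROI pairs reduced to the member
ipsi- or contralateral to the stimulated side, -90 vs +90) and per-ROI
sound-level decoding (48 vs 58 dB at a fixed source).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats as sstats
from sklearn.svm import SVC

from .core import TrialTensor, ValidationError
from .features import FeatureTable
from .probe import ROI_PAIRS

__all__ = [
    "Condition",
    "ContrastSpec",
    "DecodingResult",
    "fisher_scores",
    "select_top",
    "loocv_svm",
    "pair_hemispheres",
    "sound_level_decoding",
    "summarize_accuracies",
    "compare_conditions",
    "LATERAL_CONTRASTS",
    "FRONT30_CONTRASTS",
]


@dataclass(frozen=True)
class Condition:
    """A predicate over (location_deg, intensity_db); None matches anything."""

    location_deg: int | None = None
    intensity_db: int | None = None

    def matches(self, label: tuple[int, int]) -> bool:
        loc, db = label
        return (self.location_deg is None or loc == self.location_deg) and (
            self.intensity_db is None or db == self.intensity_db
        )

    def __str__(self) -> str:
        loc = "*" if self.location_deg is None else f"{self.location_deg:+d}"
        db = "*" if self.intensity_db is None else str(self.intensity_db)
        return f"{loc}deg@{db}dB"


@dataclass(frozen=True)
class ContrastSpec:
    """A binary decoding problem: trials of class_a vs trials of class_b."""

    class_a: Condition
    class_b: Condition
    name: str = ""

    def __str__(self) -> str:
        return self.name or f"{self.class_a} vs {self.class_b}"

    def split(self, labels: Sequence[tuple[int, int]]) -> tuple[list[int], list[int]]:
        rows_a = [i for i, lab in enumerate(labels) if self.class_a.matches(lab)]
        rows_b = [i for i, lab in enumerate(labels) if self.class_b.matches(lab)]
        overlap = set(rows_a) & set(rows_b)
        if overlap:
            raise ValidationError(f"contrast {self}: predicates overlap on trials {sorted(overlap)}")
        if not rows_a or not rows_b:
            raise ValidationError(f"contrast {self}: one class selects no trials")
        return rows_a, rows_b


def _contrast(loc_a, loc_b, db, name):
    return ContrastSpec(Condition(loc_a, db), Condition(loc_b, db), name)


#: the six lateral/front contrasts (means reported per intensity)
LATERAL_CONTRASTS: tuple[ContrastSpec, ...] = tuple(
    _contrast(a, b, db, f"{a:+d}/{b:+d}@{db}")
    for db in (48, 58)
    for a, b in ((-90, 0), (0, 90), (-90, 90))
)

#: the six +/-30 deg contrasts
FRONT30_CONTRASTS: tuple[ContrastSpec, ...] = tuple(
    _contrast(a, b, db, f"{a:+d}/{b:+d}@{db}")
    for db in (48, 58)
    for a, b in ((-30, 0), (0, 30), (-30, 30))
)


@dataclass
class DecodingResult:
    """LOOCV outcome for one contrast."""

    per_dim_accuracy: dict[int, float]
    best_dim: int
    best_accuracy: float
    selection_counts: dict[str, int]
    fold_predictions: list[int]
    fold_truth: list[int]
    contrast: str = ""

    @property
    def n_obs(self) -> int:
        return len(self.fold_predictions)


def fisher_scores(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-feature Fisher criterion for a binary problem.

    ``values`` is observations x features; ``labels`` a binary vector.
    Returns non-negative scores; +inf where both class variances vanish but
    the means differ, 0 where the class means coincide.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes.size}")
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]

    def _var(x: np.ndarray) -> np.ndarray:
        return x.var(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])

    num = (a.mean(axis=0) - b.mean(axis=0)) ** 2
    den = _var(a) + _var(b)
    scores = np.empty(values.shape[1])
    zero_den = den <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(zero_den, np.where(num > 0, np.inf, 0.0), num / np.where(zero_den, 1.0, den))
    return scores


def select_top(scores: np.ndarray, dim: int) -> np.ndarray:
    """Indices of the ``dim`` highest-scoring features.

    Ties (and +inf sentinels) break by ascending feature index, i.e. by the
    deterministic descriptor order (unit, window, statistic).
    """
    scores = np.asarray(scores, dtype=float)
    if dim < 1:
        raise ValidationError(f"dim must be >= 1, got {dim}")
    if dim > scores.size:
        raise ValidationError(f"dim {dim} exceeds feature count {scores.size}")
    order = np.argsort(-scores, kind="stable")
    return order[:dim]


def _fit_predict(x_train, y_train, x_test, C):
    clf = SVC(kernel="linear", C=C)
    clf.fit(x_train, y_train)
    return clf.predict(x_test)


def loocv_svm(
    ft: FeatureTable,
    contrast: ContrastSpec,
    dims: Iterable[int] | None = None,
    C: float = 1.0,
    selection: Literal["per_fold", "global"] = "per_fold",
) -> DecodingResult:
    """Leave-one-out linear-SVM decoding of one binary contrast.

    With ``selection='per_fold'`` (default, leakage-free) standardisation
    and the Fisher ranking are recomputed on each training fold;
    ``'global'`` computes them once on all trials before cross-validation.
    """
    rows_a, rows_b = contrast.split(ft.labels)
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise ValidationError(f"contrast {contrast}: need >= 2 observations per class")
    if len(rows_a) != len(rows_b):
        warnings.warn(
            f"contrast {contrast}: unbalanced classes ({len(rows_a)} vs {len(rows_b)})",
            stacklevel=2,
        )
    rows = rows_a + rows_b
    X = ft.values[rows]
    y = np.array([0] * len(rows_a) + [1] * len(rows_b))
    n = len(rows)
    dims = list(dims) if dims is not None else list(range(1, 21))
    if max(dims) > ft.n_features:
        raise ValidationError(f"dim {max(dims)} exceeds feature count {ft.n_features}")

    if selection == "global":
        mu, sd = X.mean(axis=0), X.std(axis=0)
        Xg = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        global_order = select_top(fisher_scores(Xg, y), max(dims))

    predictions = np.empty((len(dims), n), dtype=int)
    fold_orders: list[np.ndarray] = []
    for i in range(n):
        train = np.r_[np.arange(i), np.arange(i + 1, n)]
        if selection == "per_fold":
            mu, sd = X[train].mean(axis=0), X[train].std(axis=0)
            ok = sd > 0
            Xs = np.where(ok, (X - mu) / np.where(ok, sd, 1.0), 0.0)
            order = select_top(fisher_scores(Xs[train], y[train]), max(dims))
        else:
            Xs = Xg
            order = global_order
        fold_orders.append(order)
        for d_idx, dim in enumerate(dims):
            cols = order[:dim]
            predictions[d_idx, i] = _fit_predict(Xs[train][:, cols], y[train], Xs[i : i + 1, cols], C)[0]

    per_dim = {dim: float((predictions[d_idx] == y).mean()) for d_idx, dim in enumerate(dims)}
    best_acc = max(per_dim.values())
    best_dim = min(d for d, acc in per_dim.items() if acc == best_acc)
    counts: Counter[str] = Counter()
    for order in fold_orders:
        for col in order[:best_dim]:
            counts[str(ft.descriptors[col])] += 1
    best_idx = dims.index(best_dim)
    return DecodingResult(
        per_dim_accuracy=per_dim,
        best_dim=best_dim,
        best_accuracy=best_acc,
        selection_counts=dict(counts),
        fold_predictions=predictions[best_idx].tolist(),
        fold_truth=y.tolist(),
        contrast=str(contrast),
    )


def pair_hemispheres(
    tt: TrialTensor, side: Literal["ipsi", "contra"]
) -> TrialTensor:
    """Reduce symmetric ROI pairs to the member on one side of the source.

    Input must be a ROI-level tensor containing only -90 and +90 deg trials.
    ``ipsi`` takes the left-hemisphere ROI for -90 deg sources and the
    right-hemisphere ROI for +90 deg (``contra``: the opposite).  Output has
    5 units, one per mirrored ROI pair, labelled by the pair's left member.
    """
    if tt.unit_kind != "roi":
        raise ValidationError("pair_hemispheres expects a ROI-level tensor")
    if side not in ("ipsi", "contra"):
        raise ValidationError(f"side must be ipsi/contra, got {side!r}")
    bad = [lab for lab in tt.labels if lab[0] not in (-90, 90)]
    if bad:
        raise ValidationError(f"non-lateral trials present: {sorted(set(bad))}")
    col = {uid: j for j, uid in enumerate(tt.unit_ids)}
    out = np.empty((tt.n_trials, len(ROI_PAIRS), tt.n_samples))
    for i, (loc, _) in enumerate(tt.labels):
        # left member for (-90, ipsi) and (+90, contra); right member otherwise
        take_left = (loc == -90) == (side == "ipsi")
        for k, (left_roi, right_roi) in enumerate(ROI_PAIRS):
            roi = left_roi if take_left else right_roi
            out[i, k, :] = tt.data[i, col[roi], :]
    return TrialTensor(
        data=out,
        labels=list(tt.labels),
        fs_hz=tt.fs_hz,
        unit_kind="roi",
        unit_ids=[p[0] for p in ROI_PAIRS],
        window_s=tt.window_s,
    )


def sound_level_decoding(
    ft: FeatureTable,
    location_deg: int,
    dims: Iterable[int] | None = None,
    C: float = 1.0,
) -> dict[int, DecodingResult]:
    """Decode 48 vs 58 dB at one source location, separately per ROI.

    Each ROI uses only its own 14 x 5 = 70 candidate features; returns
    ``{roi_id: DecodingResult}``.
    """
    contrast = ContrastSpec(
        Condition(location_deg, 48), Condition(location_deg, 58),
        name=f"48/58dB@{location_deg:+d}",
    )
    contrast.split(ft.labels)  # validates both classes are present
    roi_ids = sorted({d.unit_id for d in ft.descriptors})
    out: dict[int, DecodingResult] = {}
    for roi in roi_ids:
        cols = [j for j, d in enumerate(ft.descriptors) if d.unit_id == roi]
        sub = ft.select_features(cols)
        d = list(dims) if dims is not None else list(range(1, 21))
        out[roi] = loocv_svm(sub, contrast, dims=d, C=C)
    return out


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_accuracies(
    per_subject: Mapping[str, float], threshold: float = 0.70
) -> tuple[float, int, int]:
    """Group summary of per-subject accuracies (fractions in [0, 1]).

    Returns ``(mean_percent, n_at_or_above_threshold, n_total)`` with the
    mean reported as a percentage rounded half-up to 2 decimals and an
    inclusive threshold count.
    """
    if not per_subject:
        raise ValidationError("per_subject map is empty")
    vals = np.array(list(per_subject.values()), dtype=float)
    mean_pct = _round_half_up(float(vals.mean()) * 100.0, 2)
    n_above = int(np.sum(vals >= threshold - 1e-12))
    return mean_pct, n_above, vals.size


def compare_conditions(
    acc_a: Sequence[float],
    acc_b: Sequence[float],
    test: Literal["anova_oneway", "wilcoxon_signed_rank"] = "anova_oneway",
) -> tuple[float, float]:
    """Compare two accuracy vectors; returns (statistic, two-sided p)."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if test == "anova_oneway":
        res = sstats.f_oneway(a, b)
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon_signed_rank":
        if a.size != b.size:
            raise ValidationError("paired test requires equal-length vectors")
        if np.allclose(a, b):
            return 0.0, 1.0  # all-zero differences: no evidence either way
        res = sstats.wilcoxon(a, b)
        return float(res.statistic), float(res.pvalue)
    raise ValidationError(f"unknown test {test!r}")


def decode_contrasts(
    ft: FeatureTable,
    contrasts: Iterable[ContrastSpec],
    dims: Iterable[int] | None = None,
    C: float = 1.0,
    selection: Literal["per_fold", "global"] = "per_fold",
) -> dict[str, DecodingResult]:
    """Run :func:`loocv_svm` over a batch of contrasts."""
    d = list(dims) if dims is not None else list(range(1, 21))
    return {str(c): loocv_svm(ft, c, dims=d, C=C, selection=selection) for c in contrasts}
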