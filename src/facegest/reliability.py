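"""Landmark-validation metrics: MEAD, RMSE, and inter-rater ICC.

MEAD (mean Euclidean absolute distance) compares predicted to manually
labeled landmark positions on matched frames, counting a prediction only
when its likelihood is strictly above the cutoff and the manual point is
present.  RMSE is the root mean squared Euclidean error on matched
points, used to compare candidate models' exported predictions.  Inter-
rater reliability uses the intraclass correlation coefficient ICC(2,1)
(two-way random effects, absolute agreement, single rater) on the paired
coordinate values, with x and y pooled as separate subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .io_dlc import FrameObservation
from .scheme import LandmarkScheme


@dataclass
class MeadReport:
    """Per-landmark MEAD +/- SD (pixels) and detection counts."""

    per_landmark: pd.DataFrame  # index landmark; columns mead, sd, n_detections
    overall_mean: float
    overall_sd: float
    n_frames: int
    cutoff: float

    def to_csv(self, path) -> None:
        table = self.per_landmark.copy()
        table.loc["Overall"] = [self.overall_mean, self.overall_sd, int(self.per_landmark["n_detections"].sum())]
        table.to_csv(path, index_label="Key-points")


@dataclass
class IccReport:
    """ICC(2,1) estimate with 95% CI, pooled over axes and per axis."""

    estimate: float
    ci_lower: float
    ci_upper: float
    per_axis: dict[str, float]
    n_raters: int
    n_subjects: int

    def __post_init__(self) -> None:
        bounds = (self.ci_lower, self.ci_upper)
        if all(np.isfinite(b) for b in bounds) and not (
            self.ci_lower - 1e-9 <= self.estimate <= self.ci_upper + 1e-9
        ):
            raise ValueError("ICC estimate outside its confidence interval")


def _match(
    reference: Sequence[FrameObservation], other: Sequence[FrameObservation]
) -> list[tuple[FrameObservation, FrameObservation]]:
    index = {(o.clip_id, o.frame_index): o for o in other}
    pairs = [
        (ref, index[(ref.clip_id, ref.frame_index)])
        for ref in reference
        if (ref.clip_id, ref.frame_index) in index
    ]
    if not pairs:
        raise ValueError("no overlapping (clip, frame) keys between the two sets")
    return pairs


def _paired_errors(
    manual: Sequence[FrameObservation],
    predicted: Sequence[FrameObservation],
    scheme: LandmarkScheme,
    cutoff: float | None,
) -> list[np.ndarray]:
    """Per-landmark lists of Euclidean errors over valid matched points."""
    pairs = _match(manual, predicted)
    errors: list[list[float]] = [[] for _ in scheme.names]
    for man, pred in pairs:
        dist = np.hypot(*(pred.coords - man.coords).T)
        for j in range(len(scheme)):
            if np.isnan(man.coords[j]).any() or man.likelihood[j] == 0:
                continue  # no manual reference for this landmark
            if cutoff is not None and not pred.likelihood[j] > cutoff:
                continue  # prediction not detected
            if np.isnan(pred.coords[j]).any():
                continue
            errors[j].append(float(dist[j]))
    return [np.array(e) for e in errors]


def mead(
    manual: Sequence[FrameObservation],
    predicted: Sequence[FrameObservation],
    scheme: LandmarkScheme,
    cutoff: float = 0.6,
) -> MeadReport:
    """Mean Euclidean absolute distance per landmark over above-cutoff detections.

    Landmarks with zero detections are reported with NaN mean/SD and
    n_detections 0.  The overall row pools every retained error.
    """
    errors = _paired_errors(manual, predicted, scheme, cutoff)
    rows = []
    for name, err in zip(scheme.names, errors):
        if len(err) == 0:
            rows.append((name, np.nan, np.nan, 0))
        else:
            sd = err.std(ddof=1) if len(err) > 1 else np.nan
            rows.append((name, err.mean(), sd, len(err)))
    per_landmark = pd.DataFrame(
        rows, columns=["landmark", "mead", "sd", "n_detections"]
    ).set_index("landmark")
    pooled = np.concatenate([e for e in errors if len(e)]) if any(len(e) for e in errors) else np.array([])
    if len(pooled) == 0:
        overall_mean, overall_sd = np.nan, np.nan
    else:
        overall_mean = float(pooled.mean())
        overall_sd = float(pooled.std(ddof=1)) if len(pooled) > 1 else np.nan
    n_frames = len({(m.clip_id, m.frame_index) for m in manual})
    return MeadReport(
        per_landmark=per_landmark,
        overall_mean=overall_mean,
        overall_sd=overall_sd,
        n_frames=n_frames,
        cutoff=cutoff,
    )


def rmse(
    labeled: Sequence[FrameObservation],
    predicted: Sequence[FrameObservation],
    scheme: LandmarkScheme,
) -> tuple[pd.Series, float]:
    """Root mean squared Euclidean error per landmark and pooled (pixels)."""
    errors = _paired_errors(labeled, predicted, scheme, cutoff=None)
    per_landmark = pd.Series(
        [np.sqrt(np.mean(e**2)) if len(e) else np.nan for e in errors],
        index=list(scheme.names),
        name="rmse",
    )
    pooled = np.concatenate([e for e in errors if len(e)])
    return per_landmark, float(np.sqrt(np.mean(pooled**2)))


def icc(
    rater_a: Sequence[FrameObservation],
    rater_b: Sequence[FrameObservation],
    scheme: LandmarkScheme,
) -> IccReport:
    """Inter-rater ICC(2,1) on paired landmark coordinates.

    Each (frame, landmark, axis) is one subject rated by both annotators;
    per-axis estimates are reported alongside the pooled one so either
    convention can be inspected.  Points either rater left unplaced are
    excluded.
    """
    pairs = _match(rater_a, rater_b)
    rows = []
    for man_a, man_b in pairs:
        for j, name in enumerate(scheme.names):
            if np.isnan(man_a.coords[j]).any() or np.isnan(man_b.coords[j]).any():
                continue
            for axis_i, axis in enumerate("xy"):
                subject = (man_a.clip_id, man_a.frame_index, name, axis)
                rows.append((subject, "A", axis, man_a.coords[j, axis_i]))
                rows.append((subject, "B", axis, man_b.coords[j, axis_i]))
    if not rows:
        raise ValueError("no commonly labeled points between the raters")
    long = pd.DataFrame(rows, columns=["subject", "rater", "axis", "value"])
    long["subject"] = long["subject"].astype(str)
    if long["subject"].nunique() < 2:
        raise ValueError("ICC needs at least 2 subjects")

    pooled = icc2_single(
        long.pivot(index="subject", columns="rater", values="value").to_numpy()
    )
    per_axis = {}
    for axis, sub in long.groupby("axis"):
        if sub["subject"].nunique() >= 2:
            matrix = sub.pivot(index="subject", columns="rater", values="value")
            per_axis[axis] = icc2_single(matrix.to_numpy())[0]
    return IccReport(
        estimate=pooled[0],
        ci_lower=pooled[1],
        ci_upper=pooled[2],
        per_axis=per_axis,
        n_raters=2,
        n_subjects=long["subject"].nunique(),
    )


def icc2_single(ratings: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(2,1) with its exact F-based confidence interval.

    ``ratings`` is an (n_subjects, k_raters) matrix.  Two-way random
    effects, absolute agreement, single rater: the mean squares of the
    two-way ANOVA without replication give

        ICC(2,1) = (MSB - MSE) / (MSB + (k-1) MSE + k (MSJ - MSE) / n)

    with MSB between subjects, MSJ between raters, MSE residual.  The
    interval follows Shrout & Fleiss via a Satterthwaite-style df for the
    rater term.  Perfect agreement (MSE = MSJ = 0) returns (1, 1, 1).
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be (n_subjects >= 2, k_raters >= 2)")
    if np.isnan(ratings).any():
        raise ValueError("ratings must be complete (no NaN)")
    n, k = ratings.shape
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ssb = k * np.sum((row_means - grand) ** 2)  # between subjects
    ssj = n * np.sum((col_means - grand) ** 2)  # between raters
    sst = np.sum((ratings - grand) ** 2)
    sse = sst - ssb - ssj
    msb = ssb / (n - 1)
    msj = ssj / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)

    denom = msb + (k - 1) * mse + k * (msj - mse) / n
    if denom == 0.0:
        raise ValueError("no variance in ratings; ICC undefined")
    # perfect (or numerically perfect) agreement
    if mse <= 1e-12 * msb and msj <= 1e-12 * msb:
        return 1.0, 1.0, 1.0
    est = (msb - mse) / denom

    # Shrout & Fleiss (1979) interval for ICC(2,1)
    fj = msj / mse if mse > 0 else np.inf
    with np.errstate(over="ignore", invalid="ignore"):
        vn = (k - 1) * (n - 1) * (k * est * fj + n * (1 + (k - 1) * est) - k * est) ** 2
        vd = (n - 1) * k**2 * est**2 * fj**2 + (n * (1 + (k - 1) * est) - k * est) ** 2
        v = vn / vd
    if not np.isfinite(v):  # fj -> inf limit
        v = (k - 1) * (n - 1)
    f1 = f_dist.ppf(1 - alpha / 2, n - 1, v)
    f2 = f_dist.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msb - f1 * mse) / (
        f1 * (k * msj + (k * n - k - n) * mse) + n * msb
    )
    upper = n * (f2 * msb - mse) / (
        k * msj + (k * n - k - n) * mse + n * f2 * msb
    )
    return float(est), float(lower), float(upper)
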