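"""Synthetic landmark data with the statistical structure the pipeline assumes.

Frames are generated from a canonical 13-landmark face template (unit
inner-eye distance, y-down, already roll-aligned).  Each frame is the
template deformed by its class's gesture parameters (mouth opening, mouth
width, eyelid aperture) plus per-frame shape jitter, mapped through a
random similarity transform (rotation, uniform scale, translation) into
the 960 x 540 working image, then perturbed by additive observation
noise.  Per-landmark detection likelihoods come from a two-component
mixture — a cutoff-passing high component and a cutoff-failing low
component — with elevated dropout on the mouth-side points, mirroring the
detection asymmetry seen in real tracking.

Deformations act in the template frame before the similarity transform,
so the class signal survives inner-eye normalization exactly as real
facial gestures would.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_dlc import (
    CONTEXTS,
    VOICINGS,
    ClipLabel,
    FrameObservation,
    write_clip_labels,
    write_manual_labels,
    write_predictions,
)
from .scheme import DEFAULT_SCHEME, LandmarkScheme

#: Canonical face layout, unit inner-eye distance, y increases downward.
#: Eyes sit on y=0; the mouth opens toward positive y.
TEMPLATE: dict[str, tuple[float, float]] = {
    "RightEye_top": (0.80, -0.18),
    "RightEye_Bottom": (0.80, 0.15),
    "RightEye_Inner": (0.50, 0.00),
    "RightEye_Outer": (1.10, 0.05),
    "LeftEye_top": (-0.80, -0.18),
    "LeftEye_Bottom": (-0.80, 0.15),
    "LeftEye_Inner": (-0.50, 0.00),
    "LeftEye_Outer": (-1.10, 0.05),
    "Nosetip": (0.00, 0.60),
    "Mouth_Top": (0.00, 1.00),
    "Mouth_Bottom": (0.00, 1.25),
    "Mouth_Right": (0.45, 1.12),
    "Mouth_Left": (-0.45, 1.12),
}

_EYE_GROUPS = {
    "RightEye_top": ("RightEye_Inner", -0.18),
    "RightEye_Bottom": ("RightEye_Inner", 0.15),
    "LeftEye_top": ("LeftEye_Inner", -0.18),
    "LeftEye_Bottom": ("LeftEye_Inner", 0.15),
}

MOUTH_SIDE = ("Mouth_Right", "Mouth_Left")


@dataclass(frozen=True)
class ClassParams:
    """Gesture-deformation parameters for one class, in inner-eye-distance units."""

    mouth_open: float = 0.0  # jaw drop added to Mouth_Bottom (and corners follow)
    mouth_width_delta: float = 0.0  # widening of the mouth corners
    eye_aperture: float = 1.0  # 1 = eyes open, 0 = closed
    sigma_shape: float = 0.05  # per-frame shape jitter SD
    mouth_dropout: float | None = None  # override mouth-side dropout rate


@dataclass(frozen=True)
class SyntheticScenario:
    """Generator settings: classes, transforms, noise, dropout, sizes, seed."""

    classes: dict[str, ClassParams]
    task: str = "context"  # which label the class names populate
    clips_per_class: int = 100
    frames_per_clip: int = 10
    rotation_max: float = np.deg2rad(25.0)  # per-frame roll range (radians)
    scale_range: tuple[float, float] = (40.0, 90.0)  # inner-eye distance in pixels
    translation_box: tuple[float, float, float, float] = (200.0, 760.0, 120.0, 420.0)
    sigma_obs: float = 2.0  # additive coordinate noise (pixels)
    base_dropout: float = 0.05  # per-landmark detection-failure rate
    mouth_top_bottom_dropout: float = 0.08
    mouth_side_dropout: float = 0.20
    seed: int = 0
    scheme: LandmarkScheme = DEFAULT_SCHEME

    def __post_init__(self) -> None:
        problems = []
        if not self.classes:
            problems.append("classes must be non-empty")
        valid = set(CONTEXTS) | set(VOICINGS)
        for label in self.classes:
            if label not in valid:
                problems.append(f"unknown class label {label!r}")
        if self.scale_range[0] <= 0 or self.scale_range[1] < self.scale_range[0]:
            problems.append("scale_range must be positive and ordered")
        if self.sigma_obs < 0:
            problems.append("sigma_obs must be >= 0")
        for name in ("base_dropout", "mouth_top_bottom_dropout", "mouth_side_dropout"):
            if not 0.0 <= getattr(self, name) < 1.0:
                problems.append(f"{name} must lie in [0, 1)")
        if self.clips_per_class < 1 or self.frames_per_clip < 1:
            problems.append("clips_per_class and frames_per_clip must be >= 1")
        if problems:
            raise ValueError("invalid scenario: " + "; ".join(problems))

    def dropout_rates(self, params: ClassParams | None = None) -> np.ndarray:
        """Per-landmark detection-failure probabilities, in scheme order."""
        rates = np.full(len(self.scheme), self.base_dropout)
        for name in ("Mouth_Top", "Mouth_Bottom"):
            if name in self.scheme.names:
                rates[self.scheme.index(name)] = self.mouth_top_bottom_dropout
        side = self.mouth_side_dropout
        if params is not None and params.mouth_dropout is not None:
            side = params.mouth_dropout
        for name in MOUTH_SIDE:
            if name in self.scheme.names:
                rates[self.scheme.index(name)] = side
        return rates


@dataclass
class SyntheticDataset:
    """Generated frames plus the ground truth needed for recovery tests."""

    predictions: list[FrameObservation]
    clip_labels: dict[str, ClipLabel]
    manual: list[FrameObservation]  # noise-free subset in manual-label form
    truth_coords: dict[tuple[str, int], np.ndarray]  # noise-free image coords
    truth_params: dict[str, ClassParams]
    scenario: SyntheticScenario

    def write(self, outdir: str | Path) -> None:
        """Write per-clip prediction CSVs, a manual subset, and clip labels."""
        outdir = Path(outdir)
        pred_dir = outdir / "predictions"
        man_dir = outdir / "manual"
        pred_dir.mkdir(parents=True, exist_ok=True)
        man_dir.mkdir(parents=True, exist_ok=True)
        scheme = self.scenario.scheme
        by_clip: dict[str, list[FrameObservation]] = {}
        for obs in self.predictions:
            by_clip.setdefault(obs.clip_id, []).append(obs)
        for clip_id, frames in by_clip.items():
            write_predictions(frames, pred_dir / f"{clip_id}.csv", scheme)
        man_by_clip: dict[str, list[FrameObservation]] = {}
        for obs in self.manual:
            man_by_clip.setdefault(obs.clip_id, []).append(obs)
        for clip_id, frames in man_by_clip.items():
            write_manual_labels(frames, man_dir / f"{clip_id}.csv", scheme)
        write_clip_labels(self.clip_labels, outdir / "clip_labels.csv")


def class_template(scheme: LandmarkScheme, params: ClassParams) -> np.ndarray:
    """The template deformed by one class's gesture parameters (no jitter)."""
    coords = {name: np.array(TEMPLATE[name]) for name in scheme.names}
    # eyelid aperture: lids collapse toward the eye's horizontal midline
    for lid, (anchor, offset) in _EYE_GROUPS.items():
        if lid in coords and anchor in coords:
            coords[lid] = coords[anchor] + np.array(
                [coords[lid][0] - coords[anchor][0], offset * params.eye_aperture]
            )
    # jaw drop: the lower lip carries the full opening, corners follow halfway
    if "Mouth_Bottom" in coords:
        coords["Mouth_Bottom"][1] += params.mouth_open
    for corner_sign, corner in (("+", "Mouth_Right"), ("-", "Mouth_Left")):
        if corner in coords:
            coords[corner][1] += 0.5 * params.mouth_open
            widen = 0.5 * params.mouth_width_delta
            coords[corner][0] += widen if corner_sign == "+" else -widen
    return np.stack([coords[name] for name in scheme.names])


def _similarity(coords: np.ndarray, angle: float, scale: float, shift: np.ndarray) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return scale * coords @ rot.T + shift


def generate(scenario: SyntheticScenario, manual_clips: int = 2) -> SyntheticDataset:
    """Generate the full synthetic dataset for a scenario.

    ``manual_clips`` clips per class also receive noise-free manual labels
    (the ground truth re-expressed in the annotation dialect), supporting
    MEAD/RMSE validation against the noisy predictions.
    """
    rng = np.random.default_rng(scenario.seed)
    scheme = scenario.scheme
    x0, x1, y0, y1 = scenario.translation_box
    predictions: list[FrameObservation] = []
    manual: list[FrameObservation] = []
    clip_labels: dict[str, ClipLabel] = {}
    truth_coords: dict[tuple[str, int], np.ndarray] = {}

    for label, params in scenario.classes.items():
        base = class_template(scheme, params)
        dropout = scenario.dropout_rates(params)
        for clip_i in range(scenario.clips_per_class):
            clip_id = f"{label}_{clip_i:04d}"
            if scenario.task == "voicing":
                voicing = label
                context = "vo" if label == "vo" else "oa"
            else:
                context = label
                voicing = "vo" if label == "vo" else "un"
            clip_labels[clip_id] = ClipLabel(
                clip_id=clip_id, voicing=voicing, context=context
            )
            with_manual = clip_i < manual_clips
            for frame_i in range(scenario.frames_per_clip):
                shape = base + rng.normal(0.0, params.sigma_shape, size=base.shape)
                angle = rng.uniform(-scenario.rotation_max, scenario.rotation_max)
                scale = rng.uniform(*scenario.scale_range)
                shift = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
                true = _similarity(shape, angle, scale, shift)
                observed = true + rng.normal(0.0, scenario.sigma_obs, size=true.shape)
                low = rng.random(len(scheme)) < dropout
                likelihood = np.where(
                    low,
                    rng.uniform(0.0, 0.55, size=len(scheme)),
                    rng.uniform(0.75, 1.0, size=len(scheme)),
                )
                truth_coords[(clip_id, frame_i)] = true
                predictions.append(
                    FrameObservation(
                        clip_id=clip_id,
                        frame_index=frame_i,
                        coords=observed,
                        likelihood=likelihood,
                    )
                )
                if with_manual:
                    manual.append(
                        FrameObservation(
                            clip_id=clip_id,
                            frame_index=frame_i,
                            coords=true.copy(),
                            likelihood=np.ones(len(scheme)),
                        )
                    )
    return SyntheticDataset(
        predictions=predictions,
        clip_labels=clip_labels,
        manual=manual,
        truth_coords=truth_coords,
        truth_params=dict(scenario.classes),
        scenario=scenario,
    )


def make_two_raters(
    dataset: SyntheticDataset, sigma_rater: float, seed: int = 0
) -> tuple[list[FrameObservation], list[FrameObservation]]:
    """Two annotators' labels: ground truth plus independent Gaussian noise."""
    if sigma_rater < 0:
        raise ValueError("sigma_rater must be >= 0")
    rng = np.random.default_rng(seed)
    raters: list[list[FrameObservation]] = [[], []]
    for (clip_id, frame_i), true in dataset.truth_coords.items():
        for rater in raters:
            rater.append(
                FrameObservation(
                    clip_id=clip_id,
                    frame_index=frame_i,
                    coords=true + rng.normal(0.0, sigma_rater, size=true.shape),
                    likelihood=np.ones(true.shape[0]),
                )
            )
    return raters[0], raters[1]


# ---------------------------------------------------------------------------
# Scenario presets


def two_class_scenario(
    mouth_open_voiced: float = 0.5,
    mouth_open_unvoiced: float = 0.1,
    sigma_shape: float = 0.12,
    clips_per_class: int = 1000,
    seed: int = 0,
    **overrides,
) -> SyntheticScenario:
    """Voiced vs. unvoiced: vocalizing faces open the mouth more on average.

    The default within-class shape jitter is deliberately large relative to
    the mean opening difference: many calls are emitted with a closed or
    semi-open mouth, so the two configuration distributions overlap and
    classification is informative but imperfect.
    """
    return SyntheticScenario(
        classes={
            "vo": ClassParams(mouth_open=mouth_open_voiced, sigma_shape=sigma_shape),
            "un": ClassParams(mouth_open=mouth_open_unvoiced, sigma_shape=sigma_shape),
        },
        task="voicing",
        clips_per_class=clips_per_class,
        seed=seed,
        **overrides,
    )


def eight_class_scenario(
    clips_per_class: int = 100, seed: int = 0, **overrides
) -> SyntheticScenario:
    """The eight behavioral contexts with qualitatively distinct gestures.

    Yawning is an extreme mouth opening with near-closed eyes; vocalization
    a large opening (hence confusable with yawning); feeding a moderate
    opening with extra mouth-side dropout; resting closes the eyes; social
    activity widens the mouth corners; scanning/locomotion/other-activity
    are near-neutral and differ mainly in shape variability.
    """
    return SyntheticScenario(
        classes={
            "yw": ClassParams(mouth_open=1.2, eye_aperture=0.15),
            "vo": ClassParams(mouth_open=0.8),
            "fe": ClassParams(mouth_open=0.35, mouth_dropout=0.35),
            "rs": ClassParams(mouth_open=0.05, eye_aperture=0.10),
            "sa": ClassParams(mouth_open=0.20, mouth_width_delta=0.30),
            "sc": ClassParams(sigma_shape=0.04),
            "lo": ClassParams(sigma_shape=0.08),
            "oa": ClassParams(sigma_shape=0.12),
        },
        task="context",
        clips_per_class=clips_per_class,
        seed=seed,
        **overrides,
    )


def null_scenario(
    n_classes: int, clips_per_class: int, seed: int = 0, **overrides
) -> SyntheticScenario:
    """Zero class effect: every class shares identical generation parameters."""
    if n_classes == 2:
        labels, task = list(VOICINGS), "voicing"
    elif n_classes == 8:
        labels, task = list(CONTEXTS), "context"
    else:
        raise ValueError("null scenarios cover the 2- and 8-class designs")
    neutral = ClassParams(mouth_open=0.3)
    return SyntheticScenario(
        classes={label: neutral for label in labels},
        task=task,
        clips_per_class=clips_per_class,
        seed=seed,
        **overrides,
    )
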