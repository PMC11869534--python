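"""Facial alignment and pairwise-distance geometry.

Alignment removes in-plane head roll by rotating each frame so the line
through the two inner-eye landmarks is horizontal at 180 degrees (the
right-to-left inner-eye vector points along negative x in the y-down image
frame).  Distances are the Euclidean lengths of all landmark pairs,
optionally normalized by the inner-eye distance, which makes the feature
vector invariant to translation, rotation, and uniform scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .io_dlc import FrameObservation
from .scheme import LandmarkScheme


class DegenerateGeometryError(ValueError):
    """Geometry is degenerate (e.g. coincident normalization landmarks)."""


class MissingLandmarkError(ValueError):
    """A required landmark coordinate is missing (NaN)."""


@dataclass
class AlignedFrame(FrameObservation):
    """A frame after roll alignment; records the rotation that was applied."""

    rotation_angle_applied: float = 0.0


@dataclass
class DistanceVector:
    """Condensed upper-triangle pairwise distances for one frame.

    Entries follow the scheme's condensed (lexicographic-by-index) pair
    order; length n(n-1)/2.  ``normalized`` means every entry has been
    divided by the normalization-pair distance (that entry is exactly 1).
    """

    values: np.ndarray
    clip_id: str
    frame_index: int
    fully_crossed: bool = True
    normalized: bool = False

    def __len__(self) -> int:
        return len(self.values)


def _inner_eye_vector(frame: FrameObservation, scheme: LandmarkScheme) -> np.ndarray:
    a, b = scheme.normalization_pair
    right = frame.coords[scheme.index(a)]
    left = frame.coords[scheme.index(b)]
    if np.isnan(right).any() or np.isnan(left).any():
        raise MissingLandmarkError(
            f"clip {frame.clip_id!r} frame {frame.frame_index}: "
            f"normalization landmarks {a}/{b} missing"
        )
    return left - right


def rotation_angle(frame: FrameObservation, scheme: LandmarkScheme) -> float:
    """Roll angle phi (radians, in (-pi, pi]) that aligns the inner-eye line.

    phi = pi - atan2(dy, dx) for d = LeftEye_Inner - RightEye_Inner, so that
    rotating every point by phi sends the inner-eye vector to direction 180
    degrees (negative x, zero y) in the y-down image frame.
    """
    delta = _inner_eye_vector(frame, scheme)
    if np.hypot(*delta) == 0.0:
        raise DegenerateGeometryError(
            f"clip {frame.clip_id!r} frame {frame.frame_index}: "
            "normalization landmarks coincide"
        )
    phi = math.pi - math.atan2(delta[1], delta[0])
    if phi > math.pi:  # wrap to (-pi, pi]
        phi -= 2.0 * math.pi
    return phi


def align_frame(frame: FrameObservation, scheme: LandmarkScheme) -> AlignedFrame:
    """Rotate all landmarks by the frame's roll angle about the inner-eye midpoint.

    Rotation is an isometry, so pairwise distances are unchanged; the step
    standardizes exported coordinates.  Likelihoods pass through untouched.
    """
    phi = rotation_angle(frame, scheme)
    a, b = scheme.normalization_pair
    center = 0.5 * (frame.coords[scheme.index(a)] + frame.coords[scheme.index(b)])
    c, s = math.cos(phi), math.sin(phi)
    rot = np.array([[c, -s], [s, c]])
    coords = (frame.coords - center) @ rot.T + center
    return AlignedFrame(
        clip_id=frame.clip_id,
        frame_index=frame.frame_index,
        coords=coords,
        likelihood=frame.likelihood.copy(),
        rotation_angle_applied=phi,
    )


def is_fully_crossed(frame: FrameObservation, cutoff: float = 0.6) -> bool:
    """True iff every landmark's likelihood is strictly above the cutoff."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    return bool(np.all(frame.likelihood > cutoff))


def distance_vector(frame: FrameObservation, scheme: LandmarkScheme) -> DistanceVector:
    """All-pairs Euclidean distances in condensed order (78 entries for 13 points)."""
    if np.isnan(frame.coords).any():
        missing = [
            scheme.names[j] for j in range(len(scheme)) if np.isnan(frame.coords[j]).any()
        ]
        raise MissingLandmarkError(
            f"clip {frame.clip_id!r} frame {frame.frame_index}: "
            f"NaN coordinates for {', '.join(missing)}"
        )
    return DistanceVector(
        values=pdist(frame.coords),
        clip_id=frame.clip_id,
        frame_index=frame.frame_index,
    )


def normalize(dv: DistanceVector, scheme: LandmarkScheme) -> DistanceVector:
    """Divide every distance by the normalization-pair distance.

    The normalization entry becomes exactly 1; the vector is then invariant
    under any similarity transform of the source coordinates.
    """
    ref = dv.values[scheme.normalization_index]
    if not ref > 0:
        raise DegenerateGeometryError(
            f"clip {dv.clip_id!r} frame {dv.frame_index}: "
            "normalization distance is zero"
        )
    values = dv.values / ref
    values[scheme.normalization_index] = 1.0
    return DistanceVector(
        values=values,
        clip_id=dv.clip_id,
        frame_index=dv.frame_index,
        fully_crossed=dv.fully_crossed,
        normalized=True,
    )
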