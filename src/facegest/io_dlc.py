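"""Readers and writers for the DeepLabCut CSV dialect and clip-label tables.

Prediction files carry three header rows (``scorer`` / ``bodyparts`` /
``coords``) with an ``x, y, likelihood`` triplet per landmark and one row
per video frame.  Manual-annotation files use the same dialect without the
likelihood column.  Landmarks are matched by name, never by column
position.  Missing points are kept as NaN coordinates with likelihood 0 so
that inclusion decisions stay with the downstream cutoff filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .scheme import LandmarkScheme

#: The eight behavioral context codes: vocalization, feeding, locomotion,
#: resting, scanning, social activity, other activity, yawning.
CONTEXTS: tuple[str, ...] = ("vo", "fe", "lo", "rs", "sc", "sa", "oa", "yw")

#: Voicing codes: voiced / unvoiced.
VOICINGS: tuple[str, ...] = ("vo", "un")


class DialectError(ValueError):
    """The file does not follow the expected three-header-row CSV dialect."""


class SchemaError(ValueError):
    """The file's landmark set does not cover the scheme."""


class CategoryError(ValueError):
    """A label value falls outside the fixed category sets."""


@dataclass
class FrameObservation:
    """One frame's landmark coordinates (pixels, image frame, y down)."""

    clip_id: str
    frame_index: int
    coords: np.ndarray  # (n_landmarks, 2) float, NaN where missing
    likelihood: np.ndarray  # (n_landmarks,) float in [0, 1]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (n_landmarks, 2)")
        if self.likelihood.shape != (self.coords.shape[0],):
            raise ValueError("likelihood must have one entry per landmark")
        finite = self.likelihood[np.isfinite(self.likelihood)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValueError("likelihoods must lie in [0, 1]")


@dataclass(frozen=True)
class ClipLabel:
    """Voicing and behavioral-context label for one clip."""

    clip_id: str
    voicing: str
    context: str
    individual_id: str | None = None

    def __post_init__(self) -> None:
        if self.voicing not in VOICINGS:
            raise CategoryError(f"unknown voicing {self.voicing!r} for clip {self.clip_id!r}")
        if self.context not in CONTEXTS:
            raise CategoryError(f"unknown context {self.context!r} for clip {self.clip_id!r}")
        if self.context == "vo" and self.voicing != "vo":
            raise CategoryError(
                f"clip {self.clip_id!r}: context 'vo' implies voicing 'vo', got {self.voicing!r}"
            )


# ---------------------------------------------------------------------------
# DLC-dialect tables


def _read_dialect(path: str | Path, expect_likelihood: bool) -> pd.DataFrame:
    try:
        frame = pd.read_csv(
            path, header=[0, 1, 2], index_col=0, float_precision="round_trip"
        )
    except (pd.errors.ParserError, IndexError) as exc:
        raise DialectError(f"{path}: not a three-header-row landmark CSV ({exc})") from exc
    # the first column's three header cells surface as the column level names
    if list(frame.columns.names) != ["scorer", "bodyparts", "coords"]:
        raise DialectError(
            f"{path}: header rows must be scorer/bodyparts/coords, "
            f"got {list(frame.columns.names)!r}"
        )
    coords_level = frame.columns.get_level_values(2)
    expected = {"x", "y", "likelihood"} if expect_likelihood else {"x", "y"}
    unexpected = set(coords_level) - expected
    if unexpected:
        raise DialectError(f"{path}: unexpected coords columns {sorted(unexpected)}")
    return frame


def _extract(
    frame: pd.DataFrame,
    path: str | Path,
    scheme: LandmarkScheme,
    clip_id: str | None,
    with_likelihood: bool,
) -> list[FrameObservation]:
    if clip_id is None:
        clip_id = Path(path).stem
    bodyparts = set(frame.columns.get_level_values(1))
    missing = [name for name in scheme.names if name not in bodyparts]
    if missing:
        raise SchemaError(f"{path}: landmark columns missing for {', '.join(missing)}")
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise DialectError(f"{path}: duplicated frame index values {dupes}")

    n = len(scheme)
    xs = np.empty((len(frame), n))
    ys = np.empty((len(frame), n))
    lik = np.ones((len(frame), n))
    for j, name in enumerate(scheme.names):
        block = frame.xs(name, axis=1, level=1)
        block.columns = block.columns.get_level_values(-1)
        xs[:, j] = block["x"].to_numpy(dtype=float)
        ys[:, j] = block["y"].to_numpy(dtype=float)
        if with_likelihood:
            lik[:, j] = block["likelihood"].to_numpy(dtype=float)

    # blank cells: NaN coordinates, likelihood forced to 0
    nan_mask = np.isnan(xs) | np.isnan(ys)
    lik[nan_mask] = 0.0

    observations = []
    for r, idx in enumerate(frame.index):
        observations.append(
            FrameObservation(
                clip_id=clip_id,
                frame_index=int(idx),
                coords=np.column_stack([xs[r], ys[r]]),
                likelihood=lik[r],
            )
        )
    return observations


def read_predictions(
    path: str | Path, scheme: LandmarkScheme, clip_id: str | None = None
) -> list[FrameObservation]:
    """Read a pose-estimation prediction CSV (x/y/likelihood per landmark).

    ``clip_id`` defaults to the file's stem.  Landmarks are located by the
    ``bodyparts`` header row, so column order is irrelevant.
    """
    frame = _read_dialect(path, expect_likelihood=True)
    return _extract(frame, path, scheme, clip_id, with_likelihood=True)


def read_manual_labels(
    path: str | Path, scheme: LandmarkScheme, clip_id: str | None = None
) -> list[FrameObservation]:
    """Read a manual-annotation CSV (x/y per landmark, no likelihood).

    Present points get likelihood 1; blank cells become NaN coordinates with
    likelihood 0.
    """
    frame = _read_dialect(path, expect_likelihood=False)
    return _extract(frame, path, scheme, clip_id, with_likelihood=False)


def _to_table(
    frames: Sequence[FrameObservation],
    scheme: LandmarkScheme,
    scorer: str,
    with_likelihood: bool,
) -> pd.DataFrame:
    per_lm = ("x", "y", "likelihood") if with_likelihood else ("x", "y")
    columns = pd.MultiIndex.from_tuples(
        [(scorer, name, c) for name in scheme.names for c in per_lm],
        names=("scorer", "bodyparts", "coords"),
    )
    rows = []
    for obs in frames:
        row = []
        for j in range(len(scheme)):
            row.extend(obs.coords[j])
            if with_likelihood:
                row.append(obs.likelihood[j])
        rows.append(row)
    index = pd.Index([obs.frame_index for obs in frames])
    return pd.DataFrame(rows, index=index, columns=columns)


def write_predictions(
    frames: Sequence[FrameObservation],
    path: str | Path,
    scheme: LandmarkScheme,
    scorer: str = "facegest",
) -> None:
    """Write predictions in the three-header-row dialect (round-trip exact)."""
    _to_table(frames, scheme, scorer, with_likelihood=True).to_csv(path)


def write_manual_labels(
    frames: Sequence[FrameObservation],
    path: str | Path,
    scheme: LandmarkScheme,
    scorer: str = "manual",
) -> None:
    """Write manual annotations (x/y only); likelihood-0 points become blanks."""
    table = _to_table(frames, scheme, scorer, with_likelihood=False)
    # blank out points the annotator did not place
    for obs_i, obs in enumerate(frames):
        for j, name in enumerate(scheme.names):
            if obs.likelihood[j] == 0 or np.isnan(obs.coords[j]).any():
                table.iloc[obs_i, 2 * j] = np.nan
                table.iloc[obs_i, 2 * j + 1] = np.nan
    table.to_csv(path)


# ---------------------------------------------------------------------------
# Clip labels


def read_clip_labels(path: str | Path) -> dict[str, ClipLabel]:
    """Read the clip-label CSV (columns clip_id, voicing, context[, individual_id])."""
    table = pd.read_csv(path, dtype=str)
    required = {"clip_id", "voicing", "context"}
    if not required.issubset(table.columns):
        raise DialectError(f"{path}: clip-label table needs columns {sorted(required)}")
    labels: dict[str, ClipLabel] = {}
    for row in table.itertuples(index=False):
        if row.clip_id in labels:
            raise DialectError(f"{path}: duplicate clip_id {row.clip_id!r}")
        labels[row.clip_id] = ClipLabel(
            clip_id=row.clip_id,
            voicing=row.voicing,
            context=row.context,
            individual_id=getattr(row, "individual_id", None),
        )
    return labels


def write_clip_labels(labels: Mapping[str, ClipLabel] | Iterable[ClipLabel], path: str | Path) -> None:
    values = labels.values() if isinstance(labels, Mapping) else labels
    pd.DataFrame(
        [
            {
                "clip_id": lab.clip_id,
                "voicing": lab.voicing,
                "context": lab.context,
                "individual_id": lab.individual_id,
            }
            for lab in values
        ]
    ).to_csv(path, index=False)
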