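"""Feature tabulation and correlation-based pruning.

A feature table holds one row per fully-crossed frame and one column per
normalized pair distance, excluding the normalization pair itself (that
column is identically 1).  For a 13-landmark scheme this yields 77
feature columns.  Highly inter-correlated columns are then reduced to one
representative per correlated group by a deterministic greedy elimination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import DistanceVector
from .io_dlc import ClipLabel
from .scheme import LandmarkScheme

#: Non-feature columns of a feature table.
LABEL_COLUMNS: tuple[str, ...] = ("clip_id", "frame_index", "voicing", "context")


def feature_columns(scheme: LandmarkScheme, sep: str = "-") -> list[str]:
    """Pair-named feature columns: all pairs minus the constant normalization pair."""
    labels = scheme.pair_labels(sep=sep)
    labels.pop(scheme.normalization_index)
    return labels


def split_columns(table: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Partition a feature table's columns into (features, labels)."""
    labels = [c for c in table.columns if c in LABEL_COLUMNS]
    feats = [c for c in table.columns if c not in LABEL_COLUMNS]
    return feats, labels


def tabulate(
    vectors: Sequence[DistanceVector],
    scheme: LandmarkScheme,
    clip_labels: Mapping[str, ClipLabel] | None = None,
) -> pd.DataFrame:
    """Build the labeled feature table from normalized distance vectors.

    Every input must be normalized and fully crossed; the normalization-pair
    entry (identically 1) is dropped, leaving n(n-1)/2 - 1 feature columns.
    Clip identity is preserved, and voicing/context labels are attached when
    a clip-label map is given.
    """
    cols = feature_columns(scheme)
    norm_idx = scheme.normalization_index
    rows = np.empty((len(vectors), len(cols)))
    meta: dict[str, list] = {"clip_id": [], "frame_index": []}
    for r, dv in enumerate(vectors):
        if not dv.normalized or not dv.fully_crossed:
            raise ValueError(
                f"clip {dv.clip_id!r} frame {dv.frame_index}: tabulate requires "
                "normalized, fully-crossed distance vectors"
            )
        rows[r] = np.delete(dv.values, norm_idx)
        meta["clip_id"].append(dv.clip_id)
        meta["frame_index"].append(dv.frame_index)
    table = pd.DataFrame(rows, columns=cols)
    table["clip_id"] = meta["clip_id"]
    table["frame_index"] = meta["frame_index"]
    if clip_labels is not None:
        table["voicing"] = [clip_labels[c].voicing for c in meta["clip_id"]]
        table["context"] = [clip_labels[c].context for c in meta["clip_id"]]
    if table[cols].isna().any().any():
        raise ValueError("feature table contains NaN cells")
    return table


@dataclass
class PruningReport:
    """Outcome of correlation pruning: what survived, what fell, and why."""

    retained: list[str]
    dropped: list[tuple[str, str, float]]  # (column, partner it clashed with, |r|)
    threshold: float


def prune_correlated(
    table: pd.DataFrame, threshold: float = 0.75
) -> tuple[pd.DataFrame, PruningReport]:
    """Drop features until no retained pair's |Pearson r| exceeds ``threshold``.

    Greedy elimination: repeatedly locate the most correlated remaining pair
    above the threshold and drop whichever member has the larger mean
    absolute correlation with all other remaining features (ties: drop the
    later column in canonical order).  Deterministic given table and
    threshold; one representative of each correlated group survives.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    feats, labels = split_columns(table)
    if len(table) < 2:
        raise ValueError("pruning needs at least 2 rows")
    values = table[feats].to_numpy(dtype=float)
    if (values.std(axis=0) == 0).any():
        constant = [f for f, s in zip(feats, values.std(axis=0)) if s == 0]
        raise ValueError(f"zero-variance feature columns: {', '.join(constant)}")

    corr = np.abs(np.corrcoef(values, rowvar=False))
    np.fill_diagonal(corr, 0.0)
    alive = list(range(len(feats)))
    dropped: list[tuple[str, str, float]] = []
    while True:
        sub = corr[np.ix_(alive, alive)]
        flat = int(np.argmax(sub))
        i, j = divmod(flat, len(alive))
        if sub[i, j] <= threshold:
            break
        a, b = alive[i], alive[j]
        others = [k for k in alive if k not in (a, b)]
        mean_a = corr[a, others].mean() if others else 0.0
        mean_b = corr[b, others].mean() if others else 0.0
        # drop the member more entangled with the rest; ties fall on the later column
        victim, partner = (a, b) if mean_a > mean_b else (b, a)
        dropped.append((feats[victim], feats[partner], float(corr[a, b])))
        alive.remove(victim)
    retained = [feats[k] for k in alive]
    reduced = table[retained + labels].copy()
    return reduced, PruningReport(retained=retained, dropped=dropped, threshold=threshold)
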