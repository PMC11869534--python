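"""Landmark scheme: the ordered set of named facial key points.

The default scheme is the 13-point face layout used for cotton-top
tamarins (four points per eye, nose tip, four mouth points).  Distances
are later normalized by the inner-eye pair, which stays rigid under
facial movement.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterator

import yaml

#: Canonical 13 facial key points, in scheme order.
DEFAULT_LANDMARKS: tuple[str, ...] = (
    "RightEye_top",
    "RightEye_Bottom",
    "RightEye_Inner",
    "RightEye_Outer",
    "LeftEye_top",
    "LeftEye_Bottom",
    "LeftEye_Inner",
    "LeftEye_Outer",
    "Nosetip",
    "Mouth_Top",
    "Mouth_Bottom",
    "Mouth_Right",
    "Mouth_Left",
)

#: Pair whose distance is invariant to facial movement; used for normalization.
DEFAULT_NORMALIZATION_PAIR: tuple[str, str] = ("RightEye_Inner", "LeftEye_Inner")


@dataclass(frozen=True)
class LandmarkScheme:
    """Ordered landmark names plus the designated normalization pair."""

    names: tuple[str, ...] = DEFAULT_LANDMARKS
    normalization_pair: tuple[str, str] = DEFAULT_NORMALIZATION_PAIR

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        if len(self.names) < 3:
            raise ValueError("a scheme needs at least 3 landmarks")
        if len(self.normalization_pair) != 2:
            raise ValueError("normalization_pair must name exactly two landmarks")
        missing = set(self.normalization_pair) - set(self.names)
        if missing:
            raise ValueError(f"normalization_pair not in scheme: {sorted(missing)}")
        if self.normalization_pair[0] == self.normalization_pair[1]:
            raise ValueError("normalization_pair landmarks must differ")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def n_pairs(self) -> int:
        """Number of unordered landmark pairs, n(n-1)/2."""
        n = len(self.names)
        return n * (n - 1) // 2

    def iter_pairs(self) -> Iterator[tuple[str, str]]:
        """Pairs in condensed (lexicographic-by-index) order."""
        return combinations(self.names, 2)

    def pair_labels(self, sep: str = "-") -> list[str]:
        """Column labels like ``"Nosetip-Mouth_Top"`` in condensed order."""
        return [f"{a}{sep}{b}" for a, b in self.iter_pairs()]

    def condensed_index(self, name_a: str, name_b: str) -> int:
        """Position of the (unordered) pair in the condensed distance vector."""
        i, j = sorted((self.index(name_a), self.index(name_b)))
        if i == j:
            raise ValueError("a pair needs two distinct landmarks")
        n = len(self.names)
        return n * i - i * (i + 1) // 2 + (j - i - 1)

    @property
    def normalization_index(self) -> int:
        """Condensed index of the normalization pair."""
        return self.condensed_index(*self.normalization_pair)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_yaml(cls, path: str | Path) -> "LandmarkScheme":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            names=tuple(raw["landmarks"]),
            normalization_pair=tuple(raw["normalization_pair"]),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "landmarks": list(self.names),
                    "normalization_pair": list(self.normalization_pair),
                },
                fh,
                sort_keys=False,
            )


DEFAULT_SCHEME = LandmarkScheme()
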