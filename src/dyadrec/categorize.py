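"""Movement-direction categorization of bounding-box trajectories.

Each frame-to-frame displacement of the box center is coded into one of two
categorical schemes:

* **simple** (3 codes): 0 no horizontal movement, 1 right, 2 left — only the
  horizontal displacement component is used;
* **detailed** (9 codes): 0 no movement, 1 left, 2 up-left, 3 up, 4 up-right,
  5 right, 6 down-right, 7 down, 8 down-left.

"Up" means toward the top of the image, i.e. decreasing y under the image
coordinate convention.  Category boundaries are sign-based with a per-axis
dead-zone ``eps``: a displacement component of magnitude <= eps counts as no
movement along that axis.  The default eps of 0 treats any nonzero
displacement as movement, which suits integer-quantized tracker output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .trajectory import BoundingBox, BoxTrajectory


class CategorizationError(ValueError):
    pass


@dataclass(frozen=True)
class CoordinateSystem:
    """A finite movement-direction code set (code 0 = no movement)."""

    name: str
    n_categories: int

    def __post_init__(self) -> None:
        if self.name not in ("simple", "detailed"):
            raise CategorizationError(f"unknown coordinate system {self.name!r}")

    @property
    def codes(self) -> np.ndarray:
        return np.arange(self.n_categories)


SIMPLE = CoordinateSystem("simple", 3)
DETAILED = CoordinateSystem("detailed", 9)

#: detailed code -> simple code (horizontal component only)
DETAILED_TO_SIMPLE = {0: 0, 1: 2, 2: 2, 3: 0, 4: 1, 5: 1, 6: 1, 7: 0, 8: 2}

# (sign(dx), sign(dy)) -> detailed code, with y-down image coordinates
_DETAILED_BY_SIGN = {
    (0, 0): 0,
    (-1, 0): 1,   # left
    (-1, -1): 2,  # up-left
    (0, -1): 3,   # up
    (1, -1): 4,   # up-right
    (1, 0): 5,    # right
    (1, 1): 6,    # down-right
    (0, 1): 7,    # down
    (-1, 1): 8,   # down-left
}


def get_system(name: str) -> CoordinateSystem:
    if name == "simple":
        return SIMPLE
    if name == "detailed":
        return DETAILED
    raise CategorizationError(f"unknown coordinate system {name!r}")


@dataclass
class CategoricalSeries:
    """A per-frame-transition movement-direction code sequence.

    Length is one less than the trajectory it came from (one code per
    transition between consecutive frames).
    """

    codes: np.ndarray
    fps: float
    system: CoordinateSystem
    dyad_id: str = ""
    role: str = ""
    label: str = field(default="")

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= self.system.n_categories):
            raise CategorizationError(
                f"codes outside 0..{self.system.n_categories - 1} for system {self.system.name!r}"
            )
        if self.fps <= 0:
            raise CategorizationError("fps must be positive")

    def __len__(self) -> int:
        return len(self.codes)

    def head(self, n: int) -> "CategoricalSeries":
        return replace(self, codes=self.codes[:n].copy())

    def category_frequencies(self) -> np.ndarray:
        """Empirical probability of each code, length ``n_categories``."""
        return np.bincount(self.codes, minlength=self.system.n_categories) / max(len(self.codes), 1)


def box_center(box: BoundingBox) -> tuple[float, float]:
    """Center of a bounding box, ``(x + w/2, y + h/2)`` in pixels."""
    if not box.valid:
        raise CategorizationError(
            f"frame {box.frame}: box is invalid; run interpolate_gaps before extracting centers"
        )
    return (box.x + box.w / 2.0, box.y + box.h / 2.0)


def classify_step(dx: float, dy: float, system: CoordinateSystem, eps: float = 0.0) -> int:
    """Code a single displacement (dx, dy) under the chosen scheme.

    dy is in image coordinates: negative dy is upward on screen.
    """
    if eps < 0:
        raise CategorizationError("eps must be >= 0")
    if not (np.isfinite(dx) and np.isfinite(dy)):
        raise CategorizationError("displacement must be finite")
    sx = 0 if abs(dx) <= eps else (1 if dx > 0 else -1)
    if system.name == "simple":
        return {0: 0, 1: 1, -1: 2}[sx]
    sy = 0 if abs(dy) <= eps else (1 if dy > 0 else -1)
    return _DETAILED_BY_SIGN[(sx, sy)]


def _classify_steps(dx: np.ndarray, dy: np.ndarray, system: CoordinateSystem, eps: float) -> np.ndarray:
    sx = np.where(np.abs(dx) <= eps, 0, np.sign(dx)).astype(int)
    if system.name == "simple":
        return np.choose(sx + 1, [2, 0, 1])
    sy = np.where(np.abs(dy) <= eps, 0, np.sign(dy)).astype(int)
    lut = np.empty((3, 3), dtype=np.int64)
    for (a, b), code in _DETAILED_BY_SIGN.items():
        lut[a + 1, b + 1] = code
    return lut[sx + 1, sy + 1]


def categorize(
    traj: BoxTrajectory,
    system: CoordinateSystem | str = DETAILED,
    eps: float = 0.0,
    role: str = "",
) -> CategoricalSeries:
    """Convert a fully valid trajectory into a movement-direction series.

    ``codes[t]`` describes the displacement of the box center from frame t
    to frame t+1, so the output has length N-1.
    """
    if isinstance(system, str):
        system = get_system(system)
    if eps < 0:
        raise CategorizationError("eps must be >= 0")
    if not traj.valid.all():
        raise CategorizationError(
            "trajectory contains invalid frames; apply interpolate_gaps first"
        )
    centers = traj.centers
    steps = np.diff(centers, axis=0)
    codes = _classify_steps(steps[:, 0], steps[:, 1], system, eps)
    return CategoricalSeries(
        codes, fps=traj.fps, system=system, dyad_id=traj.dyad_id, role=role,
        label=traj.feature_label,
    )


def simplify(series: CategoricalSeries) -> CategoricalSeries:
    """Project a detailed-system series onto the simple system."""
    if series.system.name == "simple":
        return replace(series, codes=series.codes.copy())
    lut = np.array([DETAILED_TO_SIMPLE[c] for c in range(9)])
    return replace(series, codes=lut[series.codes], system=SIMPLE)


#: left<->right swaps under a horizontal mirror, per system
_MIRROR_SIMPLE = np.array([0, 2, 1])
_MIRROR_DETAILED = np.array([0, 5, 4, 3, 2, 1, 8, 7, 6])


def mirror_horizontal(series: CategoricalSeries) -> CategoricalSeries:
    """Swap left/right codes, for mirrored-camera geometries.

    When the two partners face each other (or one is seen through a mirror),
    the same physical direction appears reversed in one of the series; apply
    this to one series before cross-recurrence to make directions
    commensurate.
    """
    lut = _MIRROR_SIMPLE if series.system.name == "simple" else _MIRROR_DETAILED
    return replace(series, codes=lut[series.codes])
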