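"""Categorical cross-recurrence: recurrence plot and diagonal-wise lag profile.

Two equal-length categorical series recur at time pair (i, j) when their
codes match exactly.  The binary recurrence plot puts the parent (leader
candidate) on the horizontal axis and the infant (follower candidate) on the
vertical axis.  Summing matches along diagonals of the plot gives the
recurrence rate as a function of temporal offset — the lag profile:

    rr[tau] = 100 / (N - |tau|) * sum_t 1[parent(t) == infant(t - tau)]

Under this convention an infant echoing the parent's movement Delta frames
late produces a profile peak at tau = -Delta: negative peak lags mean the
parent leads, positive ones mean the infant leads.

Each diagonal is normalised by its own number of aligned pairs (N - |tau|),
so recurrence rates remain comparable across lags despite the shrinking
overlap at the plot's corners.  The profile is computed by a matrix-free
shifted comparison in O(N * L); the full N x N plot is materialised only
where the anisotropic line measures need it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categorize import CategoricalSeries


class CrqaError(ValueError):
    pass


@dataclass
class RecurrencePlot:
    """Binary cross-recurrence matrix.

    ``matrix[i, j] = 1`` iff the infant's code at time i equals the parent's
    code at time j; parent time runs along the horizontal axis (columns),
    infant time along the vertical axis (rows).
    """

    matrix: np.ndarray
    fps: float
    dyad_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise CrqaError(f"recurrence plot must be square, got {self.matrix.shape}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def recurrence_rate(self) -> float:
        """Global percentage of recurrent points."""
        return 100.0 * float(self.matrix.mean())


@dataclass
class LagProfile:
    """Recurrence rate per lag over a symmetric grid of frame offsets."""

    lags: np.ndarray          # frame offsets, -L..+L
    rr: np.ndarray            # percent, 0..100
    n_overlap: np.ndarray     # aligned pairs per lag
    fps: float
    dyad_id: str = ""
    condition: str = field(default="real")

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=np.int64)
        self.rr = np.asarray(self.rr, dtype=float)
        self.n_overlap = np.asarray(self.n_overlap, dtype=np.int64)
        if not (len(self.lags) == len(self.rr) == len(self.n_overlap)):
            raise CrqaError("lag grid, rr and n_overlap must have equal lengths")

    def __len__(self) -> int:
        return len(self.lags)

    @property
    def lag_ms(self) -> np.ndarray:
        return 1000.0 * self.lags / self.fps

    @property
    def lag_s(self) -> np.ndarray:
        return self.lags / self.fps

    def mean_rr(self) -> float:
        return float(self.rr.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_frames": self.lags,
                "lag_ms": self.lag_ms,
                "rr_percent": self.rr,
                "n_overlap": self.n_overlap,
                "condition": self.condition,
            }
        )


def _check_pair(parent: CategoricalSeries, infant: CategoricalSeries) -> None:
    if len(parent) != len(infant):
        raise CrqaError(
            f"series lengths differ ({len(parent)} vs {len(infant)}); apply trim_pair first"
        )
    if parent.fps != infant.fps:
        raise CrqaError(f"fps mismatch: {parent.fps} vs {infant.fps}")
    if parent.system.name != infant.system.name:
        raise CrqaError(
            f"coordinate systems differ: {parent.system.name} vs {infant.system.name}"
        )


def cross_recurrence_matrix(parent: CategoricalSeries, infant: CategoricalSeries) -> RecurrencePlot:
    """Full binary recurrence plot between two equal-length series."""
    _check_pair(parent, infant)
    matrix = infant.codes[:, None] == parent.codes[None, :]
    return RecurrencePlot(matrix, fps=parent.fps, dyad_id=parent.dyad_id or infant.dyad_id)


def lag_profile(
    parent: CategoricalSeries,
    infant: CategoricalSeries,
    max_lag_s: float = 4.0,
    condition: str = "real",
) -> LagProfile:
    """Diagonal-wise recurrence rate over lags -max_lag_s .. +max_lag_s.

    At 25 fps and max_lag_s=4 this spans 201 lag bins.  The peak's sign
    follows the leader-follower convention described in the module
    docstring (negative = parent leads).
    """
    _check_pair(parent, infant)
    L_float = max_lag_s * parent.fps
    L = int(round(L_float))
    if abs(L_float - L) > 1e-9:
        raise CrqaError(f"max_lag_s*fps must be an integer frame count, got {L_float}")
    n = len(parent)
    if n <= L:
        raise CrqaError(f"series length {n} must exceed the lag window {L}")
    p, f = parent.codes, infant.codes
    lags = np.arange(-L, L + 1)
    rr = np.empty(2 * L + 1)
    n_overlap = n - np.abs(lags)
    for k, tau in enumerate(lags):
        if tau >= 0:
            matches = p[tau:] == f[: n - tau]
        else:
            matches = p[: n + tau] == f[-tau:]
        rr[k] = 100.0 * int(matches.sum()) / matches.size
    return LagProfile(
        lags, rr, n_overlap, fps=parent.fps,
        dyad_id=parent.dyad_id or infant.dyad_id, condition=condition,
    )


def lag_profile_from_matrix(plot: RecurrencePlot, max_lag_s: float = 4.0) -> LagProfile:
    """Lag profile by summing the recurrence plot's diagonals.

    Slower than :func:`lag_profile` but agrees with it exactly; kept as the
    cross-checkable second route.  Diagonal offset +tau of the matrix
    (infant rows i, parent columns j = i + tau) collects pairs where
    parent time leads infant time by tau... concretely, matrix[i, i + tau]
    compares infant(i) with parent(i + tau), i.e. parent(t) vs
    infant(t - tau), matching the direct computation.
    """
    L = int(round(max_lag_s * plot.fps))
    n = plot.n
    if n <= L:
        raise CrqaError(f"series length {n} must exceed the lag window {L}")
    lags = np.arange(-L, L + 1)
    rr = np.array(
        [
            100.0 * int(np.diagonal(plot.matrix, offset=tau).sum()) / (n - abs(tau))
            for tau in lags
        ]
    )
    return LagProfile(lags, rr, n - np.abs(lags), fps=plot.fps, dyad_id=plot.dyad_id)


def subsample_profile(profile: LagProfile, target_rate_hz: float) -> LagProfile:
    """Keep every (fps / target_rate)-th lag, retaining lag 0 and endpoints.

    25 fps profiles over +-4 s (201 bins) subsampled to 6.25 Hz retain the
    51 lags {-100, -96, ..., 96, 100} frames.
    """
    stride_f = profile.fps / target_rate_hz
    stride = int(round(stride_f))
    if abs(stride_f - stride) > 1e-9 or stride < 1:
        raise CrqaError(
            f"fps {profile.fps} not divisible by target rate {target_rate_hz}"
        )
    keep = profile.lags % stride == 0
    return LagProfile(
        profile.lags[keep], profile.rr[keep], profile.n_overlap[keep],
        fps=profile.fps, dyad_id=profile.dyad_id, condition=profile.condition,
    )


def peak_lag(profile: LagProfile) -> tuple[float, str]:
    """Location of the profile maximum in ms, with the leader reading.

    Negative peak lag means the parent leads, positive the infant, zero is
    synchronous.  Ties are resolved toward lag 0, then toward the negative
    side, with a warning.
    """
    if len(profile) == 0:
        raise CrqaError("empty profile")
    rr = profile.rr
    best = rr.max()
    tied = np.flatnonzero(rr == best)
    if len(tied) > 1:
        warnings.warn(
            f"profile peak tied across {len(tied)} lags; choosing the one nearest lag 0",
            stacklevel=2,
        )
        tied_lags = profile.lags[tied]
        # nearest to zero; negative wins a symmetric tie
        order = np.lexsort((tied_lags, np.abs(tied_lags)))
        lag_frames = int(tied_lags[order[0]])
    else:
        lag_frames = int(profile.lags[tied[0]])
    lag_ms = 1000.0 * lag_frames / profile.fps
    if lag_frames < 0:
        label = "parent-leading"
    elif lag_frames > 0:
        label = "infant-leading"
    else:
        label = "synchronous"
    return lag_ms, label


def average_profiles(profiles: list[LagProfile]) -> tuple[LagProfile, np.ndarray]:
    """Per-lag mean profile across dyads, plus the per-lag SD.

    All profiles must share the same lag grid and fps.  The SD is the
    population standard deviation across the supplied profiles (0 for a
    single profile).
    """
    if not profiles:
        raise CrqaError("no profiles to average")
    ref = profiles[0]
    for p in profiles[1:]:
        if len(p) != len(ref) or np.any(p.lags != ref.lags) or p.fps != ref.fps:
            raise CrqaError("profiles have mismatched lag grids")
    stack = np.vstack([p.rr for p in profiles])
    mean = LagProfile(
        ref.lags.copy(), stack.mean(axis=0), ref.n_overlap.copy(),
        fps=ref.fps, condition=ref.condition,
    )
    return mean, stack.std(axis=0)
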