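"""Synthetic coupled leader-follower trajectories with known ground truth.

Emulates the free-play episodes the pipeline targets: a parent sweeps an
object smoothly left and right in front of an infant (sinusoidal horizontal
path with a small, slower vertical undulation), and the infant's head echoes
the object's direction of movement after a fixed frame lag.  The follower
copies the *direction* (sign pair) of the leader's displacement, not its
position, so the injected coupling lives exactly in the categorical space
the cross-recurrence pipeline measures and its ground-truth lag is exact by
construction.

Degradations mimic real tracker output: with probability ``noise_p`` a
follower step's direction is replaced by a uniformly random one (infant
motor jitter / tracking error), and each frame of either trajectory is
independently marked invalid with probability ``dropout_p`` (tracker
misses, to exercise interpolation).  The first and last frames stay valid —
a tracker is initialised on its first frame — so dropout produces interior
gaps.

All randomness flows from explicit seeds; no global state is touched.
Cohort generation derives per-dyad seeds deterministically from a single
master seed, so a cohort is reproducible regardless of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .trajectory import BoxTrajectory

#: the nine (sign(dx), sign(dy)) direction cells, index-aligned for sampling
_SIGN_PAIRS = [(0, 0), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1)]


class SimulationError(ValueError):
    pass


@dataclass
class DyadSimParams:
    """Ground-truth parameters for one simulated parent-infant dyad.

    Defaults reflect a typical free-play episode: 25 frames/s video, an
    episode of ~23.5 s, an object swept ~120 px side to side every 4 s with
    a small vertical undulation, and the infant echoing the object's
    direction 6 frames (240 ms) later.
    """

    n_frames: int = 588
    fps: float = 25.0
    lag_frames: int = 6
    amplitude_px: float = 120.0
    period_s: float = 4.0
    vertical_amplitude_px: float = 6.0
    vertical_period_s: float = 2.7
    noise_p: float = 0.1
    dropout_p: float = 0.05
    box_w: float = 40.0
    box_h: float = 40.0
    seed: int | np.random.SeedSequence = 0
    max_lag_s: float = 4.0

    def validate(self) -> None:
        if not (0 <= self.noise_p < 1 and 0 <= self.dropout_p < 1):
            raise SimulationError("noise_p and dropout_p must lie in [0, 1)")
        if self.lag_frames < 0:
            raise SimulationError("lag_frames must be >= 0")
        min_frames = self.lag_frames + 2 * self.fps * self.max_lag_s
        if self.n_frames <= min_frames:
            raise SimulationError(
                f"n_frames={self.n_frames} too short: need > {min_frames:.0f} "
                f"(lag_frames + twice the lag window)"
            )
        if self.fps <= 0 or self.period_s <= 0 or self.vertical_period_s <= 0:
            raise SimulationError("fps and periods must be positive")


def _leader_positions(params: DyadSimParams, rng: np.random.Generator) -> np.ndarray:
    """(N, 2) center positions for the leader's sweep, random phase per dyad."""
    t = np.arange(params.n_frames)
    phase = rng.uniform(0, 2 * np.pi)
    phase_v = rng.uniform(0, 2 * np.pi)
    x = 376.0 + params.amplitude_px * np.sin(2 * np.pi * t / (params.period_s * params.fps) + phase)
    y = 291.0 + params.vertical_amplitude_px * np.sin(
        2 * np.pi * t / (params.vertical_period_s * params.fps) + phase_v
    )
    return np.column_stack([x, y])


def _sign_pairs_of_steps(steps: np.ndarray) -> np.ndarray:
    return np.sign(steps).astype(int)


def _follower_positions(
    leader_centers: np.ndarray, params: DyadSimParams, rng: np.random.Generator
) -> np.ndarray:
    """Build follower centers whose step directions copy the leader's, lagged.

    Step t (from frame t to t+1) copies the sign pair of the leader's step
    t - lag; the first ``lag`` steps, which have no leader history, get
    random directions.  Magnitudes are resampled per frame, so only the
    direction — the quantity the pipeline codes — is coupled.
    """
    n_steps = params.n_frames - 1
    leader_signs = _sign_pairs_of_steps(np.diff(leader_centers, axis=0))
    signs = np.empty((n_steps, 2), dtype=int)
    lag = params.lag_frames
    for t in range(n_steps):
        if t < lag:
            signs[t] = _SIGN_PAIRS[rng.integers(9)]
        else:
            signs[t] = leader_signs[t - lag]
    # direction noise: replace with a uniformly random direction cell
    noisy = rng.random(n_steps) < params.noise_p
    for t in np.flatnonzero(noisy):
        signs[t] = _SIGN_PAIRS[rng.integers(9)]
    mag_x = rng.uniform(0.5, 2.5, size=n_steps)
    mag_y = rng.uniform(0.2, 1.0, size=n_steps)
    steps = np.column_stack([signs[:, 0] * mag_x, signs[:, 1] * mag_y])
    start = np.array([376.0, 150.0])
    centers = np.vstack([start, start + np.cumsum(steps, axis=0)])
    return centers


def _to_trajectory(
    centers: np.ndarray,
    params: DyadSimParams,
    rng: np.random.Generator,
    feature_label: str,
    dyad_id: str,
) -> BoxTrajectory:
    n = len(centers)
    valid = rng.random(n) >= params.dropout_p
    valid[0] = True
    valid[-1] = True
    return BoxTrajectory(
        x=centers[:, 0] - params.box_w / 2.0,
        y=centers[:, 1] - params.box_h / 2.0,
        w=np.full(n, params.box_w),
        h=np.full(n, params.box_h),
        valid=valid,
        fps=params.fps,
        feature_label=feature_label,
        dyad_id=dyad_id,
    )


def generate_dyad(
    params: DyadSimParams, dyad_id: str = "dyad"
) -> tuple[BoxTrajectory, BoxTrajectory, dict]:
    """One simulated dyad: (parent trajectory, infant trajectory, truth).

    Deterministic given ``params.seed``.  The truth record stores the
    injected lag, noise and dropout levels for downstream recovery checks.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    leader = _leader_positions(params, rng)
    follower = _follower_positions(leader, params, rng)
    parent = _to_trajectory(leader, params, rng, "object", dyad_id)
    infant = _to_trajectory(follower, params, rng, "infant_face", dyad_id)
    truth = {
        "dyad_id": dyad_id,
        "lag_frames": params.lag_frames,
        "lag_ms": 1000.0 * params.lag_frames / params.fps,
        "noise_p": params.noise_p,
        "dropout_p": params.dropout_p,
        "n_frames": params.n_frames,
        "fps": params.fps,
        "seed": str(params.seed),
    }
    return parent, infant, truth


@dataclass
class CohortHeterogeneity:
    """Per-dyad jitter applied when generating a cohort.

    ``length_range_s`` draws each dyad's episode length uniformly (defaults
    span 15-41 s, i.e. 375-1027 frames at 25 fps); ``lag_jitter_frames``
    adds a uniform integer jitter in [-j, +j] to the injected lag.
    """

    length_range_s: tuple[float, float] | None = (15.0, 41.0)
    lag_jitter_frames: int = 0


@dataclass
class Dyad:
    """A simulated dyad bundle as produced by :func:`generate_cohort`."""

    dyad_id: str
    parent: BoxTrajectory
    infant: BoxTrajectory
    truth: dict = field(default_factory=dict)


def generate_cohort(
    n_dyads: int = 21,
    params: DyadSimParams | None = None,
    heterogeneity: CohortHeterogeneity | None = None,
    master_seed: int = 0,
) -> list[Dyad]:
    """Generate a cohort of dyads with deterministically derived seeds.

    Per-dyad episode lengths and lags are jittered per the heterogeneity
    settings; pass ``heterogeneity=None`` for a homogeneous cohort (all dyads
    share the base parameters and differ only in their random streams).
    """
    if n_dyads < 2:
        raise SimulationError("a cohort needs at least 2 dyads")
    base = params if params is not None else DyadSimParams()
    seeds = np.random.SeedSequence(master_seed).spawn(n_dyads + 1)
    jitter_rng = np.random.default_rng(seeds[-1])
    dyads = []
    for i in range(n_dyads):
        p = replace(base, seed=seeds[i])
        if heterogeneity is not None:
            if heterogeneity.length_range_s is not None:
                lo, hi = heterogeneity.length_range_s
                p.n_frames = int(round(jitter_rng.uniform(lo, hi) * base.fps))
            if heterogeneity.lag_jitter_frames:
                j = heterogeneity.lag_jitter_frames
                p.lag_frames = max(0, base.lag_frames + int(jitter_rng.integers(-j, j + 1)))
        dyad_id = f"dyad{i + 1:02d}"
        parent, infant, truth = generate_dyad(p, dyad_id=dyad_id)
        dyads.append(Dyad(dyad_id, parent, infant, truth))
    return dyads
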