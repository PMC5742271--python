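"""Surrogate baselines for validating cross-recurrence lag profiles.

Two controls distinguish genuine temporal coupling from chance and from
task-driven similarity:

* **shuffled baseline** — the infant series is randomly permuted and the
  lag profile recomputed against the intact parent series.  Shuffling
  preserves each series' category frequencies, so the baseline sits at the
  chance level 100 * sum_c p_c q_c and is flat across lags; any peak in the
  real profile above it reflects temporal structure, not marginal
  composition.
* **random-pair baseline** — the parent is paired with infants from other
  dyads performing the same task.  Residual recurrence here is produced by
  the task itself rather than this dyad's interaction.

Both baselines are bit-for-bit reproducible under a fixed seed; cohort runs
fan the pipeline seed out to per-dyad streams through a deterministic
spawn so results do not depend on dyad ordering.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .categorize import CategoricalSeries
from .crqa import CrqaError, LagProfile, average_profiles, lag_profile
from .trajectory import trim_pair


def shuffled_baseline(
    parent: CategoricalSeries,
    infant: CategoricalSeries,
    max_lag_s: float = 4.0,
    n_shuffles: int = 1,
    seed: int | np.random.SeedSequence | None = 0,
) -> LagProfile:
    """Average lag profile of the parent against shuffled infant surrogates.

    Each surrogate permutes the infant's codes uniformly at random, keeping
    marginal category frequencies exact.  ``n_shuffles`` independent
    surrogates are averaged; one shuffle is the literal single-surrogate
    control, more reduce the baseline's Monte-Carlo variance.
    """
    if n_shuffles < 1:
        raise CrqaError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(n_shuffles):
        surrogate = replace(infant, codes=rng.permutation(infant.codes))
        profiles.append(lag_profile(parent, surrogate, max_lag_s, condition="shuffled"))
    mean, _ = average_profiles(profiles)
    mean.dyad_id = parent.dyad_id
    mean.condition = "shuffled"
    return mean


def random_pair_baseline(
    parent: CategoricalSeries,
    pool: list[CategoricalSeries],
    k: int = 5,
    max_lag_s: float = 4.0,
    seed: int | np.random.SeedSequence | None = 0,
) -> LagProfile:
    """Average lag profile of the parent against k non-partner infants.

    The pool must not contain the parent's own infant.  Each sampled infant
    is trimmed with the parent to their common length before profiling,
    and the k profiles are averaged on the shared lag grid.
    """
    if k < 1:
        raise CrqaError("k must be >= 1")
    if k > len(pool):
        raise CrqaError(f"k={k} exceeds pool size {len(pool)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=k, replace=False)
    profiles = []
    for idx in chosen:
        p_trim, other = trim_pair(parent, pool[idx])
        profiles.append(lag_profile(p_trim, other, max_lag_s, condition="random_paired"))
    mean, _ = average_profiles(profiles)
    mean.dyad_id = parent.dyad_id
    mean.condition = "random_paired"
    return mean


def chance_recurrence_rate(parent: CategoricalSeries, infant: CategoricalSeries) -> float:
    """Analytic chance level 100 * sum_c p_c q_c for independent series."""
    p = parent.category_frequencies()
    q = infant.category_frequencies()
    return 100.0 * float(p @ q)


def spawn_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Derive n independent, order-stable child seed sequences."""
    return np.random.SeedSequence(master_seed).spawn(n)
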