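"""Topographic consistency test (TCT).

A permutation test for the presence of evoked activity: if subjects
share a common field topography at a latency, the GFP of the
across-subject mean map is larger than when each subject's electrode
values are randomly shuffled (which preserves every subject's own GFP
but destroys cross-subject spatial alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EvokedDataset
from .topographic import gfp

__all__ = ["TCTResult", "tct_test", "significant_runs"]


@dataclass
class TCTResult:
    condition: str
    p: np.ndarray = field(repr=False)  # per time point
    observed_gfp: np.ndarray = field(repr=False)
    n_permutations: int
    seed: int | None

    def __post_init__(self) -> None:
        pmin = 1.0 / (self.n_permutations + 1)
        if (self.p < pmin - 1e-12).any() or (self.p > 1 + 1e-12).any():
            raise ValueError("p-values outside (0, 1] or below the permutation floor")


def tct_test(
    evoked: EvokedDataset,
    condition: str,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> TCTResult:
    """Run the TCT for one condition at every time point.

    Observed statistic: GFP of the across-subject mean topography.
    Null: independently permute the channel values within each
    subject's topography at each time point, re-average, recompute the
    GFP.  p = (1 + #{null >= observed}) / (1 + n_permutations).
    """
    stack = evoked.stack(condition)  # (n_subj, C, T)
    if stack.shape[0] < 2:
        raise ValueError("TCT needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    observed = gfp(stack.mean(axis=0), axis=0)
    exceed = np.zeros(stack.shape[2], dtype=int)
    chunk = max(1, int(1e6 // stack.size))
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        block = np.broadcast_to(stack, (b, *stack.shape))
        shuffled = rng.permuted(block, axis=2)
        null = gfp(shuffled.mean(axis=1), axis=1)  # (b, T)
        exceed += (null >= observed).sum(axis=0)
        done += b
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return TCTResult(
        condition=condition,
        p=p,
        observed_gfp=observed,
        n_permutations=n_permutations,
        seed=seed,
    )


def significant_runs(result: TCTResult, alpha: float = 0.05) -> list[tuple[int, int]]:
    """Maximal half-open sample runs with p < alpha (no correction applied;
    callers impose their own duration criteria)."""
    sig = result.p < alpha
    runs = []
    start = None
    for t, s in enumerate(sig):
        if s and start is None:
            start = t
        elif not s and start is not None:
            runs.append((start, t))
            start = None
    if start is not None:
        runs.append((start, len(sig)))
    return runs
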