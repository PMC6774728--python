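"""Monte-Carlo null for observing the same SNP in multiple replicates.

If de novo mutations are neutral and uniformly distributed over the
genome, observing a mutation is equivalent to drawing marbles from a vase
without replacement: the vase holds one marble per evaluable genomic
position, and each replicate draws as many marbles as it has observed
mutations.  The probability that the empirically observed number of
positions is shared across replicates under this null is estimated by
simulation; a grid over vase sizes asks how small the pool of mutable
sites would have to be before the observed overlap stops being surprising.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass
class OverlapNullConfig:
    """Parameters of the marble-drawing null model."""

    vase_size: int                 # evaluable genomic positions
    draws: Sequence[int]           # mutations observed per replicate
    observed: int                  # positions shared by all replicates
    n_sims: int = 100_000
    seed: int = 0

    def __post_init__(self):
        self.draws = tuple(int(k) for k in self.draws)
        if any(k > self.vase_size for k in self.draws):
            raise ValueError("draws cannot exceed the vase size")
        if self.observed > min(self.draws):
            raise ValueError("observed overlap cannot exceed the smallest draw")


@dataclasses.dataclass
class OverlapResult:
    p_value: float
    distribution: np.ndarray       # simulated overlap count per simulation
    expected: float                # mean simulated overlap
    observed: int
    mode: str                      # "all" or "pairwise"


def _draw_distinct(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k distinct uniform integers from [0, n); rejection top-up, O(k)."""
    out = np.unique(rng.integers(0, n, size=k))
    while out.size < k:
        extra = rng.integers(0, n, size=k - out.size)
        out = np.unique(np.concatenate([out, extra]))
    return out


def simulate_overlap(cfg: OverlapNullConfig, mode: str = "all") -> OverlapResult:
    """Estimate P(overlap >= observed) under the uniform-drawing null.

    ``mode="all"`` counts positions drawn by every replicate (repeated in
    all of them); ``mode="pairwise"`` counts positions drawn by at least
    two replicates.  The p-value uses the add-one estimator
    (1 + #exceedances) / (1 + n_sims), which never reports exactly zero
    from a finite simulation.
    """
    if mode not in ("all", "pairwise"):
        raise ValueError("mode must be 'all' or 'pairwise'")
    rng = np.random.default_rng(cfg.seed)
    n_rep = len(cfg.draws)
    need = n_rep if mode == "all" else 2
    counts = np.empty(cfg.n_sims, dtype=np.int64)
    for s in range(cfg.n_sims):
        pooled = np.concatenate(
            [_draw_distinct(rng, cfg.vase_size, k) for k in cfg.draws]
        )
        pooled.sort()
        # runs of equal values; within-replicate draws are distinct, so a
        # run of length m means the position was drawn by m replicates
        is_new = np.empty(pooled.size, dtype=bool)
        is_new[0] = True
        np.not_equal(pooled[1:], pooled[:-1], out=is_new[1:])
        run_ids = np.cumsum(is_new)
        run_len = np.bincount(run_ids)
        counts[s] = int((run_len >= need).sum())
    exceed = int((counts >= cfg.observed).sum())
    p = (1 + exceed) / (1 + cfg.n_sims)
    return OverlapResult(p, counts, float(counts.mean()), cfg.observed, mode)


def vase_size_grid(observed: int, draws: int, grid: Sequence[int],
                   n_sims: int = 10_000, seed: int = 0,
                   mode: str = "all") -> pd.DataFrame:
    """Overlap null across a grid of vase sizes.

    Every replicate draws the same number of marbles (the empirical
    minimum across replicates), and for each vase size N the expected
    overlap and P(overlap >= observed) are reported.  The returned frame
    carries ``largest_nonextreme_N`` in ``attrs``: the largest grid N at
    which the observed overlap is not extreme (p > 0.05) — i.e. how large
    the pool of mutable sites may be while still producing the observed
    recurrence by chance.
    """
    rows = []
    ss = np.random.SeedSequence(seed).spawn(len(grid))
    for N, child in zip(grid, ss):
        if N < draws:
            raise ValueError("grid vase sizes must be >= draws")
        cfg = OverlapNullConfig(vase_size=int(N), draws=(draws,) * 3,
                                observed=observed, n_sims=n_sims,
                                seed=child.generate_state(1)[0] % (2**31))
        res = simulate_overlap(cfg, mode=mode)
        rows.append({"vase_size": int(N), "expected_overlap": res.expected,
                     "p_value": res.p_value})
    df = pd.DataFrame(rows)
    ok = df[df["p_value"] > 0.05]
    df.attrs["largest_nonextreme_N"] = (
        int(ok["vase_size"].max()) if len(ok) else None
    )
    return df
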