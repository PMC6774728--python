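"""Reading, writing and resampling of popoolation2-style ``sync`` tables.

A sync file is a tab-separated table with one row per genomic site:
chromosome, 1-based position, reference base, then one ``A:T:C:G:N:del``
count block per sample (here: per time point).  A block of all zeros
encodes a missing observation (zero coverage), which is distinct from an
observed frequency of 0%.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: column order of a sync count block
SYNC_BASES = ("A", "T", "C", "G", "N", "del")
#: indices of the four nucleotides within a count block
NUC_IDX = {"A": 0, "T": 1, "C": 2, "G": 3}


@dataclasses.dataclass
class SyncTable:
    """Per-site nucleotide counts across time points for one species/replicate.

    Attributes
    ----------
    chrom : array of str, shape (n_sites,)
    pos : array of int, shape (n_sites,)
        1-based positions, strictly increasing within each chromosome.
    ref : array of str, shape (n_sites,)
        Reference base per site.
    counts : array of int, shape (n_sites, n_timepoints, 6)
        Counts in ``A:T:C:G:N:del`` order.
    timepoints : list
        Labels (typically sampling days) for the time-point axis.  The sync
        dialect itself carries no labels; they are kept here for bookkeeping
        and dropped on :func:`write_sync`.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    counts: np.ndarray
    timepoints: list = dataclasses.field(default_factory=list)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 3 or self.counts.shape[2] != 6:
            raise ValueError("counts must have shape (n_sites, n_timepoints, 6)")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if not self.timepoints:
            self.timepoints = list(range(self.counts.shape[1]))
        if len(self.timepoints) != self.counts.shape[1]:
            raise ValueError("timepoints length does not match count blocks")

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.counts.shape[1]

    def coverage(self) -> np.ndarray:
        """Total read depth per (site, time point), N and del included."""
        return self.counts.sum(axis=2)

    def missing(self) -> np.ndarray:
        """Boolean mask of zero-coverage (site, time point) cells."""
        return self.coverage() == 0

    def copy(self) -> "SyncTable":
        return SyncTable(
            self.chrom.copy(), self.pos.copy(), self.ref.copy(),
            self.counts.copy(), list(self.timepoints),
        )


def read_sync(path, timepoints: Sequence | None = None) -> SyncTable:
    """Parse a sync file.

    Raises
    ------
    ValueError
        If a row carries a different number of count blocks than the first
        row (the offending line number is reported), or a block is malformed.
    """
    path = Path(path)
    chroms, poss, refs, rows = [], [], [], []
    n_blocks = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected at least 4 columns")
            blocks = fields[3:]
            if n_blocks is None:
                n_blocks = len(blocks)
            elif len(blocks) != n_blocks:
                raise ValueError(
                    f"{path}:{lineno}: {len(blocks)} count blocks, expected {n_blocks}"
                )
            try:
                row = [[int(x) for x in b.split(":")] for b in blocks]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed count block") from exc
            if any(len(b) != 6 for b in row):
                raise ValueError(f"{path}:{lineno}: count block is not A:T:C:G:N:del")
            chroms.append(fields[0])
            poss.append(int(fields[1]))
            refs.append(fields[2])
            rows.append(row)
    counts = np.asarray(rows, dtype=np.int64) if rows else np.zeros((0, 0, 6), np.int64)
    tps = list(timepoints) if timepoints is not None else None
    return SyncTable(np.asarray(chroms, dtype=object), np.asarray(poss),
                     np.asarray(refs, dtype=object), counts,
                     tps if tps is not None else [])


def write_sync(table: SyncTable, path) -> None:
    """Write a :class:`SyncTable` in the popoolation2 dialect (lossless)."""
    with open(path, "w") as fh:
        for i in range(table.n_sites):
            blocks = "\t".join(
                ":".join(map(str, table.counts[i, j])) for j in range(table.n_timepoints)
            )
            fh.write(f"{table.chrom[i]}\t{table.pos[i]}\t{table.ref[i]}\t{blocks}\n")


def mask_coverage(table: SyncTable, coverage_floor: float = 10.0,
                  sd_multiplier: float = 3.0, min_mean_coverage: float = 10.0):
    """Apply the per-time-point coverage mask and time-point drop rule.

    Per time point, a site is set to "not available" (all-zero block) when
    its coverage is ``<= coverage_floor`` or falls outside
    mean +/- ``sd_multiplier``*SD, where mean and SD are taken over the
    non-missing sites of that time point.  Time points whose mean coverage
    over non-missing sites is below ``min_mean_coverage`` are removed
    entirely.

    Returns
    -------
    (SyncTable, dict)
        The masked table and a report with per-time-point masked-site counts
        and the labels of dropped time points.
    """
    table = table.copy()
    cov = table.coverage().astype(float)
    was_missing = cov == 0
    report = {"masked_per_timepoint": {}, "dropped_timepoints": []}
    keep_tp = []
    for j, label in enumerate(table.timepoints):
        obs = cov[~was_missing[:, j], j]
        if obs.size == 0:
            report["dropped_timepoints"].append(label)
            continue
        if obs.size >= 2:
            mean, sd = obs.mean(), obs.std(ddof=1)
        else:
            mean, sd = obs.mean(), 0.0
        bad = (cov[:, j] <= coverage_floor) | (cov[:, j] < mean - sd_multiplier * sd) \
            | (cov[:, j] > mean + sd_multiplier * sd)
        bad &= ~was_missing[:, j]
        table.counts[bad, j, :] = 0
        report["masked_per_timepoint"][label] = int(bad.sum())
        # mean over sites still observed after masking decides the drop
        remaining = table.counts[:, j, :].sum(axis=1)
        remaining = remaining[remaining > 0]
        if remaining.size == 0 or remaining.mean() < min_mean_coverage:
            report["dropped_timepoints"].append(label)
        else:
            keep_tp.append(j)
    table.counts = table.counts[:, keep_tp, :]
    table.timepoints = [table.timepoints[j] for j in keep_tp]
    return table, report


def downsample_coverage(table: SyncTable, target_mean: float,
                        seed: int | np.random.Generator = 0) -> SyncTable:
    """Binomially thin read counts to an average per-position coverage.

    Each time point whose mean coverage (over non-missing sites) exceeds
    ``target_mean`` has every base count thinned with probability
    ``target_mean / current_mean``; expected allele frequencies are
    unchanged and the shape of the empirical coverage distribution is kept.
    Time points already at or below the target are left untouched.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = table.copy()
    cov = table.coverage().astype(float)
    for j in range(table.n_timepoints):
        obs = cov[cov[:, j] > 0, j]
        if obs.size == 0:
            continue
        current = obs.mean()
        if current <= target_mean:
            continue
        p = target_mean / current
        table.counts[:, j, :] = rng.binomial(table.counts[:, j, :], p)
    return table
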