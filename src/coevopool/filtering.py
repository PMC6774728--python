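"""Locus filtering for pooled-sequencing allele-frequency time series.

Starting from a :class:`~coevopool.sync.SyncTable`, this module derives
per-locus derived-allele frequency trajectories and applies the filtering
cascade used for isogenic-start evolution experiments:

1. indel proximity mask (+/- 10 bp around every indel call),
2. ancestral purity (any site already variable at time point 0 is an
   artifact, because the populations start from a single cell),
3. coverage-scaled detection limit (a trajectory must exceed the limit at
   more than one time point to be distinguishable from sequencing error),
4. missing-data cap,

followed by collapsing of tightly linked SNPs (within 1000 bp, highly
correlated trajectories) that cannot be told apart from a single
structural event.  Every step's removals are recorded in a ledger so the
cascade is auditable.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sync import SyncTable, NUC_IDX

# severity ranking used when collapsed SNPs carry different effect labels
EFFECT_SEVERITY = {
    "nonsense/frameshift": 3,
    "missense": 2,
    "synonymous": 1,
    "intergenic": 0,
}
# effect classes whose carriers are unlikely to be selection targets
NEUTRAL_EFFECTS = ("synonymous", "intergenic")


@dataclasses.dataclass
class FilterConfig:
    """Thresholds of the locus-filtering cascade.

    Defaults are the host (algal) settings; :meth:`for_species` switches the
    coverage-scaled thresholds between host and virus.
    """

    detection_threshold: float = 0.25       # host 0.25, virus 0.05
    min_timepoints_above: int = 2           # "more than one time point"
    ancestral_purity: float = 0.99          # ancestral allele >= 99% at t0
    indel_mask_radius: int = 10             # bp up- and downstream, inclusive
    max_missing: int = 3                    # host 3, virus 1
    coverage_floor: float = 10.0            # <=10x masked
    coverage_sd_multiplier: float = 3.0     # mean +/- 3 SD
    min_mean_coverage: float = 10.0         # drop whole time point below this
    collapse_window: int = 1000             # bp
    collapse_correlation: float = 0.9       # Pearson r over shared time points
    downsample_target: float = 1000.0       # virus coverage downsampling

    def __post_init__(self):
        for name in ("detection_threshold", "ancestral_purity"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.indel_mask_radius < 0 or self.collapse_window < 0:
            raise ValueError("radii and windows must be >= 0")

    @classmethod
    def for_species(cls, species: str, **overrides) -> "FilterConfig":
        if species == "host":
            base = dict(detection_threshold=0.25, max_missing=3)
        elif species == "virus":
            base = dict(detection_threshold=0.05, max_missing=1)
        else:
            raise ValueError("species must be 'host' or 'virus'")
        base.update(overrides)
        return cls(**base)


@dataclasses.dataclass
class TrajectoryMatrix:
    """Loci x time points derived-allele frequencies with metadata.

    Attributes
    ----------
    freqs : DataFrame
        Index: locus id ("chrom:pos"); columns: time-point labels; values:
        derived-allele frequency in [0,1] or NaN for missing.
    meta : DataFrame
        Index matching ``freqs``; columns ``chrom``, ``pos``, ``derived``
        (base), ``effect`` (label or None) and ``members`` (list of locus
        ids merged into the row; singleton before collapsing).
    """

    freqs: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if not self.freqs.index.equals(self.meta.index):
            raise ValueError("freqs and meta must share the same locus index")
        vals = self.freqs.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
                raise ValueError("frequencies must lie in [0,1]")

    @property
    def n_loci(self) -> int:
        return len(self.freqs)

    def subset(self, keep) -> "TrajectoryMatrix":
        return TrajectoryMatrix(self.freqs.loc[keep].copy(), self.meta.loc[keep].copy())

    def with_effects(self, effects: pd.DataFrame) -> "TrajectoryMatrix":
        """Attach effect labels from a (chrom, pos, effect) table."""
        meta = self.meta.copy()
        lookup = {(c, p): e for c, p, e in
                  effects[["chrom", "pos", "effect"]].itertuples(index=False)}
        meta["effect"] = [lookup.get((c, p), meta["effect"].iloc[i])
                          for i, (c, p) in enumerate(zip(meta["chrom"], meta["pos"]))]
        return TrajectoryMatrix(self.freqs.copy(), meta)


def derive_frequencies(table: SyncTable) -> TrajectoryMatrix:
    """Compute the derived-allele frequency trajectory of every site.

    The derived allele of a site is the nonreference nucleotide with the
    highest mean frequency across non-missing time points (ties broken by
    base order A<C<G<T for determinism).  Per time point the frequency is
    derived count / total nucleotide count; zero-coverage blocks propagate
    as missing.  Sites whose reference base is not A/C/G/T are skipped with
    a warning.
    """
    n_sites, n_tp = table.n_sites, table.n_timepoints
    nuc = table.counts[:, :, :4].astype(float)          # A,T,C,G
    total = nuc.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(total[:, :, None] > 0, nuc / total[:, :, None], np.nan)

    ids, rows, chroms, poss, derived = [], [], [], [], []
    # alphabetical preference order over the A,T,C,G block layout
    alpha_order = [NUC_IDX[b] for b in ("A", "C", "G", "T")]
    for i in range(n_sites):
        ref = table.ref[i]
        if ref not in NUC_IDX:
            warnings.warn(f"site {table.chrom[i]}:{table.pos[i]}: reference base "
                          f"{ref!r} not in A/C/G/T, skipped")
            continue
        mean_f = np.nanmean(freq[i], axis=0) if not np.all(np.isnan(freq[i])) \
            else np.zeros(4)
        mean_f = np.where(np.isnan(mean_f), 0.0, mean_f)
        best, best_val = None, -1.0
        for k in alpha_order:
            if k == NUC_IDX[ref]:
                continue
            if mean_f[k] > best_val + 1e-12:   # strict improvement: ties keep earlier
                best, best_val = k, mean_f[k]
        base = "ATCG"[best]
        ids.append(f"{table.chrom[i]}:{table.pos[i]}")
        rows.append(freq[i, :, best])
        chroms.append(table.chrom[i])
        poss.append(int(table.pos[i]))
        derived.append(base)

    freqs = pd.DataFrame(rows, index=ids, columns=list(table.timepoints))
    meta = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "derived": derived,
         "effect": [None] * len(ids), "members": [[i] for i in ids]},
        index=ids,
    )
    return TrajectoryMatrix(freqs, meta)


def filter_trajectories(traj: TrajectoryMatrix,
                        indel_positions: Iterable[tuple] = (),
                        cfg: FilterConfig | None = None):
    """Apply the filtering cascade; return the survivors and a removal ledger.

    Steps run in a fixed order — indel mask, ancestral purity, detection
    limit, missingness — and the ledger records how many loci each step
    removed, so ``input = output + sum(removed)`` always holds.

    Parameters
    ----------
    indel_positions : iterable of (chrom, pos)
        Indel calls; every SNP within ``cfg.indel_mask_radius`` bp
        (inclusive) of one, on the same chromosome, is discarded.
    """
    cfg = cfg or FilterConfig()
    ledger = {"input": traj.n_loci}
    vals = traj.freqs.to_numpy(dtype=float)
    meta = traj.meta
    alive = np.ones(traj.n_loci, dtype=bool)

    # 1. indel proximity mask
    by_chrom: dict = {}
    for c, p in indel_positions:
        by_chrom.setdefault(c, []).append(int(p))
    hit = np.zeros(traj.n_loci, dtype=bool)
    if by_chrom:
        for i, (c, p) in enumerate(zip(meta["chrom"], meta["pos"])):
            ps = by_chrom.get(c)
            if ps and any(abs(p - q) <= cfg.indel_mask_radius for q in ps):
                hit[i] = True
    ledger["indel_mask"] = int((alive & hit).sum())
    alive &= ~hit

    # 2. ancestral purity: derived > 1 - purity at the first time point
    t0 = vals[:, 0]
    impure = ~np.isnan(t0) & (t0 > 1.0 - cfg.ancestral_purity)
    ledger["ancestral"] = int((alive & impure).sum())
    alive &= ~impure

    # 3. detection limit: must exceed the threshold at >= min time points
    above = np.nansum(vals > cfg.detection_threshold, axis=1)
    undetected = above < cfg.min_timepoints_above
    ledger["detection"] = int((alive & undetected).sum())
    alive &= ~undetected

    # 4. missingness cap
    n_missing = np.isnan(vals).sum(axis=1)
    gappy = n_missing > cfg.max_missing
    ledger["missingness"] = int((alive & gappy).sum())
    alive &= ~gappy

    out = traj.subset(traj.freqs.index[alive])
    ledger["output"] = out.n_loci
    return out, ledger


def _severity(effect) -> int:
    return EFFECT_SEVERITY.get(effect, -1)


def collapse_linked_snps(traj: TrajectoryMatrix,
                         cfg: FilterConfig | None = None) -> TrajectoryMatrix:
    """Merge SNPs that are physically close and move together.

    Two loci link when they sit on the same chromosome within
    ``cfg.collapse_window`` bp and their trajectories have Pearson
    correlation >= ``cfg.collapse_correlation`` over at least three shared
    non-missing time points; clusters are the connected components
    (single linkage).  A cluster becomes one row with member-averaged
    frequencies (per non-missing time point), the position of its first
    member, and the most severe member effect.
    """
    cfg = cfg or FilterConfig()
    n = traj.n_loci
    if n <= 1:
        return traj.subset(traj.freqs.index)
    vals = traj.freqs.to_numpy(dtype=float)
    meta = traj.meta

    order = np.lexsort((meta["pos"].to_numpy(), meta["chrom"].astype(str).to_numpy()))
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    chrom_arr = meta["chrom"].to_numpy()
    pos_arr = meta["pos"].to_numpy()
    for a_idx in range(len(order)):
        i = order[a_idx]
        for b_idx in range(a_idx + 1, len(order)):
            j = order[b_idx]
            if chrom_arr[j] != chrom_arr[i]:
                break
            if pos_arr[j] - pos_arr[i] > cfg.collapse_window:
                break
            shared = ~np.isnan(vals[i]) & ~np.isnan(vals[j])
            if shared.sum() < 3:
                continue  # correlation undefined, pair cannot link
            x, y = vals[i, shared], vals[j, shared]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if r >= cfg.collapse_correlation:
                union(i, j)

    clusters: dict = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    ids, rows, meta_rows = [], [], []
    for root in sorted(clusters, key=lambda r: (str(chrom_arr[r]), pos_arr[r],
                                                min(clusters[r]))):
        members = sorted(clusters[root], key=lambda i: (pos_arr[i], i))
        sub = vals[members]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            merged = np.nanmean(sub, axis=0)
        first = members[0]
        member_ids = []
        for m in members:
            member_ids.extend(meta["members"].iloc[m])
        effects = [meta["effect"].iloc[m] for m in members]
        best_effect = max(effects, key=_severity)
        ids.append(traj.freqs.index[first])
        rows.append(merged)
        meta_rows.append({"chrom": chrom_arr[first], "pos": int(pos_arr[first]),
                          "derived": meta["derived"].iloc[first],
                          "effect": best_effect, "members": member_ids})

    freqs = pd.DataFrame(rows, index=ids, columns=traj.freqs.columns)
    return TrajectoryMatrix(freqs, pd.DataFrame(meta_rows, index=ids))


def tally_effects(traj: TrajectoryMatrix) -> dict:
    """Count loci per predicted-effect class.

    Returns a dict with one count per class (missing labels under
    ``unannotated``) and the fraction of annotated loci that are
    synonymous or intergenic — the hitchhiker-dominated classes.
    """
    counts = {k: 0 for k in EFFECT_SEVERITY}
    counts["unannotated"] = 0
    for e in traj.meta["effect"]:
        if e in EFFECT_SEVERITY:
            counts[e] += 1
        else:
            counts["unannotated"] += 1
    annotated = sum(counts[k] for k in EFFECT_SEVERITY)
    neutralish = sum(counts[k] for k in NEUTRAL_EFFECTS)
    counts["fraction_synonymous_intergenic"] = (
        neutralish / annotated if annotated else float("nan")
    )
    return counts


def write_trajectories(traj: TrajectoryMatrix, path) -> None:
    """Write a trajectory TSV: locus id, effect, one column per time point."""
    out = traj.freqs.copy()
    out.insert(0, "effect", [e if e is not None else "NA" for e in traj.meta["effect"]])
    out.to_csv(path, sep="\t", index_label="locus", na_rep="NA")


def read_trajectories(path) -> TrajectoryMatrix:
    df = pd.read_csv(path, sep="\t", index_col="locus", na_values="NA")
    effect = df.pop("effect")
    chrom = [i.rsplit(":", 1)[0] for i in df.index]
    pos = [int(i.rsplit(":", 1)[1]) for i in df.index]
    freq_cols = {}
    for c in df.columns:
        try:
            freq_cols[c] = float(c) if "." in c else int(c)
        except ValueError:
            freq_cols[c] = c
    df = df.rename(columns=freq_cols)
    meta = pd.DataFrame({"chrom": chrom, "pos": pos,
                         "derived": [None] * len(df),
                         "effect": [None if e == "NA" else e for e in effect],
                         "members": [[i] for i in df.index]}, index=df.index)
    return TrajectoryMatrix(df, meta)
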