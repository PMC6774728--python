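"""Infection-assay processing: susceptibility calls, resistance and
infectivity ranges, phenotypic match/mismatch intervals and the
resistance-growth trade-off.

The assay grows each host clone (isolated from one sampling day) against
virus populations from every sampled day, in four technical replicates,
alongside virus-free controls.  A clone is susceptible to a virus when its
growth with the virus is clearly below its virus-free growth (mean + 2 SD
with virus below mean - 2 SD of the control) or is negative outright.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

SUSCEPTIBLE = "susceptible"
RESISTANT = "resistant"


def call_susceptibility(virus_growth: Sequence[float],
                        control_growth: Sequence[float]) -> str:
    """Binary call from technical-replicate growth rates.

    Susceptible iff mean_v + 2 SD_v < mean_c - 2 SD_c (strict) or
    mean_v < 0; SDs use denominator n-1.  Requires >= 2 replicates on
    each side.
    """
    v = np.asarray(virus_growth, dtype=float)
    c = np.asarray(control_growth, dtype=float)
    v, c = v[~np.isnan(v)], c[~np.isnan(c)]
    if c.size < 2:
        raise ValueError("missing or insufficient control replicates")
    if v.size < 2:
        raise ValueError("need at least two virus-exposed replicates")
    mv, sv = v.mean(), v.std(ddof=1)
    mc, sc = c.mean(), c.std(ddof=1)
    if mv < 0 or (mv + 2 * sv < mc - 2 * sc):
        return SUSCEPTIBLE
    return RESISTANT


@dataclasses.dataclass
class InfectionMatrix:
    """Host clone x virus time point growth rates with susceptibility calls.

    Built from a long-format assay table with columns ``clone``,
    ``host_day`` (day the clone was isolated), ``virus_day`` (NaN for
    virus-free controls), ``rep``, ``growth_rate`` and ``is_control``.
    """

    data: pd.DataFrame
    calls: pd.DataFrame = None  # index: clone, columns: virus_day

    def __post_init__(self):
        if self.calls is None:
            self.calls = self._make_calls()

    @classmethod
    def from_csv(cls, path) -> "InfectionMatrix":
        df = pd.read_csv(path)
        df["is_control"] = df["is_control"].astype(bool)
        return cls(df)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def _make_calls(self) -> pd.DataFrame:
        df = self.data
        controls = {
            clone: grp["growth_rate"].to_numpy()
            for clone, grp in df[df["is_control"]].groupby("clone")
        }
        clones = sorted(df["clone"].unique())
        vdays = sorted(df.loc[~df["is_control"], "virus_day"].dropna().unique())
        calls = pd.DataFrame(index=clones, columns=vdays, dtype=object)
        grouped = df[~df["is_control"]].groupby(["clone", "virus_day"])
        for (clone, vday), grp in grouped:
            if clone not in controls:
                raise ValueError(f"clone {clone!r} has no virus-free control")
            calls.loc[clone, vday] = call_susceptibility(
                grp["growth_rate"].to_numpy(), controls[clone])
        return calls

    def host_day_of(self) -> pd.Series:
        """Map clone -> isolation day."""
        return self.data.groupby("clone")["host_day"].first()

    def n_comparisons(self) -> int:
        """Number of clone-by-virus-time-point cells assayed."""
        return int(self.calls.notna().sum().sum())

    def control_growth(self) -> pd.Series:
        """Mean virus-free growth rate per clone."""
        return (self.data[self.data["is_control"]]
                .groupby("clone")["growth_rate"].mean())


@dataclasses.dataclass
class PhenoInterval:
    start: float
    end: float
    state: str                  # "match" or "mismatch"
    trigger: str                # "initial" | "resistance evolution" | "infectivity evolution"


def ranges(matrix: InfectionMatrix):
    """Resistance range per clone and infectivity range per virus time point.

    Resistance range: proportion of assayed virus time points a clone
    resists; infectivity range: proportion of assayed clones a virus
    population infects.  Missing cells are excluded from denominators;
    empty rows/columns yield NaN.
    """
    calls = matrix.calls
    res = calls.apply(lambda row: (row == RESISTANT).sum() / row.notna().sum()
                      if row.notna().any() else np.nan, axis=1)
    inf = calls.apply(lambda col: (col == SUSCEPTIBLE).sum() / col.notna().sum()
                      if col.notna().any() else np.nan, axis=0)
    return res, inf


def _pop_resistant(matrix: InfectionMatrix) -> pd.DataFrame:
    """host_day x virus_day: any clone from that day resistant?"""
    host_day = matrix.host_day_of()
    calls = matrix.calls.copy()
    calls["__hday"] = host_day.reindex(calls.index)
    grouped = calls.groupby("__hday")
    res = grouped.agg(lambda col: (col == RESISTANT).any())
    return res


def classify_match_mismatch(matrix: InfectionMatrix) -> list:
    """Tile the assayed period into phenotypic match/mismatch intervals.

    The experiment starts in a phenotypic match (the ancestral virus
    infects the ancestral host).  Resistance evolution at host day h:
    clones from h resist some past-or-contemporary virus day that clones
    from the previous host day did not resist, and the resistance is
    maintained at the next host day.  Infectivity evolution at virus day
    v: some host day's clones, resistant to the preceding virus day, are
    infected by virus from v, maintained at the next virus day.  Events
    are placed at the day the phenotype is first observed; a phenotype not
    maintained at the next time step is ignored.  Phenotype presence is
    judged by any clone carrying it, irrespective of its frequency.
    """
    popR = _pop_resistant(matrix)
    host_days = sorted(popR.index)
    virus_days = sorted(popR.columns)
    if len(host_days) < 2 and len(virus_days) < 2:
        return [PhenoInterval(min(host_days + virus_days),
                              max(host_days + virus_days), "match", "initial")]

    events = []  # (day, kind)
    # resistance evolution: scan host days (need previous and next for
    # novelty and maintenance)
    for i in range(1, len(host_days) - 1):
        h_prev, h, h_next = host_days[i - 1], host_days[i], host_days[i + 1]
        for v in virus_days:
            if v > h:
                continue  # past and contemporary virus only
            gained = popR.loc[h, v] and not popR.loc[h_prev, v]
            maintained = popR.loc[h_next, v]
            if gained and maintained:
                events.append((h, "resistance evolution"))
                break
    # infectivity evolution: scan virus days
    for j in range(1, len(virus_days) - 1):
        v_prev, v, v_next = virus_days[j - 1], virus_days[j], virus_days[j + 1]
        for h in host_days:
            was_resistant = popR.loc[h, v_prev]
            infected_now = not popR.loc[h, v]
            maintained = not popR.loc[h, v_next]
            if was_resistant and infected_now and maintained:
                events.append((v, "infectivity evolution"))
                break
    events.sort()

    first = min(host_days[0], virus_days[0])
    last = max(host_days[-1], virus_days[-1])
    state_of = {"resistance evolution": "mismatch", "infectivity evolution": "match"}
    intervals = []
    cur_start, cur_state, cur_trigger = first, "match", "initial"
    for day, kind in events:
        new_state = state_of[kind]
        if new_state == cur_state:
            continue
        if day > cur_start:
            intervals.append(PhenoInterval(cur_start, day, cur_state, cur_trigger))
        cur_start, cur_state, cur_trigger = day, new_state, kind
    intervals.append(PhenoInterval(cur_start, last, cur_state, cur_trigger))
    return intervals


@dataclasses.dataclass
class TradeoffResult:
    r: float
    p_value: float
    n: int
    defined: bool


def tradeoff_correlation(control_growth: pd.Series,
                         resistance_range: pd.Series) -> TradeoffResult:
    """Pearson correlation of virus-free growth with resistance range.

    A negative correlation indicates a cost of resistance.  Returns an
    undefined (flagged) result when either variable has zero variance.
    Requires >= 3 clones present in both series.
    """
    joined = pd.concat([control_growth.rename("g"),
                        resistance_range.rename("r")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need at least three clones")
    g, r = joined["g"].to_numpy(), joined["r"].to_numpy()
    if np.std(g) == 0 or np.std(r) == 0:
        return TradeoffResult(float("nan"), float("nan"), len(joined), False)
    rho, p = stats.pearsonr(g, r)
    return TradeoffResult(float(rho), float(p), len(joined), True)
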