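"""Diversity dynamics: per-time-point nucleotide diversity, sweep calls,
selection-coefficient estimates, population-size smoothing and the
fit-vs-growth association.

Nucleotide diversity is the mean expected heterozygosity 2p(1-p) over the
variable loci with data at a time point (no genome-length normalisation:
only relative changes through time are interpreted).  A selective sweep
shows up as a marked drop of diversity between consecutive time points.
Selection coefficients are Malthusian (log-fitness) coefficients of a
haploid single-locus model, estimated from the log-odds change of the
allele frequency; both organisms here are asexual, so the sweeping
genotype behaves as a single haploid locus.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .filtering import TrajectoryMatrix


@dataclasses.dataclass
class DiversitySeries:
    """Per-time-point diversity with per-replicate normalisation."""

    table: pd.DataFrame  # columns: timepoint, pi, n_loci, relative

    @property
    def timepoints(self):
        return list(self.table["timepoint"])

    def pi(self) -> np.ndarray:
        return self.table["pi"].to_numpy()


@dataclasses.dataclass
class SweepCall:
    interval: tuple
    drop: float          # fractional diversity loss over the interval
    passed: bool


@dataclasses.dataclass
class SelectionEstimate:
    locus: str
    s: float             # per generation (Malthusian)
    p0: float
    p1: float
    generations: float
    clamped: bool = False


def nucleotide_diversity(traj: TrajectoryMatrix) -> DiversitySeries:
    """pi(t) = mean of 2 p (1-p) over loci with data at t.

    Loci missing at a time point are excluded from that time point's mean;
    a time point where every locus is missing gets NaN.  ``relative`` is
    pi normalised by its maximum over the series.
    """
    if traj.n_loci == 0:
        raise ValueError("need at least one locus")
    vals = traj.freqs.to_numpy(dtype=float)
    het = 2.0 * vals * (1.0 - vals)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pi = np.nanmean(het, axis=0)
    n_loci = (~np.isnan(vals)).sum(axis=0)
    maxpi = np.nanmax(pi) if np.any(~np.isnan(pi)) else np.nan
    rel = pi / maxpi if maxpi and maxpi > 0 else np.full_like(pi, np.nan)
    table = pd.DataFrame({"timepoint": list(traj.freqs.columns), "pi": pi,
                          "n_loci": n_loci, "relative": rel})
    return DiversitySeries(table)


def detect_sweeps(div: DiversitySeries, drop_threshold: float = 0.5) -> list:
    """Flag intervals whose diversity falls by at least ``drop_threshold``.

    Works on ratios, so it is invariant to rescaling pi.  Returns one
    :class:`SweepCall` per consecutive pair of time points with data,
    ``passed`` marking intervals with pi(t+1) <= (1-threshold) * pi(t).
    """
    tps = div.timepoints
    pi = div.pi()
    have = ~np.isnan(pi)
    idx = np.flatnonzero(have)
    if idx.size < 2:
        raise ValueError("need at least two time points with diversity")
    calls = []
    for a, b in zip(idx[:-1], idx[1:]):
        if pi[a] <= 0:
            drop = 0.0
        else:
            drop = 1.0 - pi[b] / pi[a]
        calls.append(SweepCall((tps[a], tps[b]), float(drop),
                               bool(pi[b] <= (1.0 - drop_threshold) * pi[a]
                                    and pi[a] > 0)))
    return calls


def estimate_selection(p0: float, p1: float, t0: float, t1: float,
                       generations_per_day: float = 1.0,
                       detection_limit: float = 0.05,
                       locus: str = "") -> SelectionEstimate:
    """Selection coefficient from the log-odds change of an allele frequency.

    Haploid model with Malthusian fitness: one generation maps p to
    p e^s / (p e^s + 1 - p), so logit(p) increases by exactly s per
    generation and s = [logit(p1) - logit(p0)] / (generations elapsed).
    Boundary frequencies (0 or 1) are clamped to half the detection limit
    away from the boundary and flagged.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    eps = detection_limit / 2.0
    clamped = False
    q0, q1 = float(p0), float(p1)
    for name, q in (("p0", q0), ("p1", q1)):
        if not 0 <= q <= 1:
            raise ValueError(f"{name} must be in [0,1]")
    if q0 <= 0 or q0 >= 1:
        q0 = np.clip(q0, eps, 1 - eps)
        clamped = True
    if q1 <= 0 or q1 >= 1:
        q1 = np.clip(q1, eps, 1 - eps)
        clamped = True
    gens = (t1 - t0) * generations_per_day
    s = (np.log(q1 / (1 - q1)) - np.log(q0 / (1 - q0))) / gens
    return SelectionEstimate(locus, float(s), float(p0), float(p1),
                             float(gens), clamped)


@dataclasses.dataclass
class PopSizeSeries:
    """Daily abundances with spline-smoothed log10 trajectories."""

    table: pd.DataFrame          # columns: day, host, virus
    _splines: dict = dataclasses.field(default_factory=dict, repr=False)

    def smoothed_log10(self, species: str, day) -> np.ndarray | float:
        """Evaluate the smoothed log10 abundance at (an array of) days."""
        spline, lo, hi = self._splines[species]
        day_arr = np.asarray(day, dtype=float)
        if np.any(day_arr < lo) or np.any(day_arr > hi):
            raise ValueError(f"day outside observed range [{lo}, {hi}]")
        out = spline(day_arr)
        return float(out) if out.ndim == 0 else out

    def growth_rate(self, species: str, day: float, window: float = 3.0) -> float:
        """Average growth (log10 units/day) over the window leading up to ``day``."""
        a = self.smoothed_log10(species, day - window)
        b = self.smoothed_log10(species, day)
        return (b - a) / window


def smooth_popsize(series: pd.DataFrame) -> PopSizeSeries:
    """Natural cubic-spline smoothing of log10 population sizes.

    ``series`` needs columns ``day``, ``host`` and ``virus``.  Each
    species' spline interpolates log10(count) at the days where its count
    is positive (zeros — e.g. virus before introduction — are left out of
    that species' spline).  At least 4 such days are required.
    """
    for col in ("day", "host", "virus"):
        if col not in series.columns:
            raise ValueError(f"missing column {col!r}")
    out = PopSizeSeries(series.copy().reset_index(drop=True))
    for species in ("host", "virus"):
        mask = series[species].to_numpy(dtype=float) > 0
        days = series["day"].to_numpy(dtype=float)[mask]
        vals = np.log10(series[species].to_numpy(dtype=float)[mask])
        if days.size >= 4:
            spline = CubicSpline(days, vals, bc_type="natural")
            out._splines[species] = (spline, days.min(), days.max())
    return out


@dataclasses.dataclass
class FitGrowthResult:
    slope: float
    z: float
    p_value: float
    method: str          # "mixed" or "fixed" (fallback)


def associate_fit_with_growth(data: pd.DataFrame) -> FitGrowthResult:
    """Logistic regression of the neutral-fit indicator on population growth.

    ``data`` needs columns ``fit`` (0/1: neutrality test passed),
    ``growth`` (log10 units/day over the 3 days before sampling) and
    ``replicate``.  Fitted as a binomial GLMM with a per-replicate random
    intercept (variational Bayes); with a single replicate, or if the
    mixed fit fails (e.g. complete separation), falls back to a
    fixed-effects logistic fit with a warning.
    """
    import statsmodels.api as sm
    from scipy.stats import norm

    df = data.dropna(subset=["fit", "growth"]).copy()
    df["fit"] = df["fit"].astype(int)
    n_rep = df["replicate"].nunique()
    if n_rep >= 2:
        try:
            from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
            model = BinomialBayesMixedGLM.from_formula(
                "fit ~ growth", {"rep": "0 + C(replicate)"}, df)
            fit = model.fit_vb()
            i = list(fit.model.exog_names).index("growth")
            slope = float(fit.fe_mean[i])
            sd = float(fit.fe_sd[i])
            z = slope / sd
            return FitGrowthResult(slope, z, float(2 * norm.sf(abs(z))), "mixed")
        except Exception as exc:  # pragma: no cover - depends on data pathology
            warnings.warn(f"mixed-effects fit failed ({exc}); "
                          "falling back to fixed-effects logistic regression")
    else:
        warnings.warn("single replicate: random effect degenerate; "
                      "falling back to fixed-effects logistic regression")
    X = sm.add_constant(df["growth"].to_numpy(dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(df["fit"].to_numpy(), X,
                     family=sm.families.Binomial()).fit()
    slope = float(res.params[1])
    z = float(res.tvalues[1])
    return FitGrowthResult(slope, z, float(res.pvalues[1]), "fixed")
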