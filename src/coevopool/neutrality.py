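"""Luria-Delbruck universal neutrality-curve test on variant allele frequencies.

During a purely neutral exponential expansion, de novo mutations enter the
population at rate mu per division and the cumulative number of variants at
frequency >= f follows the power law

    M(f) = (mu / beta) * (1/f - 1/fmax),

with beta the effective rate of surviving offspring.  After normalising the
empirical cumulative curve and transforming frequency to
x = (1/f - 1/fmax) / (1/fmin - 1/fmax), the curve collapses onto the
identity line y = x, independent of mu and beta.  Deviations — extra
probability mass at cohort frequencies under clonal interference, or no
growth at all — bend the curve away from the identity, which is quantified
by the Kolmogorov distance (max vertical deviation) and the area under the
curve.
"""

from __future__ import annotations

import dataclasses

import numpy as np

#: default analysis window on the frequency axis
DEFAULT_FMIN = 0.05
DEFAULT_FMAX = 0.40


@dataclasses.dataclass
class VAFSample:
    """Derived-allele frequencies at one time point, with analysis window."""

    frequencies: np.ndarray
    fmin: float = DEFAULT_FMIN
    fmax: float = DEFAULT_FMAX

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.frequencies = self.frequencies[~np.isnan(self.frequencies)]
        if not (0 < self.fmin < self.fmax < 1):
            raise ValueError("require 0 < fmin < fmax < 1")

    def in_window(self) -> np.ndarray:
        f = self.frequencies
        return f[(f >= self.fmin) & (f <= self.fmax)]


@dataclasses.dataclass
class NeutralityFitResult:
    """Outcome of :func:`assess_fit`.

    ``passed`` is None when too few variants fall in the window to attempt
    a fit ("no call"); otherwise True iff both the Kolmogorov distance and
    the AUC are below their thresholds.
    """

    n: int
    ks: float
    auc: float
    passed: bool | None
    x: np.ndarray
    y: np.ndarray
    ks_threshold: float = 0.25
    auc_threshold: float = 3.0

    @property
    def no_call(self) -> bool:
        return self.passed is None


def theoretical_M(f, mu: float, beta: float, fmax: float):
    """Closed-form cumulative variant count M(f) = (mu/beta)(1/f - 1/fmax).

    Frequencies above ``fmax`` return 0 by convention; nonpositive
    frequencies are an error.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    out = (mu / beta) * np.clip(1.0 / f - 1.0 / fmax, 0.0, None)
    return float(out) if out.ndim == 0 else out


def universal_curve(sample: VAFSample, min_variants: int = 5):
    """Normalised empirical cumulative curve against transformed 1/f.

    For each window variant with frequency f_i, the empirical cumulative
    count is the number of window variants with frequency >= f_i;
    y_i = count / max(count) and x_i = (1/f_i - 1/fmax)/(1/fmin - 1/fmax).
    Under neutral expansion the points lie on y = x.  Returns ``None``
    (no call) when fewer than ``min_variants`` variants fall in the window.
    """
    f = np.sort(sample.in_window())[::-1]
    n = f.size
    if n < min_variants:
        return None
    counts = np.arange(1, n + 1, dtype=float)   # M-hat at each f, descending f
    y = counts / counts[-1]
    x = (1.0 / f - 1.0 / sample.fmax) / (1.0 / sample.fmin - 1.0 / sample.fmax)
    x = np.clip(x, 0.0, 1.0)
    return x, y


def assess_fit(sample: VAFSample, ks_threshold: float = 0.25,
               auc_threshold: float = 3.0, min_variants: int = 5) -> NeutralityFitResult:
    """Judge whether a VAF sample matches the neutral-expansion power law.

    The Kolmogorov distance is max |y_i - x_i|; the AUC is the trapezoidal
    area under the normalised (x, y) curve (the origin is included so the
    curve spans the unit interval).  A time point passes when both
    statistics fall below their thresholds; the Kolmogorov criterion is the
    discriminating one on normalised curves.
    """
    curve = universal_curve(sample, min_variants=min_variants)
    if curve is None:
        n = sample.in_window().size
        return NeutralityFitResult(n, float("nan"), float("nan"), None,
                                   np.empty(0), np.empty(0),
                                   ks_threshold, auc_threshold)
    x, y = curve
    ks = float(np.max(np.abs(y - x)))
    xs = np.concatenate(([0.0], x[::-1]))
    ys = np.concatenate(([0.0], y[::-1]))
    auc = float(np.trapezoid(ys, xs))
    passed = bool(ks < ks_threshold and auc < auc_threshold)
    return NeutralityFitResult(x.size, ks, auc, passed, x, y,
                               ks_threshold, auc_threshold)


def required_mutation_rate(genome_length: float, divisions: float) -> float:
    """Per-site, per-division mutation rate needed for hitchhikers to be seen.

    For a neutral mutation to reach ~10% frequency purely by hitchhiking on
    a sweeping cell, it must arise within the first ``divisions`` divisions
    of that cell, so observing power-law diversity after a sweep needs a
    mutation probability of roughly 1 / (genome_length * divisions)
    substitutions per position per cell division.
    """
    if genome_length <= 0 or divisions <= 0:
        raise ValueError("genome_length and divisions must be positive")
    return 1.0 / (genome_length * divisions)
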