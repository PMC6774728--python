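"""Forward simulation of every pipeline input, with known ground truth.

Three layers are simulated:

* **Within-host genetic diversity** — a generation-synchronous branching
  process: every cell divides, each daughter survives with probability
  (1 + beta)/2, and mutation events arrive at rate mu per division, each
  founding a new lineage.  In the supercritical limit the variant allele
  frequencies (VAFs) follow the Luria-Delbruck power law
  M(f) = (mu/beta)(1/f - 1/fmax).  A clonal-interference variant pools
  several such expansions as competing cohorts.

* **Ecology** — a discrete-time chemostat recursion (logistic host growth,
  mass-action infection, burst release, virus decay, constant dilution)
  over explicit host/virus genotype classes arranged in an arms-race
  staircase: virus type j infects host types <= j.  Sweep-schedule events
  seed new resistant host or newly infective virus types.

* **Observation** — Pool-seq count sampling (Poisson coverage, binomial
  allele sampling, uniform base-substitution errors) producing sync
  tables, plus an infection-assay generator emitting technical-replicate
  growth rates.

All randomness flows from one seed through named per-component generators,
so each sub-simulator is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import warnings
import zlib
from typing import Sequence

import numpy as np
import pandas as pd

from .sync import SyncTable


@dataclasses.dataclass
class SweepEvent:
    """A scheduled adaptive event: at ``generation``, a genotype with
    selection coefficient ``s`` appears; ``phenotype_change`` is
    "resistance" (new host type) or "infectivity" (new virus type)."""

    generation: float
    s: float
    phenotype_change: str = "resistance"


@dataclasses.dataclass
class SimConfig:
    """All knobs of the forward simulations.

    Genetic parameters are desk-scale: the mutation rate is expressed per
    genome per division, and its default (together with ``beta`` and
    ``n_generations``) yields a final population >= 1e5 carrying >= 50
    variants in the 5-40% analysis window, the regime in which the
    neutrality-curve statistics are well resolved.  Ecological rates are
    per day; the chemostat dilution default matches a supply rate of 0.1
    per day.
    """

    # branching-process genetics
    per_division_mutation_rate: float = 5.0   # mu, substitutions/genome/division
    offspring_survival_rate: float = 0.7      # beta, effective surviving-offspring rate
    genome_length: int = 42_000_000           # bp
    n_generations: int = 26
    initial_size: int = 1
    # chemostat ecology
    carrying_capacity: float = 2e6            # cells/ml
    dilution_rate: float = 0.1                # per day
    host_growth_rate: float = 1.2             # per day
    adsorption_rate: float = 6e-8             # ml/(particle day)
    burst_size: float = 50.0                  # particles per lysed cell
    virus_decay_rate: float = 0.5             # per day
    host_initial: float = 1e5
    virus_inoculum: float = 1e4
    virus_introduction_day: float = 12.0
    total_days: float = 100.0
    step_days: float = 0.1                    # sub-daily Euler step
    generations_per_day: float = 1.0          # ~100 days ~ 100 generations
    sweep_schedule: list = dataclasses.field(default_factory=list)
    sweep_seed_count: float = 10.0            # cells/particles seeding a new type
    # Pool-seq observation
    coverage_mean: float = 100.0              # x
    sequencing_error_rate: float = 0.002      # per base
    seed: int = 0

    def __post_init__(self):
        rates = {
            "per_division_mutation_rate": self.per_division_mutation_rate,
            "host_growth_rate": self.host_growth_rate,
            "adsorption_rate": self.adsorption_rate,
            "burst_size": self.burst_size,
            "virus_decay_rate": self.virus_decay_rate,
            "coverage_mean": self.coverage_mean,
            "sequencing_error_rate": self.sequencing_error_rate,
        }
        for name, v in rates.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.dilution_rate < 1:
            raise ValueError("dilution_rate must lie in [0, 1) per day")
        if not 0 < self.offspring_survival_rate <= 1:
            raise ValueError("offspring_survival_rate (beta) must be in (0, 1]")
        if self.initial_size < 1:
            raise ValueError("initial_size must be >= 1")
        self.sweep_schedule = [
            e if isinstance(e, SweepEvent) else SweepEvent(**e)
            for e in self.sweep_schedule
        ]

    def rng(self, component: str) -> np.random.Generator:
        """Named per-component generator derived from the master seed."""
        tag = zlib.crc32(component.encode())
        return np.random.default_rng([self.seed, tag])


@dataclasses.dataclass
class LineageRecord:
    """Ground-truth record of one lineage of the branching process."""

    lineage_id: int
    parent_id: int                   # -1 for the founding lineage
    mutation_positions: np.ndarray   # 1-based bp, carried in addition to the parent's
    final_count: int
    fitness: float = 1.0
    counts_per_generation: np.ndarray | None = None


@dataclasses.dataclass
class ExpansionResult:
    """Outcome of a neutral (or per-cohort) expansion.

    ``status`` is "ok" or "extinct".  ``vafs`` holds the frequency of every
    mutation segregating in the final population, aligned with
    ``positions``; the full lineage table (including extinct lineages) is
    kept for ground-truth checks.  New mutations are stored flat:
    ``mutation_lineage[k]`` is the lineage in which mutation k arose.
    """

    status: str
    vafs: np.ndarray
    positions: np.ndarray
    final_size: int
    parent: np.ndarray
    gen_born: np.ndarray
    mutation_positions: np.ndarray   # all mutations ever generated (1-based bp)
    mutation_lineage: np.ndarray
    final_counts: np.ndarray
    subtree_counts: np.ndarray
    history: list | None = None

    @property
    def extinct(self) -> bool:
        return self.status == "extinct"

    def lineage_records(self):
        for i in range(self.parent.size):
            pos = self.mutation_positions[self.mutation_lineage == i]
            counts = (np.array([h[i] if i < h.size else 0 for h in self.history])
                      if self.history is not None else None)
            yield LineageRecord(i, int(self.parent[i]), pos,
                                int(self.final_counts[i]), 1.0, counts)


def simulate_neutral_expansion(config: SimConfig,
                               rng: np.random.Generator | None = None,
                               track_history: bool = False) -> ExpansionResult:
    """Neutral expansion with mutation accumulation; returns true VAFs.

    Each generation, every cell divides; each daughter survives with
    probability (1 + beta)/2, so the expected per-generation growth factor
    is 1 + beta.  Each daughter independently acquires Poisson(mu/2) new
    mutations at uniform genomic positions (mu per division in total);
    every mutated surviving daughter founds a new lineage carrying its new
    mutations on top of everything its parent carries.  Extinction before
    ``n_generations`` yields an explicit "extinct" result rather than an
    exception.
    """
    rng = rng if rng is not None else config.rng("neutral_expansion")
    mu = config.per_division_mutation_rate
    beta = config.offspring_survival_rate
    p_survive = (1.0 + beta) / 2.0
    q_mut = 1.0 - np.exp(-mu / 2.0)   # a daughter carries >= 1 new mutation
    L = config.genome_length

    parent = [np.array([-1], dtype=np.int64)]
    gen_born = [np.array([0], dtype=np.int64)]
    mut_pos: list = []
    mut_lin: list = []
    counts = np.array([config.initial_size], dtype=np.int64)
    n_lineages = 1
    history = [counts.copy()] if track_history else None

    def _result(status, counts_arr):
        parent_a = np.concatenate(parent)
        gen_a = np.concatenate(gen_born)
        mpos = (np.concatenate(mut_pos) if mut_pos else np.empty(0, np.int64))
        mlin = (np.concatenate(mut_lin) if mut_lin else np.empty(0, np.int64))
        final_counts = np.zeros(parent_a.size, dtype=np.int64)
        final_counts[:counts_arr.size] = counts_arr
        total = int(counts_arr.sum())
        subtree = final_counts.copy()
        if gen_a.size and gen_a.max() > 0:
            # parents are created strictly earlier, so accumulating child
            # counts newest generation first respects the dependencies
            for g in range(int(gen_a.max()), 0, -1):
                idx = np.flatnonzero(gen_a == g)
                np.add.at(subtree, parent_a[idx], subtree[idx])
        if total > 0 and mpos.size:
            freqs = subtree[mlin] / total
            keep = freqs > 0
            vafs, positions = freqs[keep], mpos[keep]
        else:
            vafs, positions = np.empty(0), np.empty(0, np.int64)
        return ExpansionResult(status, vafs, positions, total, parent_a, gen_a,
                               mpos, mlin, final_counts, subtree, history)

    for g in range(1, config.n_generations + 1):
        daughters = 2 * counts
        if mu > 0:
            mutated = rng.binomial(daughters, q_mut)
        else:
            mutated = np.zeros_like(daughters)
        surviving_new = rng.binomial(mutated, p_survive)
        counts = rng.binomial(daughters - mutated, p_survive)
        n_new = int(surviving_new.sum())
        if n_new:
            parents_new = np.repeat(np.arange(surviving_new.size), surviving_new)
            new_ids = np.arange(n_lineages, n_lineages + n_new, dtype=np.int64)
            parent.append(parents_new.astype(np.int64))
            gen_born.append(np.full(n_new, g, dtype=np.int64))
            # zero-truncated Poisson(mu/2) mutations per mutated daughter
            k = rng.poisson(mu / 2.0, size=n_new)
            zero = k == 0
            while zero.any():
                k[zero] = rng.poisson(mu / 2.0, size=int(zero.sum()))
                zero = k == 0
            mut_lin.append(np.repeat(new_ids, k))
            mut_pos.append(rng.integers(1, L + 1, size=int(k.sum()), dtype=np.int64))
            counts = np.concatenate([counts, np.ones(n_new, dtype=np.int64)])
            n_lineages += n_new
        if track_history:
            history.append(counts.copy())
        if counts.sum() == 0:
            return _result("extinct", counts)

    return _result("ok", counts)


@dataclasses.dataclass
class ClonalInterferenceResult:
    vafs: np.ndarray
    positions: np.ndarray
    cohort_fractions: np.ndarray
    founder_positions: np.ndarray    # hitchhikers private to each cohort


def simulate_clonal_interference(config: SimConfig, n_cohorts: int = 2,
                                 selection_coefficients: Sequence[float] | None = None,
                                 selection_generations: float = 6.0,
                                 n_founder_mutations: int | None = None,
                                 rng: np.random.Generator | None = None
                                 ) -> ClonalInterferenceResult:
    """VAFs of a population split into competing beneficial cohorts.

    Cohort i carries selection coefficient s_i; after
    ``selection_generations`` generations of competition the cohort
    fractions are conditioned to w_i proportional to (1 + s_i)^g.  Each
    cohort contributes private hitchhikers at exactly its cohort
    frequency — the mutations accumulated along its selected line of
    descent while it rose from a single cell, by default
    Poisson(mu/2 x rise duration) with the rise duration
    log(cohort size)/log(1+s) — plus an internal neutral-expansion
    spectrum rescaled by the cohort frequency.  The hitchhiker mass at
    cohort frequencies is what breaks the single-expansion power law
    (the rescaled continuous spectra alone would still sum to a 1/f
    shape).
    """
    rng = rng if rng is not None else config.rng("clonal_interference")
    if selection_coefficients is None:
        selection_coefficients = (0.5, 0.3)[:n_cohorts] if n_cohorts <= 2 else \
            tuple(0.5 / (i + 1) for i in range(n_cohorts))
    s = np.asarray(selection_coefficients, dtype=float)
    if s.size != n_cohorts:
        raise ValueError("need one selection coefficient per cohort")
    if n_cohorts == 1:
        # degenerate case: a single cohort is just a neutral expansion
        res = simulate_neutral_expansion(config, rng=rng)
        return ClonalInterferenceResult(res.vafs, res.positions,
                                        np.array([1.0]), np.empty(0, np.int64))
    if len(set(map(float, s))) != n_cohorts or np.any(s <= 0):
        raise ValueError("cohorts need distinct positive selection coefficients")

    w = (1.0 + s) ** selection_generations
    w = w / w.sum()
    if np.any(w > 0.99):
        warnings.warn("a cohort has effectively fixed before sampling "
                      f"(fractions {np.round(w, 3)}); returning VAFs anyway")

    mu = config.per_division_mutation_rate
    beta = config.offspring_survival_rate
    pop_scale = (1.0 + beta) ** config.n_generations
    vafs, positions, founders = [], [], []
    for wi, si in zip(w, s):
        res = simulate_neutral_expansion(config, rng=rng)
        for _ in range(5):
            if not res.extinct:
                break
            res = simulate_neutral_expansion(config, rng=rng)
        if res.extinct:
            raise RuntimeError("cohort expansion went extinct repeatedly")
        vafs.append(res.vafs * wi)
        positions.append(res.positions)
        if n_founder_mutations is None:
            rise_generations = np.log(max(wi * pop_scale, 2.0)) / np.log1p(si)
            k = int(rng.poisson(mu / 2.0 * rise_generations))
        else:
            k = int(n_founder_mutations)
        fpos = rng.integers(1, config.genome_length + 1, size=k, dtype=np.int64)
        vafs.append(np.full(k, wi))
        positions.append(fpos)
        founders.append(fpos)
    return ClonalInterferenceResult(np.concatenate(vafs), np.concatenate(positions),
                                    w, np.concatenate(founders))


@dataclasses.dataclass
class ChemostatResult:
    popsize: pd.DataFrame            # day, host, virus (daily totals)
    host_type_freqs: pd.DataFrame    # day x host type fraction
    virus_type_freqs: pd.DataFrame   # day x virus type fraction


def simulate_chemostat(config: SimConfig) -> ChemostatResult:
    """Discrete-time host-virus chemostat with explicit genotype classes.

    Euler recursion at ``config.step_days`` resolution: logistic host
    growth minus dilution minus mass-action infection; virus gains
    ``burst_size`` particles per infection and loses to decay plus
    dilution.  Genotypes form an arms-race staircase (virus type j
    infects host types <= j); sweep-schedule events seed new types with
    ``sweep_seed_count`` individuals.  All abundances are clamped
    nonnegative at every step; numerical blow-up raises an error naming
    ``step_days``.
    """
    h = config.step_days
    if h <= 0:
        raise ValueError("step_days must be positive")
    r, K = config.host_growth_rate, config.carrying_capacity
    d = config.dilution_rate
    phi, b, m = config.adsorption_rate, config.burst_size, config.virus_decay_rate

    n_host = 1 + sum(1 for e in config.sweep_schedule
                     if e.phenotype_change == "resistance")
    n_virus = 1 + sum(1 for e in config.sweep_schedule
                      if e.phenotype_change == "infectivity")
    H = np.zeros(n_host)
    V = np.zeros(n_virus)
    H[0] = config.host_initial

    events = []
    hi, vi = 0, 0
    for e in config.sweep_schedule:
        day = e.generation / config.generations_per_day
        if e.phenotype_change == "resistance":
            hi += 1
            events.append((day, "H", hi))
        else:
            vi += 1
            events.append((day, "V", vi))
    events.sort()

    n_steps = int(round(config.total_days / h))
    days_out, host_out, virus_out = [], [], []
    hfreq_out, vfreq_out = [], []
    virus_added = config.virus_inoculum <= 0
    next_event = 0
    next_day = 0.0

    for step in range(n_steps + 1):
        t = step * h
        if not virus_added and t >= config.virus_introduction_day:
            V[0] += config.virus_inoculum
            virus_added = True
        while next_event < len(events) and t >= events[next_event][0]:
            _, kind, idx = events[next_event]
            if kind == "H":
                H[idx] += config.sweep_seed_count
            else:
                V[idx] += config.sweep_seed_count
            next_event += 1

        if t >= next_day - 1e-9:
            days_out.append(round(next_day))
            host_out.append(H.sum())
            virus_out.append(V.sum())
            hfreq_out.append(H / H.sum() if H.sum() > 0 else np.zeros_like(H))
            vfreq_out.append(V / V.sum() if V.sum() > 0 else np.zeros_like(V))
            next_day += 1.0

        total_h = H.sum()
        # virus pressure on host type i: all virus types j >= i infect it
        pressure = np.array([V[i:].sum() for i in range(n_host)])
        dH = r * H * (1.0 - total_h / K) - d * H - phi * H * pressure
        # virus type j feeds on host types <= j
        prey = np.array([H[: j + 1].sum() for j in range(n_virus)])
        dV = b * phi * V * prey - (d + m) * V
        # Euler stability: the step must resolve the fastest local rate
        fastest = max(r, d + m,
                      float(phi * pressure.max(initial=0.0)),
                      float(b * phi * prey.max(initial=0.0)))
        if h * fastest > 2.0 or not (np.all(np.isfinite(H)) and
                                     np.all(np.isfinite(V))):
            raise ValueError(
                "numerical blow-up in the chemostat recursion; decrease the "
                f"integration step 'step_days' (currently {h})")
        H = np.maximum(H + h * dH, 0.0)
        V = np.maximum(V + h * dV, 0.0)

    popsize = pd.DataFrame({"day": days_out, "host": host_out, "virus": virus_out})
    hfq = pd.DataFrame(hfreq_out, index=days_out,
                       columns=[f"host_type_{i}" for i in range(n_host)])
    vfq = pd.DataFrame(vfreq_out, index=days_out,
                       columns=[f"virus_type_{j}" for j in range(n_virus)])
    return ChemostatResult(popsize, hfq, vfq)


def sample_poolseq(true_freqs: pd.DataFrame, config: SimConfig,
                   chrom: str = "chr1",
                   positions: np.ndarray | None = None,
                   n_background: int = 1000,
                   rng: np.random.Generator | None = None) -> SyncTable:
    """Pool-seq observation of true allele-frequency trajectories.

    ``true_freqs`` is loci x time points in [0,1] (NaN = population not
    sequenced at that time point, emitted as a zero-coverage block).  Per
    site and time point, coverage ~ Poisson(coverage_mean) and the derived
    read count ~ Binomial(coverage, freq); every read is then misread with
    probability ``sequencing_error_rate``, uniformly to one of the other
    three bases.  ``n_background`` invariant monomorphic sites are added so
    coverage-based filters see a realistic site pool.
    """
    rng = rng if rng is not None else config.rng("poolseq")
    vals = true_freqs.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
        raise ValueError("frequencies must lie in [0,1]")
    if config.coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    n_var, n_tp = vals.shape
    n_sites = n_var + n_background

    if positions is None:
        positions = np.sort(rng.choice(config.genome_length, size=n_var,
                                       replace=False) + 1)
    else:
        positions = np.asarray(positions, dtype=np.int64)
        if positions.size != n_var:
            raise ValueError("positions length must match true_freqs rows")
    bg_pos = np.empty(0, dtype=np.int64)
    if n_background:
        taken = set(map(int, positions))
        bg = rng.choice(config.genome_length, size=int(n_background * 1.2) + 8,
                        replace=False) + 1
        bg_pos = np.array([p for p in bg if int(p) not in taken][:n_background],
                          dtype=np.int64)

    bases = np.array(list("ACGT"))
    ref_var = bases[rng.integers(0, 4, n_var)]
    derived = np.array([bases[(np.flatnonzero(bases != rb))[rng.integers(0, 3)]]
                        for rb in ref_var])
    ref_bg = bases[rng.integers(0, 4, bg_pos.size)]

    all_pos = np.concatenate([positions, bg_pos])
    all_ref = np.concatenate([ref_var, ref_bg])
    all_derived = np.concatenate([derived, np.array(["-"] * bg_pos.size)])
    all_freq = np.vstack([vals, np.zeros((bg_pos.size, n_tp))])
    order = np.argsort(all_pos, kind="stable")
    all_pos, all_ref = all_pos[order], all_ref[order]
    all_derived, all_freq = all_derived[order], all_freq[order]

    sync_order = "ATCG"
    counts = np.zeros((all_pos.size, n_tp, 6), dtype=np.int64)
    err = config.sequencing_error_rate
    cov = rng.poisson(config.coverage_mean, size=(all_pos.size, n_tp))
    cov[np.isnan(all_freq)] = 0
    freq_filled = np.where(np.isnan(all_freq), 0.0, all_freq)
    derived_reads = rng.binomial(cov, freq_filled)
    ref_reads = cov - derived_reads

    def scatter(n_reads: np.ndarray, true_base: np.ndarray):
        """Distribute reads of a true base over observed bases with errors."""
        correct = rng.binomial(n_reads, 1.0 - err) if err > 0 else n_reads
        wrong = n_reads - correct
        for bi, base in enumerate("ACGT"):
            sel = true_base == base
            if not sel.any():
                continue
            col = sync_order.index(base)
            counts[sel, :, col] += correct[sel]
            if err > 0:
                others = [sync_order.index(x) for x in "ACGT" if x != base]
                w = wrong[sel]
                split = rng.multinomial(w.ravel(), [1 / 3] * 3).reshape(w.shape + (3,))
                for k, col2 in enumerate(others):
                    counts[sel, :, col2] += split[..., k]

    scatter(ref_reads, all_ref)
    scatter(derived_reads, all_derived)
    return SyncTable(np.full(all_pos.size, chrom, dtype=object), all_pos,
                     all_ref, counts, list(true_freqs.columns))


def staircase_resistance(host_days: Sequence[float], virus_days: Sequence[float],
                         resistance_days: Sequence[float],
                         infectivity_days: Sequence[float]) -> pd.DataFrame:
    """Arms-race resistance relation: host day h resists virus day v iff the
    host's resistance level (number of resistance events at or before h)
    exceeds the virus's infectivity level."""
    rows = {}
    for hd in host_days:
        lvl_h = sum(1 for dday in resistance_days if dday <= hd)
        rows[hd] = {vd: lvl_h > sum(1 for dday in infectivity_days if dday <= vd)
                    for vd in virus_days}
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def simulate_infection_assay(resistance: pd.DataFrame, noise_sd: float = 0.05,
                             n_clones: int = 10, control_mean: float = 1.0,
                             susceptible_mean: float = -0.5,
                             rng: np.random.Generator | None = None,
                             n_reps: int = 4) -> pd.DataFrame:
    """Growth-rate table of a cross-infection assay.

    ``resistance`` is host day x virus day (True = hosts of that day
    resist that virus).  Every host day contributes ``n_clones`` clones;
    each clone x virus cell gets ``n_reps`` technical-replicate growth
    rates (resistant cells near the virus-free control mean, susceptible
    cells strongly reduced/negative) plus ``n_reps`` virus-free controls
    per clone.  Returns the long-format assay table consumed by
    :class:`~coevopool.phenotypes.InfectionMatrix`.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = []
    for hd in resistance.index:
        for c in range(n_clones):
            clone = f"t{hd}_c{c}"
            for rep in range(n_reps):
                rows.append({"clone": clone, "host_day": hd, "virus_day": np.nan,
                             "rep": rep, "is_control": True,
                             "growth_rate": control_mean + noise_sd * rng.standard_normal()})
            for vd in resistance.columns:
                mean = control_mean if resistance.loc[hd, vd] else susceptible_mean
                for rep in range(n_reps):
                    rows.append({"clone": clone, "host_day": hd, "virus_day": vd,
                                 "rep": rep, "is_control": False,
                                 "growth_rate": mean + noise_sd * rng.standard_normal()})
    return pd.DataFrame(rows)


@dataclasses.dataclass
class CoevolutionRun:
    """Bundle of all synthetic inputs for one replicate, with ground truth."""

    sync: SyncTable
    popsize: pd.DataFrame
    assay: pd.DataFrame
    true_freqs: pd.DataFrame
    effects: pd.DataFrame
    truth: dict


def simulate_coevolution_experiment(config: SimConfig | None = None,
                                    seed: int | None = None) -> CoevolutionRun:
    """One synthetic host replicate: ecology, genetics and observation.

    The scenario mirrors the canonical experiment: an isogenic host
    population accumulates standing hitchhiking variation during its
    initial expansion, the virus is introduced at day 12, and a resistant
    genotype seeded at day 15 sweeps while the virus suppresses the
    susceptible background.  The sweep purges the standing variation,
    drives host population growth, and the expanding resistant cohort
    regenerates diversity as a fresh Luria-Delbruck spectrum.  Sampling
    days, the sweep window and all true frequencies are returned as
    ground truth.
    """
    if config is None:
        config = SimConfig(
            coverage_mean=1000.0,
            sweep_schedule=[SweepEvent(16.0, 0.9, "resistance"),
                            SweepEvent(40.0, 0.9, "infectivity"),
                            SweepEvent(50.0, 0.9, "resistance")],
        )
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = config.rng("scenario")

    sample_days = [0, 6, 12, 18, 24, 30, 36, 44]
    chem = simulate_chemostat(config)
    f_sweep = chem.host_type_freqs["host_type_1"].reindex(sample_days).to_numpy()

    # standing variation from the initial expansion (hitchhikers on the
    # founding background), purged as the resistant cohort takes over
    n_standing = 200
    standing = rng.uniform(0.15, 0.65, size=n_standing)
    # new cohort: fresh neutral spectrum inside the sweeping genotype
    cohort_cfg = config
    cohort_rng = config.rng("cohort_expansion")
    res = simulate_neutral_expansion(cohort_cfg, rng=cohort_rng)
    while res.extinct:
        res = simulate_neutral_expansion(cohort_cfg, rng=cohort_rng)
    new_vafs = res.vafs[res.vafs >= 0.02]
    n_hitch = 5

    n_loci = n_standing + 1 + n_hitch + new_vafs.size
    freqs = np.zeros((n_loci, len(sample_days)))
    for j, day in enumerate(sample_days):
        fs = f_sweep[j]
        row = 0
        ramp = 1.0 if day >= 6 else 0.0     # standing variants arise days 0-6
        freqs[row:row + n_standing, j] = standing * (1 - fs) * ramp
        row += n_standing
        freqs[row:row + 1 + n_hitch, j] = fs  # sweep locus + linked hitchhikers
        row += 1 + n_hitch
        freqs[row:, j] = new_vafs * fs

    positions = np.sort(rng.choice(config.genome_length, size=n_loci,
                                   replace=False) + 1)
    true_freqs = pd.DataFrame(freqs, index=[f"chr1:{p}" for p in positions],
                              columns=sample_days)

    labels = np.array(["intergenic", "synonymous", "missense",
                       "nonsense/frameshift"])
    effect = labels[rng.choice(4, size=n_loci, p=[0.45, 0.25, 0.25, 0.05])]
    effects = pd.DataFrame({"chrom": "chr1", "pos": positions, "effect": effect})

    sync = sample_poolseq(true_freqs, config, positions=positions,
                          n_background=2000, rng=config.rng("poolseq"))

    res_days = [e.generation / config.generations_per_day
                for e in config.sweep_schedule if e.phenotype_change == "resistance"]
    inf_days = [e.generation / config.generations_per_day
                for e in config.sweep_schedule if e.phenotype_change == "infectivity"]
    assay_host_days = sample_days
    assay_virus_days = [d for d in sample_days if d >= config.virus_introduction_day]
    relation = staircase_resistance(assay_host_days, assay_virus_days,
                                    res_days, inf_days)
    assay = simulate_infection_assay(relation, rng=config.rng("assay"))

    truth = {
        "sample_days": sample_days,
        "sweep_start_day": res_days[0] if res_days else None,
        "sweep_fixation_day": None,
        "f_sweep": dict(zip(sample_days, map(float, f_sweep))),
        "resistance_days": res_days,
        "infectivity_days": inf_days,
        "n_standing": n_standing,
        "n_new_cohort": int(new_vafs.size),
    }
    fixed = [d for d, f in truth["f_sweep"].items() if f >= 0.95]
    truth["sweep_fixation_day"] = min(fixed) if fixed else None
    return CoevolutionRun(sync, chem.popsize, assay, true_freqs, effects, truth)


def simulate_wright_fisher(s: float, N: int, p0: float, n_generations: int,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Haploid Wright-Fisher allele-frequency trajectory under selection.

    Malthusian fitness w = e^s: the deterministic map is
    p -> p e^s / (p e^s + 1 - p), followed by binomial resampling of N
    individuals.  Returns the frequency at generations 0..n_generations.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    w = np.exp(s)
    traj = np.empty(n_generations + 1)
    p = float(p0)
    traj[0] = p
    for g in range(1, n_generations + 1):
        p_det = p * w / (p * w + (1.0 - p))
        p = rng.binomial(N, p_det) / N
        traj[g] = p
    return traj
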