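"""Derived-allele calling, the filtering cascade and SNP collapsing."""

import numpy as np
import pandas as pd
import pytest

from coevopool import (
    FilterConfig,
    TrajectoryMatrix,
    collapse_linked_snps,
    derive_frequencies,
    filter_trajectories,
    tally_effects,
)

from conftest import make_sync


def traj_from(freqs: dict, timepoints, chrom="chr1", effects=None):
    """Build a TrajectoryMatrix from {'chr1:100': [f0, f1, ...]}."""
    ids = list(freqs)
    df = pd.DataFrame([freqs[i] for i in ids], index=ids, columns=timepoints)
    meta = pd.DataFrame({
        "chrom": [i.rsplit(":", 1)[0] for i in ids],
        "pos": [int(i.rsplit(":", 1)[1]) for i in ids],
        "derived": ["C"] * len(ids),
        "effect": [effects.get(i) if effects else None for i in ids],
        "members": [[i] for i in ids],
    }, index=ids)
    return TrajectoryMatrix(df, meta)


class TestDeriveFrequencies:
    def test_simple_frequency(self):
        counts = np.zeros((1, 1, 6), dtype=int)
        counts[0, 0, 0] = 90   # A (ref)
        counts[0, 0, 2] = 10   # C
        traj = derive_frequencies(make_sync(counts))
        assert traj.freqs.iloc[0, 0] == pytest.approx(0.10)
        assert traj.meta["derived"].iloc[0] == "C"

    def test_highest_mean_nonreference_wins(self):
        # C averages 0.2 over time, G only 0.05: C is the derived allele
        counts = np.zeros((1, 2, 6), dtype=int)
        counts[0, :, 0] = [70, 80]   # A ref
        counts[0, :, 2] = [25, 15]   # C: 0.25, 0.15
        counts[0, :, 3] = [5, 5]     # G: 0.05, 0.05
        traj = derive_frequencies(make_sync(counts))
        assert traj.meta["derived"].iloc[0] == "C"
        assert traj.freqs.iloc[0].tolist() == pytest.approx([0.25, 0.15])

    def test_tie_broken_alphabetically(self):
        counts = np.zeros((1, 1, 6), dtype=int)
        counts[0, 0, 0] = 80
        counts[0, 0, 2] = 10   # C
        counts[0, 0, 3] = 10   # G, tied: C < G alphabetically
        traj = derive_frequencies(make_sync(counts))
        assert traj.meta["derived"].iloc[0] == "C"

    def test_non_acgt_reference_skipped_with_warning(self):
        counts = np.ones((2, 1, 6), dtype=int) * 10
        table = make_sync(counts, ref=["N", "A"])
        with pytest.warns(UserWarning, match="reference base"):
            traj = derive_frequencies(table)
        assert traj.n_loci == 1

    def test_missing_propagates(self):
        counts = np.zeros((1, 2, 6), dtype=int)
        counts[0, 1, 0] = 50
        counts[0, 1, 1] = 50
        traj = derive_frequencies(make_sync(counts))
        assert np.isnan(traj.freqs.iloc[0, 0])


class TestFilterCascade:
    tps = [0, 10, 20, 30, 40]

    def test_single_excursion_above_threshold_removed(self):
        # reaches 0.30 only once: indistinguishable from error at 0.25 limit
        traj = traj_from({"chr1:100": [0.0, 0.30, 0.1, 0.1, 0.1],
                          "chr1:200": [0.0, 0.30, 0.4, 0.1, 0.1]}, self.tps)
        out, ledger = filter_trajectories(traj, cfg=FilterConfig())
        assert list(out.freqs.index) == ["chr1:200"]
        assert ledger["detection"] == 1

    def test_ancestral_variation_removed(self):
        # 2% derived at day 0 violates the isogenic start (<99% ancestral)
        traj = traj_from({"chr1:100": [0.02, 0.4, 0.4, 0.4, 0.4],
                          "chr1:200": [0.005, 0.4, 0.4, 0.4, 0.4]}, self.tps)
        out, ledger = filter_trajectories(traj, cfg=FilterConfig())
        assert list(out.freqs.index) == ["chr1:200"]
        assert ledger["ancestral"] == 1

    def test_missingness_cap_host(self):
        nan = np.nan
        tps = list(range(8))
        traj = traj_from({
            "chr1:100": [0.0, 0.4, 0.4, nan, nan, nan, nan, 0.4],  # 4 missing
            "chr1:200": [0.0, 0.4, 0.4, nan, nan, nan, 0.4, 0.4],  # 3 missing
        }, tps)
        out, ledger = filter_trajectories(traj, cfg=FilterConfig(max_missing=3))
        assert list(out.freqs.index) == ["chr1:200"]
        assert ledger["missingness"] == 1

    def test_indel_mask_radius_inclusive(self):
        traj = traj_from({"chr1:100": [0.0, 0.4, 0.4, 0.4, 0.4],
                          "chr1:111": [0.0, 0.4, 0.4, 0.4, 0.4]}, self.tps)
        out, ledger = filter_trajectories(traj, [("chr1", 110)], FilterConfig())
        # 100 is 10 bp away (inclusive) -> masked; 111 is 1 bp away -> masked
        assert out.n_loci == 0
        assert ledger["indel_mask"] == 2
        out2, _ = filter_trajectories(traj, [("chr1", 111)], FilterConfig())
        assert list(out2.freqs.index) == ["chr1:100"]

    def test_ledger_counts_are_conserved(self, rng):
        n = 300
        tps = list(range(6))
        freqs = {}
        for i in range(n):
            row = rng.uniform(0, 0.6, 6)
            row[0] = rng.choice([0.0, 0.05])
            if rng.random() < 0.3:
                row[rng.integers(1, 6, size=rng.integers(1, 5))] = np.nan
            freqs[f"chr1:{(i + 1) * 50}"] = row
        traj = traj_from(freqs, tps)
        indels = [("chr1", int(p)) for p in rng.integers(1, n * 50, 20)]
        out, ledger = filter_trajectories(traj, indels, FilterConfig())
        removed = sum(ledger[k] for k in
                      ("indel_mask", "ancestral", "detection", "missingness"))
        assert ledger["input"] == ledger["output"] + removed
        assert ledger["output"] == out.n_loci

    def test_filtering_is_idempotent(self, rng):
        tps = list(range(6))
        freqs = {f"chr1:{(i + 1) * 50}": rng.uniform(0, 0.6, 6) for i in range(200)}
        traj = traj_from(freqs, tps)
        once, _ = filter_trajectories(traj, cfg=FilterConfig())
        twice, ledger2 = filter_trajectories(once, cfg=FilterConfig())
        assert list(twice.freqs.index) == list(once.freqs.index)
        assert all(ledger2[k] == 0 for k in
                   ("indel_mask", "ancestral", "detection", "missingness"))


class TestCollapse:
    tps = [0, 10, 20, 30]

    def test_close_identical_trajectories_merge(self):
        t = [0.0, 0.3, 0.5, 0.4]
        traj = traj_from({"chr1:100": t, "chr1:200": t}, self.tps)
        out = collapse_linked_snps(traj)
        assert out.n_loci == 1
        assert out.freqs.iloc[0].tolist() == pytest.approx(t)
        assert sorted(out.meta["members"].iloc[0]) == ["chr1:100", "chr1:200"]

    def test_distant_loci_not_merged(self):
        t = [0.0, 0.3, 0.5, 0.4]
        traj = traj_from({"chr1:100": t, "chr1:2100": t}, self.tps)
        assert collapse_linked_snps(traj).n_loci == 2

    def test_uncorrelated_close_loci_not_merged(self):
        traj = traj_from({"chr1:100": [0.0, 0.3, 0.5, 0.4],
                          "chr1:200": [0.5, 0.1, 0.4, 0.05]}, self.tps)
        assert collapse_linked_snps(traj).n_loci == 2

    def test_too_few_shared_timepoints_cannot_link(self):
        nan = np.nan
        traj = traj_from({"chr1:100": [0.1, 0.3, nan, nan],
                          "chr1:200": [0.1, 0.3, 0.5, 0.2]}, self.tps)
        assert collapse_linked_snps(traj).n_loci == 2

    def test_most_severe_effect_kept_and_members_recoverable(self):
        t = [0.0, 0.3, 0.5, 0.4]
        traj = traj_from({"chr1:100": t, "chr1:300": t, "chr1:5000": t}, self.tps,
                         effects={"chr1:100": "synonymous",
                                  "chr1:300": "missense",
                                  "chr1:5000": "intergenic"})
        out = collapse_linked_snps(traj)
        assert out.n_loci == 2
        merged = out.meta.loc["chr1:100"]
        assert merged["effect"] == "missense"
        all_members = sorted(m for row in out.meta["members"] for m in row)
        assert all_members == sorted(traj.freqs.index)

    def test_never_increases_rows(self, rng):
        tps = list(range(5))
        freqs = {f"chr1:{int(p)}": rng.uniform(0, 1, 5)
                 for p in np.sort(rng.choice(10000, 50, replace=False) + 1)}
        traj = traj_from(freqs, tps)
        assert collapse_linked_snps(traj).n_loci <= traj.n_loci


class TestTallyEffects:
    def test_counts_by_class(self):
        traj = traj_from({f"chr1:{i}": [0.1] for i in (1, 2, 3, 4)}, [0],
                         effects={"chr1:1": "missense", "chr1:2": "missense",
                                  "chr1:3": "missense", "chr1:4": "synonymous"})
        tally = tally_effects(traj)
        assert tally["missense"] == 3 and tally["synonymous"] == 1
        assert tally["fraction_synonymous_intergenic"] == pytest.approx(0.25)

    def test_empty_matrix_all_zero(self):
        traj = traj_from({"chr1:1": [0.1]}, [0]).subset([])
        tally = tally_effects(traj)
        assert all(tally[k] == 0 for k in
                   ("missense", "synonymous", "intergenic", "nonsense/frameshift"))

    def test_unannotated_counted_separately(self):
        traj = traj_from({"chr1:1": [0.1], "chr1:2": [0.2]}, [0],
                         effects={"chr1:1": "intergenic"})
        assert tally_effects(traj)["unannotated"] == 1


class TestTrueVariantRecovery:
    def test_no_false_negatives_from_bookkeeping(self):
        # every programmed variant that is clearly detectable (true
        # frequency above the threshold with margin at >= 2 time points,
        # observed at enough time points after coverage masking) must
        # survive the cascade
        from coevopool import mask_coverage, simulate_coevolution_experiment

        run = simulate_coevolution_experiment(seed=21)
        table, _ = mask_coverage(run.sync)
        traj = derive_frequencies(table)
        cfg = FilterConfig(detection_threshold=0.05, max_missing=3)
        out, _ = filter_trajectories(traj, cfg=cfg)
        surviving = set(out.freqs.index)

        true = run.true_freqs
        clearly_detectable = true.index[
            ((true > 0.08).sum(axis=1) >= 2) & (true[0] == 0.0)]
        observed_enough = traj.freqs.loc[
            traj.freqs.index.intersection(clearly_detectable)]
        observed_enough = observed_enough.index[
            observed_enough.isna().sum(axis=1) <= cfg.max_missing]
        missing = [l for l in observed_enough if l not in surviving]
        assert not missing, f"lost true variants: {missing[:5]}"
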