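"""Cross-infection assay: susceptibility calls, ranges, match/mismatch.

Processes a simulated clone-by-virus growth-rate assay into binary
susceptibility calls, per-clone resistance ranges, per-virus infectivity
ranges and the alternating phenotypic match/mismatch intervals.
"""

import numpy as np

from coevopool import (InfectionMatrix, classify_match_mismatch, ranges,
                       simulate_infection_assay, staircase_resistance,
                       tradeoff_correlation)

days = [0, 10, 20, 30, 40, 50]
relation = staircase_resistance(days, days, resistance_days=[15, 45],
                                infectivity_days=[35])
assay = simulate_infection_assay(relation, noise_sd=0.05, n_clones=10,
                                 rng=np.random.default_rng(1))
matrix = InfectionMatrix(assay)
print(f"{matrix.n_comparisons()} clone x virus comparisons called")

res_range, inf_range = ranges(matrix)
by_day = res_range.groupby(matrix.host_day_of()).mean()
print("mean resistance range by host day:", dict(by_day.round(2)))
print("infectivity range by virus day:  ", dict(inf_range.round(2)))

for iv in classify_match_mismatch(matrix):
    print(f"  {iv.state:8s} days {iv.start}-{iv.end}  ({iv.trigger})")

trade = tradeoff_correlation(matrix.control_growth(), res_range)
print(f"growth-vs-resistance correlation r = {trade.r:.2f} (p = {trade.p_value:.2f}); "
      "a negative value would indicate a cost of resistance.")
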