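"""Bland-Altman agreement analysis of a simulated validation run.

Plots device-minus-reference differences against the mean of the two
methods, with the protocol's ±5/10/15 mmHg bands and the classical
±1.96 SD limits of agreement, and checks how many points stay inside.
"""

from eshval import CohortSpec, PAPER_LIKE_DEVICE, ba_plot, ba_table, generate_cohort, inside_limits
from eshval.differences import build_cohort_pairs

cohort = generate_cohort(CohortSpec(seed=7), PAPER_LIKE_DEVICE)
pairs = build_cohort_pairs(cohort.sessions)

points = ba_table(pairs["sbp"]) + ba_table(pairs["dbp"])
out = ba_plot(points, limits=(5, 10, 15), out_path="bland_altman.png")
print("plot written to", out)

for ptype in ("sbp", "dbp"):
    for limit in (5, 10, 15):
        fraction, all_inside = inside_limits(ba_table(pairs[ptype]), limit)
        print(f"{ptype.upper()} within ±{limit:>2} mmHg: {fraction:6.1%}"
              f"{'  (all inside)' if all_inside else ''}")
# A device in good agreement keeps every point inside the ±15 mmHg band and
# the vast majority inside ±5 mmHg.
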