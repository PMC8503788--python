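"""Grade published-style achieved counts directly, without raw data.

Feeds pooled band counts and per-subject tallies straight into the grading
rules — useful for replaying any validation write-up's summary table.
"""

from eshval import grade_part1, grade_part2, overall_verdict
from eshval.grading import Part1Result, Part2Result

# counts of differences within 5/10/15 mmHg out of 99 comparisons
sbp_counts = (97, 99, 99)
dbp_counts = (98, 99, 99)

p1_sbp = Part1Result(counts=sbp_counts, grade=grade_part1(sbp_counts))
p1_dbp = Part1Result(counts=dbp_counts, grade=grade_part1(dbp_counts))
print("Part 1 SBP", sbp_counts, "->", p1_sbp.grade)
print("Part 1 DBP", dbp_counts, "->", p1_dbp.grade)

# per-subject tallies: 33 subjects with >=2 of 3 within 5 mmHg, 0 with none
g2, g3 = grade_part2((33, 0))
p2 = Part2Result(33, 0, g2, g3)
print("Part 2 (33, 0) ->", (g2, g3))

print("Overall:", overall_verdict(p1_sbp, p1_dbp, p2, p2))
# PASS means every component grade passed; a single failing component
# (e.g. only 23 subjects with 2/3 within 5) flips the overall verdict.
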