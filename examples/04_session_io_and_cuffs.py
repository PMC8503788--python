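"""Write a cohort to CSV, read it back, and apply the cuff-size rule.

Cohort files are flat CSV, one row per subject, with the screening funnel
in `#` comment lines — diff-able and spreadsheet-safe.
"""

import tempfile
from pathlib import Path

from eshval import CohortSpec, generate_screening_funnel, read_sessions, select_cuff, write_sessions

cohort = generate_screening_funnel(CohortSpec(seed=3))

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "cohort.csv"
    write_sessions(cohort, path)
    print("header of the written file:")
    print("\n".join(path.read_text().splitlines()[:4]))
    back = read_sessions(path)
    print("round-trip identical:", back.sessions == cohort.sessions)

# auscultatory cuff selection from arm circumference (cm)
for arm in (18, 30, 42, 42.1):
    print(f"arm {arm:>5} cm -> {select_cuff(arm)} cuff")
# The reference measurement is only valid with a correctly sized cuff;
# circumference below 17 cm has no supported cuff and raises an error.
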