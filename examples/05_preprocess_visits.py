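"""Annualise raw visit-level measurements with the trial exclusion rules.

Shows the preprocessing conventions on a tiny hand-made visit table:
measurements under 6 months post-randomisation are dropped (initial
treatment effect), implausible values are filtered, within-year values are
averaged, and patients without baseline or without follow-up are excluded —
with every exclusion counted.
"""

import pandas as pd

from riskpath.synthdata import preprocess_panel

raw = pd.DataFrame(
    [("A", 0, "hba1c", 7.0),     # baseline
     ("A", 3, "hba1c", 6.1),     # < 6 months: excluded
     ("A", 9, "hba1c", 7.0), ("A", 11, "hba1c", 7.4),   # year 1 -> 7.2
     ("A", 21, "hba1c", 7.6), ("A", 23, "hba1c", 99.0),  # 99 out of range
     ("B", 0, "hba1c", 8.1),     # baseline only: excluded
     ("B", 0, "sbp", 141.0), ("B", 15, "sbp", 137.0),
     ("C", 14, "hba1c", 7.3)],   # no baseline: excluded
    columns=["patient", "month", "variable", "value"])

annual, log = preprocess_panel(raw, ranges={"hba1c": (3, 20),
                                            "sbp": (60, 250)})
print(annual.to_string(index=False))
print("\nexclusion log:")
for key, count in log.items():
    print(f"  {key}: {count}")

# Patient A's two in-range year-1 readings average to 7.2; the month-3 value
# and the implausible 99 never reach the panel, and B/C survive only for the
# variables where they have both baseline and follow-up.
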