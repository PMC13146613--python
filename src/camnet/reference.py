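"""Published descriptive statistics of the reference ED cohorts.

These count tables summarise the two emergency-department cohorts whose
shape the synthetic generators emulate: a 6,001-patient urban ED cohort
(2,731 AMI) and a 3,605-record triage-only cohort (1,462 AMI).  Rows are
outcome levels (AMI = 0, AMI = 1); columns are variable states.  They are
inputs for descriptive-statistic checks and the guideline-rule baseline —
nothing in the modelling pipeline depends on them.
"""

from __future__ import annotations

import numpy as np

#: Outcome-by-state counts, 6,001-patient ED cohort (selected variables).
ED_DESCRIPTIVE_COUNTS: dict[str, list[list[int]]] = {
    "sex": [[1568, 1702], [1020, 1711]],
    "smoking": [[2457, 813], [1574, 1157]],
    "chest_pain": [[2924, 346], [1371, 1360]],
    "DYS": [[1965, 1305], [563, 2168]],
    "CD": [[2642, 628], [1294, 1437]],
    "diabetes": [[1966, 1304], [1613, 1118]],
    "UA": [[9, 2910, 351], [2, 2356, 373]],
    "cTnI": [[3047, 223], [2688, 43]],
}

#: Outcome-by-state counts, 3,605-record triage cohort.
TRIAGE_DESCRIPTIVE_COUNTS: dict[str, list[list[int]]] = {
    "sex": [[983, 1160], [621, 841]],
    "chest_pain": [[1586, 557], [776, 686]],
}

#: Joint counts of troponin elevation vs ischemia evidence by outcome.
#: Columns: troponin elevated & (chest pain or STSA); troponin elevated &
#: neither; troponin normal & (chest pain or STSA); troponin normal &
#: neither.  Rows: AMI = 0, AMI = 1.
TROPONIN_RULE_COUNTS = np.array(
    [[15, 208, 508, 2539], [16, 27, 1658, 1030]]
)
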