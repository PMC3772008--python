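"""Reference inputs from the stratified-soil Mn(II)-oxidizer survey.

These small tables are the published inputs the analysis pipeline re-derives
summaries from: the per-horizon activity-category counts of the isolate
survey, the genus distribution of the 24 ARDRA-representative high-activity
isolates, and the reported per-horizon DGGE Shannon indices (used only as a
qualitative ordering reference; the underlying densitometric gel data were
never released).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "TABLE1_COUNTS",
    "GENUS_COUNTS",
    "REPORTED_SHANNON",
    "activity_records_from_table1",
]

#: Horizon x activity-category isolate counts from the soil survey.
TABLE1_COUNTS = pd.DataFrame(
    [[8, 32, 143, 9], [22, 17, 54, 67], [20, 29, 19, 83]],
    index=["A", "B", "C"],
    columns=["high", "medium", "low", "none"],
)

#: Genus distribution of the 24 ARDRA-representative high-activity isolates.
GENUS_COUNTS = {
    "Arthrobacter": 5,
    "Bacillus": 5,
    "Aurantimonas": 2,
    "Pseudomonas": 2,
    "Escherichia": 2,
    "Microbacterium": 1,
    "Cupriavidus": 1,
    "Variovorax": 1,
    "Cellulomonas": 1,
    "Paracoccus": 1,
    "Ralstonia": 1,
    "Rhodococcus": 1,
    "Agromyces": 1,
}

#: Reported per-horizon Shannon indices of the untreated-soil DGGE lanes.
REPORTED_SHANNON = {"A": 2.72, "B": 1.89, "C": 1.48}


def activity_records_from_table1():
    """Expand :data:`TABLE1_COUNTS` into per-isolate activity records.

    Representative in-category concentrations are drawn deterministically at
    each category's midpoint semantics via :func:`mnox.simulate.simulate_activity_table`
    with seed 0; this helper is a convenience for tabulation-only analyses,
    where only horizon and category matter.
    """
    from .simulate import simulate_activity_table

    spec = {h: TABLE1_COUNTS.loc[h].to_dict() for h in TABLE1_COUNTS.index}
    return simulate_activity_table(spec, seed=0)
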