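#!/usr/bin/env python
"""Tabulate Mn(II)-oxidizing activity by soil horizon and category.

Reads the synthetic isolate records (whose horizon x category structure is
the survey's), builds the contingency table, and reports the compiled
per-category counts, the share of each category in the whole isolate set,
and the horizon breakdown within the low- and high-activity categories.
"""

from pathlib import Path

from mnox.oxidation import read_activity_csv, tabulate

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_activity_csv(RESULTS / "synthetic" / "activity.csv")
    table = tabulate(records)
    table.to_frame().to_csv(RESULTS / "activity_table.csv")
    table.within_category_percentages.round(1).to_csv(
        RESULTS / "activity_within_category_pct.csv"
    )

    print(table.to_frame())
    print(f"\ntotal isolates: {table.grand_total}")
    print("share of all isolates (%):",
          {k: float(v) for k, v in table.column_percentages.round(1).items()})
    print("low-activity isolates by horizon (%):",
          {k: float(v) for k, v in table.within_category_percentages['low'].round(1).items()})
    print("high-activity isolates by horizon (%):",
          {k: float(v) for k, v in table.within_category_percentages['high'].round(1).items()})
    print(f"isolates with any activity: {table.active_fraction_percent:.1f}%")


if __name__ == "__main__":
    main()
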