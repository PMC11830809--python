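#!/usr/bin/env python
"""Cumulative activity scores and qPCR-projected community profiles.

Reads the report produced by 02_electron_budgets.py and presents the
five-indicator activity score per reactor plus the depth-normalized,
qPCR-projected class-level community table (with shallow samples
excluded). Writes results/activity_scores.tsv and
results/community_percent.tsv.
"""

import json
from pathlib import Path

import pandas as pd

REPORT = Path("results/report/report.json")


def main() -> None:
    report = json.loads(REPORT.read_text())
    details = report["details"]

    activity = pd.DataFrame(
        {rid: d["activity_components"] for rid, d in details.items()}
    ).T.sort_values("total", ascending=False)
    activity.round(3).rename_axis("reactor_id").to_csv(
        "results/activity_scores.tsv", sep="\t"
    )
    print("activity scores (components in [0,1], total in [0,5]):")
    print(activity.round(2).to_string())

    community = report["community"]
    excluded = community["excluded"]
    if excluded:
        print("\nexcluded samples:")
        for e in excluded:
            print(f"  {e['sample_id']}: {e['reason']}")
    table = pd.DataFrame(community["normalized_percent"]).fillna(0.0)
    table.round(2).rename_axis("taxon").to_csv(
        "results/community_percent.tsv", sep="\t"
    )
    print("\nqPCR-projected class-level abundances (%):")
    print(table.round(1).to_string())
    print(
        "\nnote: the 'Archaea' block comes from the qPCR domain split —"
        " universal amplicon primers resolve no archaeal taxa."
    )


if __name__ == "__main__":
    main()
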