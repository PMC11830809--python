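#!/usr/bin/env python
"""Analyze the synthetic experiment: coulombs, budgets, classifications.

Runs the full pipeline on the dataset written by 01_simulate_reactors.py
and compares the donor-budget classification of every reactor against
the generator's ground truth. Writes the per-reactor report (JSON + TSV)
under results/report/.
"""

from pathlib import Path

import pandas as pd

from biocathode.pipeline import run_analyze

DATASET = Path("results/synthetic_dataset")
OUT = Path("results/report")


def main() -> None:
    report = run_analyze(DATASET / "config.yaml", OUT)
    truth = pd.read_csv(DATASET / "truth.tsv", sep="\t")
    expected = dict(zip(truth["reactor_id"], truth["expected_classification"]))

    print(f"analyzed {len(report['summary'])} reactors -> {OUT}\n")
    rows = []
    for r in report["summary"]:
        rid = r["reactor_id"]
        rows.append(
            {
                "reactor": rid,
                "Q_cathode_C": round(r["q_cathode_C"], 1),
                "Q_products_C": round(r["q_products_C"], 1),
                "CE_%": None if r["ce_total_percent"] is None else round(r["ce_total_percent"], 1),
                "classification": r["classification"],
                "matches_truth": r["classification"] == expected[rid],
            }
        )
    table = pd.DataFrame(rows)
    print(table.to_string(index=False))
    n_match = int(table["matches_truth"].sum())
    print(f"\n{n_match}/{len(table)} classifications match the generating scenario")
    flagged = [r["reactor_id"] for r in report["summary"] if r["ce_over_100"]]
    if flagged:
        print(f"CE > 100% (additional donors required): {', '.join(flagged)}")


if __name__ == "__main__":
    main()
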