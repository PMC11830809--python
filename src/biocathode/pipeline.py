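"""End-to-end orchestration: simulate datasets, analyze them, write reports.

``run_analyze`` consumes a YAML config binding files to reactors and
produces a per-reactor report covering the electrochemical summary, the
donor budget with its classification, HER feasibility at the reactor's
pH and temperature, the cumulative activity score, and the qPCR-projected
community table. ``analyze_inputs`` is the same computation on in-memory
objects (used by tests and the synthetic recovery studies);
``run_simulate`` writes a synthetic experiment in exactly the formats
``run_analyze`` reads.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Optional, Sequence

import pandas as pd
import yaml

from biocathode import io as bio_io
from biocathode.budget import build_donor_budget
from biocathode.community import (
    activity_scores,
    aggregate_taxa,
    depth_normalize,
    qpcr_domain_normalize,
)
from biocathode.datatypes import (
    AmpliconTable,
    BiofilmScore,
    CODMeasurement,
    CurrentTrace,
    MetaboliteSeries,
    QPCRResult,
    ReactorRecord,
)
from biocathode.electrochem import coulombs_to_h2_mM, summarize_trace
from biocathode.synth import ExperimentDataset, ReactorBundle, generate_experiment
from biocathode.thermo import (
    HERCondition,
    celsius_to_kelvin,
    her_feasible,
    her_potential,
    load_threshold_table,
    threshold_at_temperature,
)

DEFAULT_OPTIONS: dict[str, Any] = {
    "thiosulfate_tolerance": 0.5,
    "overpotential_V": 0.2,
    "target_depth": 100_000,
    "min_depth": None,
    "depth_mode": "proportional",
    "subsample_seed": 0,
    "community_rank": "class",
    "community_min_percent": 1.0,
}


def analyze_inputs(
    records: Sequence[ReactorRecord],
    traces: dict[str, CurrentTrace],
    metabolites: dict[str, list[MetaboliteSeries]],
    cod: dict[str, CODMeasurement],
    qpcr: dict[str, QPCRResult],
    biofilm: dict[str, BiofilmScore],
    amplicons: Optional[AmpliconTable] = None,
    options: Optional[dict[str, Any]] = None,
) -> dict[str, Any]:
    """Run every analysis stage over in-memory inputs; returns the report.

    A failure in one reactor is recorded under ``errors`` and does not
    stop the others. Missing inputs (no COD, no amplicon sample) yield
    partial rows with explicit None markers.
    """
    opts = {**DEFAULT_OPTIONS, **(options or {})}
    thresholds = load_threshold_table()
    summary_rows: list[dict[str, Any]] = []
    details: dict[str, Any] = {}
    errors: dict[str, str] = {}
    indicator_rows: dict[str, dict[str, float]] = {}

    for record in records:
        rid = record.reactor_id
        try:
            trace = traces[rid]
            ts = summarize_trace(trace)
            deltas = {m.compound_name: m.delta_mM for m in metabolites.get(rid, [])}
            budget = build_donor_budget(
                record,
                q_cathode_C=ts.total_coulombs_C,
                metabolite_deltas_mM=deltas,
                cod=cod.get(rid),
                thiosulfate_tolerance=opts["thiosulfate_tolerance"],
            )
            p_h2 = threshold_at_temperature(thresholds, record.temperature_C)
            cond = HERCondition(
                ph=record.ph,
                temperature_K=celsius_to_kelvin(record.temperature_C),
                p_h2_atm=p_h2,
            )
            e_her = her_potential(cond)
            feasible = her_feasible(
                record.cathode_potential_V_SHE, cond, opts["overpotential_V"]
            )
            organic_acid_production = sum(
                d for n, d in deltas.items() if d > 0 and n in budget.product_breakdown_C
            )
            q = qpcr.get(rid)
            bf = biofilm.get(rid)
            indicator_rows[rid] = {
                "biofilm": bf.score if bf else 0.0,
                "bacterial_qpcr": q.bacterial_copies_per_cm2 if q else 0.0,
                "archaeal_qpcr": q.archaeal_copies_per_cm2 if q else 0.0,
                "organic_acids": organic_acid_production,
                "biocoulombs": ts.biocoulombs_C,
            }
            summary_rows.append(
                {
                    "reactor_id": rid,
                    "inoculum": record.inoculum,
                    "temperature_C": record.temperature_C,
                    "ph": record.ph,
                    "electron_acceptor": record.electron_acceptor,
                    "j_1h_A_per_cm2": ts.j_1h_A_per_cm2,
                    "j_max_A_per_cm2": ts.j_max_A_per_cm2,
                    "t_at_jmax_s": ts.t_at_jmax_s,
                    "fold_increase": ts.fold_increase,
                    "total_coulombs_C": ts.total_coulombs_C,
                    "biocoulombs_C": ts.biocoulombs_C,
                    "q_cathode_C": budget.q_cathode_C,
                    "q_formate_C": budget.q_formate_C,
                    "q_thiosulfate_C": budget.q_thiosulfate_C,
                    "q_yeast_extract_C": budget.q_yeast_extract_C,
                    "q_products_C": budget.q_products_C,
                    "ce_total_percent": budget.ce_total_percent,
                    "ce_over_100": budget.ce_over_100,
                    "carbon_fixation_flag": budget.carbon_fixation_flag,
                    "thiosulfate_is_donor": budget.thiosulfate_is_donor,
                    "membrane_crossover_caveat": budget.membrane_crossover_caveat,
                    "classification": budget.classification,
                    "her_potential_V": e_her,
                    "her_feasible": feasible,
                    "h2_max_mM": coulombs_to_h2_mM(
                        ts.total_coulombs_C, record.catholyte_volume_L
                    ),
                    "organic_acids_mM": organic_acid_production,
                    "biofilm_score": bf.score if bf else None,
                    "bacterial_copies_per_cm2": (
                        q.bacterial_copies_per_cm2 if q else None
                    ),
                    "archaeal_copies_per_cm2": (
                        q.archaeal_copies_per_cm2 if q else None
                    ),
                }
            )
            details[rid] = {
                "product_breakdown_C": budget.product_breakdown_C,
                "ce_per_product_percent": budget.ce_per_product_percent,
                "metabolite_deltas_mM": deltas,
            }
        except Exception as exc:  # keep processing the other reactors
            errors[rid] = f"{type(exc).__name__}: {exc}"

    # Activity scores need the across-reactor maxima, hence a second pass.
    activity: Optional[pd.DataFrame] = None
    if indicator_rows:
        activity = activity_scores(pd.DataFrame(indicator_rows).T)
        act_total = activity["total"].to_dict()
        for row in summary_rows:
            row["activity_total"] = act_total.get(row["reactor_id"])
        for rid in details:
            if rid in activity.index:
                details[rid]["activity_components"] = activity.loc[rid].to_dict()

    community: dict[str, Any] = {}
    if amplicons is not None and amplicons.counts.shape[1] > 0:
        normalized, excluded = depth_normalize(
            amplicons,
            target_depth=opts["target_depth"],
            min_depth=opts["min_depth"],
            mode=opts["depth_mode"],
            seed=opts["subsample_seed"],
        )
        aggregated = aggregate_taxa(
            normalized,
            rank=opts["community_rank"],
            min_percent=opts["community_min_percent"],
        )
        projected: dict[str, dict[str, float]] = {}
        for sample in aggregated.columns:
            rel = aggregated[sample] / aggregated[sample].sum() * 100.0
            if sample in qpcr:
                try:
                    projected[sample] = qpcr_domain_normalize(rel, qpcr[sample]).to_dict()
                except ValueError:
                    projected[sample] = {"_flag": "no qPCR signal"}
            else:
                projected[sample] = rel.to_dict()
        community = {
            "excluded": excluded.to_dict(orient="records"),
            "normalized_percent": projected,
        }

    return {
        "summary": summary_rows,
        "details": details,
        "community": community,
        "errors": errors,
        "options": {k: v for k, v in opts.items()},
    }


def analyze_bundles(
    bundles: Sequence[ReactorBundle],
    amplicons: Optional[AmpliconTable] = None,
    options: Optional[dict[str, Any]] = None,
) -> dict[str, Any]:
    """Analyze synthetic reactor bundles (in-memory fast path)."""
    return analyze_inputs(
        records=[b.record for b in bundles],
        traces={b.record.reactor_id: b.trace for b in bundles},
        metabolites={b.record.reactor_id: b.metabolites for b in bundles},
        cod={b.record.reactor_id: b.cod for b in bundles},
        qpcr={b.record.reactor_id: b.qpcr for b in bundles},
        biofilm={b.record.reactor_id: b.biofilm for b in bundles},
        amplicons=amplicons,
        options=options,
    )


def run_analyze(config_path, outdir, options: Optional[dict[str, Any]] = None) -> dict:
    """File-based entry point: read the config, analyze, write the report."""
    records, bindings = bio_io.read_reactor_config(config_path)
    traces, metabolites = {}, {}
    for record in records:
        binding = bindings["reactors"][record.reactor_id]
        if binding.get("trace"):
            traces[record.reactor_id] = bio_io.read_trace(
                binding["trace"],
                area_cm2=record.cathode_area_cm2,
                reactor_id=record.reactor_id,
            )
        if binding.get("metabolites"):
            metabolites[record.reactor_id] = bio_io.read_metabolites(
                binding["metabolites"], reactor_id=record.reactor_id
            )
    tables = bindings["tables"]
    cod = bio_io.read_cod_table(tables["cod"]) if tables.get("cod") else {}
    qpcr = bio_io.read_qpcr_table(tables["qpcr"]) if tables.get("qpcr") else {}
    biofilm = (
        bio_io.read_biofilm_table(tables["biofilm"]) if tables.get("biofilm") else {}
    )
    amplicons = None
    if tables.get("amplicon_counts") and tables.get("amplicon_taxonomy"):
        amplicons = bio_io.read_amplicon(
            tables["amplicon_counts"], tables["amplicon_taxonomy"]
        )
    merged_options = {**bindings.get("options", {}), **(options or {})}
    report = analyze_inputs(
        records, traces, metabolites, cod, qpcr, biofilm, amplicons, merged_options
    )
    bio_io.write_report(report, outdir)
    return report


def run_simulate(
    outdir,
    master_seed: int = 0,
    scenario_mix: Optional[Sequence] = None,
    n_replicates: int = 1,
    trace_dt_s: float = 60.0,
) -> ExperimentDataset:
    """Write a synthetic experiment in the pipeline's input formats.

    Produces per-reactor trace and metabolite files, the shared COD/qPCR/
    biofilm and amplicon tables, a ground-truth TSV, and a ready-to-run
    config.yaml, so that ``run_analyze(outdir / 'config.yaml', ...)``
    closes the loop without manual edits.
    """
    outdir = Path(outdir)
    (outdir / "traces").mkdir(parents=True, exist_ok=True)
    (outdir / "metabolites").mkdir(parents=True, exist_ok=True)
    dataset = generate_experiment(
        scenario_mix=scenario_mix,
        master_seed=master_seed,
        n_replicates=n_replicates,
        trace_dt_s=trace_dt_s,
    )
    cod_rows, qpcr_rows, biofilm_rows, reactor_entries = [], [], [], []
    for bundle in dataset.bundles:
        rid = bundle.record.reactor_id
        bio_io.write_trace(bundle.trace, outdir / "traces" / f"{rid}.csv")
        bio_io.write_metabolites(
            bundle.metabolites, outdir / "metabolites" / f"{rid}.csv"
        )
        cod_rows.append(
            {
                "reactor_id": rid,
                "cod_initial_gO2_per_L": bundle.cod.cod_initial_gO2_per_L,
                "cod_final_gO2_per_L": bundle.cod.cod_final_gO2_per_L,
            }
        )
        qpcr_rows.append(
            {
                "reactor_id": rid,
                "bacterial_copies_per_cm2": bundle.qpcr.bacterial_copies_per_cm2,
                "archaeal_copies_per_cm2": bundle.qpcr.archaeal_copies_per_cm2,
            }
        )
        biofilm_rows.append({"reactor_id": rid, "score": bundle.biofilm.score})
        reactor_entries.append(
            {
                "reactor_id": rid,
                "inoculum": bundle.record.inoculum,
                "temperature_C": bundle.record.temperature_C,
                "ph": bundle.record.ph,
                "electron_acceptor": bundle.record.electron_acceptor,
                "trace": f"traces/{rid}.csv",
                "metabolites": f"metabolites/{rid}.csv",
            }
        )
    pd.DataFrame(cod_rows).to_csv(outdir / "cod.csv", index=False)
    pd.DataFrame(qpcr_rows).to_csv(outdir / "qpcr.csv", index=False)
    pd.DataFrame(biofilm_rows).to_csv(outdir / "biofilm.csv", index=False)
    bio_io.write_amplicon(
        dataset.amplicons,
        outdir / "amplicon_counts.tsv",
        outdir / "amplicon_taxonomy.tsv",
    )
    dataset.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    config = {
        "defaults": {},
        "tables": {
            "cod": "cod.csv",
            "qpcr": "qpcr.csv",
            "biofilm": "biofilm.csv",
            "amplicon_counts": "amplicon_counts.tsv",
            "amplicon_taxonomy": "amplicon_taxonomy.tsv",
        },
        "reactors": reactor_entries,
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return dataset
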