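"""Cumulative microbial-activity scoring and community-table normalizations.

Two independent pieces live here. The activity score condenses five
heterogeneous indicators of microbial activity per reactor — biofilm
coverage, bacterial and archaeal 16S copies, organic acid production,
and biocoulombs — into one comparable number by normalizing each to
[0, 1] and summing. Continuous indicators are divided by their maximum
across all reactors; the ordinal biofilm score by its scale maximum (5).

The community-table operations prepare amplicon data for display and
ordination: fixed-depth normalization with exclusion of shallow samples,
rank-level aggregation with an "other" pool, and projection of bacterial
relative abundances onto the bacteria-vs-archaea split measured by qPCR
(universal amplicon primers can miss archaea entirely, so amplicon
proportions alone misrepresent archaea-dominated electrodes).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from biocathode.datatypes import TAXONOMY_RANKS, AmpliconTable, QPCRResult

ACTIVITY_CONTINUOUS = (
    "bacterial_qpcr",
    "archaeal_qpcr",
    "organic_acids",
    "biocoulombs",
)
BIOFILM_SCALE_MAX = 5.0


def activity_scores(indicators: pd.DataFrame) -> pd.DataFrame:
    """Per-reactor activity components in [0, 1] and their total in [0, 5].

    ``indicators`` is indexed by reactor id with columns ``biofilm`` (0-5)
    plus the four continuous indicators (any non-negative unit). Each
    continuous column is divided by its across-reactor maximum (all-zero
    columns score 0 everywhere); biofilm is divided by 5. The result holds
    the five components plus ``total``.
    """
    required = ("biofilm",) + ACTIVITY_CONTINUOUS
    missing = [c for c in required if c not in indicators.columns]
    if missing:
        raise ValueError(f"indicator table missing columns: {missing}")
    if len(indicators) < 1:
        raise ValueError("need at least one reactor")
    biofilm = indicators["biofilm"]
    if ((biofilm < 0) | (biofilm > BIOFILM_SCALE_MAX)).any():
        raise ValueError("biofilm scores must lie in [0, 5]")
    out = pd.DataFrame(index=indicators.index)
    out["biofilm"] = biofilm / BIOFILM_SCALE_MAX
    for col in ACTIVITY_CONTINUOUS:
        values = indicators[col].astype(float)
        if (values < 0).any():
            raise ValueError(f"indicator {col!r} has negative values")
        peak = values.max()
        out[col] = values / peak if peak > 0 else 0.0
    out["total"] = out[list(required)].sum(axis=1)
    return out


def depth_normalize(
    table: AmpliconTable,
    target_depth: int = 100_000,
    min_depth: Optional[int] = None,
    mode: str = "proportional",
    seed: Optional[int] = None,
) -> tuple[AmpliconTable, pd.DataFrame]:
    """Normalize every sample to a fixed read depth; exclude shallow ones.

    Samples with fewer than ``min_depth`` reads (default: the target depth
    itself) are dropped and listed in the returned exclusion table with
    their depth and reason. Remaining samples are brought to exactly
    ``target_depth`` either by proportional rescaling (default; fractional
    counts rounded to the nearest integer with the residual assigned to the
    most abundant taxon so column sums are exact) or by seeded subsampling
    without replacement (multivariate hypergeometric draw).
    """
    if mode not in ("proportional", "subsample"):
        raise ValueError("mode must be 'proportional' or 'subsample'")
    threshold = target_depth if min_depth is None else min_depth
    depths = table.sample_depths()
    excluded = [
        {
            "sample_id": s,
            "depth": int(depths[s]),
            "reason": f"depth {int(depths[s])} < minimum {threshold}",
        }
        for s in table.sample_ids
        if depths[s] < threshold
    ]
    kept = [s for s in table.sample_ids if depths[s] >= threshold]
    rng = np.random.default_rng(seed)
    columns = {}
    for s in kept:
        counts = table.counts[s].to_numpy(dtype=np.int64)
        if mode == "subsample":
            columns[s] = rng.multivariate_hypergeometric(counts, target_depth)
        else:
            scaled = counts * (target_depth / counts.sum())
            rounded = np.round(scaled).astype(np.int64)
            residual = target_depth - int(rounded.sum())
            if residual != 0:
                rounded[int(np.argmax(counts))] += residual
            columns[s] = rounded
    normalized = pd.DataFrame(columns, index=table.counts.index, dtype=np.int64)
    if not kept:
        normalized = table.counts.iloc[:, :0].copy()
    return (
        AmpliconTable(counts=normalized, taxonomy=table.taxonomy.copy()),
        pd.DataFrame(excluded, columns=["sample_id", "depth", "reason"]),
    )


def qpcr_domain_normalize(
    bacterial_relative_percent: pd.Series, qpcr: QPCRResult
) -> pd.Series:
    """Project bacterial relative abundances onto the qPCR domain split.

    ``bacterial_relative_percent`` sums to 100 (%) over bacterial taxa for
    one sample. With f = bacterial / (bacterial + archaeal) copies, each
    displayed taxon becomes relative% * f and a single ``Archaea`` block
    takes 100 * (1 - f), so the output still sums to 100%. (A single block
    is used because universal amplicon primers resolve no archaeal taxa.)

    Raises when both qPCR counts are zero: the projection is undefined and
    the sample should be flagged upstream.
    """
    total = qpcr.bacterial_copies_per_cm2 + qpcr.archaeal_copies_per_cm2
    if total == 0:
        raise ValueError(
            f"sample {qpcr.reactor_id}: no qPCR signal; projection undefined"
        )
    values = bacterial_relative_percent.astype(float)
    if len(values) and not np.isclose(values.sum(), 100.0, atol=1e-6):
        raise ValueError("bacterial relative abundances must sum to 100%")
    f = qpcr.bacterial_copies_per_cm2 / total
    projected = values * f
    projected.loc["Archaea"] = 100.0 * (1.0 - f)
    return projected


def aggregate_taxa(
    table: AmpliconTable,
    rank: str,
    min_percent: Optional[float] = None,
    top_n: Optional[int] = None,
) -> pd.DataFrame:
    """Sum ASV counts by taxon at a rank, pooling rare taxa into "other".

    A taxon is kept when its relative abundance reaches ``min_percent`` in
    at least one sample (and, if ``top_n`` is given, when it ranks among
    the top_n by maximum abundance); everything else is pooled into an
    ``other`` row. ASVs unassigned at the rank aggregate under "NA".
    """
    if rank not in TAXONOMY_RANKS:
        raise ValueError(f"unknown rank {rank!r}; allowed: {TAXONOMY_RANKS}")
    labels = table.taxonomy[rank].fillna("NA")
    grouped = table.counts.groupby(labels).sum()
    if len(grouped) == 0 or table.counts.shape[1] == 0:
        return grouped
    percent = grouped / grouped.sum(axis=0) * 100.0
    max_percent = percent.max(axis=1).sort_values(ascending=False)
    keep = max_percent.index
    if min_percent is not None:
        keep = [t for t in keep if max_percent[t] >= min_percent]
    if top_n is not None:
        keep = list(keep)[:top_n]
    keep = [t for t in max_percent.index if t in set(keep)]
    kept = grouped.loc[keep]
    pooled = grouped.drop(index=keep).sum(axis=0)
    if pooled.sum() > 0:
        kept.loc["other"] = pooled
    return kept
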