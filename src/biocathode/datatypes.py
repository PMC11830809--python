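"""Domain types for cathodic enrichment reactor datasets.

All containers are validated on construction; internal units are SI
(seconds, amperes, litres, moles) with mM and days confined to I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from biocathode.constants import (
    DEFAULT_CATHODE_AREA_CM2,
    DEFAULT_CATHODE_POTENTIAL_V_SHE,
    DEFAULT_CATHOLYTE_VOLUME_L,
    DEFAULT_DURATION_S,
)

INOCULA = ("BJ", "LC2")
ELECTRON_ACCEPTORS = ("FeOx", "NO3", "O2", "SO4", "CO2", "HCOO")
POLARITY_CONVENTIONS = ("cathodic_negative", "magnitude")
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class ReactorRecord:
    """Metadata for one reactor: factor levels plus geometry and operation.

    Factor levels (inoculum, temperature, pH, acceptor) are explicit fields;
    the free-text id is never parsed. Defaults reflect the standard H-cell
    setup: 0.25 L catholyte, 6-day run, 1.5 x 1.5 cm graphite plate cathode
    (geometric single-face area) poised at -0.6 V vs SHE.
    """

    reactor_id: str
    inoculum: str
    temperature_C: float
    ph: float
    electron_acceptor: str
    catholyte_volume_L: float = DEFAULT_CATHOLYTE_VOLUME_L
    duration_s: float = DEFAULT_DURATION_S
    cathode_area_cm2: float = DEFAULT_CATHODE_AREA_CM2
    cathode_potential_V_SHE: float = DEFAULT_CATHODE_POTENTIAL_V_SHE

    def __post_init__(self) -> None:
        if self.inoculum not in INOCULA:
            raise ValueError(
                f"unknown inoculum {self.inoculum!r}; allowed: {INOCULA}"
            )
        if self.electron_acceptor not in ELECTRON_ACCEPTORS:
            raise ValueError(
                f"unknown electron_acceptor {self.electron_acceptor!r}; "
                f"allowed: {ELECTRON_ACCEPTORS}"
            )
        if not self.catholyte_volume_L > 0:
            raise ValueError("catholyte_volume_L must be > 0")
        if not self.cathode_area_cm2 > 0:
            raise ValueError("cathode_area_cm2 must be > 0")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be > 0")
        if not 0 <= self.temperature_C <= 150:
            raise ValueError("temperature_C outside [0, 150]")
        if not 0 <= self.ph <= 14:
            raise ValueError("ph outside [0, 14]")


@dataclass
class CurrentTrace:
    """Chronoamperometry record for one reactor cathode.

    ``polarity_convention`` documents how the instrument signed the current:
    ``cathodic_negative`` (reduction currents negative, the potentiostat
    default) or ``magnitude``. All downstream statistics use |I|.
    """

    reactor_id: str
    time_s: np.ndarray
    current_A: np.ndarray
    area_cm2: float
    polarity_convention: str = "cathodic_negative"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_A = np.asarray(self.current_A, dtype=float)
        if self.polarity_convention not in POLARITY_CONVENTIONS:
            raise ValueError(
                f"unknown polarity {self.polarity_convention!r}; "
                f"allowed: {POLARITY_CONVENTIONS}"
            )
        if self.time_s.ndim != 1 or self.time_s.shape != self.current_A.shape:
            raise ValueError("time_s and current_A must be 1-D and equal length")
        if len(self.time_s) < 2:
            raise ValueError("trace needs at least 2 samples")
        if self.time_s[0] < 0:
            raise ValueError("time must be >= 0")
        diffs = np.diff(self.time_s)
        if np.any(diffs <= 0):
            idx = int(np.argmax(diffs <= 0))
            raise ValueError(
                f"time not increasing at row {idx + 1} "
                f"(t={self.time_s[idx + 1]!r} after t={self.time_s[idx]!r})"
            )
        if not self.area_cm2 > 0:
            raise ValueError("area_cm2 must be > 0")
        if not np.all(np.isfinite(self.current_A)):
            raise ValueError("current contains non-finite values")

    @property
    def abs_current_A(self) -> np.ndarray:
        return np.abs(self.current_A)

    @property
    def abs_j_A_per_cm2(self) -> np.ndarray:
        """Magnitude of the current density on the geometric electrode area."""
        return np.abs(self.current_A) / self.area_cm2

    @property
    def span_s(self) -> tuple[float, float]:
        return float(self.time_s[0]), float(self.time_s[-1])


@dataclass
class MetaboliteSeries:
    """Concentration time course of one compound in one reactor (mM)."""

    reactor_id: str
    compound_name: str
    timepoints_s: np.ndarray
    concentrations_mM: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints_s = np.asarray(self.timepoints_s, dtype=float)
        self.concentrations_mM = np.asarray(self.concentrations_mM, dtype=float)
        if self.timepoints_s.shape != self.concentrations_mM.shape:
            raise ValueError("timepoints and concentrations must have equal length")
        if np.any(np.diff(self.timepoints_s) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.concentrations_mM < 0):
            raise ValueError("concentrations must be >= 0")

    @property
    def delta_mM(self) -> float:
        """Final minus initial concentration (consumption negative)."""
        return float(self.concentrations_mM[-1] - self.concentrations_mM[0])


@dataclass(frozen=True)
class CODMeasurement:
    """Initial and final chemical oxygen demand for one reactor, g O2/L."""

    reactor_id: str
    cod_initial_gO2_per_L: float
    cod_final_gO2_per_L: float

    def __post_init__(self) -> None:
        if self.cod_initial_gO2_per_L < 0 or self.cod_final_gO2_per_L < 0:
            raise ValueError("COD values must be >= 0")


@dataclass(frozen=True)
class QPCRResult:
    """Absolute 16S copy numbers on the cathode, per cm2, by domain."""

    reactor_id: str
    bacterial_copies_per_cm2: float
    archaeal_copies_per_cm2: float

    def __post_init__(self) -> None:
        if self.bacterial_copies_per_cm2 < 0 or self.archaeal_copies_per_cm2 < 0:
            raise ValueError("copy numbers must be >= 0")


@dataclass(frozen=True)
class BiofilmScore:
    """Ordinal microscopy score, 0 (none) to 5 (full electrode coverage)."""

    reactor_id: str
    score: int

    def __post_init__(self) -> None:
        if not isinstance(self.score, (int, np.integer)) or not 0 <= self.score <= 5:
            raise ValueError("biofilm score must be an integer in [0, 5]")


@dataclass
class AmpliconTable:
    """ASV count matrix with an aligned rank-lineage taxonomy.

    ``counts``: DataFrame indexed by asv_id, one integer column per sample.
    ``taxonomy``: DataFrame indexed by asv_id with the fixed rank columns
    domain..genus; unassigned ranks hold the string "NA".
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.values < 0).any():
            raise ValueError("counts must be >= 0")
        if not np.allclose(counts.values, np.round(counts.values)):
            raise ValueError("counts must be integral")
        self.counts = counts.astype(np.int64)
        missing = [r for r in TAXONOMY_RANKS if r not in self.taxonomy.columns]
        if missing:
            raise ValueError(f"taxonomy missing ranks: {missing}")
        if not self.counts.index.equals(self.taxonomy.index):
            self.taxonomy = self.taxonomy.reindex(self.counts.index)
            if self.taxonomy.isna().all(axis=1).any():
                raise ValueError("taxonomy does not cover all ASVs in counts")
        self.taxonomy = self.taxonomy.fillna("NA")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_depths(self) -> pd.Series:
        return self.counts.sum(axis=0)
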