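import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from biocathode.datatypes import AmpliconTable, CurrentTrace, ReactorRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def flat_trace() -> CurrentTrace:
    """Constant 10 mA magnitude over 6 days, cathodic sign, 1 h sampling."""
    t = np.arange(0.0, 518_400.0 + 1, 3600.0)
    return CurrentTrace(
        reactor_id="flat",
        time_s=t,
        current_A=np.full_like(t, -0.010),
        area_cm2=2.25,
    )


@pytest.fixture
def reactor_record() -> ReactorRecord:
    return ReactorRecord(
        reactor_id="LC2-75-4.5-NO3",
        inoculum="LC2",
        temperature_C=75.0,
        ph=4.5,
        electron_acceptor="NO3",
    )


@pytest.fixture
def toy_amplicons() -> AmpliconTable:
    """Three samples at depths 200k / 150k / 45k over four genera."""
    counts = pd.DataFrame(
        {
            "R1": [100_000, 60_000, 30_000, 10_000],
            "R2": [75_000, 45_000, 22_500, 7_500],
            "R3": [20_000, 15_000, 7_000, 3_000],
        },
        index=["ASV1", "ASV2", "ASV3", "ASV4"],
    )
    taxonomy = pd.DataFrame(
        {
            "domain": ["Bacteria"] * 4,
            "phylum": ["Firmicutes", "Firmicutes", "Proteobacteria", "Bacteroidota"],
            "class": ["Bacilli", "Bacilli", "Gammaproteobacteria", "Bacteroidia"],
            "order": ["Bacillales", "Bacillales", "Alteromonadales", "Marinifilales"],
            "family": ["Bacillaceae", "Bacillaceae", "Pseudoalteromonadaceae", "NA"],
            "genus": ["Bacillus", "Anaerobacillus", "Pseudoalteromonas", "NA"],
        },
        index=counts.index,
    )
    return AmpliconTable(counts=counts, taxonomy=taxonomy)
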