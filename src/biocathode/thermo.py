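"""Nernstian feasibility of cathodic hydrogen evolution (HER).

The half reaction 2H+ + 2e- -> H2 has equilibrium potential (vs SHE,
with E0 = 0 at every temperature by the SHE convention):

    E = -(R T ln10 / F) * pH - (R T / 2F) * ln(p_H2)

where p_H2 is the hydrogen partial pressure (atm) at which downstream
hydrogenotrophic metabolism is just sustainable — the H2 threshold. A
cathode poised below E (minus an overpotential allowance) can in
principle sustain abiotic H2 production at that threshold.

Thresholds are rarely known directly; the module therefore supports
calibrating p_H2 from a known (E, pH, T) anchor and interpolating
between calibrated temperatures (log-linear in p_H2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from biocathode.constants import FARADAY, GAS_CONSTANT

LN10 = math.log(10.0)


@dataclass(frozen=True)
class HERCondition:
    """pH, absolute temperature and the H2 threshold partial pressure."""

    ph: float
    temperature_K: float
    p_h2_atm: float

    def __post_init__(self) -> None:
        if not self.temperature_K > 0:
            raise ValueError("temperature_K must be > 0")
        if not self.p_h2_atm > 0:
            raise ValueError("p_h2_atm must be > 0")


def her_potential(cond: HERCondition) -> float:
    """Equilibrium HER potential in V vs SHE for the given condition."""
    rt_f = GAS_CONSTANT * cond.temperature_K / FARADAY
    return -rt_f * LN10 * cond.ph - rt_f / 2.0 * math.log(cond.p_h2_atm)


def calibrate_h2_threshold(
    e_anchor_V: float, ph: float, temperature_K: float
) -> float:
    """Invert the Nernst expression: the p_H2 (atm) reproducing an anchor E.

    Round-trips exactly: her_potential at the calibrated pressure returns
    the anchor potential to machine precision.
    """
    if not math.isfinite(e_anchor_V):
        raise ValueError("anchor potential must be finite")
    rt_f = GAS_CONSTANT * temperature_K / FARADAY
    return math.exp(-(2.0 / rt_f) * (e_anchor_V + rt_f * LN10 * ph))


def her_feasible(
    e_cathode_V: float, cond: HERCondition, overpotential_V: float = 0.2
) -> bool:
    """Whether the poised cathode can drive H2 evolution past the threshold.

    True iff E_cathode <= E_HER(cond) - overpotential. The overpotential
    allowance accounts for the sluggish HER kinetics on graphite.
    """
    if overpotential_V < 0:
        raise ValueError("overpotential must be >= 0")
    return e_cathode_V <= her_potential(cond) - overpotential_V


def celsius_to_kelvin(temperature_C: float) -> float:
    return temperature_C + 273.15


def load_threshold_table(path=None) -> pd.DataFrame:
    """H2 threshold pressures per temperature, calibrated from anchors.

    The bundled anchor table lists (temperature_C, ph, e_anchor_V) points;
    each is inverted to a p_H2. The returned frame has columns
    temperature_C and p_h2_atm, one row per anchor temperature.
    """
    if path is None:
        source = resources.files("biocathode.data").joinpath("h2_anchors.tsv")
        with resources.as_file(source) as p:
            anchors = pd.read_csv(p, sep="\t")
    else:
        anchors = pd.read_csv(path, sep="\t")
    rows = [
        {
            "temperature_C": row.temperature_C,
            "p_h2_atm": calibrate_h2_threshold(
                row.e_anchor_V, row.ph, celsius_to_kelvin(row.temperature_C)
            ),
        }
        for row in anchors.itertuples(index=False)
    ]
    return pd.DataFrame(rows).sort_values("temperature_C").reset_index(drop=True)


def threshold_at_temperature(table: pd.DataFrame, temperature_C: float) -> float:
    """p_H2 at an arbitrary temperature, log-linear between calibrated rows."""
    temps = table["temperature_C"].to_numpy(dtype=float)
    logp = np.log(table["p_h2_atm"].to_numpy(dtype=float))
    return float(np.exp(np.interp(temperature_C, temps, logp)))
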