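"""Stoichiometric electron accounting and donor-budget classification.

The central question for a cathodic enrichment: can the electrons embodied
in the organic acids produced be supplied by the cathode alone
(electrotrophy / microbial electrosynthesis), or only by also drawing on
soluble donors — formate, thiosulfate, yeast extract — in which case the
cathode at most assisted a fermentation (electro-fermentation)?

Charge bookkeeping is done in coulombs. For a product P with electron
count ne produced at Δ[P] mol/L in catholyte volume V:

    Q_P = F * ne * Δ[P] * V          (coulombs embodied in P)
    CE_P = Q_P / Q_cathode * 100     (coulombic efficiency, %)

and the total CE is the sum of the per-product CEs. A total above 100%
means the cathode cannot be the sole donor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from biocathode.compounds import DEFAULT_REGISTRY, CompoundSpec
from biocathode.constants import FARADAY, GRAMS_O2_PER_MOL_E
from biocathode.datatypes import CODMeasurement, ReactorRecord

THIOSULFATE_NE = 8  # S2O3^2- -> 2 SO4^2-
FORMATE_NE = 2
SULFATE_PER_THIOSULFATE = 2.0

CLASS_CATHODE_SUFFICIENT = "cathode_sufficient"
CLASS_MULTI_DONOR = "multi_donor_electrofermentation"
CLASS_DONOR_DEFICIT = "donor_deficit_flag"


@dataclass
class ElectronBudget:
    """Coulombs available per donor vs coulombs embodied in products."""

    reactor_id: str
    q_cathode_C: float
    q_formate_C: float = 0.0
    q_thiosulfate_C: float = 0.0
    q_yeast_extract_C: float = 0.0
    q_products_C: float = 0.0
    product_breakdown_C: dict[str, float] = field(default_factory=dict)
    ce_per_product_percent: dict[str, float] = field(default_factory=dict)
    ce_total_percent: Optional[float] = None
    classification: str = CLASS_CATHODE_SUFFICIENT
    ce_over_100: bool = False
    carbon_fixation_flag: bool = False
    thiosulfate_is_donor: bool = False
    membrane_crossover_caveat: bool = False

    @property
    def q_donors_total_C(self) -> float:
        return (
            self.q_cathode_C
            + self.q_formate_C
            + self.q_thiosulfate_C
            + self.q_yeast_extract_C
        )


@dataclass(frozen=True)
class IronReductionResult:
    """Extent of Fe(III) reduction and its consistency with magnetite.

    Magnetite Fe3O4 holds one Fe(II) per three Fe, so reduction that stops
    at magnetite caps the Fe(II) fraction at 1/3.
    """

    fe2_mM: float
    fe_total_mM: float
    fraction_reduced: float
    magnetite_consistent: bool


def coulombic_efficiency(
    delta_mM: float, ne: int, volume_L: float, coulombs_C: float
) -> Optional[float]:
    """CE% = F * ne * Δ[P] * V / Q * 100 for one product.

    Δ[P] is the concentration increase over the run (mM). Returns None
    (undefined, reported missing) when Q == 0.
    """
    if delta_mM < 0:
        raise ValueError("delta_mM must be >= 0 for a product")
    if coulombs_C < 0:
        raise ValueError("coulombs_C must be >= 0")
    if coulombs_C == 0:
        return None
    delta_mol_per_L = delta_mM / 1000.0
    return FARADAY * ne * delta_mol_per_L * volume_L / coulombs_C * 100.0


def product_coulombs(delta_mM: float, ne: int, volume_L: float) -> float:
    """Coulombs embodied in Δ[P] mM of a product with ne electrons/mol."""
    return FARADAY * ne * (delta_mM / 1000.0) * volume_L


def cod_to_coulombs(delta_cod_gO2_per_L: float, volume_L: float) -> float:
    """Convert a COD decrease (g O2/L) into coulombs.

    8 g of COD correspond to one mole of electrons (4 e- per 32 g O2).
    Only a non-negative decrease contributes; callers handle the
    carbon-fixation case (COD increase) before calling.
    """
    if delta_cod_gO2_per_L < 0:
        raise ValueError("delta_cod must be >= 0; COD increases contribute 0 C")
    return delta_cod_gO2_per_L * volume_L / GRAMS_O2_PER_MOL_E * FARADAY


def organic_acid_cod_correction(
    deltas_mM: Mapping[str, float],
    specs: Mapping[str, CompoundSpec] = DEFAULT_REGISTRY,
    volume_L: float = 0.25,
) -> float:
    """Total COD (g O2) of the organic acids produced, Σ Δ[P]·V·8·ne.

    Subtracted from the final COD measurement before attributing the
    remaining decrease to yeast-extract consumption. Linear in each delta.
    """
    total = 0.0
    for name, delta in deltas_mM.items():
        if delta <= 0:
            continue
        spec = specs[name]
        mol = delta / 1000.0 * volume_L
        total += mol * spec.cod_gO2_per_mol
    return total


def thiosulfate_donor_check(
    delta_thio_mM: float,
    delta_sulfate_mM: float,
    volume_L: float,
    tolerance: float = 0.5,
) -> tuple[bool, float]:
    """Decide whether thiosulfate acted as an electron donor.

    Oxidation of thiosulfate to sulfate (S2O3^2- -> 2 SO4^2- + 8 e-) is
    accepted only when consumption and production are concomitant and
    near-stoichiometric: sulfate produced per thiosulfate consumed within
    (1 ± tolerance) of the 2:1 ratio. Deltas are final - initial, so
    consumption is negative. Returns (is_donor, donor coulombs).
    """
    consumed = -delta_thio_mM
    if consumed <= 0 or delta_sulfate_mM <= 0:
        return False, 0.0
    ratio = delta_sulfate_mM / (SULFATE_PER_THIOSULFATE * consumed)
    if not (1.0 - tolerance) <= ratio <= (1.0 + tolerance):
        return False, 0.0
    mol = consumed / 1000.0 * volume_L
    return True, mol * THIOSULFATE_NE * FARADAY


def formate_coulombs(delta_formate_mM: float, volume_L: float) -> float:
    """Donor coulombs from formate consumption (HCOO- -> CO2 + 2 e-).

    Delta is final - initial; production (delta > 0) contributes nothing
    on the donor side (it is routed to the product side instead).
    """
    consumed = -delta_formate_mM
    if consumed <= 0:
        return 0.0
    return consumed / 1000.0 * volume_L * FORMATE_NE * FARADAY


def yeast_extract_coulombs(
    cod: CODMeasurement,
    product_cod_gO2: float,
    volume_L: float,
) -> tuple[float, bool]:
    """Coulombs attributed to yeast-extract consumption, and a flag.

    The COD of the produced organic acids is subtracted from the final COD
    before the comparison, so that acid production is not mistaken for
    remaining yeast extract. The attributable decrease is
    COD_initial - (COD_final - COD_products), floored at 0. A corrected
    final COD above the initial one is hypothesized to reflect carbon
    fixation into biomass (electroautotrophy) and raises a flag.
    """
    corrected_final = cod.cod_final_gO2_per_L - product_cod_gO2 / volume_L
    delta = cod.cod_initial_gO2_per_L - corrected_final
    if delta <= 0:
        return 0.0, True
    return cod_to_coulombs(delta, volume_L), False


def iron_reduction_extent(
    fe2_mM: float, fe_total_mM: float, tolerance: float = 0.05
) -> IronReductionResult:
    """Fraction of iron reduced and consistency with magnetite stoichiometry.

    Reduction of ferrihydrite to magnetite converts one third of the iron
    to Fe(II); a measured fraction <= 1/3 + tolerance is consistent.
    """
    if fe2_mM < 0 or fe_total_mM <= 0:
        raise ValueError("concentrations must be positive")
    if fe2_mM > fe_total_mM:
        raise ValueError("Fe(II) cannot exceed total Fe")
    fraction = fe2_mM / fe_total_mM
    return IronReductionResult(
        fe2_mM=fe2_mM,
        fe_total_mM=fe_total_mM,
        fraction_reduced=fraction,
        magnetite_consistent=fraction <= (1.0 / 3.0 + tolerance),
    )


def build_donor_budget(
    reactor: ReactorRecord,
    q_cathode_C: float,
    metabolite_deltas_mM: Mapping[str, float],
    cod: Optional[CODMeasurement] = None,
    specs: Mapping[str, CompoundSpec] = DEFAULT_REGISTRY,
    thiosulfate_tolerance: float = 0.5,
) -> ElectronBudget:
    """Assemble the per-reactor electron budget and classify it.

    ``q_cathode_C`` is the *total* integrated charge over the run (the CE
    denominator), not the baseline-subtracted biocoulombs. Deltas are
    final - initial in mM keyed by registry compound name (plus optional
    "sulfate"/"thiosulfate" entries for the donor check).

    Classification:
      - cathode_sufficient: Q_products <= Q_cathode;
      - multi_donor_electrofermentation: Q_cathode < Q_products <= all donors;
      - donor_deficit_flag: products exceed every accounted donor (an
        unaccounted donor, or losses through the anion-exchange membrane).
    """
    volume = reactor.catholyte_volume_L
    budget = ElectronBudget(reactor_id=reactor.reactor_id, q_cathode_C=q_cathode_C)

    # Product side: positive deltas of registered organic species.
    for name, delta in metabolite_deltas_mM.items():
        spec = specs.get(name)
        if spec is None or spec.elements is None or delta <= 0:
            continue
        q = product_coulombs(delta, spec.ne, volume)
        budget.product_breakdown_C[name] = q
        budget.q_products_C += q

    # Donor side.
    if "formic acid" in metabolite_deltas_mM:
        budget.q_formate_C = formate_coulombs(
            metabolite_deltas_mM["formic acid"], volume
        )
    if "thiosulfate" in metabolite_deltas_mM:
        is_donor, q_thio = thiosulfate_donor_check(
            metabolite_deltas_mM["thiosulfate"],
            metabolite_deltas_mM.get("sulfate", 0.0),
            volume,
            tolerance=thiosulfate_tolerance,
        )
        budget.thiosulfate_is_donor = is_donor
        budget.q_thiosulfate_C = q_thio
        if metabolite_deltas_mM["thiosulfate"] < 0 and not is_donor:
            # consumption without matching sulfate production: plausibly
            # respiration or loss through the anion-exchange membrane
            budget.membrane_crossover_caveat = True
    if cod is not None:
        product_cod = organic_acid_cod_correction(
            {k: v for k, v in metabolite_deltas_mM.items() if k in specs},
            specs,
            volume,
        )
        budget.q_yeast_extract_C, budget.carbon_fixation_flag = (
            yeast_extract_coulombs(cod, product_cod, volume)
        )

    # Coulombic efficiencies against the cathode charge.
    if q_cathode_C > 0:
        budget.ce_per_product_percent = {
            name: q / q_cathode_C * 100.0
            for name, q in budget.product_breakdown_C.items()
        }
        budget.ce_total_percent = budget.q_products_C / q_cathode_C * 100.0
        budget.ce_over_100 = budget.ce_total_percent > 100.0

    if budget.q_products_C <= q_cathode_C:
        budget.classification = CLASS_CATHODE_SUFFICIENT
    elif budget.q_products_C <= budget.q_donors_total_C:
        budget.classification = CLASS_MULTI_DONOR
    else:
        budget.classification = CLASS_DONOR_DEFICIT
    return budget
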