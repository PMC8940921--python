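"""Unit conventions and the central conversion table.

Internal conventions (everything crossing a module boundary uses these):

=============  =======================  ==========================
quantity       unit                     note
=============  =======================  ==========================
time           d (days)                 solver and output grids
concentration  µM (µmol L⁻¹)            DOC in µM carbon
cell density   cells ml⁻¹
geometry       mm                       plate scale
cell radius    µm                       phycosphere scale
diffusivity    m² s⁻¹                   free-solution and effective
per-cell rate  fmol cell⁻¹ d⁻¹          exudation, uptake, quota
well volume    µl
=============  =======================  ==========================

All conversions between these and SI live here so a unit error has one
place to hide.
"""

SECONDS_PER_DAY = 86_400.0

#: µm -> m
UM_TO_M = 1e-6
#: mm -> m
MM_TO_M = 1e-3
#: mm² -> m²
MM2_TO_M2 = 1e-6
#: µl -> m³
UL_TO_M3 = 1e-9
#: ml -> m³
ML_TO_M3 = 1e-6

#: mol m⁻³ -> µM  (1 mol m⁻³ = 1 mM)
MOL_PER_M3_TO_UM = 1e3
#: µM -> mol m⁻³
UM_TO_MOL_PER_M3 = 1e-3

#: fmol -> mol
FMOL_TO_MOL = 1e-15
#: fmol cell⁻¹ d⁻¹ -> mol s⁻¹ (per cell)
FMOL_PER_DAY_TO_MOL_PER_S = FMOL_TO_MOL / SECONDS_PER_DAY

#: (fmol cell⁻¹ d⁻¹) × (cells ml⁻¹) -> µM d⁻¹
#: fmol/ml = 1e-15 mol / 1e-3 L = 1e-12 mol L⁻¹ = 1e-6 µmol L⁻¹
PER_CELL_RATE_TO_UM_PER_DAY = 1e-6


def wall_exchange_rate_per_day(d_eff: float, area_mm2: float,
                               thickness_mm: float, volume_ul: float) -> float:
    """Volumetric exchange rate d_eff·A/(L·V) of one porous wall, in d⁻¹.

    Parameters are in the internal units (d_eff in m² s⁻¹, area in mm²,
    thickness in mm, volume in µl).
    """
    k_si = d_eff * (area_mm2 * MM2_TO_M2) / (thickness_mm * MM_TO_M) / (volume_ul * UL_TO_M3)
    return k_si * SECONDS_PER_DAY
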