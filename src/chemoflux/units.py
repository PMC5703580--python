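"""Unit conversions between internal model units and bioprocess units.

Internal computation uses hours, mM, mmol/gDW/h and gDW/L.  Figures and
plant operation commonly use days and cell counts; converting between gDW
and cells requires a dry weight per cell (grams), e.g. 0.9 ng for a HeLa-like
mammalian cell or 350 pg for CHO.
"""

from __future__ import annotations

HOURS_PER_DAY = 24.0

#: default dry weight of one mammalian (HeLa-like) cell, grams
DW_PER_CELL_DEFAULT = 0.9e-9
#: dry weight of one CHO cell, grams
DW_PER_CELL_CHO = 350e-12


def convert(value: float, from_unit: str, to_unit: str,
            dry_weight_per_cell: float = DW_PER_CELL_DEFAULT) -> float:
    """Convert ``value`` between supported unit pairs.

    Supported pairs (either direction):

    - ``gDW*h/L``  <-> ``Mcells*day/mL``   (xi; Mcells = 10^6 cells)
    - ``1/h``      <-> ``1/day``           (rates)
    - ``gDW/L``    <-> ``Mcells/mL``       (cell density)
    """
    key = (from_unit, to_unit)
    if from_unit == to_unit:
        return value
    # gDW -> cells: divide by dry weight per cell; /1000 for L -> mL;
    # /1e6 for cells -> Mcells
    gdw_to_mcells_per_ml = 1.0 / dry_weight_per_cell / 1000.0 / 1e6
    factors = {
        ("1/h", "1/day"): HOURS_PER_DAY,
        ("1/day", "1/h"): 1.0 / HOURS_PER_DAY,
        ("gDW/L", "Mcells/mL"): gdw_to_mcells_per_ml,
        ("Mcells/mL", "gDW/L"): 1.0 / gdw_to_mcells_per_ml,
        ("gDW*h/L", "Mcells*day/mL"): gdw_to_mcells_per_ml / HOURS_PER_DAY,
        ("Mcells*day/mL", "gDW*h/L"): HOURS_PER_DAY / gdw_to_mcells_per_ml,
    }
    if key not in factors:
        raise ValueError(f"unsupported unit conversion {from_unit} -> {to_unit}")
    return value * factors[key]
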