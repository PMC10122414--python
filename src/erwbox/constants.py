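"""Physical constants and unit conversions used throughout the package.

All carbon bookkeeping is done internally in moles of carbon; the
conversions below are the single place where mass units are defined.
"""

M_C = 12.011
"""Molar mass of carbon, g/mol."""

M_CO2 = 44.009
"""Molar mass of CO2, g/mol."""

GTCO2_PER_GTC = M_CO2 / M_C
"""GtCO2 per GtC (the exact form of the conventional 44/12)."""

GTC_PER_PPM = 2.124
"""Atmospheric carbon mass per ppm of CO2 (GtC/ppm)."""

MOL_PER_GTC = 1.0e15 / M_C
"""mol C per GtC."""

MOL_PER_GTCO2 = 1.0e15 / M_CO2
"""mol CO2 per GtCO2."""

MOL_PER_PPM = GTC_PER_PPM * MOL_PER_GTC
"""mol C in the atmosphere per ppm of CO2."""

OCEAN_AREA = 3.61e14
"""Global ocean surface area, m^2."""

OCEAN_VOLUME = 1.33e18
"""Global ocean volume, m^3."""

SEAWATER_DENSITY = 1027.0
"""Reference seawater density, kg/m^3."""

SECONDS_PER_YEAR = 3.1536e7
"""Seconds per (365-day) year."""

SV_TO_M3_PER_YEAR = 1.0e6 * SECONDS_PER_YEAR
"""m^3/yr per Sverdrup."""

EARTH_AREA = 5.101e14
"""Earth surface area, m^2 (for radiative-forcing heat budgets)."""


def ppm_to_gtc(ppm):
    return ppm * GTC_PER_PPM


def gtc_to_ppm(gtc):
    return gtc / GTC_PER_PPM


def gtc_to_gtco2(gtc):
    return gtc * GTCO2_PER_GTC


def gtco2_to_gtc(gtco2):
    return gtco2 / GTCO2_PER_GTC
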