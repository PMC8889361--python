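"""Published reference values from the two-year Darab safflower field study.

These constants anchor the synthetic scenario (so the virtual experiment has
the statistical structure of the real one) and serve as inputs for report
reproduction: monthly CWSI cells, monthly color-quality scores, baseline
coefficients, trait-prediction equations, water totals and yields.

Keys: cultivars are "Goldasht" and "Local Isfahan"; regimes are
well_watered (100% FC), mild (75% FC), severe (50% FC), most_severe (25% FC)
and unirrigated; years are the growing-season labels "2017" and "2018".
"""
from __future__ import annotations

CULTIVARS = ("Goldasht", "Local Isfahan")
REGIMES = ("well_watered", "mild", "severe", "most_severe")
ALL_REGIMES = REGIMES + ("unirrigated",)
YEARS = ("2017", "2018")
SEASON_MONTHS = (4, 5, 6, 7)  # April through July

#: Irrigation regime definitions: fraction of the refill-to-field-capacity depth.
REGIME_FRACTIONS = {
    "well_watered": 1.00,
    "mild": 0.75,
    "severe": 0.50,
    "most_severe": 0.25,
}

#: Lower (non-stressed) baseline Tc-Ta = a*VPD + b per cultivar-year.
#: Local Isfahan coefficients are published only as a slope range
#: (-1.06 to -1.08); intercept 0.6 is the package's anchoring choice.
LOWER_BASELINES = {
    ("Goldasht", "2017"): (-0.85, 0.75),
    ("Goldasht", "2018"): (-0.87, 0.57),
    ("Local Isfahan", "2017"): (-1.06, 0.60),
    ("Local Isfahan", "2018"): (-1.08, 0.60),
}

#: Upper (fully stressed) limit (Tc-Ta)ul in degC per cultivar-year.
UPPER_LIMITS = {
    ("Goldasht", "2017"): 7.8,
    ("Goldasht", "2018"): 8.9,
    ("Local Isfahan", "2017"): 10.8,
    ("Local Isfahan", "2018"): 11.5,
}

#: Mean monthly CWSI per (regime, cultivar, year), April..July.
MONTHLY_CWSI = {
    ("well_watered", "Goldasht", "2017"): {4: 0.071, 5: 0.124, 6: 0.244, 7: 0.267},
    ("well_watered", "Goldasht", "2018"): {4: 0.097, 5: 0.217, 6: 0.266, 7: 0.291},
    ("well_watered", "Local Isfahan", "2017"): {4: 0.084, 5: 0.131, 6: 0.256, 7: 0.277},
    ("well_watered", "Local Isfahan", "2018"): {4: 0.112, 5: 0.231, 6: 0.278, 7: 0.311},
    ("mild", "Goldasht", "2017"): {4: 0.125, 5: 0.291, 6: 0.323, 7: 0.364},
    ("mild", "Goldasht", "2018"): {4: 0.139, 5: 0.310, 6: 0.386, 7: 0.381},
    ("mild", "Local Isfahan", "2017"): {4: 0.133, 5: 0.315, 6: 0.366, 7: 0.389},
    ("mild", "Local Isfahan", "2018"): {4: 0.185, 5: 0.343, 6: 0.401, 7: 0.397},
    ("severe", "Goldasht", "2017"): {4: 0.486, 5: 0.496, 6: 0.620, 7: 0.674},
    ("severe", "Goldasht", "2018"): {4: 0.511, 5: 0.581, 6: 0.659, 7: 0.691},
    ("severe", "Local Isfahan", "2017"): {4: 0.514, 5: 0.544, 6: 0.672, 7: 0.721},
    ("severe", "Local Isfahan", "2018"): {4: 0.556, 5: 0.613, 6: 0.679, 7: 0.795},
    ("most_severe", "Goldasht", "2017"): {4: 0.514, 5: 0.611, 6: 0.643, 7: 0.701},
    ("most_severe", "Goldasht", "2018"): {4: 0.556, 5: 0.687, 6: 0.714, 7: 0.784},
    ("most_severe", "Local Isfahan", "2017"): {4: 0.623, 5: 0.698, 6: 0.745, 7: 0.831},
    ("most_severe", "Local Isfahan", "2018"): {4: 0.657, 5: 0.745, 6: 0.789, 7: 0.901},
}

#: Printed seasonal CWSI means (2-decimal) per (regime, cultivar, year).
SEASONAL_CWSI = {
    ("well_watered", "Goldasht", "2017"): 0.18,
    ("well_watered", "Goldasht", "2018"): 0.22,
    ("well_watered", "Local Isfahan", "2017"): 0.19,
    ("well_watered", "Local Isfahan", "2018"): 0.23,
    ("mild", "Goldasht", "2017"): 0.28,
    ("mild", "Goldasht", "2018"): 0.30,
    ("mild", "Local Isfahan", "2017"): 0.30,
    ("mild", "Local Isfahan", "2018"): 0.33,
    ("severe", "Goldasht", "2017"): 0.57,
    ("severe", "Goldasht", "2018"): 0.61,
    ("severe", "Local Isfahan", "2017"): 0.61,
    ("severe", "Local Isfahan", "2018"): 0.66,
    ("most_severe", "Goldasht", "2017"): 0.62,
    ("most_severe", "Goldasht", "2018"): 0.69,
    ("most_severe", "Local Isfahan", "2017"): 0.72,
    ("most_severe", "Local Isfahan", "2018"): 0.77,
}

#: Monthly visual color-quality scores [initial(late March), Apr, May, Jun, Jul]
#: per (regime, cultivar, year). The severe/Goldasht/2018 May score is read as 4,
#: the only monotone-declining sequence consistent with its printed seasonal mean.
MONTHLY_COLOR = {
    ("well_watered", "Goldasht", "2017"): [8, 7, 6, 5, 6],
    ("well_watered", "Goldasht", "2018"): [8, 7, 6, 5, 6],
    ("well_watered", "Local Isfahan", "2017"): [8, 6, 5, 4, 3],
    ("well_watered", "Local Isfahan", "2018"): [8, 6, 5, 4, 3],
    ("mild", "Goldasht", "2017"): [8, 7, 6, 4, 6],
    ("mild", "Goldasht", "2018"): [8, 6, 5, 4, 5],
    ("mild", "Local Isfahan", "2017"): [8, 5, 4, 3, 3],
    ("mild", "Local Isfahan", "2018"): [8, 5, 3, 3, 2],
    ("severe", "Goldasht", "2017"): [8, 5, 4, 3, 3],
    ("severe", "Goldasht", "2018"): [8, 5, 4, 3, 2],
    ("severe", "Local Isfahan", "2017"): [8, 4, 3, 3, 2],
    ("severe", "Local Isfahan", "2018"): [8, 3, 3, 2, 2],
    ("most_severe", "Goldasht", "2017"): [8, 3, 3, 2, 2],
    ("most_severe", "Goldasht", "2018"): [8, 3, 2, 2, 2],
    ("most_severe", "Local Isfahan", "2017"): [8, 3, 2, 2, 1],
    ("most_severe", "Local Isfahan", "2018"): [8, 2, 2, 2, 1],
    ("unirrigated", "Goldasht", "2017"): [8, 4, 1, 1, 1],
    ("unirrigated", "Goldasht", "2018"): [8, 2, 1, 1, 1],
    ("unirrigated", "Local Isfahan", "2017"): [8, 3, 1, 1, 1],
    ("unirrigated", "Local Isfahan", "2018"): [8, 1, 1, 1, 1],
}

#: Printed seasonal color-quality means (1-decimal).
SEASONAL_COLOR = {
    ("well_watered", "Goldasht", "2017"): 6.4,
    ("well_watered", "Goldasht", "2018"): 6.4,
    ("well_watered", "Local Isfahan", "2017"): 5.2,
    ("well_watered", "Local Isfahan", "2018"): 5.2,
    ("mild", "Goldasht", "2017"): 6.2,
    ("mild", "Goldasht", "2018"): 5.6,
    ("mild", "Local Isfahan", "2017"): 4.6,
    ("mild", "Local Isfahan", "2018"): 4.2,
    ("severe", "Goldasht", "2017"): 4.6,
    ("severe", "Goldasht", "2018"): 4.4,
    ("severe", "Local Isfahan", "2017"): 4.0,
    ("severe", "Local Isfahan", "2018"): 3.6,
    ("most_severe", "Goldasht", "2017"): 3.6,
    ("most_severe", "Goldasht", "2018"): 3.4,
    ("most_severe", "Local Isfahan", "2017"): 3.2,
    ("most_severe", "Local Isfahan", "2018"): 3.0,
    ("unirrigated", "Goldasht", "2017"): 3.0,
    ("unirrigated", "Goldasht", "2018"): 2.6,
    ("unirrigated", "Local Isfahan", "2017"): 2.8,
    ("unirrigated", "Local Isfahan", "2018"): 2.4,
}

#: Total water consumed (irrigation + rainfall, mm), Goldasht 2017, per regime.
WATER_TOTALS_GOLDASHT_2017 = {
    "well_watered": 570.3,
    "mild": 425.5,
    "severe": 283.5,
    "most_severe": 140.3,
}

#: Seed yield (g m^-2): Goldasht 2017 and Local Isfahan 2018, per regime.
SEED_YIELDS = {
    ("Goldasht", "2017"): {
        "well_watered": 1571.0,
        "mild": 1152.0,
        "severe": 891.0,
        "most_severe": 393.0,
    },
    ("Local Isfahan", "2018"): {
        "well_watered": 1123.0,
        "mild": 805.0,
        "severe": 533.0,
        "most_severe": 297.0,
    },
}

#: Leaf relative water content (%) under stress, 2017, per cultivar.
RWC_2017 = {
    "Goldasht": {"mild": 55.0, "most_severe": 28.0},
    "Local Isfahan": {"mild": 51.0, "most_severe": 21.0},
}

#: Linear CWSI-trait prediction equations (slope, intercept).
TRAIT_RELATIONS = {
    "rwc_pct": (-79.129, 81.316),
    "seed_yield_gm2": (-1695.4, 1601.3),
}

#: Recommended seasonal-CWSI band for acceptable deficit irrigation.
RECOMMENDED_BAND = (0.28, 0.33)

#: Monthly midday (maximum) air-temperature envelope, degC, April..July.
MAX_TEMP_ENVELOPE = {
    "2017": {4: 29.8, 5: 34.4, 6: 39.7, 7: 42.7},
    "2018": {4: 33.2, 5: 38.1, 6: 42.4, 7: 44.2},
}
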