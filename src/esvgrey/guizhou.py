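"""Published study tables for Guizhou Province (karst southwest China).

Guizhou is the canonical worked example shipped with this package: a
17.6-million-hectare karst province whose land-use structure shifted
markedly between the 2009 and 2018 land-change surveys (construction land
up ~12%, forest land down ~1%).  Three published inputs are transcribed
here:

* per-hectare ecosystem-service value coefficients for six vegetated /
  aquatic land-use categories, decomposed into nine service functions
  (benefit-transfer coefficients in the Costanza/Xie tradition, CNY per
  hm2 per year; construction land is priced at zero);
* surveyed category areas for 2009 and 2018 (hm2), which close exactly on
  the provincial territory total;
* the observed ranges of seven socioeconomic driver variables over
  2009-2018, used to bound synthetic driver trajectories.

Everything else in the package treats these as ordinary inputs; nothing
is hard-wired to Guizhou.
"""

from __future__ import annotations

TERRITORY_HM2: float = 17_609_858.0
"""Provincial land area in hm2; category areas close on this total."""

SERVICES: tuple[str, ...] = (
    "gas regulation",
    "climate regulation",
    "hydrological regulation",
    "waste treatment",
    "soil formation and retention",
    "biodiversity protection",
    "food production",
    "raw material",
    "recreation and culture",
)

#: CNY per hm2 per year, service -> category.  Construction land is an
#: explicit zero column so closure checks always see all 7 categories.
VALUE_COEFFICIENTS: dict[str, dict[str, float]] = {
    "gas regulation": {
        "forest land": 3097.00, "garden land": 1265.50, "grass land": 707.90,
        "cultivated land": 442.40, "water area": 0.0, "unused land": 0.0,
        "construction land": 0.0,
    },
    "climate regulation": {
        "forest land": 2389.10, "garden land": 1170.30, "grass land": 796.40,
        "cultivated land": 787.50, "water area": 407.00, "unused land": 0.0,
        "construction land": 0.0,
    },
    "hydrological regulation": {
        "forest land": 2831.50, "garden land": 41.50, "grass land": 707.90,
        "cultivated land": 530.90, "water area": 18033.20, "unused land": 26.50,
        "construction land": 0.0,
    },
    "waste treatment": {
        "forest land": 1159.20, "garden land": 722.10, "grass land": 1159.20,
        "cultivated land": 1451.20, "water area": 16086.60, "unused land": 8.80,
        "construction land": 0.0,
    },
    "soil formation and retention": {
        "forest land": 3450.90, "garden land": 1291.90, "grass land": 1725.50,
        "cultivated land": 1291.90, "water area": 8.80, "unused land": 17.70,
        "construction land": 0.0,
    },
    "biodiversity protection": {
        "forest land": 2884.60, "garden land": 16.60, "grass land": 964.50,
        "cultivated land": 628.20, "water area": 2203.30, "unused land": 300.80,
        "construction land": 0.0,
    },
    "food production": {
        "forest land": 88.50, "garden land": 356.90, "grass land": 265.50,
        "cultivated land": 884.90, "water area": 88.50, "unused land": 8.80,
        "construction land": 0.0,
    },
    "raw material": {
        "forest land": 2300.06, "garden land": 1145.40, "grass land": 44.20,
        "cultivated land": 88.50, "water area": 8.80, "unused land": 0.0,
        "construction land": 0.0,
    },
    "recreation and culture": {
        "forest land": 1132.60, "garden land": 547.80, "grass land": 35.40,
        "cultivated land": 8.80, "water area": 3840.20, "unused land": 8.80,
        "construction land": 0.0,
    },
}

#: Published per-category coefficient totals (CNY/hm2/yr), used as a
#: transcription cross-check against the column sums of VALUE_COEFFICIENTS.
PUBLISHED_COLUMN_TOTALS: dict[str, float] = {
    "forest land": 19333.46,
    "garden land": 6558.00,
    "grass land": 6406.50,
    "cultivated land": 6114.30,
    "water area": 40676.40,
    "unused land": 371.40,
    "construction land": 0.0,
}

#: Surveyed areas (hm2) from the 2009 and 2018 land-change surveys.
AREAS_2009: dict[str, float] = {
    "cultivated land": 4_562_515.0,
    "garden land": 157_805.0,
    "forest land": 9_008_978.0,
    "grass land": 1_630_923.0,
    "construction land": 1_521_870.0,
    "water area": 243_584.0,
    "unused land": 484_183.0,
}

AREAS_2018: dict[str, float] = {
    "cultivated land": 4_526_175.0,
    "garden land": 162_535.0,
    "forest land": 8_924_861.0,
    "grass land": 1_571_846.0,
    "construction land": 1_703_828.0,
    "water area": 244_853.0,
    "unused land": 475_759.0,
}

#: Observed 2009-2018 ranges (and means) of the seven candidate driving
#: factors of ESV change: total population (TP, million persons),
#: urbanization level (UL, fraction), gross domestic product (GDP,
#: billion CNY), secondary / tertiary industry proportions (SIP / TIP,
#: percent), total investment in fixed assets (TIFA, billion CNY) and the
#: annual afforestation programme area (AP, hm2).
DRIVER_RANGES: dict[str, dict[str, float]] = {
    "TP":   {"mean": 35.24,     "low": 34.69,     "high": 36.0},
    "UL":   {"mean": 0.39,      "low": 0.30,      "high": 0.48},
    "GDP":  {"mean": 896.34,    "low": 391.27,    "high": 1535.32},
    "SIP":  {"mean": 38.50,     "low": 35.86,     "high": 41.6},
    "TIP":  {"mean": 47.76,     "low": 44.6,      "high": 50.09},
    "TIFA": {"mean": 903.60,    "low": 245.10,    "high": 1836.36},
    "AP":   {"mean": 25149.27,  "low": 18053.33,  "high": 50586.67},
}

STUDY_YEARS: tuple[int, int] = (2009, 2018)
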