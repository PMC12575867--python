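"""Bundled case-study inputs: nine West African forest patches.

Published patch-level figures for nine community-adjacent forest patches in
Togo, Benin, Nigeria and Cameroon: forest area (ha) at the 2010 and 2022
epochs from Landsat-derived classifications, and the site-level percentages
of survey respondents reporting each perceived-change category over the
ten-year recall period. Two sites additionally carry 2000/2022 endpoint
areas. These printed values are inputs to the convergence analysis; the
underlying rasters and respondent-level survey data are not distributed.
"""

from __future__ import annotations

import pandas as pd

# patch -> (country, area_2010_ha, area_2022_ha, ten-year response % by category)
PATCHES: dict[str, dict] = {
    "Agou": {
        "country": "Togo",
        "area_2010_ha": 2346.0,
        "area_2022_ha": 2280.9,
        "responses_10y_pct": {"Decreased": 93.0},
        "responses_5y_pct": {"Decreased": 95.0},
    },
    "Elavagnon-Todji": {
        "country": "Togo",
        "area_2010_ha": 680.8,
        "area_2022_ha": 648.4,
        "responses_10y_pct": {"Decreased": 95.0},
        "responses_5y_pct": {"Decreased": 94.0},
    },
    "Koui": {
        "country": "Togo",
        "area_2010_ha": 130.9,
        "area_2022_ha": 125.6,
        "responses_10y_pct": {"Increased": 54.0, "Decreased": 30.0},
        "responses_5y_pct": {"Increased": 55.0, "Decreased": 28.0},
    },
    "Ewè-Adakplamè": {
        "country": "Benin",
        "area_2010_ha": 586.9,
        "area_2022_ha": 505.4,
        "area_2000_ha": 619.0,
        "area_2022_full_ha": 505.0,
        "responses_10y_pct": {"Decreased": 93.0},
        "responses_5y_pct": {"Decreased": 92.0},
    },
    "Hlanzoun": {
        "country": "Benin",
        "area_2010_ha": 568.4,
        "area_2022_ha": 548.6,
        "area_2000_ha": 547.0,
        "responses_10y_pct": {"Increased": 46.0, "Decreased": 35.0},
        "responses_5y_pct": {"Increased": 45.0, "Decreased": 33.0},
    },
    "Iko": {
        "country": "Nigeria",
        "area_2010_ha": 3554.2,
        "area_2022_ha": 3423.5,
        "responses_10y_pct": {"Decreased": 77.0},
        "responses_5y_pct": {"Decreased": 82.0},
    },
    "Ikot": {
        "country": "Nigeria",
        "area_2010_ha": 1270.7,
        "area_2022_ha": 1253.0,
        "responses_10y_pct": {"Decreased": 65.0},
        "responses_5y_pct": {"Decreased": 65.0},
    },
    "Mbangassina": {
        "country": "Cameroon",
        "area_2010_ha": 1007.0,
        "area_2022_ha": 991.2,
        "responses_10y_pct": {"Decreased": 94.0},
        "responses_5y_pct": {"Decreased": 97.0},
    },
    "Ngam-Kondomeyos": {
        "country": "Cameroon",
        "area_2010_ha": 1285.0,
        "area_2022_ha": 1283.9,
        "responses_10y_pct": {"Decreased": 95.0},
        "responses_5y_pct": {"Decreased": 97.0},
    },
}

#: published convergence-matrix category per patch (ten-year comparison)
PUBLISHED_ASSESSMENT: dict[str, str] = {
    "Agou": "full_convergence",
    "Elavagnon-Todji": "full_convergence",
    "Ewè-Adakplamè": "full_convergence",
    "Iko": "full_convergence",
    "Hlanzoun": "partial_convergence",
    "Koui": "partial_convergence",
    "Ngam-Kondomeyos": "dissonance",
    "Mbangassina": "dissonance",
    "Ikot": "dissonance",
}


def patch_table() -> pd.DataFrame:
    """The nine-patch endpoint areas as a tidy frame."""
    rows = []
    for name, d in PATCHES.items():
        rows.append(
            {
                "patch_id": name,
                "country": d["country"],
                "area_2010_ha": d["area_2010_ha"],
                "area_2022_ha": d["area_2022_ha"],
            }
        )
    return pd.DataFrame(rows)
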