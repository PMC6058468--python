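"""Bundled reference measurements from the ten-donor postprandial study.

Two small per-donor tables of DLS readouts on healthy adult volunteers:

* :func:`donor_ic_table` — hydrodynamic size (nm) and contribution to
  scattering (%) of the food-CIC fraction per donor, before eating and at
  the 3.5 h accumulation maximum;
* :func:`isotype_table` — per-donor antibody-panel results at 3.5 h:
  aggregate size (nm) and the proportion of total scattering (%) carried
  by ICs of each probed isotype combination.

These printed per-donor values are inputs to the package: the cohort Mean
and SD rows of the published tables are recomputed from them with
:func:`cicdls.kinetics.population_summary`, and the cohort means also
parameterize the synthetic-data presets.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["donor_ic_table", "isotype_table"]

_DONORS = ["D10", "A10", "A05", "B03", "C04", "B01", "A18", "FF", "A12", "C14"]

# columns: pre-meal size nm, pre-meal contribution %, 3.5 h size nm,
# 3.5 h contribution %
_IC_ROWS = [
    (109, 8.5, 122, 78.6),
    (119, 7.1, 120, 78.6),
    (109, 2.6, 121, 78.1),
    (116, 8.3, 120, 78.8),
    (127, 4.1, 123, 79.8),
    (121, 3.7, 121, 78.5),
    (123, 6.9, 122, 79.3),
    (115, 7.3, 120, 78.7),
    (118, 8.5, 122, 78.3),
    (109, 2.6, 121, 78.6),
]

# per panel: (size nm, proportion %) per donor, at 3.5 h after eating
_ISOTYPE_ROWS = {
    "IgG1": [
        (267.2, 33.1), (267.2, 32.4), (267.2, 34.3), (262.0, 33.9),
        (267.2, 28.7), (287.1, 33.2), (267.2, 33.3), (267.2, 34.0),
        (286.2, 34.4), (282.4, 33.3),
    ],
    "IgG3": [
        (267.2, 3.7), (267.2, 3.9), (267.2, 2.7), (247.3, 5.1),
        (267.2, 4.1), (252.5, 4.6), (267.2, 4.7), (267.2, 3.3),
        (254.7, 5.6), (247.2, 3.6),
    ],
    "IgA": [
        (267.2, 40.7), (267.2, 41.4), (267.2, 41.0), (267.2, 42.1),
        (267.2, 43.0), (267.2, 42.3), (267.2, 42.4), (267.2, 42.1),
        (267.2, 42.2), (267.2, 42.4),
    ],
    "IgG1+IgG3": [
        (317.4, 36.8), (311.0, 36.3), (312.1, 37.0), (304.0, 39.1),
        (327.1, 32.9), (323.3, 37.9), (316.8, 38.0), (325.8, 37.3),
        (321.5, 40.0), (303.0, 36.8),
    ],
    "IgG1+IgA": [
        (653.0, 3.7), (653.0, 3.1), (653.0, 3.3), (653.0, 2.7),
        (653.0, 2.9), (653.0, 2.7), (653.0, 4.0), (653.0, 3.0),
        (653.0, 3.2), (653.0, 3.5),
    ],
}


def donor_ic_table() -> pd.DataFrame:
    """Per-donor food-CIC size and contribution, pre-meal and at 3.5 h."""
    return pd.DataFrame(
        _IC_ROWS,
        index=pd.Index(_DONORS, name="donor"),
        columns=[
            "premeal_size_nm",
            "premeal_contribution_pct",
            "peak_size_nm",
            "peak_contribution_pct",
        ],
    )


def isotype_table() -> pd.DataFrame:
    """Per-donor isotyping results at 3.5 h, long format.

    Columns: donor, panel, size_nm, proportion_pct.
    """
    records = []
    for panel, rows in _ISOTYPE_ROWS.items():
        for donor, (size, prop) in zip(_DONORS, rows):
            records.append(
                {
                    "donor": donor,
                    "panel": panel,
                    "size_nm": size,
                    "proportion_pct": prop,
                }
            )
    return pd.DataFrame(records)
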