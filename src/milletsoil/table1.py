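"""Published group means and standard errors from the two-year field trial.

The trial compared a pure chemical fertilizer control (NPK) with three
partial organic replacement treatments in which 50 % of fertilizer N was
supplied by composted cow (CM), pig (PM) or sheep (SM) manure, at equal
total N-P2O5-K2O rates (225 / 135 / 112.5 kg ha^-1).  Each treatment had
three replicate plots, sampled in 2022 and 2023.

These tables are the package's canonical reference input: they seed the
synthetic generator and drive the printed-table report stage.  Values are
means +/- standard errors with n = 3.
"""

from __future__ import annotations

import io as _io
from importlib import resources

import pandas as pd

TREATMENTS = ("NPK", "CM", "PM", "SM")
YEARS = (2022, 2023)
N_REPLICATES = 3

#: Measured soil variables, in presentation order.
SOIL_VARIABLES = (
    "pH", "SP", "TC", "TN", "TP", "TK", "NH4", "NO3", "AP", "AK",
    "CAT", "INV", "NAG", "URE", "ALP", "GLS",
)

#: The ten physicochemical indicators entering the soil quality index.
SQI_INDICATORS = ("pH", "SP", "TC", "TN", "TP", "TK", "NH4", "NO3", "AP", "AK")

#: The six enzyme activities entering ecological multifunctionality.
EMF_FUNCTIONS = ("CAT", "INV", "NAG", "URE", "ALP", "GLS")

UNITS = {
    "pH": "unitless", "SP": "%",
    "TC": "g/kg", "TN": "g/kg", "TP": "g/kg", "TK": "g/kg",
    "NH4": "mg/kg", "NO3": "mg/kg", "AP": "mg/kg", "AK": "mg/kg",
    "CAT": "U/g", "INV": "U/g", "NAG": "U/g", "URE": "U/g",
    "ALP": "U/g", "GLS": "U/g",
    "SQI": "unitless", "EMF": "z-score",
    "yield": "kg/ha", "flavonoid": "mg/g",
}

# variable -> year -> (NPK, CM, PM, SM)
MEANS = {
    "pH":  {2022: (8.72, 8.60, 8.64, 8.67),   2023: (8.29, 8.03, 8.14, 8.16)},
    "SP":  {2022: (48.20, 49.65, 50.28, 49.91), 2023: (47.71, 49.95, 51.33, 50.35)},
    "TC":  {2022: (9.62, 10.20, 10.43, 10.71),  2023: (9.55, 10.22, 10.53, 10.90)},
    "TN":  {2022: (1.60, 1.79, 1.83, 1.81),     2023: (1.63, 1.83, 1.90, 1.87)},
    "TP":  {2022: (1.49, 1.62, 1.79, 1.88),     2023: (1.53, 1.74, 1.90, 2.04)},
    "TK":  {2022: (12.17, 13.36, 12.64, 12.70), 2023: (12.37, 13.63, 13.28, 13.33)},
    "NH4": {2022: (17.39, 18.29, 19.66, 18.96), 2023: (17.69, 18.76, 20.33, 19.47)},
    "NO3": {2022: (8.95, 9.89, 10.92, 10.35),   2023: (10.15, 11.37, 12.87, 11.93)},
    "AP":  {2022: (31.12, 38.66, 48.29, 40.89), 2023: (35.88, 44.91, 56.77, 47.98)},
    "AK":  {2022: (102.17, 142.59, 95.65, 129.70), 2023: (101.16, 129.80, 87.41, 121.56)},
    "CAT": {2022: (0.84, 1.03, 0.92, 1.03),     2023: (0.91, 1.25, 1.03, 1.16)},
    "INV": {2022: (17.87, 19.59, 23.38, 22.21), 2023: (18.26, 20.06, 25.12, 23.05)},
    "NAG": {2022: (6.02, 6.69, 7.03, 7.42),     2023: (6.46, 7.42, 7.82, 8.29)},
    "URE": {2022: (0.39, 0.54, 0.63, 0.50),     2023: (0.48, 0.69, 0.90, 0.62)},
    "ALP": {2022: (0.09, 0.15, 0.12, 0.11),     2023: (0.09, 0.16, 0.14, 0.12)},
    "GLS": {2022: (25.47, 31.80, 37.64, 28.44), 2023: (28.16, 35.58, 43.33, 31.89)},
}

SES = {
    "pH":  {2022: (0.01, 0.02, 0.02, 0.03),   2023: (0.02, 0.01, 0.02, 0.04)},
    "SP":  {2022: (0.43, 0.92, 0.36, 0.70),   2023: (0.26, 0.43, 0.36, 0.76)},
    "TC":  {2022: (0.17, 0.17, 0.06, 0.18),   2023: (0.10, 0.34, 0.24, 0.17)},
    "TN":  {2022: (0.01, 0.11, 0.11, 0.08),   2023: (0.05, 0.02, 0.02, 0.15)},
    "TP":  {2022: (0.01, 0.03, 0.03, 0.01),   2023: (0.03, 0.04, 0.07, 0.14)},
    "TK":  {2022: (0.35, 0.45, 0.15, 0.33),   2023: (0.48, 0.22, 0.60, 0.12)},
    "NH4": {2022: (0.53, 0.19, 0.67, 0.65),   2023: (0.17, 0.14, 0.54, 1.18)},
    "NO3": {2022: (0.10, 0.27, 0.37, 0.70),   2023: (0.29, 0.12, 0.27, 0.96)},
    "AP":  {2022: (4.10, 1.80, 3.29, 1.35),   2023: (4.57, 1.96, 3.02, 2.50)},
    "AK":  {2022: (1.80, 3.52, 7.50, 3.01),   2023: (7.41, 2.70, 1.16, 5.73)},
    "CAT": {2022: (0.02, 0.04, 0.04, 0.06),   2023: (0.02, 0.02, 0.06, 0.05)},
    "INV": {2022: (0.61, 0.79, 2.38, 2.28),   2023: (1.39, 0.14, 1.31, 1.03)},
    "NAG": {2022: (0.14, 0.32, 0.13, 0.32),   2023: (0.37, 0.19, 0.35, 0.19)},
    "URE": {2022: (0.01, 0.06, 0.02, 0.01),   2023: (0.02, 0.07, 0.07, 0.01)},
    "ALP": {2022: (0.01, 0.01, 0.02, 0.01),   2023: (0.01, 0.01, 0.01, 0.01)},
    "GLS": {2022: (3.53, 1.64, 3.82, 0.72),   2023: (0.82, 4.67, 3.03, 1.55)},
}

#: Published composite indices (derived quantities, kept separate from the
#: measured variables so they never leak into index recomputation).
INDEX_MEANS = {
    "SQI": {2022: (0.36, 1.44, 1.58, 1.64), 2023: (0.33, 0.94, 1.56, 1.47)},
    "EMF": {2022: (-1.20, 0.32, 0.65, 0.23), 2023: (-1.23, 0.31, 0.75, 0.17)},
}

INDEX_SES = {
    "SQI": {2022: (0.08, 0.30, 0.04, 0.03), 2023: (0.07, 0.06, 0.17, 0.31)},
    "EMF": {2022: (0.15, 0.13, 0.27, 0.38), 2023: (0.04, 0.04, 0.07, 0.14)},
}


def summary_frame(include_indices: bool = True) -> pd.DataFrame:
    """Long-format summary of the published table.

    Returns a DataFrame with columns
    ``variable, year, treatment, mean, se``; one row per cell.
    """
    rows = []
    means = dict(MEANS)
    ses = dict(SES)
    if include_indices:
        means.update(INDEX_MEANS)
        ses.update(INDEX_SES)
    for var, by_year in means.items():
        for year, vals in by_year.items():
            for trt, m, s in zip(TREATMENTS, vals, ses[var][year]):
                rows.append({"variable": var, "year": year, "treatment": trt,
                             "mean": m, "se": s})
    return pd.DataFrame(rows)


def mean_sample_table() -> "pd.DataFrame":
    """Replicate-level frame with every replicate set to its group mean.

    Gives 24 pseudo-replicate rows (4 treatments x 2 years x 3 replicates)
    carrying the 16 measured variables; useful as a deterministic stand-in
    when only group means are available.
    """
    rows = []
    for year in YEARS:
        for ti, trt in enumerate(TREATMENTS):
            for rep in range(1, N_REPLICATES + 1):
                row = {"treatment": trt, "year": year, "replicate": rep}
                for var in SOIL_VARIABLES:
                    row[var] = MEANS[var][year][ti]
                rows.append(row)
    return pd.DataFrame(rows)


def treatment_mean_table() -> "pd.DataFrame":
    """One row per (treatment, year) at the group mean (8 rows).

    This is the pool on which the published composite indices are
    reproduced: with only group means available, the four treatment means
    of a year act as the standardization/scoring pool.
    """
    rows = []
    for year in YEARS:
        for ti, trt in enumerate(TREATMENTS):
            row = {"treatment": trt, "year": year, "replicate": 1}
            for var in SOIL_VARIABLES:
                row[var] = MEANS[var][year][ti]
            rows.append(row)
    return pd.DataFrame(rows)


def packaged_fixture_path():
    """Path to the packaged ``table1_means.csv`` fixture."""
    return resources.files("milletsoil.data") / "table1_means.csv"


def load_packaged_fixture() -> pd.DataFrame:
    with packaged_fixture_path().open("r", encoding="utf-8") as fh:
        return pd.read_csv(_io.StringIO(fh.read()))
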