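"""Published community-level reference tables (Canada, 2009-2014).

These are the printed summary tables of the public national community
well-being dataset built from restricted CCHS/GSS microdata and 2011 NHS
aggregates over 1216 similarly-sampled regions (776 urban/tracted, 440
rural/non-tracted).  The microdata themselves are not downloadable; the
tables are shipped so the comparison machinery can be exercised against
the published group means, and to document the calibration targets of
the synthetic generator (grand mean 8.04, within-community SD 1.66,
between-region SD 0.22-0.23, rural-minus-urban gap 0.17).

Each comparison table carries the two group means with their
heteroskedasticity-robust SEs and the printed difference.  Printed means
are rounded to two decimals, so ``mean_a - mean_b`` can differ from the
printed difference by one unit in the last digit; rows where the printed
columns are arithmetically consistent are flagged.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

N_REGIONS = 1216
N_URBAN = 776
N_RURAL = 440
GRAND_MEAN_SWL = 8.04
BETWEEN_REGION_SD = 0.22
WITHIN_REGION_SD = 1.66
MEAN_REGION_SE = 0.08
URBAN_RURAL_GAP = -0.17  # urban minus rural, points
AGE_GAP_SHARE = 0.03  # composition-only share of the urban/rural gap

_SUMMARY = """variable\tmean\tsd
Satisfaction with Life\t8.04\t0.23
Std. Deviation of SWL\t1.66\t0.19
Community Belonging\t0.73\t0.08
Log Mean HH Income\t11.23\t0.27
Unemployment (percent)\t7.95\t3.81
Housing Over 30% of Income\t0.23\t0.08
Proportion Foreign Born\t0.17\t0.16
Proportion Religious\t0.76\t0.13
Proportion Indigenous ID\t0.06\t0.12
Proportion Resided 5+ Years\t0.62\t0.10
Proportion University Degree\t0.62\t0.10
Median Commute (minutes)\t19.12\t6.69
Log Population Density\t5.24\t2.88
"""

# Top vs bottom life-satisfaction quintile, all 1216 regions.
_QUINTILES_ALL = """variable\tmean_a\tse_a\tmean_b\tse_b\tdiff\tdiff_se
Satisfaction with Life\t8.33\t0.01\t7.70\t0.01\t0.63\t0.01
Std. Deviation of SWL\t1.52\t0.01\t1.82\t0.01\t-0.30\t0.02
Community Belonging\t0.77\t0.01\t0.67\t0.00\t0.10\t0.01
Log Mean HH Income\t11.24\t0.02\t11.16\t0.02\t0.08\t0.02
Unemployment (percent)\t8.26\t0.36\t8.91\t0.20\t-0.65\t0.41
Housing Over 30% of Income\t0.17\t0.00\t0.30\t0.00\t-0.13\t0.01
Proportion Foreign Born\t0.08\t0.00\t0.30\t0.01\t-0.23\t0.01
Proportion Religious\t0.82\t0.01\t0.71\t0.01\t0.11\t0.01
Proportion Indigenous ID\t0.05\t0.01\t0.06\t0.01\t-0.01\t0.01
Proportion Resided 5+ Years\t0.68\t0.01\t0.57\t0.01\t0.11\t0.01
Proportion University Degree\t0.61\t0.01\t0.62\t0.01\t-0.01\t0.01
Median Commute (minutes)\t17.01\t0.39\t21.82\t0.45\t-4.81\t0.60
Log Population Density\t3.47\t0.17\t7.15\t0.16\t-3.68\t0.23
"""

# Urban (tracted) vs rural (non-tracted) regions.
_URBAN_RURAL = """variable\tmean_a\tse_a\tmean_b\tse_b\tdiff\tdiff_se
Satisfaction with Life\t7.97\t0.01\t8.15\t0.01\t-0.17\t0.01
Std. Deviation of SWL\t1.65\t0.01\t1.67\t0.01\t-0.02\t0.01
Community Belonging\t0.69\t0.00\t0.78\t0.00\t-0.09\t0.00
Log Mean HH Income\t11.29\t0.01\t11.12\t0.01\t0.17\t0.01
Unemployment (percent)\t7.35\t0.08\t9.02\t0.26\t-1.67\t0.27
Housing Over 30% of Income\t0.25\t0.00\t0.18\t0.00\t0.08\t0.00
Proportion Foreign Born\t0.22\t0.01\t0.06\t0.00\t0.17\t0.01
Proportion Religious\t0.75\t0.00\t0.79\t0.01\t-0.04\t0.01
Proportion Indigenous ID\t0.03\t0.00\t0.08\t0.01\t-0.05\t0.01
Proportion Resided 5+ Years\t0.60\t0.00\t0.67\t0.00\t-0.08\t0.01
Proportion University Degree\t0.67\t0.00\t0.55\t0.00\t0.11\t0.00
Median Commute (minutes)\t21.70\t0.22\t14.71\t0.25\t6.99\t0.33
Log Population Density\t6.92\t0.06\t2.29\t0.10\t4.63\t0.12
"""

# Top vs bottom quintile among the 776 urban regions.
_QUINTILES_URBAN = """variable\tmean_a\tse_a\tmean_b\tse_b\tdiff\tdiff_se
Satisfaction with Life\t8.2\t0.01\t7.65\t0.01\t0.62\t0.01
Std. Deviation of SWL\t1.48\t0.01\t1.84\t0.01\t-0.35\t0.02
Community Belonging\t0.72\t0.01\t0.66\t0.00\t0.06\t0.01
Log Mean HH Income\t11.43\t0.02\t11.12\t0.02\t0.31\t0.03
Unemployment (percent)\t6.12\t0.13\t9.04\t0.20\t-2.91\t0.24
Housing Over 30% of Income\t0.19\t0.00\t0.32\t0.00\t-0.13\t0.01
Proportion Foreign Born\t0.12\t0.01\t0.34\t0.01\t-0.22\t0.02
Proportion Religious\t0.79\t0.01\t0.70\t0.01\t0.09\t0.01
Proportion Indigenous ID\t0.03\t0.00\t0.04\t0.00\t-0.01\t0.00
Proportion Resided 5+ Years\t0.64\t0.01\t0.55\t0.01\t0.08\t0.01
Proportion University Degree\t0.70\t0.01\t0.62\t0.01\t0.07\t0.01
Median Commute (minutes)\t20.73\t0.45\t23.17\t0.50\t-2.44\t0.68
Log Population Density\t5.91\t0.14\t7.87\t0.08\t-1.97\t0.16
"""

# Top vs bottom quintile among the 440 rural regions.
_QUINTILES_RURAL = """variable\tmean_a\tse_a\tmean_b\tse_b\tdiff\tdiff_se
Satisfaction with Life\t8.39\t0.01\t7.89\t0.01\t0.50\t0.02
Std. Deviation of SWL\t1.53\t0.02\t1.80\t0.02\t-0.27\t0.03
Community Belonging\t0.81\t0.01\t0.77\t0.01\t0.04\t0.01
Log Mean HH Income\t11.11\t0.02\t11.15\t0.02\t-0.04\t0.03
Unemployment (percent)\t10.64\t0.75\t9.28\t0.55\t1.36\t0.93
Housing Over 30% of Income\t0.16\t0.01\t0.19\t0.01\t-0.03\t0.01
Proportion Foreign Born\t0.05\t0.01\t0.06\t0.00\t-0.01\t0.01
Proportion Religious\t0.85\t0.01\t0.74\t0.01\t0.11\t0.02
Proportion Indigenous ID\t0.08\t0.02\t0.15\t0.02\t-0.07\t0.03
Proportion Resided 5+ Years\t0.71\t0.01\t0.64\t0.01\t0.06\t0.01
Proportion University Degree\t0.55\t0.01\t0.54\t0.01\t0.01\t0.01
Median Commute (minutes)\t14.48\t0.57\t13.92\t0.64\t0.56\t0.86
Log Population Density\t2.00\t0.21\t2.12\t0.29\t-0.12\t0.36
"""


def _parse(text: str) -> pd.DataFrame:
    return pd.read_csv(StringIO(text), sep="\t").set_index("variable")


def summary_stats() -> pd.DataFrame:
    """All-regions mean and SD per variable."""
    return _parse(_SUMMARY)


def quintile_table() -> pd.DataFrame:
    """Top (a) vs bottom (b) life-satisfaction quintile, all regions."""
    return _parse(_QUINTILES_ALL)


def urban_rural_table() -> pd.DataFrame:
    """Urban/tracted (a) vs rural/non-tracted (b) regions."""
    return _parse(_URBAN_RURAL)


def urban_quintile_table() -> pd.DataFrame:
    """Top vs bottom quintile within the urban regions."""
    return _parse(_QUINTILES_URBAN)


def rural_quintile_table() -> pd.DataFrame:
    """Top vs bottom quintile within the rural regions."""
    return _parse(_QUINTILES_RURAL)


def arithmetically_consistent(table: pd.DataFrame) -> pd.Series:
    """Rows whose printed means reproduce the printed difference exactly.

    Printed means are rounded to the displayed precision, so some rows'
    differences disagree with ``mean_a - mean_b`` by one unit in the last
    printed digit; only consistent rows support exact reproduction.
    """
    return (table["mean_a"] - table["mean_b"]).round(2) == table["diff"].round(2)
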