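"""Published reference tables from the switchgrass drought-adaptation study
this pipeline models, transcribed as machine-readable fixtures.

These are the printed summary tables of the originating field experiment
(404 genotypes, CV drought / UC control, 2019–2022; AMMI subset of 24
genotypes × 8 environments). The raw plant data are not public, so these
tables serve as regression anchors: the arithmetic conventions implemented
here (repeatability R = Vg/Vp, AMMI sums of squares, Gollob degrees of
freedom, sqrt-singular-value score scaling) must reproduce their internal
relationships.

``make_fixture_tables`` writes all four as CSVs.
"""

from __future__ import annotations

from io import StringIO
from pathlib import Path

import pandas as pd

__all__ = [
    "reference_variance_components",
    "reference_c1_constants",
    "reference_ammi_anova",
    "reference_ammi_scores",
    "make_fixture_tables",
]

_VARIANCE_COMPONENTS = """\
year,treatment,Vg,Vp,R
2019,CV,530654.89,839764.08,0.63
2019,UC,353617.41,728616.16,0.49
2020,CV,331640.61,997327.24,0.33
2020,UC,378310.46,1021137.62,0.37
2021,CV,207718.63,668504.68,0.31
2021,UC,792607.53,1654216.53,0.48
2022,CV,62063.54,271506.21,0.23
2022,UC,413679.04,916472.04,0.45
"""

_C1_CONSTANTS = """\
year,C1_SD0,C1_SD1,C1_SD2
2019,1,2.6,4.8
2020,1,1.9,3.2
2021,1,2.0,3.4
2022,1,1.8,2.8
"""

_AMMI_ANOVA = """\
source,df,SS,MS,F
Genotypes,23,13429905,583909,2.41
Environments,7,54182532,7740362,31.98
Interactions,161,38967120,242032,
IPCA 1,29,21865873,753996,7.81
IPCA 2,27,6960918,257812,2.67
Residuals,105,10140330,96575,
"""

# Mean biomass yield (g·plant⁻¹) and IPCA scores; environments then genotypes.
_AMMI_SCORES = """\
kind,name,mean,IPCA1,IPCA2
environment,CV19,2221,-35.33,29.46
environment,CV20,1895,-15.02,-13.16
environment,CV21,1587,-8.62,-22.14
environment,CV22,881,-3.62,-23.03
environment,UC19,1674,-21.58,6.94
environment,UC20,1942,14.39,4.64
environment,UC21,2869,36.70,22.02
environment,UC22,2064,33.09,-4.72
genotype,J009.C,1868,2.77,0.94
genotype,J022.A,2076,5.69,9.22
genotype,J177.A,1800,-10.86,8.54
genotype,J188.A,1374,-35.43,-2.56
genotype,J191.A,1250,25.33,-15.48
genotype,J211.A,2081,-10.60,4.20
genotype,J218.A,1894,0.34,-7.32
genotype,J222.A,2400,0.63,10.15
genotype,J230.A,1954,-5.36,-13.31
genotype,J247.A,1823,12.43,-13.50
genotype,J251.C,1914,8.02,5.09
genotype,J295.A,2186,-1.97,8.47
genotype,J323.A,1814,6.82,2.85
genotype,J324.A,1966,10.65,12.55
genotype,J326.A,1647,-4.12,-15.32
genotype,J456.C,1854,-9.22,11.26
genotype,J463.A,2388,37.13,17.99
genotype,J496.C,2188,-18.21,5.82
genotype,J497.C,1928,-10.52,0.93
genotype,J514.A,1648,3.91,-17.79
genotype,J587.A,1887,-9.83,0.26
genotype,J587.B,2016,-5.50,8.72
genotype,J653.C,1611,4.48,-17.49
genotype,Rambo4,1830,3.43,-4.24
"""


def reference_variance_components() -> pd.DataFrame:
    """Per year × treatment genetic and phenotypic variances with printed R."""
    return pd.read_csv(StringIO(_VARIANCE_COMPONENTS))


def reference_c1_constants() -> pd.DataFrame:
    """DAI isoline threshold constants at SD levels 0, 1, 2 per year."""
    return pd.read_csv(StringIO(_C1_CONSTANTS))


def reference_ammi_anova() -> pd.DataFrame:
    """AMMI ANOVA of the 24 × 8 BLUP subset (Gollob axis df)."""
    return pd.read_csv(StringIO(_AMMI_ANOVA))


def reference_ammi_scores() -> pd.DataFrame:
    """Mean yields and IPCA1/IPCA2 scores for the 24 genotypes and 8
    environments of the AMMI subset."""
    return pd.read_csv(StringIO(_AMMI_SCORES))


def make_fixture_tables(out_dir) -> dict[str, Path]:
    """Write all reference tables as CSVs into ``out_dir``; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "variance_components": reference_variance_components(),
        "c1_constants": reference_c1_constants(),
        "ammi_anova": reference_ammi_anova(),
        "ammi_scores": reference_ammi_scores(),
    }
    paths = {}
    for name, df in tables.items():
        p = out / f"reference_{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
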