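"""ROI-level Pearson correlations between age and regional uptake.

Pooled and sex-stratified correlations with two-sided p-values from the
t-transform (n-2 degrees of freedom) and Bonferroni correction over the
number of regions tested (four striatal ROIs by default).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import REGIONS

__all__ = ["CorrelationResult", "pearson_age_correlation", "sex_stratified_correlation"]


@dataclass(frozen=True)
class CorrelationResult:
    region: str
    stratum: str  # {all, male, female}
    n: int
    r: float
    p_unc: float
    p_bonf: float


def _pearson(age: np.ndarray, y: np.ndarray, region: str) -> tuple[float, float]:
    if len(age) < 3:
        raise ValueError(f"need n >= 3 observations, got {len(age)}")
    if np.ptp(age) == 0 or np.ptp(y) == 0:
        raise ValueError(f"zero variance in age or uptake for region '{region}'")
    res = stats.pearsonr(age, y)
    return float(res.statistic), float(res.pvalue)


def pearson_age_correlation(
    roi_table: pd.DataFrame,
    regions: tuple[str, ...] = REGIONS,
    m: int = 4,
    stratum: str = "all",
) -> list[CorrelationResult]:
    """Pearson r of age against each region, Bonferroni-corrected over ``m`` tests.

    ``roi_table`` carries the cohort covariates (``age``) alongside one
    column per region, as produced by the generator or the extraction stage.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    age = roi_table["age"].to_numpy(dtype=float)
    out = []
    for region in regions:
        y = roi_table[region].to_numpy(dtype=float)
        r, p = _pearson(age, y, region)
        out.append(
            CorrelationResult(
                region=region, stratum=stratum, n=len(age),
                r=r, p_unc=p, p_bonf=min(1.0, m * p),
            )
        )
    return out


def sex_stratified_correlation(
    roi_table: pd.DataFrame, regions: tuple[str, ...] = REGIONS, m: int = 4
) -> list[CorrelationResult]:
    """Same correlations restricted to the male and female strata."""
    out = []
    for sex in ("male", "female"):
        sub = roi_table[roi_table["sex"] == sex]
        if len(sub) < 3:
            raise ValueError(f"stratum '{sex}' too small (n={len(sub)} < 3)")
        out.extend(pearson_age_correlation(sub, regions=regions, m=m, stratum=sex))
    return out


def results_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tabulate correlation results, one row per region x stratum."""
    return pd.DataFrame([asdict(r) for r in results])
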