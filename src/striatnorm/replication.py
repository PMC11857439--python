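"""Replicate-cohort summaries of the headline effect sizes.

These loops regenerate the default synthetic cohort many times and summarize
the quantities the analysis reports: the age correlation of each striatal
region and the test-half explained variance of the normative model.  They
are what the repository's reproduction script runs.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import normative as nm
from . import synthetic as syn

__all__ = ["replicate_age_correlations", "replicate_normative_ev", "replicate_seeds"]


def replicate_seeds(base_seed: int, n_rep: int) -> list[int]:
    """Per-replicate seeds derived from one base seed (kept below 2**31)."""
    return [int((base_seed * 1000 + i) % 2**31) for i in range(1, n_rep + 1)]


def replicate_age_correlations(
    n_rep: int = 200, base_seed: int = 1, regions=syn.REGIONS
) -> dict[str, np.ndarray]:
    """Per-replicate sample Pearson r between age and each region's uptake."""
    out = {r: np.empty(n_rep) for r in regions}
    for k, s in enumerate(replicate_seeds(base_seed, n_rep)):
        cohort = syn.generate_cohort(seed=s)
        table = syn.generate_roi_suv(cohort, seed=s + 2**19)
        for r in regions:
            out[r][k] = stats.pearsonr(table["age"], table[r]).statistic
    return out


def replicate_normative_ev(
    region: str, n_rep: int = 200, base_seed: int = 1
) -> np.ndarray:
    """Per-replicate test-half EV of the warped-BLR fit for one region.

    Each replicate draws a fresh default cohort, splits it into balanced
    halves, fits the model on the training half and scores EV of the
    back-transformed median predictions on the test half.
    """
    evs = np.empty(n_rep)
    for k, s in enumerate(replicate_seeds(base_seed, n_rep)):
        cohort = syn.generate_cohort(seed=s)
        table = syn.generate_roi_suv(cohort, seed=s + 2**19)
        res = nm.run_normative(table, regions=(region,), seed=s)
        evs[k] = res[region].ev_test
    return evs
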