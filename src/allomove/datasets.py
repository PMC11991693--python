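"""Bundled example data: the published narwhal composite-stress cohort.

The underlying study tracked 10 narwhal (*Monodon monoceros*) in Eclipse
Sound, each given a veterinary health assessment at tagging.  The raw
records are not publicly deposited, but the per-parameter stress scores and
the three-state movement summaries are published, and those printed values
are reproduced here as machine-usable inputs: the score table drives the
deterministic index computations, and the state-level stream means anchor
the synthetic-data generator's default truth.

Score columns use ``NaN`` for a dimension that was not measurable for that
individual (blank in the published table); the predator dimension is blank
for every individual captured with no predators sighted, and the calf
dimension is blank for males.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

# Nine scored stress dimensions, in scoring order.
SCORE_COLUMNS = [
    "healed_scars",
    "fresh_wounds",
    "ectoparasites",
    "predators",
    "calf",
    "bci",
    "cortisol",
    "dhea_s",
    "cort_dhea_ratio",
]

# Published per-parameter scores for the 10 tagged narwhal.  Empty cells in
# the source table (unavailable dimensions) are left blank here.
_COHORT_CSV = """\
id,length_cm,sex,healed_scars,fresh_wounds,ectoparasites,predators,calf,bci,cortisol,dhea_s,cort_dhea_ratio
MM-01,466,M,0,0,0,,,,0,0,0
MM-02,400,F,0,0,0,,0,,,,
MM-03,400,F,0.5,0,0,,0,1,0,0,0
MM-04,432,M,0.5,2,0,,,0,1,0,1
MM-05,488,M,0.5,0,1,,,,1,0,
MM-06,458,M,0.5,2,0,,,,0,1,0
MM-07,430,M,0.5,0,0,,,0,,,
MM-08,375,F,0,0,0,,0,0,,,
MM-12,425,F,0.5,0,1,1,1,1,1,0,1
MM-13,298,M,0,0,0,,,,,,
"""

# Published three-state summaries for the five data streams.  Gamma-stream
# values are state means on the natural scale; `turn_concentration` is the
# von Mises concentration (only reported for transiting; the foraging-state
# values here are plausible fill-ins for simulation, not published numbers).
STATE_MEANS = pd.DataFrame(
    {
        "state": ["transiting", "foraging_shallow", "foraging_deep"],
        "step_m": [3832.04, 2587.0, 2528.5],
        "max_depth_m": [46.4, 153.0, 481.5],
        "wiggles_m": [26.6, 89.5, 327.3],
        "dist_shore_km": [4.58, 2.12, 8.7],
        "turn_concentration": [1.57, 0.6, 0.6],
        "turn_concentration_published": [True, False, False],
    }
).set_index("state")

# Hormone cut-points reported for the cohort: cortisol upper quartile
# (ng/ml), DHEA-S lower quartile (ng/ml), cortisol:DHEA upper quartile.
PUBLISHED_THRESHOLDS = {
    "cortisol_upper": 42.3,
    "dhea_s_lower": 5.75,
    "cort_dhea_ratio_upper": 98.2,
}


def narwhal_cohort() -> pd.DataFrame:
    """Per-parameter stress scores for the published 10-narwhal cohort.

    Returns a DataFrame indexed by individual id with ``length_cm``, ``sex``
    and the nine score columns (``NaN`` = dimension unavailable).  Totals,
    dimension counts and the composite index itself are deliberately *not*
    included: recompute them with :mod:`allomove.health`.
    """
    df = pd.read_csv(io.StringIO(_COHORT_CSV), index_col="id")
    for col in SCORE_COLUMNS:
        df[col] = df[col].astype(float)
    return df


def narwhal_csi() -> pd.Series:
    """Composite stress index per individual, recomputed from the scores.

    Values are rounded to 2 dp (ties away from zero), i.e. exactly the
    published per-individual index values.
    """
    from allomove.health import StressScoreBreakdown, composite_stress_index

    df = narwhal_cohort()
    out = {}
    for ind, row in df.iterrows():
        scores = {c: row[c] for c in SCORE_COLUMNS if np.isfinite(row[c])}
        out[ind] = composite_stress_index(StressScoreBreakdown.from_scores(scores))
    return pd.Series(out, name="csi")
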