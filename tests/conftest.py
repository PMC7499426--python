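import numpy as np
import pandas as pd
import pytest

from larvaswim import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Small default cohort: 4 clutches x 3 fish x 2 genotypes."""
    return generate_cohort(CohortConfig(seed=1, fish_per_clutch_per_genotype=3))


@pytest.fixture(scope="session")
def mut_fish(cohort):
    return cohort[cohort.genotype == "mut"].iloc[0]


@pytest.fixture(scope="session")
def wt_fish(cohort):
    return cohort[cohort.genotype == "wt"].iloc[0]


def make_trace(tail_angle, rate=100.0, x=None, y=None):
    """Build a minimal trace table around a tail-angle array."""
    n = len(tail_angle)
    return pd.DataFrame({
        "frame_index": np.arange(n),
        "time_s": np.arange(n) / rate,
        "x_mm": np.zeros(n) if x is None else np.asarray(x, dtype=float),
        "y_mm": np.zeros(n) if y is None else np.asarray(y, dtype=float),
        "heading_deg": np.zeros(n),
        "tail_angle_deg": np.asarray(tail_angle, dtype=float),
    })


def match_bouts(gt, intervals, slack=10):
    """Pair ground-truth bouts with detected intervals by onset proximity.

    Returns (pairs, n_missed, n_spurious) where pairs maps gt row index to
    the detected interval.
    """
    used = set()
    pairs = {}
    for idx, row in gt.iterrows():
        best = None
        for j, (s, e) in enumerate(intervals):
            if j in used:
                continue
            if abs(s - row.onset_frame) <= slack:
                best = j
                break
        if best is not None:
            used.add(best)
            pairs[idx] = intervals[best]
    return pairs, len(gt) - len(pairs), len(intervals) - len(used)
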