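"""Shared fixtures: seeded scene batches with their segmentations."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from blebquant.validation import SegmentedScene, build_scenes

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

N_BATCH_SCENES = 20  # x 10 cells = 200 cells for recovery checks


@pytest.fixture(scope="session")
def scene_batch() -> list[SegmentedScene]:
    """Twenty default scenes (10 non-touching cells each), fully segmented."""
    return build_scenes(range(N_BATCH_SCENES))


@pytest.fixture(scope="session")
def touching_scenes() -> list[SegmentedScene]:
    """Five two-cell scenes rendered as touching pairs."""
    return build_scenes(
        range(1000, 1005),
        n_cells=2,
        touching_pair_fraction=1.0,
        blebbing_fraction=0.0,
        image_height=512,
        image_width=512,
    )


@pytest.fixture(scope="session")
def single_scene(scene_batch) -> SegmentedScene:
    return scene_batch[0]


def iou(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return (a & b).sum() / union if union else 0.0


def match_label(label_map: np.ndarray, truth_mask: np.ndarray) -> int:
    """Label with the largest overlap with a ground-truth mask (0 if none)."""
    vals = label_map[truth_mask]
    vals = vals[vals > 0]
    return int(np.bincount(vals).argmax()) if vals.size else 0


# ---------------------------------------------------------------------------
# Independent statistics oracles (no scipy/statsmodels involvement)
# ---------------------------------------------------------------------------

def hypergeom_pmf(x: int, r1: int, r2: int, c1: int) -> float:
    """P(X = x) for the 2x2 table with fixed margins, via log-factorials."""
    n = r1 + r2
    lf = math.lgamma

    def logc(a, b):
        return lf(a + 1) - lf(b + 1) - lf(a - b + 1)

    return math.exp(logc(r1, x) + logc(r2, c1 - x) - logc(n, c1))


def fisher_two_sided_enumeration(table) -> float:
    """Two-sided Fisher p by full enumeration (point-probability rule)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = hypergeom_pmf(a, r1, r2, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        p = hypergeom_pmf(x, r1, r2, c1)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


def bh_step_up(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the step-up definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
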