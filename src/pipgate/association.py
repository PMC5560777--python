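"""The composite relative PIP2 association number.

For every frame the score sums, over all four pockets, the hydrogen-bond
counts of 0'K, 5'K and the 6' residue with the lipid 5'-phosphate and
subtracts the count of the competing non-lipid interaction between the 6'
residue and 9'E.  A high score indicates the 5'-phosphate is engaged in its
canonical site; the score decays toward zero as the lipid disengages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hbonds import DEFAULT_PAIRS, HBondCriteria, pair_timeseries
from .structures import PocketAssignment, ResidueRoleMap, Trajectory

#: Component pairs and their sign in the score.
SCORE_TERMS = (
    ("0'K-5'PO4", +1),
    ("5'K-5'PO4", +1),
    ("6'-5'PO4", +1),
    ("6'-9'E", -1),
)


@dataclass
class AssociationScoreSeries:
    """Per-frame association score with its per-pair breakdown.

    ``breakdown[label]`` is the pocket-summed count of that component pair
    per frame; ``score`` is the signed sum of the breakdown and may be
    negative.  ``smoothed`` is a running mean (truncated at the edges) with
    the window used stored in ``smooth_window_ns``.
    """

    times: np.ndarray
    score: np.ndarray  # signed integer, per frame
    smoothed: np.ndarray
    breakdown: dict[str, np.ndarray]
    smooth_window_ns: float

    def __post_init__(self):
        recomposed = np.zeros_like(self.score)
        for label, sign in SCORE_TERMS:
            recomposed = recomposed + sign * self.breakdown[label]
        if not np.array_equal(recomposed, self.score):
            raise ValueError("breakdown does not sum to score")


def running_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean with truncated windows at the edges."""
    values = np.asarray(values, dtype=float)
    if window <= 1:
        return values.copy()
    half = window // 2
    cum = np.concatenate([[0.0], np.cumsum(values)])
    n = values.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cum[hi] - cum[lo]) / (hi - lo)


def association_score_series(
    traj: Trajectory,
    roles: ResidueRoleMap,
    pockets: PocketAssignment,
    criteria: HBondCriteria = HBondCriteria(),
    smooth_window_ns: float = 10.0,
) -> AssociationScoreSeries:
    """Compute the relative PIP2 association number over a trajectory.

    The 6'-9'E subtraction uses the configured 6' donor (lysine NZ in WT,
    tyrosine OH in 6'Y, where it is typically zero throughout).
    """
    breakdown: dict[str, np.ndarray] = {}
    for label, _sign in SCORE_TERMS:
        series = pair_timeseries(traj, DEFAULT_PAIRS[label], roles, pockets, criteria)
        breakdown[label] = np.sum([s.counts for s in series], axis=0)
    score = np.zeros(traj.n_frames, dtype=int)
    for label, sign in SCORE_TERMS:
        score += sign * breakdown[label]
    dt = float(np.median(np.diff(traj.times))) if traj.n_frames > 1 else 1.0
    window = max(int(round(smooth_window_ns / dt)), 1)
    smoothed = running_mean(score, window)
    return AssociationScoreSeries(
        times=traj.times,
        score=score,
        smoothed=smoothed,
        breakdown=breakdown,
        smooth_window_ns=smooth_window_ns,
    )
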