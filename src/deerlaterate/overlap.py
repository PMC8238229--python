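"""Distribution-overlap restraint score for ranking structural models.

For each restrained pair the inner product between the simulated and
experimental distance distributions is computed on a common grid; the
score contribution is -ln of that overlap, summed over pairs (lower is
better). A vanishing overlap would give ln(0); following the convention
that the floor is the log of the smallest normal single-precision float,
such terms are set to 87.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .forward import DistanceDistribution

__all__ = ["ScoreReport", "overlap_score", "OVERLAP_FLOOR"]

#: -ln floor: ln of the smallest normal float32 is about -87.3; the
#: conventional cap used for non-overlapping distributions is 87.0
OVERLAP_FLOOR = 87.0
_FLT_MIN = float(np.finfo(np.float32).tiny)


@dataclass
class ScoreReport:
    """Per-pair -ln overlap terms and their total."""

    per_pair_terms: dict[str, float]
    inner_products: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.per_pair_terms.values()))


def _resample(dist: DistanceDistribution, centers: np.ndarray) -> np.ndarray:
    p = np.interp(centers, dist.bin_centers, dist.probabilities, left=0.0, right=0.0)
    total = p.sum()
    if total <= 0:
        return p
    return p / total


def overlap_score(
    sim: dict[str, DistanceDistribution],
    exp: dict[str, DistanceDistribution],
) -> ScoreReport:
    """Score agreement between simulated and experimental distributions.

    ``sim`` and ``exp`` map pair ids to normalized distributions. When a
    pair's grids differ, the simulated distribution is linearly
    resampled onto the experimental grid and renormalized. Symmetric in
    its arguments on a common grid.
    """
    if set(sim) != set(exp):
        missing = set(sim) ^ set(exp)
        raise ValueError(f"sim/exp pair ids differ: {sorted(missing)}")
    terms: dict[str, float] = {}
    inners: dict[str, float] = {}
    for pair_id in sorted(sim):
        ps, pe = sim[pair_id], exp[pair_id]
        if ps.bin_centers.shape == pe.bin_centers.shape and np.allclose(
            ps.bin_centers, pe.bin_centers, rtol=0, atol=1e-9
        ):
            p_sim = ps.probabilities
        else:
            p_sim = _resample(ps, pe.bin_centers)
        inner = float(np.dot(p_sim, pe.probabilities))
        inners[pair_id] = inner
        if inner < _FLT_MIN:
            terms[pair_id] = OVERLAP_FLOOR
        else:
            terms[pair_id] = min(-math.log(inner), OVERLAP_FLOOR)
    return ScoreReport(per_pair_terms=terms, inner_products=inners)
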