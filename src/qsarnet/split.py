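"""Sphere-exclusion partitioning into training and test sets.

Rational splitting: rather than sampling the test set at random, compounds
are assigned so that every test compound lies within a Euclidean sphere of
radius ``r`` around some training compound, guaranteeing that each test
prediction is an interpolation from nearby training chemistry.

The variant implemented here is a deterministic max-min (farthest-point)
sweep: the first center is the compound with the highest activity (ties
broken by lexicographically smallest ID, so the split covers the top of the
activity range), each center joins the training set, unassigned compounds
inside its sphere join the test set, and the next center is the unassigned
compound farthest from all existing centers. The radius is tuned by
bisection so the achieved test fraction is as close as possible to the
requested target. The split is recomputed whenever the descriptor subset
changes, because distances — and hence the rational partition — live in the
current descriptor space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data_io import logger
from .errors import ValidationError
from .table import DescriptorTable


@dataclass
class SplitResult:
    train_ids: list[str]
    test_ids: list[str]
    radius: float
    seed_compound: str

    @property
    def test_fraction(self) -> float:
        m = len(self.train_ids) + len(self.test_ids)
        return len(self.test_ids) / m if m else 0.0


def _assign(
    D: np.ndarray, first: int, radius: float, id_rank: np.ndarray
) -> tuple[list[int], list[int]]:
    """One sphere-exclusion sweep at a fixed radius; returns index lists."""
    m = D.shape[0]
    unassigned = np.ones(m, dtype=bool)
    mindist = np.full(m, np.inf)    # distance to nearest center so far
    train: list[int] = []
    test: list[int] = []
    c = first
    while True:
        unassigned[c] = False
        train.append(c)
        captured = np.flatnonzero(unassigned & (D[c] <= radius))
        test.extend(int(i) for i in captured)
        unassigned[captured] = False
        if not unassigned.any():
            break
        mindist = np.minimum(mindist, D[c])
        masked = np.where(unassigned, mindist, -np.inf)
        # farthest-from-centers; ties -> lexicographically smallest ID
        cand = np.flatnonzero(masked == masked.max())
        c = int(cand[np.argmin(id_rank[cand])])
    return train, test


def sphere_exclusion_split(
    table: DescriptorTable,
    test_fraction: float = 0.2,
    max_bisection_iters: int = 40,
) -> SplitResult:
    """Deterministic sphere-exclusion train/test split.

    Parameters
    ----------
    table
        Descriptor table; descriptors should already be normalized so that
        Euclidean distance is meaningful.
    test_fraction
        Target fraction of compounds in the test set, in (0, 1). The radius
        achieving the closest fraction is found by bisection over
        [0, max pairwise distance]; if the target is unreachable the closest
        achievable split is returned with a warning.
    """
    if table.m < 5:
        raise ValidationError(f"need at least 5 compounds, got {table.m}")
    if not (0 < test_fraction < 1):
        raise ValidationError("test_fraction must be in (0, 1)")
    ids = table.compound_ids
    y = table.y
    # first center: highest activity, ties -> lexicographically smallest ID
    top = np.flatnonzero(y == y.max())
    first = min(top, key=lambda i: ids[i])
    D = squareform(pdist(table.X))
    id_rank = np.argsort(np.argsort(np.asarray(ids, dtype=object)))

    best: tuple[float, float, list[int], list[int]] | None = None

    def evaluate(radius: float) -> float:
        nonlocal best
        train, test = _assign(D, first, radius, id_rank)
        frac = len(test) / table.m
        dev = abs(frac - test_fraction)
        if best is None or dev < best[0] - 1e-12 or (
            abs(dev - best[0]) <= 1e-12 and radius < best[1]
        ):
            best = (dev, radius, train, test)
        return frac

    lo, hi = 0.0, float(D.max())
    evaluate(lo)
    if hi > 0:
        evaluate(hi)
        for _ in range(max_bisection_iters):
            mid = 0.5 * (lo + hi)
            frac = evaluate(mid)
            if frac < test_fraction:
                lo = mid
            else:
                hi = mid
    assert best is not None
    dev, radius, train, test = best
    if dev > 0.5 / table.m + 1e-12:
        logger.warning(
            "sphere_exclusion_split: target test fraction %.3f unreachable; "
            "closest achieved is %.3f at radius %.4g",
            test_fraction, len(test) / table.m, radius,
        )
    result = SplitResult(
        train_ids=[ids[i] for i in sorted(train)],
        test_ids=[ids[i] for i in sorted(test)],
        radius=radius,
        seed_compound=ids[first],
    )
    logger.info(
        "sphere_exclusion_split: %d train / %d test (target fraction %.3f, "
        "achieved %.3f, radius %.4g, seed compound %s)",
        len(result.train_ids), len(result.test_ids), test_fraction,
        result.test_fraction, radius, result.seed_compound,
    )
    return result
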