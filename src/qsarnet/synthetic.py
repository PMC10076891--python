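"""Synthetic descriptor tables with known generative structure.

Emulates the shape of a MOE/CDK-style descriptor export: blocks of highly
inter-correlated descriptors (redundant size/lipophilicity families), a
small active subset that actually drives the activity through a linear or
tanh-saturating link, Gaussian assay noise, optionally wildly mixed column
scales, and planted activity outliers placed in dense or sparse regions of
descriptor space. Because the generative record (true coefficients, outlier
IDs, block membership) is returned alongside the table, every downstream
operation — pruning, washing, splitting, training, variable selection — can
be tested against a known ground truth.

Block correlation uses a shared-factor construction: descriptors in a block
with correlation rho are sqrt(rho) * block_factor + sqrt(1-rho) * noise,
which gives exactly rho as the population within-block correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data_io import logger
from .errors import ValidationError
from .table import DescriptorTable


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic descriptor table.

    Parameters
    ----------
    m, k
        Number of compounds and of descriptors.
    blocks
        Sizes of correlated descriptor blocks (leading columns, in order);
        descriptors beyond the blocks are independent.
    rho
        Within-block population correlation, in [0, 1).
    active
        Indices of the descriptors that truly drive the activity.
    link
        "linear" or "tanh" (saturating response).
    noise_sd
        Standard deviation of additive Gaussian activity noise.
    n_outliers, outlier_sigma, outlier_dense
        Planted activity outliers: how many, their deviation in units of the
        local activity sd, and whether they sit in dense descriptor regions
        (detectable) or sparse ones (protected by the neighbour-count rule).
    mixed_scales
        Rescale every third descriptor column by 1000 to exercise
        normalization, as raw descriptor exports do.
    """

    m: int = 200
    k: int = 10
    blocks: tuple[int, ...] = ()
    rho: float = 0.0
    active: tuple[int, ...] = (0, 1)
    link: str = "linear"
    noise_sd: float = 0.1
    n_outliers: int = 0
    outlier_sigma: float = 6.0
    outlier_dense: bool = True
    mixed_scales: bool = False
    radius_quantile: float = 0.10   # neighbourhood rule used to plant outliers
    seed: int = 0

    def validate(self) -> "SyntheticSpec":
        if self.m < 3 or self.k < 1:
            raise ValidationError("need m >= 3 compounds and k >= 1 descriptors")
        if not (0 <= self.rho < 1):
            raise ValidationError("rho must be in [0, 1)")
        if sum(self.blocks) > self.k:
            raise ValidationError("block sizes exceed descriptor count")
        if any(b < 1 for b in self.blocks):
            raise ValidationError("block sizes must be positive")
        if not self.active or any(not 0 <= a < self.k for a in self.active):
            raise ValidationError("active indices must lie in [0, k)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.link not in ("linear", "tanh"):
            raise ValidationError("link must be 'linear' or 'tanh'")
        if self.n_outliers < 0 or self.n_outliers >= self.m:
            raise ValidationError("n_outliers must be in [0, m)")
        return self


@dataclass
class GroundTruth:
    """What the generator actually did — the oracle for downstream tests."""

    coefficients: dict[str, float]
    active_names: list[str]
    outlier_ids: list[str]
    block_of: dict[str, int]        # descriptor name -> block index (-1: none)
    column_scales: dict[str, float]
    link: str
    noise_sd: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def generate(spec: SyntheticSpec) -> tuple[DescriptorTable, GroundTruth]:
    """Draw one descriptor table according to ``spec``; bit-exact per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    m, k = spec.m, spec.k
    names = [f"d{i + 1:03d}" for i in range(k)]
    ids = [f"C{i + 1:04d}" for i in range(m)]

    X = np.empty((m, k))
    block_of = {name: -1 for name in names}
    col = 0
    for b, size in enumerate(spec.blocks):
        factor = rng.standard_normal(m)
        for _ in range(size):
            eps = rng.standard_normal(m)
            X[:, col] = np.sqrt(spec.rho) * factor + np.sqrt(1 - spec.rho) * eps
            block_of[names[col]] = b
            col += 1
    while col < k:
        X[:, col] = rng.standard_normal(m)
        col += 1

    active = sorted(spec.active)
    coef = rng.uniform(1.0, 2.0, size=len(active)) * rng.choice(
        (-1.0, 1.0), size=len(active))
    signal = X[:, active] @ coef
    if spec.link == "tanh":
        signal = np.tanh(signal)
    y = signal + (rng.normal(0.0, spec.noise_sd, size=m) if spec.noise_sd > 0
                  else 0.0)

    outlier_ids: list[str] = []
    if spec.n_outliers > 0:
        # standardized space so the neighbourhood rule matches the washer's
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        if not spec.outlier_dense:
            # push the chosen compounds to a remote corner of descriptor
            # space so their neighbourhoods stay below the significance rule
            chosen = list(range(spec.n_outliers))
            X[chosen] = X[chosen] + 10.0 * X.std(axis=0)
            Z = (X - X.mean(axis=0)) / X.std(axis=0)
            dists = squareform(pdist(Z))
            r = np.quantile(dists[np.triu_indices(m, 1)], spec.radius_quantile)
        else:
            dists = squareform(pdist(Z))
            r = np.quantile(dists[np.triu_indices(m, 1)], spec.radius_quantile)
            np.fill_diagonal(dists, np.inf)
            counts = (dists <= r).sum(axis=1)
            chosen = list(np.argsort(-counts)[: spec.n_outliers])
        np.fill_diagonal(dists, np.inf)
        for i in chosen:
            mask = dists[i] <= r
            local = y[mask]
            sd = float(local.std()) if mask.sum() > 1 else float(y.std())
            sd = sd if sd > 0 else float(y.std())
            mu = float(local.mean()) if mask.any() else float(y.mean())
            sign = 1.0 if rng.random() < 0.5 else -1.0
            y[i] = mu + sign * spec.outlier_sigma * sd
            outlier_ids.append(ids[i])

    scales = {name: 1.0 for name in names}
    if spec.mixed_scales:
        for j in range(0, k, 3):
            X[:, j] *= 1000.0
            scales[names[j]] = 1000.0

    table = DescriptorTable(
        pd.DataFrame(X, index=pd.Index(ids, name="compound_id"), columns=names),
        pd.Series(y, index=ids, name="activity"),
        activity_name="activity",
    )
    truth = GroundTruth(
        coefficients={names[a]: float(c) for a, c in zip(active, coef)},
        active_names=[names[a] for a in active],
        outlier_ids=outlier_ids,
        block_of=block_of,
        column_scales=scales,
        link=spec.link,
        noise_sd=spec.noise_sd,
    )
    logger.info(
        "generate: m=%d k=%d blocks=%s rho=%.2f active=%s outliers=%s seed=%d",
        m, k, spec.blocks, spec.rho, truth.active_names, outlier_ids, spec.seed,
    )
    return table, truth
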