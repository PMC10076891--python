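"""Wrapper variable selection: search descriptor subsets of size k.

For every candidate subset the table is restricted to those columns, the
sphere-exclusion split is rebuilt (distances change with the descriptor
space, so the rational partition must too), a fresh network is trained with
early stopping, and the model is scored. The selection score is
min(q2_train, r2_test) — a subset must perform on both the internal
training set and the external test set, and the minimum aggregates the two
conservatively; a sum score is available behind a flag.

Exhaustive search enumerates all C(K, k) subsets in lexicographic order;
random search draws distinct subsets uniformly without replacement up to
``max_evals``. Every subset's training seed is derived from the master seed
and the subset's own column indices, so results are bit-identical whether
subsets are evaluated serially or in parallel, and the full run is
reproducible from the master seed alone.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .data_io import RunConfig, logger
from .errors import ValidationError
from .metrics import ModelReport, accept_model, q_squared, r_squared
from .network import forward, init_network, train
from .split import sphere_exclusion_split
from .table import DescriptorTable


@dataclass
class SubsetResult:
    descriptors: tuple[str, ...]
    indices: tuple[int, ...]
    score: float
    report: ModelReport


@dataclass
class SelectionRun:
    """Full audit trail of one variable-selection run."""

    K: int
    k: int
    strategy: str
    max_evals: int
    results: list[SubsetResult] = field(default_factory=list)
    best: SubsetResult | None = None
    best_accepted: bool = False

    @property
    def n_evaluated(self) -> int:
        return len(self.results)


def _subset_seed(master: int, indices: tuple[int, ...]) -> int:
    """Training seed for one subset: depends on the subset identity, not on
    evaluation order, so parallel and serial runs agree bit-for-bit."""
    return int(
        np.random.SeedSequence([master, *indices]).generate_state(1)[0] % (2**31)
    )


def evaluate_subset(
    table: DescriptorTable,
    indices: tuple[int, ...],
    config: RunConfig,
    master_seed: int,
) -> SubsetResult:
    """Split, train and score one descriptor subset."""
    names = [table.descriptor_names[i] for i in indices]
    sub = table.select_descriptors(names)
    split = sphere_exclusion_split(sub, config.split.test_fraction)
    tr = sub.select_compounds(split.train_ids)
    te = sub.select_compounds(split.test_ids)
    seed = _subset_seed(master_seed, indices)
    init_seed = seed  # init shares the subset seed; shuffles/dropout derive from it
    params = init_network(
        (len(names), *config.network.hidden_layers, 1),
        use_bias=config.network.use_bias,
        seed=init_seed,
    )
    y_loc = float(tr.y.mean())
    y_scale = float(tr.y.std()) or 1.0
    trained, state = train(
        params, tr.X, (tr.y - y_loc) / y_scale,
        te.X, (te.y - y_loc) / y_scale, config.network, seed=seed,
    )
    h_train = forward(trained, tr.X) * y_scale + y_loc
    h_test = forward(trained, te.X) * y_scale + y_loc
    report = ModelReport(
        q2_train=q_squared(tr.y, h_train),
        q2_test=q_squared(te.y, h_test),
        r2_test=r_squared(te.y, h_test),
        n_train=tr.m,
        n_test=te.m,
        descriptors=names,
        stopping_epoch=state.best_epoch,
        config=config.to_dict(),
    )
    score = min(report.q2_train, report.r2_test)
    return SubsetResult(tuple(names), tuple(indices), score, report)


def select_descriptors(
    table: DescriptorTable,
    k: int,
    strategy: str = "exhaustive",
    max_evals: int = 10000,
    config: RunConfig | None = None,
    seed: int | None = None,
    score: str = "min",
    n_jobs: int = 1,
) -> SelectionRun:
    """Search descriptor subsets of size ``k`` for the best model.

    Ranking: higher score wins; ties break by higher r2_test, then by
    lexicographic subset order. If no subset clears the acceptance
    thresholds the best one is still returned, flagged unaccepted.
    """
    config = (config or RunConfig()).validate()
    master = config.seed if seed is None else seed
    K = table.n
    if not (1 <= k <= K):
        raise ValidationError(f"k must be in [1, {K}], got {k}")
    if strategy not in ("exhaustive", "random"):
        raise ValidationError(f"unknown strategy {strategy!r}")
    if score not in ("min", "sum"):
        raise ValidationError(f"unknown score {score!r}")
    n_total = math.comb(K, k)
    if strategy == "exhaustive":
        if n_total > max_evals:
            raise ValidationError(
                f"exhaustive search needs {n_total} evaluations, "
                f"max_evals is {max_evals}"
            )
        subsets = list(itertools.combinations(range(K), k))
    else:
        rng = np.random.default_rng(
            np.random.SeedSequence([master, n_total]).generate_state(1)[0]
        )
        budget = min(max_evals, n_total)
        seen: set[tuple[int, ...]] = set()
        while len(seen) < budget:
            cand = tuple(sorted(rng.choice(K, size=k, replace=False).tolist()))
            seen.add(cand)
        subsets = sorted(seen)
    logger.info(
        "select_descriptors: %s search, K=%d, k=%d, %d subsets, seed %d",
        strategy, K, k, len(subsets), master,
    )

    if n_jobs == 1:
        results = [evaluate_subset(table, s, config, master) for s in subsets]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(evaluate_subset)(table, s, config, master) for s in subsets
        )
    if score == "sum":
        for r in results:
            r.score = r.report.q2_train + r.report.r2_test

    def rank_key(r: SubsetResult):
        # higher score, then higher r2_test, then lexicographically earlier
        return (-r.score, -r.report.r2_test, r.descriptors)

    best = min(results, key=rank_key)
    run = SelectionRun(
        K=K, k=k, strategy=strategy, max_evals=max_evals,
        results=results, best=best,
        best_accepted=accept_model(
            best.report, config.varselect.q2_threshold,
            config.varselect.r2_threshold,
        ),
    )
    if not run.best_accepted:
        logger.warning(
            "select_descriptors: no subset met the acceptance thresholds "
            "(best %s: %s)", best.descriptors, best.report.summary(),
        )
    else:
        logger.info(
            "select_descriptors: best subset %s (%s)",
            best.descriptors, best.report.summary(),
        )
    return run
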