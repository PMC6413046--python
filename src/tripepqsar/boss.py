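"""Bootstrapping soft shrinkage (BOSS) variable selection.

Each shrinkage iteration draws 1000 variable subsets by weighted bootstrap
(p draws with replacement over the live variables; the distinct drawn labels
form a sub-model), fits a PLS sub-model per subset, and turns the
normalized absolute regression coefficients (scaled space, each sub-model
voting with total mass 1) into the next round's sampling weights.  Variables
that accumulate zero weight stop being sampled and drop out -- shrinkage is
soft: survival is driven by the weights, never by a hard top-k cut.  Every
iteration's live set is scored by cross-validation, and the best-scoring
subset over the whole trajectory is refit on the full data to produce the
returned model.  Aggregating many runs gives per-variable selection
frequencies; high-frequency variables are the informative ones.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import boss_submodels, cv_press
from .pls import (CVScheme, DEFAULT_MAX_COMPONENTS, autoscale, cross_validate,
                  fit_pls, select_components)
from .scales import EncodedDataset

#: safety cap on shrinkage iterations (reached only on degenerate data)
MAX_ITERATIONS = 120


@dataclass
class BossRun:
    """Outcome of a single BOSS run."""

    selected_variables: list[str]
    q2: float
    r2: float
    optpc: int
    n_iterations: int
    seed: int
    live_counts: list[int] = field(default_factory=list)


@dataclass
class BossAggregate:
    """Selection frequencies and model statistics over repeated runs."""

    n_runs: int
    frequency: dict[str, int]
    q2_mean: float
    q2_sd: float
    r2_mean: float
    r2_sd: float
    optpc_mean: float
    optpc_sd: float
    runs: list[BossRun] = field(default_factory=list, repr=False)

    def frequency_frame(self):
        import pandas as pd

        items = sorted(self.frequency.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(items, columns=["variable", "frequency"])


def _inner_q2(Xs, yc, tss, live, cv_folds, cmax, rng):
    """k-fold Q2 of the live-variable model (on globally scaled data)."""
    Xl = np.ascontiguousarray(Xs[:, live])
    n = Xl.shape[0]
    fold_of = rng.permutation(np.arange(n, dtype=np.int64) % cv_folds)
    ceff = max(1, min(cmax, len(live), n - int(np.bincount(fold_of).max()) - 1))
    press = cv_press(Xl, yc, fold_of, cv_folds, ceff, True)
    return float(np.max(1.0 - press / tss))


def boss_run(
    data: EncodedDataset,
    n_sub: int = 1000,
    seed: int = 0,
    cv: CVScheme = CVScheme(),
    max_components: int = DEFAULT_MAX_COMPONENTS,
    inner_cv_folds: int = 5,
    top_fraction: float = 0.02,
) -> BossRun:
    """One seeded BOSS shrinkage trajectory; returns the best subset refit.

    The sub-model component count is fixed per iteration to
    min(optPC of the full model, live-variable count, n-1); candidate
    subsets are ranked with a cheap seeded k-fold CV during the run and the
    winner is refit and reported with the scheme in ``cv`` (default LOO).
    """
    n, p = data.X.shape
    if p < 2:
        raise ValueError("BOSS needs at least 2 variables")
    if np.std(data.y) < 1e-12:
        raise ValueError("response has zero variance")
    rng = np.random.default_rng(seed)
    Xs, yc, _ = autoscale(data.X, data.y)
    tss = float((yc ** 2).sum())
    # sub-models only rank variables; single precision is plenty for votes
    Xs32 = np.ascontiguousarray(Xs, dtype=np.float32)
    yc32 = yc.astype(np.float32)

    q2_full = cross_validate(data.X, data.y, cv, max_components)
    c_full = select_components(q2_full)

    live = np.arange(p)
    weights = np.full(p, 1.0 / p)
    best_q2 = -np.inf
    best_live = live.copy()
    live_counts = [p]
    iteration = 0
    stagnant = 0
    while iteration < MAX_ITERATIONS and live.size > 1 and stagnant < 10:
        iteration += 1
        # weighted bootstrap in variable space: p_live draws per sub-model;
        # the distinct drawn indices form each sub-model
        draws = rng.choice(live, size=(n_sub, live.size), replace=True,
                           p=weights[live]).astype(np.int64)
        c_sub = max(1, min(c_full, n - 1))
        contrib, rmse = boss_submodels(Xs32, yc32, draws, c_sub)
        # soft shrinkage: only the best-fitting sub-models vote on the next
        # round's sampling weights
        n_best = max(1, int(round(top_fraction * n_sub)))
        best = np.argsort(rmse)[:n_best]
        w_acc = contrib[best].sum(axis=0)
        if w_acc.sum() <= 0:
            raise RuntimeError("all sub-model coefficients vanished")
        new_live = np.flatnonzero(w_acc > 0)
        stagnant = stagnant + 1 if new_live.size == live.size else 0
        weights = w_acc / w_acc.sum()
        live = new_live
        live_counts.append(int(live.size))
        q2_here = _inner_q2(Xs, yc, tss, live, inner_cv_folds,
                            max_components, rng)
        if q2_here > best_q2:
            best_q2 = q2_here
            best_live = live.copy()

    subset = data.select_variables(best_live)
    q2_curve = cross_validate(subset.X, subset.y, cv, max_components)
    optpc = select_components(q2_curve)
    model = fit_pls(subset.X, subset.y, optpc)
    return BossRun(
        selected_variables=[data.variable_labels[j] for j in best_live],
        q2=float(q2_curve[optpc - 1]),
        r2=float(model.r2),
        optpc=optpc,
        n_iterations=iteration,
        seed=seed,
        live_counts=live_counts,
    )


def boss_aggregate(
    data: EncodedDataset,
    n_runs: int = 100,
    n_sub: int = 1000,
    base_seed: int = 0,
    cv: CVScheme = CVScheme(),
    max_components: int = DEFAULT_MAX_COMPONENTS,
) -> BossAggregate:
    """Run BOSS with consecutive seeds and aggregate selection frequencies."""
    runs = [
        boss_run(data, n_sub=n_sub, seed=base_seed + r, cv=cv,
                 max_components=max_components)
        for r in range(n_runs)
    ]
    freq = {label: 0 for label in data.variable_labels}
    for run in runs:
        for label in run.selected_variables:
            freq[label] += 1
    q2 = np.array([r.q2 for r in runs])
    r2 = np.array([r.r2 for r in runs])
    pc = np.array([r.optpc for r in runs], dtype=float)
    sd = (lambda a: float(a.std(ddof=1)) if len(a) > 1 else 0.0)
    return BossAggregate(
        n_runs=n_runs, frequency=freq,
        q2_mean=float(q2.mean()), q2_sd=sd(q2),
        r2_mean=float(r2.mean()), r2_sd=sd(r2),
        optpc_mean=float(pc.mean()), optpc_sd=sd(pc),
        runs=runs,
    )


def top_variables(agg: BossAggregate, threshold: int = 75) -> list[str]:
    """Labels selected in strictly more than ``threshold`` runs, by frequency."""
    if threshold > agg.n_runs:
        raise ValueError("threshold exceeds the number of runs")
    hits = [(label, f) for label, f in agg.frequency.items() if f > threshold]
    hits.sort(key=lambda kv: (-kv[1], kv[0]))
    return [label for label, _ in hits]
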