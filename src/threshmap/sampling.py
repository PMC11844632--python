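"""Electrode-selection strategies for threshold mapping.

Three strategies decide which electrodes to measure when only a subset can
be afforded:

* uniform -- random without replacement; the unbiased baseline.
* spatial -- Poisson-disk sampling (PDS) adapted to the discrete grid:
  enforces a minimum pairwise spacing so samples cover the array evenly.
* adaptive -- variance-based active learning: start from a small random
  subset, fit a GP, and repeatedly measure the electrode with the largest
  posterior standard deviation.

All strategies return a :class:`SamplingPlan` that is exactly reproducible
from its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .grid import ElectrodeGrid, ThresholdMap
from . import gpr

__all__ = [
    "SamplingPlan",
    "PDSParams",
    "uniform_sample",
    "poisson_disk_sample",
    "adaptive_sample",
    "STRATEGIES",
]

STRATEGIES = ("uniform", "spatial", "adaptive")


@dataclass(frozen=True)
class SamplingPlan:
    """An ordered electrode selection plus the provenance to replay it."""

    strategy: str
    ordered_ids: tuple[int, ...]
    n_requested: int
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.ordered_ids)) != len(self.ordered_ids):
            raise ValueError("sampling plan contains duplicate electrode ids")
        if len(self.ordered_ids) != self.n_requested:
            raise ValueError(
                f"plan has {len(self.ordered_ids)} ids, requested {self.n_requested}"
            )

    @property
    def ids(self) -> np.ndarray:
        return np.asarray(self.ordered_ids, dtype=int)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "strategy": self.strategy,
                "ordered_ids": list(self.ordered_ids),
                "n_requested": self.n_requested,
                "seed": self.seed,
                "params": self.params,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SamplingPlan":
        text = Path(str(source)).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            strategy=d["strategy"],
            ordered_ids=tuple(int(i) for i in d["ordered_ids"]),
            n_requested=int(d["n_requested"]),
            seed=int(d["seed"]),
            params=d.get("params", {}),
        )


def _eligible(grid: ElectrodeGrid, eligible_ids: Sequence[int] | None) -> np.ndarray:
    if eligible_ids is None:
        return grid.active_ids
    ids = np.unique(np.asarray(eligible_ids, dtype=int))
    if not np.isin(ids, grid.active_ids).all():
        raise ValueError("eligible_ids must be active electrodes")
    return ids


def uniform_sample(
    grid: ElectrodeGrid,
    n: int,
    seed: int,
    eligible_ids: Sequence[int] | None = None,
) -> SamplingPlan:
    """Draw ``n`` distinct electrodes uniformly at random, in draw order."""
    pool = _eligible(grid, eligible_ids)
    if not 1 <= n <= pool.size:
        raise ValueError(f"requested {n} of {pool.size} eligible electrodes")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n, replace=False)
    return SamplingPlan("uniform", tuple(int(i) for i in chosen), n, seed)


@dataclass(frozen=True)
class PDSParams:
    """Poisson-disk parameters, following the Bridson annulus convention.

    ``initial_radius = None`` picks ``sqrt(W * H / n)`` for grid extent
    W x H in pitch units -- the spacing at which n disks tile the array.
    Candidates are grid electrodes in the annulus [r, annulus_factor * r]
    around a frontier point; after ``k_attempts`` rejected proposals the
    frontier point retires.  If the frontier empties before n electrodes are
    placed, the radius shrinks by ``shrink_factor`` and sampling resumes, so
    a plan of exactly n electrodes always exists; the final (smallest)
    radius is recorded in the plan.
    """

    initial_radius: float | None = None
    annulus_factor: float = 2.0
    k_attempts: int = 30
    shrink_factor: float = 0.8


def poisson_disk_sample(
    grid: ElectrodeGrid,
    n: int,
    seed: int,
    params: PDSParams = PDSParams(),
    eligible_ids: Sequence[int] | None = None,
) -> SamplingPlan:
    """Spatially even selection via discrete Poisson-disk sampling.

    Every pairwise distance among the selected electrodes is at least the
    final radius recorded in ``plan.params["final_radius"]``.
    """
    pool = _eligible(grid, eligible_ids)
    if not 1 <= n <= pool.size:
        raise ValueError(f"requested {n} of {pool.size} eligible electrodes")
    rng = np.random.default_rng(seed)
    pos = grid.positions
    if params.initial_radius is not None:
        r = float(params.initial_radius)
    else:
        w = grid.n_cols * grid.pitch
        h = grid.n_rows * grid.pitch
        r = float(np.sqrt(w * h / n))

    selected: list[int] = [int(rng.choice(pool))]
    while len(selected) < n:
        frontier = list(selected)
        progress = False
        while frontier and len(selected) < n:
            f = int(rng.choice(len(frontier)))
            fpos = pos[frontier[f]]
            d_f = np.linalg.norm(pos[pool] - fpos, axis=1)
            in_annulus = (d_f >= r) & (d_f <= params.annulus_factor * r)
            candidates = pool[in_annulus & ~np.isin(pool, selected)]
            accepted = False
            for _ in range(params.k_attempts):
                if candidates.size == 0:
                    break
                c = int(rng.choice(candidates))
                d_sel = np.linalg.norm(pos[selected] - pos[c], axis=1)
                if (d_sel >= r).all():
                    selected.append(c)
                    frontier.append(c)
                    accepted = progress = True
                    break
                candidates = candidates[candidates != c]
            if not accepted:
                frontier.pop(f)
        if len(selected) < n and not progress:
            # the annulus proposal stalled at this radius; admit any electrode
            # that still honors the spacing, else relax the spacing itself
            unsel = pool[~np.isin(pool, selected)]
            dmin = np.linalg.norm(
                pos[unsel][:, None, :] - pos[selected][None, :, :], axis=-1
            ).min(axis=1)
            ok = unsel[dmin >= r]
            if ok.size:
                selected.append(int(rng.choice(ok)))
            else:
                r *= params.shrink_factor
    return SamplingPlan(
        "spatial",
        tuple(int(i) for i in selected),
        n,
        seed,
        params={
            "final_radius": r,
            "annulus_factor": params.annulus_factor,
            "k_attempts": params.k_attempts,
            "shrink_factor": params.shrink_factor,
        },
    )


def min_pairwise_distance(grid: ElectrodeGrid, ids: Sequence[int]) -> float:
    """Smallest pairwise distance among electrodes (inf for < 2 ids)."""
    ids = np.asarray(ids, dtype=int)
    if ids.size < 2:
        return float("inf")
    return float(pdist(grid.positions_of(ids)).min())


def adaptive_sample(
    tmap: ThresholdMap,
    n_total: int,
    family: str = "matern15",
    n_init: int = 5,
    seed: int = 0,
    config: gpr.GPConfig = gpr.GPConfig(),
    eligible_ids: Sequence[int] | None = None,
) -> SamplingPlan:
    """Uncertainty-driven selection: measure where the GP is least certain.

    The first ``n_init`` electrodes are drawn uniformly; each subsequent
    electrode is the unselected one with the largest posterior standard
    deviation under a GP fitted to the thresholds measured so far (ties
    break toward the lowest electrode id).  Hyperparameters are re-optimized
    each iteration unless ``config.optimize`` is False.
    """
    pool = _eligible(tmap.grid, eligible_ids)
    if not 1 <= n_init <= n_total <= pool.size:
        raise ValueError(
            f"need 1 <= n_init ({n_init}) <= n_total ({n_total}) <= {pool.size}"
        )
    init = uniform_sample(tmap.grid, n_init, seed, eligible_ids=pool)
    selected = list(init.ordered_ids)
    while len(selected) < n_total:
        gp = gpr.fit(tmap, selected, family, config=config, seed=seed)
        remaining = pool[~np.isin(pool, selected)]
        pred = gpr.predict(gp, tmap.grid, remaining)
        # argmax with lowest-id tie-break: ids are ascending, argmax takes first
        best = int(remaining[int(np.argmax(pred.std_transformed))])
        selected.append(best)
    return SamplingPlan(
        "adaptive",
        tuple(int(i) for i in selected),
        n_total,
        seed,
        params={"n_init": n_init, "family": family, "optimize": config.optimize},
    )
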