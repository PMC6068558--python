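"""Parallel subrange PSO over the physiological boxes.

On the full large-scale bound (fr 12-60 bpm, fh 48-180 bpm) a single
swarm needs many more iterations to converge than on the narrow at-rest
box.  The remedy: split each rate range into its at-rest and after-sport
halves, giving four (fr, fh) boxes including the cross combinations
(e.g. resting respiration with an elevated heart rate); the amplitude
ranges are identical in all boxes.  An independent swarm runs in each
box, all are stopped as soon as any one reaches the convergence
threshold (0.2 nominally, 0.3 under body motion), and the box with the
minimum final cost wins — whether or not any box converged, so a budget
exhaustion still yields the best-so-far answer.  A box whose swarm
stalls above the threshold restarts with a fresh independent population
while budget remains; the restarts are what make the scheme robust on
the heavily multimodal large-amplitude landscape.

The boxes advance in lockstep, one generation per round, with the
early-stop check only at the generation barrier; per-box seeds derive
deterministically from the master seed, so the result is independent of
execution order or interleaving.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .estimation import (
    CostEvaluator,
    EstimationResult,
    OptimizerSettings,
    ParameterBounds,
    PSOState,
    _StallMonitor,
)
from .signal_model import IQSignal, PhysioParams, RadarConfig

__all__ = ["SubrangeScheme", "parallel_pso_estimate"]


@dataclass(frozen=True)
class SubrangeScheme:
    """An ordered set of named parameter boxes to search concurrently."""

    boxes: tuple[tuple[str, ParameterBounds], ...]

    def __post_init__(self) -> None:
        if len(self.boxes) == 0:
            raise ValueError("subrange scheme must contain at least one box")

    @classmethod
    def default(cls) -> "SubrangeScheme":
        """The four-box cross product of rest/sport rate ranges.

        fr in {rest [12,30], sport [30,60]} x fh in {rest [48,90],
        sport [90,180]} bpm; mr in [0, 6] mm and mh in [0.05, 1] mm in
        every box.
        """
        fr_ranges = {"fr_rest": (12.0, 30.0), "fr_sport": (30.0, 60.0)}
        fh_ranges = {"fh_rest": (48.0, 90.0), "fh_sport": (90.0, 180.0)}
        boxes = []
        for fr_name, fr_rng in fr_ranges.items():
            for fh_name, fh_rng in fh_ranges.items():
                name = f"{fr_name}+{fh_name}"
                boxes.append(
                    (
                        name,
                        ParameterBounds.from_ranges(
                            (0.0, 6.0), (0.05, 1.0), fr_rng, fh_rng, name
                        ),
                    )
                )
        return cls(boxes=tuple(boxes))

    @classmethod
    def single(cls, bounds: ParameterBounds) -> "SubrangeScheme":
        """Degenerate one-box scheme (equivalent to a plain wide-bound PSO)."""
        return cls(boxes=((bounds.name or "full", bounds),))

    def __len__(self) -> int:
        return len(self.boxes)


def parallel_pso_estimate(
    bmes: IQSignal,
    cfg: RadarConfig = RadarConfig(),
    scheme: Optional[SubrangeScheme] = None,
    settings: Optional[OptimizerSettings] = None,
    domain: str = "time",
) -> EstimationResult:
    """Subrange PSO with synchronous early stop and minimum-cost selection.

    Each box gets its own swarm (``settings.population_size`` particles,
    default 50) seeded with ``settings.seed + box_index``.  The shared
    ``settings.max_evaluations`` budget (default 2e5, the 5-s real-time
    allowance; use 4e5 under body motion) counts cost evaluations summed
    over all boxes.  Stopping: any box's best cost <= ``settings.threshold``
    at a generation barrier, or budget exhaustion — in either case the box
    with the lowest best-so-far cost is returned, annotated with its box
    name and all per-box final costs.
    """
    scheme = scheme or SubrangeScheme.default()
    settings = settings or OptimizerSettings(population_size=50, max_evaluations=200_000)
    swarm = settings.population_size or 50
    n_boxes = len(scheme)
    base_seed = 0 if settings.seed is None else settings.seed
    stall_window = settings.stall_generations or 20

    ev = CostEvaluator(bmes, cfg, domain)
    total_budget = settings.max_evaluations
    # a fresh swarm ramps its inertia over at most this many iterations
    run_iters = max(1, min(total_budget // (n_boxes * swarm), PSOState.W_RAMP_CAP))

    restarts = [0] * n_boxes

    def fresh_state(idx: int) -> PSOState:
        # deterministic per-(box, restart) seed derived from the master seed;
        # restart 0 of box i uses base_seed + i
        seed = base_seed + idx + restarts[idx] * 100_003
        return PSOState(
            ev,
            scheme.boxes[idx][1],
            swarm,
            np.random.default_rng(seed),
            run_iters,
        )

    states = [fresh_state(i) for i in range(n_boxes)]
    # each box owns an equal share of the budget, which makes the outcome
    # exactly independent of box execution order / interleaving
    per_box_budget = total_budget // n_boxes
    box_evals = [s.evaluations for s in states]
    stalls = [_StallMonitor(stall_window, settings.tolerance, s.gbest_cost) for s in states]
    # best-so-far per box across restarts
    box_best = [(s.gbest_cost, s.gbest.copy()) for s in states]

    def any_converged() -> bool:
        return any(c <= settings.threshold for c, _ in box_best)

    active = [True] * n_boxes
    while not any_converged() and any(active):
        for idx, state in enumerate(states):
            if not active[idx]:
                continue
            if box_evals[idx] + swarm > per_box_budget:
                active[idx] = False
                continue
            best = state.step()
            box_evals[idx] += swarm
            stalls[idx].update(best)
            if best < box_best[idx][0]:
                box_best[idx] = (best, state.gbest.copy())
            if best > settings.tolerance and (
                state.iteration >= run_iters or stalls[idx].stalled
            ):
                # stalled without an acceptable solution: independent restart
                if box_evals[idx] + swarm <= per_box_budget:
                    restarts[idx] += 1
                    states[idx] = fresh_state(idx)
                    box_evals[idx] += states[idx].evaluations
                    stalls[idx] = _StallMonitor(
                        stall_window, settings.tolerance, states[idx].gbest_cost
                    )
                    if states[idx].gbest_cost < box_best[idx][0]:
                        box_best[idx] = (states[idx].gbest_cost, states[idx].gbest.copy())
                else:
                    active[idx] = False
        # early-stop decision only at the synchronous generation barrier
    evaluations = sum(box_evals)

    costs = [c for c, _ in box_best]
    winner = int(np.argmin(costs))
    win_cost, win_x = box_best[winner]
    win_name = scheme.boxes[winner][0]
    return EstimationResult(
        params=PhysioParams.from_array(win_x).canonical(),
        final_cost=win_cost,
        method="pso_parallel",
        domain=domain,
        evaluations=evaluations,
        seed=settings.seed,
        subrange=win_name,
        converged=win_cost <= settings.threshold,
        box_costs={name: float(c) for (name, _), c in zip(scheme.boxes, costs)},
    )
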