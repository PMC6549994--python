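"""Spatial allocation of change demand by ranked transition potential.

A single greedy pass over all (pixel, transition) candidates sorted by
descending potential: each transition claims its top-ranked eligible pixels
until its demand is met; a pixel contested by several transitions goes to
the one for which its potential is highest, and the losers continue down
their rankings.  Ties are broken by a seeded, logged permutation of pixel
indices, making the whole allocation deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .drivers import distance_to_class
from .grid import CategoricalRaster
from .markov import ChangeDemand, TransitionProbabilityMatrix, change_demand
from .mlp import PotentialStack, TransitionSubModel, predict_potentials

__all__ = ["AllocationResult", "allocate", "project"]


@dataclass
class AllocationResult:
    """Outcome of one allocation step."""

    projected: CategoricalRaster
    demanded: np.ndarray   # K x K pixels requested (off-diagonal)
    realized: np.ndarray   # K x K pixels actually transitioned
    unmet: np.ndarray      # K x K pixels short
    conflicts: list[dict] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.array_equal(self.realized + self.unmet, self.demanded):
            raise ValueError("realized + unmet != demanded")


def _demand_pixels(demand: ChangeDemand, cell_area: float) -> np.ndarray:
    """Convert hectare demand to whole pixels with round-half-even."""
    return np.rint(demand.D / cell_area).astype(np.int64)


def allocate(current: CategoricalRaster, potentials: PotentialStack,
             demand: ChangeDemand, seed: int = 0) -> AllocationResult:
    """Allocate off-diagonal change demand onto the map by ranked potential."""
    legend = current.legend
    if demand.legend != legend:
        raise ValueError("demand legend differs from map legend")
    k = len(legend)
    cell_area = current.transform.cell_area_ha
    demanded = _demand_pixels(demand, cell_area)
    np.fill_diagonal(demanded, 0)

    transitions: list[tuple[int, int]] = []
    for i in range(k):
        for j in range(k):
            if i != j and demanded[i, j] > 0:
                pair = (legend.codes[i], legend.codes[j])
                if pair not in potentials:
                    raise ValueError(
                        f"demanded transition {legend.names[i]!r} -> "
                        f"{legend.names[j]!r} has no potential raster"
                    )
                transitions.append(pair)

    rng = np.random.default_rng(seed)
    tie_break = rng.permutation(current.values.size)

    cand_pot, cand_pix, cand_trans = [], [], []
    for t_id, (code_i, code_j) in enumerate(transitions):
        pot = potentials[(code_i, code_j)]
        eligible = (current.values == code_i) & current.valid & pot.valid & (pot.values > 0)
        flat = np.flatnonzero(eligible.ravel())
        cand_pot.append(pot.values.ravel()[flat])
        cand_pix.append(flat)
        cand_trans.append(np.full(flat.size, t_id, dtype=np.int64))
    realized = np.zeros((k, k), dtype=np.int64)
    conflicts: list[dict] = []
    out = current.values.copy()
    if transitions:
        pot_all = np.concatenate(cand_pot)
        pix_all = np.concatenate(cand_pix)
        trans_all = np.concatenate(cand_trans)
        order = np.lexsort((trans_all, tie_break[pix_all], -pot_all))
        remaining = {t_id: int(demanded[legend.index(i), legend.index(j)])
                     for t_id, (i, j) in enumerate(transitions)}
        assigned: dict[int, int] = {}
        for idx in order:
            t_id = int(trans_all[idx])
            if remaining[t_id] == 0:
                continue
            pix = int(pix_all[idx])
            if pix in assigned:
                conflicts.append({"pixel": pix, "won_by": transitions[assigned[pix]],
                                  "lost_by": transitions[t_id]})
                continue
            assigned[pix] = t_id
            remaining[t_id] -= 1
            code_i, code_j = transitions[t_id]
            out.ravel()[pix] = code_j
            realized[legend.index(code_i), legend.index(code_j)] += 1
    projected = CategoricalRaster(out, current.nodata, current.transform,
                                  current.crs_tag, legend)
    unmet = demanded - realized
    return AllocationResult(projected, demanded, realized, unmet, conflicts, seed)


def project(current: CategoricalRaster,
            models: Mapping[int, TransitionSubModel],
            static_variables: Mapping[str, object],
            dynamic_variables: Mapping[str, Sequence[int]],
            matrix: TransitionProbabilityMatrix,
            steps: int = 1, seed: int = 0) -> tuple[CategoricalRaster, list[AllocationResult]]:
    """Project the map over the matrix horizon in one or more steps.

    Each step recomputes the dynamic distance variables from the current map,
    predicts potentials with every sub-model, derives per-step demand from
    the per-step matrix (the principal ``steps``-th root of ``matrix``), and
    allocates.  ``steps=1`` reduces exactly to a single allocation of the
    full-horizon demand.
    """
    if steps < 1:
        raise ValueError(f"steps must be >= 1, got {steps}")
    legend = current.legend
    p_step = matrix if steps == 1 else _matrix_root(matrix, steps)
    seeds = np.random.SeedSequence(seed).generate_state(steps)
    results: list[AllocationResult] = []
    state = current
    for step in range(steps):
        variables: dict[str, object] = dict(static_variables)
        for name, target in dynamic_variables.items():
            variables[name] = distance_to_class(state, target)
        stack = PotentialStack({})
        for origin, model in models.items():
            stack = stack.merge(predict_potentials(model, variables, state))
        demand = change_demand(p_step, state.class_areas_ha())
        result = allocate(state, stack, demand, seed=int(seeds[step]))
        results.append(result)
        state = result.projected
    return state, results


def _matrix_root(matrix: TransitionProbabilityMatrix, steps: int) -> TransitionProbabilityMatrix:
    from .markov import _principal_power

    return TransitionProbabilityMatrix(
        _principal_power(matrix.P, 1.0 / steps),
        matrix.horizon_years / steps, matrix.legend)
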