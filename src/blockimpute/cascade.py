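"""Ordered, containment-constrained imputation of design subsets.

Each subset block is imputed in turn; when a target subset is imputed, the
variables of previously imputed subsets may enter as predictors *only if*
those subsets cover every participant of the target (the admissibility
rule). This prevents conditioning a block on values that were never
acquired — and would otherwise have to be fabricated — for part of its
population.

The order itself is optimised. The default objective scores a plan by the
number of conditioning variables available to each target, weighted by the
target's block size (n x p): more usable side information earlier means
more imputation power. Because that objective decomposes over ordered
pairs of subsets, an exact exhaustive search over all orderings reduces to
dynamic programming over the 2^S lattice of already-imputed subset sets
(32,768 states for 15 subsets instead of 15! permutations). Many orders can
tie at the optimum; ties are broken by preferring, at each step, the target
with the largest immediate conditioning gain, then the smallest subset id.

A cross-validated alternative objective (``cv_error``) scores complete
orders by the leave-one-out error of the executed cascade; it is exact but
expensive, so it brute-forces permutations and is guarded to small designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .cohort import ClinicalMatrix, Subset, SubsetDesign, subset_view, write_back
from .exceptions import ConfigError, ContainmentError, DesignError
from .imputer import ImputedMatrix, ImputerConfig, impute

DEFAULT_EXCLUSIONS = ("diagnosis",)


@dataclass(frozen=True)
class CascadeStep:
    target: int
    conditioners: tuple  # subset ids, already imputed and admissible


@dataclass
class CascadePlan:
    """An ordered imputation plan over the design's subsets."""

    steps: list  # of CascadeStep
    score: float = 0.0

    @property
    def order(self):
        return [s.target for s in self.steps]

    def validate(self, design: SubsetDesign) -> None:
        """Each subset exactly once; conditioners precede their target and
        cover its participants."""
        ids = [s.subset_id for s in design.subsets]
        if sorted(self.order) != sorted(ids):
            raise DesignError("plan does not visit each subset exactly once")
        done = set()
        for step in self.steps:
            target = design.subset(step.target)
            for c in step.conditioners:
                if c not in done:
                    raise DesignError(
                        f"conditioner {c} not yet imputed at step for {step.target}"
                    )
                if not target.participants <= design.subset(c).participants:
                    raise ContainmentError(
                        f"subset {c} does not cover subset {step.target}"
                    )
            done.add(step.target)

    def to_dict(self):
        return {
            "score": self.score,
            "steps": [
                {
                    "order": i + 1,
                    "input": s.target,
                    "output": f"{s.target}*",
                    "conditioned_to": list(s.conditioners),
                }
                for i, s in enumerate(self.steps)
            ],
        }


def admissible_conditioners(target_id, candidate_ids, design: SubsetDesign):
    """Exactly the candidates whose participant set contains the target's."""
    target = design.subset(target_id)
    return {
        c
        for c in candidate_ids
        if c != target_id
        and target.participants <= design.subset(c).participants
    }


def _pair_tables(design: SubsetDesign):
    ids = sorted(s.subset_id for s in design.subsets)
    parts = {s.subset_id: s.participants for s in design.subsets}
    nvars = {s.subset_id: len(s.variables) for s in design.subsets}
    weight = {
        s.subset_id: len(s.participants) * len(s.variables)
        for s in design.subsets
    }
    admissible = {
        t: [c for c in ids if c != t and parts[t] <= parts[c]] for t in ids
    }
    return ids, nvars, weight, admissible


def search_cascade_plan(
    design: SubsetDesign,
    objective: str = "conditioning_variables",
    matrix: ClinicalMatrix | None = None,
    imputer_config: ImputerConfig | None = None,
    max_bruteforce_subsets: int = 7,
) -> CascadePlan:
    """Find the ordering of subsets maximizing the objective, exhaustively.

    ``conditioning_variables`` runs the exact DP over imputed-subset sets;
    ``cv_error`` scores every permutation by executed-cascade leave-one-out
    error (requires ``matrix`` and ``imputer_config``; guarded to
    ``max_bruteforce_subsets``)."""
    if objective == "conditioning_variables":
        return _search_dp(design)
    if objective == "cv_error":
        if matrix is None or imputer_config is None:
            raise ConfigError(
                "cv_error objective needs a matrix and an imputer config"
            )
        return _search_cv(design, matrix, imputer_config, max_bruteforce_subsets)
    raise ConfigError(f"unknown objective {objective!r}")


def _search_dp(design: SubsetDesign) -> CascadePlan:
    ids, nvars, weight, admissible = _pair_tables(design)
    S = len(ids)
    pos = {sid: k for k, sid in enumerate(ids)}
    full = (1 << S) - 1

    def gain(t, state):
        g = sum(nvars[c] for c in admissible[t] if state >> pos[c] & 1)
        return g * weight[t]

    # f[state] = best total gain for imputing the remaining subsets
    f = np.full(1 << S, -1.0)
    f[full] = 0.0

    # iterate states by decreasing popcount so successors are ready
    states = sorted(range(1 << S), key=lambda s: -bin(s).count("1"))
    for state in states:
        if state == full:
            continue
        best = -1.0
        for t in ids:
            if state >> pos[t] & 1:
                continue
            val = gain(t, state) + f[state | (1 << pos[t])]
            if val > best:
                best = val
        f[state] = best

    # reconstruct: stay on optimal paths; among ties prefer the largest
    # immediate gain, then the smallest subset id
    steps = []
    state = 0
    while state != full:
        candidates = []
        for t in ids:
            if state >> pos[t] & 1:
                continue
            g = gain(t, state)
            if np.isclose(g + f[state | (1 << pos[t])], f[state]):
                candidates.append((-g, t))
        candidates.sort()
        _, chosen = candidates[0]
        done = {ids[k] for k in range(S) if state >> k & 1}
        conds = tuple(sorted(admissible_conditioners(chosen, done, design)))
        steps.append(CascadeStep(target=chosen, conditioners=conds))
        state |= 1 << pos[chosen]
    return CascadePlan(steps=steps, score=float(f[0]))


def score_order(order, design: SubsetDesign) -> float:
    """Score a complete ordering under the conditioning_variables objective
    (used by tests as a brute-force cross-check of the DP)."""
    _, nvars, weight, admissible = _pair_tables(design)
    total = 0.0
    done: set = set()
    for t in order:
        avail = [c for c in admissible[t] if c in done]
        total += weight[t] * sum(nvars[c] for c in avail)
        done.add(t)
    return total


def plan_from_order(order, design: SubsetDesign) -> CascadePlan:
    steps = []
    done: set = set()
    for t in order:
        conds = tuple(sorted(admissible_conditioners(t, done, design)))
        steps.append(CascadeStep(target=t, conditioners=conds))
        done.add(t)
    return CascadePlan(steps=steps, score=score_order(order, design))


def _search_cv(design, matrix, imputer_config, max_subsets) -> CascadePlan:
    from .evaluation import loo_cv_errors  # local import; avoids cycle

    ids = sorted(s.subset_id for s in design.subsets)
    if len(ids) > max_subsets:
        raise ConfigError(
            f"cv_error objective brute-forces permutations; {len(ids)} subsets "
            f"exceed the limit of {max_subsets}"
        )
    best_plan, best_err = None, np.inf
    for order in permutations(ids):
        plan = plan_from_order(list(order), design)
        errors = loo_cv_errors(
            matrix,
            imputer_config,
            design=design,
            plan=plan,
            mode="fast",
            max_cells_per_variable=3,
            seed=imputer_config.seed,
        )
        err = float(errors["re"][~errors["undefined"]].mean())
        if err < best_err or (
            np.isclose(err, best_err) and plan.order < best_plan.order
        ):
            best_plan, best_err = plan, err
    best_plan.score = -best_err
    return best_plan


def execute_cascade(
    matrix: ClinicalMatrix,
    design: SubsetDesign,
    plan: CascadePlan,
    imputer_config: ImputerConfig,
    exclusions=DEFAULT_EXCLUSIONS,
) -> ImputedMatrix:
    """Run the plan: per step, build the target block plus its admissible
    conditioning columns, impute it, and write back only the target block's
    missing cells.

    Excluded variables (by default the diagnosis label, which must not leak
    into the imputation) never appear in any view. Structurally absent
    cells are never assigned. Observed cells pass through untouched."""
    plan.validate(design)
    design.validate(matrix)
    exclusions = set(exclusions)
    working = matrix.copy()
    original_mask = matrix.missing_mask
    rounds = 0
    converged = True
    trace = []
    for k, step in enumerate(plan.steps):
        cond_vars = []
        for c in step.conditioners:
            cond_vars.extend(
                v for v in design.subset(c).variables if v not in exclusions
            )
        target = design.subset(step.target)
        own = [v for v in target.variables if v not in exclusions]
        view = subset_view(working, design, step.target, cond_vars)
        if exclusions:
            keep = [v for v in view.variable_names if v not in exclusions]
            view = ClinicalMatrix(
                view.values[keep],
                [view.spec(v) for v in keep],
                view.structural[keep],
            )
        if view.m == 0:
            continue
        step_cfg = imputer_config
        if imputer_config.seed is not None:
            step_cfg = imputer_config.with_seed(imputer_config.seed + k)
        result = impute(view, step_cfg)
        # write back only the target subset's own (non-excluded) columns
        write_back(
            working,
            SubsetDesign(
                subsets=[
                    Subset(
                        subset_id=target.subset_id,
                        participants=target.participants,
                        variables=tuple(own),
                        group_label=target.group_label,
                    )
                ],
                groups=design.groups,
            ),
            step.target,
            result.values,
        )
        rounds = max(rounds, result.rounds)
        converged = converged and result.converged
        trace.append(
            {"subset_id": step.target, "rounds": result.rounds,
             "converged": result.converged, "trace": result.trace}
        )
    return ImputedMatrix(
        values=working.values,
        mask=original_mask,
        rounds=rounds,
        converged=converged,
        trace=trace,
    )
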