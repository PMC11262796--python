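"""Linear-programming services on the steady-state flux polytope.

Every operation here works on ``{v : S v = 0, lb <= v <= ub}`` using
``scipy.optimize.linprog`` (HiGHS):

* :func:`maximize_flux` — the theoretical maximum of one reaction (FBA with
  that reaction as objective), the base quantity for fractional constraints.
* :func:`flux_variability` — per-reaction (min, max) feasible flux (FVA).
* :func:`check_capacity` — can every protected function (witnessed by a named
  reaction) still carry flux?  Used as the guard during model pruning.
* :func:`interior_point` — a Chebyshev-style strictly interior point used to
  initialise the uniform sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, stoichiometric_matrix

__all__ = [
    "LPResult",
    "InteriorPoint",
    "LPError",
    "CapacitySpec",
    "maximize_flux",
    "flux_variability",
    "check_capacity",
    "interior_point",
]

#: default threshold for "carries flux": far above LP tolerance (~1e-9),
#: far below any physiological flux on the +-1000 bound scale
CAPACITY_EPSILON = 1e-6


class LPError(RuntimeError):
    pass


@dataclass
class LPResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: Optional[float] = None
    flux_vector: Optional[np.ndarray] = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class InteriorPoint:
    flux_vector: np.ndarray
    margin: float
    degenerate: bool
    pinned: List[int] = field(default_factory=list)


@dataclass
class CapacitySpec:
    """Witness reactions for protected metabolic functions.

    Each entry maps a function name (e.g. ``"atp_production"``) to the
    reaction id whose nonzero feasible flux witnesses that the function is
    still available in the network.
    """

    witnesses: Dict[str, str]
    epsilon: float = CAPACITY_EPSILON

    def validate(self, model: MetabolicModel) -> None:
        rids = set(model.reaction_ids)
        unknown = {f: r for f, r in self.witnesses.items() if r not in rids}
        if unknown:
            raise KeyError(
                f"capacity witnesses not in model: {unknown} "
                f"(configure protected_reactions to match the model)"
            )


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _solve(S, c, bounds) -> LPResult:
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return LPResult(status=status)
    return LPResult(status="optimal", objective_value=-res.fun, flux_vector=res.x)


def maximize_flux(model: MetabolicModel, reaction_id: str) -> LPResult:
    """Maximum steady-state flux through one reaction (its FBA optimum)."""
    rids = model.reaction_ids
    if reaction_id not in rids:
        raise KeyError(f"no reaction {reaction_id!r} in model")
    S = stoichiometric_matrix(model)
    c = np.zeros(len(rids))
    c[rids.index(reaction_id)] = -1.0  # linprog minimises
    bounds = [(r.lb, r.ub) for r in model.reactions]
    return _solve(S, c, bounds)


def flux_variability(
    model: MetabolicModel, reaction_ids: Optional[Sequence[str]] = None
) -> Dict[str, Tuple[float, float]]:
    """Feasible (min, max) flux per reaction under the model's constraints."""
    rids = model.reaction_ids
    if reaction_ids is None:
        reaction_ids = rids
    unknown = set(reaction_ids) - set(rids)
    if unknown:
        raise KeyError(f"no reactions {sorted(unknown)} in model")
    S = stoichiometric_matrix(model)
    bounds = [(r.lb, r.ub) for r in model.reactions]
    out: Dict[str, Tuple[float, float]] = {}
    for rid in reaction_ids:
        j = rids.index(rid)
        c = np.zeros(len(rids))
        c[j] = -1.0
        hi = _solve(S, c, bounds)
        c[j] = 1.0
        lo = _solve(S, c, bounds)
        if not (hi.optimal and lo.optimal):
            raise LPError(
                f"FVA failed for {rid!r}: max {hi.status}, min {lo.status}"
            )
        out[rid] = (-lo.objective_value, hi.objective_value)
    return out


def check_capacity(model: MetabolicModel, spec: CapacitySpec) -> bool:
    """True iff every protected-function witness can carry flux >= epsilon."""
    spec.validate(model)
    for rid in spec.witnesses.values():
        res = maximize_flux(model, rid)
        if not res.optimal or res.objective_value < spec.epsilon:
            return False
    return True


def interior_point(
    model: MetabolicModel, pinned_extra: Optional[Iterable[int]] = None
) -> InteriorPoint:
    """A strictly feasible flux vector with maximal box margin.

    Solves ``max delta  s.t.  S v = 0,  lb_j + delta <= v_j <= ub_j - delta``
    over the non-pinned coordinates (pinned: lb == ub, plus any indices in
    ``pinned_extra``, e.g. coordinates FVA shows to be forced by
    conservation).  ``margin`` is the achieved delta; ``degenerate`` flags a
    zero-volume polytope in which some free coordinate must sit on its bound.
    """
    S = stoichiometric_matrix(model)
    m, r = S.shape
    lb = np.array([rx.lb for rx in model.reactions])
    ub = np.array([rx.ub for rx in model.reactions])
    pinned = {j for j in range(r) if ub[j] - lb[j] <= 1e-12}
    if pinned_extra is not None:
        pinned |= set(pinned_extra)
    pinned = sorted(pinned)

    # variables: v (r) then delta
    c = np.zeros(r + 1)
    c[-1] = -1.0
    A_eq = np.hstack([S, np.zeros((m, 1))])
    b_eq = np.zeros(m)
    A_ub_rows, b_ub = [], []
    for j in range(r):
        if j in pinned:
            continue
        row = np.zeros(r + 1)
        row[j], row[-1] = -1.0, 1.0  # lb_j + delta <= v_j
        A_ub_rows.append(row)
        b_ub.append(-lb[j])
        row = np.zeros(r + 1)
        row[j], row[-1] = 1.0, 1.0  # v_j + delta <= ub_j
        A_ub_rows.append(row)
        b_ub.append(ub[j])
    bounds = [(lb[j], ub[j]) for j in range(r)] + [(0.0, None)]
    if not A_ub_rows:  # every coordinate pinned
        res = linprog(
            np.zeros(r), A_eq=S, b_eq=np.zeros(m),
            bounds=[(lb[j], ub[j]) for j in range(r)], method="highs",
        )
        if res.status != 0:
            raise LPError("model is infeasible; no interior point exists")
        return InteriorPoint(res.x, 0.0, True, pinned)
    res = linprog(
        c,
        A_ub=np.array(A_ub_rows),
        b_ub=np.array(b_ub),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        raise LPError("model is infeasible; no interior point exists")
    delta = float(res.x[-1])
    return InteriorPoint(
        flux_vector=res.x[:r],
        margin=delta,
        degenerate=delta <= 1e-9,
        pinned=pinned,
    )
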