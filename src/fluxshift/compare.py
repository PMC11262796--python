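"""Comparative constraint construction and per-reaction flux-shift detection.

The comparison encodes two hypothesised physiological asymmetries between a
model pair (A = bat-fibroblast-like, B = human-fibroblast-like):

* A has *greater Complex I activity*: the Complex I lower bound in A is set
  to ``f_hi`` (default 70%) of its theoretical maximum, while in B the upper
  bound is set to ``f_lo`` (default 30%) of its own maximum.
* B has *greater mitochondrial oxygen intake*: mirrored on the O2 transport
  reaction — lower bound in B at ``f_hi`` of max, upper bound in A at
  ``f_lo`` of max — with an explicit check that B's O2 lower bound strictly
  exceeds A's O2 upper bound.

After uniform sampling of both constrained polytopes,
:func:`compare_distributions` flags reactions whose flux distributions have
separated (low histogram overlap and a large median shift relative to the
pooled IQR), and :func:`flag_reversed_reactions` extracts those that flipped
to negative flux in A — the readout that identifies reversed succinate
dehydrogenase (Complex II) operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .lp import maximize_flux
from .model import MetabolicModel
from .sampling import FluxSamples

__all__ = [
    "ConstraintError",
    "ReactionShift",
    "ReactionShiftReport",
    "apply_fraction_bound",
    "build_constrained_pair",
    "compare_distributions",
    "flag_reversed_reactions",
    "sensitivity_sweep",
]

DEFAULT_OVERLAP_THRESHOLD = 0.2
DEFAULT_SHIFT_THRESHOLD = 1.0
N_OVERLAP_BINS = 50


class ConstraintError(ValueError):
    pass


@dataclass
class ReactionShift:
    reaction_id: str
    median_a: float
    median_b: float
    iqr_a: float
    iqr_b: float
    overlap: float
    sign_flip: bool
    shifted: bool


@dataclass
class ReactionShiftReport:
    shifts: List[ReactionShift]
    overlap_threshold: float
    shift_threshold: float

    def __getitem__(self, reaction_id: str) -> ReactionShift:
        for s in self.shifts:
            if s.reaction_id == reaction_id:
                return s
        raise KeyError(reaction_id)

    def shifted_reactions(self) -> List[str]:
        return [s.reaction_id for s in self.shifts if s.shifted]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    s.reaction_id,
                    s.median_a,
                    s.median_b,
                    s.iqr_a,
                    s.iqr_b,
                    s.overlap,
                    s.sign_flip,
                    s.shifted,
                )
                for s in self.shifts
            ],
            columns=[
                "reaction_id",
                "median_a",
                "median_b",
                "iqr_a",
                "iqr_b",
                "overlap",
                "sign_flip",
                "shifted",
            ],
        )


def apply_fraction_bound(
    model: MetabolicModel,
    reaction_id: str,
    kind: str,
    fraction: float,
    theoretical_max: Optional[float] = None,
) -> MetabolicModel:
    """Set a bound to ``fraction`` of the reaction's theoretical maximum.

    ``kind="lower"`` raises the lower bound (forcing high activity),
    ``kind="upper"`` lowers the upper bound (capping activity); the opposite
    bound is untouched.  The theoretical maximum M is the FBA optimum of the
    reaction, computed here unless a precomputed ``theoretical_max`` is
    given (pass one when M must refer to the model *before* other
    constraints were applied).  M is recorded in the returned model's
    provenance.  Errors if M <= 0 (a fractional bound is then undefined), if
    the new bound conflicts with the opposite bound, or if it makes the
    model infeasible.
    """
    if kind not in ("lower", "upper"):
        raise ValueError(f"kind must be 'lower' or 'upper', got {kind!r}")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if theoretical_max is None:
        res = maximize_flux(model, reaction_id)
        if not res.optimal:
            raise ConstraintError(
                f"cannot compute theoretical maximum of {reaction_id!r}: "
                f"LP status {res.status}"
            )
        M = res.objective_value
    else:
        M = theoretical_max
    if M <= 0:
        raise ConstraintError(
            f"theoretical maximum of {reaction_id!r} is {M:g} <= 0; "
            "a fractional bound is undefined"
        )
    new = model.copy()
    rx = new.get_reaction(reaction_id)
    bound = fraction * M
    if kind == "lower":
        if bound > rx.ub:
            raise ConstraintError(
                f"{reaction_id!r}: new lower bound {bound:g} exceeds upper "
                f"bound {rx.ub:g}"
            )
        rx.lb = bound
    else:
        if bound < rx.lb:
            raise ConstraintError(
                f"{reaction_id!r}: new upper bound {bound:g} is below lower "
                f"bound {rx.lb:g}"
            )
        rx.ub = bound
    check = maximize_flux(new, reaction_id)
    if not check.optimal:
        raise ConstraintError(
            f"setting {kind} bound of {reaction_id!r} to {bound:g} "
            f"({fraction:.0%} of max {M:g}) makes the model infeasible"
        )
    new.log(
        f"apply_fraction_bound: {reaction_id} {kind} := {fraction:g} * "
        f"max {M:.10g} = {bound:.10g}"
    )
    return new


def build_constrained_pair(
    model_a: MetabolicModel,
    model_b: MetabolicModel,
    ci_id: str = "CI_MitoCore",
    o2_id: str = "O2tm",
    f_hi: float = 0.7,
    f_lo: float = 0.3,
) -> Tuple[MetabolicModel, MetabolicModel]:
    """Constrain a model pair so A favours Complex I and B favours O2 uptake.

    A gets ``ci lb = f_hi * max_A(ci)`` and ``o2 ub = f_lo * max_A(o2)``;
    B gets ``ci ub = f_lo * max_B(ci)`` and ``o2 lb = f_hi * max_B(o2)``.
    All four theoretical maxima are computed on the *unconstrained* input
    models before any bound is set.  Raises :class:`ConstraintError` unless
    B's O2 lower bound strictly exceeds A's O2 upper bound (the intended
    ordering of oxygen intake), or if either constrained model is
    infeasible.
    """
    maxima = {}
    for label, model in (("A", model_a), ("B", model_b)):
        for rid in (ci_id, o2_id):
            res = maximize_flux(model, rid)
            if not res.optimal or res.objective_value <= 0:
                raise ConstraintError(
                    f"theoretical maximum of {rid!r} in model {label} is not "
                    f"a positive optimum (status {res.status}); fractional "
                    "bounds are undefined"
                )
            maxima[(label, rid)] = res.objective_value

    def constrain(model, label, ci_bound, o2_bound):
        new = model.copy()
        (ci_kind, ci_frac), (o2_kind, o2_frac) = ci_bound, o2_bound
        for rid, kind, frac in ((ci_id, ci_kind, ci_frac),
                                (o2_id, o2_kind, o2_frac)):
            M = maxima[(label, rid)]
            rx = new.get_reaction(rid)
            value = frac * M
            if kind == "lower":
                rx.lb = value
            else:
                rx.ub = value
            if rx.lb > rx.ub:
                raise ConstraintError(
                    f"model {label}: {rid!r} bounds conflict after setting "
                    f"{kind} to {value:g} ({frac:.0%} of max {M:g})"
                )
            new.log(
                f"build_constrained_pair: {label} {rid} {kind} := "
                f"{frac:g} * max {M:.10g} = {value:.10g}"
            )
        feas = maximize_flux(new, ci_id)
        if not feas.optimal:
            raise ConstraintError(
                f"model {label} infeasible under fractional bounds "
                f"(f_hi={f_hi}, f_lo={f_lo})"
            )
        return new

    a = constrain(model_a, "A", ("lower", f_hi), ("upper", f_lo))
    b = constrain(model_b, "B", ("upper", f_lo), ("lower", f_hi))
    o2_ub_a = a.get_reaction(o2_id).ub
    o2_lb_b = b.get_reaction(o2_id).lb
    if not o2_lb_b > o2_ub_a:
        raise ConstraintError(
            f"O2 ordering violated: lower bound in B ({o2_lb_b:g}) must "
            f"strictly exceed upper bound in A ({o2_ub_a:g}); "
            f"check f_hi/f_lo ({f_hi}/{f_lo}) and the models' O2 maxima"
        )
    return a, b


def _overlap_coefficient(a: np.ndarray, b: np.ndarray, n_bins: int) -> float:
    """Histogram intersection over shared bins spanning the pooled
    1st-99th percentile range (robust to single outlier draws)."""
    pooled = np.concatenate([a, b])
    lo, hi = np.percentile(pooled, [1, 99])
    if hi - lo <= 1e-12:
        # both effectively constant at the same value
        return 1.0 if abs(np.median(a) - np.median(b)) <= 1e-12 else 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    fa, _ = np.histogram(np.clip(a, lo, hi), bins=edges)
    fb, _ = np.histogram(np.clip(b, lo, hi), bins=edges)
    pa = fa / fa.sum()
    pb = fb / fb.sum()
    return float(np.minimum(pa, pb).sum())


def compare_distributions(
    samples_a: FluxSamples,
    samples_b: FluxSamples,
    shift_threshold: float = DEFAULT_SHIFT_THRESHOLD,
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> ReactionShiftReport:
    """Per-reaction comparison of two flux-sample sets.

    A reaction is *shifted* when its histogram overlap falls below
    ``overlap_threshold`` and the absolute median difference exceeds
    ``shift_threshold`` times the pooled IQR; *sign_flip* marks medians of
    strictly opposite sign.
    """
    shared = [r for r in samples_a.reaction_ids if r in set(samples_b.reaction_ids)]
    if not shared:
        raise ValueError("sample sets share no reactions")
    shifts = []
    for rid in shared:
        a = samples_a.column(rid)
        b = samples_b.column(rid)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        q1a, q3a = np.percentile(a, [25, 75])
        q1b, q3b = np.percentile(b, [25, 75])
        pooled_q1, pooled_q3 = np.percentile(np.concatenate([a, b]), [25, 75])
        pooled_iqr = pooled_q3 - pooled_q1
        overlap = _overlap_coefficient(a, b, N_OVERLAP_BINS)
        shifted = (overlap < overlap_threshold) and (
            abs(med_a - med_b) > shift_threshold * pooled_iqr
        )
        shifts.append(
            ReactionShift(
                reaction_id=rid,
                median_a=med_a,
                median_b=med_b,
                iqr_a=float(q3a - q1a),
                iqr_b=float(q3b - q1b),
                overlap=overlap,
                sign_flip=med_a * med_b < 0,
                shifted=shifted,
            )
        )
    return ReactionShiftReport(
        shifts=shifts,
        overlap_threshold=overlap_threshold,
        shift_threshold=shift_threshold,
    )


def flag_reversed_reactions(report: ReactionShiftReport) -> List[str]:
    """Shifted reactions whose flux went negative in model A while staying
    non-negative in model B, sorted by |median shift| descending."""
    hits = [
        s
        for s in report.shifts
        if s.shifted and s.median_a < 0 <= s.median_b
    ]
    hits.sort(key=lambda s: abs(s.median_a - s.median_b), reverse=True)
    return [s.reaction_id for s in hits]


def sensitivity_sweep(
    model_a: MetabolicModel,
    model_b: MetabolicModel,
    sampler,
    ci_id: str,
    o2_id: str,
    f_hi_values: Tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9),
    f_lo_values: Tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5),
) -> pd.DataFrame:
    """Sweep the constraint fractions and record which reactions reverse.

    ``sampler`` is a callable ``model -> FluxSamples`` so callers control
    sample size and seeding.  Grid cells whose constraints are infeasible
    (or violate the O2 ordering) are recorded with ``feasible = False``.
    """
    rows = []
    for f_hi in f_hi_values:
        for f_lo in f_lo_values:
            try:
                a, b = build_constrained_pair(
                    model_a, model_b, ci_id, o2_id, f_hi, f_lo
                )
            except ConstraintError as exc:
                rows.append((f_hi, f_lo, False, "", str(exc)))
                continue
            report = compare_distributions(sampler(a), sampler(b))
            reversed_ids = flag_reversed_reactions(report)
            rows.append((f_hi, f_lo, True, ";".join(reversed_ids), ""))
    return pd.DataFrame(
        rows, columns=["f_hi", "f_lo", "feasible", "reversed_reactions", "note"]
    )
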