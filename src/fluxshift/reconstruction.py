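"""Context-specific reconstruction: omics presence calls and model pruning.

A gene is called *absent* on a platform when its signal falls below a
platform cutoff in a majority of replicates — below 5 counts in 2 of 3
samples for transcripts, below 2000 abundance units in 2 of 3 samples for
proteins; for other replicate counts the 2-of-3 rule generalises to
ceil((n+1)/2)-of-n.  Calls from the two platforms are merged conservatively:
a gene is absent only if absent on every platform where it was measured,
present if present anywhere.

Pruning then removes, in deterministic lexicographic order, each reaction
whose GPR evaluates inactive under the merged calls — but only if the
reduced model retains flux-carrying capacity for the protected functions
(ATP production, TCA cycle, glycolysis by default).  Reactions whose removal
would break a protected function are retained and logged as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .lp import CapacitySpec, check_capacity
from .model import INACTIVE, MetabolicModel, evaluate_gpr

__all__ = [
    "PresenceCallSet",
    "PruneLog",
    "PruneEntry",
    "call_presence",
    "merge_presence",
    "prune_model",
]

PRESENT = "present"
ABSENT = "absent"
UNMEASURED = "unmeasured"

DEFAULT_CUTOFFS = {"transcript": 5.0, "protein": 2000.0}


@dataclass
class PresenceCallSet:
    calls: Dict[str, str]
    thresholds: Dict[str, object] = field(default_factory=dict)
    provenance: List[str] = field(default_factory=list)

    def __getitem__(self, gene: str) -> str:
        return self.calls.get(gene, UNMEASURED)

    def genes_with(self, status: str) -> List[str]:
        return sorted(g for g, s in self.calls.items() if s == status)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.calls), "call": list(self.calls.values())}
        ).sort_values("gene", ignore_index=True)


@dataclass
class PruneEntry:
    reaction_id: str
    action: str  # removed | retained_capacity | retained_active
    reason: str


@dataclass
class PruneLog:
    entries: List[PruneEntry] = field(default_factory=list)

    def removed(self) -> List[str]:
        return [e.reaction_id for e in self.entries if e.action == "removed"]

    def with_action(self, action: str) -> List[str]:
        return [e.reaction_id for e in self.entries if e.action == action]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.reaction_id, e.action, e.reason) for e in self.entries],
            columns=["reaction_id", "action", "reason"],
        )


def majority_rule(n_samples: int) -> int:
    """Generalisation of the 2-of-3 rule: ceil((n+1)/2) of n replicates."""
    return math.ceil((n_samples + 1) / 2)


def call_presence(
    expression: pd.DataFrame,
    platform: str,
    cutoff: Optional[float] = None,
    min_below: Optional[int] = None,
) -> PresenceCallSet:
    """Threshold a genes x samples table into present/absent calls.

    A gene is absent iff its value is below ``cutoff`` in at least
    ``min_below`` samples (default: majority of replicates), present
    otherwise.  Genes not in the table are implicitly unmeasured.
    """
    if platform not in DEFAULT_CUTOFFS:
        raise ValueError(
            f"platform must be one of {sorted(DEFAULT_CUTOFFS)}, got {platform!r}"
        )
    if expression.shape[1] < 2:
        raise ValueError("need at least 2 samples for presence calling")
    if (expression.to_numpy() < 0).any():
        bad = expression.index[(expression < 0).any(axis=1)].tolist()
        raise ValueError(f"negative expression values for genes: {bad}")
    if cutoff is None:
        cutoff = DEFAULT_CUTOFFS[platform]
    n = expression.shape[1]
    k = min_below if min_below is not None else majority_rule(n)
    below = (expression < cutoff).sum(axis=1)
    calls = {
        str(gene): (ABSENT if count >= k else PRESENT)
        for gene, count in below.items()
    }
    return PresenceCallSet(
        calls=calls,
        thresholds={
            "platform": platform,
            "cutoff": cutoff,
            "min_samples_below": k,
            "n_samples": n,
        },
        provenance=[
            f"call_presence: {platform}, cutoff {cutoff}, "
            f"absent if < cutoff in >= {k} of {n} samples"
        ],
    )


def merge_presence(
    transcript_calls: PresenceCallSet, protein_calls: PresenceCallSet
) -> PresenceCallSet:
    """Combine per-platform calls: present anywhere wins; absent requires
    absence on every platform where the gene was measured."""
    genes = set(transcript_calls.calls) | set(protein_calls.calls)
    merged: Dict[str, str] = {}
    for g in genes:
        states = [transcript_calls[g], protein_calls[g]]
        if PRESENT in states:
            merged[g] = PRESENT
        elif ABSENT in states:
            merged[g] = ABSENT
        else:
            merged[g] = UNMEASURED
    return PresenceCallSet(
        calls=merged,
        thresholds={
            "transcript": transcript_calls.thresholds,
            "protein": protein_calls.thresholds,
        },
        provenance=(
            transcript_calls.provenance
            + protein_calls.provenance
            + ["merge_presence: present-anywhere / absent-everywhere-measured"]
        ),
    )


def prune_model(
    model: MetabolicModel,
    calls: PresenceCallSet,
    capacity: CapacitySpec,
) -> Tuple[MetabolicModel, PruneLog]:
    """Remove reactions inactivated by absent genes, guarding capacity.

    Candidates (GPR evaluates inactive; unknown counts as active) are visited
    in lexicographic id order; each is removed only if the protected-function
    witnesses still carry flux afterwards.  The log records one entry per
    base-model reaction.  Deterministic given (model, calls, capacity).
    """
    if not check_capacity(model, capacity):
        raise ValueError(
            "base model fails the protected-function capacity check; "
            "refusing to prune"
        )
    status = {r.id: evaluate_gpr(r.gpr, calls.calls) for r in model.reactions}
    candidates = sorted(rid for rid, s in status.items() if s == INACTIVE)
    keep = set(model.reaction_ids)
    log = PruneLog()
    for rid in candidates:
        trial = model.subset(keep - {rid})
        if check_capacity(trial, capacity):
            keep.discard(rid)
            log.entries.append(
                PruneEntry(rid, "removed", "GPR inactive; capacity preserved")
            )
        else:
            log.entries.append(
                PruneEntry(
                    rid,
                    "retained_capacity",
                    "GPR inactive but removal breaks a protected function",
                )
            )
    for rid in model.reaction_ids:
        if rid not in {e.reaction_id for e in log.entries}:
            log.entries.append(
                PruneEntry(rid, "retained_active", f"GPR {status[rid]}")
            )
    context = model.subset(keep)
    context.log(
        f"prune_model: removed {len(log.removed())} of "
        f"{len(model.reactions)} reactions"
    )
    return context, log


def order_sensitive_reactions(
    model: MetabolicModel,
    calls: PresenceCallSet,
    capacity: CapacitySpec,
) -> List[str]:
    """Diagnostic: reactions whose prune outcome differs when candidates are
    visited in reverse lexicographic order.  Empty when deletions do not
    interact through the capacity guard."""
    _, forward = prune_model(model, calls, capacity)

    if not check_capacity(model, capacity):  # pragma: no cover - guarded above
        raise ValueError("base model fails capacity")
    status = {r.id: evaluate_gpr(r.gpr, calls.calls) for r in model.reactions}
    candidates = sorted(
        (rid for rid, s in status.items() if s == INACTIVE), reverse=True
    )
    keep = set(model.reaction_ids)
    removed_rev = set()
    for rid in candidates:
        trial = model.subset(keep - {rid})
        if check_capacity(trial, capacity):
            keep.discard(rid)
            removed_rev.add(rid)
    return sorted(set(forward.removed()) ^ removed_rev)
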