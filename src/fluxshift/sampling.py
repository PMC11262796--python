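"""Uniform sampling of the steady-state flux polytope by hit-and-run MCMC.

The polytope ``P = {v : S v = 0, lb <= v <= ub}`` is parameterised on the
null space of S: after pinning coordinates that FVA shows to be fixed, a
basis N of the remaining null space gives ``v = v0 + N x`` with ``v0`` a
strictly interior point (Chebyshev-style, from :func:`fluxshift.lp.interior_point`).
Hit-and-run then walks in x: pick a random direction, intersect the line
with the box constraints to get a chord, jump to a uniform point on it.
With any symmetric, non-degenerate direction distribution the uniform law on
P is stationary; to mix well on elongated polytopes the direction
distribution is isotropised by an ellipsoidal rounding transform estimated
from the covariance of a pilot run.

Randomness comes from a counter-based Philox generator so a single integer
seed makes the output bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .lp import LPError, flux_variability, interior_point
from .model import MetabolicModel, stoichiometric_matrix

__all__ = [
    "FluxSamples",
    "sample_fluxes",
    "convergence_diagnostics",
    "flux_histogram",
    "write_samples",
    "read_samples",
]

#: tolerance used both by the emitted-sample invariant checks and by the
#: FVA-based detection of pinned (zero-width) coordinates
FEASIBILITY_TOL = 1e-6
_PIN_TOL = 1e-9


@dataclass
class FluxSamples:
    """Draws from one polytope: matrix (n_samples x n_reactions) plus the
    chain bookkeeping needed for diagnostics and provenance."""

    matrix: np.ndarray
    reaction_ids: List[str]
    seed: int
    chain_index: np.ndarray  # which chain produced each row
    warmup: int
    thinning: int
    n_chains: int

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def column(self, reaction_id: str) -> np.ndarray:
        if reaction_id not in self.reaction_ids:
            raise KeyError(f"no reaction {reaction_id!r} in samples")
        return self.matrix[:, self.reaction_ids.index(reaction_id)]

    def by_chain(self) -> List[np.ndarray]:
        return [
            self.matrix[self.chain_index == c] for c in range(self.n_chains)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.reaction_ids)


def _chord_interval(v, u, lb, ub):
    """Per-chain [tmin, tmax] of {t : lb <= v + t u <= ub}; v,u: (c, r)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        to_ub = (ub - v) / u
        to_lb = (lb - v) / u
    pos = u > 1e-13
    neg = u < -1e-13
    hi = np.where(pos, to_ub, np.where(neg, to_lb, np.inf))
    lo = np.where(pos, to_lb, np.where(neg, to_ub, -np.inf))
    return lo.max(axis=1), hi.min(axis=1)


def sample_fluxes(
    model: MetabolicModel,
    n: int = 5000,
    seed: int = 0,
    warmup: int = 1000,
    thinning: Optional[int] = None,
    n_chains: int = 4,
    rounding: bool = True,
) -> FluxSamples:
    """Draw ``n`` flux vectors uniformly from the model's flux polytope.

    Parameters
    ----------
    n
        Total number of post-warmup draws across all chains.
    seed
        Integer seed; fully determines the output (Philox bit stream).
    warmup
        Burn-in steps per chain before any draw is recorded.
    thinning
        Hit-and-run steps between recorded draws; defaults to
        ``max(1, 10 * dim)`` where ``dim`` is the free polytope dimension.
    n_chains
        Independent chains started from jittered interior points.
    rounding
        Estimate an ellipsoidal rounding transform from a pilot run and draw
        directions from the fitted covariance (recommended for elongated
        polytopes).
    """
    rids = model.reaction_ids
    r = len(rids)
    S = stoichiometric_matrix(model)
    lb = np.array([rx.lb for rx in model.reactions], dtype=float)
    ub = np.array([rx.ub for rx in model.reactions], dtype=float)

    # FVA identifies coordinates pinned by conservation, not just lb == ub
    fva = flux_variability(model)
    fva_lo = np.array([fva[rid][0] for rid in rids])
    fva_hi = np.array([fva[rid][1] for rid in rids])
    pinned_mask = (fva_hi - fva_lo) <= _PIN_TOL
    pinned_vals = (fva_hi + fva_lo) / 2.0
    free = ~pinned_mask

    ip = interior_point(model, pinned_extra=np.flatnonzero(pinned_mask))
    v_full = ip.flux_vector.copy()
    v_full[pinned_mask] = pinned_vals[pinned_mask]

    # null-space basis restricted to free coordinates; pinned columns of S
    # contribute a constant that the particular solution v_full absorbs
    S_free = S[:, free]
    N = null_space(S_free) if S_free.size else np.zeros((0, 0))
    dim = N.shape[1] if N.size else 0
    if dim == 0:
        warnings.warn(
            "flux polytope has no free directions; returning its single point",
            stacklevel=2,
        )
        return FluxSamples(
            matrix=v_full[None, :],
            reaction_ids=rids,
            seed=seed,
            chain_index=np.zeros(1, dtype=int),
            warmup=warmup,
            thinning=thinning or 1,
            n_chains=1,
        )

    if thinning is None:
        thinning = max(1, 10 * dim)
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")

    rng = np.random.Generator(np.random.Philox(seed))
    lb_f, ub_f = lb[free], ub[free]
    v0 = v_full[free]

    # chain states in x-space; v = v0 + x @ N.T, exact by construction
    x = np.zeros((n_chains, dim))
    # jitter starts along random chords so chains are over-dispersed
    for c in range(n_chains):
        d = rng.standard_normal(dim)
        d /= np.linalg.norm(d)
        u = (N @ d)[None, :]
        tmin, tmax = _chord_interval((v0 + x[c] @ N.T)[None, :], u, lb_f, ub_f)
        t = tmin[0] + (0.2 + 0.6 * rng.random()) * (tmax[0] - tmin[0])
        x[c] += t * d

    L = np.eye(dim)  # rounding transform (directions ~ N(0, L L^T))

    def step(x, n_steps, collect_every=0):
        collected = []
        v = v0[None, :] + x @ N.T
        for s in range(n_steps):
            g = rng.standard_normal((n_chains, dim))
            d = g @ L.T
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            u = d @ N.T  # (chains, r_free)
            tmin, tmax = _chord_interval(v, u, lb_f, ub_f)
            width = np.maximum(tmax - tmin, 0.0)
            t = tmin + rng.random(n_chains) * width
            x = x + t[:, None] * d
            v = v0[None, :] + x @ N.T
            # guard against float excursions at the boundary
            np.clip(v, lb_f, ub_f, out=v)
            if collect_every and (s + 1) % collect_every == 0:
                collected.append(x.copy())
        return x, collected

    if rounding:
        pilot_steps = max(200, 5 * dim)
        x, pilot = step(x, pilot_steps, collect_every=max(1, dim))
        X = np.concatenate(pilot, axis=0)
        if X.shape[0] > dim + 1:
            cov = np.cov(X, rowvar=False)
            cov = np.atleast_2d(cov) + 1e-10 * np.eye(dim)
            try:
                L = np.linalg.cholesky(cov)
                scale = np.exp(np.mean(np.log(np.diag(L))))
                L = L / scale  # keep direction scale O(1)
            except np.linalg.LinAlgError:
                L = np.eye(dim)

    x, _ = step(x, warmup)

    per_chain = int(np.ceil(n / n_chains))
    draws = np.empty((n_chains, per_chain, r))
    for k in range(per_chain):
        x, _ = step(x, thinning)
        v = v0[None, :] + x @ N.T
        full = np.tile(pinned_vals, (n_chains, 1))
        full[:, free] = v
        draws[:, k, :] = full

    matrix = draws.reshape(n_chains * per_chain, r)[:n]
    chain_index = np.repeat(np.arange(n_chains), per_chain)[:n]

    # invariant check on every emitted row
    resid = np.abs(S @ matrix.T).max(axis=0)
    scale = np.maximum(1.0, np.abs(matrix).max(axis=1))
    if (resid > FEASIBILITY_TOL * scale).any():  # pragma: no cover
        raise LPError("sampler produced rows violating S v = 0")
    if ((matrix < lb - FEASIBILITY_TOL) | (matrix > ub + FEASIBILITY_TOL)).any():
        raise LPError("sampler produced rows violating bounds")  # pragma: no cover

    return FluxSamples(
        matrix=matrix,
        reaction_ids=rids,
        seed=seed,
        chain_index=chain_index,
        warmup=warmup,
        thinning=thinning,
        n_chains=n_chains,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _split_chains(chains: List[np.ndarray]) -> List[np.ndarray]:
    halves = []
    for c in chains:
        h = len(c) // 2
        halves.extend([c[:h], c[h : 2 * h]])
    return halves


def _rhat(split: List[np.ndarray]) -> float:
    M = len(split)
    N = len(split[0])
    means = np.array([c.mean() for c in split])
    variances = np.array([c.var(ddof=1) for c in split])
    W = variances.mean()
    B = N * means.var(ddof=1)
    if W <= 0:
        return np.nan
    var_plus = (N - 1) / N * W + B / N
    # floor at 1: sub-unit values are finite-sample noise, not better mixing
    return float(max(1.0, np.sqrt(var_plus / W)))


def _ess(split: List[np.ndarray]) -> float:
    # pooled autocorrelation with Geyer initial-positive-sequence truncation
    M = len(split)
    N = len(split[0])
    means = np.array([c.mean() for c in split])
    variances = np.array([c.var(ddof=1) for c in split])
    W = variances.mean()
    B = N * means.var(ddof=1)
    var_plus = (N - 1) / N * W + B / N
    if var_plus <= 0:
        return np.nan
    rho_sum = 0.0
    for t in range(1, N):
        acov_t = np.mean(
            [
                np.mean((c[:-t] - c.mean()) * (c[t:] - c.mean()))
                for c in split
            ]
        )
        rho = 1.0 - (W - acov_t) / var_plus
        if rho < 0.0:
            break
        rho_sum += rho
    ess = M * N / (1.0 + 2.0 * rho_sum)
    return float(min(ess, M * N))


def convergence_diagnostics(samples: FluxSamples) -> pd.DataFrame:
    """Split-chain R-hat and effective sample size per reaction.

    Constant (pinned) reactions are flagged ``applicable = False`` rather
    than reported as NaN-bearing statistics.
    """
    if samples.n_chains < 2:
        raise ValueError(
            "convergence diagnostics need >= 2 chains; rerun the sampler "
            "with n_chains >= 2"
        )
    chains = samples.by_chain()
    if min(len(c) for c in chains) < 50:
        raise ValueError("need >= 50 draws per chain for diagnostics")
    rows = []
    for j, rid in enumerate(samples.reaction_ids):
        cols = [c[:, j] for c in chains]
        pooled = np.concatenate(cols)
        if pooled.max() - pooled.min() <= 1e-12:
            rows.append((rid, False, None, None))
            continue
        split = _split_chains(cols)
        rows.append((rid, True, _rhat(split), _ess(split)))
    return pd.DataFrame(
        rows, columns=["reaction_id", "applicable", "rhat", "ess"]
    )


def flux_histogram(
    samples: FluxSamples, reaction_id: str, n_bins: int = 50
) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of one reaction's sampled flux; frequencies sum to 1."""
    col = samples.column(reaction_id)
    lo, hi = col.min(), col.max()
    if hi - lo <= 1e-12:  # constant flux: single occupied bin
        edges = np.linspace(lo - 0.5, lo + 0.5, n_bins + 1)
        freqs = np.zeros(n_bins)
        freqs[n_bins // 2] = 1.0
        return edges, freqs
    counts, edges = np.histogram(col, bins=n_bins, range=(lo, hi))
    return edges, counts / counts.sum()


# ---------------------------------------------------------------------------
# text serialisation (TSV + sidecar metadata)
# ---------------------------------------------------------------------------

def write_samples(samples: FluxSamples, path: Union[str, Path]) -> Path:
    """Write draws as TSV (rows = draws) and a ``.meta.tsv`` sidecar."""
    path = Path(path)
    df = samples.to_frame()
    df.insert(0, "chain", samples.chain_index)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = path.with_suffix(path.suffix + ".meta.tsv")
    with open(meta, "w", encoding="utf-8") as fh:
        fh.write("key\tvalue\n")
        for key in ("seed", "warmup", "thinning", "n_chains"):
            fh.write(f"{key}\t{getattr(samples, key)}\n")
    return path


def read_samples(path: Union[str, Path]) -> FluxSamples:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    chain = df.pop("chain").to_numpy(dtype=int)
    meta_path = path.with_suffix(path.suffix + ".meta.tsv")
    meta: Dict[str, int] = {}
    if meta_path.exists():
        m = pd.read_csv(meta_path, sep="\t")
        meta = dict(zip(m["key"], m["value"].astype(int)))
    return FluxSamples(
        matrix=df.to_numpy(dtype=float),
        reaction_ids=list(df.columns),
        seed=meta.get("seed", -1),
        chain_index=chain,
        warmup=meta.get("warmup", 0),
        thinning=meta.get("thinning", 1),
        n_chains=meta.get("n_chains", int(chain.max()) + 1),
    )
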