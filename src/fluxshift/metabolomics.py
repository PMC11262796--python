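"""Targeted-metabolomics index statistics for a two-group comparison.

When the two groups are different species, absolute abundances are not
directly comparable, so the informative statistics are *intra-sample* ratios
(e.g. succinate/fumarate computed within each replicate, which cancels any
per-sample scaling) and adenylate energy-state indices:

* adenylate energy charge  ``(ATP + 0.5 ADP) / (ATP + ADP + AMP)``
  (Atkinson), in [0, 1], lower = slower metabolism;
* AMP fraction  ``AMP / (AMP + ADP + ATP)``, the AMP share of the pool;
* ATP/ADP ratio, the standard readout of cellular energy status.

Group differences use the unpaired two-sided Student's (equal-variance)
t-test with Benjamini-Hochberg FDR correction applied per analysis family.
The pi-value ``LFC * (-log10 p)`` combines effect size and significance for
rank-based downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetaboliteTable",
    "RatioStat",
    "EnergyState",
    "intra_sample_ratio",
    "adenylate_indices",
    "fold_changes",
    "bh_adjust",
    "pi_value_rank",
]


@dataclass
class MetaboliteTable:
    """Metabolites x samples absolute abundances with two group labels."""

    abundances: pd.DataFrame  # rows = metabolites, columns = samples
    groups: pd.Series  # sample -> group label

    def __post_init__(self) -> None:
        if (self.abundances.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        missing = set(self.abundances.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        self.groups = self.groups.loc[list(self.abundances.columns)]

    @property
    def group_names(self) -> List[str]:
        return sorted(self.groups.unique())

    def samples_of(self, group: str) -> List[str]:
        return [s for s in self.abundances.columns if self.groups[s] == group]

    def row(self, metabolite: str) -> pd.Series:
        if metabolite not in self.abundances.index:
            raise KeyError(f"metabolite {metabolite!r} not in table")
        return self.abundances.loc[metabolite]

    def require_two_groups(self) -> Tuple[str, str]:
        names = self.group_names
        if len(names) != 2:
            raise ValueError(f"need exactly two groups, found {names}")
        for g in names:
            if len(self.samples_of(g)) < 2:
                raise ValueError(f"group {g!r} has < 2 samples")
        return names[0], names[1]


@dataclass
class RatioStat:
    numerator: str
    denominator: str
    per_sample: pd.Series
    group_means: Dict[str, float]
    group_sds: Dict[str, float]
    t_statistic: float
    p_value: float
    q_value: Optional[float] = None


@dataclass
class EnergyState:
    per_sample: pd.DataFrame  # columns: energy_charge, amp_fraction, atp_adp
    summary: pd.DataFrame  # one row per (index, group): mean, sd
    tests: pd.DataFrame  # one row per index: t, p, q


def _ttest(x: np.ndarray, y: np.ndarray, log_transform: bool = False):
    if log_transform:
        x, y = np.log(x), np.log(y)
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def intra_sample_ratio(
    table: MetaboliteTable,
    numerator: str,
    denominator: str,
    log_transform: bool = False,
) -> RatioStat:
    """Ratio of two metabolites computed within each sample, then compared
    between groups with a Student's t-test (optionally on log ratios)."""
    g1, g2 = table.require_two_groups()
    num = table.row(numerator)
    den = table.row(denominator)
    zero = den[den == 0]
    if len(zero):
        raise ValueError(
            f"zero denominator ({denominator}) in samples: "
            f"{list(zero.index)}"
        )
    ratios = num / den
    x = ratios[table.samples_of(g1)].to_numpy(dtype=float)
    y = ratios[table.samples_of(g2)].to_numpy(dtype=float)
    t, p = _ttest(x, y, log_transform)
    return RatioStat(
        numerator=numerator,
        denominator=denominator,
        per_sample=ratios,
        group_means={g1: float(x.mean()), g2: float(y.mean())},
        group_sds={g1: float(x.std(ddof=1)), g2: float(y.std(ddof=1))},
        t_statistic=t,
        p_value=p,
    )


def ratio_panel(
    table: MetaboliteTable,
    pairs: Sequence[Tuple[str, str]],
    log_transform: bool = False,
) -> List[RatioStat]:
    """A family of intra-sample ratios with BH correction across the panel."""
    ratio_stats = [
        intra_sample_ratio(table, n, d, log_transform) for n, d in pairs
    ]
    qs = bh_adjust([r.p_value for r in ratio_stats])
    for r, q in zip(ratio_stats, qs):
        r.q_value = float(q)
    return ratio_stats


ENERGY_INDICES = ("energy_charge", "amp_fraction", "atp_adp")


def adenylate_indices(
    table: MetaboliteTable,
    amp: str = "AMP",
    adp: str = "ADP",
    atp: str = "ATP",
) -> EnergyState:
    """Per-sample adenylate energy charge, AMP pool fraction and ATP/ADP,
    with group summaries and BH-corrected t-tests across the three indices."""
    g1, g2 = table.require_two_groups()
    a = table.row(amp).astype(float)
    d = table.row(adp).astype(float)
    t_ = table.row(atp).astype(float)
    pool = a + d + t_
    empty = pool[pool == 0]
    if len(empty):
        raise ValueError(
            f"adenylate pool is zero in samples: {list(empty.index)}"
        )
    per_sample = pd.DataFrame(
        {
            "energy_charge": (t_ + 0.5 * d) / pool,
            "amp_fraction": a / pool,
            "atp_adp": t_ / d.replace(0, np.nan),
        }
    )
    summary_rows, test_rows = [], []
    for index in ENERGY_INDICES:
        vals = per_sample[index]
        x = vals[table.samples_of(g1)].to_numpy(dtype=float)
        y = vals[table.samples_of(g2)].to_numpy(dtype=float)
        for g, arr in ((g1, x), (g2, y)):
            summary_rows.append(
                (index, g, float(np.nanmean(arr)),
                 float(np.nanstd(arr, ddof=1)))
            )
        t, p = _ttest(x, y)
        test_rows.append((index, t, p))
    tests = pd.DataFrame(test_rows, columns=["index", "t", "p"])
    # zero-variance identical groups give NaN p; exclude them from the family
    tests["q"] = np.nan
    valid = tests["p"].notna()
    if valid.any():
        tests.loc[valid, "q"] = bh_adjust(tests.loc[valid, "p"].tolist())
    return EnergyState(
        per_sample=per_sample,
        summary=pd.DataFrame(
            summary_rows, columns=["index", "group", "mean", "sd"]
        ),
        tests=tests,
    )


def fold_changes(
    table: MetaboliteTable,
    numerator_group: Optional[str] = None,
    denominator_group: Optional[str] = None,
) -> pd.DataFrame:
    """Per-metabolite ratio of group means (numerator group / denominator
    group).  Metabolites whose denominator mean is zero are flagged
    ``undefined`` rather than dropped."""
    g1, g2 = table.require_two_groups()
    num_g = numerator_group or g1
    den_g = denominator_group or g2
    if {num_g, den_g} - set(table.group_names):
        raise ValueError(f"groups must be among {table.group_names}")
    num_mean = table.abundances[table.samples_of(num_g)].mean(axis=1)
    den_mean = table.abundances[table.samples_of(den_g)].mean(axis=1)
    undefined = den_mean == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = num_mean / den_mean
    fc[undefined] = np.nan
    return pd.DataFrame(
        {
            "fold_change": fc,
            "undefined": undefined,
            "mean_" + num_g: num_mean,
            "mean_" + den_g: den_mean,
        }
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pi_value_rank(
    lfc: Union[float, np.ndarray], p: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Ranking score ``LFC * (-log10 p)``: signed like the fold change and
    growing with significance.  ``p`` must be in (0, 1]; floor tiny p-values
    before calling."""
    lfc = np.asarray(lfc, dtype=float)
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError(
            "p-values must be in (0, 1]; floor zeros before ranking"
        )
    score = lfc * (-np.log10(p))
    return float(score) if score.ndim == 0 else score
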