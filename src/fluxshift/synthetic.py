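"""Synthetic inputs: a toy central-metabolism network, expression counts
with a planted absent-gene set, and metabolomics tables with planted group
effects.

The toy network is a fixed 24-reaction model of central energy metabolism:
glucose uptake feeding a lumped glycolysis, pyruvate oxidation into a TCA
loop whose succinate dehydrogenase step (``CII_toy``) is the only reversible
TCA reaction, an electron transport chain (``CI_toy``/``CIII_toy``/
``CIV_toy``) coupled to a proton-motive pool driving ATP synthase, oxygen
transport (``O2tm_toy``), a proton leak, and exchanges for glucose, oxygen,
lactate, succinate, fumarate and water.  Because quinol produced by Complex I
can be re-oxidised either by Complex III (oxygen-dependent) or by succinate
dehydrogenase running in reverse (fumarate -> succinate), constraining the
network to high Complex I flux and low oxygen intake forces the reverse SDH
route — the ischemia-like regime the comparison stage is designed to detect.
Every reaction carries a one-gene GPR (``<reaction id>_g``) so presence
calls map one-to-one onto reactions.

The generators emulate the structure of real inputs, not their full
complexity: negative-binomial counts with a designated absent-gene set
(no batch effects or length bias), and log-normal absolute abundances with
configurable group fold-changes whose defaults plant the study-scale
succinate/fumarate and adenylate effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .compare import build_constrained_pair
from .lp import CapacitySpec, check_capacity, flux_variability, maximize_flux
from .model import MetabolicModel, Metabolite, Reaction
from .metabolomics import MetaboliteTable

__all__ = [
    "ToyScenarioConfig",
    "build_toy_network",
    "toy_capacity_spec",
    "simulate_expression",
    "simulate_metabolomics",
    "DEFAULT_BASELINES",
    "DEFAULT_EFFECTS",
]

TOY_CI = "CI_toy"
TOY_CII = "CII_toy"
TOY_O2 = "O2tm_toy"

#: protected-function witnesses for the toy network: ATP production
#: (ATP synthase), TCA cycle (citrate synthase), glycolysis (lumped step)
TOY_PROTECTED = {
    "atp_production": "ATPS",
    "tca_cycle": "CS",
    "glycolysis": "GLYC",
}

#: group-W baseline absolute abundances (pmol per 1e6 cells scale);
#: succinate/fumarate baseline ratio 1.07
DEFAULT_BASELINES: Dict[str, float] = {
    "succinate": 107.0,
    "fumarate": 100.0,
    "citrate": 150.0,
    "malate": 120.0,
    "alpha_ketoglutarate": 50.0,
    "pyruvate": 100.0,
    "lactate": 800.0,
    "AMP": 300.0,
    "ADP": 1000.0,
    "ATP": 3000.0,
}

#: group-P fold changes relative to the group-W baselines: succinate raised
#: so the planted intra-sample succinate/fumarate ratio is 5.44 vs 1.07;
#: adenylates set for a threefold-lower ATP/ADP and a lower energy charge
DEFAULT_EFFECTS: Dict[str, float] = {
    "succinate": 5.44 / 1.07,
    "lactate": 0.5,
    "AMP": 3.0,
    "ADP": 1.2,
    "ATP": 0.4,
}


@dataclass
class ToyScenarioConfig:
    seed: int = 0
    absent_genes: Tuple[str, ...] = ("LDH_g", "ME_g")
    mean_present: float = 100.0
    mean_absent: float = 1.0
    dispersion: float = 10.0
    protein_mean_present: float = 50000.0
    protein_mean_absent: float = 500.0
    effects: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    sigma: float = 0.1
    sigma_met: float = 0.03
    f_hi: float = 0.7
    f_lo: float = 0.3
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not self.mean_absent < 5.0 < self.mean_present:
            raise ValueError(
                "transcript means must straddle the presence cutoff of 5"
            )
        if not self.protein_mean_absent < 2000.0 < self.protein_mean_present:
            raise ValueError(
                "protein means must straddle the presence cutoff of 2000"
            )
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if any(f <= 0 for f in self.effects.values()):
            raise ValueError("fold changes must be positive")


def _rxn(rid, stoich, lb=0.0, ub=1000.0, subsystem=""):
    return Reaction(
        id=rid, stoich=stoich, lb=lb, ub=ub, gpr=f"{rid}_g", subsystem=subsystem
    )


def build_toy_network(verify: bool = True) -> MetabolicModel:
    """The fixed 24-reaction toy central-metabolism network.

    With ``verify=True`` (the default) the construction is checked at build
    time: the model is feasible, passes the protected-function capacity
    check, and the constrained scenario (Complex I lower-bounded at 70% of
    max, oxygen transport capped at 30%) admits negative succinate
    dehydrogenase flux.  A failure indicates a broken fixture, not bad user
    input.
    """
    mets = [
        Metabolite("glc_c", "c", "glucose"),
        Metabolite("pyr_c", "c", "pyruvate"),
        Metabolite("lac_c", "c", "lactate"),
        Metabolite("accoa_m", "m", "acetyl-CoA"),
        Metabolite("oaa_m", "m", "oxaloacetate"),
        Metabolite("cit_m", "m", "citrate"),
        Metabolite("akg_m", "m", "alpha-ketoglutarate"),
        Metabolite("succ_m", "m", "succinate"),
        Metabolite("fum_m", "m", "fumarate"),
        Metabolite("mal_m", "m", "malate"),
        Metabolite("nad_m", "m", "NAD+"),
        Metabolite("nadh_m", "m", "NADH"),
        Metabolite("q_m", "m", "ubiquinone"),
        Metabolite("qh2_m", "m", "ubiquinol"),
        Metabolite("cytc_ox_m", "m", "cytochrome c (oxidised)"),
        Metabolite("cytc_red_m", "m", "cytochrome c (reduced)"),
        Metabolite("pmf_m", "m", "proton-motive charge"),
        Metabolite("atp_c", "c", "ATP"),
        Metabolite("adp_c", "c", "ADP"),
        Metabolite("o2_e", "e", "oxygen (extracellular)"),
        Metabolite("o2_m", "m", "oxygen (mitochondrial)"),
        Metabolite("h2o_m", "m", "water"),
    ]
    rxns = [
        _rxn("EX_glc", {"glc_c": 1}, 0, 10, "exchange"),
        _rxn(
            "GLYC",
            {"glc_c": -1, "adp_c": -2, "nad_m": -2,
             "pyr_c": 2, "atp_c": 2, "nadh_m": 2},
            0, 1000, "glycolysis",
        ),
        _rxn("LDH", {"pyr_c": -1, "nadh_m": -1, "lac_c": 1, "nad_m": 1},
             0, 1000, "fermentation"),
        _rxn("EX_lac", {"lac_c": -1}, 0, 1000, "exchange"),
        _rxn("PDH", {"pyr_c": -1, "nad_m": -1, "accoa_m": 1, "nadh_m": 1},
             0, 1000, "pyruvate metabolism"),
        _rxn("PC", {"pyr_c": -1, "atp_c": -1, "oaa_m": 1, "adp_c": 1},
             0, 1000, "anaplerosis"),
        _rxn("CS", {"accoa_m": -1, "oaa_m": -1, "cit_m": 1}, 0, 1000, "tca"),
        _rxn("IDH", {"cit_m": -1, "nad_m": -1, "akg_m": 1, "nadh_m": 1},
             0, 1000, "tca"),
        _rxn("AKGDH", {"akg_m": -1, "nad_m": -1, "succ_m": 1, "nadh_m": 1},
             0, 1000, "tca"),
        # the reversible SDH step: succinate + Q <=> fumarate + QH2
        _rxn(TOY_CII, {"succ_m": -1, "q_m": -1, "fum_m": 1, "qh2_m": 1},
             -1000, 1000, "tca/etc"),
        _rxn("FUM", {"fum_m": -1, "mal_m": 1}, -1000, 1000, "tca"),
        _rxn("MDH", {"mal_m": -1, "nad_m": -1, "oaa_m": 1, "nadh_m": 1},
             -1000, 1000, "tca"),
        _rxn("ME", {"mal_m": -1, "nad_m": -1, "pyr_c": 1, "nadh_m": 1},
             0, 1000, "anaplerosis"),
        _rxn(TOY_CI, {"nadh_m": -1, "q_m": -1, "nad_m": 1, "qh2_m": 1,
                      "pmf_m": 4},
             0, 1000, "etc"),
        _rxn("CIII_toy", {"qh2_m": -1, "cytc_ox_m": -2, "q_m": 1,
                          "cytc_red_m": 2, "pmf_m": 2},
             0, 1000, "etc"),
        _rxn("CIV_toy", {"cytc_red_m": -2, "o2_m": -0.5, "cytc_ox_m": 2,
                         "h2o_m": 1, "pmf_m": 2},
             0, 1000, "etc"),
        _rxn("ATPS", {"adp_c": -1, "pmf_m": -3, "atp_c": 1},
             0, 1000, "oxidative phosphorylation"),
        _rxn("LEAK", {"pmf_m": -1}, 0, 1000, "etc"),
        _rxn("ATPM", {"atp_c": -1, "adp_c": 1}, 0, 1000, "demand"),
        _rxn(TOY_O2, {"o2_e": -1, "o2_m": 1}, 0, 1000, "transport"),
        _rxn("EX_o2", {"o2_e": 1}, 0, 20, "exchange"),
        _rxn("EX_succ", {"succ_m": -1}, 0, 1000, "exchange"),
        _rxn("EX_fum", {"fum_m": 1}, 0, 60, "exchange"),
        _rxn("EX_h2o", {"h2o_m": -1}, 0, 1000, "exchange"),
    ]
    model = MetabolicModel(metabolites=mets, reactions=rxns, objective="ATPM")
    model.log("build_toy_network: fixed 24-reaction central-metabolism toy")
    if verify:
        _verify_toy(model)
    return model


def toy_capacity_spec() -> CapacitySpec:
    return CapacitySpec(witnesses=dict(TOY_PROTECTED))


def _verify_toy(model: MetabolicModel) -> None:
    atp = maximize_flux(model, "ATPM")
    if not atp.optimal or atp.objective_value <= 0:
        raise AssertionError("toy network fixture broken: no ATP flux")
    if not check_capacity(model, toy_capacity_spec()):
        raise AssertionError("toy network fixture broken: capacity check fails")
    a, _ = build_constrained_pair(
        model, model, ci_id=TOY_CI, o2_id=TOY_O2, f_hi=0.7, f_lo=0.3
    )
    lo, _hi = flux_variability(a, [TOY_CII])[TOY_CII]
    if lo >= 0:
        raise AssertionError(
            "toy network fixture broken: constrained scenario does not "
            f"admit negative SDH flux (FVA min {lo:g})"
        )


def simulate_expression(
    model: MetabolicModel, config: ToyScenarioConfig
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial expression tables (transcript, protein) for the
    model's genes, with the configured absent set drawn at low mean.

    Returns two genes x replicates DataFrames; the ground-truth absent set
    is ``config.absent_genes``.  Bit-deterministic for a fixed config.
    """
    genes = model.genes()
    unknown = set(config.absent_genes) - set(genes)
    if unknown:
        raise ValueError(f"absent genes not in model: {sorted(unknown)}")
    rng = np.random.Generator(np.random.Philox(config.seed))
    frames = []
    for mean_present, mean_absent in (
        (config.mean_present, config.mean_absent),
        (config.protein_mean_present, config.protein_mean_absent),
    ):
        data = np.empty((len(genes), config.n_replicates))
        for i, g in enumerate(genes):
            mu = mean_absent if g in config.absent_genes else mean_present
            # NB with size r and mean mu: p = r / (r + mu)
            r = config.dispersion
            data[i] = rng.negative_binomial(
                r, r / (r + mu), size=config.n_replicates
            )
        frames.append(
            pd.DataFrame(
                data,
                index=genes,
                columns=[f"rep{k + 1}" for k in range(config.n_replicates)],
            )
        )
    return frames[0], frames[1]


def simulate_metabolomics(
    config: ToyScenarioConfig,
    baselines: Optional[Dict[str, float]] = None,
    group_labels: Tuple[str, str] = ("P", "W"),
) -> MetaboliteTable:
    """Log-normal absolute-abundance table with planted group fold-changes.

    Group W samples are drawn around the baselines; group P samples around
    baseline x fold-change for metabolites in the effect map (fold 1
    otherwise).  Noise is multiplicative log-normal with two components
    mirroring targeted-metabolomics data: a per-sample scale factor
    (``config.sigma``, shared by all metabolites of a sample — cell number
    and extraction efficiency) and a small per-metabolite residual
    (``config.sigma_met``).  Intra-sample ratios cancel the shared factor,
    which is what makes them the robust cross-species statistic.  Three
    replicates per group by default.
    """
    if not config.effects:
        raise ValueError("effect map must be non-empty")
    if baselines is None:
        baselines = dict(DEFAULT_BASELINES)
    unknown = set(config.effects) - set(baselines)
    if unknown:
        raise ValueError(f"effects for unknown metabolites: {sorted(unknown)}")
    rng = np.random.Generator(np.random.Philox(config.seed + 1))
    p_label, w_label = group_labels
    n = config.n_replicates
    columns = [f"{p_label}{k + 1}" for k in range(n)] + [
        f"{w_label}{k + 1}" for k in range(n)
    ]
    sample_scale = np.exp(config.sigma * rng.standard_normal(2 * n))
    rows = {}
    for met, base in baselines.items():
        fold = config.effects.get(met, 1.0)
        residual = np.exp(config.sigma_met * rng.standard_normal(2 * n))
        values = (
            np.concatenate([np.full(n, base * fold), np.full(n, base)])
            * sample_scale
            * residual
        )
        rows[met] = values
    abundances = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    groups = pd.Series(
        [p_label] * n + [w_label] * n, index=columns, name="group"
    )
    return MetaboliteTable(abundances=abundances, groups=groups)
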