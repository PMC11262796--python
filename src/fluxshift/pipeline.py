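"""Pipeline orchestration: reconstruction -> sampling -> comparison -> stats.

A run is described by a :class:`RunConfig` (usually loaded from a YAML
file).  :func:`run_full` executes the whole comparative workflow and writes
every intermediate artifact into a run directory:

* presence calls and prune logs per condition,
* context models in the native format,
* four flux-sample files (2 models x {control, constrained}) with sidecar
  metadata,
* the per-reaction shift report,
* metabolite statistics (when a metabolomics table is supplied),
* ``manifest.json`` with SHA-256 checksums of every artifact and
  ``run.log`` recording seeds, thresholds and every theoretical maximum
  used — the pivotal intermediate numbers of the analysis.

Reruns of the same config are byte-identical (all randomness flows from the
single mandatory seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import io as model_io
from .compare import (
    build_constrained_pair,
    compare_distributions,
    flag_reversed_reactions,
)
from .lp import CapacitySpec, maximize_flux
from .metabolomics import (
    MetaboliteTable,
    adenylate_indices,
    fold_changes,
    ratio_panel,
)
from .model import MetabolicModel
from .reconstruction import call_presence, merge_presence, prune_model
from .sampling import flux_histogram, read_samples, sample_fluxes, write_samples

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_full",
    "render_report",
    "load_config",
    "read_expression_table",
    "read_metabolite_table",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class SamplerSettings:
    n: int = 5000
    warmup: int = 1000
    thinning: Optional[int] = None
    n_chains: int = 4


@dataclass
class ConditionInputs:
    """Per-condition inputs: a base model plus optional omics tables."""

    model_dir: str
    transcripts: Optional[str] = None
    proteins: Optional[str] = None


@dataclass
class RunConfig:
    seed: int
    conditions: Dict[str, ConditionInputs]  # exactly two, keyed by label
    condition_a: str
    condition_b: str
    ci_reaction: str
    o2_reaction: str
    protected_reactions: Dict[str, str]
    out_dir: str
    f_hi: float = 0.7
    f_lo: float = 0.3
    transcript_cutoff: float = 5.0
    protein_cutoff: float = 2000.0
    capacity_epsilon: float = 1e-6
    overlap_threshold: float = 0.2
    shift_threshold: float = 1.0
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    metabolomics: Optional[str] = None
    metabolomics_groups: Optional[str] = None
    ratio_pairs: Tuple[Tuple[str, str], ...] = ()

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an integer seed")
        if set(self.conditions) != {self.condition_a, self.condition_b}:
            raise ValueError(
                "conditions must be keyed exactly by condition_a/condition_b"
            )
        for label, cond in self.conditions.items():
            for path in (cond.model_dir, cond.transcripts, cond.proteins):
                if path is not None and not Path(path).exists():
                    raise FileNotFoundError(
                        f"condition {label!r}: missing input {path}"
                    )
        for path in (self.metabolomics, self.metabolomics_groups):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"missing input {path}")


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a RunConfig from YAML; nested keys mirror the dataclass."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise ValueError(f"{path}: config must set an integer seed")
    raw["conditions"] = {
        label: ConditionInputs(**cond)
        for label, cond in raw.get("conditions", {}).items()
    }
    if "sampler" in raw:
        raw["sampler"] = SamplerSettings(**raw["sampler"])
    if "ratio_pairs" in raw:
        raw["ratio_pairs"] = tuple(tuple(p) for p in raw["ratio_pairs"])
    return RunConfig(**raw)


def read_expression_table(path: Union[str, Path]) -> pd.DataFrame:
    """Genes x samples delimited table; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_metabolite_table(
    abundances_path: Union[str, Path], groups_path: Union[str, Path]
) -> MetaboliteTable:
    """Metabolites x samples table plus a two-column sample->group map."""
    abundances = pd.read_csv(abundances_path, sep="\t", index_col=0)
    gmap = pd.read_csv(groups_path, sep="\t", index_col=0)
    groups = gmap.iloc[:, 0]
    return MetaboliteTable(abundances=abundances, groups=groups)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _child_seed(base: int, stream: int) -> int:
    return int(
        np.random.SeedSequence([base, stream]).generate_state(1)[0] % (2**31)
    )


def run_full(config: RunConfig) -> Path:
    """Execute the comparative flux-sampling workflow; returns the run dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: List[str] = [f"seed: {config.seed}"]
    capacity = CapacitySpec(
        witnesses=dict(config.protected_reactions),
        epsilon=config.capacity_epsilon,
    )

    def stage(name):
        log_lines.append(f"stage: {name}")

    # ---- reconstruction per condition ---------------------------------
    contexts: Dict[str, MetabolicModel] = {}
    for label in (config.condition_a, config.condition_b):
        cond = config.conditions[label]
        try:
            base = model_io.read_native(cond.model_dir)
        except Exception as exc:
            raise PipelineError(f"reconstruction[{label}]: {exc}") from exc
        stage(f"reconstruction[{label}]")
        if cond.transcripts or cond.proteins:
            calls = None
            if cond.transcripts:
                tcalls = call_presence(
                    read_expression_table(cond.transcripts),
                    "transcript",
                    cutoff=config.transcript_cutoff,
                )
                calls = tcalls
            if cond.proteins:
                pcalls = call_presence(
                    read_expression_table(cond.proteins),
                    "protein",
                    cutoff=config.protein_cutoff,
                )
                calls = merge_presence(calls, pcalls) if calls else pcalls
            try:
                context, prune_log = prune_model(base, calls, capacity)
            except Exception as exc:
                raise PipelineError(f"reconstruction[{label}]: {exc}") from exc
            calls.to_frame().to_csv(
                out / f"presence_{label}.tsv", sep="\t", index=False
            )
            prune_log.to_frame().to_csv(
                out / f"prune_log_{label}.tsv", sep="\t", index=False
            )
            log_lines.append(
                f"pruned[{label}]: removed {len(prune_log.removed())} "
                f"reactions of {len(base.reactions)}"
            )
        else:
            context = base
            log_lines.append(f"pruned[{label}]: no omics supplied; base model")
        model_io.write_native(context, out / f"model_{label}")
        contexts[label] = context

    # ---- constrained pair ---------------------------------------------
    stage("constraints")
    model_a = contexts[config.condition_a]
    model_b = contexts[config.condition_b]
    try:
        constrained_a, constrained_b = build_constrained_pair(
            model_a,
            model_b,
            ci_id=config.ci_reaction,
            o2_id=config.o2_reaction,
            f_hi=config.f_hi,
            f_lo=config.f_lo,
        )
    except Exception as exc:
        raise PipelineError(f"constraints: {exc}") from exc
    for model in (constrained_a, constrained_b):
        for line in model.provenance:
            if "build_constrained_pair" in line:
                log_lines.append(line)

    # ---- sampling ------------------------------------------------------
    sample_files = {}
    runs = [
        ("control", config.condition_a, model_a, 1),
        ("control", config.condition_b, model_b, 2),
        ("constrained", config.condition_a, constrained_a, 3),
        ("constrained", config.condition_b, constrained_b, 4),
    ]
    samples = {}
    for kind, label, model, stream in runs:
        stage(f"sampling[{kind}:{label}]")
        seed = _child_seed(config.seed, stream)
        try:
            s = sample_fluxes(
                model,
                n=config.sampler.n,
                seed=seed,
                warmup=config.sampler.warmup,
                thinning=config.sampler.thinning,
                n_chains=config.sampler.n_chains,
            )
        except Exception as exc:
            raise PipelineError(f"sampling[{kind}:{label}]: {exc}") from exc
        path = out / f"samples_{kind}_{label}.tsv"
        write_samples(s, path)
        sample_files[f"{kind}:{label}"] = path.name
        samples[(kind, label)] = s
        log_lines.append(f"sampled[{kind}:{label}]: n={s.n_samples} seed={seed}")

    # ---- comparison ----------------------------------------------------
    stage("comparison")
    report = compare_distributions(
        samples[("constrained", config.condition_a)],
        samples[("constrained", config.condition_b)],
        shift_threshold=config.shift_threshold,
        overlap_threshold=config.overlap_threshold,
    )
    report.to_frame().to_csv(out / "shift_report.tsv", sep="\t", index=False)
    reversed_ids = flag_reversed_reactions(report)
    (out / "reversed_reactions.tsv").write_text(
        "reaction_id\n" + "".join(f"{r}\n" for r in reversed_ids),
        encoding="utf-8",
    )
    log_lines.append(f"reversed_reactions: {','.join(reversed_ids) or '(none)'}")

    control_report = compare_distributions(
        samples[("control", config.condition_a)],
        samples[("control", config.condition_b)],
        shift_threshold=config.shift_threshold,
        overlap_threshold=config.overlap_threshold,
    )
    control_report.to_frame().to_csv(
        out / "shift_report_control.tsv", sep="\t", index=False
    )

    # ---- metabolite statistics ----------------------------------------
    if config.metabolomics:
        stage("metabolite_stats")
        table = read_metabolite_table(
            config.metabolomics, config.metabolomics_groups
        )
        try:
            stats = ratio_panel(table, list(config.ratio_pairs) or [])
            if stats:
                pd.DataFrame(
                    [
                        {
                            "numerator": r.numerator,
                            "denominator": r.denominator,
                            **{f"mean_{g}": v for g, v in r.group_means.items()},
                            **{f"sd_{g}": v for g, v in r.group_sds.items()},
                            "t": r.t_statistic,
                            "p": r.p_value,
                            "q": r.q_value,
                        }
                        for r in stats
                    ]
                ).to_csv(out / "ratio_stats.tsv", sep="\t", index=False)
            energy = adenylate_indices(table)
            energy.summary.to_csv(
                out / "energy_state_summary.tsv", sep="\t", index=False
            )
            energy.tests.to_csv(
                out / "energy_state_tests.tsv", sep="\t", index=False
            )
            fold_changes(table).to_csv(out / "fold_changes.tsv", sep="\t")
        except Exception as exc:
            raise PipelineError(f"metabolite_stats: {exc}") from exc

    # ---- manifest and log ---------------------------------------------
    stage("manifest")
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    config_dict = dataclasses.asdict(config)
    (out / "config.yaml").write_text(
        yaml.safe_dump(config_dict, sort_keys=True), encoding="utf-8"
    )
    artifacts = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": config.seed,
        "sample_files": sample_files,
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in artifacts
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return out


def render_report(run_dir: Union[str, Path], n_bins: int = 50) -> Path:
    """Regenerate per-reaction histogram tables from a completed run.

    Writes ``report/hist_<kind>_<reaction>.tsv`` (bin edges and frequencies
    for both conditions over shared bins) for every reaction in the shift
    report, plus a copy of the shift table.  Idempotent; fails with the list
    of missing artifacts if the run is incomplete.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    required = [manifest_path, run_dir / "shift_report.tsv"]
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        required += [
            run_dir / name for name in manifest.get("sample_files", {}).values()
        ]
    missing = [str(p) for p in required if not p.exists()]
    if missing:
        raise PipelineError(f"incomplete run; missing artifacts: {missing}")

    report_dir = run_dir / "report"
    report_dir.mkdir(exist_ok=True)
    shift = pd.read_csv(run_dir / "shift_report.tsv", sep="\t")
    shift.to_csv(report_dir / "shift_report.tsv", sep="\t", index=False)

    by_kind: Dict[str, List[Tuple[str, Path]]] = {}
    for key, name in manifest.get("sample_files", {}).items():
        kind, label = key.split(":", 1)
        by_kind.setdefault(kind, []).append((label, run_dir / name))
    for kind, entries in by_kind.items():
        loaded = [(label, read_samples(path)) for label, path in entries]
        shared = set.intersection(
            *(set(s.reaction_ids) for _, s in loaded)
        )
        for rid in sorted(shared):
            cols = {}
            pooled = np.concatenate(
                [s.column(rid) for _, s in loaded]
            )
            lo, hi = pooled.min(), pooled.max()
            if hi - lo <= 1e-12:
                lo, hi = lo - 0.5, hi + 0.5
            edges = np.linspace(lo, hi, n_bins + 1)
            cols["bin_left"] = edges[:-1]
            cols["bin_right"] = edges[1:]
            for label, s in loaded:
                counts, _ = np.histogram(s.column(rid), bins=edges)
                cols[f"freq_{label}"] = counts / max(counts.sum(), 1)
            pd.DataFrame(cols).to_csv(
                report_dir / f"hist_{kind}_{rid}.tsv", sep="\t", index=False
            )

    metabolite_tables = [
        "ratio_stats.tsv",
        "energy_state_summary.tsv",
        "energy_state_tests.tsv",
        "fold_changes.tsv",
    ]
    present = [t for t in metabolite_tables if (run_dir / t).exists()]
    for t in present:
        (report_dir / t).write_bytes((run_dir / t).read_bytes())
    if not present:
        (report_dir / "metabolite_stats_absent.txt").write_text(
            "no metabolomics input was supplied to this run\n",
            encoding="utf-8",
        )
    return report_dir
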