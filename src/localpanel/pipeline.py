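"""Pipeline orchestration: simulate -> qc -> impute/crossval -> report.

Runs the full desk-scale experiment from one declarative config, writing
every intermediate in an interchange format (VCF, IMPUTE2 hap/legend/
sample, genetic map, TSV) plus a manifest recording stage order, input
hashes and the seed.  Any stage failure raises a stage-tagged error;
outputs written before the failure are retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .crossval import (improvement_grid, poor_to_well_crosstab, run_crossval,
                       summarize_bins)
from .io import (config_hash, write_genetic_map, write_impute2_panel,
                 write_tsv, write_vcf)
from .lshmm import HmmParams
from .qc import (QcThresholds, apply_sequence_qc, filter_subject_call_rate,
                 merge_array_sequence, restrict_to_global_panel)
from .synthpop import SimConfig, inject_switch_errors, simulate_populations

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]

log = logging.getLogger("localpanel")


class PipelineStageError(RuntimeError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    hmm: HmmParams = field(default_factory=HmmParams)
    out_dir: str = "localpanel_run"
    seed: int = 0
    log_level: str = "INFO"
    genetic_map: str | None = None  # external map file; simulated map if None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            if isinstance(sim.get("quality_model"), dict):
                from .synthpop import QualityModel
                sim["quality_model"] = QualityModel(**sim["quality_model"])
            d["sim"] = SimConfig(**sim)
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QcThresholds(**d["qc"])
        if "hmm" in d and isinstance(d["hmm"], dict):
            d["hmm"] = HmmParams(**d["hmm"])
        return cls(**d)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    sim_cfg = dataclasses.replace(config.sim, seed=seed)
    manifest: dict = {"tool": f"localpanel v{__version__}", "seed": seed,
                      "config_hash": config_hash(config.to_dict()),
                      "stages": []}

    def record(stage, outputs):
        manifest["stages"].append({"stage": stage,
                                   "outputs": [str(p) for p in outputs]})

    # -- simulate ----------------------------------------------------------
    @_stage("simulate")
    def do_simulate():
        truth = simulate_populations(sim_cfg)
        outputs = [
            write_impute2_panel(truth.global_panel, out / "global_panel",
                                seed=seed, config=sim_cfg)[0],
            write_vcf(truth.local_truth, out / "local_truth.vcf",
                      seed=seed, config=sim_cfg),
            write_vcf(truth.local_called_genotypes, out / "local_called.vcf",
                      seed=seed, config=sim_cfg),
            write_genetic_map(truth.site_map, out / "genetic_map.txt",
                              seed=seed, config=sim_cfg),
        ]
        import pandas as pd
        dose = truth.local_truth.to_genotypes()
        truth_df = pd.DataFrame(dose.calls.T,
                                columns=[str(s) for s in dose.subjects])
        truth_df.insert(0, "site_id", truth.site_map.ids)
        outputs.append(write_tsv(truth_df, out / "truth_dosage.tsv",
                                 seed=seed, config=sim_cfg))
        record("simulate", outputs)
        return truth

    truth = do_simulate()

    # external genetic map overrides the simulated one
    @_stage("genetic_map")
    def do_map():
        from .io import genetic_positions, read_genetic_map
        p = Path(config.genetic_map)
        if not p.exists():
            raise FileNotFoundError(str(p))
        map_df = read_genetic_map(p)
        truth.site_map.cm = genetic_positions(map_df, truth.site_map.pos)

    if config.genetic_map is not None:
        do_map()

    # -- qc ----------------------------------------------------------------
    @_stage("qc")
    def do_qc():
        seq = truth.local_called_genotypes.take_sites(truth.site_map.is_exomic)
        seq_qc, rep_seq = apply_sequence_qc(seq, config.qc)
        merged, rep_merge = merge_array_sequence(truth.local_array_calls,
                                                 seq_qc)
        merged, rep_panel = restrict_to_global_panel(merged,
                                                     truth.global_panel)
        merged, rep_subj = filter_subject_call_rate(merged)
        import pandas as pd
        frames = [r.to_frame() for r in (rep_seq, rep_merge, rep_panel,
                                         rep_subj)]
        report = pd.concat(frames, ignore_index=True)
        outputs = [
            write_tsv(report, out / "qc_report.tsv", seed=seed, config=sim_cfg),
            write_vcf(merged, out / "qc_filtered.vcf", seed=seed,
                      config=sim_cfg),
        ]
        record("qc", outputs)
        return merged, rep_merge

    do_qc()

    # -- crossval ----------------------------------------------------------
    @_stage("crossval")
    def do_crossval():
        local_panel = truth.local_truth
        if sim_cfg.phase_switch_rate > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, 2 ** 20]))
            local_panel = inject_switch_errors(local_panel,
                                               sim_cfg.phase_switch_rate, rng)
        table = run_crossval(truth, config.hmm, local_panel=local_panel)
        outputs = [write_tsv(table, out / "accuracy_records.tsv", seed=seed,
                             config=sim_cfg)]
        t1 = summarize_bins(table, bin_by="local")
        outputs.append(write_tsv(t1.round(3), out / "table1.tsv", seed=seed,
                                 config=sim_cfg))
        strata = summarize_bins(table, bin_by="global")
        outputs.append(write_tsv(strata.round(3), out / "global_strata.tsv",
                                 seed=seed, config=sim_cfg))
        import pandas as pd
        frac_poor, rescued = poor_to_well_crosstab(table)
        cross = pd.DataFrame([{"frac_poor_one_panel": frac_poor,
                               "frac_poor_rescued_two_panel": rescued}])
        outputs.append(write_tsv(cross.round(4), out / "crosstab.tsv",
                                 seed=seed, config=sim_cfg))
        means, counts = improvement_grid(table)
        outputs.append(write_tsv(means.round(3), out / "grid_mean.tsv",
                                 seed=seed, config=sim_cfg, index=True))
        outputs.append(write_tsv(counts, out / "grid_counts.tsv", seed=seed,
                                 config=sim_cfg, index=True))
        record("crossval", outputs)
        return table

    do_crossval()

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
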