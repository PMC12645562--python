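"""End-to-end pipeline: simulate or ingest, correct, enrich, summarize, test.

File dialects (all UTF-8, comma-separated, mandatory header row, leading
``#`` comment lines carrying the seed and a configuration hash so every
output is traceable to the run that produced it):

* ``mids.csv`` — sample_id, group, tissue, metabolite, n_carbons, m0...mN
  (raw isotopologue intensities; ragged tails empty).
* ``ground_truth.csv`` — uncorrupted simulator MIDs plus configured fluxes.
* ``ltt.csv`` — animal_id, group, time_min, lactate_mM.
* ``enrichments.csv`` — corrected fractions plus molecular enrichment,
  normalized ratio and cycling ratio per sample/metabolite (>= 9 significant
  digits; undefined ratios are empty fields with a reason code in ``flags``).
* ``cycling.csv`` — the 3-carbon subset with the cycling statistic.
* ``auc.csv`` — per-animal trapezoidal AUC.
* ``stats_report.json`` — decision-tree results with full audit trails.

Normalization follows the compartment rule: plasma metabolites normalize to
plasma lactate, tissue metabolites to the same tissue's lactate, always within
the same animal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinetics, simulate, stats
from .isotope import DEFAULT_P13, DEFAULT_TRACER_PURITY, DataError, process_mid_table

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Everything a pipeline run needs; echoed (hashed) into every output file."""

    out_dir: str = "results"
    seed: int = 0
    p13: float = DEFAULT_P13
    tracer_purity: float = DEFAULT_TRACER_PURITY
    tracer_metabolite: str = "lactate"
    preset: str = "cohort-default"
    n_animals: int = 5
    noise_cv: float = 0.05
    ltt_noise_sd: float = 0.4
    ltt_n_animals: int = 15
    baseline_subtract: bool = False
    mids_path: str | None = None
    ltt_path: str | None = None
    extra: dict = field(default_factory=dict)

    def hash(self) -> str:
        # the output directory does not affect the computation: two runs of
        # the same configuration into different folders share a hash
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _write_csv(frame: pd.DataFrame, path: Path, config: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"# lactrace {__version__}\n"
        f"# seed: {config.seed}\n"
        f"# config_hash: {config.hash()}\n"
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False, float_format="%.10g")


def read_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#")
    if frame.empty:
        raise DataError(f"{path}: no data rows")
    return frame


# ---------------------------------------------------------------------------
# Commands
# ---------------------------------------------------------------------------

PRESETS = ("cohort-default",)


def cmd_simulate(config: RunConfig) -> dict[str, Path]:
    """Simulate the tracing cohort and the tolerance tests; write the raw tables."""
    if config.preset not in PRESETS:
        raise DataError(f"unknown preset '{config.preset}'; available: {PRESETS}")
    out = Path(config.out_dir)
    mids, truth = simulate.emit_cohort(
        n_animals=config.n_animals,
        noise_cv=config.noise_cv,
        seed=config.seed,
        p13=config.p13,
        tracer_purity=config.tracer_purity,
    )
    presets = kinetics.default_ltt_presets(noise_sd=config.ltt_noise_sd)
    curves = []
    for i, (group, params) in enumerate(presets.items()):
        params.seed = config.seed * 1009 + i  # distinct, reproducible per group
        curves.extend(kinetics.simulate_ltt(params, config.ltt_n_animals, group=group))
    ltt = kinetics.curves_to_frame(curves)
    paths = {
        "mids": out / "mids.csv",
        "ground_truth": out / "ground_truth.csv",
        "ltt": out / "ltt.csv",
    }
    _write_csv(mids, paths["mids"], config)
    _write_csv(truth, paths["ground_truth"], config)
    _write_csv(ltt, paths["ltt"], config)
    return paths


def cmd_correct(config: RunConfig) -> pd.DataFrame:
    """Correct the MID table and compute all tracer statistics (enrichments.csv)."""
    mids_path = config.mids_path or str(Path(config.out_dir) / "mids.csv")
    mids = read_csv(mids_path)
    enriched = process_mid_table(
        mids,
        p13=config.p13,
        tracer_purity=config.tracer_purity,
        tracer_metabolite=config.tracer_metabolite,
    )
    _write_csv(enriched, Path(config.out_dir) / "enrichments.csv", config)
    cyc = enriched[enriched["n_carbons"] == 3][
        ["sample_id", "group", "tissue", "metabolite", "cycling_ratio", "flags"]
    ]
    _write_csv(cyc, Path(config.out_dir) / "cycling.csv", config)
    return enriched


def cmd_ltt_auc(config: RunConfig) -> pd.DataFrame:
    """Per-animal trapezoidal AUC table from ltt.csv."""
    ltt_path = config.ltt_path or str(Path(config.out_dir) / "ltt.csv")
    curves = kinetics.frame_to_curves(read_csv(ltt_path))
    auc = pd.DataFrame.from_records([
        {
            "animal_id": c.animal_id,
            "group": c.group,
            "auc_mM_min": kinetics.auc_trapezoid(c, baseline_subtract=config.baseline_subtract),
        }
        for c in curves
    ])
    _write_csv(auc, Path(config.out_dir) / "auc.csv", config)
    return auc


def _result_to_dict(res: stats.GroupComparisonResult) -> dict:
    return {
        "endpoint": res.endpoint,
        "path": res.path,
        "transformation": res.transformation,
        "omnibus_test": res.omnibus_test,
        "omnibus_statistic": res.omnibus_statistic,
        "omnibus_p": res.omnibus_p,
        "posthoc_method": res.posthoc_method,
        "pairwise": {f"{a} vs {b}": p for (a, b), p in res.pairwise.items()},
        "excluded": [
            {"group": g, "value": v, "reason": r} for g, v, r in res.excluded
        ],
        "audit": res.audit,
    }


def cmd_stats(config: RunConfig, enriched: pd.DataFrame | None = None,
              auc: pd.DataFrame | None = None) -> dict:
    """Run the decision tree on every endpoint and write stats_report.json."""
    if enriched is None:
        enriched = cmd_correct(config)
    if auc is None:
        auc = cmd_ltt_auc(config)
    report: dict[str, dict] = {}

    def endpoint(name: str, column: str, block: pd.DataFrame) -> None:
        values = {
            g: sub[column].dropna().to_numpy()
            for g, sub in block.groupby("group", sort=False)
        }
        values = {g: v for g, v in values.items() if v.size >= 3}
        if len(values) < 2:
            return
        pooled = np.concatenate(list(values.values()))
        if np.ptp(pooled) == 0:
            return  # degenerate endpoint (e.g. the tracer's own unit ratio)
        try:
            report[name] = _result_to_dict(stats.select_and_compare(values, endpoint=name))
        except DataError as exc:
            report[name] = {"endpoint": name, "error": str(exc)}

    for (tissue, metabolite), block in enriched.groupby(["tissue", "metabolite"], sort=False):
        endpoint(f"{tissue}/{metabolite}/normalized_ratio", "normalized_ratio", block)
        if int(block["n_carbons"].iloc[0]) == 3:
            endpoint(f"{tissue}/{metabolite}/cycling_ratio", "cycling_ratio", block)
    endpoint("ltt/auc", "auc_mM_min", auc)

    ltt_path = config.ltt_path or str(Path(config.out_dir) / "ltt.csv")
    curves = kinetics.frame_to_curves(read_csv(ltt_path))
    report["ltt/curves"] = _result_to_dict(stats.compare_curves(curves))

    out_path = Path(config.out_dir) / "stats_report.json"
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w", encoding="utf-8") as fh:
        json.dump(
            {"seed": config.seed, "config_hash": config.hash(), "endpoints": report},
            fh, indent=2,
        )
    return report


def cmd_analyze(config: RunConfig) -> dict:
    """Full analysis chain: correct -> enrich -> ratios -> AUC -> statistics."""
    enriched = cmd_correct(config)
    auc = cmd_ltt_auc(config)
    return cmd_stats(config, enriched=enriched, auc=auc)


def cmd_all(config: RunConfig) -> dict:
    """simulate then analyze, end to end, under one seed."""
    cmd_simulate(config)
    return cmd_analyze(config)
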