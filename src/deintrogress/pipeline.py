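"""One-call orchestration of the full de-introgression analysis.

``run_pipeline`` executes: locus filtering -> admixture estimation ->
hybrid-class simulation/threshold calibration -> classification and recovery
trajectory -> temporal drift-vs-selection scan -> genomic-cline introgression
tests, writing every stage's table (TSV with provenance headers) under the
configured output directory and returning the tables in memory.

A single global seed fans out to fixed per-stage offsets so any stage can be
rerun in isolation and reproduce byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .admixture import estimate_admixture, hybrid_index
from .genotype_io import (
    CollectionMeta,
    GenotypeMatrix,
    filter_loci,
    read_genotype_table,
)
from .genomic_clines import (
    classify_introgression,
    fit_clines,
    select_informative_loci,
    simulate_neutral_null,
)
from .hybrid_classes import (
    CLASS_NAMES,
    COARSE_WILD_MAX,
    PAPER_THRESHOLDS,
    calibrate_thresholds,
    classify,
    recovery_trajectory,
    simulate_hybrid_class,
    summarize_simulated_classes,
)
from .popgen import allele_freqs
from .synthetic_data import ScenarioConfig, simulate_stocking_scenario
from .temporal_selection import scan_selection

logger = logging.getLogger("deintrogress")

# fixed per-stage seed offsets (global seed + offset, kept below 2**31)
STAGE_SEED_OFFSETS = {
    "simulate": 101,
    "admixture": 202,
    "class_sim": 303,
    "selection": 404,
    "clines": 505,
}


@dataclass
class PipelineConfig:
    """Everything one run needs; see field comments for units/defaults."""

    # input: either a genotype file + metadata, or a synthetic scenario
    genotype_path: str | None = None
    genotype_format: str = "wide_csv"
    metadata_path: str | None = None
    scenario: ScenarioConfig | None = None

    out_dir: str = "results/pipeline"
    seed: int = 0

    # filtering
    maf_min: float = 0.05
    r2_max: float = 0.8
    polymorphic_in: tuple[str, ...] = ()

    # admixture
    n_restarts: int = 5
    n_bootstrap: int = 200
    admixture_ci_level: float = 0.90

    # classification
    threshold_source: str = "calibrate"  # or "paper_default"
    n_sim_per_class: int = 50

    # selection scan
    Ne_list: tuple[int, ...] = (100, 200)
    generation_time: float = 3.5

    # clines
    cline_top_frac: float = 0.05
    cline_fst_min: float = 0.03
    cline_null_individuals: int = 2000
    cline_null_refits: int = 999
    external_outliers: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a run configuration (optionally with a nested scenario block)."""
        import yaml

        from .synthetic_data import ScenarioConfig, SelectedLocus

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scenario = raw.pop("scenario", None)
        if scenario is not None:
            selected = [
                SelectedLocus(**s) for s in scenario.pop("selected_loci", [])
            ]
            for key in ("stocking_schedule", "maf_bounds", "rivers", "selected_freqs"):
                if key in scenario and scenario[key] is not None:
                    scenario[key] = tuple(scenario[key])
            if "sampling_schedule" in scenario:
                scenario["sampling_schedule"] = tuple(
                    tuple(x) for x in scenario["sampling_schedule"]
                )
            raw["scenario"] = ScenarioConfig(
                selected_loci=tuple(selected), **scenario
            )
        for key in ("polymorphic_in", "Ne_list", "external_outliers"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir", None)  # analytical settings only, not output location
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        return (self.seed + STAGE_SEED_OFFSETS[stage]) % (2**31)


def _write_table(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    header = (
        f"# deintrogress {__version__}; seed={config.seed}; "
        f"config_hash={config.config_hash()}\n"
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    paths: dict[str, Path]
    thresholds: object
    warnings: list[str] = field(default_factory=list)


def run_pipeline(
    config: PipelineConfig,
    gm: GenotypeMatrix | None = None,
    meta: Sequence[CollectionMeta] | None = None,
) -> PipelineResult:
    """Run every stage on file, in-memory or simulated input.

    Input priority: explicit (gm, meta) arguments, then ``genotype_path``,
    then ``scenario``. Raises with the failing stage's name on error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    paths: dict[str, Path] = {}
    warnings_list: list[str] = []
    t0 = time.perf_counter()
    log_lines: list[str] = []

    def stage_done(name: str) -> None:
        log_lines.append(f"{name}\t{time.perf_counter() - t0:.2f}s")
        logger.info("stage %s done at %.2fs", name, time.perf_counter() - t0)

    def fail(stage: str, err: Exception) -> RuntimeError:
        manifest = out / "partial_manifest.txt"
        manifest.write_text("\n".join(str(p) for p in paths.values()) + "\n")
        exc = RuntimeError(f"pipeline stage {stage!r} failed: {err}")
        exc.__cause__ = err
        return exc

    # ---- input -------------------------------------------------------------
    try:
        if gm is None:
            if config.genotype_path is not None:
                gm, meta = read_genotype_table(
                    config.genotype_path, config.genotype_format, config.metadata_path
                )
            elif config.scenario is not None:
                scenario = config.scenario
                if scenario.seed != config.stage_seed("simulate"):
                    scenario = ScenarioConfig(
                        **{**asdict_scenario(scenario), "seed": config.stage_seed("simulate")}
                    )
                gm, meta, _truth = simulate_stocking_scenario(scenario)
            else:
                raise ValueError("no input: set genotype_path or scenario")
        if meta is None or not len(meta):
            raise ValueError("metadata required")
    except Exception as e:  # noqa: BLE001
        raise fail("input", e)
    stage_done("input")

    bysample = {m.sample_id: m for m in meta}

    # ---- filter ------------------------------------------------------------
    try:
        gm_f, report = filter_loci(
            gm,
            meta,
            maf_min=config.maf_min,
            r2_max=config.r2_max,
            polymorphic_in=config.polymorphic_in,
        )
        tables["filter_report"] = report.removed
        paths["filter_report"] = out / "filter_report.tsv"
        _write_table(report.removed, paths["filter_report"], config)
    except Exception as e:  # noqa: BLE001
        raise fail("filter", e)
    stage_done("filter")

    # ---- admixture ---------------------------------------------------------
    try:
        hat_ref = [s for s in gm_f.individuals if bysample[s].role == "hatchery_reference"]
        wild_ref = [s for s in gm_f.individuals if bysample[s].role == "wild_reference"]
        if not hat_ref:
            raise ValueError("no hatchery_reference individuals in metadata")
        labels = {s: "hat_ref" for s in hat_ref}
        labels.update({s: "wild_ref" for s in wild_ref})
        # separate K=2 run per river: between-river structure otherwise leaks
        # into the wild/hatchery axis and biases q in opposite directions
        rivers = sorted(
            {bysample[s].river for s in gm_f.individuals if bysample[s].role == "wild_caught"}
        )
        ref_ids = wild_ref + hat_ref
        frames = []
        for i, river in enumerate(rivers):
            river_ids = [
                s
                for s in gm_f.individuals
                if bysample[s].role == "wild_caught" and bysample[s].river == river
            ]
            sub = gm_f.subset(ref_ids + river_ids)
            fit = estimate_admixture(
                sub,
                labels,
                n_restarts=config.n_restarts,
                n_bootstrap=config.n_bootstrap,
                ci_level=config.admixture_ci_level,
                seed=config.stage_seed("admixture") + i,
            )
            tbl = fit.as_table()
            frames.append(tbl[tbl["sample_id"].isin(river_ids)])
            if not fit.converged:
                warnings_list.append(
                    f"admixture restarts disagreed beyond 0.01 in q ({river})"
                )
        # reference individuals are pinned by definition
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": ref_ids,
                    "q": [0.0] * len(wild_ref) + [1.0] * len(hat_ref),
                    "ci_low": [0.0] * len(wild_ref) + [1.0] * len(hat_ref),
                    "ci_high": [0.0] * len(wild_ref) + [1.0] * len(hat_ref),
                    "n_loci_used": [
                        int(n) for n in (~gm_f.missing[[gm_f.individual_index(s) for s in ref_ids]]).sum(axis=1)
                    ],
                }
            )
        )
        q_table = pd.concat(frames, ignore_index=True)
        q_table["collection_label"] = [
            bysample[s].collection_label for s in q_table["sample_id"]
        ]
        q_table["river"] = [bysample[s].river for s in q_table["sample_id"]]
        q_table["year"] = [bysample[s].year for s in q_table["sample_id"]]
        q_table["role"] = [bysample[s].role for s in q_table["sample_id"]]
        tables["admixture_q"] = q_table
        paths["admixture_q"] = out / "admixture_q.tsv"
        _write_table(q_table, paths["admixture_q"], config)
    except Exception as e:  # noqa: BLE001
        raise fail("admixture", e)
    stage_done("admixture")

    # ---- hybrid-class simulation + thresholds ------------------------------
    try:
        wild_proxy = _wild_proxies(q_table, wild_ref)
        freqs = allele_freqs(
            gm_f, groups={"WILD_PROXY": wild_proxy, "HAT": hat_ref}
        )
        wild_freqs, hat_freqs = freqs["WILD_PROXY"], freqs["HAT"]
        sim_q = {}
        rng_seed = config.stage_seed("class_sim")
        sims = {}
        for i, cname in enumerate(CLASS_NAMES):
            sim_gm = simulate_hybrid_class(
                wild_freqs, hat_freqs, cname, n=config.n_sim_per_class,
                seed=rng_seed + i,
            )
            sims[cname] = sim_gm
            sim_fit = hybrid_index(sim_gm, wild_freqs, hat_freqs)
            sim_q[cname] = sim_fit.h
        if config.threshold_source == "calibrate":
            thresholds, class_report = calibrate_thresholds(sim_q)
        elif config.threshold_source == "paper_default":
            thresholds = PAPER_THRESHOLDS
            class_report = summarize_simulated_classes(sim_q)
        else:
            raise ValueError(
                f"unknown threshold_source {config.threshold_source!r}"
            )
        tables["class_simulation"] = class_report
        paths["class_simulation"] = out / "class_simulation.tsv"
        _write_table(class_report, paths["class_simulation"], config)
    except Exception as e:  # noqa: BLE001
        raise fail("class_sim", e)
    stage_done("class_sim")

    # ---- classify + trajectory --------------------------------------------
    try:
        wild_caught = q_table[q_table["role"] == "wild_caught"]
        summary = classify(
            wild_caught[["sample_id", "collection_label", "q"]], thresholds
        )
        tables["class_assignments"] = summary.per_individual
        tables["class_fractions"] = summary.per_collection
        paths["class_assignments"] = out / "class_assignments.tsv"
        paths["class_fractions"] = out / "class_fractions.tsv"
        _write_table(summary.per_individual, paths["class_assignments"], config)
        _write_table(summary.per_collection, paths["class_fractions"], config)
        years = {
            m.collection_label: m.year for m in meta if m.role == "wild_caught"
        }
        traj_frames = []
        for river in rivers:
            wc_river = wild_caught[wild_caught["river"] == river]
            if wc_river["collection_label"].nunique() < 2:
                continue
            summary_r = classify(
                wc_river[["sample_id", "collection_label", "q"]], thresholds
            )
            traj = recovery_trajectory(summary_r, years)
            traj = traj.copy()
            traj.insert(0, "river", river)
            traj["percent_change_mean_q"] = traj.attrs["percent_change_mean_q"]
            traj_frames.append(traj)
        if not traj_frames:
            raise ValueError("no river has >= 2 collections for a trajectory")
        traj_out = pd.concat(traj_frames, ignore_index=True)
        tables["trajectory"] = traj_out
        paths["trajectory"] = out / "trajectory.tsv"
        _write_table(traj_out, paths["trajectory"], config)
    except Exception as e:  # noqa: BLE001
        raise fail("classify", e)
    stage_done("classify")

    # ---- selection scan ----------------------------------------------------
    try:
        hybrid_class = dict(
            zip(summary.per_individual["sample_id"], summary.per_individual["hybrid_class"])
        )
        scan_frames = []
        for river in rivers:  # each river is its own population: scan separately
            river_ids = [
                s
                for s in gm_f.individuals
                if bysample[s].role == "wild_caught" and bysample[s].river == river
            ]
            scan_r = scan_selection(
                gm_f.subset(river_ids),
                meta,
                hybrid_class,
                Ne_list=config.Ne_list,
                generation_time=config.generation_time,
            )
            scan_r.insert(0, "river", river)
            scan_frames.append(scan_r)
        scan = pd.concat(scan_frames, ignore_index=True)
        tables["selection_scan"] = scan
        paths["selection_scan"] = out / "selection_scan.tsv"
        _write_table(scan, paths["selection_scan"], config)
    except Exception as e:  # noqa: BLE001
        raise fail("selection", e)
    stage_done("selection")

    # ---- genomic clines ----------------------------------------------------
    try:
        informative = select_informative_loci(
            gm_f,
            wild_proxy,
            hat_ref,
            loading_top_frac=config.cline_top_frac,
            fst_min=config.cline_fst_min,
            external_outliers=config.external_outliers,
        )
        loci = informative["locus_id"].tolist()
        wild_ids = set(wild_caught["sample_id"])
        cline_frames = []
        for i, river in enumerate(rivers):  # per-river cohorts, as for admixture
            cohort = [
                s
                for s in gm_f.individuals
                if s in wild_ids and bysample[s].river == river
            ]
            gm_cohort = gm_f.subset(cohort)
            hi = hybrid_index(gm_cohort, wild_freqs, hat_freqs)
            fits = fit_clines(gm_cohort, hi.h, wild_freqs, hat_freqs, loci=loci)
            null = simulate_neutral_null(
                hi.h,
                wild_freqs,
                hat_freqs,
                loci=loci,
                n_individuals=config.cline_null_individuals,
                n_refits=config.cline_null_refits,
                seed=config.stage_seed("clines") + i,
            )
            cline_r = classify_introgression(fits, null)
            cline_r.insert(0, "river", river)
            cline_frames.append(cline_r)
        cline_table = pd.concat(cline_frames, ignore_index=True)
        cline_table = cline_table.merge(informative, on="locus_id", how="left")
        tables["clines"] = cline_table
        paths["clines"] = out / "clines.tsv"
        _write_table(cline_table, paths["clines"], config)
    except Exception as e:  # noqa: BLE001
        raise fail("clines", e)
    stage_done("clines")

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(tables=tables, paths=paths, thresholds=thresholds, warnings=warnings_list)


def _wild_proxies(q_table: pd.DataFrame, wild_ref: Sequence[str]) -> list[str]:
    """WILD-proxy panel: explicit wild references when present, else the
    coarse q < 0.20 screen over wild-caught fish."""
    if len(wild_ref):
        return list(wild_ref)
    wc = q_table[q_table["role"] == "wild_caught"]
    proxies = wc.loc[wc["q"] < COARSE_WILD_MAX, "sample_id"].tolist()
    if not proxies:
        raise ValueError(
            f"no wild proxies: no wild_reference role and no wild-caught fish "
            f"with q < {COARSE_WILD_MAX}"
        )
    return proxies


def asdict_scenario(scenario: ScenarioConfig) -> dict:
    d = asdict(scenario)
    d["selected_loci"] = scenario.selected_loci
    d["stocking_schedule"] = scenario.stocking_schedule
    d["sampling_schedule"] = scenario.sampling_schedule
    d["rivers"] = scenario.rivers
    d["maf_bounds"] = scenario.maf_bounds
    return d
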