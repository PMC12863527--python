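"""Configuration and the stage driver tying the pipeline together.

Stage order follows the study workflow: simulate → screen → network →
pathway → mediate → mr.  One global seed fans out to per-stage seeds via
``numpy.random.SeedSequence(seed).spawn`` in that fixed stage order, so a
stage can be rerun in isolation with its own seed and reproduce the full
run.  Every run writes a log recording the thresholds actually used plus
a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from adipomet import anthropometry, io, mediation, mr, network, pathways
from adipomet import screening as scr
from adipomet import synthetic
from adipomet.schemas import write_schemas

STAGES = ("simulate", "screen", "network", "pathway", "mediate", "mr")

STEP1_COVARIATES = [
    "age", "education", "income", "diet_score", "smoking", "drinking",
    "physical_activity",
]
STEP2_COVARIATES = [
    "age", "diet_score", "smoking", "drinking", "bmi", "physical_activity",
    "chronic_hepatitis", "cirrhosis", "cholelithiasis", "t2dm",
]
MEDIATION_COVARIATES = [
    "age", "education", "income", "diet_score", "smoking", "drinking",
    "physical_activity", "chronic_hepatitis", "cirrhosis", "cholelithiasis",
    "t2dm",
]


@dataclass
class PipelineConfig:
    outdir: str = "adipomet_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # simulate
    n_pairs: int = 322
    n_metabolites: int = 186
    # screen
    fdr_level: float = 0.05
    rcs_knots: int = 4
    exposures: tuple[str, ...] = anthropometry.EXPOSURES
    # network
    pc_alpha: float = 0.05
    pc_max_cond_set: int = 3
    walktrap_steps: int = 4
    # pathway
    pathway_gmt: str | None = None
    pathway_topology_dir: str | None = None
    # mediate
    max_clusters: int = 10
    n_boot: int = 1000
    mediation_exposure: str = "bmi"
    # mr
    mr_p_threshold: float = 5e-8
    mr_p_threshold_metabolite: float = 5e-6
    mr_ld_r2: float = 0.001
    mr_window_kb: float = 10_000

    def validate(self):
        checks = [
            (0 < self.fdr_level < 1, "fdr_level in (0,1)"),
            (self.rcs_knots in (3, 4, 5), "rcs_knots in {3,4,5}"),
            (0 < self.pc_alpha < 1, "pc_alpha in (0,1)"),
            (self.pc_max_cond_set >= 0, "pc_max_cond_set >= 0"),
            (self.walktrap_steps >= 1, "walktrap_steps >= 1"),
            (self.n_boot >= 0, "n_boot >= 0"),
            (0 < self.mr_p_threshold < 1, "mr_p_threshold in (0,1)"),
            (self.max_clusters >= 1, "max_clusters >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["exposures"] = list(self.exposures)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["stages"] = tuple(d.get("stages", STAGES))
        d["exposures"] = tuple(d.get("exposures", anthropometry.EXPOSURES))
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return dict(zip(STAGES, children))


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Stage outputs land under ``config.outdir``; each stage logs the
    thresholds it used.  A stage failure halts every downstream stage and
    is recorded as a structured error in the returned bundle.  The pathway
    stage is skipped (with a logged reason) when no pathway library is
    configured or the file is missing; later stages do not depend on it.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("adipomet.pipeline")
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("config_hash=%s seed=%d stages=%s", config.hash(), config.seed,
             ",".join(config.stages))
    config.to_yaml(outdir / "config.yaml")
    write_schemas(outdir)

    seeds = stage_seeds(config.seed)
    bundle: dict = {"config_hash": config.hash(), "errors": []}
    halted = False
    t0 = time.time()

    def fail(stage, exc):
        nonlocal halted
        bundle["errors"].append(
            {"stage": stage, "error": type(exc).__name__, "message": str(exc)}
        )
        log.error("stage=%s failed: %s", stage, exc)
        halted = True

    sim = None
    try:
        if "simulate" in config.stages:
            cfg = synthetic.CohortSimConfig(
                n_pairs=config.n_pairs,
                n_metabolites=config.n_metabolites,
                seed=_seed_int(seeds["simulate"]),
            )
            sim = synthetic.generate_matched_cohort(cfg)
            derived = anthropometry.derive_indices(sim.cohort)
            sim.cohort = pd.concat([sim.cohort, derived], axis=1)
            io.write_cohort(sim.cohort, sim.metabolites, sim.annotations,
                            outdir / "cohort.tsv",
                            outdir / "metabolite_annotations.tsv")
            log.info("stage=simulate n_pairs=%d n_metabolites=%d",
                     config.n_pairs, config.n_metabolites)
            bundle["cohort"] = sim
    except Exception as exc:  # noqa: BLE001 - structured error record
        fail("simulate", exc)

    step1, step2, intermediates = {}, None, []
    if not halted and "screen" in config.stages and sim is not None:
        try:
            for expo in config.exposures:
                step1[expo] = scr.fit_exposure_metabolite(
                    sim.cohort, sim.metabolites, expo, STEP1_COVARIATES,
                    n_knots=config.rcs_knots, fdr_level=config.fdr_level,
                )
            step2 = scr.fit_conditional_logistic(
                sim.cohort, sim.metabolites, STEP2_COVARIATES,
                n_knots=config.rcs_knots, fdr_level=config.fdr_level,
            )
            intermediates, incidence = scr.meet_in_middle(step1, step2)
            pd.concat(step1.values()).to_csv(
                outdir / "screen_step1.tsv", sep="\t", index=False)
            step2.to_csv(outdir / "screen_step2.tsv", sep="\t", index=False)
            incidence.reset_index(names="metabolite").to_csv(
                outdir / "intermediates.tsv", sep="\t", index=False)
            log.info("stage=screen fdr=%.3f knots=%d n_intermediate=%d",
                     config.fdr_level, config.rcs_knots, len(intermediates))
            bundle["screen"] = {"step1": step1, "step2": step2,
                                "intermediates": intermediates}
        except Exception as exc:  # noqa: BLE001
            fail("screen", exc)

    if not halted and "network" in config.stages and len(intermediates) >= 2:
        try:
            controls = sim.cohort["is_case"] == 0
            rho, pmat = network.partial_spearman(
                sim.metabolites.loc[controls, intermediates],
                sim.cohort.loc[controls, ["age", "fasting_hours"]],
            )
            edges = network.pc_skeleton(
                sim.metabolites.loc[controls, intermediates].apply(np.log2),
                alpha=config.pc_alpha, max_cond_set=config.pc_max_cond_set,
            )
            edge_df = network.build_network(edges, rho)
            modules, degree = network.walktrap_modules(
                edge_df, nodes=intermediates, steps=config.walktrap_steps)
            edge_df.to_csv(outdir / "network_edges.tsv", sep="\t",
                           index=False)
            pd.DataFrame({"metabolite": modules.index,
                          "module": modules.to_numpy(),
                          "degree": degree.to_numpy()}).to_csv(
                outdir / "network_modules.tsv", sep="\t", index=False)
            log.info("stage=network alpha=%.3f max_cond=%d steps=%d "
                     "n_edges=%d n_modules=%d", config.pc_alpha,
                     config.pc_max_cond_set, config.walktrap_steps,
                     len(edge_df), modules.nunique())
            bundle["network"] = {"rho": rho, "edges": edge_df,
                                 "modules": modules, "degree": degree}
        except Exception as exc:  # noqa: BLE001
            fail("network", exc)

    if not halted and "pathway" in config.stages:
        gmt = config.pathway_gmt
        if gmt is None or not Path(gmt).exists():
            log.info("stage=pathway skipped reason=no_pathway_library")
            bundle["pathway"] = {"status": "skipped",
                                 "reason": "no_pathway_library"}
        else:
            try:
                sets = pathways.read_gmt(gmt)
                topo = {}
                if config.pathway_topology_dir:
                    for f in Path(config.pathway_topology_dir).glob("*.tsv"):
                        topo[f.stem] = pathways.read_topology(f)
                lib = pathways.PathwayLibrary(sets, topo)
                res = pathways.ora_hypergeometric(
                    set(intermediates), set(sim.metabolites.columns), lib)
                res.to_csv(outdir / "pathway_results.tsv", sep="\t",
                           index=False)
                log.info("stage=pathway n_pathways=%d", len(res))
                bundle["pathway"] = {"status": "ok", "results": res}
            except Exception as exc:  # noqa: BLE001
                fail("pathway", exc)

    if not halted and "mediate" in config.stages and intermediates:
        try:
            clusters = mediation.cluster_mediators(
                sim.metabolites[intermediates], config.max_clusters)
            med = mediation.parallel_mediation(
                sim.cohort, config.mediation_exposure, clusters,
                MEDIATION_COVARIATES, n_boot=config.n_boot,
                seed=_seed_int(seeds["mediate"]),
            )
            mediation.decomposition_table(med, clusters).to_csv(
                outdir / "mediation.tsv", sep="\t", index=False)
            log.info("stage=mediate exposure=%s max_clusters=%d boot=%d",
                     config.mediation_exposure, config.max_clusters,
                     config.n_boot)
            bundle["mediation"] = med
        except Exception as exc:  # noqa: BLE001
            fail("mediate", exc)

    if not halted and "mr" in config.stages:
        try:
            ss_cfg = synthetic.SumStatsSimConfig(
                theta_xm=0.3, theta_my=0.4, theta_xy_direct=0.1,
                seed=_seed_int(seeds["mr"]),
            )
            exp_s, med_s, out_s = synthetic.generate_sumstats(ss_cfg)
            res = mr.run_univariable(
                exp_s, out_s, p_threshold=config.mr_p_threshold,
                ld_r2=config.mr_ld_r2, window_kb=config.mr_window_kb,
                seed=_seed_int(seeds["mr"]),
            )
            tab = mr.estimates_table(res["estimates"], "exposure", "outcome")
            tab.to_csv(outdir / "mr_estimates.tsv", sep="\t", index=False)
            log.info("stage=mr p_thresh=%.1e ld_r2=%.4f window_kb=%.0f "
                     "n_estimates=%d", config.mr_p_threshold, config.mr_ld_r2,
                     config.mr_window_kb, len(tab))
            bundle["mr"] = res
        except Exception as exc:  # noqa: BLE001
            fail("mr", exc)

    log.info("done elapsed=%.1fs errors=%d", time.time() - t0,
             len(bundle["errors"]))
    log.removeHandler(handler)
    handler.close()
    return bundle
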