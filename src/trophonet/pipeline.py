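"""End-to-end pipeline: assess → rarefy → diversity → filter → networks →
topology → trend comparison, with a reproducibility manifest.

Every run is driven by a :class:`PipelineConfig`; the manifest written next
to the outputs records the config, its hash, the seed and library versions,
and alone suffices to re-run the analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .community import bray_curtis, diversity_table, rarefy
from .network import (
    build_network,
    compare_topologies,
    cross_kingdom_composition,
    filter_low_abundance,
    topology,
)
from .simulate import GradientScenario, generate_dataset
from .stats import env_community_correlation
from .trophic import assess_sites

logger = logging.getLogger(__name__)

GROUPS = ("L", "M", "H")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Either the five input paths or ``scenario_path`` (a synthetic-data
    scenario) must be set.  Defaults follow the study protocol: 27,000-read
    rarefaction, 0.01% abundance filter, |rho| ≥ 0.6 with BH q < 0.05 edge
    gate, 999 permutations, 10 Louvain restarts.
    """

    chemistry: str | None = None
    phyto_counts: str | None = None
    bact_counts: str | None = None
    taxonomy: str | None = None
    groups: str | None = None
    scenario_path: str | None = None
    rarefaction_depth: int = 27000
    filter_min_rel: float = 0.0001
    edge_threshold: float = 0.6
    alpha: float = 0.05
    n_perm: int = 999
    louvain_restarts: int = 10
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if not 0 < self.edge_threshold <= 1:
            raise ValueError("edge_threshold must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        has_files = all([self.chemistry, self.phyto_counts, self.bact_counts,
                         self.taxonomy, self.groups])
        if not has_files and self.scenario_path is None:
            raise ValueError("supply either all five input paths or scenario_path")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _stage_seed(seed: int, stage: int) -> int:
    """Per-stage substream below 2**31, derived from the run seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stage,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a result bundle (also on disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result: dict = {"config": asdict(config), "config_hash": config.config_hash()}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # ---- load or simulate ---------------------------------------------
    name = stage("load")
    try:
        if config.scenario_path is not None:
            scenario = io.read_scenario(config.scenario_path)
            scenario.seed = config.seed
            ds = generate_dataset(scenario)
            io.write_dataset(ds, outdir / "simulated")
            chemistry, phyto, bact = ds.chemistry, ds.phyto, ds.bact
            result["truth_sidecar"] = str(outdir / "simulated" / "truth.json")
        else:
            chemistry = io.read_chemistry(config.chemistry)
            phyto = io.read_abundance(config.phyto_counts, config.taxonomy, config.groups)
            bact = io.read_abundance(config.bact_counts, config.taxonomy, config.groups)
    except Exception as e:  # noqa: BLE001 - rethrown with stage context
        raise PipelineStageError(name, e) from e

    # ---- trophic assessment -------------------------------------------
    name = stage("trophic_assessment")
    try:
        assessments, summary = assess_sites(chemistry)
        io.write_assessments(assessments, chemistry, outdir / "assessments.csv")
        io.write_json(io.summary_to_dict(summary), outdir / "trophic_summary.json")
        result["trophic_summary"] = io.summary_to_dict(summary)
    except Exception as e:
        raise PipelineStageError(name, e) from e

    # ---- rarefaction + diversity --------------------------------------
    name = stage("diversity")
    try:
        bact_rare = rarefy(bact, config.rarefaction_depth, _stage_seed(config.seed, 1))
        div_b = diversity_table(bact_rare)
        div_p = diversity_table(phyto)
        div = pd.concat([div_p.assign(kingdom="phytoplankton"),
                         div_b.assign(kingdom="bacteria")])
        div.to_csv(outdir / "diversity.csv")
        result["diversity"] = div
    except Exception as e:
        raise PipelineStageError(name, e) from e

    # ---- distance matrices --------------------------------------------
    name = stage("distances")
    try:
        d_phyto = bray_curtis(phyto, use_relative=True)
        d_bact = bray_curtis(bact_rare, use_relative=False)
        io.write_distance_matrix(d_phyto, outdir / "bray_curtis_phyto.csv")
        io.write_distance_matrix(d_bact, outdir / "bray_curtis_bact.csv")
        result["distances"] = {"phyto": d_phyto, "bact": d_bact}
    except Exception as e:
        raise PipelineStageError(name, e) from e

    # ---- environment-community permutation correlations ---------------
    name = stage("env_association")
    try:
        chem_df = pd.DataFrame(
            [{"site_id": r.site_id, "tn": r.tn, "tp": r.tp,
              "chl_a": r.chl_a, "secchi": r.secchi} for r in chemistry]
        ).set_index("site_id")
        mantel_out = {}
        for label, dmat in result["distances"].items():
            common = [s for s in dmat.index if s in chem_df.index]
            sub = dmat.loc[common, common].to_numpy()
            mantel_out[label] = {}
            for vi, var in enumerate(("tn", "tp", "chl_a", "secchi")):
                res = env_community_correlation(
                    chem_df.loc[common, var].to_numpy(), sub,
                    n_perm=config.n_perm,
                    seed=_stage_seed(config.seed, 10 + vi),
                )
                mantel_out[label][var] = {
                    "r": res.r, "p": res.p, "n_perm": res.n_perm, "n": res.n,
                }
        io.write_json(mantel_out, outdir / "env_mantel.json")
        result["env_mantel"] = mantel_out
    except Exception as e:
        raise PipelineStageError(name, e) from e

    # ---- networks per group -------------------------------------------
    name = stage("networks")
    try:
        phyto_f = filter_low_abundance(phyto, config.filter_min_rel)
        bact_f = filter_low_abundance(bact_rare, config.filter_min_rel)
        # one combined table over the shared (pooled-filter) node set
        counts = pd.concat([phyto_f.counts, bact_f.counts]).fillna(0.0)
        combined = type(phyto)(
            counts=counts,
            taxonomy=pd.concat([phyto_f.taxonomy, bact_f.taxonomy])
            .loc[lambda d: ~d.index.duplicated()],
            group=phyto.group,
        )
        networks, topologies, composition = {}, [], {}
        for group in GROUPS:
            if combined.group is None or group not in set(combined.group.dropna()):
                continue
            net = build_network(
                combined, group=group,
                threshold_r=config.edge_threshold, alpha=config.alpha,
            )
            networks[group] = net
            top = topology(net, louvain_restarts=config.louvain_restarts,
                           seed=_stage_seed(config.seed, 20))
            topologies.append(top)
            composition[group] = cross_kingdom_composition(net)
            io.export_network(net, outdir / f"network_{group}")
        io.write_json({t.group: t.as_dict() for t in topologies},
                      outdir / "topology.json")
        io.write_json({g: c.to_dict(orient="records") for g, c in composition.items()},
                      outdir / "cross_kingdom.json")
        result["networks"] = networks
        result["topologies"] = topologies
        result["cross_kingdom"] = composition
    except Exception as e:
        raise PipelineStageError(name, e) from e

    # ---- trend comparison ---------------------------------------------
    name = stage("trends")
    try:
        if len(result["topologies"]) >= 2:
            trends = compare_topologies(result["topologies"])
            trends.to_csv(outdir / "trends.csv", index=False)
            result["trends"] = trends
    except Exception as e:
        raise PipelineStageError(name, e) from e

    # ---- manifest ------------------------------------------------------
    manifest = {
        "package": "trophonet",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    io.write_json(manifest, outdir / "manifest.json")
    result["manifest"] = manifest
    return result
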