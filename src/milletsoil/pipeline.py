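"""End-to-end orchestration: simulate -> indices -> diversity -> network
-> statistics -> report.

Stages communicate through files (CSV/TSV/JSON) in the output directory
so any stage can be inspected or rerun in isolation; a manifest records
the configuration hash and all seeds.  Every stochastic stage takes an
explicit seed, so a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import group_stats as gs
from . import indices as ind
from . import network as net
from . import synth, table1
from .io import (AbundanceTable, SoilSampleTable, load_soil_table,
                 write_abundance_table, write_soil_table)

log = logging.getLogger("milletsoil")


@dataclass
class PipelineConfig:
    """Configuration for a full run; round-trips losslessly to YAML."""

    seed: int = 1
    out_dir: str = "milletsoil_out"
    soil_csv: str | None = None       # None -> simulate
    replicates: int = 3
    community_replicates: int = 10    # networks need more samples
    kingdoms: tuple[str, ...] = ("bacteria", "fungi", "archaea")
    depth: int = 20000
    r_min: float = 0.6
    network_alpha: float = 0.05
    permanova_permutations: int = 999
    permanova_seed: int | None = None
    stats_alpha: float = 0.05
    skip_community: bool = False

    def validate(self) -> None:
        if self.permanova_seed is None and not self.skip_community:
            raise ValueError("permanova_seed must be set (reproducibility)")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if "kingdoms" in raw:
            raw["kingdoms"] = tuple(raw["kingdoms"])
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the scientific configuration (output location
        excluded, so reruns into different directories compare equal)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                         default=str).encode()
                              ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report bundle (also written to
    ``report.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: soil data ---------------------------------------------
    if config.soil_csv is not None:
        soil = load_soil_table(config.soil_csv)
        log.info("loaded soil table from %s", config.soil_csv)
    else:
        tc = synth.TrialConfig(replicates=config.replicates)
        soil = synth.generate_soil_dataset(tc, seed=config.seed)
        write_soil_table(soil, out / "soil.csv")
        log.info("simulated soil table (%d samples)", len(soil.data))

    # --- stage: indices -----------------------------------------------
    idx = ind.index_summary(soil)
    tc = synth.TrialConfig(replicates=config.replicates)
    yields = synth.generate_yields(tc, seed=config.seed + 1)
    yields["PFP_N"] = ind.compute_pfp(yields["yield_kg_ha"], tc.n_rate)
    yields["AE_N"] = ind.compute_aen(yields["yield_kg_ha"],
                                     yields["y0_kg_ha"], tc.n_rate)
    idx.to_csv(out / "sqi_emf_nue.csv", index=False)
    yields.to_csv(out / "yields_nue.csv", index=False)

    # --- stage: community ---------------------------------------------
    permanova_results = {}
    network_summaries = {}
    if not config.skip_community:
        ctc = synth.TrialConfig(replicates=config.community_replicates)
        csoil = synth.generate_soil_dataset(ctc, seed=config.seed + 2)
        for ki, kingdom in enumerate(config.kingdoms):
            cc = synth.CommunityConfig(kingdom=kingdom, depth=config.depth)
            table = synth.generate_abundance_dataset(
                cc, csoil, seed=config.seed + 10 + ki)
            write_abundance_table(table, out / f"abundance_{kingdom}.tsv")
            counts = (table.matrix * config.depth).round()
            alpha_df = comm.alpha_diversity_table(counts)
            alpha_df.to_csv(out / f"alpha_{kingdom}.csv")
            dm = comm.bray_curtis(table.matrix.T.to_numpy())
            ordn = comm.pcoa(dm, k=2)
            pd.DataFrame(ordn.coordinates[:, :2],
                         index=table.samples,
                         columns=["PCo1", "PCo2"]).to_csv(
                out / f"pcoa_{kingdom}.csv")
            labels = [s.split("_")[0] for s in table.samples]
            pr = comm.permanova(dm, labels,
                                n_perm=config.permanova_permutations,
                                seed=config.permanova_seed)
            permanova_results[kingdom] = {
                "pseudo_F": pr.pseudo_f, "p_value": pr.p_value,
                "n_permutations": pr.n_permutations}
            # per-treatment networks from the strongly-coupled community
            # profile (correlations are not estimable otherwise)
            nets = {}
            ntable = synth.generate_abundance_dataset(
                synth.network_community_config(kingdom,
                                               depth=config.depth),
                csoil, seed=config.seed + 20 + ki)
            filtered = net.filter_taxa(ntable)
            for trt in table1.TREATMENTS:
                cols = [s for s, lab in zip(ntable.samples, labels)
                        if lab == trt]
                sub = AbundanceTable(kingdom,
                                     filtered.matrix[cols]).as_relative()
                try:
                    g = net.build_network(sub, r_min=config.r_min,
                                          alpha=config.network_alpha)
                except ValueError as exc:
                    log.warning("network for %s/%s failed: %s", kingdom,
                                trt, exc)
                    continue
                if g.number_of_edges() > 0:
                    modules, q = net.detect_modules(g, seed=config.seed)
                    roles = net.zipi(g, modules)
                    topo = net.topology(g, modules)
                    pd.DataFrame([dataclasses.asdict(r) for r in roles]
                                 ).to_csv(
                        out / f"node_roles_{kingdom}_{trt}.csv",
                        index=False)
                else:
                    topo = net.topology(g)
                net.edge_list(g).to_csv(
                    out / f"edges_{kingdom}_{trt}.tsv", sep="\t",
                    index=False)
                nets[trt] = topo.to_dict()
            network_summaries[kingdom] = nets
        with open(out / "permanova.json", "w", encoding="utf-8") as fh:
            json.dump(permanova_results, fh, indent=2)
        with open(out / "topology.json", "w", encoding="utf-8") as fh:
            json.dump(network_summaries, fh, indent=2, default=float)

    # --- stage: statistics and report ---------------------------------
    duncan_rows = []
    for year in sorted(soil.data["year"].unique()):
        sub = soil.subset(year=year)
        for var in sub.variables:
            res = gs.anova_duncan(sub.data[var], sub.data["treatment"],
                                  alpha=config.stats_alpha)
            duncan_rows.append({
                "variable": var, "year": int(year),
                "F": res.f_statistic, "p": res.p_value,
                **{f"mean_{g}": m for g, m in res.means.items()},
                **{f"letter_{g}": l for g, l in res.letters.items()}})
    pd.DataFrame(duncan_rows).to_csv(out / "anova_duncan.csv", index=False)

    summary = build_summary(soil, idx)
    report = gs.fold_change_report(summary)
    bundle = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "fold_changes": _jsonable(report),
        "permanova": permanova_results,
        "network_topology": network_summaries,
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2, default=float)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump({"config": dataclasses.asdict(config),
                   "digest": config.digest()}, fh, indent=2, default=str)
    return bundle


def build_summary(soil: SoilSampleTable,
                  idx: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format (variable, year, treatment, mean) summary from a
    replicate table, optionally including computed SQI/EMF."""
    frames = [soil.data]
    if idx is not None:
        frames = [soil.data.merge(idx, on=["treatment", "year",
                                           "replicate"])]
    df = frames[0]
    variables = [c for c in df.columns
                 if c not in ("treatment", "year", "replicate")]
    melted = df.melt(id_vars=["treatment", "year"], value_vars=variables,
                     var_name="variable", value_name="value")
    out = (melted.groupby(["variable", "year", "treatment"], observed=True)
           ["value"].mean().rename("mean").reset_index())
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return float(obj)
    return obj
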