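"""End-to-end pipeline driver: alpha -> beta -> vpa -> network -> integrated.

Each stage is independent where possible: a failing stage is recorded in
the provenance manifest and later stages that do not depend on it still
run.  All outputs are tidy CSVs carrying the config hash in a header
comment; re-running with the same config reproduces them byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd

from . import alpha as alpha_mod
from . import beta as beta_mod
from . import network as net_mod
from . import ordination as ord_mod
from .core import ENV_GROUP_MAP
from .io import TableSet, write_csv

log = logging.getLogger("ciliateco")


@dataclass
class PipelineConfig:
    """Everything a run needs; serializes losslessly to/from a dict."""

    output_dir: str = "results"
    # thresholds
    r_threshold: float = 0.2
    p_threshold: float = 0.05
    min_occurrence: int = 2
    min_rel_abund: float = 0.005
    # permutation counts
    n_perm: int = 999
    er_reps: int = 1000
    # NMDS
    nmds_dims: int = 2
    nmds_starts: int = 20
    nmds_max_iter: int = 300
    # ordination
    varpart_method: str = "rda"
    varpart_transform: str = "hellinger"
    forward_alpha: float = 0.05
    # seeds per stage
    seeds: dict = field(default_factory=lambda: {
        "beta": 101, "vpa": 202, "network": 303, "integrated": 404})
    shannon_base: str = "e"
    corr_method: str = "spearman"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def override_seed(self, seed: int) -> None:
        self.seeds = {k: (seed * 1000 + i) % (2**31)
                      for i, k in enumerate(sorted(self.seeds))}


def _stage_alpha(tables: TableSet, cfg: PipelineConfig, outdir: Path, h: str) -> dict:
    records = alpha_mod.alpha_metrics(tables.community, base=cfg.shannon_base)
    write_csv(records, outdir / "alpha_records.csv", h, index_label="sample_id")
    tukey_rows = []
    for metric in records.columns:
        for grouping in ("season", "zone"):
            try:
                t = alpha_mod.tukey_hsd(records[metric],
                                        tables.frame.grouping(grouping))
                t.insert(0, "grouping", grouping)
                t.insert(0, "metric", metric)
                tukey_rows.append(t)
            except ValueError as exc:
                log.warning("Tukey %s/%s skipped: %s", metric, grouping, exc)
    tukey = pd.concat(tukey_rows, ignore_index=True) if tukey_rows else pd.DataFrame()
    write_csv(tukey, outdir / "alpha_tukey.csv", h, index=False)
    shared = {
        grouping: alpha_mod.shared_species(tables.community,
                                           tables.frame.grouping(grouping))
        for grouping in ("season", "zone")
    }
    out = {"alpha_records": records, "tukey": tukey, "shared_species": shared}
    if tables.env is not None:
        corr = alpha_mod.alpha_env_correlation(records, tables.env,
                                               method=cfg.corr_method)
        write_csv(corr, outdir / "alpha_env_correlation.csv", h, index=False)
        out["alpha_env_correlation"] = corr
    return out


def _stage_beta(tables: TableSet, cfg: PipelineConfig, outdir: Path, h: str) -> dict:
    seed = cfg.seeds["beta"]
    dm = beta_mod.bray_curtis(tables.community)
    write_csv(pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)),
              outdir / "bray_curtis.csv", h, index_label="sample_id")
    coords, stress = beta_mod.nmds(dm, k=cfg.nmds_dims, n_starts=cfg.nmds_starts,
                                   max_iter=cfg.nmds_max_iter, seed=seed)
    write_csv(coords, outdir / "nmds_coordinates.csv", h, index_label="sample_id")
    tests = []
    season = tables.frame.grouping("season")
    zone = tables.frame.grouping("zone")
    tests.append({"test": "anosim", "grouping": "season",
                  **beta_mod.anosim(dm, season, cfg.n_perm, seed).as_dict()})
    tests.append({"test": "anosim", "grouping": "zone",
                  **beta_mod.anosim(dm, zone, cfg.n_perm, seed + 1).as_dict()})
    mantel_rows = []
    if tables.env is not None:
        for i, var in enumerate(tables.env.variables):
            try:
                res = beta_mod.mantel(dm, beta_mod.env_distance(tables.env, var),
                                      n_perm=cfg.n_perm, seed=seed + 10 + i)
                mantel_rows.append({"variable": var, **res.as_dict()})
            except ValueError as exc:
                mantel_rows.append({"variable": var, "statistic": float("nan"),
                                    "p_value": float("nan"),
                                    "n_permutations": cfg.n_perm,
                                    "seed": seed + 10 + i,
                                    "method": f"skipped: {exc}"})
    test_df = pd.DataFrame(tests)
    write_csv(test_df, outdir / "beta_tests.csv", h, index=False)
    mantel_df = pd.DataFrame(mantel_rows)
    write_csv(mantel_df, outdir / "mantel_env.csv", h, index=False)
    gd = beta_mod.group_dissimilarity(dm, zone, seed=seed + 500)
    write_csv(gd, outdir / "group_dissimilarity_zone.csv", h, index=False)
    return {"distance": dm, "nmds_coordinates": coords, "nmds_stress": stress,
            "tests": test_df, "mantel": mantel_df, "group_dissimilarity": gd}


def _stage_vpa(tables: TableSet, cfg: PipelineConfig, outdir: Path, h: str) -> dict:
    if tables.env is None:
        raise ValueError("VPA needs an environment table")
    seed = cfg.seeds["vpa"]
    axes = ord_mod.pcnm(tables.frame.data[["longitude", "latitude"]])
    write_csv(axes.scores, outdir / "pcnm_scores.csv", h, index_label="sample_id")
    sets = ord_mod.build_predictor_sets(tables.frame, tables.env, axes)

    traces, selected_sets = [], {}
    for name, X in sets.items():
        sel = ord_mod.forward_select(
            tables.community, X, alpha=cfg.forward_alpha, n_perm=cfg.n_perm,
            seed=seed, method=cfg.varpart_method,
            transform=cfg.varpart_transform)
        tr = sel.trace.copy()
        tr.insert(0, "set", name)
        traces.append(tr)
        if sel.selected:
            selected_sets[name] = X[sel.selected]
    write_csv(pd.concat(traces, ignore_index=True),
              outdir / "forward_selection_trace.csv", h, index=False)

    def run_part(tag: str, names: list[str]) -> pd.DataFrame | None:
        use = {n: selected_sets[n] for n in names if n in selected_sets}
        if len(use) < 2:
            log.warning("varpart %s skipped: fewer than 2 non-empty sets", tag)
            return None
        vp = ord_mod.varpart(tables.community, use, method=cfg.varpart_method,
                             transform=cfg.varpart_transform,
                             n_perm=cfg.n_perm, seed=seed)
        s = vp.as_series().rename("adjusted_r2").to_frame()
        s.insert(0, "partition", tag)
        return s.reset_index(names="fraction")

    temspa = pd.concat([selected_sets[n] for n in ("season", "vertical", "horizontal")
                        if n in selected_sets], axis=1)
    envsel = pd.concat([selected_sets[n] for n in ("physical", "chemical", "food")
                        if n in selected_sets], axis=1)
    parts = []
    if temspa.shape[1] and envsel.shape[1]:
        vp = ord_mod.varpart(tables.community,
                             {"TemSpa": temspa, "Env": envsel},
                             method=cfg.varpart_method,
                             transform=cfg.varpart_transform,
                             n_perm=cfg.n_perm, seed=seed)
        s = vp.as_series().rename("adjusted_r2").to_frame()
        s.insert(0, "partition", "TemSpa_vs_Env")
        parts.append(s.reset_index(names="fraction"))
    for tag, names in (("temspa_components", ["season", "vertical", "horizontal"]),
                       ("env_components", ["physical", "chemical", "food"])):
        res = run_part(tag, names)
        if res is not None:
            parts.append(res)
    fractions = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    write_csv(fractions, outdir / "varpart_fractions.csv", h, index=False)
    return {"pcnm": axes, "selected": selected_sets, "fractions": fractions}


def _network_outputs(net, table, frame, outdir: Path, h: str, tag: str,
                     cfg: PipelineConfig, seed: int) -> dict:
    partition, q = net_mod.detect_modules(net, seed=seed)
    topo = net_mod.topology(net, partition)
    null = net_mod.er_ensemble(topo.n_nodes, topo.n_edges,
                               reps=cfg.er_reps, seed=seed + 1)
    null_means = null.mean().to_dict()
    summary = pd.DataFrame([
        {"metric": k, "real": getattr(topo, k),
         "null_mean": null_means.get(k, float("nan")),
         "null_sd": null.std().to_dict().get(k, float("nan"))}
        for k in ("clustering", "avg_path_length", "modularity")
    ])
    try:
        sigma = net_mod.small_world_sigma(topo, null_means)
    except ValueError as exc:
        log.warning("small-world sigma undefined: %s", exc)
        sigma = float("nan")
    edges = net.edge_table()
    edges["module_source"] = edges["source"].map(partition)
    write_csv(edges, outdir / f"{tag}_edges.csv", h, index=False)
    write_csv(summary, outdir / f"{tag}_null_summary.csv", h, index=False)
    report = net_mod.module_report(table, net, partition)
    write_csv(report, outdir / f"{tag}_modules.csv", h)
    pref = net_mod.module_preference(table, partition, frame)
    write_csv(pref, outdir / f"{tag}_module_preference.csv", h)
    nx.write_graphml(net.graph, outdir / f"{tag}.graphml")
    return {"network": net, "partition": partition, "modularity": q,
            "topology": topo, "null_summary": summary, "sigma": sigma,
            "module_report": report, "module_preference": pref}


def _stage_network(tables: TableSet, cfg: PipelineConfig, outdir: Path, h: str) -> dict:
    seed = cfg.seeds["network"]
    kept = net_mod.filter_taxa(tables.community, cfg.min_occurrence,
                               cfg.min_rel_abund)
    sub = tables.community.subset_taxa(kept)
    annotations = {}
    if tables.traits is not None:
        annotations = {t: tables.traits.data.loc[t].to_dict()
                       for t in kept if t in tables.traits.data.index}
    net = net_mod.build_network({"ciliate": (sub.data, "ciliate")},
                                cfg.r_threshold, cfg.p_threshold,
                                annotations=annotations)
    return _network_outputs(net, tables.community, tables.frame,
                            outdir, h, "ciliate_network", cfg, seed)


def _stage_integrated(tables: TableSet, cfg: PipelineConfig, outdir: Path,
                      h: str) -> dict:
    if tables.phyto is None or tables.env is None:
        raise ValueError("integrated network needs phytoplankton and environment tables")
    seed = cfg.seeds["integrated"]
    kept_c = net_mod.filter_taxa(tables.community, cfg.min_occurrence,
                                 cfg.min_rel_abund)
    kept_p = net_mod.filter_taxa(tables.phyto, cfg.min_occurrence,
                                 cfg.min_rel_abund)
    annotations = {}
    if tables.traits is not None:
        annotations.update({t: tables.traits.data.loc[t].to_dict()
                            for t in kept_c if t in tables.traits.data.index})
    if tables.phyto_traits is not None:
        annotations.update({t: tables.phyto_traits.data.loc[t].to_dict()
                            for t in kept_p if t in tables.phyto_traits.data.index})
    net = net_mod.build_network(
        {
            "ciliate": (tables.community.data[kept_c], "ciliate"),
            "phytoplankton": (tables.phyto.data[kept_p], "phytoplankton"),
            "environment": (tables.env.data, "environment"),
        },
        cfg.r_threshold, cfg.p_threshold, annotations=annotations)
    out = _network_outputs(net, tables.community, tables.frame,
                           outdir, h, "integrated_network", cfg, seed)
    traits = tables.traits.data if tables.traits is not None else None
    phylum = (tables.phyto_traits.data["phylum"]
              if tables.phyto_traits is not None else None)
    classification = net_mod.classify_edges(
        out["network"], traits=traits, phylum_map=phylum,
        env_groups=dict(ENV_GROUP_MAP) | {"Chla": "food"})
    write_csv(classification.counts, outdir / "integrated_edge_classes.csv", h,
              index_label="edge_class")
    out["edge_classification"] = classification
    return out


STAGES = {
    "alpha": _stage_alpha,
    "beta": _stage_beta,
    "vpa": _stage_vpa,
    "network": _stage_network,
    "integrated": _stage_integrated,
}


def run_pipeline(tables: TableSet, cfg: PipelineConfig,
                 stages: tuple = ("alpha", "beta", "vpa", "network", "integrated"),
                 ) -> dict:
    """Run the requested stages in order, writing outputs and a manifest."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    results: dict = {}
    manifest = {"config": cfg.to_dict(), "config_hash": h, "stages": {}}
    for name in stages:
        t0 = time.perf_counter()
        try:
            results[name] = STAGES[name](tables, cfg, outdir, h)
            manifest["stages"][name] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 2)}
            log.info("stage %s finished in %.1fs", name,
                     time.perf_counter() - t0)
        except Exception as exc:  # stage isolation is the contract
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            log.warning("stage %s failed: %s", name, exc)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
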