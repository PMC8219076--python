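"""End-to-end orchestration: simulate/load -> rarefy -> alpha -> beta ->
composition -> bipartite -> co-correlation network -> report.

A single master seed determines every stochastic stage: each stage derives
its own seed as ``crc32(stage_name) XOR master`` (mod 2^31), so reruns with
the same config are identical and stages can be reproduced in isolation.
The report echoes the full config with a hash, and every percentage in it
is re-derived from the counts in the same report before it is written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import alpha as alpha_mod
from . import beta as beta_mod
from . import networks as net_mod
from . import tables
from .synth import SynthConfig, generate_community, write_simulation

__all__ = ["RunConfig", "stage_seed", "run_pipeline", "load_inputs"]

log = logging.getLogger("otukit")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (zlib.crc32(stage.encode("utf-8")) ^ (master & 0xFFFFFFFF)) % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on.

    When ``table_path`` is unset the input is simulated from ``synth`` (its
    seed replaced by the stage seed derived from ``seed``, so the master
    seed is the single reproducibility knob).
    """

    outdir: str = "otukit_run"
    seed: int = 0
    # inputs: either the three file paths, or a simulation
    table_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    # stage parameters
    rarefaction_depth: int | str = "min"
    alpha_test: str = "t"
    n_permutations: int = 999
    others_threshold: float = 0.01
    min_total_reads: int = 5
    rho_min: float = 0.75
    edge_alpha: float = 0.05
    edge_mode: str = "positive"
    prefilter_top_n: int = 100
    min_prevalence: int = 4
    top_hubs: int = 6
    heatmap_top_n: int = 40

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "synth" in raw and isinstance(raw["synth"], dict):
            raw["synth"] = SynthConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in raw["synth"].items()
            })
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the analytic parameters (output location excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_inputs(config: RunConfig, outdir: Path):
    """Read the three TSVs, or simulate them when no table path is given."""
    if config.table_path is None:
        cfg = dataclasses.replace(config.synth, seed=stage_seed(config.seed, "simulate"))
        table, tax, info, truth = generate_community(cfg)
        write_simulation(outdir / "input", table, tax, info, truth)
        log.info("simulate: %d taxa x %d samples", *table.shape)
        return table, tax, info, truth
    for name, path in (
        ("count table", config.table_path),
        ("taxonomy", config.taxonomy_path),
        ("metadata", config.metadata_path),
    ):
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"{name} file not found: {path}")
    table = tables.read_count_table(config.table_path)
    tax = tables.read_taxonomy(config.taxonomy_path)
    info = tables.read_sample_info(config.metadata_path)
    tables.validate_sample_info(info, table)
    return table, tax, info, None


def _perm_test_rows(dm, info, config) -> pd.DataFrame:
    """The four permutation-test rows: the 3-habitat contrast plus the
    MC-vs-RC contrast within each habitat (ANOSIM and Adonis per row)."""
    rows = []
    contrasts = [("Sediment vs. Water vs. Intestine", list(dm.ids), "habitat")]
    for hab in tables.HABITATS:
        ids = [s for s in dm.ids if info.at[s, "habitat"] == hab]
        contrasts.append((f"MC-{hab} vs. RC-{hab}", ids, "mode"))
    for i, (name, ids, by) in enumerate(contrasts):
        sub = dm.filter(ids)
        labels = [info.at[s, by] for s in ids]
        an = beta_mod.anosim(
            sub, labels, config.n_permutations, stage_seed(config.seed, f"anosim{i}")
        )
        ad = beta_mod.adonis(
            sub, labels, config.n_permutations, stage_seed(config.seed, f"adonis{i}")
        )
        rows.append(
            {
                "group": name,
                "anosim_R": an.statistic,
                "anosim_p": an.p_value,
                "permutations": config.n_permutations,
                "adonis_F": ad.statistic,
                "adonis_R2": ad.r_squared,
                "adonis_p": ad.p_value,
            }
        )
    return pd.DataFrame(rows)


def _check_report_consistency(report: dict) -> None:
    """Every percentage in the report must re-derive from its counts."""
    s = report["bipartite"]["summary"]
    n = s["n_genera"]
    for kind in ("one", "two", "three"):
        expect = float(np.round(100.0 * s[f"{kind}_env_count"] / n, 2))
        if s[f"{kind}_env_pct"] != expect:
            raise AssertionError(
                f"report inconsistency: {kind}_env_pct {s[f'{kind}_env_pct']} != {expect}"
            )
    for hab, sharing in report["bipartite"]["sharing"].items():
        total = sharing["total"]
        for key, val in sharing.items():
            if key.endswith("_pct"):
                cnt = sharing[key.replace("_pct", "_count")]
                expect = float(np.round(100.0 * cnt / total, 2))
                if val != expect:
                    raise AssertionError(f"report inconsistency: {hab}.{key}")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write all outputs under ``config.outdir``, and
    return the report (also written as ``report.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": _version(),
    }

    table, tax, info, _ = load_inputs(config, outdir)

    # --- rarefaction -------------------------------------------------------
    rarefied = tables.rarefy(
        table, config.rarefaction_depth, stage_seed(config.seed, "rarefy")
    )
    tables.write_count_table(rarefied, outdir / "rarefied.tsv")
    depth = int(rarefied.sum(axis=0).iloc[0])
    log.info("rarefy: depth %d, %d taxa x %d samples", depth, *rarefied.shape)
    report["rarefaction"] = {"depth": depth, "n_taxa": int(rarefied.shape[0])}

    # --- alpha diversity ---------------------------------------------------
    adf = alpha_mod.alpha_diversity(rarefied)
    adf.to_csv(outdir / "alpha.tsv", sep="\t")
    atests = alpha_mod.pairwise_tests(adf, info, by="habitat", test=config.alpha_test)
    atests.to_csv(outdir / "alpha_tests.tsv", sep="\t", index=False)
    report["alpha"] = {
        "mean_coverage": float(adf["coverage"].mean()),
        "shannon_range": [float(adf["shannon"].min()), float(adf["shannon"].max())],
    }

    # --- beta diversity ----------------------------------------------------
    dm = beta_mod.bray_curtis(rarefied)
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        outdir / "distance.tsv", sep="\t"
    )
    ord_ = beta_mod.pcoa(dm)
    ord_.coordinates.to_csv(outdir / "pcoa.tsv", sep="\t")
    dend = beta_mod.upgma(dm)
    (outdir / "upgma.nwk").write_text(dend.to_newick() + "\n", encoding="utf-8")
    perm = _perm_test_rows(dm, info, config)
    perm.to_csv(outdir / "permutation_tests.tsv", sep="\t", index=False)
    report["beta"] = {
        "pc1_pct": float(np.round(100 * ord_.proportion_explained[0], 2)),
        "pc2_pct": float(np.round(100 * ord_.proportion_explained[1], 2))
        if len(ord_.proportion_explained) > 1
        else None,
        "permutation_tests": perm.to_dict(orient="records"),
    }

    # --- composition -------------------------------------------------------
    genus = tables.aggregate_rank(rarefied, tax, "genus")
    phylum = tables.aggregate_rank(rarefied, tax, "phylum")
    rel_phylum = tables.relative_abundance(phylum)
    binned = tables.bin_others(rel_phylum, config.others_threshold)
    binned.to_csv(outdir / "phylum_composition.tsv", sep="\t")
    rel_genus = tables.relative_abundance(genus)
    top = tables.top_n_taxa(genus, min(config.heatmap_top_n, genus.shape[0]))
    tables.log10_abundance(rel_genus.loc[top]).to_csv(outdir / "heatmap_matrix.tsv", sep="\t")
    report["composition"] = {
        "n_phyla": int(phylum.shape[0]),
        "n_genera": int(genus.shape[0]),
        "n_phyla_after_binning": int(binned.shape[0]),
    }
    log.info("composition: %d phyla, %d genera", phylum.shape[0], genus.shape[0])

    # --- bipartite genus-environment network -------------------------------
    bip = net_mod.build_bipartite(genus, info, config.min_total_reads)
    assignment, summary = net_mod.classify_env_clusters(bip)
    nx.write_graphml(bip, outdir / "bipartite.graphml")
    pd.Series(assignment, name="cluster").rename_axis("genus").to_csv(
        outdir / "env_clusters.tsv", sep="\t"
    )
    sharing = {h: net_mod.habitat_sharing(assignment, h) for h in tables.HABITATS}
    report["bipartite"] = {
        "summary": dataclasses.asdict(summary),
        "sharing": sharing,
    }
    log.info("bipartite: %d genera kept (>= %d reads)", summary.n_genera, config.min_total_reads)

    # --- co-correlation network -------------------------------------------
    eligible = net_mod.node_prefilter(genus, config.prefilter_top_n, config.min_prevalence)
    rho, pmat, flagged = net_mod.spearman_matrix(rel_genus, eligible)
    edges = net_mod.filter_edges(rho, pmat, config.rho_min, config.edge_alpha, config.edge_mode)
    conet_report: dict[str, Any] = {"n_candidate_taxa": len(eligible), "n_constant_flagged": len(flagged)}
    if edges:
        g = net_mod.build_conet(edges)
        metrics = net_mod.graph_metrics(g)
        partition, q = net_mod.detect_modules(
            g, seed=stage_seed(config.seed, "louvain")
        )
        net_mod.assign_environment_labels(g, genus, info, partition)
        hubs = net_mod.hub_ranking(g, config.top_hubs)
        nx.write_graphml(g, outdir / "conet.graphml")
        pd.DataFrame(edges, columns=["source", "target", "rho", "p"]).to_csv(
            outdir / "conet_edges.tsv", sep="\t", index=False
        )
        pd.DataFrame.from_dict(dict(g.nodes(data=True)), orient="index").rename_axis(
            "genus"
        ).to_csv(outdir / "conet_nodes.tsv", sep="\t")
        conet_report.update(
            dataclasses.asdict(metrics),
            modularity=q,
            n_modules=len(set(partition.values())),
            hubs=[
                {"genus": n, "degree": d, "clustering": c, "betweenness": b}
                for n, d, c, b in hubs
            ],
        )
        log.info(
            "conet: %d nodes, %d edges, Q=%.3f", metrics.n_nodes, metrics.n_edges, q
        )
    else:
        conet_report.update(n_nodes=0, n_edges=0)
        log.info("conet: no edge survived the filters")
    report["conet"] = conet_report

    _check_report_consistency(report)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _version() -> str:
    from . import __version__

    return __version__
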