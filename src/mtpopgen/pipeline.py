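"""Orchestration: run the whole analysis from a config to report tables.

Stages run in a fixed order (seqio -> diversity -> distances -> structure ->
neutrality -> mismatch -> network); every table is written as TSV with a
provenance header (package version, seed, config hash) plus a JSON
manifest sufficient to re-run any stage.  Lineage assignment is an input;
a convenience helper derives a surrogate assignment by single-linkage
clustering on K2P distances at a user threshold, for use when no
tree-based assignment is available.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import distances as dist_mod
from . import diversity as div_mod
from . import mismatch as mm_mod
from . import network as net_mod
from . import neutrality as neut_mod
from . import structure as struct_mod
from .seqio import (
    GroupingScheme,
    HaplotypeDataset,
    PopulationMap,
    base_composition,
    collapse_haplotypes,
    read_fasta,
    site_classes,
)

STAGES = ("seqio", "diversity", "distances", "structure", "neutrality",
          "mismatch", "network")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    fasta: str
    population_map: str
    grouping: str | None = None
    lineages: str | None = None          # TSV haplotype -> lineage (optional)
    output_dir: str = "mtpopgen-out"
    seed: int = 1
    permutations: int = 1000
    bootstrap: int = 1000
    neutrality_reps: int = 10000
    confidence: float = 0.95
    mu_site_per_year: float = 0.957e-8   # 0.957% per site per Myr
    k_sites: int | None = None           # defaults to retained-site count
    generation_years: float = 1.0
    rate_convention: str = "pairwise_divergence"
    gap_policy: str = "exclude_sites"
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def assign_lineages_by_threshold(hd: HaplotypeDataset, threshold: float = 0.03):
    """Surrogate lineage assignment: single-linkage clusters of haplotypes
    with K2P distance below ``threshold``.  A stand-in for tree-derived
    lineages, labelled as such in the manifest."""
    import networkx as nx

    ids = [h for h, _ in hd.haplotypes]
    mat = dist_mod.k2p_matrix(ids, [s for _, s in hd.haplotypes]).d
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if mat[i, j] < threshold:
                g.add_edge(ids[i], ids[j])
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    return {h: f"L{k + 1}" for k, comp in enumerate(comps) for h in comp}


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = [f"mtpopgen {__version__}", f"seed {cfg.seed}", f"config {cfg.config_hash()}"]
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "stages": [],
        "outputs": {},
    }
    rng = np.random.default_rng(cfg.seed)
    seeds = {s: int(rng.integers(1, 2**31 - 1)) for s in STAGES}
    manifest["stage_seeds"] = seeds

    stage = "seqio"
    try:
        aln = read_fasta(cfg.fasta)
        pm = PopulationMap.read(cfg.population_map)
        hd = collapse_haplotypes(aln, pm, gap_policy=cfg.gap_policy)
        comp = base_composition(aln)
        sc = site_classes(hd)
        _write_tsv(sc.to_frame(), out / "site_classes.tsv", prov)
        _write_tsv(
            pd.DataFrame([comp]), out / "base_composition.tsv", prov
        )
        manifest["stages"].append(stage)
        manifest["outputs"]["site_classes"] = "site_classes.tsv"
        manifest["n_individuals"] = hd.n
        manifest["n_haplotypes"] = hd.h
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, exc) from exc

    if cfg.lineages:
        lin_tab = pd.read_csv(cfg.lineages, sep="\t")
        lineage_of = dict(zip(lin_tab["haplotype"], lin_tab["lineage"]))
        manifest["lineage_source"] = cfg.lineages
    else:
        lineage_of = assign_lineages_by_threshold(hd)
        manifest["lineage_source"] = "surrogate: single-linkage K2P < 0.03"
    lineages: dict[str, list[str]] = {}
    for h, lin in lineage_of.items():
        lineages.setdefault(lin, []).append(h)
    lineage_pops = {
        lin: [p for p in hd.populations
              if hd.counts.loc[hd.counts.index.isin(haps), p].sum() > 0]
        for lin, haps in lineages.items()
    }

    k_sites = cfg.k_sites or len(hd.retained_sites)

    if "diversity" in cfg.stages:
        stage = "diversity"
        try:
            table = div_mod.diversity_table(hd)
            _write_tsv(table, out / "diversity.tsv", prov)
            manifest["stages"].append(stage)
            manifest["outputs"]["diversity"] = "diversity.tsv"
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    if "distances" in cfg.stages:
        stage = "distances"
        try:
            tbl = dist_mod.group_mean_distances(
                [h for h, _ in hd.haplotypes],
                [s for _, s in hd.haplotypes],
                lineage_of, B=cfg.bootstrap, seed=seeds[stage],
            )
            _write_tsv(
                tbl.combined().reset_index().rename(columns={"index": "lineage"}),
                out / "lineage_k2p.tsv", prov,
            )
            manifest["stages"].append(stage)
            manifest["outputs"]["distances"] = "lineage_k2p.tsv"
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    if "structure" in cfg.stages:
        stage = "structure"
        try:
            gs = (GroupingScheme.read(cfg.grouping) if cfg.grouping
                  else GroupingScheme(
                      {p: lin for lin, pops in lineage_pops.items() for p in pops},
                      name="lineage-groups"))
            res = struct_mod.amova(hd, gs, R=cfg.permutations, seed=seeds[stage])
            _write_tsv(res.to_frame(), out / "amova.tsv", prov)
            fst = struct_mod.pairwise_fst(hd, R=cfg.permutations, seed=seeds[stage])
            _write_tsv(fst.phi_st.reset_index(), out / "pairwise_fst.tsv", prov)
            geo = struct_mod.great_circle_matrix(pm)
            mantel = struct_mod.mantel_test(
                fst.phi_st.to_numpy(), geo.loc[fst.populations, fst.populations],
                R=cfg.permutations, seed=seeds[stage],
            )
            (out / "mantel.json").write_text(json.dumps({
                "r": mantel.r, "p_value": mantel.p_value,
                "p_greater": mantel.p_greater, "p_less": mantel.p_less,
                "permutations": mantel.permutations, "method": mantel.method,
            }, indent=2))
            manifest["stages"].append(stage)
            manifest["outputs"]["structure"] = ["amova.tsv", "pairwise_fst.tsv", "mantel.json"]
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    if "neutrality" in cfg.stages:
        stage = "neutrality"
        try:
            rows = []
            for lin, pops in sorted(lineage_pops.items()):
                counts = hd.subset_counts(pops)
                if counts.sum() < 4:
                    continue
                res = neut_mod.neutrality_test(
                    hd, pops, reps=cfg.neutrality_reps, seed=seeds[stage]
                )
                rows.append({
                    "lineage": lin, "N": res.n, "h": res.k_obs, "S": res.S,
                    "pi_hat": res.pi_hat, "D": res.D, "p_D": res.p_D,
                    "Fs": res.Fs, "p_Fs": res.p_Fs,
                })
            _write_tsv(pd.DataFrame(rows), out / "neutrality.tsv", prov)
            manifest["stages"].append(stage)
            manifest["outputs"]["neutrality"] = "neutrality.tsv"
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    if "mismatch" in cfg.stages:
        stage = "mismatch"
        try:
            reports = {}
            for lin, pops in sorted(lineage_pops.items()):
                counts = hd.subset_counts(pops)
                n_lin = int(counts.sum())
                if n_lin < 4:
                    continue
                md = mm_mod.observed_mismatch(hd, pops)
                try:
                    fit = mm_mod.fit_expansion(md, seed=seeds[stage])
                except mm_mod.FitError:
                    continue
                fit = mm_mod.bootstrap_gof(
                    fit, n_lin, B=cfg.bootstrap, seed=seeds[stage]
                )
                et = mm_mod.expansion_time(
                    fit.tau, cfg.mu_site_per_year, k_sites,
                    cfg.generation_years, cfg.rate_convention,
                )
                reports[lin] = {
                    "n": n_lin, "tau": fit.tau, "theta0": fit.theta0,
                    "theta1": fit.theta1, "SSD": fit.SSD, "p_SSD": fit.p_SSD,
                    "raggedness": fit.raggedness_index,
                    "p_raggedness": fit.p_raggedness,
                    "expansion_time_Ma": et.t_Ma,
                }
                pd.DataFrame({
                    "differences": np.arange(md.d_max + 1),
                    "observed": md.frequencies,
                    "expected": fit.expected,
                }).to_csv(out / f"mismatch_{lin}.tsv", sep="\t", index=False)
            (out / "mismatch.json").write_text(json.dumps(reports, indent=2))
            manifest["stages"].append(stage)
            manifest["outputs"]["mismatch"] = "mismatch.json"
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    if "network" in cfg.stages:
        stage = "network"
        try:
            net = net_mod.build_network(hd, confidence=cfg.confidence)
            _write_tsv(net.edge_table(), out / "network_edges.tsv", prov)
            _write_tsv(net.membership_table(), out / "network_membership.tsv", prov)
            net.write_graphml(out / "network.graphml")
            manifest["stages"].append(stage)
            manifest["outputs"]["network"] = ["network_edges.tsv",
                                              "network_membership.tsv",
                                              "network.graphml"]
            manifest["connection_limit"] = net.connection_limit_steps
            manifest["subnetworks"] = len(net.subnetworks)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def compare_groupings(
    hd: HaplotypeDataset,
    schemes: list[GroupingScheme],
    R: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """AMOVA per candidate grouping scheme, ranked by F_CT (ties broken by
    fewer groups) - the usual search for the most parsimonious subdivision."""
    if len(schemes) < 1:
        raise ValueError("need at least one scheme")
    rows = []
    for gs in schemes:
        res = struct_mod.amova(hd, gs, R=R, seed=seed)
        rows.append({
            "scheme": gs.name or f"{len(gs.groups)}-groups",
            "groups": len(gs.groups),
            "F_CT": res.F_CT, "p_CT": res.p_CT,
            "F_SC": res.F_SC, "F_ST": res.F_ST,
        })
    out = pd.DataFrame(rows).sort_values(
        ["F_CT", "groups"], ascending=[False, True]
    ).reset_index(drop=True)
    return out
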