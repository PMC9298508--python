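"""End-to-end orchestration: data (synthetic or on disk) -> rarefaction ->
diversity -> co-occurrence networks -> EMF -> inference, under one config
with per-stage seeds and a provenance report.

Stage RNG streams are derived from the master seed by stable hashing, so
adding a stage never perturbs the draws of earlier stages; identical
config + seed reproduces identical output hashes.
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
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from . import diversity, emf, network as conet, permstats, synthetic, tables
from ._util import derive_seed

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    #: paths to existing inputs; if None, data are generated synthetically
    count_paths: dict[str, str] | None = None
    sample_path: str | None = None
    env_path: str | None = None
    #: synthetic generation settings (used when count_paths is None)
    richness: dict[str, int] = field(
        default_factory=lambda: dict(synthetic.DEFAULT_RICHNESS))
    rarefaction_depths: dict[str, int] = field(
        default_factory=lambda: {"bacteria": 6000, "fungi": 6000, "archaea": 6000})
    dominance_threshold: float = 1e-4
    r_threshold: float = 0.7
    p_threshold: float = 0.05
    correction: str = "none"
    #: sample selections networks are built for, e.g. [{"disturbance": "P", "surface": "G"}]
    network_groups: list[dict[str, str]] = field(
        default_factory=lambda: [{"disturbance": "P"}, {"disturbance": "PL"}])
    emf_columns: tuple[str, ...] = emf.FUNCTION_COLUMNS
    n_permutations: int = 999
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for domain, depth in self.rarefaction_depths.items():
            if depth < 1:
                raise ValueError(f"rarefaction depth for {domain} must be >= 1")
        if self.count_paths is not None:
            for domain, p in self.count_paths.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"{domain} count table not found: {p}")
            for p in (self.sample_path, self.env_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"metadata/environment table missing: {p}")


@dataclass
class RunReport:
    config: dict
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, **info):
        self.stages.append({"stage": stage, **info})

    def add_output(self, path: Path):
        self.outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def save(self, path: Path):
        with open(path, "w") as fh:
            json.dump({
                "config": self.config, "stages": self.stages,
                "warnings": self.warnings, "outputs": self.outputs,
            }, fh, indent=2, default=str)


def _load_or_generate(cfg: PipelineConfig, report: RunReport):
    if cfg.count_paths is not None:
        frame = tables.read_sample_frame(cfg.sample_path)
        env = tables.read_env_table(cfg.env_path)
        counts = {d: tables.read_count_table(p, format="tsv", domain=d)
                  for d, p in cfg.count_paths.items()}
        report.record("load", n_samples=len(frame))
        return frame, counts, env
    design_seed = derive_seed(cfg.seed, "design")
    frame = synthetic.generate_design(synthetic.DesignConfig(seed=design_seed))
    counts = {}
    for domain, n_otus in cfg.richness.items():
        ccfg = synthetic.CommunityConfig(
            n_otus=n_otus, seed=derive_seed(cfg.seed, f"counts:{domain}"))
        counts[domain] = synthetic.generate_counts(frame, ccfg, domain)
    env = synthetic.generate_env(frame, synthetic.GradientConfig(),
                                 seed=derive_seed(cfg.seed, "env"))
    report.record("synthesize", n_samples=len(frame),
                  richness=dict(cfg.richness))
    return frame, counts, env


def run_pipeline(cfg: PipelineConfig, outdir) -> RunReport:
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(cfg))

    frame, counts, env = _load_or_generate(cfg, report)
    missing = set(cfg.emf_columns) - set(env.columns)
    if missing:
        raise ValueError(f"EMF columns missing from environment table: {sorted(missing)}")
    tables.write_sample_frame(frame, outdir / "samples.tsv")
    tables.write_env_table(env, outdir / "environment.tsv")

    # rarefaction and per-domain diversity
    rarefied: dict[str, tables.CountTable] = {}
    beta: dict[str, DistanceMatrix] = {}
    alpha_frames = {}
    for domain, table in counts.items():
        depth = cfg.rarefaction_depths[domain]
        rt = tables.rarefy(table, depth, seed=derive_seed(cfg.seed, f"rarefy:{domain}"))
        dropped = set(table.sample_ids) - set(rt.sample_ids)
        if dropped:
            report.warnings.append(
                f"rarefy[{domain}]: dropped {len(dropped)} sample(s) below depth {depth}")
        rarefied[domain] = rt
        tables.write_count_table(rt, outdir / f"counts_{domain}_rarefied.tsv")
        alpha = diversity.alpha_diversity(rt)
        alpha_frames[domain] = alpha
        alpha.to_csv(outdir / f"alpha_{domain}.tsv", sep="\t")
        dm = diversity.bray_curtis(rt)
        beta[domain] = dm
        pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
            outdir / f"braycurtis_{domain}.tsv", sep="\t")
        diversity.within_group_similarity(dm, frame).to_csv(
            outdir / f"similarity_{domain}.tsv", sep="\t", index=False)
        report.record(f"diversity:{domain}", depth=depth,
                      n_samples=rt.shape[0], n_otus=rt.shape[1])

    # per-group networks, per domain and cross-domain
    topo_rows = []
    pair_frames = []
    for group in cfg.network_groups:
        gname = "_".join(f"{v}" for v in group.values())
        dominant = {}
        for domain, rt in rarefied.items():
            sub = tables.subset_by_group(rt, frame, **group)
            dom = tables.filter_dominant(sub, cfg.dominance_threshold)
            dominant[domain] = dom
            res = conet.spearman_all_pairs(dom)
            hist = conet.correlation_histogram(res)
            hist.to_frame().to_csv(outdir / f"corr_hist_{gname}_{domain}.tsv",
                                   sep="\t", index=False)
            net = conet.build_network(res, cfg.r_threshold, cfg.p_threshold,
                                      correction=cfg.correction, domains=domain)
            conet.export_network(net, outdir / f"network_{gname}_{domain}.graphml")
            if net.number_of_nodes():
                topo = conet.topology_summary(
                    net, community_seed=derive_seed(cfg.seed, f"louvain:{gname}:{domain}"))
                topo_rows.append({"group": gname, "domain": domain, **topo.to_dict()})
        # rarefaction can drop different samples per domain; the merged
        # cross-domain table uses the intersection
        common = set.intersection(*(set(t.sample_ids) for t in dominant.values()))
        aligned = [
            tables.CountTable(t.data.loc[[s for s in t.sample_ids if s in common]],
                              domain=t.domain)
            for t in dominant.values()
        ]
        merged = tables.merge_domains(aligned)
        res = conet.spearman_all_pairs(merged)
        net = conet.build_network(res, cfg.r_threshold, cfg.p_threshold,
                                  correction=cfg.correction)
        xnet = conet.cross_domain_filter(net)
        conet.export_network(xnet, outdir / f"network_{gname}_crossdomain.graphml")
        conet.export_network(xnet, outdir / f"edges_{gname}_crossdomain.tsv",
                             format="edge-list-tsv")
        if xnet.number_of_nodes():
            topo = conet.topology_summary(
                xnet, community_seed=derive_seed(cfg.seed, f"louvain:{gname}:cross"))
            topo_rows.append({"group": gname, "domain": "cross-domain", **topo.to_dict()})
        pairs = conet.domain_pair_summary(xnet)
        pairs.insert(0, "group", gname)
        pair_frames.append(pairs)
        report.record(f"network:{gname}",
                      cross_domain_edges=xnet.number_of_edges())
    pd.DataFrame(topo_rows).to_csv(outdir / "topology.tsv", sep="\t", index=False)
    pd.concat(pair_frames).to_csv(outdir / "domain_pairs.tsv", sep="\t", index=False)

    # EMF
    fmat = emf.function_matrix(env, columns=cfg.emf_columns)
    scores = emf.emf_scores(fmat)
    scores.to_frame().to_csv(outdir / "emf.tsv", sep="\t")
    emf.group_emf(scores, frame).to_csv(outdir / "emf_groups.tsv", sep="\t", index=False)
    report.record("emf", grand_mean=float(scores.mean()))

    # inference
    stats_out = {}
    for domain, rt in rarefied.items():
        labels = frame.loc[rt.sample_ids, "disturbance"].to_numpy()
        res = permstats.permanova(beta[domain], labels,
                                  permutations=cfg.n_permutations,
                                  seed=derive_seed(cfg.seed, f"permanova:{domain}"))
        stats_out[f"permanova_disturbance_{domain}"] = dataclasses.asdict(res)
        env_d = DistanceMatrix(
            squareform(pdist(_zscore(env.loc[rt.sample_ids]).to_numpy())),
            ids=rt.sample_ids)
        res = permstats.mantel(beta[domain], env_d,
                               permutations=cfg.n_permutations,
                               seed=derive_seed(cfg.seed, f"mantel:{domain}"))
        stats_out[f"mantel_env_{domain}"] = dataclasses.asdict(res)
        mres = permstats.mrm(beta[domain], [env_d],
                             permutations=cfg.n_permutations,
                             seed=derive_seed(cfg.seed, f"mrm:{domain}"),
                             names=["environment"])
        stats_out[f"mrm_env_{domain}"] = {
            "coefficients": mres.coefficients.to_dict(), "r2": mres.r2,
            "p_values": mres.p_values.to_dict()}
        # enrichment vs the natural meadow
        for group in cfg.network_groups:
            rep = permstats.enrichment_ratio(rt, frame, focal=group,
                                             alpha=cfg.alpha)
            stats_out[f"enrichment_{domain}_{rep.group}"] = {
                "ratio": rep.ratio, "n_enriched": rep.n_enriched,
                "n_tested": rep.n_otus_tested}

    common = alpha_frames["bacteria"].index.intersection(alpha_frames["fungi"].index)
    reg = permstats.linear_regression(
        alpha_frames["bacteria"].loc[common, "chao1"],
        alpha_frames["fungi"].loc[common, "chao1"])
    stats_out["regression_bacteria_fungi_chao1"] = dataclasses.asdict(reg)
    common = alpha_frames["bacteria"].index.intersection(scores.index)
    reg = permstats.linear_regression(
        alpha_frames["bacteria"].loc[common, "chao1"], scores.loc[common])
    stats_out["regression_emf_bacterial_chao1"] = dataclasses.asdict(reg)
    with open(outdir / "stats.json", "w") as fh:
        json.dump(stats_out, fh, indent=2, default=float)
    report.record("inference", n_tests=len(stats_out))

    for path in sorted(outdir.iterdir()):
        if path.name != "run_report.json" and path.is_file():
            report.add_output(path)
    report.save(outdir / "run_report.json")
    return report


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1).replace(0, 1.0)
    return (df - df.mean()) / sd
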