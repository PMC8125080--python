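"""End-to-end orchestration: simulate -> screen -> cluster -> network ->
host -> lifestyle -> stats, behind one seeded configuration, with a
machine-readable run report.

Stage outputs are plain FASTA/TSV files under the run directory; logs go
to stderr; the report is JSON.  The whole run is deterministic under the
global seed (wall time excluded from the canonical report).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import hostlink, lifestyle as lifestyle_mod, network, populations, screen, stats
from .io import write_fasta, write_tsv
from .synthetic import CommunityConfig, CommunityBundle, generate_community

log = logging.getLogger("viroscope")

ALL_STAGES = ("simulate", "screen", "cluster", "network", "host", "lifestyle", "stats")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    stages: Tuple[str, ...] = ALL_STAGES
    community: CommunityConfig = field(default_factory=CommunityConfig)
    ani_min: float = populations.ANI_MIN_PCT
    af_min: float = populations.AF_MIN_PCT
    sig_min: float = network.SIG_MIN
    markov_k: int = hostlink.MARKOV_K
    spacer_id_min: float = hostlink.SPACER_ID_MIN_PCT
    fdr_alpha: float = stats.FDR_ALPHA
    n_perm: int = 999
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # the global seed drives every stochastic stage
        self.community.seed = self.seed

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        comm = raw.pop("community", {})
        if isinstance(comm, dict):
            raw["community"] = CommunityConfig(**comm)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


@dataclass
class RunReport:
    seed: int
    parameters: Dict = field(default_factory=dict)
    n_contigs: int = 0
    n_viral: int = 0
    n_viral_ge5kb: int = 0
    n_viral_ge10kb: int = 0
    n_rejected: int = 0
    n_sub_length: int = 0
    n_populations: int = 0
    n_populations_novel: int = 0
    n_vcs: int = 0
    vc_classes: Dict[str, int] = field(default_factory=dict)
    n_viruses_host_linked: int = 0
    host_linked_fraction: float = 0.0
    lifestyle_counts: Dict[str, int] = field(default_factory=dict)
    n_significant_wilcoxon: Dict[str, int] = field(default_factory=dict)
    n_significant_t: Dict[str, int] = field(default_factory=dict)
    anosim_r: Optional[float] = None
    anosim_p: Optional[float] = None
    wall_time_s: float = 0.0

    def validate(self) -> None:
        """Internal consistency of the summary accounting."""
        conf = self.lifestyle_counts.get("confident_temperate", 0)
        cand = self.lifestyle_counts.get("candidate_temperate", 0)
        assert conf + cand <= self.n_viral <= self.n_contigs
        assert self.n_populations_novel <= self.n_populations
        assert self.n_viral + self.n_rejected + self.n_sub_length == self.n_contigs

    def to_json(self, include_wall_time: bool = False) -> str:
        d = dataclasses.asdict(self)
        if not include_wall_time:
            d.pop("wall_time_s")
        return json.dumps(d, indent=2, sort_keys=True, default=str)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> RunReport:
    logging.basicConfig(level=config.log_level)
    t0 = time.perf_counter()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = dataclasses.asdict(config.community)
    params.pop("trna_library", None)
    params["score_config"] = dataclasses.asdict(config.community.score_config)
    report = RunReport(seed=config.seed, parameters={"community": params,
                                                     "ani_min": config.ani_min,
                                                     "af_min": config.af_min,
                                                     "sig_min": config.sig_min,
                                                     "markov_k": config.markov_k})
    stage = "simulate"
    try:
        log.info("simulating community (seed=%d)", config.seed)
        bundle = generate_community(config.community)
        if "simulate" in config.stages:
            bundle.write(out / "simulate")

        stage = "screen"
        decisions, summary = screen.screen_table(bundle.contigs, bundle.scores)
        write_tsv(decisions, out / "screen_decisions.tsv")
        report.n_contigs = summary["n_contigs"]
        report.n_viral = summary["n_viral"]
        report.n_viral_ge5kb = summary["n_viral_ge5kb"]
        report.n_viral_ge10kb = summary["n_viral_ge10kb"]
        report.n_rejected = summary["n_rejected"]
        report.n_sub_length = summary["n_sub_length"]
        viral_ids = list(decisions.loc[decisions["status"] == "viral", "contig_id"])
        viral_seqs = {v: bundle.contigs[v] for v in viral_ids}
        log.info("screen: %d/%d viral", len(viral_ids), summary["n_contigs"])

        stage = "cluster"
        pops: List[populations.ViralPopulation] = []
        if viral_seqs:
            pops = populations.greedy_cluster(viral_seqs, config.ani_min, config.af_min)
            populations.novelty_vs_reference(pops, viral_seqs, {})
        rows = [
            {"population_id": p.population_id, "member_id": m,
             "representative_flag": int(m == p.representative_id),
             "ani_pct": round(p.member_aniaf[m].ani_pct, 3),
             "af_pct": round(p.member_aniaf[m].af_pct, 3),
             "novel": p.novel}
            for p in pops for m in p.member_ids
        ]
        write_tsv(pd.DataFrame(rows, columns=["population_id", "member_id",
                                              "representative_flag", "ani_pct",
                                              "af_pct", "novel"]),
                  out / "populations.tsv")
        write_fasta(out / "population_representatives.fasta",
                    {p.representative_id: viral_seqs[p.representative_id] for p in pops})
        report.n_populations = len(pops)
        report.n_populations_novel = sum(bool(p.novel) for p in pops)

        stage = "network"
        assignments: List[network.ViralClusterAssignment] = []
        edges: List[dict] = []
        if pops:
            orfs = []
            for p in pops:
                orfs.extend(network.call_orfs(p.representative_id,
                                              viral_seqs[p.representative_id]))
            if orfs:
                pcs = network.cluster_proteins(orfs)
                presence = network.presence_matrix(pcs)
                assignments, edges = network.build_viral_clusters(presence, config.sig_min)
                pc_rows = [{"pc_id": pc, "orf_id": o.orf_id, "genome_id": o.genome_id}
                           for pc, mem in pcs.items() for o in mem]
                write_tsv(pd.DataFrame(pc_rows), out / "protein_clusters.tsv")
        write_tsv(pd.DataFrame([dataclasses.asdict(a) for a in assignments],
                               columns=["genome_id", "vc_id", "cls", "shares_reference"]),
                  out / "viral_clusters.tsv")
        write_tsv(pd.DataFrame(edges, columns=["a", "b", "shared", "p", "weight"]),
                  out / "vc_edges.tsv")
        report.n_vcs = len({a.vc_id for a in assignments if a.vc_id})
        report.vc_classes = {
            cls: sum(a.cls == cls for a in assignments)
            for cls in ("clustered", "outlier", "singleton")
        }

        stage = "host"
        calls: List[hostlink.HostCall] = []
        if viral_seqs:
            arrays = []
            for hid, hseq in bundle.host_bins.items():
                arrays.extend(hostlink.detect_crispr_arrays(hid, hseq))
            prophage_calls = []
            for vid, vseq in viral_seqs.items():
                prophage_calls.extend(
                    hostlink.find_prophage_links(vid, vseq, bundle.host_bins))
            crispr_calls = hostlink.match_spacers(arrays, viral_seqs, config.spacer_id_min)
            host_trnas = {
                hid: [t for t, *_ in hostlink.find_trnas(seq, bundle.trna_library)]
                for hid, seq in bundle.host_bins.items()
            }
            virus_trnas = {
                vid: [t for t, *_ in hostlink.find_trnas(seq, bundle.trna_library)]
                for vid, seq in viral_seqs.items()
            }
            trna_calls = hostlink.match_trnas(host_trnas, virus_trnas, prophage_calls)
            kmer_calls: List[hostlink.HostCall] = []
            if len(bundle.host_bins) >= 2 and len(bundle.decoy_hosts) >= hostlink.MIN_NULL_MODELS:
                models = {h: hostlink.train_markov(h, s, config.markov_k)
                          for h, s in bundle.host_bins.items()}
                nulls = [hostlink.train_markov(d, s, config.markov_k)
                         for d, s in bundle.decoy_hosts.items()]
                for vid, vseq in viral_seqs.items():
                    kmer_calls.extend(
                        hostlink.score_kmer_channel(vid, vseq, models, nulls,
                                                    prophage_calls))
            calls = prophage_calls + crispr_calls + trna_calls + kmer_calls
        call_rows = [dataclasses.asdict(c) for c in calls]
        write_tsv(pd.DataFrame(call_rows, columns=["virus_id", "host_id", "channel",
                                                   "identity_pct", "length_bp",
                                                   "loglik", "p", "accepted", "detail"]),
                  out / "host_calls.tsv")
        consensus_table, fraction = hostlink.consensus(calls, n_viruses=len(viral_seqs) or None)
        write_tsv(consensus_table, out / "host_consensus.tsv")
        report.n_viruses_host_linked = len(consensus_table)
        report.host_linked_fraction = round(fraction, 4) if viral_seqs else 0.0

        stage = "lifestyle"
        annotations = [a for a in bundle.truth.annotations if a.contig_id in viral_seqs]
        markers = lifestyle_mod.classify_markers(annotations)
        life_rows = []
        counts = {"confident_temperate": 0, "candidate_temperate": 0, "no_evidence": 0}
        for vid in viral_ids:
            atts = lifestyle_mod.find_att_pairs(vid, viral_seqs[vid], annotations)
            call = lifestyle_mod.classify_lifestyle(vid, markers.get(vid, set()), atts)
            counts[call.call] += 1
            life_rows.append({"contig_id": vid, "call": call.call,
                              "evidence": ";".join(call.evidence)})
        write_tsv(pd.DataFrame(life_rows, columns=["contig_id", "call", "evidence"]),
                  out / "lifestyle.tsv")
        report.lifestyle_counts = counts

        stage = "stats"
        if len(bundle.counts):
            lengths = {f: bundle.truth.contig_length[f] for f in bundle.counts.index}
            rpkm = stats.rpkm_matrix(bundle.counts, lengths)
            logm = stats.log_transform(rpkm)
            dm = stats.bray_curtis(logm)
            coords, evals = stats.pcoa(dm)
            design = dict(zip(bundle.design["sample_id"], bundle.design["group"]))
            r, p = stats.anosim(dm, design, n_perm=config.n_perm, seed=config.seed)
            report.anosim_r, report.anosim_p = round(r, 4), round(p, 4)
            groups = list(dict.fromkeys(bundle.design["group"]))
            contrasts = [(groups[0], g) for g in groups[1:]]
            wres = stats.wilcoxon_bh(rpkm, design, contrasts)
            tres = []
            for c in contrasts:
                tres.extend(stats.t_volcano(logm, design, c))
            write_tsv(rpkm.reset_index(), out / "rpkm.tsv")
            write_tsv(dm.reset_index(names="sample_id"), out / "bray_curtis.tsv")
            write_tsv(coords.reset_index(names="sample_id"), out / "pcoa.tsv")
            shannon_rows = [{"sample_id": s, "shannon_h": stats.shannon(rpkm[s].values)}
                            for s in rpkm.columns]
            write_tsv(pd.DataFrame(shannon_rows), out / "shannon.tsv")
            write_tsv(pd.DataFrame([dataclasses.asdict(t) for t in wres]),
                      out / "wilcoxon.tsv")
            write_tsv(pd.DataFrame([dataclasses.asdict(t) for t in tres]),
                      out / "t_volcano.tsv")
            for res, slot in ((wres, report.n_significant_wilcoxon),
                              (tres, report.n_significant_t)):
                for t in res:
                    slot.setdefault(t.contrast, 0)
                    if t.q < config.fdr_alpha:
                        slot[t.contrast] += 1
    except Exception as exc:  # noqa: BLE001 - abort with the failing stage named
        raise StageError(stage, exc) from exc

    report.wall_time_s = round(time.perf_counter() - t0, 3)
    report.validate()
    with open(out / "report.json", "w") as fh:
        fh.write(report.to_json())
    with open(out / "run_meta.json", "w") as fh:
        json.dump({"wall_time_s": report.wall_time_s}, fh)
    log.info("pipeline done in %.1fs", report.wall_time_s)
    return report
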