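"""Seeded synthetic gut-community generator with complete ground truth.

Emulates the data a bulk-metagenome virome study consumes, without reads
or external tools: host genome bins sampled from independent order-k
Markov chains (a learnable compositional host signal), phage genomes drawn
from their host's chain with extra substitution noise, temperate phages
planted back into hosts as prophages flanked by exact att direct repeats,
CRISPR arrays whose spacers are protospacers copied from target phages,
shared tRNAs, lysogeny marker genes, predictor score tables conditioned on
true viral status, and group-structured count matrices with designated
responder taxa.  Every planted feature is recorded in ground-truth tables
in the coordinates of the emitted sequences (0-based, half-open), so each
downstream detector can be scored exactly.

All randomness flows from one integer seed through ``numpy``'s Generator;
identical configs give byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lifestyle import GeneAnnotation

BASES = "ACGT"

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES
                 if a + b + c not in _STOPS]


class ConfigurationError(ValueError):
    pass


class RegenerationRequest(RuntimeError):
    """A planted feature would be ambiguous; the caller should redraw inputs."""


# ---------------------------------------------------------------- config


@dataclass
class ScoreConfig:
    """Per-label predictor score distributions (None-able channels).

    Viral contigs draw from "viral-like" distributions, everything else
    from "cellular-like" ones; each channel can be missing with its own
    probability.
    """

    viral_cat_probs: Tuple[float, ...] = (0.35, 0.20, 0.08, 0.10, 0.07, 0.05, 0.15)
    nonviral_cat_probs: Tuple[float, ...] = (0.0, 0.0, 0.02, 0.0, 0.0, 0.01, 0.97)
    viral_dvf_beta: Tuple[float, float] = (8.0, 2.0)
    nonviral_dvf_beta: Tuple[float, float] = (2.0, 8.0)
    viral_dvf_p_max: float = 0.04
    viral_marvel_beta: Tuple[float, float] = (8.0, 2.0)
    nonviral_marvel_beta: Tuple[float, float] = (2.0, 8.0)
    viral_cat_viral_prob: float = 0.6
    nonviral_cat_viral_prob: float = 0.02
    viral_nonviral_frac_range: Tuple[float, float] = (0.0, 0.35)
    nonviral_nonviral_frac_range: Tuple[float, float] = (0.45, 1.0)
    missing_dvf_prob: float = 0.10
    missing_marvel_prob: float = 0.20
    missing_cat_prob: float = 0.30

    @classmethod
    def forced_perfect(cls) -> "ScoreConfig":
        """True phages always VirSorter category 1; others carry no evidence."""
        return cls(
            viral_cat_probs=(1.0, 0, 0, 0, 0, 0, 0),
            nonviral_cat_probs=(0, 0, 0, 0, 0, 0, 1.0),
            missing_dvf_prob=1.0,
            missing_marvel_prob=1.0,
            missing_cat_prob=1.0,
            nonviral_cat_viral_prob=0.0,
            viral_cat_viral_prob=0.0,
        )

    @classmethod
    def all_missing(cls) -> "ScoreConfig":
        return cls(
            viral_cat_probs=(0, 0, 0, 0, 0, 0, 1.0),
            nonviral_cat_probs=(0, 0, 0, 0, 0, 0, 1.0),
            missing_dvf_prob=1.0,
            missing_marvel_prob=1.0,
            missing_cat_prob=1.0,
            viral_cat_viral_prob=0.0,
            nonviral_cat_viral_prob=0.0,
        )


@dataclass
class CommunityConfig:
    """Knobs of the synthetic community; defaults emulate the study design
    (three groups of five samples) at desk scale."""

    n_hosts: int = 8
    n_phages: int = 20
    host_length_bp: Tuple[int, int] = (30_000, 50_000)
    phage_length_bp: Tuple[int, int] = (15_000, 30_000)
    host_markov_order: int = 3
    phage_host_noise: float = 0.02  # substitutions vs the host chain draw
    variant_rate_range: Tuple[float, float] = (0.01, 0.03)  # within-population
    variant_fraction: float = 0.3  # of lytic, linear phages get one variant member
    temperate_fraction: float = 0.3
    circular_fraction: float = 0.2  # of lytic phages get a direct terminal repeat
    dtr_bp: int = 40
    att_core_length_bp: Tuple[int, int] = (12, 20)
    crispr_repeat_bp: Tuple[int, int] = (23, 47)
    crispr_spacer_bp: Tuple[int, int] = (26, 50)
    crispr_spacer_mismatches: int = 0
    crispr_spacers_per_host: int = 3
    n_trnas: int = 10
    trna_length_bp: Tuple[int, int] = (70, 90)
    trna_library: Optional[Dict[str, str]] = None
    n_nonviral_contigs: int = 30
    nonviral_contig_bp: Tuple[int, int] = (2_000, 20_000)
    n_decoy_hosts: int = 10
    decoy_length_bp: int = 30_000
    groups: Dict[str, int] = field(
        default_factory=lambda: {"control": 5, "treat1": 5, "treat2": 5}
    )
    responder_frac: float = 0.15
    responder_fold: float = 8.0
    sample_jitter_sd: float = 0.3  # lognormal per-sample abundance noise
    depth_per_sample: int = 200_000
    score_config: ScoreConfig = field(default_factory=ScoreConfig)
    seed: int = 0

    def validate(self) -> None:
        for name in ("host_length_bp", "phage_length_bp", "att_core_length_bp",
                     "crispr_repeat_bp", "crispr_spacer_bp", "trna_length_bp",
                     "nonviral_contig_bp"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name}: invalid range ({lo}, {hi})")
        if self.n_hosts < 1:
            raise ConfigurationError("need at least one host")
        if self.n_phages < 0:
            raise ConfigurationError("n_phages must be >= 0")
        if len(self.groups) < 2 or any(n < 2 for n in self.groups.values()):
            raise ConfigurationError("need >=2 groups with >=2 samples each")
        if self.depth_per_sample <= 0:
            raise ConfigurationError("depth_per_sample must be positive")
        if self.host_markov_order < 0:
            raise ConfigurationError("host_markov_order must be >= 0")


# ------------------------------------------------------------ ground truth


@dataclass
class GroundTruth:
    viral_status: Dict[str, bool] = field(default_factory=dict)
    topology: Dict[str, str] = field(default_factory=dict)
    contig_length: Dict[str, int] = field(default_factory=dict)
    population_id: Dict[str, str] = field(default_factory=dict)
    host_of: Dict[str, str] = field(default_factory=dict)  # source-chain host
    host_links: List[Tuple[str, str, str]] = field(default_factory=list)
    lifestyle: Dict[str, str] = field(default_factory=dict)
    features: List[dict] = field(default_factory=list)
    annotations: List[GeneAnnotation] = field(default_factory=list)
    base_abundance: Optional[pd.Series] = None
    responders: Dict[str, Dict[str, float]] = field(default_factory=dict)
    abundance: Optional[pd.DataFrame] = None

    def features_table(self) -> pd.DataFrame:
        cols = ["contig_id", "feature_type", "start", "end", "strand", "target_id", "detail"]
        return pd.DataFrame(self.features, columns=cols)

    def links_for(self, channel: str) -> set:
        return {(v, h) for v, h, c in self.host_links if c == channel}


@dataclass
class CommunityBundle:
    config: CommunityConfig
    contigs: Dict[str, str]
    host_bins: Dict[str, str]
    decoy_hosts: Dict[str, str]
    trna_library: Dict[str, str]
    scores: pd.DataFrame
    counts: pd.DataFrame
    design: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        from .io import write_fasta, write_tsv

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "contigs.fasta", self.contigs)
        write_fasta(out / "host_bins.fasta", self.host_bins)
        write_fasta(out / "decoy_hosts.fasta", self.decoy_hosts)
        write_fasta(out / "trna_library.fasta", self.trna_library)
        write_tsv(self.scores, out / "scores.tsv")
        write_tsv(self.counts.reset_index(names="feature_id"), out / "counts.tsv")
        write_tsv(self.design, out / "design.tsv")
        write_tsv(self.truth.features_table(), out / "truth_features.tsv")
        ann = pd.DataFrame(
            [dataclasses.asdict(a) for a in self.truth.annotations],
            columns=["contig_id", "start", "end", "strand", "label"],
        )
        write_tsv(ann, out / "annotations.tsv")
        cfg = dataclasses.asdict(self.config)
        cfg["trna_library"] = self.trna_library
        with open(out / "config.json", "w") as fh:
            json.dump(cfg, fh, indent=2, default=list)


# ------------------------------------------------------- sequence sampling


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _dirichlet_chain(rng: np.random.Generator, order: int) -> np.ndarray:
    """Cumulative transition rows (4**order, 4) with Dirichlet(1) rows."""
    rows = rng.dirichlet(np.ones(4), size=4 ** order)
    return np.cumsum(rows, axis=1)


def _sample_chain(rng: np.random.Generator, cum: np.ndarray, order: int, length: int) -> str:
    n_ctx = cum.shape[0]
    ctx = int(rng.integers(0, n_ctx))
    us = rng.random(length)
    rows = cum.tolist()
    mask = n_ctx // 4 if order > 0 else 1
    out = []
    for u in us:
        row = rows[ctx]
        b = 0 if u < row[0] else 1 if u < row[1] else 2 if u < row[2] else 3
        out.append(BASES[b])
        if order > 0:
            ctx = (ctx % mask) * 4 + b
    return "".join(out)


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            protected: Sequence[Tuple[int, int]] = ()) -> str:
    """Uniform substitutions at ``rate``; ``protected`` intervals are kept."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    for s, e in protected:
        hit[s:e] = False
    idx = np.nonzero(hit)[0]
    lut = {ord(b): i for i, b in enumerate(BASES)}
    enc = np.array([lut[b] for b in arr[idx]]) if idx.size else np.empty(0, dtype=int)
    shift = rng.integers(1, 4, size=idx.size)
    newb = (enc + shift) % 4
    for j, i in enumerate(idx):
        arr[i] = ord(BASES[int(newb[j])])
    return arr.tobytes().decode()


# -------------------------------------------------------- feature planting


def plant_prophage(
    host_seq: str, phage_seq: str, att_core: str, insert_pos: int
) -> Tuple[str, dict]:
    """Insert ``att_core + phage_seq + att_core`` at ``insert_pos``.

    Raises :class:`RegenerationRequest` when the att core already occurs in
    the host (or inside the phage), which would make the direct-repeat pair
    ambiguous.
    """
    if not phage_seq:
        raise ValueError("empty phage sequence")
    if not att_core:
        raise ValueError("empty att core")
    if not (0 <= insert_pos <= len(host_seq)):
        raise ValueError("insert_pos outside host")
    if att_core in host_seq or att_core in phage_seq:
        raise RegenerationRequest("att core is not unique; redraw it")
    la = len(att_core)
    modified = host_seq[:insert_pos] + att_core + phage_seq + att_core + host_seq[insert_pos:]
    record = {
        "insert_pos": insert_pos,
        "attL": (insert_pos, insert_pos + la),
        "attR": (insert_pos + la + len(phage_seq), insert_pos + 2 * la + len(phage_seq)),
        "prophage": (insert_pos, insert_pos + 2 * la + len(phage_seq)),
        "att_core": att_core,
    }
    return modified, record


def plant_crispr_array(
    host_seq: str,
    protospacers: Sequence[str],
    n_repeats: int,
    repeat_seq: str,
    insert_pos: Optional[int] = None,
    n_mismatches: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[str, dict]:
    """Insert ``repeat (spacer repeat) x (n_repeats - 1)`` into the host.

    Spacers are the protospacers with ``n_mismatches`` substitutions each.
    Raises :class:`RegenerationRequest` when the repeat already occurs in
    the host or when array boundaries would be ambiguous for an exact-repeat
    detector (equal characters flanking consecutive repeat copies).
    """
    if n_repeats < 2:
        raise ValueError("a CRISPR array needs at least 2 repeats")
    if len(protospacers) != n_repeats - 1:
        raise ValueError("need exactly n_repeats - 1 protospacers")
    if repeat_seq in host_seq:
        raise RegenerationRequest("repeat occurs in host; redraw it")
    if insert_pos is None:
        insert_pos = len(host_seq)
    spacers = []
    for sp in protospacers:
        if n_mismatches > 0:
            if rng is None:
                raise ValueError("rng required when n_mismatches > 0")
            pos = rng.choice(len(sp), size=n_mismatches, replace=False)
            chars = list(sp)
            for p in pos:
                chars[p] = BASES[(BASES.index(chars[p]) + int(rng.integers(1, 4))) % 4]
            sp = "".join(chars)
        spacers.append(sp)
    # boundary-ambiguity guards: an exact maximal-extension detector must
    # stop exactly at the planted repeat edges
    for a, b in zip(spacers[:-1], spacers[1:]):
        if a[0] == b[0] or a[-1] == b[-1]:
            raise RegenerationRequest("consecutive spacers share a boundary base")
    left_char = host_seq[insert_pos - 1] if insert_pos > 0 else ""
    right_char = host_seq[insert_pos] if insert_pos < len(host_seq) else ""
    if spacers and (left_char == spacers[0][-1] or right_char == spacers[-1][0]):
        raise RegenerationRequest("array boundary matches a spacer boundary base")
    parts = [repeat_seq]
    for sp in spacers:
        parts.extend((sp, repeat_seq))
    array = "".join(parts)
    modified = host_seq[:insert_pos] + array + host_seq[insert_pos:]
    spacer_coords = []
    cursor = insert_pos + len(repeat_seq)
    for sp in spacers:
        spacer_coords.append((sp, cursor, cursor + len(sp)))
        cursor += len(sp) + len(repeat_seq)
    record = {
        "start": insert_pos,
        "end": insert_pos + len(array),
        "repeat_seq": repeat_seq,
        "spacers": spacer_coords,
        "protospacers": list(protospacers),
    }
    return modified, record


# --------------------------------------------------------- score simulation


def simulate_tool_scores(
    truth: GroundTruth, score_config: ScoreConfig, seed: int
) -> pd.DataFrame:
    """One predictor-evidence row per contig, conditioned on true status."""
    rng = np.random.default_rng(seed)
    sc = score_config
    rows = []
    for contig_id in truth.viral_status:
        viral = truth.viral_status[contig_id]
        cat_probs = np.array(sc.viral_cat_probs if viral else sc.nonviral_cat_probs, dtype=float)
        cat_probs = cat_probs / cat_probs.sum()
        cat_draw = int(rng.choice(7, p=cat_probs))
        category = cat_draw + 1 if cat_draw < 6 else None
        a, b = sc.viral_dvf_beta if viral else sc.nonviral_dvf_beta
        dvf = float(rng.beta(a, b))
        dvf_p = float(rng.uniform(0, sc.viral_dvf_p_max)) if viral else float(rng.uniform(0, 1))
        if rng.random() < sc.missing_dvf_prob:
            dvf = dvf_p = None
        a, b = sc.viral_marvel_beta if viral else sc.nonviral_marvel_beta
        marvel = float(100 * rng.beta(a, b))
        if rng.random() < sc.missing_marvel_prob:
            marvel = None
        catp = sc.viral_cat_viral_prob if viral else sc.nonviral_cat_viral_prob
        cat_viral = bool(rng.random() < catp)
        lo, hi = sc.viral_nonviral_frac_range if viral else sc.nonviral_nonviral_frac_range
        frac = float(rng.uniform(lo, hi))
        if rng.random() < sc.missing_cat_prob:
            cat_viral, frac = None, None
        rows.append(
            {
                "contig_id": contig_id,
                "length_bp": truth.contig_length[contig_id],
                "topology": truth.topology[contig_id],
                "virsorter_category": category,
                "dvf_score": dvf,
                "dvf_p": dvf_p,
                "marvel_prob": marvel,
                "cat_viral": cat_viral,
                "cat_nonviral_gene_frac": frac,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "contig_id", "length_bp", "topology", "virsorter_category",
            "dvf_score", "dvf_p", "marvel_prob", "cat_viral", "cat_nonviral_gene_frac",
        ],
    )
    return df


# --------------------------------------------------------- count simulation


def simulate_counts(
    base_abundance: pd.Series,
    design: pd.DataFrame,
    depth: int,
    seed: int,
    responders: Optional[Mapping[str, Mapping[str, float]]] = None,
    jitter_sd: float = 0.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial per-sample counts from a base relative-abundance profile.

    Responder features are multiplied by their group fold-change, an
    optional lognormal per-sample jitter is applied, and the profile is
    renormalized before each multinomial draw of size ``depth``.  Returns
    ``(counts, true_profiles)``, both features x samples.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    samples = list(design["sample_id"])
    if base_abundance.empty:
        empty = pd.DataFrame(index=pd.Index([], name="feature_id"), columns=samples, dtype=float)
        return empty.fillna(0), empty.fillna(0)
    if not np.isclose(base_abundance.sum(), 1.0, atol=1e-8):
        raise ValueError("base abundance profile must sum to 1")
    rng = np.random.default_rng(seed)
    responders = responders or {}
    group_of = dict(zip(design["sample_id"], design["group"]))
    profiles = {}
    counts = {}
    features = list(base_abundance.index)
    for sample in samples:
        grp = group_of[sample]
        prof = base_abundance.values.astype(float).copy()
        for feat, folds in responders.items():
            if grp in folds:
                prof[features.index(feat)] *= folds[grp]
        if jitter_sd > 0:
            prof = prof * np.exp(rng.normal(0.0, jitter_sd, size=prof.size))
        prof = prof / prof.sum()
        profiles[sample] = prof
        counts[sample] = rng.multinomial(depth, prof)
    idx = pd.Index(features, name="feature_id")
    return (
        pd.DataFrame(counts, index=idx)[samples],
        pd.DataFrame(profiles, index=idx)[samples],
    )


# ---------------------------------------------------------- gene planting


def _gene_seq(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + TAA, preceded by an in-frame TAA guard."""
    body = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons - 2))
    return "TAA" + "ATG" + body + "TAA"


def _pick_insert_pos(
    rng: np.random.Generator, length: int, occupied: List[Tuple[int, int]],
    margin: int, lo: Optional[int] = None, hi: Optional[int] = None,
) -> int:
    lo = margin if lo is None else lo
    hi = length - margin if hi is None else hi
    if hi <= lo:
        raise ConfigurationError("sequence too short for requested planting")
    for _ in range(200):
        pos = int(rng.integers(lo, hi))
        if all(not (s - margin <= pos <= e + margin) for s, e in occupied):
            return pos
    raise ConfigurationError("could not find a free insertion position")


def _shift_recorded_features(truth: "GroundTruth", contig_id: str, pos: int, shift: int) -> None:
    """Keep previously recorded coordinates valid after an insertion."""
    for f in truth.features:
        if f["contig_id"] == contig_id and f["start"] >= pos:
            f["start"] += shift
            f["end"] += shift


# ------------------------------------------------------------- generation


def generate_community(config: CommunityConfig) -> CommunityBundle:
    """Generate the full synthetic bundle with ground truth (deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    # tRNA library
    if config.trna_library is not None:
        trna_library = dict(config.trna_library)
    else:
        trna_library = {
            f"tRNA_{i + 1:02d}": _random_seq(
                rng, int(rng.integers(config.trna_length_bp[0], config.trna_length_bp[1] + 1))
            )
            for i in range(config.n_trnas)
        }

    # host chains and background sequences
    order = config.host_markov_order
    host_ids = [f"host_{i + 1:02d}" for i in range(config.n_hosts)]
    chains = {h: _dirichlet_chain(rng, order) for h in host_ids}
    host_seqs: Dict[str, str] = {}
    for h in host_ids:
        L = int(rng.integers(config.host_length_bp[0], config.host_length_bp[1] + 1))
        host_seqs[h] = _sample_chain(rng, chains[h], order, L)

    # phages: lifestyle, host assignment, genes, tRNAs, att wrapping
    phage_ids = [f"phage_{i + 1:03d}" for i in range(config.n_phages)]
    phage_seqs: Dict[str, str] = {}
    phage_host: Dict[str, str] = {}
    phage_temperate: Dict[str, bool] = {}
    phage_att: Dict[str, str] = {}
    annotations_by_contig: Dict[str, List[GeneAnnotation]] = defaultdict(list)

    for pid in phage_ids:
        host = host_ids[int(rng.integers(0, config.n_hosts))]
        phage_host[pid] = host
        L = int(rng.integers(config.phage_length_bp[0], config.phage_length_bp[1] + 1))
        inner = _sample_chain(rng, chains[host], order, L)
        inner = _mutate(rng, inner, config.phage_host_noise)
        temperate = bool(rng.random() < config.temperate_fraction)
        phage_temperate[pid] = temperate
        genes: List[Tuple[int, int, str]] = []  # (start, end, label) on inner

        def insert_segment(seq: str, pos: int, segment: str) -> str:
            nonlocal genes
            genes = [
                (s + len(segment), e + len(segment), lab) if s >= pos else (s, e, lab)
                for s, e, lab in genes
            ]
            return seq[:pos] + segment + seq[pos:]

        occupied = lambda: [(s, e) for s, e, _ in genes]
        if temperate:
            seg = _gene_seq(rng, int(rng.integers(90, 140)))
            pos = _pick_insert_pos(rng, len(inner), occupied(), margin=120, lo=200, hi=1_500)
            inner = insert_segment(inner, pos, seg)
            genes.append((pos + 3, pos + len(seg), "phage integrase"))
            if rng.random() < 0.5:
                seg = _gene_seq(rng, int(rng.integers(60, 90)))
                pos = _pick_insert_pos(rng, len(inner), occupied(), margin=120, lo=2_000, hi=5_000)
                inner = insert_segment(inner, pos, seg)
                genes.append((pos + 3, pos + len(seg), "excisionase"))
            trna_id = list(trna_library)[int(rng.integers(0, len(trna_library)))]
            pos = _pick_insert_pos(rng, len(inner), occupied(), margin=120, lo=5_000, hi=len(inner) - 3_000)
            inner = insert_segment(inner, pos, trna_library[trna_id])
            truth.features.append(
                {"contig_id": pid, "feature_type": "trna", "start": pos,
                 "end": pos + len(trna_library[trna_id]), "strand": "+",
                 "target_id": trna_id, "detail": ""}
            )
        else:
            seg = _gene_seq(rng, int(rng.integers(120, 200)))
            pos = _pick_insert_pos(rng, len(inner), occupied(), margin=120, lo=1_000, hi=len(inner) - 2_000)
            inner = insert_segment(inner, pos, seg)
            genes.append((pos + 3, pos + len(seg), "major capsid protein"))

        if temperate:
            # exact att direct repeat wrapping the phage; redraw until unique
            for _ in range(100):
                la = int(rng.integers(config.att_core_length_bp[0], config.att_core_length_bp[1] + 1))
                att = _random_seq(rng, la)
                if att not in inner and att not in host_seqs[host]:
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise ConfigurationError("could not draw a unique att core")
            contig = att + inner + att
            genes = [(s + la, e + la, lab) for s, e, lab in genes]
            phage_att[pid] = att
            truth.features.append(
                {"contig_id": pid, "feature_type": "att", "start": 0, "end": la,
                 "strand": "+", "target_id": pid, "detail": "attL"}
            )
            truth.features.append(
                {"contig_id": pid, "feature_type": "att", "start": la + len(inner),
                 "end": 2 * la + len(inner), "strand": "+", "target_id": pid,
                 "detail": "attR"}
            )
            # tRNA coordinates shifted by the attL wrap
            for feat in truth.features:
                if feat["contig_id"] == pid and feat["feature_type"] == "trna":
                    feat["start"] += la
                    feat["end"] += la
            topology = "linear"
        else:
            if rng.random() < config.circular_fraction:
                contig = inner + inner[: config.dtr_bp]
                topology = "circular"
            else:
                contig = inner
                topology = "linear"

        phage_seqs[pid] = contig
        truth.viral_status[pid] = True
        truth.topology[pid] = topology
        truth.contig_length[pid] = len(inner) if topology == "circular" else len(contig)
        truth.lifestyle[pid] = "confident_temperate" if temperate else "lytic"
        truth.host_of[pid] = host
        truth.host_links.append((pid, host, "kmer"))
        for s, e, lab in genes:
            ann = GeneAnnotation(pid, s, e, "+", lab)
            truth.annotations.append(ann)
            annotations_by_contig[pid].append(ann)
            truth.features.append(
                {"contig_id": pid, "feature_type": "gene", "start": s, "end": e,
                 "strand": "+", "target_id": "", "detail": lab}
            )

    # population variants (members of the same vOTU at 1-3% substitutions)
    parents = [p for p in phage_ids
               if not phage_temperate[p] and truth.topology[p] == "linear"]
    n_variants = int(round(config.variant_fraction * len(parents)))
    variant_parents = [parents[i] for i in
                       sorted(rng.choice(len(parents), size=n_variants, replace=False))] if n_variants else []
    for parent in variant_parents:
        vid = f"{parent}v"
        rate = float(rng.uniform(*config.variant_rate_range))
        phage_seqs[vid] = _mutate(rng, phage_seqs[parent], rate)
        phage_host[vid] = phage_host[parent]
        phage_temperate[vid] = False
        truth.viral_status[vid] = True
        truth.topology[vid] = "linear"
        truth.contig_length[vid] = len(phage_seqs[vid])
        truth.lifestyle[vid] = "lytic"
        truth.host_of[vid] = phage_host[parent]
        truth.host_links.append((vid, phage_host[parent], "kmer"))
        for ann in annotations_by_contig[parent]:
            copy = GeneAnnotation(vid, ann.start, ann.end, ann.strand, ann.label)
            truth.annotations.append(copy)
            annotations_by_contig[vid].append(copy)
    all_phage_ids = phage_ids + [f"{p}v" for p in variant_parents]
    for pid in phage_ids:
        truth.population_id[pid] = f"pop_{pid}"
    for parent in variant_parents:
        truth.population_id[f"{parent}v"] = f"pop_{parent}"

    # plant temperate phages back into their hosts as prophages
    host_features: Dict[str, List[Tuple[int, int]]] = {h: [] for h in host_ids}
    for pid in phage_ids:
        if not phage_temperate[pid]:
            continue
        host = phage_host[pid]
        att = phage_att[pid]
        inner = phage_seqs[pid][len(att):-len(att)]
        for _ in range(100):
            pos = _pick_insert_pos(rng, len(host_seqs[host]), host_features[host],
                                   margin=1_100)
            try:
                modified, rec = plant_prophage(host_seqs[host], inner, att, pos)
            except RegenerationRequest:
                continue
            break
        else:  # pragma: no cover
            raise ConfigurationError("could not place prophage")
        host_seqs[host] = modified
        span = rec["prophage"]
        shift = span[1] - span[0]
        host_features[host] = [
            (s + shift, e + shift) if s >= pos else (s, e) for s, e in host_features[host]
        ] + [span]
        _shift_recorded_features(truth, host, pos, shift)
        truth.host_links.append((pid, host, "prophage"))
        truth.host_links.append((pid, host, "trna"))
        truth.features.append(
            {"contig_id": host, "feature_type": "prophage", "start": span[0],
             "end": span[1], "strand": "+", "target_id": pid, "detail": ""}
        )
        for tag, (s, e) in (("attL", rec["attL"]), ("attR", rec["attR"])):
            truth.features.append(
                {"contig_id": host, "feature_type": "att", "start": s, "end": e,
                 "strand": "+", "target_id": pid, "detail": tag}
            )

    # CRISPR arrays: spacers are protospacers copied from target phages
    crispr_targets = [p for p in phage_ids if p not in set(variant_parents)]
    for host in host_ids:
        own = [p for p in crispr_targets if phage_host[p] == host]
        if not own:
            continue
        n_sp = min(config.crispr_spacers_per_host, len(own) * 2)
        for _ in range(200):
            targets = [own[int(rng.integers(0, len(own)))] for _ in range(n_sp)]
            protospacers = []
            coords = []
            ok = True
            for t in targets:
                sl = int(rng.integers(config.crispr_spacer_bp[0], config.crispr_spacer_bp[1] + 1))
                if len(phage_seqs[t]) <= sl:
                    ok = False
                    break
                start = int(rng.integers(0, len(phage_seqs[t]) - sl))
                protospacers.append(phage_seqs[t][start : start + sl])
                coords.append((t, start, start + sl))
            if not ok:
                continue
            rl = int(rng.integers(config.crispr_repeat_bp[0], config.crispr_repeat_bp[1] + 1))
            repeat = _random_seq(rng, rl)
            pos = _pick_insert_pos(rng, len(host_seqs[host]), host_features[host], margin=200)
            try:
                modified, rec = plant_crispr_array(
                    host_seqs[host], protospacers, n_sp + 1, repeat,
                    insert_pos=pos, n_mismatches=config.crispr_spacer_mismatches, rng=rng,
                )
            except RegenerationRequest:
                continue
            break
        else:  # pragma: no cover
            raise ConfigurationError("could not place CRISPR array")
        host_seqs[host] = modified
        shift = rec["end"] - rec["start"]
        host_features[host] = [
            (s + shift, e + shift) if s >= pos else (s, e) for s, e in host_features[host]
        ] + [(rec["start"], rec["end"])]
        _shift_recorded_features(truth, host, pos, shift)
        truth.features.append(
            {"contig_id": host, "feature_type": "crispr_array", "start": rec["start"],
             "end": rec["end"], "strand": "+", "target_id": "",
             "detail": f"repeat={rec['repeat_seq']}"}
        )
        for (t, ps, pe), (sp, ss, se) in zip(coords, rec["spacers"]):
            truth.features.append(
                {"contig_id": host, "feature_type": "crispr_spacer", "start": ss,
                 "end": se, "strand": "+", "target_id": t,
                 "detail": f"protospacer={ps}-{pe}"}
            )
            if (t, host, "crispr") not in truth.host_links:
                truth.host_links.append((t, host, "crispr"))

    # non-viral contigs: fresh draws from host chains (compositionally host-like)
    nonviral_ids = []
    for i in range(config.n_nonviral_contigs):
        cid = f"frag_{i + 1:03d}"
        host = host_ids[int(rng.integers(0, config.n_hosts))]
        L = int(rng.integers(config.nonviral_contig_bp[0], config.nonviral_contig_bp[1] + 1))
        seq = _sample_chain(rng, chains[host], order, L)
        phage_seqs[cid] = seq  # goes into the contig pool only
        nonviral_ids.append(cid)
        truth.viral_status[cid] = False
        truth.topology[cid] = "linear"
        truth.contig_length[cid] = L

    contigs = {cid: phage_seqs[cid] for cid in all_phage_ids + nonviral_ids}

    # decoy hosts for the k-mer channel null
    decoys = {}
    for i in range(config.n_decoy_hosts):
        cum = _dirichlet_chain(rng, order)
        decoys[f"decoy_{i + 1:02d}"] = _sample_chain(rng, cum, order, config.decoy_length_bp)

    # predictor scores
    scores = simulate_tool_scores(truth, config.score_config,
                                  seed=int(rng.integers(0, 2**31 - 1)))

    # abundances and counts over viral features
    design = pd.DataFrame(
        [
            {"sample_id": f"{grp}_{i + 1}", "group": grp}
            for grp, n in config.groups.items()
            for i in range(n)
        ]
    )
    if all_phage_ids:
        base = pd.Series(
            rng.lognormal(0.0, 1.0, size=len(all_phage_ids)), index=all_phage_ids
        )
        base = base / base.sum()
        treat_groups = [g for g in config.groups if g != next(iter(config.groups))]
        responders: Dict[str, Dict[str, float]] = {}
        n_resp = int(round(config.responder_frac * len(all_phage_ids)))
        pool = list(all_phage_ids)
        for grp in treat_groups:
            if n_resp == 0 or not pool:
                break
            chosen = [pool[i] for i in sorted(rng.choice(len(pool), size=min(n_resp, len(pool)), replace=False))]
            for feat in chosen:
                responders.setdefault(feat, {})[grp] = config.responder_fold
                pool.remove(feat)
        counts, profiles = simulate_counts(
            base, design, config.depth_per_sample,
            seed=int(rng.integers(0, 2**31 - 1)),
            responders=responders, jitter_sd=config.sample_jitter_sd,
        )
        truth.base_abundance = base
        truth.responders = responders
        truth.abundance = profiles
    else:
        counts = pd.DataFrame(index=pd.Index([], name="feature_id"),
                              columns=list(design["sample_id"]), dtype=float)
        truth.base_abundance = pd.Series(dtype=float)
        truth.abundance = counts.copy()

    return CommunityBundle(
        config=config,
        contigs=contigs,
        host_bins=host_seqs,
        decoy_hosts=decoys,
        trna_library=trna_library,
        scores=scores,
        counts=counts,
        design=design,
        truth=truth,
    )


# -------------------------------------------------- planted population sets


def planted_population_set(
    n_populations: int,
    seed: int,
    length_range: Tuple[int, int] = (10_000, 50_000),
    members_per_population: int = 2,
    substitution_range: Tuple[float, float] = (0.01, 0.03),
) -> Tuple[Dict[str, str], Dict[str, str]]:
    """Planted vOTU benchmark: i.i.d. representatives plus mutated members.

    Representatives are independent uniform-random sequences (inter-population
    identity ~25%, far below any clustering threshold); members are copies at
    a per-population substitution rate.  Returns (genomes, true population
    label per genome).
    """
    rng = np.random.default_rng(seed)
    genomes: Dict[str, str] = {}
    labels: Dict[str, str] = {}
    for i in range(n_populations):
        rep_id = f"rep_{i + 1:03d}"
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        rep = _random_seq(rng, L)
        genomes[rep_id] = rep
        labels[rep_id] = f"pop_{i + 1:03d}"
        rate = float(rng.uniform(*substitution_range))
        for m in range(members_per_population - 1):
            mid = f"rep_{i + 1:03d}_m{m + 1}"
            genomes[mid] = _mutate(rng, rep, rate)
            labels[mid] = labels[rep_id]
    return genomes, labels
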