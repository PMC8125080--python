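"""Species-level viral population (vOTU) clustering.

Viral genomes are dereplicated into populations at >=95% average nucleotide
identity (ANI) over >=80% of the shorter genome (aligned fraction, AF) —
the community-standard species rank for uncultivated viruses.

The ANI engine finds exact shared k-mer anchors (default k=15, both
strands), chains collinear anchors into blocks, and aligns each block with
a global edit-distance alignment (edlib), summing matched columns over
aligned columns.  AF is the fraction of the shorter genome covered by
accepted blocks.  Clustering is greedy longest-first: each genome joins
the first existing representative meeting both thresholds, else seeds a
new population; ties on length break by lexicographic id, so the partition
does not depend on input order.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import edlib

from .io import revcomp

ANI_MIN_PCT = 95.0
AF_MIN_PCT = 80.0
ANCHOR_K = 15
# anchors on near-identical pairs are dense; allow indel drift proportional
# to the gap so a chance off-diagonal k-mer repeat cannot seed a bogus block
CHAIN_MAX_GAP = 5_000
CHAIN_MIN_DRIFT = 100
CHAIN_DRIFT_FRAC = 0.2
FLANK_EXTENSION = 100


@dataclass(frozen=True)
class AniAf:
    query_id: str
    target_id: str
    ani_pct: float
    af_pct: float


@dataclass
class ViralPopulation:
    population_id: str
    representative_id: str
    member_ids: List[str]
    member_aniaf: Dict[str, AniAf] = field(default_factory=dict)
    novel: Optional[bool] = None


def _cigar_matches(cigar: str) -> Tuple[int, int]:
    """(matched columns, total columns) from an edlib extended cigar."""
    matches = cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                matches += n
    return matches, cols


def _anchors(short: str, long: str, k: int) -> List[Tuple[int, int]]:
    """(i_short, j_long) pairs of exact shared k-mers, using k-mers unique in each."""
    pos_long: Dict[str, int] = {}
    seen_multi = set()
    for j in range(len(long) - k + 1):
        km = long[j : j + k]
        if km in pos_long:
            seen_multi.add(km)
        else:
            pos_long[km] = j
    counts_short: Dict[str, int] = defaultdict(int)
    for i in range(len(short) - k + 1):
        counts_short[short[i : i + k]] += 1
    out = []
    for i in range(len(short) - k + 1):
        km = short[i : i + k]
        if km in pos_long and km not in seen_multi and counts_short[km] == 1:
            out.append((i, pos_long[km]))
    return out


def _chain(anchors: List[Tuple[int, int]], k: int) -> List[Tuple[int, int, int, int]]:
    """Greedy collinear chaining; returns (i0, i1, j0, j1) block spans (end-exclusive)."""
    blocks = []
    anchors = sorted(anchors)
    cur: Optional[List[int]] = None
    prev: Optional[Tuple[int, int]] = None
    for i, j in anchors:
        if cur is None:
            cur = [i, i + k, j, j + k]
        else:
            pi, pj = prev
            di, dj = i - pi, j - pj
            allowed = max(CHAIN_MIN_DRIFT, int(CHAIN_DRIFT_FRAC * di))
            if 0 < di and 0 < dj and di <= CHAIN_MAX_GAP and abs(dj - di) <= allowed:
                cur[1], cur[3] = i + k, j + k
            else:
                blocks.append(tuple(cur))
                cur = [i, i + k, j, j + k]
        prev = (i, j)
    if cur is not None:
        blocks.append(tuple(cur))
    return blocks


def _score_strand(short: str, long: str, k: int) -> Tuple[int, int, int]:
    """(matches, columns, covered short bases) for one orientation."""
    anchors = _anchors(short, long, k)
    if not anchors:
        return 0, 0, 0
    blocks = _chain(anchors, k)
    # drop micro-blocks that are probably spurious unless they are all we have
    main = [b for b in blocks if b[1] - b[0] >= 2 * k] or blocks
    matches = cols = covered = 0
    last_end = 0
    for i0, i1, j0, j1 in sorted(main):
        if i1 <= last_end:
            continue
        # extend flanks a bounded amount so terminal anchor loss is recovered
        e_l = min(FLANK_EXTENSION, i0, j0)
        e_r = min(FLANK_EXTENSION, len(short) - i1, len(long) - j1)
        start_i = max(i0 - e_l, last_end)
        clip = start_i - (i0 - e_l)
        a = short[start_i : i1 + e_r]
        b = long[j0 - e_l + clip : j1 + e_r]
        if not a or not b:
            continue
        res = edlib.align(a, b, mode="NW", task="path")
        m, c = _cigar_matches(res["cigar"])
        matches += m
        cols += c
        covered += len(a)
        last_end = i1 + e_r
    return matches, cols, covered


def pairwise_ani_af(
    a: str, b: str, a_id: str = "a", b_id: str = "b", k: int = ANCHOR_K
) -> AniAf:
    """ANI/AF between two genomes; AF is over the shorter sequence, both strands."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return AniAf(a_id, b_id, 100.0, 100.0)
    short, long = (a, b) if len(a) <= len(b) else (b, a)
    fwd = _score_strand(short, long, k)
    rev = _score_strand(revcomp(short), long, k)
    matches, cols, covered = max(fwd, rev, key=lambda t: (t[0], t[2]))
    if cols == 0:
        return AniAf(a_id, b_id, 0.0, 0.0)
    ani = 100.0 * matches / cols
    af = min(100.0, 100.0 * covered / len(short))
    return AniAf(a_id, b_id, ani, af)


def _shared_kmer_count(a: str, b: str, k: int = ANCHOR_K) -> int:
    ka = {a[i : i + k] for i in range(0, len(a) - k + 1, k)}
    kb = {b[j : j + k] for j in range(len(b) - k + 1)}
    return len(ka & kb)


def _meets(a: str, b: str, ani_min: float, af_min: float) -> Optional[AniAf]:
    # cheap anchor prefilter: near-identical pairs share many sampled k-mers
    if _shared_kmer_count(a, b) < 3 and _shared_kmer_count(revcomp(a), b) < 3:
        return None
    hit = pairwise_ani_af(a, b)
    if hit.ani_pct >= ani_min and hit.af_pct >= af_min:
        return hit
    return None


def greedy_cluster(
    genomes: Mapping[str, str],
    ani_min: float = ANI_MIN_PCT,
    af_min: float = AF_MIN_PCT,
) -> List[ViralPopulation]:
    """Greedy longest-first clustering into viral populations."""
    ids = list(genomes)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate genome ids")
    order = sorted(ids, key=lambda g: (-len(genomes[g]), g))
    pops: List[ViralPopulation] = []
    for gid in order:
        seq = genomes[gid]
        placed = False
        for pop in pops:
            hit = _meets(seq, genomes[pop.representative_id], ani_min, af_min)
            if hit is not None:
                pop.member_ids.append(gid)
                pop.member_aniaf[gid] = AniAf(gid, pop.representative_id, hit.ani_pct, hit.af_pct)
                placed = True
                break
        if not placed:
            pop = ViralPopulation(
                population_id=f"vpop_{len(pops) + 1:04d}",
                representative_id=gid,
                member_ids=[gid],
            )
            pop.member_aniaf[gid] = AniAf(gid, gid, 100.0, 100.0)
            pops.append(pop)
    return pops


def novelty_vs_reference(
    populations: Sequence[ViralPopulation],
    genomes: Mapping[str, str],
    reference_genomes: Mapping[str, str],
    ani_min: float = ANI_MIN_PCT,
    af_min: float = AF_MIN_PCT,
) -> Dict[str, bool]:
    """Flag each population novel (True) unless its representative matches a reference."""
    flags: Dict[str, bool] = {}
    for pop in populations:
        rep = genomes[pop.representative_id]
        known = any(
            _meets(rep, ref_seq, ani_min, af_min) is not None
            for ref_seq in reference_genomes.values()
        )
        pop.novel = not known
        flags[pop.population_id] = not known
    return flags
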