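"""Temperate / lytic lifestyle calls for viral contigs.

Lysogeny marker genes (integrase / site-specific recombinase, excisionase,
phage repressor / antirepressor, ParA/B partition genes) are read from a
functional annotation table via a case-insensitive keyword map.  A contig
is a *confident* temperate phage when it carries an integrase and a pair of
attL/attR attachment sites — an exact direct repeat whose copies sit in
noncoding intervals near the contig ends (or near the integrase), separated
by at least half the contig; a contig with any lysogeny marker but no such
pair is a *candidate* temperate phage; anything else is *no evidence*.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Set, Tuple

MIN_ATT_CORE_BP = 12
MIN_ATT_SEP_FRAC = 0.5
MAX_ATT_END_DIST_BP = 2_000

MARKER_CATEGORIES = ("integrase", "excisionase", "repressor", "antirepressor", "parAB")


@dataclass(frozen=True)
class GeneAnnotation:
    contig_id: str
    start: int
    end: int
    strand: str
    label: str


@dataclass(frozen=True)
class AttPair:
    contig_id: str
    attL: Tuple[int, int]
    attR: Tuple[int, int]
    core_seq: str

    @property
    def core_len(self) -> int:
        return len(self.core_seq)


@dataclass
class LifestyleCall:
    contig_id: str
    call: str  # confident_temperate | candidate_temperate | no_evidence
    evidence: List[str]


_PARAB_RE = re.compile(r"\bpar\s?[ab]\b", re.IGNORECASE)


def marker_category(label: str) -> str:
    """Map a free-text gene label to a lysogeny marker category (or 'other')."""
    low = label.lower()
    if "integrase" in low or "site-specific recombinase" in low:
        return "integrase"
    if "excisionase" in low:
        return "excisionase"
    if "antirepressor" in low or "anti-repressor" in low:
        return "antirepressor"
    if "repressor" in low:
        return "repressor"
    if _PARAB_RE.search(label):
        return "parAB"
    return "other"


def classify_markers(annotations: Sequence[GeneAnnotation]) -> Dict[str, Set[str]]:
    """Per-contig set of lysogeny marker categories present."""
    out: Dict[str, Set[str]] = defaultdict(set)
    for ann in annotations:
        cat = marker_category(ann.label)
        if cat != "other":
            out[ann.contig_id].add(cat)
    return dict(out)


def _noncoding_mask(length: int, genes: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Complement of gene intervals, as sorted half-open intervals."""
    ivs = sorted((max(0, s), min(length, e)) for s, e in genes)
    merged: List[List[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    free = []
    cur = 0
    for s, e in merged:
        if s > cur:
            free.append((cur, s))
        cur = max(cur, e)
    if cur < length:
        free.append((cur, length))
    return free


def find_att_pairs(
    contig_id: str,
    seq: str,
    annotations: Sequence[GeneAnnotation],
    min_core: int = MIN_ATT_CORE_BP,
    min_sep_frac: float = MIN_ATT_SEP_FRAC,
    max_end_dist: int = MAX_ATT_END_DIST_BP,
) -> List[AttPair]:
    """Exact direct-repeat attL/attR pairs on an integrase-bearing contig.

    Both copies must lie entirely in noncoding intervals, be separated by at
    least ``min_sep_frac`` of the contig, and each sit within
    ``max_end_dist`` of a contig end or of an integrase gene.  Contigs with
    no integrase annotation return no pairs.
    """
    n = len(seq)
    annos = [a for a in annotations if a.contig_id == contig_id]
    integrases = [(a.start, a.end) for a in annos if marker_category(a.label) == "integrase"]
    if not integrases:
        return []
    free = _noncoding_mask(n, [(a.start, a.end) for a in annos])

    def in_noncoding(s: int, e: int) -> bool:
        return any(fs <= s and e <= fe for fs, fe in free)

    # within max_end_dist of either contig end or of an integrase interval
    def near(s: int, e: int) -> bool:
        if s <= max_end_dist or n - e <= max_end_dist:
            return True
        for gs, ge in integrases:
            if s >= ge and s - ge <= max_end_dist:
                return True
            if e <= gs and gs - e <= max_end_dist:
                return True
            if s < ge and e > gs:  # overlapping the integrase cannot be noncoding anyway
                return True
        return False

    index: Dict[str, List[int]] = defaultdict(list)
    for i in range(n - min_core + 1):
        if in_noncoding(i, i + min_core) and near(i, i + min_core):
            index[seq[i : i + min_core]].append(i)
    pairs: List[AttPair] = []
    seen_cores: Set[Tuple[int, int]] = set()
    min_sep = int(min_sep_frac * n)
    for kmer in sorted(index, key=lambda k: index[k][0]):
        poss = index[kmer]
        for ai in range(len(poss)):
            for bi in range(ai + 1, len(poss)):
                p, q = poss[ai], poss[bi]
                if q - p < min_sep:
                    continue
                # maximal exact common extension staying in bounds
                L = min_core
                while p + L < q and q + L < n and seq[p + L] == seq[q + L]:
                    L += 1
                s0 = 0
                while p - s0 - 1 >= 0 and seq[p - s0 - 1] == seq[q - s0 - 1]:
                    s0 += 1
                p0, q0 = p - s0, q - s0
                Lf = L + s0
                if not (in_noncoding(p0, p0 + Lf) and in_noncoding(q0, q0 + Lf)):
                    continue
                if not (near(p0, p0 + Lf) and near(q0, q0 + Lf)):
                    continue
                key = (p0, q0)
                if key in seen_cores:
                    continue
                seen_cores.add(key)
                pairs.append(
                    AttPair(contig_id, (p0, p0 + Lf), (q0, q0 + Lf), seq[p0 : p0 + Lf])
                )
    pairs.sort(key=lambda a: (a.attL, a.attR))
    return pairs


def classify_lifestyle(
    contig_id: str,
    markers: Set[str],
    att_pairs: Sequence[AttPair],
) -> LifestyleCall:
    """Confident needs integrase + att pair; any marker alone is candidate."""
    evidence = sorted(markers)
    if "integrase" in markers and att_pairs:
        evidence = evidence + [f"att_core_{p.core_len}bp" for p in att_pairs]
        return LifestyleCall(contig_id, "confident_temperate", evidence)
    if markers:
        return LifestyleCall(contig_id, "candidate_temperate", evidence)
    return LifestyleCall(contig_id, "no_evidence", [])
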