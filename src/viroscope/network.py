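"""Genus-level grouping of viral genomes by shared protein content.

The route mirrors gene-sharing-network taxonomy: ORFs are called by a
deterministic six-frame scan (a simplified Prodigal analogue), proteins
are clustered greedily into protein clusters (PCs) at >=30% identity over
>=70% of the centroid, genome pairs are scored by the upper-tail
hypergeometric probability of their shared PC count, and viral clusters
(VCs, ~genera) are connected components of the significance-thresholded
graph.  Every genome ends up in exactly one of three classes:

* clustered — member of a VC of size >=2;
* outlier   — shares PCs with other genomes but retains no significant edge;
* singleton — shares no PC with any other genome.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import edlib
import networkx as nx
from scipy.stats import hypergeom

from .io import revcomp

MIN_ORF_AA = 60
PC_ID_MIN = 0.30
PC_COV_MIN = 0.70
SIG_MIN = 1.0

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class Orf:
    genome_id: str
    start: int  # forward-strand coordinates, 0-based half-open
    end: int
    strand: str  # '+' | '-'
    aa_seq: str

    @property
    def orf_id(self) -> str:
        return f"{self.genome_id}:{self.start}-{self.end}({self.strand})"


@dataclass
class ViralClusterAssignment:
    genome_id: str
    vc_id: Optional[str]
    cls: str  # clustered | outlier | singleton
    shares_reference: bool = False


def _translate(nt: str) -> str:
    return "".join(_CODON_TABLE.get(nt[i : i + 3], "X") for i in range(0, len(nt) - 2, 3))


def call_orfs(genome_id: str, seq: str, min_aa: int = MIN_ORF_AA) -> List[Orf]:
    """Six-frame ATG-initiated ORFs between stops, standard genetic code.

    Within each stop-free segment the longest (first-ATG) ORF is reported.
    Coordinates are forward-strand, half-open; reverse-strand ORFs keep
    forward coordinates plus ``strand='-'``.
    """
    n = len(seq)
    orfs: List[Orf] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            aa = _translate(s[frame:])
            seg_start = 0  # codon index where current stop-free segment begins
            for idx in range(len(aa) + 1):
                if idx < len(aa) and aa[idx] != "*":
                    continue
                seg = aa[seg_start:idx]
                m = seg.find("M")
                if m != -1 and len(seg) - m >= min_aa:
                    c0 = seg_start + m  # first codon of ORF
                    c1 = idx + 1 if idx < len(aa) else idx  # include stop codon if present
                    nt0 = frame + 3 * c0
                    nt1 = frame + 3 * c1
                    if strand == "+":
                        start, end = nt0, nt1
                    else:
                        start, end = n - nt1, n - nt0
                    orfs.append(Orf(genome_id, start, end, strand, seg[m:]))
                seg_start = idx + 1
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def _identity(a: str, b: str) -> float:
    res = edlib.align(a, b, mode="NW", task="path")
    matches = cols = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                matches += n
    return matches / cols if cols else 0.0


def cluster_proteins(
    orfs: Sequence[Orf], id_min: float = PC_ID_MIN, cov_min: float = PC_COV_MIN
) -> Dict[str, List[Orf]]:
    """Greedy incremental protein clustering (length-descending centroids).

    A protein joins the first centroid it matches at >= ``id_min`` identity
    over >= ``cov_min`` of the centroid's length; otherwise it founds a new
    PC.  Candidate centroids are prefiltered by shared amino-acid 4-mers.
    """
    if not orfs:
        raise ValueError("no ORFs to cluster")
    order = sorted(orfs, key=lambda o: (-len(o.aa_seq), o.orf_id))
    centroids: List[Orf] = []
    kmer_index: Dict[str, Set[int]] = defaultdict(set)
    members: Dict[int, List[Orf]] = defaultdict(list)

    def kmers(aa: str, k: int = 4) -> Set[str]:
        return {aa[i : i + k] for i in range(len(aa) - k + 1)}

    for orf in order:
        ks = kmers(orf.aa_seq)
        cands = sorted({ci for km in ks for ci in kmer_index.get(km, ())})
        placed = False
        for ci in cands:
            cen = centroids[ci]
            if len(orf.aa_seq) < cov_min * len(cen.aa_seq):
                continue
            if _identity(orf.aa_seq, cen.aa_seq) >= id_min:
                members[ci].append(orf)
                placed = True
                break
        if not placed:
            ci = len(centroids)
            centroids.append(orf)
            members[ci].append(orf)
            for km in ks:
                kmer_index[km].add(ci)
    return {f"PC_{ci + 1:05d}": mem for ci, mem in sorted(members.items())}


def presence_matrix(pcs: Mapping[str, Sequence[Orf]]) -> Dict[str, FrozenSet[str]]:
    """Per-genome set of PCs present."""
    pres: Dict[str, Set[str]] = defaultdict(set)
    for pc_id, orfs in pcs.items():
        for orf in orfs:
            pres[orf.genome_id].add(pc_id)
    return {g: frozenset(s) for g, s in pres.items()}


def pair_significance(
    pcs_a: FrozenSet[str] | Set[str], pcs_b: FrozenSet[str] | Set[str], n_universe: int
) -> Tuple[float, float]:
    """Upper-tail hypergeometric probability of the observed PC overlap.

    Returns ``(p, weight)`` with ``weight = -log10(p)`` (0 when nothing is
    shared).
    """
    c = len(set(pcs_a) & set(pcs_b))
    if c == 0:
        return 1.0, 0.0
    p = float(hypergeom.sf(c - 1, n_universe, len(pcs_a), len(pcs_b)))
    p = min(max(p, 1e-300), 1.0)
    import math

    return p, -math.log10(p)


def build_viral_clusters(
    presence: Mapping[str, FrozenSet[str]],
    sig_min: float = SIG_MIN,
    n_universe: Optional[int] = None,
    reference_ids: Iterable[str] = (),
) -> Tuple[List[ViralClusterAssignment], List[dict]]:
    """Connected-component VCs over the significance-thresholded sharing graph.

    Returns assignments (reference genomes excluded from the report but used
    for the ``shares_reference`` flag) and the retained edge list.
    """
    refs = set(reference_ids)
    genomes = sorted(presence)
    if n_universe is None:
        n_universe = len({pc for s in presence.values() for pc in s})
    g = nx.Graph()
    g.add_nodes_from(genomes)
    edges = []
    shares_any: Set[str] = set()
    for i, a in enumerate(genomes):
        for b in genomes[i + 1 :]:
            shared = len(presence[a] & presence[b])
            if shared == 0:
                continue
            shares_any.update((a, b))
            p, w = pair_significance(presence[a], presence[b], n_universe)
            if w >= sig_min:
                g.add_edge(a, b)
                edges.append({"a": a, "b": b, "shared": shared, "p": p, "weight": w})
    assignments = []
    comp_of: Dict[str, int] = {}
    vc_comps = []
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        if len(comp) >= 2:
            vc_comps.append(sorted(comp))
    for ci, comp in enumerate(vc_comps):
        for node in comp:
            comp_of[node] = ci
    for gid in genomes:
        if gid in refs:
            continue
        if gid in comp_of:
            ci = comp_of[gid]
            vc_id = f"VC_{ci + 1:04d}"
            shares_ref = any(m in refs for m in vc_comps[ci])
            assignments.append(ViralClusterAssignment(gid, vc_id, "clustered", shares_ref))
        elif gid in shares_any:
            assignments.append(ViralClusterAssignment(gid, None, "outlier"))
        else:
            assignments.append(ViralClusterAssignment(gid, None, "singleton"))
    return assignments, edges
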