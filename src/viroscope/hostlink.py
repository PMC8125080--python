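"""Virus -> host-bin prediction through four evidence channels.

* prophage — the whole viral contig occurs verbatim (either strand) inside
  a host bin, with at least 1 kb of host flanking sequence on one side so
  that integration is distinguishable from co-assembly;
* crispr   — a spacer from a detected host CRISPR array matches the virus
  full-length, ungapped, at >=95% identity;
* trna     — an exact, full-length shared tRNA, accepted only when the same
  (virus, host) pair already has an accepted prophage link;
* kmer     — an order-(k-1) Markov model per host (k=8 by default) scores
  the virus; the best host is accepted when the Gaussian null p-value over
  decoy-host scores is ~0 (<=1e-10), or when p<0.05 and the prophage
  channel links the same pair.

A consensus table keeps every accepted call and picks a primary host by
the fixed channel priority prophage > crispr > trna > kmer.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import revcomp

CHANNEL_PRIORITY = ("prophage", "crispr", "trna", "kmer")
MIN_PROPHAGE_FLANK_BP = 1_000
CRISPR_REPEAT_BP = (23, 47)
CRISPR_SPACER_BP = (26, 50)
CRISPR_MIN_REPEATS = 2
SPACER_ID_MIN_PCT = 95.0
MARKOV_K = 8
MARKOV_PSEUDOCOUNT = 1.0
P_ZERO_EPS = 1e-10
KMER_P_MAX = 0.05
MIN_NULL_MODELS = 10

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class CrisprArray:
    host_id: str
    start: int
    end: int
    repeat_seq: str
    spacers: Tuple[Tuple[str, int, int], ...]  # (sequence, start, end)


@dataclass
class HostCall:
    virus_id: str
    host_id: str
    channel: str
    identity_pct: float = float("nan")
    length_bp: int = 0
    loglik: float = float("nan")
    p: float = float("nan")
    accepted: bool = False
    detail: str = ""


# ---------------------------------------------------------------- prophage


def find_prophage_links(
    virus_id: str,
    virus_seq: str,
    host_bins: Mapping[str, str],
    min_flank_bp: int = MIN_PROPHAGE_FLANK_BP,
) -> List[HostCall]:
    """Exact full-length embedding of the virus in a host bin, either strand."""
    if not virus_seq:
        raise ValueError("empty virus sequence")
    calls = []
    for host_id, host_seq in host_bins.items():
        for strand, probe in (("+", virus_seq), ("-", revcomp(virus_seq))):
            pos = host_seq.find(probe)
            if pos == -1:
                continue
            left = pos
            right = len(host_seq) - (pos + len(probe))
            accepted = max(left, right) >= min_flank_bp
            calls.append(
                HostCall(
                    virus_id,
                    host_id,
                    "prophage",
                    identity_pct=100.0,
                    length_bp=len(virus_seq),
                    accepted=accepted,
                    detail=f"strand={strand};pos={pos};flank_l={left};flank_r={right}",
                )
            )
            break
    return calls


# ------------------------------------------------------------------ CRISPR


def detect_crispr_arrays(
    host_id: str,
    seq: str,
    repeat_bp: Tuple[int, int] = CRISPR_REPEAT_BP,
    spacer_bp: Tuple[int, int] = CRISPR_SPACER_BP,
    min_repeats: int = CRISPR_MIN_REPEATS,
) -> List[CrisprArray]:
    """Exact-repeat CRISPR array detection.

    Seeds on repeated ``repeat_bp[0]``-mers at a spacing compatible with the
    repeat/spacer length ranges, extends the repeat to its maximal exact
    common length, then walks rightward collecting further periodic copies.
    """
    rmin, rmax = repeat_bp
    smin, smax = spacer_bp
    n = len(seq)
    if n < 2 * rmin + smin:
        return []
    index: Dict[str, List[int]] = defaultdict(list)
    for i in range(n - rmin + 1):
        index[seq[i : i + rmin]].append(i)
    arrays: List[CrisprArray] = []
    claimed: List[Tuple[int, int]] = []

    def overlaps_claimed(p: int) -> bool:
        return any(s <= p < e for s, e in claimed)

    for kmer in sorted(index, key=lambda k: index[k][0]):
        poss = index[kmer]
        if len(poss) < 2:
            continue
        p = poss[0]
        if overlaps_claimed(p):
            continue
        q = next((x for x in poss[1:] if rmin + smin <= x - p <= rmax + smax), None)
        if q is None:
            continue
        d = q - p
        lmax = min(rmax, d - smin, n - q)
        length = rmin
        while length < lmax and seq[p + length] == seq[q + length]:
            length += 1
        if not (smin <= d - length <= smax):
            continue
        repeat = seq[p : p + length]
        positions = [p, q]
        cur = q
        while True:
            lo = cur + length + smin
            hi = cur + length + smax
            nxt = seq.find(repeat, lo, hi + length)
            if nxt == -1 or nxt > hi:
                break
            positions.append(nxt)
            cur = nxt
        if len(positions) < min_repeats:
            continue
        spacers = tuple(
            (seq[a + length : b], a + length, b)
            for a, b in zip(positions[:-1], positions[1:])
        )
        start, end = positions[0], positions[-1] + length
        arrays.append(CrisprArray(host_id, start, end, repeat, spacers))
        claimed.append((start, end))
    arrays.sort(key=lambda a: a.start)
    return arrays


def _ungapped_best_match(spacer: str, target: str) -> Tuple[int, int]:
    """(min mismatches, position) of a full-length ungapped spacer placement."""
    L = len(spacer)
    if L > len(target):
        return L, -1
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    s = np.frombuffer(spacer.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    mism = (windows != s).sum(axis=1)
    pos = int(mism.argmin())
    return int(mism[pos]), pos


def match_spacers(
    arrays: Sequence[CrisprArray],
    virus_seqs: Mapping[str, str],
    id_min_pct: float = SPACER_ID_MIN_PCT,
) -> List[HostCall]:
    """Full-length ungapped spacer matching, either strand.

    A spacer of length L may carry at most ``floor((1 - id_min/100) * L)``
    mismatches.
    """
    best: Dict[Tuple[str, str], HostCall] = {}
    for arr in arrays:
        for spacer, _, _ in arr.spacers:
            L = len(spacer)
            allowed = math.floor((1.0 - id_min_pct / 100.0) * L)
            for virus_id, vseq in virus_seqs.items():
                hits = []
                for strand, probe in (("+", spacer), ("-", revcomp(spacer))):
                    mm, pos = _ungapped_best_match(probe, vseq)
                    hits.append((mm, strand, pos))
                mm, strand, pos = min(hits)
                if mm > allowed:
                    continue
                ident = 100.0 * (L - mm) / L
                key = (virus_id, arr.host_id)
                call = HostCall(
                    virus_id,
                    arr.host_id,
                    "crispr",
                    identity_pct=ident,
                    length_bp=L,
                    accepted=True,
                    detail=f"strand={strand};pos={pos};mismatches={mm}",
                )
                if key not in best or ident > best[key].identity_pct:
                    best[key] = call
    return [best[k] for k in sorted(best)]


# -------------------------------------------------------------------- tRNA


def find_trnas(seq: str, library: Mapping[str, str]) -> List[Tuple[str, int, int, str]]:
    """Locate exact library tRNA copies (either strand): (trna_id, start, end, strand)."""
    found = []
    for trna_id, trna in library.items():
        for strand, probe in (("+", trna), ("-", revcomp(trna))):
            start = 0
            while True:
                pos = seq.find(probe, start)
                if pos == -1:
                    break
                found.append((trna_id, pos, pos + len(probe), strand))
                start = pos + 1
    found.sort(key=lambda t: t[1])
    return found


def match_trnas(
    host_trnas: Mapping[str, Sequence[str]],
    virus_trnas: Mapping[str, Sequence[str]],
    prophage_calls: Sequence[HostCall],
) -> List[HostCall]:
    """Exact full-length shared tRNAs, gated on prophage-consistent pairs."""
    prophage_pairs = {
        (c.virus_id, c.host_id) for c in prophage_calls if c.channel == "prophage" and c.accepted
    }
    calls = []
    for virus_id, vts in virus_trnas.items():
        vset = set(vts)
        for host_id, hts in host_trnas.items():
            shared = vset & set(hts)
            if not shared:
                continue
            consistent = (virus_id, host_id) in prophage_pairs
            trna = sorted(shared)[0]
            calls.append(
                HostCall(
                    virus_id,
                    host_id,
                    "trna",
                    identity_pct=100.0,
                    length_bp=len(trna),
                    accepted=consistent,
                    detail=f"shared_trnas={len(shared)};prophage_consistent={consistent}",
                )
            )
    calls.sort(key=lambda c: (c.virus_id, c.host_id))
    return calls


# ---------------------------------------------------------------- k-mer/Markov


@dataclass
class MarkovHostModel:
    host_id: str
    k: int
    log_transition: np.ndarray  # shape (4**(k-1), 4)

    @property
    def order(self) -> int:
        return self.k - 1


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_IDX.items():
        out[arr == ord(base)] = idx
    return out


def _context_codes(codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """(context index, next base) for every k-mer window of an encoded sequence."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    mult = 4 ** np.arange(k - 2, -1, -1, dtype=np.int64) if k > 1 else np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    ctx = win[:, : k - 1] @ mult if k > 1 else np.zeros(win.shape[0], dtype=np.int64)
    nxt = win[:, k - 1]
    ok = (win >= 0).all(axis=1)
    return ctx[ok], nxt[ok]


def train_markov(
    host_id: str, seq: str, k: int = MARKOV_K, pseudocount: float = MARKOV_PSEUDOCOUNT
) -> MarkovHostModel:
    """Order-(k-1) Markov model with additive pseudocount.

    Counts come from the given strand; strand symmetry is handled at scoring
    time by scoring both orientations of the query.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    codes = _encode(seq)
    ctx, nxt = _context_codes(codes, k)
    counts = np.zeros((4 ** (k - 1), 4), dtype=np.float64)
    np.add.at(counts, (ctx, nxt), 1.0)
    counts += pseudocount
    log_t = np.log(counts / counts.sum(axis=1, keepdims=True))
    return MarkovHostModel(host_id, k, log_t)


def score_sequence(model: MarkovHostModel, seq: str) -> float:
    """Mean per-base log-likelihood; maximum over the two orientations."""
    vals = []
    for probe in (seq, revcomp(seq)):
        ctx, nxt = _context_codes(_encode(probe), model.k)
        if ctx.size == 0:
            raise ValueError("sequence shorter than model order")
        vals.append(float(model.log_transition[ctx, nxt].mean()))
    return max(vals)


def score_kmer_channel(
    virus_id: str,
    virus_seq: str,
    models: Mapping[str, MarkovHostModel],
    null_models: Sequence[MarkovHostModel],
    prophage_calls: Sequence[HostCall] = (),
    p_zero_eps: float = P_ZERO_EPS,
    p_max: float = KMER_P_MAX,
) -> List[HostCall]:
    """Best-host call from per-host Markov likelihoods with a decoy null."""
    if len(models) < 2:
        raise ValueError("need >=2 candidate host models")
    if len(null_models) < MIN_NULL_MODELS:
        raise ValueError(f"need >={MIN_NULL_MODELS} null models")
    scores = {hid: score_sequence(m, virus_seq) for hid, m in models.items()}
    best_host = max(sorted(scores), key=lambda h: scores[h])
    best = scores[best_host]
    null_scores = np.array([score_sequence(m, virus_seq) for m in null_models])
    mu, sd = float(null_scores.mean()), float(null_scores.std(ddof=1))
    p = float(norm.sf(best, loc=mu, scale=sd)) if sd > 0 else float(best <= mu)
    prophage_pairs = {
        (c.virus_id, c.host_id) for c in prophage_calls if c.channel == "prophage" and c.accepted
    }
    accepted = p <= p_zero_eps or (p < p_max and (virus_id, best_host) in prophage_pairs)
    return [
        HostCall(
            virus_id,
            best_host,
            "kmer",
            length_bp=len(virus_seq),
            loglik=best,
            p=p,
            accepted=accepted,
            detail=f"null_mu={mu:.4f};null_sd={sd:.4f}",
        )
    ]


# --------------------------------------------------------------- consensus


def consensus(calls: Sequence[HostCall], n_viruses: Optional[int] = None) -> Tuple[pd.DataFrame, float]:
    """Per-virus primary host by channel priority; all accepted calls retained.

    Returns the consensus table and the fraction of viruses linked (against
    ``n_viruses`` when given, else against the viruses appearing in calls).
    """
    accepted = [c for c in calls if c.accepted]
    by_virus: Dict[str, List[HostCall]] = defaultdict(list)
    for c in accepted:
        by_virus[c.virus_id].append(c)
    rows = []
    rank = {ch: i for i, ch in enumerate(CHANNEL_PRIORITY)}
    for virus_id in sorted(by_virus):
        vcalls = sorted(by_virus[virus_id], key=lambda c: (rank[c.channel], c.host_id))
        primary = vcalls[0]
        rows.append(
            {
                "virus_id": virus_id,
                "host_id": primary.host_id,
                "primary_channel": primary.channel,
                "channels": ";".join(
                    f"{c.channel}:{c.host_id}" for c in vcalls
                ),
            }
        )
    table = pd.DataFrame(rows, columns=["virus_id", "host_id", "primary_channel", "channels"])
    denom = n_viruses if n_viruses else len({c.virus_id for c in calls}) or 1
    fraction = len(table) / denom
    return table, fraction
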