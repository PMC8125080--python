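"""Two-tier ensemble triage of assembled contigs into viral / non-viral.

Each contig arrives with the evidence emitted by four virus predictors —
a VirSorter category (1–6), a DeepVirFinder score with p-value, a MARVEL
random-forest probability (0–100) and a CAT annotation summary — and is
gated by length and topology before the ensemble rule is applied:

* length gate — linear contigs must be ≥5 kb, circular contigs ≥1.5 kb
  (circular lengths are taken after trimming the terminal repeat once);
* keep gate — any VirSorter category 1–6, DeepVirFinder ≥0.7 with p<0.05,
  or MARVEL ≥70. CAT evidence alone never keeps a contig;
* tier 1 (high confidence) — VirSorter category 1/2/4/5, DeepVirFinder
  ≥0.9, or MARVEL ≥90;
* tier 2 (two-tool) — at least two of: VirSorter category 3/6,
  DeepVirFinder in [0.7, 0.9) with p<0.05, MARVEL in [70, 90), CAT support
  (annotated viral, or <40% of genes classified non-viral).

Missing predictor values never satisfy a criterion and never error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

import pandas as pd

LINEAR_MIN_BP = 5_000
CIRCULAR_MIN_BP = 1_500
DTR_MIN_BP = 20

KEEP_DVF_SCORE = 0.7
KEEP_DVF_P = 0.05
KEEP_MARVEL = 70.0
TIER1_DVF_SCORE = 0.9
TIER1_MARVEL = 90.0
TIER1_CATEGORIES = frozenset({1, 2, 4, 5})
TIER2_CATEGORIES = frozenset({3, 6})
CAT_NONVIRAL_MAX_FRAC = 0.40


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class ToolScoreRecord:
    """Per-contig predictor evidence; absent values are ``None``."""

    contig_id: str
    length_bp: int
    topology: str = "linear"
    virsorter_category: Optional[int] = None
    dvf_score: Optional[float] = None
    dvf_p: Optional[float] = None
    marvel_prob: Optional[float] = None
    cat_viral: Optional[bool] = None
    cat_nonviral_gene_frac: Optional[float] = None

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError(f"{self.contig_id}: length_bp must be positive")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"{self.contig_id}: topology must be linear|circular")
        if not _missing(self.virsorter_category) and self.virsorter_category not in range(1, 7):
            raise ValueError(f"{self.contig_id}: VirSorter category must be 1..6")
        for name, lo, hi in (
            ("dvf_score", 0, 1),
            ("dvf_p", 0, 1),
            ("marvel_prob", 0, 100),
            ("cat_nonviral_gene_frac", 0, 1),
        ):
            v = getattr(self, name)
            if not _missing(v) and not (lo <= v <= hi):
                raise ValueError(f"{self.contig_id}: {name}={v} out of [{lo},{hi}]")


@dataclass
class ScreenDecision:
    contig_id: str
    status: str  # viral | rejected | sub_length
    tier: str  # high_confidence | two_tool | none
    evidence: List[str] = field(default_factory=list)


def detect_circularity(sequence: str, min_dtr_bp: int = DTR_MIN_BP) -> str:
    """Call a contig circular iff it carries a direct terminal repeat.

    The first ``min_dtr_bp`` bases must recur exactly as a suffix; the
    repeat must not span more than half the contig.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if len(sequence) >= 2 * min_dtr_bp and sequence.endswith(sequence[:min_dtr_bp]):
        return "circular"
    return "linear"


def dtr_length(sequence: str, min_dtr_bp: int = DTR_MIN_BP) -> int:
    """Length of the maximal direct terminal repeat (0 if below threshold)."""
    best = 0
    hi = len(sequence) // 2
    for n in range(min_dtr_bp, hi + 1):
        if sequence.endswith(sequence[:n]):
            best = n
    return best


def classify_contig(record: ToolScoreRecord) -> ScreenDecision:
    """Apply the length gate and the two-tier ensemble rule to one contig."""
    min_bp = CIRCULAR_MIN_BP if record.topology == "circular" else LINEAR_MIN_BP
    if record.length_bp < min_bp:
        return ScreenDecision(record.contig_id, "sub_length", "none", [])

    cat = record.virsorter_category
    dvf, dvf_p = record.dvf_score, record.dvf_p
    marvel = record.marvel_prob

    dvf_ok = (not _missing(dvf)) and (not _missing(dvf_p)) and dvf >= KEEP_DVF_SCORE and dvf_p < KEEP_DVF_P
    keep_tokens = []
    if not _missing(cat):
        keep_tokens.append(f"virsorter_cat{cat}")
    if dvf_ok:
        keep_tokens.append(f"dvf{dvf:.2f}")
    if not _missing(marvel) and marvel >= KEEP_MARVEL:
        keep_tokens.append(f"marvel{marvel:.0f}")
    if not keep_tokens:
        return ScreenDecision(record.contig_id, "rejected", "none", [])

    tier1 = []
    if not _missing(cat) and cat in TIER1_CATEGORIES:
        tier1.append(f"virsorter_cat{cat}")
    if not _missing(dvf) and dvf >= TIER1_DVF_SCORE:
        tier1.append(f"dvf_ge0.9")
    if not _missing(marvel) and marvel >= TIER1_MARVEL:
        tier1.append("marvel_ge90")
    if tier1:
        return ScreenDecision(record.contig_id, "viral", "high_confidence", tier1)

    tier2 = []
    if not _missing(cat) and cat in TIER2_CATEGORIES:
        tier2.append(f"virsorter_cat{cat}")
    if dvf_ok and dvf < TIER1_DVF_SCORE:
        tier2.append("dvf_band")
    if not _missing(marvel) and KEEP_MARVEL <= marvel < TIER1_MARVEL:
        tier2.append("marvel_band")
    cat_support = (record.cat_viral is True) or (
        not _missing(record.cat_nonviral_gene_frac)
        and record.cat_nonviral_gene_frac < CAT_NONVIRAL_MAX_FRAC
    )
    if cat_support:
        tier2.append("cat_support")
    if len(tier2) >= 2:
        return ScreenDecision(record.contig_id, "viral", "two_tool", tier2)
    return ScreenDecision(record.contig_id, "rejected", "none", [])


def record_from_row(row: Mapping) -> ToolScoreRecord:
    def opt(key, cast):
        v = row.get(key)
        return None if _missing(v) else cast(v)

    cat_viral = row.get("cat_viral")
    if _missing(cat_viral):
        cat_viral = None
    elif isinstance(cat_viral, str):
        cat_viral = cat_viral.strip().lower() in ("true", "1", "yes")
    else:
        cat_viral = bool(cat_viral)
    return ToolScoreRecord(
        contig_id=str(row["contig_id"]),
        length_bp=int(row["length_bp"]),
        topology=str(row.get("topology", "linear")),
        virsorter_category=opt("virsorter_category", lambda v: int(v)),
        dvf_score=opt("dvf_score", float),
        dvf_p=opt("dvf_p", float),
        marvel_prob=opt("marvel_prob", float),
        cat_viral=cat_viral,
        cat_nonviral_gene_frac=opt("cat_nonviral_gene_frac", float),
    )


def screen_table(
    contigs: Optional[Mapping[str, str]],
    scores: pd.DataFrame,
) -> tuple[pd.DataFrame, Dict[str, int]]:
    """Screen every scored contig; returns the decision table and summary counts.

    ``contigs`` may be None when only the score table is available; when
    given, every score row must reference a known contig id.
    """
    if contigs is not None:
        unknown = sorted(set(scores["contig_id"].astype(str)) - set(contigs))
        if unknown:
            raise KeyError(f"score rows reference unknown contigs: {unknown}")
    decisions = []
    for _, row in scores.iterrows():
        rec = record_from_row(row)
        d = classify_contig(rec)
        decisions.append(
            {
                "contig_id": d.contig_id,
                "length_bp": rec.length_bp,
                "status": d.status,
                "tier": d.tier,
                "evidence": ";".join(d.evidence),
            }
        )
    table = pd.DataFrame(
        decisions, columns=["contig_id", "length_bp", "status", "tier", "evidence"]
    )
    viral = table[table["status"] == "viral"]
    summary = {
        "n_contigs": len(table),
        "n_viral": int(len(viral)),
        "n_viral_ge5kb": int((viral["length_bp"] >= 5_000).sum()),
        "n_viral_ge10kb": int((viral["length_bp"] >= 10_000).sum()),
        "n_rejected": int((table["status"] == "rejected").sum()),
        "n_sub_length": int((table["status"] == "sub_length").sum()),
    }
    return table, summary
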