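# viroscope

Desk-scale ecogenomics of the gut virome from bulk metagenomes, exercised
end-to-end on synthetic communities with planted ground truth.

Bulk-metagenome virome studies follow a now-standard route: contigs are
triaged into viral / non-viral with an ensemble of virus predictors,
viral genomes are dereplicated into species-level populations (vOTUs) at
≥95% average nucleotide identity (ANI) over ≥80% of the shorter genome,
genus-level groups are formed from shared protein content, hosts are
predicted through prophage, CRISPR-spacer, tRNA and k-mer-composition
evidence, lifestyles (temperate vs lytic) are called from lysogeny markers
and attL/attR attachment sites, and community shifts are quantified with
Bray–Curtis / PCoA / ANOSIM and per-feature differential-abundance tests.
`viroscope` implements that whole route as a tested, seeded, reusable
library — plus a synthetic-community generator that plants every feature
class (prophages with att repeats, CRISPR arrays with protospacer targets,
shared tRNAs, marker genes, predictor scores, group-structured counts) so
each detector can be scored exactly against ground truth without any
external data or tools.

Core definitions used throughout:

- vOTU: population at ANI ≥ 95% over an aligned fraction AF ≥ 80% of the
  shorter genome (greedy longest-first dereplication).
- Viral cluster (VC): connected component of genomes whose shared
  protein-cluster count is hypergeometrically significant
  (−log₁₀ p ≥ 1); remaining genomes are outliers (share content, no
  significant edge) or singletons (no shared content).
- Host channels: prophage (100% identity over 100% of the virus, ≥1 kb
  host flank), CRISPR (full-length spacer match ≥95% identity), tRNA
  (perfect match + prophage consistency), k-mer (order-7 Markov
  likelihood with a decoy-host Gaussian null; p ≤ 1e−10, or p < 0.05 with
  prophage agreement).
- Lifestyle: confident temperate = integrase + att direct-repeat pair;
  candidate = any lysogeny marker; otherwise no evidence.
- RPKM = count × 10⁹ / (length_bp × total mapped); tests use log₂(x+1),
  Wilcoxon or Welch-t with Benjamini–Hochberg FDR; ANOSIM
  R = (r̄_between − r̄_within)/(M/2) with permutation p.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from viroscope import CommunityConfig, RunConfig, run_pipeline

report = run_pipeline(RunConfig(outdir="out", seed=11))
print(report.n_contigs, report.n_viral, report.n_populations,
      report.lifestyle_counts, report.anosim_r, report.anosim_p)
```

prints (seed 11, default community of 8 hosts / 20 phages / 30 host
fragments across 15 samples in three groups):

```
53 23 20 {'confident_temperate': 8, 'candidate_temperate': 0, 'no_evidence': 15} 0.9973 0.001
```

Of 53 contigs, 23 pass the two-tier ensemble screen (the 6 sub-5 kb host
fragments are length-gated, the rest rejected for lack of evidence); the
23 viral contigs collapse to 20 populations (three lytic phages carry a
planted variant member at 1–3% substitutions); all 8 planted temperate
phages are called confident (integrase + att pair) and no lytic phage is;
and the three sample groups separate almost perfectly in Bray–Curtis space
(ANOSIM R = 0.997, permutation p = 0.001), driven by the planted 8×
responder taxa.  Stage-by-stage tables (screen decisions, population
membership, VC assignments, host calls and consensus, lifestyle calls,
RPKM/ordination/test results) are written under `out/`, with a JSON run
report.

The same stages are available individually from the shell:

```bash
viroscope simulate --seed 11 --outdir out/sim
viroscope screen --contigs out/sim/contigs.fasta --scores out/sim/scores.tsv --out out/decisions.tsv
viroscope run --seed 11 --outdir out/full
```

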