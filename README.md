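# tn5prefer

Analysis toolkit for **Tn5 transposase insertion preference** on naked
genomic DNA — for ATAC-seq methods developers and anyone who needs to know
where Tn5 cuts, why, and how to correct for it.

Tn5 does not insert uniformly: it favors a degenerate ~9-bp sequence motif,
flexible DNA structure (wider minor groove, larger propeller twist), and is
modulated by DNA methylation.  `tn5prefer` quantifies and dissects this
preference:

* **Insertion sites** — paired-end fragments are shifted (+4 forward /
  −5 reverse) onto the centers of the 9-bp target-site duplication;
  *paired fragments* (two fragments overlapping by exactly 9 bp) pin down
  high-confidence events.
* **Feature enrichment** — per-feature `log2(O/E)` with
  `E = feature length × (total sites / mappable genome size)`, chi-square
  goodness-of-fit testing, Benjamini–Hochberg FDR, and complete-linkage
  sample clustering.
* **Motif** — center-aligned PWM building, genome scanning with exact
  p-values (FIMO-style dynamic programming) and q < 0.001 hits, and the
  inside/outside / used/unused usage taxonomy.
* **Shape & sequence encodings** — 14 DNA-shape features by pentamer-table
  lookup over 51-bp windows, per-position PWM scores, and mono/di/tri-
  nucleotide one-hots, with seeded shuffled-table and shuffled-sequence
  negative controls.
* **Classifier** — elastic-net logistic regression (10-fold CV, features
  standardized to [0, 1], accuracy = (TP+TN)/n) separating insertion sites
  from random genomic controls; coefficient importance maps by parameter
  and window position; 70/30 cross-sample transfer.
* **Methylation** — the matched-context 9-mer procedure: tile the genome
  into 9-bp bins, classify bins by two-condition methylation (A-only /
  Both / None / B-only), average insertion frequency per shared 9-mer,
  Z-scale per condition; plus 11-level methylation stratification.
* **Bias correction** — a k-mer (default k = 19, maskable) context rate
  model; corrected signal = raw × (mean rate / context rate), total signal
  conserved.
* **Synthetic data** — genomes and insertion events with *planted* motif,
  dinucleotide, shape and methylation structure and a full truth record,
  so every stage is validated by parameter recovery.

## Worked example

```python
import numpy as np
from tn5prefer import synthetic, motif

# a 200-kb genome carrying 6 000 planted motif instances, and 50 000
# insertion events whose propensity follows the planted PWM odds ratio
cfg = synthetic.SimulationConfig(
    genome_length=200_000,
    planted_pwm=synthetic.consensus_pwm("ACAGTGGTT", 0.9),
    motif_weight=float(np.log(2)),
    n_planted_motifs=6_000,
    n_insertions=50_000,
    seed=7,
)
genome = synthetic.simulate_genome(cfg)
sites, truth = synthetic.simulate_insertions(genome, cfg)

pwm = motif.build_pwm(sites, genome, window=9)
print(pwm.consensus)
hits = motif.scan_pwm(pwm, genome, q_threshold=0.001)
usage = motif.usage_summary(sites, hits)
print(len(hits), round(usage.frac_insert_inside, 3), round(usage.frac_motif_used, 3))
```

prints

```
ACAGTGGTT
2340 0.645 1.0
```

— the learned PWM recovers the planted consensus; 2 340 genome windows
reach q < 0.001; 64.5 % of insertion events fall inside predicted motif
intervals, and every predicted interval is used by at least one event
(insertions here were planted motif-driven; on real naked DNA these
fractions are far lower, which is the paper-level observation that motif
alone cannot explain Tn5 preference).

The same stages run from the shell:

```bash
tn5prefer simulate --genome-length 200000 --n-insertions 50000 --out sim/
tn5prefer sites    --fragments sim/fragments.bed --out sites.bed
tn5prefer enrich   --sites sites.bed --features features/ --genome sim/genome.fa
tn5prefer motif build --sites sites.bed --genome sim/genome.fa --out tn5.meme
tn5prefer correct  --sites sites.bed --genome sim/genome.fa --k 7 --out corr.bg
tn5prefer run      --seed 1 --out demo/        # full end-to-end demonstration
```

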