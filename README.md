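# nucparticle

Paired-end MNase chromatin-seq particle analysis for compact genomes
(designed around *Schizosaccharomyces pombe*), plus a ground-truthed
chromatin/MNase simulator so the entire pipeline can be exercised and
validated without external sequencing data.

## The problem

Micrococcal nuclease (MNase) digests the linker DNA between nucleosomes,
leaving ~147 bp protected fragments. Sequencing both ends of each fragment
gives its genomic location *and* its size, so the chromatin particle
landscape can be stratified by particle class and mapped at high
resolution. `nucparticle` implements the standard analysis chain for such
data:

1. **Ingest** — read aligned pairs from SAM, keeping one record per proper
   pair (the mate with TLEN > 0);
2. **Size-class stratification** — retain pairs with
   `nominal·(1−0.2) ≤ TLEN ≤ nominal·(1+0.2)`; the mono-nucleosome class is
   150 ± 30 bp;
3. **Midpoint tracks** — fragment midpoints tallied in 10-bp bins per
   chromosome, written as zero-referenced three-column `.sgr` text;
4. **Smoothing** — a 3-bin moving average (feeding peak calling and
   clustering) and an Epanechnikov kernel density smoother, bandwidth
   h = 30 bp (feeding displays and site-aligned profiles):
   `s(x) = Σᵢ vᵢ K((x−xᵢ)/h)/h`, `K(u) = ¾(1−u²)·𝟙[|u|<1]`;
5. **Peak marking** — bin *i* is a positioned-nucleosome summit iff
   `v[i] > θ` (θ = 25 by default), `v[i] > v[i−1]` and `v[i] ≥ v[i+1]`;
6. **Site-aligned profiles** — strand-aware ±1,200 bp windows around
   feature anchors (TSS, ATG, called summits), summed across features and
   normalised to the window-average frequency;
7. **Clustering & statistics** — k-means (k = 9, Euclidean) of per-gene
   profile matrices with transferable row order; a subsampled two-condition
   t-test (random disjoint subsets of 100 features, 29 subsets, two-tailed
   unpaired Student's t on the subset means); and an upper-tail
   hypergeometric gene-list overlap test.

The simulator plants phased nucleosome arrays downstream of an NDR at each
TSS (+1 at 60 bp, repeat length 154 bp, occupancy 0.9, positional
fuzziness σ = 10 bp), emulates digestion level through the fragment-length
distribution, and emits proper SAM pairs plus the ground-truth centers —
so peak-calling accuracy is measurable, not assumed.

## Worked example

```python
import io
from nucparticle import *

# a 20-gene synthetic genome with known nucleosome positions
chrom_lengths, features = make_synthetic_genome(n_genes=20)
model = build_model(chrom_lengths, features)        # 220 planted nucleosomes
reads = simulate_fragments(model, WILDTYPE, LOW_DIGESTION,
                           mean_frags_per_nucleosome=50.0, seed=1)

buf = io.StringIO(); reads.write_sam(buf); buf.seek(0)
sam = read_sam(buf)
mids = stratify(sam.records, SizeClassSpec(150))    # 150±30 bp class
raw = build_histogram(mids, sam.chrom_lengths)      # 10-bp bins
ma3 = {c: moving_average_3(t) for c, t in raw.items()}

thr = suggested_peak_threshold(model, WILDTYPE, LOW_DIGESTION, 50.0,
                               SizeClassSpec(150))
peaks = mark_peaks_genome(ma3, threshold=thr)
rep = evaluate_recovery(peaks, model, tolerance_bp=10)
print(f"recovered {rep.recovery_fraction:.1%} of planted nucleosomes, "
      f"{rep.false_positives_per_kb:.3f} false positives per kb")
```

prints

```
recovered 96.4% of planted nucleosomes, 0.087 false positives per kb
```

meaning 212 of the 220 planted nucleosome centers were re-found within
±10 bp (one bin) by the full SAM→peaks chain, with 8 summits further than
10 bp from any planted center over the 92 kb synthetic genome.

There is also a CLI mirroring each stage
(`nucparticle stratify|histogram|smooth|peaks|profile|cluster|ttest|simulate|run`);
`nucparticle run --config run.yaml` executes the whole two-condition
comparison and writes a manifest with parameter fingerprints.

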