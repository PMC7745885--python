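# fourc — viewpoint-anchored 4C-seq interaction analysis

`fourc` turns circularized chromosome conformation capture sequencing
(4C-seq) data into called chromatin interactions.  4C-seq asks one
question about one locus: which parts of the genome does this
*viewpoint* touch?  The assay digests the crosslinked genome with a
primary 4-bp cutter (DpnII, `GATC`), ligates, re-digests with a
secondary cutter (Csp6I, `GTAC`), and sequences inverse-PCR products
anchored at the viewpoint, so read counts per restriction fragment
measure contact frequency.

The package covers the full analysis path for people who have mapped
reads (or fragment counts) and want interactions:

1. **in-silico double digestion** of a FASTA genome into classified
   restriction fragments (`valid`, `blind_primary`, `blind_secondary`,
   `terminal`);
2. **counting** — each read credits the fragment containing its 5′
   position;
3. **filtering and normalization** — blind fragments, fragments
   < 40 bp and fragments within 10 kb of the viewpoint are removed, and
   the profile is scaled so the summed signal within ±2 Mb of the
   viewpoint is 10⁶;
4. **model fitting and peak calling** — the cis profile is modelled as

   S(x) = B + I_v·e^(−|x−x_v|/λ) + Σᵢ Pᵢ·e^(−(x−xᵢ)²/(2σ²))

   a constant background *B*, an exponential distance decay with
   amplitude *I_v* and decay length λ fitted robustly on the left–right
   folded profile, and Gaussian interaction peaks of shared width σ
   tested against a scanning (expected-coverage) p-value at
   α = 0.0005;
5. **consensus** — significant peaks from several samples (e.g. cell
   types) are intersected at base level into shared interacting
   regions;
6. **synthetic data** — genomes and overdispersed count profiles drawn
   from the same three-component model with known truth, so every
   stage is testable end to end.

## Worked example

Simulate a 5-Mb study with known truth (decay λ = 50 kb plus two peaks
350 kb and 430 kb downstream of the viewpoint), run the pipeline, and
fit the model:

```bash
fourc simulate --length-mb 5 --depth 200000 --seed 7 --out-dir demo/
fourc run --fasta demo/genome.fa --counts demo/counts.tsv \
      --viewpoint chrS:2499922-2500078 --out-dir demo_run/
```

```
[fourc] stage digest (0.0s elapsed)
[fourc] stage count (0.2s elapsed)
[fourc] stage normalize (0.4s elapsed)
[fourc] stage call (0.4s elapsed)
[fourc] stage report (2.1s elapsed)
{"stages": ["digest", "count", "normalize", "call", "report"], "n_peaks": 2}
```

The same fit through the library surface:

```python
import fourc
from fourc import io as fio

profile = fio.read_profile_bedgraph("demo_run/profile.bedgraph")
fit = fourc.ViewpointModel(profile).fit()   # or fourc.call_interactions(profile)
print(fit.summary())
```

```
Viewpoint signal model fit
============================================================
viewpoint           chrS:2499922-2500078 (centre 2500000)
fragments (cis)     13931
background B        36.487
decay amplitude I_v 1543.86
decay length lambda 49.42 kb
residual scale      21.7845
alpha               0.0005
converged           True
significant peaks   2
------------------------------------------------------------
      centre  offset_kb    amplitude        z          p
     2855071     +355.1        953.1    19.47   5.76e-51
     2926831     +426.8        456.2     4.52   3.99e-05
```

Reading the output: the decay length comes back at 49.4 kb against a
simulated truth of 50 kb, and the two significant calls sit at +355 kb
and +427 kb — the two planted interaction peaks (+350 kb, +430 kb) in
normalized signal units, each with its scanning p-value (the expected
null fraction of the profile covered by calls at least this strong).
`fit.peaks`, `fit.background`, `fit.predict(x)` and the written
bedGraph/BED/interact/longrange files expose the same results
programmatically and to genome browsers.  Multi-sample consensus:

```bash
fourc consensus --peaks a.peaks.bed --peaks b.peaks.bed --peaks c.peaks.bed \
      --min-support 3 --out consensus.bed
```

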