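# Methods

## The signal model

A 4C-seq library reports, for one viewpoint locus at coordinate
`x_v`, the contact frequency of every restriction fragment with that
locus.  The cis profile is modelled as three independent
contributions:

```
S(x) = B + I_v * exp(-|x - x_v| / lambda)
         + sum_i P_i * exp(-(x - x_i)^2 / (2 sigma^2))
```

* `B` — a constant background (random ligation, trans-like noise),
  in normalized signal units;
* `I_v * exp(-d/lambda)` — the monotone decay of contact frequency
  with genomic distance `d` from the viewpoint; `lambda` (bp) is the
  decay length, `I_v` the decay amplitude at the viewpoint;
* Gaussian peaks of shared width `sigma` (default 20 kb) — localized
  contact excesses, the objects of interest.

The decay is assumed symmetric around the viewpoint, so `(B, I_v,
lambda)` are fitted on the left–right averaged ("folded") profile.

## Processing stages and their assumptions

**Digestion.**  Both enzyme motifs are located by overlapping scan;
fragments are the intervals between cut positions (cut at motif start
by default; the offset is configurable and nothing downstream depends
on it).  A fragment flanked by two sites of the same enzyme is
"blind": it cannot arise from a primary/secondary ligation junction
and carries no usable signal.  Chromosomes are linear; `N` bases never
match a motif.

**Counting.**  A 4C read begins at the restriction site of the
fragment it was ligated to, so a read is credited to the fragment
containing its 5′ position (start on `+`, `end − 1` on `−`).
Duplicates are counted as-is (no UMI structure exists in the assay).
Assigned + discarded (unknown chromosome / out of range) + rejected
(malformed) always equals the input read count.

**Filtering.**  Three rules, attributed in fixed order so the report
is deterministic: fragment class (blind or terminal), length
(< 40 bp), and proximity (midpoint within 10 kb of the viewpoint
centre, where self-ligation products dominate).  The 10-kb window is
read as a radius; both radii are configurable.

**Normalization.**  Retained counts are scaled so that the summed
signal of retained fragments within ±2 Mb of the viewpoint equals
`target_total` (default 10⁶, i.e. "per million in-window reads").  A
plain sum is used — no inverse-distance weighting.  `W = 0` in the
window is a hard error, since the profile scale would be undefined.

**Background fit.**  The folded profile (5-kb distance bins, bin value
= mean fragment signal, support = fragment count) is fitted by
bounded nonlinear least squares (`lambda` in [1 kb, 10 Mb]; `B, I_v
≥ 0`), initialized from the outer-bin median (B) and the log-linear
slope of the positive excess (lambda).  Two robustness devices:

* *iterative reweighting* — bin variance is taken proportional to
  (predicted mean)²/support, because count noise is approximately
  multiplicative at realistic depths; weights use the previous
  iterate's prediction;
* *guarded trimming* — after each fit, up to 10% of bins whose
  positive **relative** residual exceeds 3 robust SDs are discarded
  (putative peak contamination) and the fit repeated, twice.  Trimming
  on relative rather than absolute residuals keeps the noisy
  near-viewpoint bins from being removed preferentially (which would
  bias `lambda` upward), and the 3-SD guard means a peak-free profile
  is never trimmed at all, so the fit stays unbiased under the null.

A flat profile degenerates gracefully to `B = weighted mean, I_v = 0,
lambda = 1 kb`, flagged in the diagnostics.

**Noise model.**  The global residual scale is the Gaussian-consistent
MAD, `1.4826 * median|r - median(r)|` (reported as
`residual_scale`).  Because count noise grows with the local mean, a
distance-dependent scale `tau(x) = c * mu(x)^gamma` is additionally
fitted to binned MADs of the residuals against the fitted background
mean (`gamma` clipped to [0, 1.5]; constant fallback when `mu` has too
little dynamic range).  `tau` standardizes the residuals for peak
detection; without it, decay-region noise masquerades as peaks.

**Peak detection.**  The scan statistic at a position `c` is the
weighted least-squares amplitude of a Gaussian bump of width `sigma`
fitted **jointly with a local baseline** under a smooth Gaussian
observation window of width 2.5 sigma (truncated at 7.5 sigma).  The
joint baseline makes the statistic insensitive to smooth background
misfit; the smooth window keeps the scan field differentiable (a hard
window boundary would make the field jump every time a fragment enters
the window, fragmenting peaks into micro-maxima and inflating the
false-call rate).  The z-score is studentized by the locally estimated
weighted residual variance, which makes it invariant to local errors
in the `tau` level, and de-skewed by a first-order Cornish–Fisher step
using the robustly estimated residual skewness.

Significance uses a *scanning* p-value rather than a pointwise tail:
for this scan field the expected fraction of the profile covered by
calls (each spanning ±2 sigma) whose z exceeds `u` is

```
p(u) = 0.7028 * (1 + u^2/nu)^(-(nu-1)/2)      (t-field Rice/EC tail)
```

with the coefficient derived from the field's roughness
(`-rho''(0) = 1.2188 / sigma^2` for this window/kernel combination) and
`nu` the Satterthwaite degrees of freedom of the local variance
estimate.  The profile length cancels, and declaring calls at
`p < alpha` controls the expected null fraction of fragments inside
significant calls at `alpha`.  This accounts for the selection of
candidates as local maxima, which a plain normal tail would not.
Candidates are local maxima of the 5-fragment running mean of the
standardized residuals; significant candidates hill-climb to the best
z in their basin (so shoulders of a strong peak coalesce onto it), are
polished by a continuous local least-squares fit of (amplitude,
centre) with the centre bounded to ±1 sigma, and calls closer than
2 sigma are merged keeping the smaller p.  Large profiles are scanned
by gridded convolution (grid step sigma/40) and significant calls are
re-evaluated exactly on the fragment grid.

The threshold defaults to `alpha = 0.0005` per candidate, with no
additional multiple-testing layer.

**Consensus.**  Significant peaks from each sample are expanded to
their ±2 sigma footprints; genomic bases covered by at least
`min_support` samples form regions (merged across gaps ≤ `merge_gap`),
each recording its supporting samples and their best p-values.
Base-level intersection is robust to per-sample differences in peak
width, unlike centre matching.

## Synthetic data: what it emulates, and what it does not

`simulate_genome` draws i.i.d. bases at GC 0.41 (human-like); with two
4-bp cutters this yields a mean raw fragment length of ~130 bp and a
retained-fragment spacing of ~260 bp, a realistic fragment density.
`simulate_counts` draws negative-binomial counts whose expectation
follows the truth model S(x), scaled so the expected in-window total
equals `depth`; blind/short/near-viewpoint fragments receive
background-rate counts so the filters have real work to do.  Defaults:
depth 200,000 in-window reads, dispersion 5 (variance
`mu + mu²/5`, i.e. strongly overdispersed), background `(B = 0.5,
I_v = 20, lambda = 50 kb)` and two peaks at +350 kb (amplitude 15,
sigma 20 kb) and +430 kb (amplitude 8, sigma 30 kb) — a strong
promoter-contact-like peak plus a weaker, broader distal one inside a
±2-Mb window.

Features of real 4C libraries that the generator does **not**
emulate: mappability and GC biases along the genome, PCR duplication
structure, undigested/self-ligated viewpoint products (beyond the
exclusion-zone fragments), trans contacts, and correlated noise
between neighbouring fragments.  Passing tests therefore demonstrate
correctness of the algorithms under the stated count model, not
robustness to every artefact of real libraries.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open throughout; BED/bedGraph writers
  keep that convention.
* `curve_fit` runs with `xtol = ftol = gtol = 1e-14`, so noiseless
  parameter recovery is exact to ~1e-12 relative.
* Zero cut sites → a single terminal fragment; empty read input → all
  zero counts; all-identical residuals → a hard "zero noise" error;
  an empty residual series → an empty call list; a one-sided profile
  folds one-sided with a warning.
* All simulation randomness flows from a single integer seed; the
  fitting path contains no randomness, so identical inputs give
  byte-identical outputs (no timestamps are written).

## Known limitations

* The peak-centre precision is bounded by the peak's own count noise:
  under dispersion 5 the per-fragment coefficient of variation at a
  peak top is ~0.45 regardless of amplitude, which puts the
  centre's information bound at roughly 0.5–1.5 kb (a few
  retained-fragment spacings) for sigma = 20 kb peaks.  Centres should
  be interpreted at kilobase, not fragment, resolution; only in the
  Poisson/additive-noise limit does single-fragment localization
  become possible.
* A single shared sigma is assumed in the scan (as in the model
  equation).  Peaks much broader than sigma are still found (the
  +430 kb / sigma 30 kb default peak is called by the 20-kb scan) but
  their amplitude is attenuated and their footprint underestimated.
* The model is cis-only and one-viewpoint; trans interactions and
  matrix-level corrections (as in Hi-C balancing) are out of scope.
* The scanning p-value calibration is asymptotic in the number of
  fragments per kernel window; for very sparse fragment maps
  (window < ~30 fragments) it becomes conservative.
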