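# Methods

This note records the estimators, their defaults, and the numerical
choices behind `promoterlab`, in enough detail to re-derive every
number the package produces.

## Fluorescence scores (readproc)

For one variant, channel and technical replicate with reads
`R_1..R_4` in bins coded 1–4,

```
fluor_r = Σ_f f · R_f / Σ_f R_f            (Eq. 1)
fluor   = mean over replicates with defined fluor_r   (Eq. 2)
```

A replicate with zero reads in every bin is *undefined* (NaN) and is
excluded from the mean; a variant with no defined replicate is
undefined overall and excluded downstream.  Scores live on [1, 4]
arbitrary units (a.u.).  **Promoter threshold: 1.5 a.u., inclusive**,
per channel (GFP = top strand, RFP = bottom strand).

Mutagenesis libraries sorted into only OFF/ON bins are scored with
codes {1, 2} and mapped onto the standard scale by the unique affine
map `1 + 3·(fluor − 1)` carrying [1, 2] to [1, 4].

Quality filters (`filter_reads`): presence in the unsorted library,
nonzero reads in ≥ `min_bins` distinct bins (pooled over channels and
replicates, default 4), and insert length within [100, 200] bp.

## PWM scoring (pwm)

PWMs are per-position probability matrices over A/C/G/T; window scores
are summed log₂ odds against a uniform 25% background (bits).
Information content is `Σ_i (2 + Σ_b p_ib log₂ p_ib)` bits.  The
**Patser threshold** is `ln(IC_bits · ln 2)` — the natural log of the
information content expressed in nats.  (A matrix built with
`patser_ic_units="bits"` uses `ln(IC_bits)` instead; both readings
classify all shipped examples identically.)  A window is a *predicted
site* at score ≥ threshold and a *proto-site* at 0 < score <
threshold.  Both strands are scanned; bottom-strand hits are reported
at the 1-based top-strand start of the window they cover.  With
pseudocount 0 a never-observed base scores −∞ and the window is
neither predicted nor proto.

## Family reconstruction and P_new (families)

Pooled daughters are grouped by exact length, then clustered by
single-linkage connected components of the graph joining pairs at
Hamming distance ≤ 10.  The per-position majority base is the
reconstructed parent; ties break alphabetically (A < C < G < T) so the
consensus is order-independent.  Family filters: parent present in the
wild-type library, ≥ 500 daughters, length within [100, 200] bp.

`P_new` = (daughters with fluor ≥ 1.5) / (daughters with defined
fluor).  Undefined daughters are excluded from both numerator and
denominator because they carry no score at all.

## Mutual-information hotspots (hotspot)

At each position i, with b the daughter's base and f its fluorescence
rounded **half-up** to an integer clipped to {1, 2, 3, 4},

```
I_i = Σ_b Σ_f p_i(b, f) log₂ [ p_i(b, f) / (p_i(b) p(f)) ]   (bits)
```

Half-up rounding matters because the promoter threshold sits exactly
at 1.5.  The raw profile is smoothed with a 1-D Gaussian (σ = alpha,
default 2 bp, reflect boundaries, truncation 4σ), and hotspots are
strict local maxima of the smoothed profile above 0.0025 bits
(interior positions only; plateaus do not qualify).

**Estimator validity.**  The plug-in MI estimate is biased upward by
approximately `(r−1)(c−1) / (2 N ln 2)` bits for an r×c table with N
observations.  With 4 bases × 4 fluorescence levels this is
`9 / (2 N ln 2)`: at N = 2000 daughters the bias alone (0.0033 bits)
exceeds the hotspot threshold, while at N = 5000 it is 0.0013 bits.
Null-calibration studies therefore use ≥ 5000 daughters; applying the
caller to much smaller families will produce bias-driven hotspots.

## Site screen (site_screen)

For every (parent, PWM, window offset, strand, channel), daughters are
split into predicted-site carriers and non-carriers at that window.
When **both groups exceed 10** scored daughters, a two-sided
Mann-Whitney U test is run; all p-values of a screen run form a single
Benjamini-Hochberg family and calls require q < 0.05.  The exact U
null distribution is used whenever the data are tie-free and the
smaller group has ≤ 25 observations; otherwise the tie-corrected
normal approximation with continuity correction.

Significant windows are classified against the parent's own window:

* `gain_activating` — parent lacks the site, the strand matches the
  responding channel (top/GFP, bottom/RFP), and carrier median exceeds
  non-carrier median by ≥ 0.1 a.u.
* `loss_repressing` — parent carries the site (TF matrices only;
  sigma-factor losses are excluded as confounded with promoter loss),
  either strand, and losing the site raises the median by > 0 a.u.

## Library statistics (library_stats)

AT-content incidence uses half-open 5% bins over [40%, 70%) with an
overflow row.  Printed values use decimal round-half-up (e.g. expected
promoters = round(genes × coverage × constitutive fraction)).  Hexamer
enrichment runs two-sided Fisher's exact tests on overlapping
forward-strand hexamer counts with BH correction; the −10 box hexamers
(TATAAT and its reverse complement) always appear in the output.
Threshold calibration returns the (1 − target) empirical quantile.

## Synthetic generator (synthgen): model and scope

Ground-truth expression of a channel-oriented sequence (RFP reads the
reverse complement) is a clamped linear model:

```
activity = clip( basal
               + Σ_activators  w_a · max(0, best_top_score − threshold)
               − Σ_repressors  w_r · [predicted site on either strand],
               1.0, 4.0 )    (a.u.)
```

Activators act strand-specifically through their best top-strand
window; repression is orientation-independent.  Cells draw log-normal
noise around log(activity) (sd default 0.1), are sorted multinomially
into four bins cut at (1.75, 2.5, 3.25) a.u., and each bin's fixed
read budget is sampled multinomially over sequences in proportion to
cell occupancy.  Daughter mutation counts follow a binomial(L, rate)
truncated to [1, 10]; positions are drawn without replacement and
substitutions are uniform over the three alternatives.  All randomness
flows from one integer seed through spawned child generators, so a
fixed configuration reproduces byte-identical outputs.

**Default ground truth.**  Five activator motifs (one sigma-class,
four TF-class), each a 13-bp consensus with 94% per-position
conservation (~20.5 bits, Patser threshold 2.654).  This profile was
chosen by forward calculation, not fitting: 3-mismatch windows score
8.18 bits (predicted) and 4-mismatch windows 2.621 bits (proto-sites,
just sub-threshold), giving a random 150-mer library at 50% AT a
~15–17% promoter fraction, ~1 proto-site per sequence, and an
abundant supply of transcriptionally inactive parents.  Default
effect weight 0.35 a.u./bit of threshold excess; basal activity 1.0.
`genomic_like` parents are rejection-sampled below a quantile of the
random-class proto-site census — an operational stand-in for a genome
depleted of near-sites.

**Scope and limitations.**  The generator validates estimators; it is
not a biophysical model.  Known simplifications: position-independent
PWM energetics with a hard threshold and linear effects; no spacer
geometry between −35/−10 elements, no RNA-polymerase occupancy
competition, no epistasis beyond clamping; identical bin boundaries
and noise for both channels; no PCR jackpots, sequencing errors, or
indels; per-factor conservation uniform across positions, so
predicted/proto classes form a discrete score lattice rather than a
continuum.  Conclusions about estimator behaviour transfer; absolute
effect sizes do not.

## Validation studies (simstudies) and problem sizes

* Rank recovery: 200 sequences spread over [1, 4] a.u., sd 0.1, 10⁴
  reads/bin → Spearman ≈ 0.998.
* Planted activator: an inactive parent with one planted proto-site
  (four mismatches from the sigma consensus; every single correction
  is a predicted site), 1500 daughters, effect 0.6 a.u./bit →
  hotspot and gain_activating within ±2 bp in 100/100 replicates.
* Planted repressor: consensus activator plus a zero-pseudocount
  all-or-nothing repressor site whose weight (activator consensus
  contribution + 1 a.u.) cancels activation → loss_repressing within
  ±2 bp in 100/100 replicates.
* P_new contrast: 50 inactive parents per class (random vs
  proto-depleted), 300 daughters each → medians 0.005 vs 0.0,
  one-sided Mann-Whitney p ≈ 1.4e-6.
* Null screen: zero-effect model, one 2000-daughter family, four
  low-information PWMs → 742 tests, 0 BH-significant.
* Shuffled-fluorescence hotspots: 5000-daughter family scored through
  the pooled OFF/ON path, 100 permutations → 100% hotspot-free (see
  the MI bias note above for why N = 5000).
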