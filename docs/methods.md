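# Methods

`tfocc` models in-vivo transcription-factor (TF) site occupancy as a
function of DNA-intrinsic and chromatin features. A binding-site list is
annotated into a sites × features table, the ChIP-seq tag count around each
site serves as the quantitative occupancy target, and SVM/random-forest
models quantify how well — and through which features — occupancy can be
predicted. This note documents the models, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## Binding-site acquisition

**Log-odds PWMs.** JASPAR-style probability matrices are converted to log2
odds against the human-genome base composition A/C/G/T = 0.29/0.21/0.21/0.29
(configurable). Rows are renormalized, then

    w[i, b] = log2((p[i, b] + c·bg[b]) / ((1 + c)·bg[b]))

with pseudocount `c = 0.01` spread proportionally to the background, so a
background-equal row maps to zero weights at any pseudocount and zero
entries get a finite penalty. The pseudocount is applied before the
log-odds transform.

**P-value score thresholds.** The null score distribution of a random
N-mer under the background model is computed by exact convolution of the
per-position score distributions on a rounding grid (default 0.01 log2
units; the tests use 0.001). The threshold is the smallest grid score whose
upper tail probability is ≤ the requested P-value (default 1e-4). Accuracy
is limited only by the grid: k-mers within ~N·grid/2 of the cut may fall on
either side, which the oracle tests account for explicitly.

**Scanning and centers.** Both strands are scanned; windows containing N
are skipped rather than penalized. A site is reported as a single 0-based
center: the motif midpoint for odd lengths, the position immediately
upstream of the midpoint for even lengths (which maps to the downstream
position in forward coordinates for minus-strand hits, so scanning a
sequence and its reverse complement yields mirror-image lists). Peak-list
workflows instead take the best-scoring full-length match within ±100 bp of
the peak center (ties: smaller |offset|, then plus strand). Predicted sites
lacking ≥3 deduplicated tags within ±100 bp in every supplied ChIP library
are discarded.

## Tag coverage and track features

Tag tracks hold strand-separated, deduplicatable 5′ read positions.
Windows are inclusive (`±h` covers `2h+1` bases); the presets follow the
study design: ±100 bp for TFs/cofactors/PolII, ±250 bp for DNase, ±500 bp
for histone marks, ±50 bp for conservation, ±10 bp for SNP density and
nucleosome-occupancy tracks.

**Fragment shift.** Non-histone 5′ tags are moved toward the fragment
center by half the fragment length, estimated per library as the
displacement `d*` maximizing the plus/minus strand cross-correlation of
1-bp binned counts (FFT-based, lags 0–400 bp, summed over chromosomes).
Because 1-bp counts are sparse, the peak is first located on a 5-bp moving
average and then refined to the raw-correlation maximum inside that window;
ties resolve to the smallest lag. The shift is `round(d*/2)`. On simulated
libraries (200 sites × 20 reads, 150 bp fragments) this recovers the
planted 75 bp within ±1 bp in ≥98 % of libraries.

**Numeric tracks** (conservation, precomputed nucleosome occupancy,
histone bedGraphs) are averaged per base over the window; uncovered bases
contribute 0 and the denominator is the full window, so sparse tracks are
not inflated. SNP BEDs become per-base count tracks consumed by the same
averaging.

## Footprint shape partitioning

DNase profiles are extracted as pooled-strand counts in 10-bp bins over
±500 bp, extended by ±50 bp margins so each of the 11 shift states (−50 to
+50 bp in 10-bp steps) is fully observed. A two-class EM then partitions
sites by profile *shape*:

- **Typical class:** a shared multinomial shape over the 100 core bins,
  placed at one of the 11 displacements (uniform shift prior), plus a
  learned "edge" probability mass spread uniformly over the bins outside
  the shifted core. Every shift hypothesis thereby explains the *full*
  extraction window, which keeps likelihoods comparable across shifts —
  with a sliding sub-window instead, background sampling noise can make a
  translated solution the likelihood maximum and corrupt every shift
  estimate by a constant.
- **Atypical class:** a free multinomial over all bins, initialized flat
  and converging to flat background when the data contain no second shape.

Both emissions condition on the profile total, so classification reflects
shape, not sequencing depth. The M-step uses a Dirichlet pseudo-count
(α = 0.5 per bin) on both shapes, and the reported objective trace is the
correspondingly penalized log-likelihood, which is non-decreasing by
construction (asserted on every run). Initialization takes the typical
shape from the top decile of profiles by best-shift center-to-flank
contrast. The shape/shift decomposition is identifiable only up to a
translation absorbed by the shift grid; clipped edge states anchor the
maximum-likelihood gauge, and a guarded recentering move (roll the shape by
the posterior-mean drift, let both branches re-adapt a few E/M steps, keep
the better one) lets the EM escape translated local optima without ever
decreasing the objective. Consequently a uniform translation of all input
profiles leaves `p` unchanged and moves all shifts by one common constant
— per-site shifts are meaningful relative to the recovered aggregate
shape. After convergence the "typical" label goes deterministically to the
class with higher center-to-flank contrast; all-zero profiles are flagged
and reported at the prior with shift 0. The reported `s` is the
re-centering correction: a footprint displaced downstream by `k` bins gets
`s = −k·binsize`.

On 200 simulated profiles (30 % flat, shifts uniform on the grid) the
partition recovers class labels at ≥99 % accuracy and exact shifts for
97–100 % of typical sites.

## Sequence-intrinsic features

k-mer compositions (k = 1..5) are computed in three blocks — upstream
`[center−100, center)`, downstream `(center, center+100]`, and the full
±100 bp window; the center base belongs to the full block only. Frequencies
within each (block, k) sum to 1 and k-mers containing N are excluded from
numerator and denominator; the full set is 4032 features. Because such
compositions are largely driven by G+C, the pipeline's default feature set
carries a single G+C-content feature instead, with the full composition
available on request.

Ten dinucleotide structural scales (A-philicity, Z-DNA stability energy,
duplex disruption and stability free energies, stacking energy, DNA
denaturation, B-DNA twist, protein-DNA twist, propeller twist, bending
stiffness) are averaged over the 20 dinucleotide steps covering
±10 bp: step `i` spans bases `(center−10+i, center−10+i+1)`. The shipped
value tables are best-effort literature-style values (reverse-complement
symmetric, editable TSV); the tests exercise the mechanism, not the exact
numbers, which vary between published compilations.

## Modeling

Feature columns are z-scored (zero-variance columns dropped with a
warning); the centering/scale parameters are stored and re-applied to any
held-out table, so cross-dataset prediction never re-fits normalization.

**Classification** discriminates strong from weak sites: sites are ranked
by tag count, the top and bottom 20 % labeled (ties broken by stable
order), the middle discarded. Data are split stratified 90/10; on the 90 %
the SVM cost parameter is selected from {0.25, 0.5, 1, 2, 4, 8, 16, 32} by
leave-one-group-out CV auROC over 10 randomized, seeded, near-equal groups,
with the RBF width fixed beforehand by the median heuristic
(γ = 1/(2σ²), σ the median pairwise distance of a ≤500-point seeded
subsample). Both the CV auROC and the 10 % holdout auROC are reported,
since either may be the quantity of interest. Single-class folds trigger a
seeded refold (logged). Methods: SVM with radial or polynomial kernel, or
random forest.

**Regression** predicts the tag count itself on all sites (no subsetting)
with SVR (RBF) under the same grouped CV; the metric is the Pearson
correlation between measured targets and pooled out-of-fold predictions.
For a linear target with signal-to-noise ratio SNR the population optimum
is √(SNR/(1+SNR)); the CV PCC lands within 0.05 of it at n = 1000.

**Cross-dataset prediction** applies a fitted model to another table after
transforming it with the training normalization; missing features raise
with their names. On the training table it reproduces the resubstitution
metric exactly.

**Feature importance** is model-agnostic permutation importance: the drop
in auROC/PCC when one feature column is shuffled, averaged over
permutations (default 20), clipped at zero and normalized to sum to 1 for
stacked presentation. **RFE** removes the lowest-importance feature one at
a time, re-evaluating grouped-CV auROC at each size; at the full feature
set the curve equals the classifier's CV auROC for the same seed and cost.

**Overlap summaries** match sites whose centers lie within a configurable
distance (default 100 bp, the annotation window) transitively into
entities, and report Venn region counts, the union total, and the
percentage common to all lists rounded to one decimal.

## Synthetic data

The generator emits a complete, seeded, byte-reproducible study: an i.i.d.
background genome (default 700 kb, GC 0.41) with 300 motif instances
sampled from the PFM at non-overlapping positions (≥1.6 kb apart so no
feature windows collide), each instance's log-odds score recorded as its
true affinity. Occupancy is `max(10 + g(w·z) + ε, 0)` over z-scored latent
features (affinity; accessibility ~ N(0,1); a histone-state latent
correlated 0.7 with accessibility), `g` the identity, a rectifier, or an
affinity×accessibility interaction, ε Gaussian (sd 0.1). Archetype presets
encode recruitment styles: affinity-dominated (`ctcf_like`, w = 3/2/0.5),
chromatin-dominated (`jund_like`, w = 0/3/2), affinity-only (`rest_like`,
w = 3/0/0).

ChIP-like reads place, per fragment, a plus 5′ end near `center − L/2` and
a minus 5′ end near `center + L/2` (L = 150 bp, Gaussian jitter sd 10 bp),
with Poisson fragment counts proportional to occupancy (mean 20 per site)
and 10 % uniform background. DNase-like tags draw offsets from a footprint
shape — sharp cleavage peaks ~30 bp either side of a protected core, atop
a broad hypersensitive dome — displaced by a shift from the ±50 bp grid
for "typical" sites (70 %) and uniformly for "atypical" ones; per-site
depth scales with exp(0.5·accessibility) around 100 tags. Seven named
histone-mark tracks are sums of 300-bp Gaussian bumps with amplitude
`a·occupancy + b + noise` on a 10-bp-binned genome; conservation is
elevated inside the ±10 bp motif span; SNPs are a 1/300-per-base Poisson
process thinned to 30 % retention inside conserved spans.

What this does **not** emulate: mappability and PCR-duplicate artifacts,
chromatin-domain structure, motif clustering or co-factor grammar, diploid
variation, and the heavy-tailed occupancy distributions of real ChIP data.
Passing recovery tests therefore demonstrates the pipeline's correctness
and statistical behavior under its stated model, not performance levels on
real ENCODE-scale data.

## Reproducibility and sizes

All randomness flows from a single root seed split per stage; repeated
runs are byte-identical (asserted end-to-end). Default desk-scale sizes —
120–300 sites on 280–700 kb genomes, 8–20 seeded replicates for
recovery-rate measurements — keep the full test suite under a minute and
the acceptance script under a minute on one core, while leaving every
recovery check with comfortable statistical margin.

## Known limitations

- Cross-dataset prediction is exposed in the library (`cross_predict`),
  not the CLI: fitted kernel machines are not serialized.
- Chromosome ends are truncated using position 0 only; upper bounds are
  unknown without a sequence dictionary and windows are not clipped there.
- The P-value threshold inherits the rounding grid's resolution; callers
  needing sharper cuts can pass a finer grid at linear cost.
- Per-site footprint shifts are defined relative to the recovered
  aggregate shape (gauge fixed by recentering); absolute shifts are only
  meaningful when the cohort's displacements are centered, as they are by
  construction in the simulator.
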