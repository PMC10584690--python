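# Methods

## Accessibility model

Each sequenced molecule is modeled as a two-state Markov chain along its
called adenines: hidden state accessible (1) or inaccessible (0) to the
methyltransferase, observed state the binary methylation call. Emissions
are Bernoulli with per-adenine rates taken from control molecules —
the accessible rate from fully methylated naked-DNA controls, the
inaccessible rate from unmethylated controls — smoothed as
(k + 0.5)/(n + 0.5) so no probability is exactly zero. A saturated
positive control can still yield an emission of exactly 1.0; this is
kept (log-space guards handle it), with an optional epsilon cap off by
default.

Transitions assume a geometric run-length distribution: with expected
run length L, the per-base switching hazard is 1/L and the probability
of remaining in the same state across an inter-adenine gap of B bases is
(1 − 1/L)^B. The default L = 1000 bp is deliberately larger than a
nucleosome; it demands a high burden of evidence before switching and
suppresses spurious state flips. Larger L never increases the number of
switches in a decoded path (verified as a test invariant). The chain
starts accessible or inaccessible with probability ½ each.

Decoding is Viterbi (maximum a posteriori path), checked for exactness
against a brute-force enumeration oracle on all instances up to 12
adenines. Ties are broken toward the inaccessible state — conservative
footprint calling; ties are score-equal by construction, so the choice
affects only the reported path. Unusable adenines are dropped from the
chain and their distances absorbed into B. The decoded path (1/0 per
adenine) is expanded to a per-base track by linear interpolation
between adenines (nearest-neighbor interpolation available), with the
ends copying the nearest decoded value.

### What decoding can and cannot recover

On synthetic molecules with realistic methylation efficiencies
(accessible ≈ 0.40, protected ≈ 0.02 per adenine, adenines at half of
template positions), base-level decoded accuracy is ≈ 0.97 and per-fiber
nucleosome counts are recovered exactly on ≈ 99% of molecules. Exact
footprint *boundaries*, however, are recovered only to within a few
base pairs at best: near a boundary each accessible adenine carries only
≈ 0.9 nats of expected evidence, so the MAP switch point fluctuates by a
few adenines, and two nucleosomes flanking a short (≈ 10–30 bp) linker
are merged into a single region because the linker's ~2 expected
methylated adenines cannot pay the ~13.8-nat cost of two state switches
at L = 1000. Merging is why nucleosome counting is done by region
length, not by region number. In the noiseless limit (p_acc → 1,
p_inacc → 0) the planted footprint set is recovered exactly to
inter-adenine resolution (tested).

## Methylation thresholding

Per-adenine residual distributions are modeled as a two-component
Student-t mixture fit by the classical ECM scheme with latent gamma
scaling weights. Degrees of freedom are profiled per component by a 1-D
root solve of the stationarity condition, bounded to [1, 200]; `fix_df`
pins them instead. The likelihood surface is multimodal — a broad
near-Gaussian component can absorb the tail of a dominant narrow one —
so the fit runs 5 restarts (interquartile split first, then random data
pairs) and keeps the highest final log-likelihood. Convergence is a
log-likelihood change below 1e-6; non-convergence is flagged on the
returned object, not raised. Components are returned sorted by mean.

The cutoff is the root of π₁f₁(c) = π₂f₂(c) between the two means
(posterior responsibility ½). Weighted densities are the default —
the standard mixture-model reading of "equally likely" — with an
unweighted option. Usability requires (1) a positive component mean,
(2) a mean gap of at least 0.2 (midpoint of the 0.1–0.3 range used per
amplicon in practice; configurable), and (3) at least 2% of training
residuals above the cutoff. Calls are strict: residual > cutoff.

## Footprints and density

Inaccessible regions are maximal runs of track values ≤ 0.5
(inclusive, exactly as specified). The default nucleosome-count ladder
— below 100 bp subnucleosomal (0), below 280 mono, below 450 di, below
620 tri, then one more nucleosome per 170 bp — reflects the 147-bp core
plus the observed ~120–160-nt mono-nucleosome footprint range. Real
datasets should calibrate the ladder from their footprint-length
histogram; `suggest_cutoffs` locates histogram valleys as candidates.
Density is total nucleosomes × 1000 / template length (per kbp).

## Autocorrelograms, peaks and clustering

The autocorrelogram is the standard biased estimator
r(k) = Σ(x_t − x̄)(x_{t+k} − x̄)/Σ(x_t − x̄)², computed to lag 1000 by
default (FFT; checked against the direct definition). The spacing peak
is the highest genuine local maximum inside a 100–500 bp window
(covering observed NRLs of roughly 172–357 bp); plateaus report their
smallest lag and window-edge argmaxes of monotone stretches do not
count. Per-molecule peaks are average internucleosomal distances; they
are interpreted as NRLs only for averaged or clustered signals.

Clustering builds a k-nearest-neighbor graph (Euclidean distance on
autocorrelogram vectors) and runs Leiden at resolution 0.4, then removes
clusters smallest-first while they jointly hold under 5% of molecules.
The neighbor count defaults to n/10 clipped to [15, 50]: the community
scale of modularity-type objectives depends on total edge count, and a
fixed small k over-fragments datasets of a few hundred molecules (two
planted populations come out as 4–10 fragments at k = 15), while at the
tens-of-thousands scale the default clips to 50 and behaves like any
conventional choice. An explicit `n_neighbors` always wins. UMAP
embedding (seeded, default parameters) is provided for visualization
only.

## Array simulation and remodeling

Initial arrays are random sequential adsorption: uniform candidate
starts, accepted when the 147-bp footprint keeps ≥ 10 nt between
adjacent entry/exit points. RSA jams below the Rényi coverage limit —
a partial configuration can leave no admissible gap well before the
density bound — so after `max_attempts` consecutive rejections the
configuration is discarded and placement restarts, up to `max_restarts`
runs before a packing error. At 13 nucleosomes per 2,712-bp template
roughly a third of single runs jam; restarts make the full studied density
range (2–13 nucleosomes) reliably reachable while leaving truly infeasible
requests failing fast.

**Clamping** is a single 5′→3′ pass. Pair (i, i+1) is visible when the
current linker (using exit positions already updated by earlier moves in
the pass) is ≤ 183 nt; the 3′ nucleosome is then placed at
exit_i + d with d ~ Normal(ruler, ruler_sd) truncated at zero and
rounded (ruler_sd = 0 by default: a deterministic ruler). The 5′
nucleosome is always the barrier. Moves are clipped so a nucleosome
never overlaps its 3′ neighbor or leaves the template. The visibility
threshold is read as a *linker* length (not entry-to-entry): only this
reading lets clamping act at low densities, where the fixed-spacing
signature must still appear.

**Length sensing** runs `n_sweeps` 5′→3′ sweeps (default 500). Each
visit computes the 5′ flank (gap to the 5′ neighbor's exit, or to
position 0) and the 3′ flank (gap to the 3′ neighbor's entry, or to the
template end); the nucleosome moves `step` nt (default 1) toward a
flank only if that flank is at least the cutoff, with a fair coin when
both qualify. Because cutoff ≥ step, moves never create overlaps. One
step per visit (rather than sliding until blocked) is the default:
slide-until-blocked collapses every eligible linker to just under the
cutoff in one sweep, which destroys the density dependence that
distinguishes the two mechanisms. Termination is by sweep count — the
random direction choice yields a stochastic steady state, not a fixed
point. Post-remodeling linkers may drop below the 10-nt initialization
minimum; only non-negativity is enforced after remodeling.

Both processes only slide: nucleosome count is preserved exactly, and
identical inputs plus seed give bit-identical outputs.

### The discrimination benchmark

Simulating ≥ 200 fibers per density for densities 5–12 on 2,712-bp
templates and averaging autocorrelograms per density: clamping (ruler
20, sd 0) puts every per-density peak at 167 bp (147-bp core + 20-nt
ruler, range 0 across densities), while length sensing (cutoff 48)
produces peaks that decrease strictly with density (Pearson r ≈ −0.99).
Problem sizes used by the benchmark script: 600 fibers/density for the
clamp arm and 2000 for the length-sensing arm — at 500 one-step sweeps
the density-5 average profile is nearly flat (a nucleosome diffuses only
~22 nt RMS in 500 sweeps, so low-density fibers barely equilibrate and
their averaged peak is weak), and the larger ensemble pushes the
argmax's Monte-Carlo noise below the ~10-bp spacing between
adjacent-density peaks.

## Enrichment statistics

Fisher tests are two-sided exact tests on the 2×2 membership table per
(cluster, domain); the reported odds ratio is the sample ratio ad/bc
with infinities preserved and empty-margin tables flagged undefined
rather than dropped. Storey q-values estimate π₀ on the λ grid
0.05–0.95 (step 0.05) with a cubic smoother evaluated at the largest λ;
families under 100 tests fall back to π₀ = 1, which makes the q-values
exactly Benjamini–Hochberg. The correction family is all cluster ×
domain tests of one run. Differential matrices subtract raw odds ratios
(log-odds optional); non-finite cells propagate as NaN and are reported,
never imputed. PCA treats domains as samples (the differential matrix is
transposed), reduces to 4 components, and correlates PC1 scores with
per-domain mean densities (Pearson and Spearman, two-sided). Weighted
interval scheduling is the exact dynamic program (sort by end,
binary-search predecessor); ties prefer the earlier-ending interval.
BLAST tabular input uses query coordinates (1-based inclusive,
converted to 0-based half-open), bitscore as score and subject id as
label.

## Synthetic data

The generator emulates: 2,712-bp templates (a 2,861-bp second sequence
differs only in length), adenines at half of template positions (an A·T
pair has adenine on exactly one strand, so one merged coordinate track
holds at most one adenine per position), per-adenine methylation
efficiencies Beta-distributed with means 0.40 (accessible) and 0.02
(protected) — fixture defaults chosen to make nucleosome-scale
footprints detectable, not measured values — 147-bp footprints at
controlled counts, regular arrays with planted NRL, optional
per-nucleosome positional jitter (sd 10 bp, realistic phasing noise),
and two-component t residual mixtures with truth labels.

It does not emulate: sequence-context-dependent methylation efficiency
beyond the Beta spread, polymerase kinetics or subread structure,
sequencing error, strand-specific effects, or non-nucleosomal protein
footprints. Passing tests therefore demonstrate correctness of the
inference given the generative assumptions, not performance on real
sequencing data, where emission calibration quality dominates.

Determinism: every stochastic stage of the workflows draws a child seed
from the master seed via `numpy.random.SeedSequence` keyed by the stage
name, so stages never share random state and any stage can be re-run in
isolation.

## Known limitations

- Remodeler kinetics are step functions of flank length; real
  discrimination is continuous in flank length and rate, and nucleosomes
  are visited in a fixed 5′→3′ order.
- No sequence-dependent positioning energies, eviction, or loading.
- Footprint boundaries are resolved only to a few bp under realistic
  noise, and closely spaced nucleosomes merge (see above); dyad-level
  positioning is out of scope.
- The nucleosome-count ladder defaults are heuristic and should be
  recalibrated per dataset.
- Posterior (forward–backward) decoding is not implemented; the method
  is Viterbi-only by design.
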