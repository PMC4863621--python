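# Methods

This note documents the models behind each verification stage, the defaults
and why they were chosen, what the synthetic benchmark does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Composition membership (canonical k-mer signature)

Scaffolds are profiled as frequency vectors over canonical k-mers (k = 4 by
default: 136 dimensions; a k-mer is canonical when lexicographically ≤ its
reverse complement, which makes profiles strand-independent). Windows
containing N are skipped and do not count toward the window total.

The membership statistic compares a scaffold with the renormalized
per-dimension median of the *other* members' profiles. Two details matter
and were the decisive design choices of this module:

* **Exchangeability.** Every scaffold's distance — the query's and each null
  member's — is computed against a median that excludes that scaffold's own
  profile. If member distances were taken against a median that includes
  them (the naive construction), they are systematically shrunk relative to
  the excluded query, every query sits above the null median, and the test
  over-flags. This is measurable on the bundled benchmark: the naive
  construction produces a false-positive rate near 10% where the
  exchangeable one stays below 3%.
* **Variance balancing.** The L1 distance of an estimated frequency vector
  has sampling scale √(1/n_i + 1/n_ref): the first term is the scaffold's
  own window count (short scaffolds are noisier), the second the noise of
  the median reference itself (which dominates for long scaffolds). Raw
  distances flag short scaffolds; distances scaled by √n_i alone flag long
  ones. Distances are therefore divided by the combined scale, with
  n_ref = (2/π)·(B−1)²/Σ(1/n_j) (harmonic-mean window count of the B−1
  reference members, deflated by the asymptotic efficiency of the median).

The balanced distances are scored as a robust z — (t_q − median)/
(1.4826·MAD) over the other members — with outliers at z > 3. The MAD gets
a relative floor of 5% of the null median: bins of near-identical scaffolds
otherwise collapse the scale to ~0 and flag meaningless deviations. L1 was
kept as the distance (bounded, robust, no zero-count pathologies in 136
dimensions); the exact k, distance, and thresholds are exposed in the
configuration.

With fewer than four reference members the result carries a `low_power`
flag; a bin of one is an error.

## Coverage membership (differential coverage)

Mean per-base depth per scaffold and sample (zeros included) forms a
scaffold × sample matrix. All depths are transformed to log₂(x + 1) —
abundance noise is multiplicative — and a scaffold is tested two ways
against the other members of its bin: a per-sample robust z (median/MAD
across members, MAD floored at 0.125 log₂ units ≈ a 9% depth difference,
below which deviations are biologically meaningless), and the Pearson
correlation of its cross-sample profile with the per-sample median profile
of the members. Outlier iff correlation < 0.9 **or** max |z| > 3: the
correlation catches profile-shape mismatch (a different organism tracking
different samples), the z catches a uniformly shifted abundance. When the
member median profile has zero variance across samples the correlation is
undefined and the test degrades to the z-only rule (`degenerate` flag).

The +1 pseudo-count makes invariance to a per-sample scale factor
(sequencing depth) exact only in the large-depth limit; at realistic depths
(≳10×) verdicts are stable under scale factors of 0.5–4, which is what the
invariance checks assert.

## Misassembly screening (coverage per base)

Per-base depth along one scaffold, from bedGraph (0-based half-open,
uncovered bases = 0). Sliding windows (1,000 bp, step 500 bp) are compared
by *median* depth with the whole-scaffold median — medians on both sides for
robustness to isolated spikes. Windows at ≥ 2.0× are flagged high, ≤ 0.5×
low; adjacent same-direction windows merge; merged regions are refined
per-base with a 101-bp rolling median (the window/step grid alone places
boundaries up to half a window off, which is why refinement exists), and
regions shorter than 1,000 bp are dropped. A scaffold whose median depth is
0 is an error ("uncovered scaffold"), not a finding. When both an all-reads
and a properly-paired-only track are available, regions present only in the
all-reads track are reported separately as discordant/clipped support — the
classic chimera-junction signature.

## ESOM co-binning

A toroidal (borderless) Kohonen map trained online on the canonical 4-mer
frequency vectors of 5-kb scaffold fragments (terminal remainders ≥ 2.5 kb
kept; shorter scaffolds skipped with a warning). Grid size defaults to
~5·√n_fragments nodes at ~1:1.6 aspect (floors at 4×4). Training is the
classic online rule w ← w + α(t)·exp(−d²/2σ²(t))·(x − w) with toroidal grid
distances, α decaying linearly 0.5 → 0.05 and σ from max(rows, cols)/2 → 1.0
over 20 epochs, sample order reshuffled per epoch from one seed; runs are
bit-reproducible per seed. Initialization spans the first two principal
axes of the data (PCA plane) for reproducibility; random-uniform
initialization is retained for property tests. The U-matrix is each node's
mean weight distance to its 8 toroidal neighbors; the tiled 2×2 export is
the standard borderless rendering. BMU assignment is an exact argmin with
lexicographic (row, col) tie-break.

Co-binning: the bin's fragments (excluding the query scaffold's) define a
territory — their BMUs dilated by Chebyshev radius 1 on the torus — and the
query is co-binned when ≥ 80% of its fragments land inside. Features are
composition only; coverage columns are deliberately not appended, keeping
this stage independent of the coverage-based stages.

## Comammox synteny screen

Gene features (GFF3, 1-based, converted to 0-based half-open on read; or
TSV) carry controlled labels (amoA–E, hao, ccmA–H, bfr, copC, copD, orfM),
with a keyword map from free-text product descriptions. Three shipped
patterns: P1 amoC→amoA→amoB; P2 a cytochrome-c maturation block with ≥ 4
distinct ccm labels directly preceding hao (≥ 4 rather than all 8 to
tolerate annotation gaps); P3 bfr×2 → amoD×2 → amoE → copC → copD. Tier
"full" means all three. Matching finds minimal windows where the elements
occur in order — left-to-right, or in exact reverse order (reported with a
`reversed` flag), since "preceded by" in an assembly is orientation-relative
— with ≤ 5 intervening genes and ≤ 10 kb between consecutive matched
features; the search backtracks, so it agrees with brute-force subsequence
enumeration. Orientation is unconstrained by default ("co-oriented"
available). orfM is reported as supporting evidence but is not part of any
required pattern, since independent annotations tend to call it
hypothetical. Join candidates pair a partial gene ending within 1 kb of one
scaffold's right end with a same-label partial gene starting within 1 kb of
another's left end, with strand compatibility reported; partial flags are
stored in scaffold coordinates (5p = truncated on the low-coordinate side).

## Synthetic benchmark

The generator emulates the situation the verification stages exist for:
several co-assembled genomes with distinct composition, multi-sample
abundance structure, and planted artifacts with recorded truth.

* **Genomes** — order-2 Markov chains with genome-specific N(0, 0.5)
  transition biases and GC targets spread over 0.35–0.65; realized GC is
  rejection-adjusted to ±0.02 of target. This yields tetranucleotide
  separation comparable to unrelated bacterial genomes without copying any
  real sequence.
* **Scaffolds** — genomes tile exactly into lognormal lengths (median 40 kb,
  σ_log 0.6, min 5 kb), giving bins of roughly 8–16 scaffolds at the default
  0.5 Mb genome size.
* **Coverage** — per-genome, per-sample lognormal(0, 1) abundances times a
  30× depth scale; per-base depth is negative-binomial (size 10) smoothed
  with a 100-bp moving average to mimic read-length autocorrelation. Depth
  is simulated directly — no reads, no aligner — because the verification
  stages consume depth.
* **Planted truth** — 3 scaffolds moved to wrong bins (sequences unchanged),
  2 chimeras (15 kb + 15 kb segments from two genomes; one carries a 3×
  depth window straddling its breakpoint, emulating a collapsed repeat), and
  the comammox arrangement written onto one bin's two largest scaffolds.

Defaults: 8 genomes × 0.5 Mb, 4 samples. What the generator does *not*
emulate: sequencing error and read-level artifacts, strain mixtures and
shared plasmids, GC-dependent coverage bias, repeat-induced composition
convergence between genomes, and real gene-length/spacing distributions.
Passing recovery tests therefore demonstrates that the statistics detect
what they model — compositionally and abundance-distinct contaminants and
localized depth anomalies — not that they would resolve closely related
strains in real assemblies.

## Validation problem sizes

The recovery benchmark runs ten communities at the default size
(≈ 100 scaffolds each); across them the pipeline's union verdict
(composition ∨ coverage ∨ ESOM) is scored against the planted truth
(sensitivity, false-positive rate, chimera-window recovery). Oracle checks
use 1,000 random length lists (N50), 100 random grids (BMU), all 5-label
feature lists up to length 4 plus 400 random lists of lengths 5–10 (synteny
matching; the full ≤ 10 enumeration is ~12 million lists and adds nothing
over the mixed design), and direct enumeration of the 256 tetranucleotides.

## Numerical and degenerate-input conventions

* Coordinates are 0-based half-open everywhere internally; GFF3 is converted
  on read/write. bedGraph intervals must be sorted and non-overlapping.
* N50 uses the "cumulative ≥ total/2" convention; GC excludes N from both
  numerator and denominator and is NaN (never 0) for all-N input.
* Non-ACGTN IUPAC codes become N on read, counted and logged.
* All randomness (generator, SOM training order) descends from explicit
  integer seeds via numpy `SeedSequence`; identical seeds give byte-identical
  outputs.
* Zero-MAD robust scales fall back to floors (composition: 5% of the null
  median; coverage: 0.125 log₂ units) rather than infinities.
* Ties in BMU search break to the smallest (row, col); ties at exactly
  total/2 in N50 return the length reaching the bound.

## Known limitations

* The composition test assumes bin members are length-diverse but
  composition-homogeneous; genomic islands or rRNA operons on short
  scaffolds can legitimately exceed z = 3 in real bins.
* The coverage test needs ≥ 2 samples and gains power with ≥ 5 members;
  single-sample studies get only composition, ESOM, and misassembly stages.
* ESOM verdicts depend on fragment counts; scaffolds shorter than the
  2.5-kb fragment minimum are invisible to that stage.
* The synteny screen works on labels, not sequence homology; it cannot
  rescue annotation errors, only tolerate gaps (the ≥ 4-of-8 ccm rule).
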