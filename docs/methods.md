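# Methods

This note documents the models, defaults and design choices behind
zygopeak, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Measurement model and normalization

The pipeline starts at the tab-delimited peak export of a capillary
fragment analyzer: per sample × marker, amplicon size (bp), peak height
(RFU) and peak area.  A missing row and a zero-height row are treated
identically as "no product detected"; capillary software simply omits
peaks below its threshold, so absence is represented as NaN rather than 0
throughout.  One peak per (sample, marker) is enforced; multi-peak markers
are rejected rather than resolved by size window, because the supported
assay design has exactly one expected amplicon per primer pair.

Trait normalization is `T = (X/Y)·Z` with X the transgene-marker trait
value, Y the same sample's single-copy reference-gene value, and Z the
normalization group's median reference value.  Two consequences are relied
on downstream and tested as invariants:

* *per-sample scale invariance* — multiplying one sample's peaks by any
  γ > 0 (dilution before electrophoresis) leaves X/Y unchanged, so its
  calls cannot change as long as the group median order statistic is
  unaffected;
* *global scale equivariance* — rescaling every sample multiplies Z and all
  T by the same factor; every classifier used (pit, K-means, CCC) is
  scale-covariant, so calls are invariant.

The normalization group defaults to the population: each segregating
population gets its own Z per trait, matching the per-population analysis
the method is designed for.  Samples without a detected reference product
cannot be normalized and are classed "missing"; they are excluded from Z.
Height and area are normalized independently and never averaged; the
default calling trait is OCS-terminator peak height, the marker/trait
combination that shows the cleanest bimodality in practice (the 35S and
NPTII targets amplify less consistently), and the calling marker/trait are
configurable.

## Presence rule

Transgenic ⇔ all transgene markers and the reference amplified; null ⇔
only the reference amplified; everything else is missing.  Partial
transgene amplification (some but not all targets) is deliberately
"missing", not null: it is more likely a failed reaction than a true null,
and only unambiguous nulls should enter segregation counts.

## Splitting the transgenic class

**Pit (bimodal valley).**  A Gaussian KDE with Silverman's bandwidth
0.9·min(sd, IQR/1.34)·n^(−1/5) is evaluated on a fixed 512-point grid over
[min, max].  Local density maxima with prominence at least 5% of the
density maximum count as modes (the prominence floor keeps shoulder
artefacts on unimodal samples from being read as bimodality; the grid is
virtually padded so tight clusters at the data extremes still register as
modes).  With ≥ 2 modes, the two of highest density define the split and
the pit is the grid point of minimum density strictly between them.
Values exactly at the pit go to the hemizygous class, the larger expected
class (2/4) in a 1:2:1 population, minimising expected misassignment.  At
least 20 finite values are required by default.

**K-means (k = 2).**  In one dimension the optimal two-cluster partition
is contiguous in sorted order, so `kmeans_1d` finds the exact global
optimum by scanning the n − 1 contiguous splits with prefix sums — no
random initialisation, fully reproducible.  A classical Lloyd iteration
with deterministic seeds (10th/90th percentiles) is provided alongside and
checked against the exact optimum in tests.  The cluster with the larger
centroid is labelled homozygous: under log-phase amplification two copies
yield roughly twice the product of one.

**Cluster support (CCC).**  Sarle's Cubic Clustering Criterion compares
the observed R² = 1 − SSW/SST to its expectation under a uniform null.
Specialised to one dimension with q = 2 clusters (u = q):

    E(R²) = 1 − [((n−q)²/n)(1 + 4/n)] / [(n+q)·q²]
    CCC   = ln[(1 − E(R²)) / (1 − R²)] · √(n/2) / (0.001 + E(R²))^1.2

E(R²) → 0.75 as n grows (the R² of splitting a uniform distribution in
half).  The contract is the sign and threshold behaviour: CCC = 0 at the
null expectation, positive above, negative below, and ≥ 2 is taken as
evidence of well-supported clusters.  Numeric agreement with other CCC
implementations is not claimed.  R² = 1 (exact point masses) returns +inf
with a warning.

**Significance.**  The Tukey–Kramer HSD between the two cluster means uses
q = |m₁ − m₂| / √((MSW/2)(1/n₁ + 1/n₂)), df = n₁ + n₂ − 2; for two groups
the studentized range reduces exactly to q = t√2, so the p-value comes
from the two-sided t distribution (verified against
`scipy.stats.studentized_range` in tests).

**Final calls and the unresolved state.**  The final call comes from the
configured method (K-means by default), *gated on split support*: pit
calls require bimodality, K-means calls require CCC ≥ 2.  When the gate
fails — e.g. a uniformly homozygous parent line, whose normalized values
are unimodal — the population is flagged and its transgenic samples are
left `unresolved` instead of being forced into AA/AB classes.  This
deliberately extends the final-call vocabulary beyond
homozygous/hemizygous/null/missing: silently assigning half of a
true-breeding line to a phantom hemizygous cluster would be worse than
admitting the split is unsupported.

## Segregation and family confirmation

Goodness of fit uses both Pearson χ² = Σ(O−E)²/E and the likelihood-ratio
G = 2·ΣO·ln(O/E) (0·ln 0 = 0), df = classes − 1, no continuity correction,
with expected counts proportional to the ratio (so 3:1 ≡ 6:2).  A ratio
"fits" only when **both** tests accept at α — a conservative conjunction,
chosen because no standard combination rule exists for reporting the two
tests together.  No multiple-testing correction is applied across
populations.

Family confirmation from selfed progeny: a homozygous-predicted parent is
confirmed iff its progeny contain no nulls and no detectable hemizygous
class (by counts; when the family's normalized trait values are available,
by the absence of a bimodal split).  A hemizygous-predicted parent is
confirmed iff the progeny counts fit 1:2:1.  Transgenic progeny left
unresolved (a family whose split was unsupported) are counted as the
single class they form, i.e. homozygous; the bimodality check arbitrates.
At least 8 scored progeny are required per family by default.

## The simulator

Amplification is a discrete logistic recursion P₀ = copies·A₀,
P_{i+1} = P_i + e·P_i(1 − P_i/K): geometric growth by (1+e) per cycle far
below the capacity K, smooth saturation near it.  This reproduces the
log-phase discrimination window (at 10 cycles the 1-copy:2-copy product
ratio is 0.5 in the unsaturated limit) and the plateau (by 30 cycles at
the default K the ratio exceeds 0.95), with the ratio monotonically
non-decreasing in cycle number.  The touchdown cycles that precede the
measured program are absorbed into the calibration constants rather than
simulated — they are common to all samples and precede the measured
regime.

Defaults (one place, not a dial): e = 0.9, A₀ = 1, K = 10⁵, 10 cycles;
height_scale = 0.65 RFU and area_scale = 4.2 per product unit, chosen so
noise-free normalized OCS heights land near 800 (homozygous) and 400
(hemizygous) RFU — the scale of real BC₁S₁ data; detection threshold
50 RFU, which 5-cycle products (~32 RFU) do not reach while 10-cycle
hemizygous products (~400 RFU) comfortably do.

Noise has two multiplicative lognormal components, both mean-one:

* a **per-sample factor** (CV 15%) shared by every marker of a sample —
  template amount/quality; this is exactly what reference-gene
  normalization removes, and what makes the dilution-robustness tests
  meaningful;
* **per-peak measurement noise** (CV 8.5%, independent per marker and per
  trait).  T = (X/Y)·Z carries the noise of two peaks, so its
  within-genotype CV is √2 · 8.5% ≈ 12% — the intended study condition for
  the class-recovery and concordance benchmarks, and the regime in which
  the CCC of a clean 1:2:1 population lands in the single digits above 2.
  (Setting the per-peak CV to 12% instead would put ~17% CV on T and push
  CCC toward its null expectation.)

Per-marker amplification failure rates default to 1% (35S, OCS,
reference) and 4% (NPTII, which amplifies less consistently in practice);
together these produce ~5% missing data in a simulated population,
matching the scale seen in real campaigns.  Each simulation call takes one
integer seed; all draws flow from a single `numpy` Generator, so identical
seeds give byte-identical tables.

## Bundled datasets

Two TSVs transcribe published per-population summaries of a nine-population
cotton BC₁S₁ genotyping campaign (segregation counts; K-means cluster sizes,
mean normalized OCS traits and CCC).  One cell of the cluster table
(MD51ne homozygous area, 3018.0) is inconsistent with its column's printed
average and is transcribed as printed.  Family-level progeny counts for the
selfed-progeny confirmation experiment were never published, so
`bc1s2_families_synthetic.tsv` is a synthetic reconstruction consistent
with the published class-level summaries (20 homozygous-predicted families,
19 breeding true, 456 progeny; 21 hemizygous-predicted families all fitting
1:2:1, 488 progeny); it is labelled synthetic in its filename and loader.

## What the simulation benchmarks do and do not show

The test battery (20-seed class recovery ≥ 95%, pit/K-means disagreement
≤ 5%, cluster-mean ratio in [0.45, 0.55], type-I error of the 1:2:1 tests
at nominal 5% over 2000 null replicates at n = 240) demonstrates that the
pipeline recovers known genotypes under the generator's assumptions:
single-locus Mendelian segregation, lognormal multiplicative noise,
independent per-marker failures, log-phase kinetics equal across samples.
Real data can violate these in ways the simulator does not emulate —
primer-specific efficiency drift across plates, correlated failures,
partial digests, off-target peaks, copy numbers above two — so passing
these benchmarks bounds algorithmic, not assay, error.  Problem sizes in
the default suite (populations of 240, 20 seeds, 2000 null replicates)
were chosen to match the study design the tool targets while keeping the
whole suite fast on a laptop.

## Numerical conventions

* Median: middle order statistic (odd n) or mean of the two middle order
  statistics (even n).
* K-means ties: the exhaustive scan takes the first minimal split in
  sorted order; Lloyd assignment ties go to the lower cluster.
* Degenerate inputs raise typed errors rather than returning silently:
  zero-variance values (pit, K-means, HSD), empty groups, all-identical
  values.
* Reports round trait means to one decimal and order populations
  alphabetically, so repeated runs are byte-identical.
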