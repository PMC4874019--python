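# Methods

## The comparative design

The package tests whether molecular evolutionary rates increase with
temperature (and decrease with absolute latitude) using contrasts between
sister species. On a phylogeny whose branch lengths are substitutions per
site, the two members of a species pair have evolved for the same amount
of time since their most recent common ancestor, so the two tip-to-MRCA
path lengths estimate relative substitution rates directly and the tree
never needs to be dated. A PGLS-style regression is not applicable here
because one variable (the rate) is a property of branches while the other
(temperature, latitude) is a property of tips; paired contrasts sidestep
the mismatch.

### Pair sampling

One algorithm run proceeds as follows. All tips start unblocked. A focal
tip is drawn uniformly at random from the unblocked tips. Its candidate
partners are the unblocked tips of its sister clade — the clade subtended
by the sibling(s) of its parent node (after unary-node collapse the parent
is always the smallest branching ancestor; polytomies are allowed).
Candidates must differ from the focal tip by at least the temperature
threshold (default 5.3 °C; 10 °C is a documented robustness alternative).
Among admissible candidates the patristically closest is chosen, ties
broken uniformly at random. On success, every tip descending from the
pair's MRCA is blocked; on failure the focal tip alone is blocked for the
rest of the run. The run ends when no unblocked tip remains.

Two rules keep the contrasts independent in the Maddison sense:

* the search never ascends beyond the sister clade — a focal tip whose
  close relatives all miss the threshold yields no pair rather than a
  phylogenetically distant one;
* a focal tip whose parent clade already contains tips from a previously
  sampled pair's clade yields no pair, because any pair formed there would
  have an MRCA clade nesting around the earlier contrast. Together with
  clade blocking this guarantees that the clades subtended by accepted
  pairs' MRCAs are pairwise disjoint.

Runs are repeated with independent random streams; a run is kept when it
produces at least `min_pairs_per_run` pairs (and a usable contrast table),
until `n_kept_runs` are kept. Identical pairings can recur across runs and
are deliberately not de-duplicated; each run records a content hash of its
pairing so duplication is auditable.

### Contrasts

*Temperature mode*: x = cooler species' branch length, y = warmer species'
branch length. A temperature effect appears as an MA slope above 1.

*Absolute-latitude mode*: pairs are oriented by |latitude|;
x = |lat|_hi − |lat|_lo ≥ 0 and y = (bl_hi − bl_lo)/mean(bl_hi, bl_lo),
the standardized branch-length difference, which is antisymmetric,
scale-free and bounded in [−2, 2]. Orientation fixes the sign of the
regression: under this convention faster evolution at low latitude makes
the expected slope negative, and the test is two-sided against 0. Pairs
exactly tied on the orientation variable, or with two zero branch lengths
(0/0), are dropped with a logged warning rather than jittered.

### Major-axis regression

The MA line minimizes summed squared perpendicular distances — the first
principal axis of the sample covariance matrix — and treats the two
branch lengths symmetrically (axis exchange inverts the slope), which is
the appropriate errors-in-both-variables model when x and y are measured
the same way. With s_xy = 0 the axis is horizontal (slope 0) when
s_xx > s_yy and undefined (vertical) otherwise; the undefined case raises
an explicit error instead of overflowing.

The default confidence interval inverts the exact F-test of a
hypothesized slope β (residual scores y − βx uncorrelated with axis
scores x + βy under H0). In the rotated frame this gives

    limits = tan(θ̂ ± ½·arcsin(2√Q/(λ1 − λ2))),  Q = F₍₁,ₙ₋₂₎ λ1 λ2/(n − 2),

with λ1 ≥ λ2 the covariance eigenvalues. When 2√Q ≥ λ1 − λ2 no direction
can be rejected and the interval is unbounded; angle wrap past ±π/2 makes
one limit infinite. A pairs-percentile bootstrap interval is available by
flag. Coverage of the analytic interval is verified empirically (95% ± 2
points at n = 50 for equal-noise bivariate data on a unit-slope line).

### Replicate aggregation

For each kept run the MA fit is classified against the reference slope
(1 for temperature mode, 0 for latitude mode): `sig_above` if the whole
95% CI lies above it, `sig_below` if below, otherwise not significant.
Across replicates the summary reports the mean and median slope, the
empirical 2.5–97.5 percentile band of the slopes (linear-interpolation
percentile estimator), the three significance counts, and the range of
pair counts. When both modes are requested they run on the *same* kept
pair sets, so their run ids and pairing hashes correspond exactly.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with one tunable causal knob.

| stage | model | defaults |
|---|---|---|
| tree | Yule crown process, grown from 2 lineages to `n_tips`, one extra Exp(nλ) wait at the end | n_tips = 400, λ = 1 /time |
| temperature | Brownian motion along the chronogram | σ = 4.5 °C/√time, root 18 °C |
| latitude | \|lat\| = clamp((T_eq − T)/k + ε, 0, 90), random hemisphere | T_eq = 27 °C, k = 0.6 °C/deg, sd(ε) = 3° |
| branch lengths | r = r₀·exp(β·(T̄ − T_ref)), T̄ = mean of edge endpoint temperatures; length = r·duration × mean-1 lognormal noise | r₀ = 0.05 subs/site/time, T_ref = 18 °C, β = 0, σ_b = 0.1 |

Crown age has expectation (1/λ)Σ_{k=2..n} 1/k, so a 400-tip tree is ≈ 5.6
time units deep: tip temperatures then span roughly −15 to 50 °C
(SD ≈ 10 °C) and root-to-tip molecular depths are ≈ 0.3 substitutions per
site, comparable to a large squamate ML phylogeny. β = ln(2)/10 makes the
rate double per 10 °C — the canonical MTE-like effect size; β = 0 with
noise disabled is an exact clock, used as an exact end-to-end sanity path
(every pair's two branch lengths are equal, every MA fit collapses to
slope 1).

Two defaults were fixed by pilot calibration of the null pipeline rather
than taken from literature:

* **σ (temperature BM) = 4.5** places the typical kept-run pair count
  (~41 at the 5.3 °C threshold on 400 tips) comfortably above the 30-pair
  keep bar, mirroring the margin real analyses have between their typical
  and minimum pair counts; smaller values leave the typical count sitting
  on the bar and make some generated datasets unable to yield any kept run.
* **σ_b (lognormal branch noise) = 0.1** (≈10% per-branch rate scatter)
  keeps the dataset-level wobble of the null median slope within ±0.05 of
  1 while leaving per-replicate CIs wide enough that the null excess-call
  fraction stays near the nominal rate. Larger scatter inflates both.

What the generator does *not* emulate: phylogenetic error (the tree is
known), saturation and node-density artifacts (no underestimation of long
branches), latitude as anything but a noisy mirror of temperature (no
independent latitudinal effect, no range shifts or dispersal history),
life-history covariates of rate, and non-Brownian niche evolution. A
passing null/effect calibration therefore shows the *pipeline* is
unbiased and sensitive under these idealized conditions, not that real
data are free of those confounds.

## Numerical and design notes

* Replicates on one dataset share that dataset's single noise
  realization, so the replicate spread understates full sampling
  uncertainty — the median slope of 200 replicates can sit a few percent
  away from 1 under the null for an unlucky tree. This pseudo-replication
  is inherent to re-running the sampler on fixed data and is why the null
  calibration is assessed with both a median-slope band and a
  significance-fraction cap.
* Determinism: every analysis seeds a `SeedSequence`; attempt *i* of the
  sampler always consumes the *i*-th spawned stream, so results are
  byte-identical across reruns and independent of how many runs are
  rejected.
* Tie-breaking among equally close partners is uniform via the run's
  stream; distance ties are exact float equality, which on simulated trees
  occurs only for exactly repeated branch lengths.
* Zero-length terminal branches are retained (they occur legitimately in
  ML trees); a 0/0 standardized difference is dropped, not imputed.
* Name matching between tree and traits trims whitespace and treats space
  and underscore as the same separator; no synonymy resolution is
  attempted, and every non-match is reported.
* The scale used by the calibration tests and the acceptance script —
  400 tips, 200 kept replicates, ≥30 pairs per run — is the package's
  scaled-down analogue of a full analysis (thousands of tips, 1,000 kept
  runs of ≥50 pairs), chosen to keep the whole verification suite fast
  while preserving the pair-count-to-bar margin of the full design.
* Known limitation: when an analysis requests a run yield the input
  cannot deliver (e.g. `min_pairs_per_run` above the achievable pair
  count), the sampler stops at its attempt cap and reports the observed
  yield rather than looping forever.
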