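# Methods

## The contact-cut profile

A domain boundary at position p separates a contact (i, j) exactly when
i < p ≤ j. The predictor therefore scores each position by the number of
contacts a cut there would disrupt, smoothed for robustness: for every
contact (i, j), one Gaussian kernel of standard deviation σ is centred on
each residue r strictly between the pair (i < r < j), and the density

    profile(p) = Σ_contacts Σ_{i<r<j} φ((p − r)/σ) / σ,   p = 1..L

is evaluated at integer residue positions only and normalized to unit sum
(a discrete PDF over the chain). Contacts at sequence separation ≤ 1 have
no strictly interior residue and contribute nothing; the standard input
filter (separation ≥ 5, top 1000 by score) removes them anyway. Contact
scores do not weight the kernels: the quantity modelled is a count of
disrupted contacts, and rank already selected the credible ones. The
implementation is a counts-vector/Gaussian-matrix product; the test suite
pins it to a naive triple-loop reference at 1e−9.

Strictly-interior kernel placement, integer-grid evaluation, unit-sum
normalization and unweighted kernels are all deliberate choices where the
underlying description is loose; each is centralised here so alternatives
(e.g. score-weighted kernels) can be judged against them.

## Cut-point detection

The first derivative of the profile at p is estimated as the ordinary
least-squares slope of the profile values over positions p − 5 .. p + 5
(windows truncate at the chain ends; a central-difference estimator is
available via `estimator="central"` for sensitivity checks). Scanning left
to right, a cut point is reported where the slope changes sign from
negative to nonnegative; a zero-slope plateau reports its central position
(lower index on ties), and slopes within 1e−9 of the largest magnitude
times machine-level noise are snapped to zero so exactly symmetric minima
resolve deterministically. Positions 1 and L are never cut points; a
monotone or flat profile yields a single-domain call, as does an empty
filtered contact list. Cut points c1 < c2 < … partition the chain into
contiguous domains [1, c1−1], [c1, c2−1], …, labelled ordinally — the
method cannot propose discontinuous domains. No minimum domain length is
enforced by default (`min_domain=0`).

## Bandwidth schemes

σ controls the smoothing/resolution trade-off: undersmoothed profiles
overpredict boundaries, oversmoothed ones collapse to single domains.
Schemes: `fixed:c` (σ = c residues), `linear:n` (σ = L/n; default L/15,
the best-performing choice on real benchmarks), `log:k` (σ = log_k L),
`power:x` (σ = L^(1/x)) and `amise`. The AMISE scheme treats the kernel
centres (with multiplicity) as the sample of a univariate KDE and solves
the stationarity condition of the asymptotic mean integrated squared error,

    d/dh AMISE(h) = −R(K)/(n h²) + h³ σ_K⁴ R(f″) = 0,

with Gaussian-kernel constants R(K) = 1/(2√π), σ_K = 1 and the
normal-reference plug-in R(f″) = 3/(8√π s⁵), s being the weighted standard
deviation of the centre positions. The root is found by the secant method
started from h = 1 and h = L (tolerance 1e−6, ≤ 100 iterations); the
stationarity condition also has a closed form, which the tests use to check
the solver. All of these constants are implementation choices.

## The naive length-based predictor

Training records are (chain length L, domain count N, boundary positions),
with N ≥ 4 pooled into a "4+" class. The model holds class priors P(N)
(empirical frequencies), per-class Gaussian KDEs f_N(L) over chain lengths
(Silverman's rule; a unit-width kernel for degenerate classes), and
per-class boundary-position profiles over sequences rescaled to 1000 cells:
boundary p in a chain of length L accumulates into cell
floor(1000·(p−1)/L), and the histogram is then smoothed with a Gaussian
kernel whose width is Silverman's rule over the cell sample (floored at one
cell) and normalized — raw cell counts are far too spiky for derivative-
based peak detection. The single-domain class contributes no boundaries;
its profile is identically zero rather than unit-sum.

Prediction for a query length L: P(N|L) ∝ f_N(L)·P(N) (falling back to the
priors if all densities underflow), the 1000-cell profiles are rescaled to
L residues by exact fractional interval overlap (mass-conserving; for
L = 100 residue 1 is the sum of cells 0–9), and the posterior mixture
Σ_N P(N|L)·b_N(r) is cut at its peaks using the same windowed-slope
detector (sign change + to ≤ 0). The mixture reading is the default; a
`map_n` flag restricts to the maximum-a-posteriori class instead. Note the
mixture almost always contains some boundary mass, so truly single-domain
calls arise only when the single-domain class holds all posterior weight —
a known bias of this reading, kept because it uses the full posterior.

## The homology endpoint predictor

Alignment endpoint tables (columns target_id, ali_start, ali_end, bitscore)
come from an upstream domain-library profile-HMM search, which is outside
this package. Start and end positions each add one count at their residue;
the profile is smoothed by repeated moving averaging (window 5 either side,
10 iterations — both configurable, the schedule being an implementation
choice) and candidate peaks are accepted greedily in decreasing height
order (ties toward the lower position) subject to a minimum distance of 60
residues from both termini and from every accepted boundary. Chains of
≤ 120 residues therefore always return single-domain.

## Structure-derived contacts

For interior residue r with flanking Cαs C1 and C3, B is the orthogonal
projection of Cα(r) onto the C1–C3 line and the pseudo-Cβ is
Cα(r) + 2·(Cα(r) − B)/‖Cα(r) − B‖ — exactly 2 Å from the Cα, pointing away
from the local backbone axis, approximating the side-chain direction
without needing any atom beyond the backbone trace. Terminal residues and
degenerate geometries (collinear triples, coincident flanking Cαs,
threshold 1e−6 Å) fall back to the Cα itself so every residue stays
eligible. Contacts are all pairs with pseudo-Cβ distance ≤ 8 Å, ranked by
negated distance (shortest first) — any monotone score gives the same
top-N set. PDB input is read through gemmi, Cα atoms only, renumbered
sequentially with gaps logged.

## NDO assessment

Reference and prediction each label residues by domain (per-domain labels:
discontinuous segments of one domain share its label, ordered by first
residue) or leave them unlabelled (linkers). The overlap matrix counts
residues carrying each (reference, predicted) label pair over residues
labelled on both sides; Gale–Shapley stable matching (reference side
proposing, preferences by descending overlap, ties toward the lower label,
unequal sides padded with zero-overlap dummies) realigns the arbitrary
predicted labels. With l = residues labelled on both sides and M = residues
whose matched labels agree, the score is max(0, 100·(2M − l)/l)
(`balanced`) or 100·M/l (`fraction`). Both are offered because the exact
normalization in circulation varies; `balanced` is the default since the
truncation at zero is only meaningful when mismatches penalize, but the
variant is always an explicit parameter downstream. Residues labelled in
the reference but falling in a predicted linker are excluded from l (the
"ignored" reading); that choice is localised in `ndo_score` for sensitivity
testing. Proposer choice does not affect which matching is produced here
because tie-breaking is total and deterministic.

## Synthetic data

The contact simulator generates the statistical structure the predictor
exploits, not physical 3D geometry. For a chain with given domain lengths,
every pair (i, j) with j − i ≥ 5 enters independently: same-domain pairs
with probability p_intra·exp(−(j−i)/λ), cross-domain pairs with probability
p_inter; uniformly random extra pairs are then added so they make up
noise_frac of the final list. True contacts draw scores from Beta(5, 2),
noise from Beta(2, 5) — overlapping, so rank filtering is informative but
imperfect. Defaults: p_intra = 0.08, p_inter = 0.002, λ = 100,
noise_frac = 0.2. λ is set at the scale of a domain so intra-domain
contacts span whole domains, as compactness in 3D implies; p_inter yields
interface-scale cross-contact counts for typical two-domain chains. Because
cross-domain pairs are uniform, their boundary-spanning count grows with
the product of the flanking region sizes — unlike real interfaces, which
are localized — so long multidomain chains are *harder* than their real
counterparts. What passing tests on these fixtures shows is that the
pipeline recovers boundaries when the intra/inter contrast premise holds;
they say nothing about contact-prediction quality on real sequences.

The benchmark protein sampler draws 2, 3 or 4 domains with weights
0.70/0.20/0.10 (two-domain chains dominate real domain databases) and
domain sizes uniform on 80–180 residues (median ≈ 130, a typical globular
domain). Other generators: an ideal α-helix Cα trace (radius 2.3 Å, rise
1.5 Å, 100°/residue — consecutive Cα distance ≈ 3.8 Å) for geometry tests;
length-model training tables (class priors 0.5/0.3/0.15/0.05, lognormal
lengths with median 130·N and log-sd 0.25, boundaries at uniform spacing
with Gaussian jitter of 6% of L); and alignment endpoints jittered around
true domain termini. Every generator is a pure function of its arguments
and seed.

## Benchmark conditions and frozen bounds

The boundary-recovery regression runs 200 simulated proteins from the
benchmark sampler at seed 42, predicts with bandwidth L/15, and counts true
boundaries matched by a predicted cut within ±10 residues. The run is
bit-reproducible; the frozen regression bound is 69% recovery (measured
once at these conditions and then fixed). Recovery is near-perfect for
two-domain chains (~90% of boundaries) and degrades for three- and
four-domain chains, where σ = L/15 oversmooths — the same
high-bandwidth underprediction the bandwidth sweep exhibits. The
monotonicity check (40 fixtures, seed 7, 25% single-domain) verifies that
per-fixture predicted domain counts never increase across fixed bandwidths
{1, 5, 10, 20, 30, 40, 50}. These sizes keep the full suite in the tens of
seconds while leaving the trends far from sampling noise.

## Numerical notes and limitations

- Profiles are exact Gaussian sums (no kernel truncation); cost is O(L²)
  per profile, negligible for chains up to a few thousand residues.
- Degenerate inputs: empty filtered contact lists, all-adjacent contacts,
  flat profiles and zero-spread AMISE samples all have defined behaviour
  (single-domain calls or explicit errors) rather than silent NaNs.
- The KDE predictor cannot produce discontinuous domains; on references
  with discontinuous domains its ceiling NDO is below 100 by construction.
- The exhaustive stable-matching verification enumerates all 2×2 matrices
  with entries ≤ 5 and all 3×3 with entries ≤ 3, plus seeded random 3×3/4×4
  samples with larger entries; full 3×3 enumeration at entries ≤ 5 (10.1M
  matrices) adds no new tie/size structure and is omitted for runtime.
- The naive predictor's mixture reading overpredicts boundaries whenever
  the posterior puts any weight off the single-domain class (see above).
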