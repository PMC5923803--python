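# Methods

## Model and assumptions

The receptor model treats each sample as a non-negative mixture of a small
number of fixed source fingerprints: `D = C·R` with `D` the m × r
compounds × samples concentration matrix, `C ≥ 0` the m × n profile matrix
and `R ≥ 0` the n × r strength matrix. The assumptions this carries:

- source profiles are constant across samples (no weathering/degradation
  differentiating sites);
- every compound is fully observed and non-negative; no detection-limit
  censoring or missing-value imputation is attempted — ingestion rejects
  such cells instead;
- measurement error is multiplicative and unbiased, with a per-cell
  coefficient of variation (CV).

## Fitting procedure

1. **Average scaling.** Each compound row is divided by its mean, stored
   for exact back-scaling. This equalizes the leverage of abundant and
   trace species in the least-squares objective; without it the fit is
   dominated by the few highest-concentration compounds.
2. **Initial extraction.** Truncated SVD of the scaled matrix — the best
   rank-n approximation. No mean-centering is applied: the model is a
   non-centered bilinear form, and centering would destroy the
   non-negativity of the target factorization. The SVD sign
   indeterminacy is fixed by making each loading column's
   largest-magnitude entry positive.
3. **Non-negative rotation.** Alternating non-negativity-constrained
   least squares (NNLS per row of `C`, per column of `R`) in scaled
   space. Both matrices are constrained: scores are physical source
   strengths, so negative entries in either factor are meaningless. After
   every sweep the termination statistic — the sum of squares of the
   negative entries of the back-scaled `C` — is evaluated; the solution
   is flagged `converged` exactly when it is below the tolerance
   (default 1e-4). Sweeps continue until the residual is stationary
   (relative improvement below 1e-10) or `max_iter` (default 500) is
   reached. Non-convergence yields a flagged result, not an exception,
   so factor-count scans never abort.
4. **Minimum-volume refinement** (default, `refine="minvol"`). When both
   factors are strictly positive, the non-negative factorization is not
   unique: any `(C·M, M⁻¹·R)` with both products non-negative fits
   equally well, and the alternating updates stop at an arbitrary —
   typically extremal, data-cone-hugging — point of that set. Following
   the minimum-volume tradition in receptor modeling (smallest enclosing
   simplex / edge-finding), we pick the feasible rotation `M` minimizing
   the log-volume `log det(Ĉᵀ Ĉ)` of the column-normalized profiles,
   solved with SLSQP over the n² entries of `M` starting at the
   identity. The refined rotation is accepted only if it is feasible
   (entries above −1e-6 of the matrix scale) and preserves the
   reconstruction; otherwise the alternating-update solution is kept.
   This choice is identifiable precisely when some samples are strongly
   dominated by single sources — the situation coastal sediment surveys
   with hotspot sites exhibit, and the regime the synthetic generator
   emulates. On synthetic truths it reduces overall-contribution errors
   from several percentage points to well under one.
5. **Cleanup and ordering.** Residual negative entries (each tiny by the
   termination criterion) are clamped to zero with the clamped mass
   recorded; factors are ordered by reconstructed mass, descending.

**Contributions.** The percent contribution of factor k to sample j is
`100 · Σ_i C_ik R_kj / Σ_k' Σ_i C_ik' R_k'j`; columns sum to 100. The
overall figure is the unweighted mean of per-sample percentages by
default. The phrase "average of factor scores" admits a second reading —
each factor's share of the summed totals, which up-weights
high-concentration samples — so that concentration-weighted variant is
computed as well and always reported alongside
(`ContributionTable.overall_weighted`, the `weighted_pct` column).

## Factor-count diagnostics

All three statistics are computed from the *unrotated* model (scaling →
truncated SVD → back-scaling), so they measure the explanatory power of
each added dimension before non-negativity spends any freedom:

- **COD** per compound: `1 − SSE_i/SST_i` against the compound's own mean,
  on back-scaled reconstructions in original units. Negative values
  (fits worse than the row-mean null) are reported as computed.
- **Cumulative percent variance**: share of the total sum of squares of
  the scaled matrix carried by the top n squared singular values.
- **Exner function**: `sqrt(Σ(S−Ŝ)²/Σ(S−mean(S))²)` on the scaled
  matrices; 0 is a perfect fit, 1 the grand-mean null, < 0.1 is the
  conventional threshold for an excellent reconstruction.

The recommendation rule returns every factor count with Exner < 0.1 and
cumulative variance > 95%, annotates which compounds remain below a COD
floor (default 0.8) at each count, and flags the smallest qualifying
count as the parsimonious choice.

## Source identification

Cosine similarity between modeled and library profiles, which for
non-negative vectors lies in [0, 1] and is scale-invariant (so it is
indifferent to profile normalization). Each factor flags its best-matching
source plus any source within `tie_delta` (default 0.02) of the maximum:
a factor that is really a blend of two sources then carries both flags.
Libraries are aligned to the data's compound axis by case-insensitive
label match; up to 2 missing compounds are tolerated with a warning, more
is an error.

## Monte Carlo uncertainty

Each replicate perturbs every cell by
`D_ij = A_ij + cv_ij·A_ij·[2·erf⁻¹(2U_ij − 1)]`, `U_ij ~ Uniform(0,1)`.
Two conventions are supported because the bracket `2·erf⁻¹(2U−1)` is a
zero-mean normal deviate with standard deviation √2, not 1:
`convention="printed"` (default) keeps the factor 2 as written above;
`"unit_sd"` uses `√2·erf⁻¹(2U−1)`, a standard normal. The CV may be a
scalar, per-compound vector or full matrix; it is a required, logged
input in CLI mode (default 0.1 in the library API). Negative perturbed
cells are redrawn up to 100 times, then clamped to zero with a logged
count — preserving non-negativity without biasing low-CV runs.

Each replicate gets its own child stream of the master seed
(`SeedSequence.spawn`), so enlarging `n_runs` extends the ensemble without
reshuffling earlier replicates. Every replicate is refit from scratch,
permutation-aligned to the base solution by maximizing summed profile
cosine similarity (Hungarian assignment), and only converged replicates
enter the per-entry mean/SD summaries (their count is reported;
> 50% failures abort with diagnostics). At `cv = 0` all replicates are
bit-identical to the base fit and the SDs are reported as exact zeros
rather than the ~1-ulp artifacts of averaging n identical floats.

## Synthetic data generator

`generate_truth` draws column-stochastic profiles and strictly positive
scores; `synthesize_dataset` forms `P·S` and applies the same noise law
as the Monte Carlo module. Design choices:

- **Separation knob.** The compound axis is partitioned into n blocks;
  each source gets a Dirichlet profile on its own block (pairwise
  orthogonal), then every column is convexly mixed with one shared base
  profile: `sep·own + (1−sep)·shared`. One scalar thus sweeps profiles
  continuously from orthogonal (`sep=1`) to collinear (`sep→0`), the
  regime where similar fingerprints inflate contribution uncertainty.
  Default 0.8: distinct but realistically overlapping combustion
  profiles.
- **Score law.** i.i.d. log-normal with shape σ = 1.5. This makes the
  dominant source's per-sample share span roughly 40–96% across 32
  sites — the site-to-site heterogeneity coastal sediment surveys
  report, with some stations nearly single-source. An optional hotspot
  multiplier scales one sample up to mimic a heavily impacted harbor
  station, stress-testing what average scaling exists to counter.
- **Example profile library.** `synthetic_profile_library()` ships six
  source-shaped columns (coal-type sources weighted toward heavy,
  engine-type toward light PAHs) over the 15 default compounds. These
  are deterministic synthetic stand-ins for exercising the matching and
  reporting machinery — they are not literature emission profiles.

What the generator does *not* emulate: detection-limit censoring,
compound-specific analytical error, profile weathering between source and
sediment, spatial correlation among sites, or correlated source
strengths. Passing recovery tests therefore demonstrate correctness of
the algorithmics under the model's own assumptions, not robustness of the
method on field data that violates them.

## Numerical choices and degenerate inputs

- Convergence tolerance 1e-4 on the negative-entry statistic; with NNLS
  updates the statistic is typically exactly 0 at termination.
- ANLS stationarity threshold: relative residual improvement 1e-10;
  refinement acceptance: feasibility within 1e-6 of matrix scale,
  reconstruction preserved to 1e-6 relative.
- Ties in factor ordering are broken stably; SVD sign fixed as above.
- Zero compound rows, zero-sum profile columns, zero-norm vectors,
  constant rows (COD), grand-mean-constant matrices (Exner) and samples
  with zero reconstructed total are hard errors naming the offender.
- All numeric CSV output is written in full double precision, so
  identical runs produce byte-identical files.

## Problem sizes

The test suite and the acceptance script run at the study scale —
15 compounds × 32 samples, 2–3 factors — with ensembles of 5–200
replicates for ensemble-level checks and 1000 replicates where the noise
law's zero-mean property itself is under test; a single fit takes tens of
milliseconds, a 200-replicate ensemble well under a minute.

## Known limitations

- The minimum-volume identification assumes some near-pure samples; with
  thoroughly mixed sites (all samples similar blends) the rotational
  ambiguity is real and contributions carry irreducible uncertainty that
  no point estimator resolves — the Monte Carlo SDs then widen, which is
  the honest signal.
- Factor counts are diagnosed, not automated: the recommendation rule
  reports qualifying counts and leaves the choice to the analyst.
- No uncertainty-weighted least squares (PMF-style), rotational-ambiguity
  exploration (FPEAK), bootstrap-over-samples, or diagnostic-ratio source
  identification.
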