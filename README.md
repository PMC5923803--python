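# fannc — sediment PAH source apportionment by non-negative factor analysis

`fannc` apportions the polycyclic aromatic hydrocarbon (PAH) burden of
surface sediments among emission sources — traffic, diesel engines,
residential coal combustion and the like — from nothing but a table of
measured concentrations. It is a receptor model: no emission inventories
are needed, only the observation that each source leaves a characteristic
chemical fingerprint in the mixture that settles at each sampling site.

It is written for environmental chemists and chemometricians working with
compounds × samples concentration tables (e.g. 15 priority PAHs over a few
dozen sediment stations, in ng/g dry weight).

## The model

The concentration matrix is factorized as a non-negative bilinear form

```
D(m×r) = C(m×n) · R(n×r)
```

where `D` holds `m` compounds over `r` samples, the columns of `C` are the
*source profiles* (relative chemical composition of each of `n` sources)
and the rows of `R` are the *source strengths* at every sample. The fit
proceeds by

1. **average scaling** — each compound row of `D` is divided by its mean so
   abundant species do not dominate the least-squares objective;
2. **initial extraction** — truncated singular value decomposition of the
   scaled matrix;
3. **rotation to non-negativity** — alternating non-negativity-constrained
   least-squares sweeps over `C` and `R`, iterated until the termination
   statistic, the sum of squares of negative entries of the *back-scaled*
   `C`, falls below 1e-4;
4. **minimum-volume refinement** — among the equally-well-fitting
   non-negative factorizations, the rotation with the smallest profile
   simplex is selected (identifiable when some sites are dominated by a
   single source);
5. **back-scaling** — profiles are returned to concentration units.

Around the core factorization the package provides:

- **factor-count diagnostics**: per-compound coefficient of determination
  (COD), cumulative percent variance, and the Exner function, scanned over
  candidate factor counts (Exner < 0.1 and cumulative variance > 95% mark
  an excellent reconstruction);
- **source identification** by cosine similarity,
  `cos(A,B) = A·B/(‖A‖‖B‖) ∈ [0, 1]`, between modeled profiles and a
  literature profile library, with best-match (and near-tie) flags;
- **Monte Carlo uncertainty analysis**: every cell is perturbed as
  `D_ij = A_ij + cv·A_ij·[2·erf⁻¹(2U_ij − 1)]` with `U_ij ~ Uniform(0,1)`,
  the full fit is repeated (1000 times by default), replicates are
  permutation-aligned to the base solution, and the standard deviations of
  profiles and percent contributions become the reported error bars;
- a **synthetic-data generator** with known ground truth (column-stochastic
  profiles, log-normal scores, the same multiplicative noise law) so the
  entire pipeline is testable as a parameter-recovery problem.

## Worked example

Generate a synthetic 15-compound × 32-sample dataset from three sources
with 5% multiplicative noise, scan the factor count, then quantify source
contributions with a 200-replicate uncertainty ensemble:

```sh
fannc simulate --cv 0.05 --seed 7 --out sim/
fannc diagnose --input sim/concentrations.csv --factors 1:5 --out diag.csv
fannc mc --input sim/concentrations.csv --factors 3 --mc-runs 200 --cv 0.1 \
     --seed 7 --out mc/
```

The diagnostic scan prints which factor counts qualify:

```
n=3: Exner 0.0402 < 0.1, cumulative variance 99.88% > 95.0%; all compound CODs ≥ 0.8
n=4: Exner 0.0321 < 0.1, cumulative variance 99.93% > 95.0%; all compound CODs ≥ 0.8
n=5: Exner 0.0268 < 0.1, cumulative variance 99.95% > 95.0%; all compound CODs ≥ 0.8
parsimonious choice: n=3
```

i.e. three factors are the smallest count that reconstructs the data
excellently — matching the three sources the data were built from. The
uncertainty run then prints mean ± SD percent contributions over the
converged replicates:

```
factor 1: 28.0 ± 0.9 %
factor 2: 32.6 ± 0.8 %
factor 3: 39.4 ± 1.0 %
200/200 replicates converged; wrote mc/
```

The generating truth for this seed put the three sources at 26.8%, 33.3%
and 39.9% of the total PAH burden (`sim/manifest.txt`), so each recovered
contribution lands within about one standard deviation of its true share.
`mc/` also contains the per-sample contribution tables, normalized
profiles ± SD, and a run-metadata file with the seed and convergence
status. With real data you would add
`fannc match --profiles library.csv ...` to name the factors against
literature source fingerprints.

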