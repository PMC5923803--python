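"""Factor analysis with non-negative constraints (FA-NNC).

The receptor model factorizes the compounds × samples concentration
matrix as ``D ≈ C·R`` with ``C`` (m × n) holding source profiles and
``R`` (n × r) holding source strengths per sample.  The fit runs in four
stages, in the order they appear below:

1. *Average scaling*: each compound row of ``D`` is divided by its mean so
   high-concentration species do not dominate the least-squares fit.
2. *Initial extraction*: the best rank-n approximation of the scaled
   matrix from a truncated singular value decomposition.
3. *Non-negative rotation*: alternating non-negativity-constrained
   least-squares sweeps over ``C`` and ``R`` in scaled space.  After every
   sweep the termination statistic — the sum of squares of the negative
   entries of the *back-scaled* ``C`` — is evaluated; the fit counts as
   converged once it is below the tolerance (default 1e-4).
4. *Back-scaling and cleanup*: profile rows are multiplied back by the
   stored row means, any residual negative entries (each tiny by the
   termination criterion) are clamped to zero and the clamped mass is
   recorded.

Factors are ordered by explained reconstruction mass, descending, so the
output order is reproducible despite the inherent permutation
indeterminacy of bilinear models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, nnls

from .io import ConcentrationMatrix

#: entries of the cleaned score matrix may not dip below this
SCORE_NEG_TOL = -1e-8


@dataclass(frozen=True)
class ScaledMatrix:
    """Row-mean-scaled concentration matrix plus the means to undo it."""

    values: np.ndarray          # (m, r), each row has mean 1
    row_means: np.ndarray       # (m,), strictly positive
    compound_labels: tuple[str, ...] = ()
    sample_labels: tuple[str, ...] = ()
    units: str = ""


@dataclass(frozen=True)
class FactorSolution:
    """A converged (or flagged) FA-NNC factorization.

    ``loadings`` is the back-scaled profile matrix ``C`` in concentration
    units; ``scores`` the unitless strength matrix ``R``.  ``neg_ss`` is
    the terminating value of the convergence statistic and ``converged``
    is exactly ``neg_ss < tol``.  ``clamped_mass`` records how much
    (absolute) negative mass the final cleanup removed.
    """

    loadings: np.ndarray        # (m, n), concentration units
    scores: np.ndarray          # (n, r)
    n_factors: int
    neg_ss: float
    iterations: int
    converged: bool
    relative_residual: float
    clamped_mass: float = 0.0
    compound_labels: tuple[str, ...] = ()
    sample_labels: tuple[str, ...] = ()


@dataclass(frozen=True)
class ContributionTable:
    """Percent source contributions per sample and overall.

    ``per_sample`` columns sum to 100.  ``overall`` is the unweighted mean
    of per-sample percentages; ``overall_weighted`` is the share of the
    summed reconstructed totals.  ``overall_sd`` is filled by the Monte
    Carlo ensemble when one is run.
    """

    per_sample: np.ndarray      # (n, r), percent
    overall: np.ndarray         # (n,), percent
    overall_weighted: np.ndarray
    overall_sd: np.ndarray | None = None
    factor_labels: tuple[str, ...] = ()
    sample_labels: tuple[str, ...] = ()


def average_scale(cm: ConcentrationMatrix) -> ScaledMatrix:
    """Divide each compound row by its arithmetic mean.

    The stored ``row_means`` make back-scaling exact: multiplying row *i*
    of the scaled values by ``row_means[i]`` reproduces the original row.
    """
    means = cm.values.mean(axis=1)
    bad = np.where(means <= 0)[0]
    if bad.size:
        raise ValueError(f"zero row mean for compound {cm.compound_labels[bad[0]]!r}")
    return ScaledMatrix(
        values=cm.values / means[:, None],
        row_means=means,
        compound_labels=cm.compound_labels,
        sample_labels=cm.sample_labels,
        units=cm.units,
    )


def unrotated_factor_model(sm: ScaledMatrix, n: int):
    """Best rank-``n`` least-squares factorization of the scaled matrix.

    Returns ``(C0, R0, variance_fractions)`` where ``C0·R0`` is the
    truncated-SVD reconstruction and ``variance_fractions[k]`` is the
    fraction of the total sum of squares carried by component ``k``
    (non-increasing).  The decomposition is not centered: the model is a
    non-centered bilinear form, and centering would break the
    non-negativity of the target factorization.

    Sign convention: each column of ``C0`` has its largest-magnitude entry
    positive, for reproducibility.
    """
    m, r = sm.values.shape
    if not 1 <= n <= min(m, r):
        raise ValueError(f"n_factors={n} outside [1, {min(m, r)}]")
    U, s, Vt = np.linalg.svd(sm.values, full_matrices=False)
    signs = np.sign(U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs
    Vt = Vt * signs[:, None]
    C0 = U[:, :n] * s[:n]
    R0 = Vt[:n, :]
    total = float(np.sum(s**2))
    variance_fractions = (s[:n] ** 2) / total if total > 0 else np.zeros(n)
    return C0, R0, variance_fractions


def _nnls_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A x_j - b_j|| s.t. x_j ≥ 0 for every column b_j of B."""
    X = np.empty((A.shape[1], B.shape[1]))
    for j in range(B.shape[1]):
        X[:, j], _ = nnls(A, B[:, j])
    return X


def _minimum_volume_refine(C: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve rotational ambiguity by shrinking the profile cone.

    Alternating updates stop at *a* non-negative factorization, but when
    both factors are strictly positive a continuum of equally good
    factorizations ``(C·M, M⁻¹·R)`` exists.  Following the
    minimum-volume tradition in receptor modeling (edge-finding /
    smallest enclosing simplex), this picks the feasible rotation ``M``
    minimizing the log-volume of the column-normalized profile simplex,
    subject to both rotated matrices staying non-negative.  The choice
    is identifiable when some samples are strongly dominated by single
    sources — the situation field datasets with hotspot sites exhibit.

    Operates in scaled space; reconstruction ``C·R`` is unchanged up to
    solver tolerance.
    """
    n = C.shape[1]
    if n < 2:
        return C, R
    I = np.eye(n)

    def unpack(x: np.ndarray) -> np.ndarray:
        return I + x.reshape(n, n)

    def objective(x: np.ndarray) -> float:
        CM = C @ unpack(x)
        sums = CM.sum(axis=0)
        if np.any(sums <= 0):
            return 1e6
        Ch = CM / sums
        return float(np.linalg.slogdet(Ch.T @ Ch + 1e-8 * I)[1])

    def profile_nonneg(x: np.ndarray) -> np.ndarray:
        return (C @ unpack(x)).ravel()

    def score_nonneg(x: np.ndarray) -> np.ndarray:
        try:
            return np.linalg.solve(unpack(x), R).ravel()
        except np.linalg.LinAlgError:
            return -np.ones(R.size)

    res = minimize(
        objective, np.zeros(n * n), method="SLSQP",
        constraints=[{"type": "ineq", "fun": profile_nonneg},
                     {"type": "ineq", "fun": score_nonneg}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    M = unpack(res.x)
    try:
        R_new = np.linalg.solve(M, R)
    except np.linalg.LinAlgError:
        return C, R
    C_new = C @ M
    # accept only a feasible, fit-preserving rotation; on solver failure
    # keep the alternating-update solution
    feas = max(C.max(), 1.0) * 1e-6
    if C_new.min() < -feas or R_new.min() < -feas * max(R.max(), 1.0):
        return C, R
    old_resid = np.linalg.norm(C @ R - C_new @ R_new)
    if old_resid > 1e-6 * np.linalg.norm(C @ R):
        return C, R
    return C_new, R_new


def nnc_rotate(C0: np.ndarray, R0: np.ndarray, sm: ScaledMatrix,
               tol: float = 1e-4, max_iter: int = 500,
               refine: str = "minvol") -> FactorSolution:
    """Rotate an initial factor pair to non-negativity.

    Alternating constrained least squares in scaled space: each sweep
    re-solves ``C`` with ``R`` fixed and ``R`` with ``C`` fixed, both under
    elementwise non-negativity (scores are physical source strengths, so
    ``R`` is constrained too).  Sweeps continue until the fit is
    stationary; the solution is flagged converged when the termination
    statistic — sum of squared negative entries of the back-scaled ``C`` —
    is below ``tol``.  Non-convergence within ``max_iter`` returns a
    flagged solution, never raises, so factor-count scans cannot abort.

    With ``refine="minvol"`` (the default) a minimum-volume rotation is
    applied afterwards to resolve the rotational ambiguity among
    equally-well-fitting non-negative factorizations; ``refine="none"``
    returns the raw alternating-update fixed point.  The termination
    statistic is re-evaluated on the refined solution.
    """
    if refine not in ("minvol", "none"):
        raise ValueError("refine must be 'minvol' or 'none'")
    S = sm.values
    m, r = S.shape
    n = C0.shape[1]
    if R0.shape != (n, r) or C0.shape != (m, n):
        raise ValueError("C0/R0 shapes inconsistent with the scaled matrix")

    C, R = C0.copy(), R0.copy()
    s_norm = float(np.linalg.norm(S))
    neg_ss = float(np.sum(np.minimum(C * sm.row_means[:, None], 0.0) ** 2))
    prev_resid = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # C update: rows of C are independent NNLS problems against R^T
        C = _nnls_rows(R.T, S.T).T
        R = _nnls_rows(C, S)
        back_C = C * sm.row_means[:, None]
        neg_ss = float(np.sum(np.minimum(back_C, 0.0) ** 2))
        resid = float(np.linalg.norm(S - C @ R))
        if neg_ss < tol and prev_resid - resid <= 1e-10 * max(s_norm, 1.0):
            break
        prev_resid = resid

    if refine == "minvol":
        C, R = _minimum_volume_refine(C, R)

    back_C = C * sm.row_means[:, None]
    neg_ss = float(np.sum(np.minimum(back_C, 0.0) ** 2))
    converged = neg_ss < tol
    clamped = float(np.sum(np.abs(np.minimum(back_C, 0.0)))
                    + np.sum(np.abs(np.minimum(R, 0.0))))
    back_C = np.maximum(back_C, 0.0)
    R = np.maximum(R, 0.0)

    D = sm.values * sm.row_means[:, None]
    rel_resid = float(np.linalg.norm(D - back_C @ R) / np.linalg.norm(D))

    # order factors by reconstructed mass, descending (ties: stable)
    mass = back_C.sum(axis=0) * R.sum(axis=1)
    order = np.argsort(-mass, kind="stable")
    return FactorSolution(
        loadings=back_C[:, order],
        scores=R[order, :],
        n_factors=n,
        neg_ss=neg_ss,
        iterations=iterations,
        converged=converged,
        relative_residual=rel_resid,
        clamped_mass=clamped,
        compound_labels=sm.compound_labels,
        sample_labels=sm.sample_labels,
    )


def fit_fannc(cm: ConcentrationMatrix, n_factors: int,
              tol: float = 1e-4, max_iter: int = 500,
              refine: str = "minvol") -> FactorSolution:
    """Full pipeline: average scaling → SVD extraction → non-negative rotation."""
    sm = average_scale(cm)
    C0, R0, _ = unrotated_factor_model(sm, n_factors)
    return nnc_rotate(C0, R0, sm, tol=tol, max_iter=max_iter, refine=refine)


def reconstruct(fs: FactorSolution) -> np.ndarray:
    """Model reconstruction ``C·R`` in original concentration units."""
    if fs.loadings.shape[1] != fs.scores.shape[0]:
        raise ValueError("loadings/scores dimension mismatch")
    return fs.loadings @ fs.scores


def normalize_profiles(fs: FactorSolution | np.ndarray) -> np.ndarray:
    """Column-normalize loading profiles to sum to 1 (display/matching only).

    The complementary scale is *not* pushed into the scores; cosine
    similarity is scale-invariant so matching results are unaffected.
    """
    L = fs.loadings if isinstance(fs, FactorSolution) else np.asarray(fs, dtype=float)
    sums = L.sum(axis=0)
    if np.any(sums <= 0):
        k = int(np.where(sums <= 0)[0][0])
        raise ValueError(f"degenerate factor {k}: loading column sums to {sums[k]}")
    return L / sums


def contributions(fs: FactorSolution, weighting: str = "unweighted") -> ContributionTable:
    """Percent contribution of each factor to each sample's total.

    ``per_sample[k, j]`` is the share of sample *j*'s reconstructed total
    attributable to factor *k*, in percent; columns sum to 100.  The
    overall figure is the unweighted mean of per-sample percentages by
    default (``weighting="unweighted"``); ``"weighted"`` instead reports
    each factor's share of the summed totals, which up-weights
    high-concentration samples.  Both are stored on the returned table.
    """
    if weighting not in ("unweighted", "weighted"):
        raise ValueError("weighting must be 'unweighted' or 'weighted'")
    col_mass = fs.loadings.sum(axis=0)            # (n,)
    per_factor = col_mass[:, None] * fs.scores    # (n, r) factor totals per sample
    totals = per_factor.sum(axis=0)               # (r,)
    zero = np.where(totals <= 0)[0]
    if zero.size:
        lab = (fs.sample_labels[zero[0]] if fs.sample_labels
               else f"index {zero[0]}")
        raise ValueError(f"sample {lab} has zero reconstructed total")
    per_sample = 100.0 * per_factor / totals
    overall_unweighted = per_sample.mean(axis=1)
    overall_weighted = 100.0 * per_factor.sum(axis=1) / totals.sum()
    overall = overall_unweighted if weighting == "unweighted" else overall_weighted
    return ContributionTable(
        per_sample=per_sample,
        overall=overall,
        overall_weighted=overall_weighted,
        factor_labels=tuple(f"{k + 1} of {fs.n_factors}" for k in range(fs.n_factors)),
        sample_labels=fs.sample_labels,
    )
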