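"""Factor-number selection diagnostics.

Three statistics are scanned over candidate factor counts, all computed
from the *unrotated* factor model (average scaling, truncated SVD,
back-scaling) so that they measure what extra factors can explain before
the non-negativity rotation spends any of that freedom:

- per-compound coefficient of determination (COD), ``1 − SSE/SST``
  against the compound's own mean, on back-scaled reconstructions;
- cumulative percent variance, from squared singular values of the
  average-scaled matrix (no additional centering — the model is a
  non-centered bilinear form);
- the Exner function, a normalized root lack-of-fit statistic evaluated
  in scaled space; values below ~0.1 conventionally indicate an
  excellent reconstruction.

``recommend_factor_count`` turns the scan into the usual reading: every
count whose Exner is under the threshold and cumulative variance over the
floor qualifies, annotated with the compounds still fit poorly (COD below
a floor) at each count, the smallest qualifying count flagged as the
parsimonious choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ScaledMatrix, average_scale, unrotated_factor_model
from .io import ConcentrationMatrix


@dataclass(frozen=True)
class DiagnosticsTable:
    """Per-compound COD plus summary rows, one column per factor count."""

    factor_counts: tuple[int, ...]
    cod: np.ndarray                  # (m, len(factor_counts))
    cumulative_variance: np.ndarray  # percents
    exner: np.ndarray
    compound_labels: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.cod,
                          index=pd.Index(self.compound_labels, name="compound"),
                          columns=[str(n) for n in self.factor_counts])
        df.loc["cumulative_variance_pct"] = self.cumulative_variance
        df.loc["exner"] = self.exner
        return df


def coefficient_of_determination(D: np.ndarray, Dhat: np.ndarray,
                                 compound_labels=None) -> np.ndarray:
    """Per-compound COD: ``1 − Σ_j(D_ij−Dhat_ij)² / Σ_j(D_ij−mean_i)²``.

    Values can be negative for fits worse than the row-mean null model;
    they are reported as computed.  A constant compound row has zero
    denominator and is a hard error.
    """
    D = np.asarray(D, dtype=float)
    Dhat = np.asarray(Dhat, dtype=float)
    if D.shape != Dhat.shape:
        raise ValueError("D and Dhat must share a shape")
    sst = np.sum((D - D.mean(axis=1, keepdims=True)) ** 2, axis=1)
    bad = np.where(sst == 0)[0]
    if bad.size:
        lab = compound_labels[bad[0]] if compound_labels else f"row {bad[0]}"
        raise ValueError(f"constant compound row {lab!r}: COD undefined")
    sse = np.sum((D - Dhat) ** 2, axis=1)
    return 1.0 - sse / sst


def cumulative_percent_variance(sm: ScaledMatrix, n: int) -> float:
    """Percent of total sum of squares carried by the top ``n`` components."""
    m, r = sm.values.shape
    if not 1 <= n <= min(m, r):
        raise ValueError(f"n={n} outside [1, {min(m, r)}]")
    s = np.linalg.svd(sm.values, compute_uv=False)
    return float(100.0 * np.sum(s[:n] ** 2) / np.sum(s**2))


def exner_function(D: np.ndarray, Dhat: np.ndarray) -> float:
    """``sqrt(Σ(D−Dhat)² / Σ(D−grand_mean(D))²)``.

    0 for a perfect reconstruction, 1 for the grand-mean null model.
    Intended to be evaluated on the average-scaled matrices, the space
    the factor model actually fits.
    """
    D = np.asarray(D, dtype=float)
    Dhat = np.asarray(Dhat, dtype=float)
    if D.shape != Dhat.shape:
        raise ValueError("D and Dhat must share a shape")
    denom = float(np.sum((D - D.mean()) ** 2))
    if denom == 0:
        raise ValueError("D equals its grand mean everywhere: Exner undefined")
    return float(np.sqrt(np.sum((D - Dhat) ** 2) / denom))


def diagnostics_table(cm: ConcentrationMatrix, n_min: int, n_max: int) -> DiagnosticsTable:
    """Scan factor counts ``n_min..n_max`` with the unrotated model.

    For each count the scaled matrix is fit by truncated SVD, the
    reconstruction is back-scaled, and per-compound COD (in original
    units), cumulative percent variance and the Exner function (in scaled
    space) are recorded.
    """
    sm = average_scale(cm)
    lim = min(cm.n_compounds, cm.n_samples)
    if not 1 <= n_min <= n_max <= lim:
        raise ValueError(f"factor range [{n_min}, {n_max}] outside [1, {lim}]")
    counts = tuple(range(n_min, n_max + 1))
    cod = np.empty((cm.n_compounds, len(counts)))
    cumvar = np.empty(len(counts))
    exner = np.empty(len(counts))
    for idx, n in enumerate(counts):
        C0, R0, _ = unrotated_factor_model(sm, n)
        Shat = C0 @ R0
        Dhat = Shat * sm.row_means[:, None]
        cod[:, idx] = coefficient_of_determination(cm.values, Dhat, cm.compound_labels)
        cumvar[idx] = cumulative_percent_variance(sm, n)
        exner[idx] = exner_function(sm.values, Shat)
    return DiagnosticsTable(
        factor_counts=counts,
        cod=cod,
        cumulative_variance=cumvar,
        exner=exner,
        compound_labels=cm.compound_labels,
    )


def recommend_factor_count(dt: DiagnosticsTable, exner_max: float = 0.1,
                           cumvar_min: float = 95.0, cod_min: float = 0.8):
    """Qualify factor counts by the Exner and cumulative-variance thresholds.

    Returns ``(recommended, rationale)``: the set of counts with
    ``exner < exner_max`` and ``cumulative_variance > cumvar_min``, and a
    human-readable rationale listing, for each qualifying count, the
    compounds whose COD is still below ``cod_min``.  The smallest
    qualifying count is flagged as the parsimonious choice.  An empty
    qualifying set is allowed and explained, never an error.
    """
    recommended: set[int] = set()
    lines: list[str] = []
    for idx, n in enumerate(dt.factor_counts):
        ok = dt.exner[idx] < exner_max and dt.cumulative_variance[idx] > cumvar_min
        if not ok:
            continue
        recommended.add(n)
        low = [dt.compound_labels[i] for i in range(dt.cod.shape[0])
               if dt.cod[i, idx] < cod_min]
        note = (f"all compound CODs ≥ {cod_min}" if not low
                else f"COD < {cod_min} for: {', '.join(low)}")
        lines.append(f"n={n}: Exner {dt.exner[idx]:.4f} < {exner_max}, "
                     f"cumulative variance {dt.cumulative_variance[idx]:.2f}% "
                     f"> {cumvar_min}%; {note}")
    if recommended:
        lines.append(f"parsimonious choice: n={min(recommended)}")
    else:
        lines.append(f"no factor count in {list(dt.factor_counts)} meets "
                     f"Exner < {exner_max} and cumulative variance > {cumvar_min}%")
    return recommended, "\n".join(lines)
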