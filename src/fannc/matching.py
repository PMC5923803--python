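"""Source identification by cosine similarity against a profile library.

A modeled factor profile is attributed to the literature source whose
fractional composition points in the most similar direction:
``cos(A, B) = A·B / (‖A‖‖B‖)``, which for non-negative vectors lies in
[0, 1] — 1 for proportional profiles, 0 for profiles with disjoint
compound support.  Because the measure is scale-invariant, it does not
matter whether profiles are normalized to sum to 1 or left in raw
loading units.

The report flags, per factor, the best-matching source plus any source
within ``tie_delta`` of that maximum — a factor that is really a blend of
two sources (e.g. coal and diesel) then carries both flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SourceProfileLibrary


@dataclass(frozen=True)
class SimilarityReport:
    """Factor × library-source cosine similarities with best-match flags."""

    similarities: np.ndarray       # (n_factors, n_sources), in [0, 1]
    best_match_flags: np.ndarray   # boolean, same shape
    factor_labels: tuple[str, ...]
    source_labels: tuple[str, ...]

    def best_matches(self, k: int) -> tuple[str, ...]:
        """Flagged source names for factor ``k``, best first."""
        idx = np.where(self.best_match_flags[k])[0]
        idx = idx[np.argsort(-self.similarities[k, idx], kind="stable")]
        return tuple(self.source_labels[i] for i in idx)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.similarities,
                          index=pd.Index(self.factor_labels, name="factor"),
                          columns=list(self.source_labels))
        df["best_match"] = ["; ".join(self.best_matches(k))
                            for k in range(len(self.factor_labels))]
        return df


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two non-negative profile vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero-norm vector")
    return float(np.dot(a, b) / (na * nb))


def similarity_report(profiles: np.ndarray, lib: SourceProfileLibrary,
                      factor_labels=None, compound_labels=None,
                      tie_delta: float = 0.02) -> SimilarityReport:
    """Compare each factor profile column against every library source.

    ``profiles`` is an m × n matrix whose columns are modeled profiles on
    the same compound axis as the library (pass ``compound_labels`` to
    have the alignment checked by name).  Each factor row flags its
    maximum plus any source within ``tie_delta`` of it.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim == 1:
        profiles = profiles[:, None]
    if compound_labels is not None:
        ours = [c.strip().lower() for c in compound_labels]
        theirs = [c.strip().lower() for c in lib.compound_labels]
        if ours != theirs:
            missing = sorted(set(ours) ^ set(theirs))
            raise KeyError(f"compound axes differ between profiles and library; "
                           f"unmatched labels: {missing}")
    if profiles.shape[0] != lib.profiles.shape[0]:
        raise ValueError("profiles and library have different compound counts")
    n = profiles.shape[1]
    if factor_labels is None:
        factor_labels = tuple(f"{k + 1} of {n}" for k in range(n))
    sims = np.empty((n, lib.n_sources))
    for k in range(n):
        for s in range(lib.n_sources):
            sims[k, s] = cosine_similarity(profiles[:, k], lib.profiles[:, s])
    flags = sims >= (sims.max(axis=1, keepdims=True) - tie_delta)
    return SimilarityReport(
        similarities=sims,
        best_match_flags=flags,
        factor_labels=tuple(factor_labels),
        source_labels=lib.source_labels,
    )
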