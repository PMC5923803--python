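"""Domain containers, CSV ingestion and report serialization.

The central object is the compounds × samples concentration matrix ``D``
that the bilinear receptor model ``D = C·R`` factorizes: rows are chemical
species (here PAHs), columns are sampling sites, cells are concentrations
(e.g. ng/g dry weight).  A :class:`SourceProfileLibrary` holds literature
source fingerprints as column-stochastic fractional compositions, one
column per candidate source.  :class:`RunConfig` collects every tunable of
the pipeline so that a run is reproducible from the config plus a seed.

All file formats are plain CSV with an explicit orientation (compounds as
rows); the reader validates rather than guesses, and ingestion rejects
missing, negative or non-numeric cells instead of imputing.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("fannc")

#: column sums of profile libraries must renormalize to 1 within this
PROFILE_SUM_TOL = 1e-9


class IngestionError(ValueError):
    """Raised when an input table violates a data invariant."""


def _check_unique(labels: Sequence[str], axis: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise IngestionError(f"duplicate {axis} label: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class ConcentrationMatrix:
    """Non-negative compounds × samples concentration table.

    Parameters
    ----------
    values
        Array of shape ``(m, r)``: ``m`` compounds, ``r`` samples.  Every
        entry must be finite and ≥ 0, and no compound row may be all
        zero (average scaling divides by row means).
    compound_labels, sample_labels
        Unique axis labels, order preserved from the source file.
    units
        Free-text concentration units, e.g. ``"ng/g dry wt"``.
    """

    values: np.ndarray
    compound_labels: tuple[str, ...]
    sample_labels: tuple[str, ...]
    units: str = "ng/g dry wt"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "compound_labels", tuple(self.compound_labels))
        object.__setattr__(self, "sample_labels", tuple(self.sample_labels))
        m, r = values.shape
        if m < 2 or r < 2:
            raise IngestionError(
                f"need at least 2 compounds and 2 samples, got {m}×{r}"
            )
        if len(self.compound_labels) != m or len(self.sample_labels) != r:
            raise IngestionError("label lengths do not match matrix shape")
        _check_unique(self.compound_labels, "compound")
        _check_unique(self.sample_labels, "sample")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise IngestionError(
                f"non-finite concentration for compound "
                f"{self.compound_labels[i]!r}, sample {self.sample_labels[j]!r}"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise IngestionError(
                f"negative concentration {values[i, j]} for compound "
                f"{self.compound_labels[i]!r}, sample {self.sample_labels[j]!r}"
            )
        zero_rows = np.where(~values.any(axis=1))[0]
        if zero_rows.size:
            raise IngestionError(
                f"all-zero compound row: {self.compound_labels[zero_rows[0]]!r}"
            )

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.compound_labels, name="compound"),
            columns=list(self.sample_labels),
        )


@dataclass(frozen=True)
class SourceProfileLibrary:
    """Literature source fingerprints: compounds × sources fractions.

    Each source column is renormalized to sum to 1 on construction;
    columns that cannot be normalized (zero sum) are rejected.
    """

    profiles: np.ndarray
    source_labels: tuple[str, ...]
    compound_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        profiles = np.asarray(self.profiles, dtype=float)
        object.__setattr__(self, "source_labels", tuple(self.source_labels))
        object.__setattr__(self, "compound_labels", tuple(self.compound_labels))
        if profiles.ndim != 2:
            raise IngestionError("profile library must be a 2-D table")
        if profiles.shape != (len(self.compound_labels), len(self.source_labels)):
            raise IngestionError("label lengths do not match profile shape")
        _check_unique(self.source_labels, "source")
        _check_unique(self.compound_labels, "compound")
        if not np.all(np.isfinite(profiles)) or np.any(profiles < 0):
            raise IngestionError("profile fractions must be finite and non-negative")
        sums = profiles.sum(axis=0)
        if np.any(sums <= 0):
            k = int(np.where(sums <= 0)[0][0])
            raise IngestionError(f"source column sums to zero: {self.source_labels[k]!r}")
        object.__setattr__(self, "profiles", profiles / sums)

    @property
    def n_sources(self) -> int:
        return self.profiles.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles,
            index=pd.Index(self.compound_labels, name="compound"),
            columns=list(self.source_labels),
        )


@dataclass
class RunConfig:
    """All tunables of an apportionment run.

    ``n_factors`` may be a single count or an inclusive ``(lo, hi)`` range
    for diagnostic scans.  ``cv`` is the coefficient of variation driving
    the Monte Carlo cell perturbation: a scalar, a per-compound vector or
    a full per-cell matrix.
    """

    n_factors: int | tuple[int, int] = 3
    neg_ss_tolerance: float = 1e-4
    max_iterations: int = 500
    mc_runs: int = 1000
    cv: float | np.ndarray = 0.1
    seed: int = 0
    exclude_compounds: tuple[str, ...] = ()
    exclude_samples: tuple[str, ...] = ()
    #: "printed" keeps the bracket 2·erfinv(2R−1) (a normal deviate with
    #: SD √2); "unit_sd" uses √2·erfinv(2R−1) (standard normal) instead.
    normal_deviate_convention: str = "printed"
    #: "unweighted": overall contribution = mean of per-sample percents;
    #: "weighted": percent of summed reconstructed totals.
    contribution_weighting: str = "unweighted"

    def __post_init__(self) -> None:
        if self.neg_ss_tolerance <= 0:
            raise ValueError("neg_ss_tolerance must be > 0")
        if self.mc_runs < 0:
            raise ValueError("mc_runs must be ≥ 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be ≥ 1")
        if np.any(np.asarray(self.cv, dtype=float) < 0):
            raise ValueError("cv must be ≥ 0")
        if self.normal_deviate_convention not in ("printed", "unit_sd"):
            raise ValueError("normal_deviate_convention must be 'printed' or 'unit_sd'")
        if self.contribution_weighting not in ("unweighted", "weighted"):
            raise ValueError("contribution_weighting must be 'unweighted' or 'weighted'")
        self.exclude_compounds = tuple(self.exclude_compounds)
        self.exclude_samples = tuple(self.exclude_samples)

    def factor_range(self) -> tuple[int, int]:
        if isinstance(self.n_factors, int):
            return (self.n_factors, self.n_factors)
        lo, hi = self.n_factors
        return (int(lo), int(hi))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "n_factors" in raw and isinstance(raw["n_factors"], list):
            raw["n_factors"] = tuple(raw["n_factors"])
        for key in ("exclude_compounds", "exclude_samples"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(str(x) for x in raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# CSV ingestion


def _read_labelled_csv(path: str | Path, kind: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise IngestionError(f"cannot parse {kind} CSV {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise IngestionError(f"{kind} CSV {path} needs a label column plus data columns")
    first = df.columns[0].strip().lower()
    if first != "compound":
        raise IngestionError(
            f"{kind} CSV {path}: first column must be named 'compound' "
            f"(compounds are rows), got {df.columns[0]!r}"
        )
    df = df.set_index(df.columns[0])
    body = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or (
                isinstance(cell, str) and not cell.strip()
            ):
                raise IngestionError(
                    f"missing cell for compound {df.index[i]!r}, column {col!r}"
                )
            try:
                body[i, j] = float(cell)
            except (TypeError, ValueError):
                raise IngestionError(
                    f"non-numeric cell {cell!r} for compound {df.index[i]!r}, "
                    f"column {col!r}"
                ) from None
    return pd.DataFrame(body, index=[str(x) for x in df.index], columns=list(df.columns))


def read_concentration_table(path: str | Path, units: str = "ng/g dry wt") -> ConcentrationMatrix:
    """Read a compounds × samples concentration CSV.

    The file has a header row of sample labels, a first column named
    ``compound``, and a fully numeric body.  Row and column order are
    preserved.
    """
    df = _read_labelled_csv(path, "concentration")
    return ConcentrationMatrix(
        values=df.to_numpy(),
        compound_labels=tuple(df.index),
        sample_labels=tuple(df.columns),
        units=units,
    )


def read_profile_library(path: str | Path) -> SourceProfileLibrary:
    """Read a compounds × sources profile-library CSV (fractions per source)."""
    df = _read_labelled_csv(path, "profile-library")
    return SourceProfileLibrary(
        profiles=df.to_numpy(),
        source_labels=tuple(df.columns),
        compound_labels=tuple(df.index),
    )


def write_concentration_table(cm: ConcentrationMatrix, path: str | Path) -> None:
    """Write a concentration matrix in the same CSV layout the reader expects.

    Values are serialized with :func:`repr` round-trip precision so that
    write-then-read is the identity on the floating-point values.
    """
    df = cm.to_frame()
    df.to_csv(path, float_format="%.17g")


def apply_exclusions(cm: ConcentrationMatrix, config: RunConfig,
                     strict: bool = True) -> ConcentrationMatrix:
    """Drop excluded compounds/samples (e.g. naphthalene, an outlier site).

    Order of the remaining rows/columns is preserved and all matrix
    invariants are re-checked.  With ``strict`` (the default) an unknown
    label is a hard error; ``strict=False`` ignores labels that are
    already absent, which makes the operation idempotent.
    """
    if strict:
        for lab in config.exclude_compounds:
            if lab not in cm.compound_labels:
                raise KeyError(f"exclusion names unknown compound: {lab!r}")
        for lab in config.exclude_samples:
            if lab not in cm.sample_labels:
                raise KeyError(f"exclusion names unknown sample: {lab!r}")
    if not config.exclude_compounds and not config.exclude_samples:
        return cm
    keep_rows = [i for i, lab in enumerate(cm.compound_labels)
                 if lab not in config.exclude_compounds]
    keep_cols = [j for j, lab in enumerate(cm.sample_labels)
                 if lab not in config.exclude_samples]
    if len(keep_rows) < 2 or len(keep_cols) < 2:
        raise IngestionError("exclusions leave fewer than 2 compounds or samples")
    logger.info(
        "exclusions: dropped %d compounds, %d samples",
        cm.n_compounds - len(keep_rows), cm.n_samples - len(keep_cols),
    )
    return ConcentrationMatrix(
        values=cm.values[np.ix_(keep_rows, keep_cols)],
        compound_labels=tuple(cm.compound_labels[i] for i in keep_rows),
        sample_labels=tuple(cm.sample_labels[j] for j in keep_cols),
        units=cm.units,
    )


def align_library(cm: ConcentrationMatrix, lib: SourceProfileLibrary,
                  max_missing: int = 2) -> SourceProfileLibrary:
    """Reorder the library's compound axis to match the concentration matrix.

    Matching is by exact label after case-normalization.  Compounds the
    library lacks are tolerated up to ``max_missing`` (the comparison then
    runs on the label intersection, with a logged warning); more than that,
    or library-only labels that shadow nothing, is a hard error.
    """
    norm = {lab.strip().lower(): i for i, lab in enumerate(lib.compound_labels)}
    rows, kept = [], []
    missing = []
    for lab in cm.compound_labels:
        key = lab.strip().lower()
        if key in norm:
            rows.append(norm[key])
            kept.append(lab)
        else:
            missing.append(lab)
    if len(missing) > max_missing:
        raise KeyError(
            f"profile library is missing {len(missing)} modeled compounds "
            f"(> {max_missing} allowed): {missing}"
        )
    if missing:
        logger.warning("profile library lacks compounds %s; matching on the "
                       "remaining %d", missing, len(kept))
    return SourceProfileLibrary(
        profiles=lib.profiles[rows, :],
        source_labels=lib.source_labels,
        compound_labels=tuple(kept),
    )


# ---------------------------------------------------------------------------
# Report serialization


def _fmt_frame(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, float_format="%.17e")


def write_apportionment_report(solution, outdir: str | Path, *,
                               diagnostics=None, similarity=None,
                               ensemble=None, config: RunConfig | None = None) -> list[Path]:
    """Serialize a run's tabular outputs to ``outdir``.

    Writes CSVs for normalized profiles (± SD when an uncertainty ensemble
    is supplied), per-sample and overall contributions (± SD likewise), the
    factor-number diagnostics table and the similarity matrix, plus a
    ``run_metadata.txt`` recording config, seed and convergence status.
    Numeric cells use full double precision so identical runs produce
    byte-identical files.
    """
    from .core import contributions, normalize_profiles

    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to {outdir}: {exc}") from exc

    written: list[Path] = []
    factor_names = [f"{k + 1} of {solution.n_factors}" for k in range(solution.n_factors)]

    profs = pd.DataFrame(normalize_profiles(solution),
                         index=pd.Index(solution.compound_labels, name="compound"),
                         columns=factor_names)
    if ensemble is not None:
        for k, name in enumerate(factor_names):
            profs[f"{name} SD"] = ensemble.profile_sd[:, k]
    _fmt_frame(profs, outdir / "profiles.csv")
    written.append(outdir / "profiles.csv")

    weighting = config.contribution_weighting if config is not None else "unweighted"
    ct = contributions(solution, weighting=weighting)
    per = pd.DataFrame(ct.per_sample, index=pd.Index(factor_names, name="factor"),
                       columns=list(solution.sample_labels))
    _fmt_frame(per, outdir / "contributions_per_sample.csv")
    written.append(outdir / "contributions_per_sample.csv")

    overall = pd.DataFrame({"mean_pct": ct.overall}, index=pd.Index(factor_names, name="factor"))
    overall["weighted_pct"] = ct.overall_weighted
    if ensemble is not None:
        overall["sd_pct"] = ensemble.contribution_overall_sd
        per_sd = pd.DataFrame(ensemble.contribution_per_sample_sd,
                              index=pd.Index(factor_names, name="factor"),
                              columns=list(solution.sample_labels))
        _fmt_frame(per_sd, outdir / "contributions_per_sample_sd.csv")
        written.append(outdir / "contributions_per_sample_sd.csv")
    _fmt_frame(overall, outdir / "contributions_overall.csv")
    written.append(outdir / "contributions_overall.csv")

    if diagnostics is not None:
        _fmt_frame(diagnostics.to_frame(), outdir / "diagnostics.csv")
        written.append(outdir / "diagnostics.csv")
    if similarity is not None:
        _fmt_frame(similarity.to_frame(), outdir / "similarity.csv")
        written.append(outdir / "similarity.csv")

    meta = [
        f"n_factors: {solution.n_factors}",
        f"converged: {solution.converged}",
        f"iterations: {solution.iterations}",
        f"neg_ss: {solution.neg_ss:.17e}",
        f"relative_residual: {solution.relative_residual:.17e}",
    ]
    if config is not None:
        meta.append(f"seed: {config.seed}")
        meta.append(f"config: {config}")
    if ensemble is not None:
        meta.append(f"mc_runs: {ensemble.n_runs}")
        meta.append(f"mc_converged: {ensemble.n_converged}")
    else:
        meta.append("mc_runs: 0 (no uncertainty ensemble; SD columns omitted)")
    (outdir / "run_metadata.txt").write_text("\n".join(meta) + "\n")
    written.append(outdir / "run_metadata.txt")
    return written
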