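"""Connectome I/O: parcellations, connectivity matrices, cohorts, vectorization.

A connectivity matrix holds tractography streamline counts between labeled
regions of one hemisphere (entry ``C[i, j]`` = streamlines seeded in region
``i`` entering region ``j``; asymmetric by construction).  A cohort is a
collection of such matrices over subjects and scan sessions sharing one
parcellation.  This module defines the canonical vectorization of a matrix
into a feature vector and the stacking of a cohort into the data matrix
``M`` (one column per subject x scan) that the motif decomposition consumes.

Two vectorization modes exist:

``symmetric`` (default)
    strict upper triangle of ``(C + C.T) / 2`` in row-major order — length
    ``D * (D - 1) / 2``.  Streamline direction from probabilistic
    tractography carries no biological meaning, so symmetrizing is the
    default.
``full``
    every off-diagonal entry in row-major order — length ``D * (D - 1)`` —
    retained for sensitivity analyses.

Diagonal (self-connection) entries are tractography artifacts and are
zeroed on load and excluded from every feature vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    DimensionError,
    DomainError,
    MissingDataError,
    ParcellationError,
    UsageError,
)

VECTORIZE_MODES = ("symmetric", "full")


@dataclass(frozen=True)
class Parcellation:
    """Ordered region labels defining matrix row/column order for a cohort."""

    labels: tuple[str, ...]
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ParcellationError("parcellation needs at least 2 regions")
        if len(set(self.labels)) != len(self.labels):
            raise ParcellationError("parcellation labels must be unique")
        if self.hemisphere not in ("left", "right"):
            raise ParcellationError(f"unknown hemisphere {self.hemisphere!r}")

    def __len__(self) -> int:
        return len(self.labels)


def hcp_mmp_labels(n_cortical: int = 180, n_callosal: int = 5) -> tuple[str, ...]:
    """Placeholder labels with the atlas's 180 cortical + 5 corpus-callosum layout.

    Synthetic cohorts use generic names (``R001`` ... ``R180``, ``CC_1`` ...
    ``CC_5``); real data supplies its own label header.
    """
    cortical = tuple(f"R{i:03d}" for i in range(1, n_cortical + 1))
    callosal = tuple(f"CC_{i}" for i in range(1, n_callosal + 1))
    return cortical + callosal


@dataclass
class ConnectivityMatrix:
    """One subject/scan/hemisphere streamline-count matrix.

    ``values`` is square, nonnegative, with a zero diagonal (enforced at
    construction).  All-zero rows or columns are legal: corpus-callosum
    parcels are target-only in seed-to-seed tractography.
    """

    values: np.ndarray
    subject: str
    scan: str
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DimensionError(f"matrix must be square, got shape {v.shape}")
        if np.any(v < 0):
            raise DomainError("streamline counts must be nonnegative")
        v = v.copy()
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class ConnectomeCohort:
    """Matrices keyed by (subject, scan) over a shared parcellation."""

    parcellation: Parcellation
    matrices: dict[tuple[str, str], ConnectivityMatrix]
    subjects: list[str] = field(default_factory=list)
    scans: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = len(self.parcellation)
        for (subj, scan), mat in self.matrices.items():
            if mat.n_regions != d:
                raise ParcellationError(
                    f"matrix ({subj}, {scan}) has {mat.n_regions} regions, "
                    f"parcellation has {d}"
                )
        if not self.subjects:
            self.subjects = sorted({s for s, _ in self.matrices})
        if not self.scans:
            self.scans = sorted({sc for _, sc in self.matrices})

    def matrix(self, subject: str, scan: str) -> ConnectivityMatrix:
        try:
            return self.matrices[(subject, scan)]
        except KeyError:
            raise MissingDataError(f"no matrix for subject {subject!r}, scan {scan!r}")

    def has(self, subject: str, scan: str) -> bool:
        return (subject, scan) in self.matrices


@dataclass
class FeatureVector:
    """Vectorized connectivity with its region-pair index."""

    entries: np.ndarray
    index_map: list[tuple[str, str]]
    mode: str


def feature_index_map(
    parcellation: Parcellation, mode: str = "symmetric"
) -> list[tuple[str, str]]:
    """Ordered (source, target) region pairs for one vectorization mode."""
    if mode not in VECTORIZE_MODES:
        raise UsageError(f"unknown vectorization mode {mode!r}")
    labels = parcellation.labels
    d = len(labels)
    if mode == "symmetric":
        return [(labels[i], labels[j]) for i in range(d) for j in range(i + 1, d)]
    return [(labels[i], labels[j]) for i in range(d) for j in range(d) if i != j]


def n_features(n_regions: int, mode: str = "symmetric") -> int:
    """Feature-vector length: D(D-1)/2 symmetric, D(D-1) full."""
    if mode == "symmetric":
        return n_regions * (n_regions - 1) // 2
    if mode == "full":
        return n_regions * (n_regions - 1)
    raise UsageError(f"unknown vectorization mode {mode!r}")


def _vectorize_values(values: np.ndarray, mode: str) -> np.ndarray:
    d = values.shape[0]
    if mode == "symmetric":
        sym = (values + values.T) / 2.0
        iu = np.triu_indices(d, k=1)
        return sym[iu]
    if mode == "full":
        off = ~np.eye(d, dtype=bool)
        return values[off]
    raise UsageError(f"unknown vectorization mode {mode!r}")


def vectorize(
    matrix: ConnectivityMatrix,
    mode: str = "symmetric",
    parcellation: Parcellation | None = None,
    log1p: bool = False,
) -> FeatureVector:
    """Vectorize one connectivity matrix.

    ``log1p=True`` applies ``log(1 + x)`` to the raw counts before
    symmetrization — an optional robustness transform, not the default
    (the analysis runs on raw streamline counts).
    """
    values = matrix.values
    if log1p:
        values = np.log1p(values)
    entries = _vectorize_values(values, mode)
    if parcellation is not None:
        if len(parcellation) != matrix.n_regions:
            raise ParcellationError("parcellation size does not match matrix")
        index_map = feature_index_map(parcellation, mode)
    else:
        anon = Parcellation(tuple(f"r{i}" for i in range(matrix.n_regions)))
        index_map = feature_index_map(anon, mode)
    return FeatureVector(entries=entries, index_map=index_map, mode=mode)


def unvectorize(
    entries: np.ndarray, n_regions: int, mode: str = "symmetric"
) -> np.ndarray:
    """Inverse of :func:`vectorize`: place features back into a D x D matrix.

    Symmetric-mode features are mirrored across the diagonal; the diagonal
    is zero.
    """
    entries = np.asarray(entries, dtype=float)
    expected = n_features(n_regions, mode)
    if entries.shape != (expected,):
        raise DimensionError(
            f"expected {expected} features for {n_regions} regions in {mode} mode, "
            f"got {entries.shape}"
        )
    out = np.zeros((n_regions, n_regions))
    if mode == "symmetric":
        iu = np.triu_indices(n_regions, k=1)
        out[iu] = entries
        out = out + out.T
    else:
        off = ~np.eye(n_regions, dtype=bool)
        out[off] = entries
    return out


def stack(
    cohort: ConnectomeCohort,
    scans: Sequence[str],
    mode: str = "symmetric",
    subjects: Sequence[str] | None = None,
    log1p: bool = False,
) -> tuple[np.ndarray, list[tuple[str, str]], list[tuple[str, str]]]:
    """Stack feature vectors into the data matrix M.

    Columns are ordered scan-major, then by the cohort's subject order, so
    downstream weight lookups are unambiguous.  Returns
    ``(M, column_index, index_map)`` where ``column_index[j]`` is the
    ``(subject, scan)`` of column ``j``.
    """
    if not scans:
        raise UsageError("at least one scan must be requested")
    if subjects is None:
        subjects = cohort.subjects
    if not subjects:
        raise UsageError("no subjects selected")
    column_index: list[tuple[str, str]] = []
    columns: list[np.ndarray] = []
    for scan in scans:
        for subj in subjects:
            mat = cohort.matrix(subj, scan)
            columns.append(
                vectorize(mat, mode=mode, log1p=log1p).entries
            )
            column_index.append((subj, scan))
    M = np.column_stack(columns)
    index_map = feature_index_map(cohort.parcellation, mode)
    return M, column_index, index_map


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def load_matrix(
    path: str | Path,
    subject: str,
    scan: str,
    hemisphere: str = "left",
    parcellation: Parcellation | None = None,
) -> ConnectivityMatrix:
    """Load one delimited matrix file (header row of labels, labeled rows).

    Comma- or tab-delimited is auto-detected.  The diagonal is zeroed on
    load; a label mismatch against ``parcellation`` raises
    :class:`ParcellationError`.
    """
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    row_labels = [str(x) for x in df.index]
    col_labels = [str(x) for x in df.columns]
    if row_labels != col_labels:
        raise DimensionError(
            f"{path}: row labels do not match column labels (non-square layout)"
        )
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise DimensionError(f"{path}: matrix is not square {values.shape}")
    if np.any(values < 0):
        raise DomainError(f"{path}: negative streamline count")
    if parcellation is not None and tuple(row_labels) != parcellation.labels:
        raise ParcellationError(
            f"{path}: labels do not match the cohort parcellation"
        )
    return ConnectivityMatrix(
        values=values, subject=subject, scan=scan, hemisphere=hemisphere
    )


def write_matrix(
    matrix: ConnectivityMatrix,
    parcellation: Parcellation,
    path: str | Path,
    sep: str = ",",
) -> Path:
    """Write a matrix as delimited text with a label header and labeled rows.

    Integer-valued matrices are written as integers so counts round-trip
    bit-identically; otherwise full float precision is used.
    """
    path = Path(path)
    values = matrix.values
    labels = list(parcellation.labels)
    if np.all(values == np.round(values)):
        df = pd.DataFrame(values.astype(np.int64), index=labels, columns=labels)
    else:
        df = pd.DataFrame(values, index=labels, columns=labels)
    df.to_csv(path, sep=sep, float_format="%.17g")
    return path


def load_parcellation(path: str | Path, hemisphere: str = "left") -> Parcellation:
    """Load a parcellation from a one-label-per-line text file."""
    labels = tuple(
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    )
    return Parcellation(labels=labels, hemisphere=hemisphere)


def write_parcellation(parcellation: Parcellation, path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(parcellation.labels) + "\n", encoding="utf-8")
    return path


def load_cohort(manifest_path: str | Path) -> ConnectomeCohort:
    """Load a cohort from a YAML/JSON manifest.

    The manifest lists ``hemisphere``, ``parcellation`` (label file),
    ``subjects``, ``scans``, and ``matrices`` as records with ``subject``,
    ``scan`` and ``path`` (relative paths resolved against the manifest
    directory).
    """
    manifest_path = Path(manifest_path)
    text = manifest_path.read_text(encoding="utf-8")
    manifest = (
        json.loads(text) if manifest_path.suffix == ".json" else yaml.safe_load(text)
    )
    base = manifest_path.parent
    hemisphere = manifest.get("hemisphere", "left")
    parc = load_parcellation(base / manifest["parcellation"], hemisphere=hemisphere)
    matrices: dict[tuple[str, str], ConnectivityMatrix] = {}
    for rec in manifest["matrices"]:
        subj, scan = str(rec["subject"]), str(rec["scan"])
        key = (subj, scan)
        if key in matrices:
            raise UsageError(f"duplicate manifest entry for {key}")
        matrices[key] = load_matrix(
            base / rec["path"], subj, scan, hemisphere=hemisphere, parcellation=parc
        )
    return ConnectomeCohort(
        parcellation=parc,
        matrices=matrices,
        subjects=[str(s) for s in manifest.get("subjects", [])],
        scans=[str(s) for s in manifest.get("scans", [])],
    )


def write_cohort_files(
    cohort: ConnectomeCohort,
    directory: str | Path,
    manifest_name: str = "cohort.yaml",
) -> Path:
    """Write all matrices, the parcellation and a manifest; return the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_parcellation(cohort.parcellation, directory / "parcellation.txt")
    records = []
    for (subj, scan) in sorted(cohort.matrices):
        fname = f"matrix_{subj}_{scan}.csv"
        write_matrix(cohort.matrices[(subj, scan)], cohort.parcellation,
                     directory / fname)
        records.append({"subject": subj, "scan": scan, "path": fname})
    manifest = {
        "hemisphere": cohort.parcellation.hemisphere,
        "parcellation": "parcellation.txt",
        "subjects": list(cohort.subjects),
        "scans": list(cohort.scans),
        "matrices": records,
    }
    manifest_path = directory / manifest_name
    manifest_path.write_text(
        yaml.safe_dump(manifest, sort_keys=False), encoding="utf-8"
    )
    return manifest_path
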