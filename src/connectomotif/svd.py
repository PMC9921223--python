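"""Network-motif decomposition of stacked connectomes by SVD.

The stacked data matrix ``M`` (features x columns, one column per
subject/scan feature vector) is factored as ``M = U S V^T``.  Columns of
``U`` are the *network motifs*: orthonormal signed patterns over region
pairs, ordered by the variance they explain across all connectivity
matrices.  The singular values give each motif's share of that variance
(explained variance = sigma_k^2 / sum sigma^2) and the rows of ``V^T``
give the motif's *prevalence* (weight) in each subject and scan.

Singular-vector signs are mathematically indeterminate; for reproducible
signed reports each motif is flipped so that its largest-absolute feature
entry is positive, with the matching weight row flipped jointly (leaving
``U S V^T`` unchanged).

Hemispheres are decomposed separately, never concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, MissingDataError, UsageError
from .io import unvectorize


@dataclass
class MotifDecomposition:
    """Thin SVD of the stacked connectome matrix, truncated at numerical rank.

    Attributes
    ----------
    motifs : (n_features, rank) array
        Columns are unit-norm network motifs (left singular vectors).
    singular_values : (rank,) array, nonincreasing.
    weights : (rank, n_columns) array
        Row k holds motif k's prevalence in each column of M (rows of V^T).
    explained_variance : (rank,) array summing to 1.
    column_index : list of (subject, scan) per column of M.
    index_map : list of (source, target) region pairs per feature.
    mode : vectorization mode of the features.
    centered : whether columns were mean-centered before the SVD.
    """

    motifs: np.ndarray
    singular_values: np.ndarray
    weights: np.ndarray
    explained_variance: np.ndarray
    column_index: list[tuple[str, str]]
    index_map: list[tuple[str, str]]
    mode: str = "symmetric"
    centered: bool = False
    column_mean: np.ndarray | None = None

    @property
    def n_motifs(self) -> int:
        return self.motifs.shape[1]

    @property
    def n_regions(self) -> int:
        L = len(self.index_map)
        # invert L = D(D-1)/2 (symmetric) or L = D(D-1) (full)
        c = 8 if self.mode == "symmetric" else 4
        return int(round((1 + np.sqrt(1 + c * L)) / 2))

    def column(self, subject: str, scan: str) -> int:
        try:
            return self.column_index.index((subject, scan))
        except ValueError:
            raise MissingDataError(
                f"no column for subject {subject!r}, scan {scan!r} in decomposition"
            )


def explained_variance(singular_values: np.ndarray) -> np.ndarray:
    """Fraction of total variance per motif: sigma_k^2 / sum(sigma^2)."""
    s = np.asarray(singular_values, dtype=float)
    if np.any(s < 0):
        raise DomainError("singular values must be nonnegative")
    total = float(np.sum(s**2))
    if total == 0.0:
        raise DomainError("all singular values are zero")
    return s**2 / total


def _fix_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each (motif, weight-row) pair so the motif's largest-|.| entry is > 0.

    Ties break to the first index (np.argmax); U S V^T is unchanged.
    """
    U = U.copy()
    Vt = Vt.copy()
    for k in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, k])))
        if U[i, k] < 0:
            U[:, k] = -U[:, k]
            Vt[k, :] = -Vt[k, :]
    return U, Vt


def decompose(
    M: np.ndarray,
    column_index: list[tuple[str, str]],
    index_map: list[tuple[str, str]],
    mode: str = "symmetric",
    center: bool = False,
    rank_tol: float | None = None,
) -> MotifDecomposition:
    """Thin SVD of M truncated at numerical rank, with fixed sign convention.

    The rank cutoff keeps sigma_k > tol with
    ``tol = max(M.shape) * eps * sigma_1`` unless ``rank_tol`` overrides it.
    ``center=True`` subtracts the column mean first (PCA-style), off by
    default: the decomposition operates on raw stacked connectomes.
    An all-zero M yields a rank-0 decomposition, not an error.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] == 0:
        raise UsageError("M must be 2-D with at least one column")
    if len(column_index) != M.shape[1]:
        raise UsageError("column_index length must equal the number of columns")
    if len(index_map) != M.shape[0]:
        raise UsageError("index_map length must equal the number of features")

    column_mean = None
    if center:
        column_mean = M.mean(axis=1)
        M = M - column_mean[:, None]

    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if s.size and s[0] > 0:
        tol = rank_tol if rank_tol is not None else max(M.shape) * np.finfo(float).eps * s[0]
        rank = int(np.sum(s > tol))
    else:
        rank = 0
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank, :]
    U, Vt = _fix_signs(U, Vt)
    ev = explained_variance(s) if rank else np.zeros(0)
    return MotifDecomposition(
        motifs=U,
        singular_values=s,
        weights=Vt,
        explained_variance=ev,
        column_index=list(column_index),
        index_map=list(index_map),
        mode=mode,
        centered=center,
        column_mean=column_mean,
    )



def prevalence(
    dec: MotifDecomposition, motif: int, subject: str, scan: str
) -> float:
    """The motif's weight in one subject/scan column (the V entry)."""
    if not 0 <= motif < dec.n_motifs:
        raise UsageError(f"motif index {motif} out of range")
    return float(dec.weights[motif, dec.column(subject, scan)])


def prevalence_change(
    dec: MotifDecomposition,
    motif: int,
    subject: str,
    scans: tuple[str, str] = ("a", "b"),
) -> float:
    """Weight difference of one motif for one subject: scans[1] minus scans[0]."""
    before, after = scans
    return prevalence(dec, motif, subject, after) - prevalence(
        dec, motif, subject, before
    )


def weight_vector(
    dec: MotifDecomposition, motif: int, subjects: list[str], scan: str
) -> np.ndarray:
    """Motif weights across subjects at one scan, aligned to subject order."""
    return np.array([prevalence(dec, motif, s, scan) for s in subjects])


def weight_change_vector(
    dec: MotifDecomposition,
    motif: int,
    subjects: list[str],
    scans: tuple[str, str] = ("a", "b"),
) -> np.ndarray:
    """Per-subject motif weight change between two scans."""
    return np.array([prevalence_change(dec, motif, s, scans) for s in subjects])


def motif_as_matrix(dec: MotifDecomposition, motif: int) -> np.ndarray:
    """The motif mapped back to a signed region x region matrix.

    Symmetric-mode features are mirrored across the diagonal; the diagonal
    is zero.  Entry squares sum to 1 over the feature positions (unit-norm
    motif).
    """
    if not 0 <= motif < dec.n_motifs:
        raise UsageError(f"motif index {motif} out of range")
    return unvectorize(dec.motifs[:, motif], dec.n_regions, dec.mode)


def reconstruction_error(dec: MotifDecomposition, M: np.ndarray) -> float:
    """Relative Frobenius error of U S V^T against M over the retained rank."""
    M = np.asarray(M, dtype=float)
    if dec.centered and dec.column_mean is not None:
        M = M - dec.column_mean[:, None]
    approx = dec.motifs @ (dec.singular_values[:, None] * dec.weights)
    denom = np.linalg.norm(M)
    if denom == 0:
        return float(np.linalg.norm(approx))
    return float(np.linalg.norm(approx - M) / denom)
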