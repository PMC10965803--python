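"""The repertoire-homology (TCRhom-style) kernel between individuals.

Two individuals' repertoires R_i = {(a_ij, w_ij)} and R_i' are compared by
an abundance-weighted best-match score

    k(R_i, R_i') = [ sum_j w_ij  max_j' s(a_ij, a_i'j')
                   + sum_j' w_i'j' max_j s(a_ij, a_i'j') ]
                   / ( sum_j w_ij + sum_j' w_i'j' ),

where s(a, b) is the global (Needleman-Wunsch, affine-gap) alignment score
under BLOSUM62 or PAM250, self-normalized to s(a, a) = 1.  The n x n matrix
K of these scores is made positive semi-definite by truncating negative
eigenvalues, after which it serves as the kernel of the hidden-feature
effect h(.) in the prediction model.

Each unique sequence pair is aligned exactly once per kernel computation
(the similarity matrix over the union of unique sequences acts as the
cache), so results are independent of how clones are shared across
individuals.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from . import _align
from .repertoire_io import AMINO_ACIDS, Repertoire

SUBSTITUTION_NAMES = ("BLOSUM62", "PAM250")


@dataclasses.dataclass
class SubstitutionMatrix:
    """A 20x20 symmetric integer substitution score table."""

    name: str
    scores: np.ndarray  # indexed by AMINO_ACIDS order
    alphabet: str = AMINO_ACIDS

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self.alphabet.index(a), self.alphabet.index(b)])


def load_substitution_matrix(name: str) -> SubstitutionMatrix:
    """Load an NCBI-standard substitution matrix (BLOSUM62 or PAM250)."""
    key = name.upper()
    if key not in SUBSTITUTION_NAMES:
        raise ValueError(
            f"unknown substitution matrix {name!r}; choose from {SUBSTITUTION_NAMES}"
        )
    m = substitution_matrices.load(key)
    scores = np.empty((20, 20))
    for i, x in enumerate(AMINO_ACIDS):
        for j, y in enumerate(AMINO_ACIDS):
            scores[i, j] = m[x, y]
    return SubstitutionMatrix(key, scores)


@dataclasses.dataclass
class HomologyKernel:
    """An n x n repertoire-homology matrix with its indexing metadata."""

    values: np.ndarray
    individual_ids: list[str]
    substitution: str
    psd_projected: bool = False
    n_truncated_eigenvalues: int = 0
    min_eigenvalue: float = float("nan")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, idx) -> "HomologyKernel":
        """The principal submatrix for the given individual positions."""
        idx = np.asarray(idx)
        return HomologyKernel(
            self.values[np.ix_(idx, idx)].copy(),
            [self.individual_ids[i] for i in idx],
            self.substitution,
            self.psd_projected,
            self.n_truncated_eigenvalues,
            self.min_eigenvalue,
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.individual_ids
        )
        df.index.name = "individual_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, substitution: str = "BLOSUM62") -> "HomologyKernel":
        df = pd.read_csv(path, index_col="individual_id")
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index], substitution)


def _as_sub(sub: SubstitutionMatrix | str) -> SubstitutionMatrix:
    return load_substitution_matrix(sub) if isinstance(sub, str) else sub


def sequence_similarity(
    a: str,
    b: str,
    sub: SubstitutionMatrix | str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    normalize: bool = True,
) -> float:
    """Alignment similarity between two CDR3 sequences.

    Returns S(a,b) / sqrt(S(a,a) S(b,b)) (floored at -1) where S is the
    global affine-gap alignment score, so that s(a, a) = 1.  With
    ``normalize=False`` the raw score is returned.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    sub = _as_sub(sub)
    flat, starts, lengths = _align.pack([a, b])
    S = _align._cross_pairs(
        flat[starts[0] : starts[0] + lengths[0]], np.zeros(1, np.int64),
        lengths[:1].copy(),
        flat[starts[1] : starts[1] + lengths[1]], np.zeros(1, np.int64),
        lengths[1:].copy(),
        sub.scores, float(gap_open), float(gap_extend), normalize,
    )
    return float(S[0, 0])


def _pack_cohort(reps: Sequence[Repertoire]):
    """Map every unique sequence in the cohort to one row of the similarity
    matrix and flatten per-repertoire index/weight lists."""
    uniq: dict[str, int] = {}
    idx_chunks: list[np.ndarray] = []
    w_chunks: list[np.ndarray] = []
    for rep in reps:
        idx = np.empty(rep.n_clones, dtype=np.int64)
        for t, (seq, _) in enumerate(rep.clones):
            if seq not in uniq:
                uniq[seq] = len(uniq)
            idx[t] = uniq[seq]
        idx_chunks.append(idx)
        w_chunks.append(rep.abundances)
    seqs = [None] * len(uniq)
    for s, i in uniq.items():
        seqs[i] = s
    offsets = np.zeros(len(reps) + 1, dtype=np.int64)
    for i, c in enumerate(idx_chunks):
        offsets[i + 1] = offsets[i] + len(c)
    idx_flat = np.concatenate(idx_chunks) if idx_chunks else np.empty(0, np.int64)
    w_flat = np.concatenate(w_chunks) if w_chunks else np.empty(0)
    return seqs, idx_flat, offsets, w_flat


def repertoire_homology(
    ri: Repertoire,
    rj: Repertoire,
    sub: SubstitutionMatrix | str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    normalize: bool = True,
) -> float:
    """Abundance-weighted best-match homology between two repertoires."""
    K = kernel_cross([ri], [rj], sub, gap_open, gap_extend, normalize)
    return float(K[0, 0])


def kernel_matrix(
    reps: Sequence[Repertoire],
    sub: SubstitutionMatrix | str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    normalize: bool = True,
) -> HomologyKernel:
    """Symmetric homology matrix over a cohort, in the given order.

    Entries are computed for i <= j and mirrored.  Under self-normalized
    similarity the diagonal is exactly 1.
    """
    if len(reps) < 2:
        raise ValueError("kernel_matrix needs at least 2 repertoires")
    sub = _as_sub(sub)
    seqs, idx_flat, offsets, w_flat = _pack_cohort(reps)
    flat, starts, lengths = _align.pack(seqs)
    S = _align._all_pairs(
        flat, starts, lengths, sub.scores, float(gap_open), float(gap_extend),
        normalize,
    )
    K = _align._assemble_kernel(S, idx_flat, offsets, w_flat, len(reps))
    return HomologyKernel(K, [r.individual_id for r in reps], sub.name)


def kernel_cross(
    reps_new: Sequence[Repertoire],
    reps_train: Sequence[Repertoire],
    sub: SubstitutionMatrix | str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    normalize: bool = True,
) -> np.ndarray:
    """n_new x n_train homology matrix between new and training individuals.

    Cross terms are raw homologies; no PSD projection is applied (projection
    is a training-set operation).
    """
    sub = _as_sub(sub)
    seqs_a, idx_a, off_a, w_a = _pack_cohort(reps_new)
    seqs_b, idx_b, off_b, w_b = _pack_cohort(reps_train)
    flat_a, st_a, ln_a = _align.pack(seqs_a)
    flat_b, st_b, ln_b = _align.pack(seqs_b)
    S = _align._cross_pairs(
        flat_a, st_a, ln_a, flat_b, st_b, ln_b,
        sub.scores, float(gap_open), float(gap_extend), normalize,
    )
    return _align._assemble_cross(
        S, idx_a, off_a, w_a, idx_b, off_b, w_b, len(reps_new), len(reps_train)
    )


def psd_project(K: HomologyKernel) -> HomologyKernel:
    """Project a symmetric homology matrix onto the PSD cone.

    Eigendecompose K = U diag(lambda) U^T and zero out negative eigenvalues
    (hard truncation, i.e. the Frobenius-nearest PSD matrix).  The number of
    truncated eigenvalues and the most negative one are recorded.
    """
    A = K.values
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("kernel matrix is not symmetric")
    lam, U = np.linalg.eigh((A + A.T) / 2.0)
    min_eig = float(lam.min())
    n_neg = int((lam < 0).sum())
    lam_clip = np.clip(lam, 0.0, None)
    P = (U * lam_clip) @ U.T
    P = (P + P.T) / 2.0
    return HomologyKernel(
        P,
        list(K.individual_ids),
        K.substitution,
        psd_projected=True,
        n_truncated_eigenvalues=n_neg,
        min_eigenvalue=min_eig,
    )
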