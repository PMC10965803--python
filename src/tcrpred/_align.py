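"""Numba-compiled global alignment scoring (Gotoh, affine gaps).

The homology kernel needs millions of pairwise CDR3 alignment scores per
matrix, so the dynamic program is compiled with numba and driven in batch
from a single compiled loop.  The scoring convention matches Biopython's
``PairwiseAligner`` with ``open_gap_score=-gap_open`` and
``extend_gap_score=-gap_extend``: the first residue of a gap costs
``gap_open``, each further residue ``gap_extend``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .repertoire_io import AMINO_ACIDS

_AA_INDEX = {c: i for i, c in enumerate(AMINO_ACIDS)}

_NEG = -1e18


def encode(seq: str) -> np.ndarray:
    """Encode an amino-acid string as int8 alphabet indices."""
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(
            f"invalid amino-acid character {exc.args[0]!r} in sequence {seq!r}"
        ) from None


def pack(seqs: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate encoded sequences into (flat, starts, lengths) arrays."""
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(np.int64)
    flat = np.empty(int(lengths.sum()), dtype=np.int8)
    for s, st, ln in zip(seqs, starts, lengths):
        flat[st : st + ln] = encode(s)
    return flat, starts, lengths


@njit(fastmath=False)
def _nw(flat_a, sa, la, flat_b, sb, lb, sub, gap_open, gap_extend, M, Ix, Iy, Mp, Ixp, Iyp):
    # Gotoh with three states over two rolling rows; returns the global score.
    Mp[0] = 0.0
    Ixp[0] = _NEG
    Iyp[0] = _NEG
    for j in range(1, lb + 1):
        Mp[j] = _NEG
        Ixp[j] = _NEG
        Iyp[j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, la + 1):
        M[0] = _NEG
        Iy[0] = _NEG
        Ix[0] = -gap_open - (i - 1) * gap_extend
        ai = flat_a[sa + i - 1]
        for j in range(1, lb + 1):
            s = sub[ai, flat_b[sb + j - 1]]
            best = Mp[j - 1]
            if Ixp[j - 1] > best:
                best = Ixp[j - 1]
            if Iyp[j - 1] > best:
                best = Iyp[j - 1]
            M[j] = best + s
            v = Mp[j] - gap_open
            if Ixp[j] - gap_extend > v:
                v = Ixp[j] - gap_extend
            if Iyp[j] - gap_open > v:
                v = Iyp[j] - gap_open
            Ix[j] = v
            h = M[j - 1] - gap_open
            if Iy[j - 1] - gap_extend > h:
                h = Iy[j - 1] - gap_extend
            if Ix[j - 1] - gap_open > h:
                h = Ix[j - 1] - gap_open
            Iy[j] = h
        for j in range(lb + 1):
            Mp[j], M[j] = M[j], Mp[j]
            Ixp[j], Ix[j] = Ix[j], Ixp[j]
            Iyp[j], Iy[j] = Iy[j], Iyp[j]
    best = Mp[lb]
    if Ixp[lb] > best:
        best = Ixp[lb]
    if Iyp[lb] > best:
        best = Iyp[lb]
    return best


@njit
def _self_scores(flat, starts, lengths, sub, gap_open, gap_extend):
    u = starts.shape[0]
    maxlen = 0
    for i in range(u):
        if lengths[i] > maxlen:
            maxlen = lengths[i]
    M = np.empty(maxlen + 1)
    Ix = np.empty(maxlen + 1)
    Iy = np.empty(maxlen + 1)
    Mp = np.empty(maxlen + 1)
    Ixp = np.empty(maxlen + 1)
    Iyp = np.empty(maxlen + 1)
    out = np.empty(u)
    for i in range(u):
        out[i] = _nw(
            flat, starts[i], lengths[i], flat, starts[i], lengths[i],
            sub, gap_open, gap_extend, M, Ix, Iy, Mp, Ixp, Iyp,
        )
    return out


@njit
def _all_pairs(flat, starts, lengths, sub, gap_open, gap_extend, normalize):
    """Dense u x u matrix of (optionally self-normalized) alignment scores."""
    u = starts.shape[0]
    maxlen = 0
    for i in range(u):
        if lengths[i] > maxlen:
            maxlen = lengths[i]
    M = np.empty(maxlen + 1)
    Ix = np.empty(maxlen + 1)
    Iy = np.empty(maxlen + 1)
    Mp = np.empty(maxlen + 1)
    Ixp = np.empty(maxlen + 1)
    Iyp = np.empty(maxlen + 1)
    self_sc = _self_scores(flat, starts, lengths, sub, gap_open, gap_extend)
    S = np.empty((u, u))
    for i in range(u):
        S[i, i] = 1.0 if normalize else self_sc[i]
        for j in range(i + 1, u):
            sc = _nw(
                flat, starts[i], lengths[i], flat, starts[j], lengths[j],
                sub, gap_open, gap_extend, M, Ix, Iy, Mp, Ixp, Iyp,
            )
            if normalize:
                sc = sc / np.sqrt(self_sc[i] * self_sc[j])
                if sc < -1.0:
                    sc = -1.0
            S[i, j] = sc
            S[j, i] = sc
    return S


@njit
def _cross_pairs(
    flat_a, starts_a, lengths_a, flat_b, starts_b, lengths_b,
    sub, gap_open, gap_extend, normalize,
):
    ua = starts_a.shape[0]
    ub = starts_b.shape[0]
    maxlen = 1
    for i in range(ua):
        if lengths_a[i] > maxlen:
            maxlen = lengths_a[i]
    for j in range(ub):
        if lengths_b[j] > maxlen:
            maxlen = lengths_b[j]
    M = np.empty(maxlen + 1)
    Ix = np.empty(maxlen + 1)
    Iy = np.empty(maxlen + 1)
    Mp = np.empty(maxlen + 1)
    Ixp = np.empty(maxlen + 1)
    Iyp = np.empty(maxlen + 1)
    self_a = _self_scores(flat_a, starts_a, lengths_a, sub, gap_open, gap_extend)
    self_b = _self_scores(flat_b, starts_b, lengths_b, sub, gap_open, gap_extend)
    S = np.empty((ua, ub))
    for i in range(ua):
        for j in range(ub):
            sc = _nw(
                flat_a, starts_a[i], lengths_a[i],
                flat_b, starts_b[j], lengths_b[j],
                sub, gap_open, gap_extend, M, Ix, Iy, Mp, Ixp, Iyp,
            )
            if normalize:
                sc = sc / np.sqrt(self_a[i] * self_b[j])
                if sc < -1.0:
                    sc = -1.0
            S[i, j] = sc
    return S


@njit
def _assemble_kernel(S, idx_flat, offsets, w_flat, n):
    """Abundance-weighted best-match homology for every repertoire pair.

    ``idx_flat[offsets[i]:offsets[i+1]]`` are individual i's rows in S and
    ``w_flat`` the matching abundances.
    """
    K = np.empty((n, n))
    for i in range(n):
        ia, ib = offsets[i], offsets[i + 1]
        wi = 0.0
        for a in range(ia, ib):
            wi += w_flat[a]
        for j in range(i, n):
            ja, jb = offsets[j], offsets[j + 1]
            wj = 0.0
            num = 0.0
            for a in range(ia, ib):
                best = _NEG
                ra = idx_flat[a]
                for b in range(ja, jb):
                    v = S[ra, idx_flat[b]]
                    if v > best:
                        best = v
                num += w_flat[a] * best
            for b in range(ja, jb):
                best = _NEG
                rb = idx_flat[b]
                for a in range(ia, ib):
                    v = S[idx_flat[a], rb]
                    if v > best:
                        best = v
                num += w_flat[b] * best
                wj += w_flat[b]
            val = num / (wi + wj)
            K[i, j] = val
            K[j, i] = val
    return K


@njit
def _assemble_cross(S, idx_a, off_a, w_a, idx_b, off_b, w_b, na, nb):
    K = np.empty((na, nb))
    for i in range(na):
        ia, ib = off_a[i], off_a[i + 1]
        wi = 0.0
        for a in range(ia, ib):
            wi += w_a[a]
        for j in range(nb):
            ja, jb = off_b[j], off_b[j + 1]
            wj = 0.0
            num = 0.0
            for a in range(ia, ib):
                best = _NEG
                ra = idx_a[a]
                for b in range(ja, jb):
                    v = S[ra, idx_b[b]]
                    if v > best:
                        best = v
                num += w_a[a] * best
            for b in range(ja, jb):
                best = _NEG
                rb = idx_b[b]
                for a in range(ia, ib):
                    v = S[idx_a[a], rb]
                    if v > best:
                        best = v
                num += w_b[b] * best
                wj += w_b[b]
            K[i, j] = num / (wi + wj)
    return K
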