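"""Extracted-feature matrix Z: k-mer counting, scaling, filtering, screening.

The explicit part of the repertoire signal is represented by contiguous
amino-acid k-mers aggregated over all CDR3 sequences of an individual,
analogous to k-gram counts in text classification.  With a 20-letter
alphabet the raw dimension is 20^k, so the pipeline is

    count -> 0.75-quantile column scaling -> 5% prevalence filter
          -> sure-independence screening to ~ n / (2 ln n) columns.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

from .repertoire_io import Repertoire


class FeatureError(Exception):
    pass


@dataclasses.dataclass
class FeatureMatrix:
    """n x p matrix of named non-negative repertoire features.

    ``scale_factors`` records the per-column divisors applied by
    :func:`quantile_scale` (``None`` before scaling), so that scaling can be
    undone and new individuals can be scored on the training scale.
    """

    values: np.ndarray
    feature_names: list[str]
    individual_ids: list[str]
    k: int
    scale_factors: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.feature_names
        )

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "individual_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, k: int = 0) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="individual_id")
        k = k or (len(df.columns[0]) if len(df.columns) else 0)
        return cls(
            df.to_numpy(dtype=float),
            [str(c) for c in df.columns],
            [str(i) for i in df.index],
            k,
        )

    def subset_rows(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.values[idx],
            list(self.feature_names),
            [self.individual_ids[i] for i in idx],
            self.k,
            self.scale_factors,
        )

    def subset_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        pos = {c: j for j, c in enumerate(self.feature_names)}
        idx = [pos[c] for c in names]
        sf = None if self.scale_factors is None else self.scale_factors[idx]
        return FeatureMatrix(
            self.values[:, idx].copy(), list(names), list(self.individual_ids),
            self.k, sf,
        )


def extract_kmers(
    rep: Repertoire, k: int, weight_by_abundance: bool = True
) -> dict[str, float]:
    """Count the contiguous k-mers of one repertoire.

    A sequence of length L contributes its L-k+1 sliding windows (none if
    L < k).  With ``weight_by_abundance`` each occurrence counts the clone's
    abundance; otherwise each occurrence counts 1.
    """
    if not 1 <= k <= 10:
        raise ValueError(f"k must be in 1..10, got {k}")
    counts: Counter[str] = Counter()
    for seq, w in rep.clones:
        mult = w if weight_by_abundance else 1.0
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += mult
    return dict(counts)


def build_feature_matrix(
    reps: Sequence[Repertoire], k: int, weight_by_abundance: bool = True
) -> FeatureMatrix:
    """Aggregate k-mer counts into the n x p matrix Z.

    Columns are the union of observed k-mers, sorted lexicographically; a
    k-mer absent from an individual scores 0.
    """
    if not reps:
        raise FeatureError("need at least one repertoire")
    per_rep = [extract_kmers(r, k, weight_by_abundance) for r in reps]
    names = sorted(set().union(*per_rep))
    if not names:
        raise FeatureError(
            f"no k-mers observed at k={k}: all sequences shorter than k"
        )
    col = {c: j for j, c in enumerate(names)}
    Z = np.zeros((len(reps), len(names)))
    for i, counts in enumerate(per_rep):
        for km, v in counts.items():
            Z[i, col[km]] = v
    return FeatureMatrix(Z, names, [r.individual_id for r in reps], k)


def quantile_scale(
    fm: FeatureMatrix, q: float = 0.75, nonzero_only: bool = False
) -> FeatureMatrix:
    """Divide each column by its q-quantile (type-7, linear interpolation).

    With ``nonzero_only`` the quantile is taken over the non-zero entries of
    the column (the convention for sparse real-data matrices); otherwise over
    all entries.  Degenerate columns fall back to division by the column max,
    and to 1 if the column is identically zero.  The applied factors are
    recorded on the result.
    """
    Z = fm.values
    scales = np.ones(fm.p)
    for j in range(fm.p):
        col = Z[:, j]
        vals = col[col != 0] if nonzero_only else col
        s = float(np.quantile(vals, q)) if vals.size else 0.0
        if s <= 0:
            s = float(col.max()) if col.size else 0.0
        if s <= 0:
            s = 1.0
        scales[j] = s
    return FeatureMatrix(
        Z / scales, list(fm.feature_names), list(fm.individual_ids), fm.k, scales
    )


def prevalence_filter(fm: FeatureMatrix, min_prevalence: float = 0.05) -> FeatureMatrix:
    """Keep columns non-zero in at least ``min_prevalence`` of individuals."""
    frac = (fm.values != 0).mean(axis=0)
    keep = frac >= min_prevalence
    if not keep.any():
        raise FeatureError(
            f"prevalence filter at {min_prevalence} removed every column; "
            "lower the threshold"
        )
    names = [c for c, k_ in zip(fm.feature_names, keep) if k_]
    sf = None if fm.scale_factors is None else fm.scale_factors[keep]
    return FeatureMatrix(
        fm.values[:, keep].copy(), names, list(fm.individual_ids), fm.k, sf
    )


def sis_dimension(n: int) -> int:
    """Default screening dimension: floor(n / (2 ln n))."""
    return int(math.floor(n / (2.0 * math.log(n))))


def sis_screen(fm: FeatureMatrix, y: np.ndarray, d: int | None = None) -> FeatureMatrix:
    """Sure-independence screening: keep the d columns with the largest
    absolute Pearson correlation with the outcome.

    Binary outcomes are treated as 0/1 numerics.  Zero-variance columns get
    correlation 0 (ranked last); ties break lexicographically by name.
    """
    y = np.asarray(y, dtype=float)
    n = fm.n
    if d is None:
        d = sis_dimension(n)
    if d < 1:
        raise ValueError("screening dimension d must be >= 1")
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    Zc = fm.values - fm.values.mean(axis=0)
    sz = np.sqrt((Zc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.abs(Zc.T @ yc) / (sz * sy)
    corr[~np.isfinite(corr)] = 0.0
    order = sorted(range(fm.p), key=lambda j: (-corr[j], fm.feature_names[j]))
    keep = sorted(order[: min(d, fm.p)], key=lambda j: fm.feature_names[j])
    names = [fm.feature_names[j] for j in keep]
    sf = None if fm.scale_factors is None else fm.scale_factors[keep]
    return FeatureMatrix(
        fm.values[:, keep].copy(), names, list(fm.individual_ids), fm.k, sf
    )
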