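"""Reading, validation and filtering of TCR repertoires and covariate tables.

A *repertoire* is one individual's collection of unique CDR3 amino-acid
sequences together with their clonal abundances.  This module is the single
source of truth for the :class:`Repertoire` data model used everywhere else:
feature extraction, the homology kernel, and the simulation harness all
consume the objects produced here.

Two on-disk dialects are supported:

* a simple CSV with columns ``individual_id,sequence,abundance`` (several
  individuals per file), and
* AIRR-style rearrangement TSV with one file-wide table whose CDR3
  amino-acid column and clone-count column default to the AIRR-C schema
  names ``junction_aa`` / ``duplicate_count`` (overridable).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The 20 standard amino-acid one-letter codes (alphabetical).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class RepertoireError(Exception):
    """Base class for repertoire data errors."""


class RepertoireFormatError(RepertoireError):
    """A repertoire or covariate file does not conform to its dialect."""


class CohortError(RepertoireError):
    """Cohort-level inconsistency (e.g. empty repertoire/covariate overlap)."""


@dataclasses.dataclass
class Repertoire:
    """One individual's TCR repertoire.

    Parameters
    ----------
    individual_id :
        Unique identifier of the individual.
    clones :
        Ordered list of ``(sequence, abundance)`` pairs.  Sequences are
        unique within a repertoire; abundances are positive.
    """

    individual_id: str
    clones: list[tuple[str, float]]

    @property
    def sequences(self) -> list[str]:
        return [s for s, _ in self.clones]

    @property
    def abundances(self) -> np.ndarray:
        return np.asarray([w for _, w in self.clones], dtype=float)

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.clones)


@dataclasses.dataclass
class FilterReport:
    """Counts of what :func:`filter_repertoires` removed, per rule."""

    clones_low_abundance: int = 0
    clones_bad_alphabet: int = 0
    individuals_too_few_clones: int = 0
    individuals_in: int = 0
    individuals_out: int = 0


@dataclasses.dataclass
class CovariateTable:
    """Per-individual outcome and adjusting covariates.

    ``table`` is indexed by ``individual_id``; ``outcome_col`` names the
    outcome column Y and every remaining column is an adjusting variable.
    """

    table: pd.DataFrame
    outcome_col: str

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.table.index]

    @property
    def y(self) -> np.ndarray:
        return self.table[self.outcome_col].to_numpy(dtype=float)

    @property
    def X(self) -> pd.DataFrame:
        return self.table.drop(columns=[self.outcome_col])

    @property
    def covariate_names(self) -> list[str]:
        return list(self.X.columns)


def _is_valid_sequence(seq: str) -> bool:
    return len(seq) > 0 and all(c in _AA_SET for c in seq)


def read_repertoires(
    path,
    format: str = "csv",
    airr_seq_col: str = "junction_aa",
    airr_count_col: str = "duplicate_count",
    airr_id_col: str = "repertoire_id",
) -> list[Repertoire]:
    """Read repertoires from a CSV or AIRR rearrangement TSV file.

    Abundances of duplicate ``(individual, sequence)`` rows are summed.
    Returns one :class:`Repertoire` per distinct individual, in file order
    of first appearance.
    """
    if format == "csv":
        df = pd.read_csv(path, dtype={0: str})
        required = ["individual_id", "sequence", "abundance"]
        id_col, seq_col, count_col = required
    elif format == "airr":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = [airr_id_col, airr_seq_col, airr_count_col]
        id_col, seq_col, count_col = required
    else:
        raise ValueError(f"unknown repertoire format: {format!r}")

    for col in required:
        if col not in df.columns:
            raise RepertoireFormatError(
                f"{path}: missing required column {col!r} "
                f"(found: {list(df.columns)})"
            )
    if df.empty:
        return []

    counts = np.empty(len(df), dtype=float)
    raw = df[count_col].to_numpy()
    for i, v in enumerate(raw):
        try:
            fv = float(v)
        except (TypeError, ValueError):
            raise RepertoireFormatError(
                f"{path}: non-numeric abundance {v!r} at data row {i + 1}"
            ) from None
        if not float(fv).is_integer():
            raise RepertoireFormatError(
                f"{path}: non-integer abundance {v!r} at data row {i + 1}"
            )
        counts[i] = fv

    out: list[Repertoire] = []
    ids = df[id_col].astype(str).to_numpy()
    seqs = df[seq_col].astype(str).to_numpy()
    order: dict[str, dict[str, float]] = {}
    for ind, seq, w in zip(ids, seqs, counts):
        clones = order.setdefault(ind, {})
        clones[seq] = clones.get(seq, 0.0) + w
    for ind, clones in order.items():
        out.append(Repertoire(ind, [(s, w) for s, w in clones.items()]))
    return out


def write_repertoires(reps: Iterable[Repertoire], path) -> None:
    """Write repertoires in the simple CSV dialect (round-trips with
    ``read_repertoires(..., format='csv')``)."""
    rows = [
        {"individual_id": r.individual_id, "sequence": s, "abundance": int(w)}
        for r in reps
        for s, w in r.clones
    ]
    pd.DataFrame(rows, columns=["individual_id", "sequence", "abundance"]).to_csv(
        path, index=False
    )


def filter_repertoires(
    reps: Sequence[Repertoire],
    min_abundance: int = 2,
    min_unique_sequences: int = 2,
) -> tuple[list[Repertoire], FilterReport]:
    """Apply the standard repertoire cleaning rules.

    Clones with abundance below ``min_abundance`` or containing any character
    outside the 20 standard amino-acid letters are removed; individuals left
    with fewer than ``min_unique_sequences`` clones are dropped entirely.
    Filtering never raises; everything removed is tallied in the report.
    """
    report = FilterReport(individuals_in=len(reps))
    kept: list[Repertoire] = []
    for rep in reps:
        clones = []
        for seq, w in rep.clones:
            if not _is_valid_sequence(seq):
                report.clones_bad_alphabet += 1
            elif w < min_abundance:
                report.clones_low_abundance += 1
            else:
                clones.append((seq, w))
        if len(clones) < min_unique_sequences:
            report.individuals_too_few_clones += 1
        else:
            kept.append(Repertoire(rep.individual_id, clones))
    report.individuals_out = len(kept)
    return kept, report


def read_covariates(
    path, id_col: str = "individual_id", outcome_col: str = "outcome"
) -> CovariateTable:
    """Read a covariate/phenotype CSV: one row per individual, one outcome
    column, remaining columns = adjusting variables."""
    df = pd.read_csv(path, dtype={id_col: str})
    for col in (id_col, outcome_col):
        if col not in df.columns:
            raise RepertoireFormatError(
                f"{path}: missing required column {col!r}"
            )
    df = df.set_index(id_col)
    df.index = df.index.astype(str)
    return CovariateTable(df, outcome_col)


def align_cohort(
    reps: Sequence[Repertoire], cov: CovariateTable
) -> tuple[list[Repertoire], CovariateTable]:
    """Restrict repertoires and covariates to their common individuals.

    Individuals with any missing covariate or outcome are dropped first.
    Both outputs come back in the canonical order (lexicographic by
    ``individual_id``), which indexes every downstream matrix (Z, K).
    """
    complete = cov.table.dropna(axis=0, how="any")
    by_id = {r.individual_id: r for r in reps}
    common = sorted(set(by_id) & set(str(i) for i in complete.index))
    if not common:
        raise CohortError(
            "no individuals shared between repertoires and complete covariate rows"
        )
    reps_out = [by_id[i] for i in common]
    cov_out = CovariateTable(complete.loc[common].copy(), cov.outcome_col)
    return reps_out, cov_out


def canonical_order(reps: Sequence[Repertoire]) -> list[Repertoire]:
    """Sort repertoires into the canonical (lexicographic-id) order."""
    return sorted(reps, key=lambda r: r.individual_id)
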