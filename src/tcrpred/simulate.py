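"""Synthetic repertoire pools and the outcome-generation benchmark harness.

The generator produces CDR3-like beta-chain repertoires — length-variable
strings over the 20 amino acids that begin with C and end with F, with a
skewed interior residue usage and Zipf-distributed clonal abundances — so
that the whole pipeline (filtering, features, kernel, model, baselines) can
be exercised without any external sequencing data.  The pool only emulates
the statistical structure the method consumes; it is not a V(D)J
recombination model.

On top of a pool, :func:`simulate_dataset` draws outcomes from the
semi-parametric generative model

    eta_i = beta0 + beta1 X_i1 + Z_i' gamma + h(R_i),
    h ~ N(0, tau K),    (K the PSD-projected homology matrix)

with the six most frequent k-mers as causal features (gamma_j ~ c0 U(-1,1)),
continuous Y = eta + N(0, sigma^2) or binary Y ~ Bernoulli(logistic(eta))
with replicates kept only when the case proportion lies in (0.3, 0.7).
:func:`run_benchmark` replicates the design and compares TCRpred against
the covariate-only GLM and the penalized-regression baselines.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import baselines as bl
from . import kmer_features as kf
from . import model as md
from .homology_kernel import HomologyKernel, kernel_matrix, psd_project
from .repertoire_io import Repertoire, filter_repertoires
from ._penalized import sigmoid

#: Interior-residue sampling weights (synthetic; loosely mimics the skewed
#: residue usage of beta-chain CDR3 loops, glycine/serine-rich).
_RESIDUE_FREQS = {
    "A": 0.055, "C": 0.010, "D": 0.040, "E": 0.050, "F": 0.035,
    "G": 0.110, "H": 0.020, "I": 0.030, "K": 0.030, "L": 0.065,
    "M": 0.010, "N": 0.040, "P": 0.045, "Q": 0.055, "R": 0.065,
    "S": 0.120, "T": 0.070, "V": 0.045, "W": 0.015, "Y": 0.090,
}

METHODS = ("basic_glm", "tcr_lasso", "tcr_ridge", "tcrpred_B", "tcrpred_P")


class SimulationError(Exception):
    pass


@dataclasses.dataclass
class SyntheticPoolSpec:
    """Shape of the synthetic repertoire pool.

    Three features of real beta-chain repertoires shape what the pipeline
    can extract from a cohort, and each is emulated here:

    * **Conserved V/J motifs.**  Real CDR3s begin with a V-segment-encoded
      motif (CASS...) and end with a J-segment motif (...QYF); every clone
      carries one of each, so motif k-mers are the *most frequent* k-mers
      and are present in every individual, while V/J usage proportions vary
      between individuals.  Each clone draws its prefix from ``v_motifs``
      and suffix from ``j_motifs`` according to individual-specific usage
      drawn from a Dirichlet with concentration ``usage_concentration``.
    * **Public clonotype clusters.**  Public clones recur across
      individuals with shared HLA background or antigen exposure and
      cluster into sequence-similar convergent families.  Latent
      *archetypes* own slices of the public library (``motifs_per_archetype``
      ancestors plus near point-mutants each); an individual belongs to one
      archetype and takes a fraction ``public_fraction`` of its clones from
      its archetype's library.  The archetype blocks give the homology
      matrix the low-rank structure the kernel model consumes, while the
      aggregate k-mer composition of different archetypes stays alike, so
      the hidden-effect channel is not trivially readable from the
      extracted features.
    * **Skewed clonal abundances.**  Clone sizes follow a truncated Zipf
      law (``abundance_zipf``, capped at ``abundance_cap``), floored at 2.

    Private (non-public) sequences use a personal interior residue profile
    (Dirichlet with concentration ``profile_concentration`` around the
    archetype profile, which by default equals the base CDR3 usage).
    """

    n_individuals: int = 1000
    clones_per_individual: tuple[int, int] = (10, 60)
    cdr3_length: tuple[int, int] = (8, 20)
    abundance_zipf: float = 1.5
    abundance_cap: int = 100
    v_motifs: tuple[str, ...] = ("CAS", "CGS", "CVS", "CLS", "CIS", "CPS")
    j_motifs: tuple[str, ...] = ("QYF", "EQF", "AFF", "QHF", "EAF", "TQF")
    usage_concentration: float = 1.6
    n_archetypes: int = 8
    archetype_concentration: float = 1e6
    profile_concentration: float = 60.0
    public_fraction: float = 0.55
    public_library_size: int = 96
    motifs_per_archetype: int = 3


#: A reduced pool for desk-scale experiments and tests.
DESK_POOL_SPEC = SyntheticPoolSpec(
    n_individuals=800, clones_per_individual=(15, 25), cdr3_length=(9, 14),
    abundance_cap=20, n_archetypes=24, public_library_size=24 * 14,
    public_fraction=0.6,
)


@dataclasses.dataclass
class SimulationConfig:
    """All generative parameters of one benchmark setting."""

    n_train: int = 500
    n_test: int = 500
    k: int = 3
    c0: float = 5.0
    tau: float = 5.0
    substitution: str = "BLOSUM62"
    outcome_type: str = "binary"
    n_causal: int = 6
    beta0: float = 2.0
    beta1: float = -1.0
    n_replicates: int = 500
    seed: int = 0
    case_prop_bounds: tuple[float, float] = (0.3, 0.7)
    continuous_noise_sd: float = 1.0
    rank_pre_scaling: bool = True
    max_redraws: int = 100


@dataclasses.dataclass
class SimulatedDataset:
    """One replicate: repertoires, covariate, outcome and the ground truth."""

    reps: list[Repertoire]
    X: np.ndarray  # n x 1
    y: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    Z: kf.FeatureMatrix  # joint, quantile-scaled
    K_raw: HomologyKernel  # joint, unprojected
    K_proj: HomologyKernel
    causal_features: list[str]
    gamma: np.ndarray
    h: np.ndarray
    eta: np.ndarray
    outcome_type: str


def generate_pool(
    spec: SyntheticPoolSpec = SyntheticPoolSpec(), seed: int = 0
) -> list[Repertoire]:
    """Generate a reproducible pool of CDR3-like repertoires.

    All sequences within an individual are unique and pass the standard
    filtering rules by construction (valid alphabet, abundance >= 2).
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(_RESIDUE_FREQS))
    base = np.array(list(_RESIDUE_FREQS.values()))
    base = base / base.sum()
    lo_c, hi_c = spec.clones_per_individual
    lo_l, hi_l = spec.cdr3_length
    nv, nj = len(spec.v_motifs), len(spec.j_motifs)
    fixed = max(len(v) for v in spec.v_motifs) + max(len(j) for j in spec.j_motifs)
    if lo_l <= fixed:
        raise SimulationError("cdr3_length too short for the V/J motifs")

    def draw_interior(p):
        L = int(rng.integers(lo_l, hi_l + 1))
        return "".join(rng.choice(letters, size=max(1, L - fixed), p=p))

    def draw_seq(p, v_usage, j_usage):
        v = spec.v_motifs[int(rng.choice(nv, p=v_usage))]
        j = spec.j_motifs[int(rng.choice(nj, p=j_usage))]
        return v + draw_interior(p) + j

    n_arch = max(1, spec.n_archetypes)
    arch_profiles = [
        rng.dirichlet(spec.archetype_concentration * base) for _ in range(n_arch)
    ]
    per_arch = max(1, spec.public_library_size // n_arch)

    def mutate(body: str, d: int) -> str:
        chars = list(body)
        for pos in rng.choice(len(chars), size=min(d, len(chars)), replace=False):
            chars[pos] = str(rng.choice(letters, p=base))
        return "".join(chars)

    # Public sequences form convergent motif families: a few ancestor
    # interiors per archetype plus near point-mutants.  V/J motifs are
    # assigned cyclically so that every archetype's library has the same
    # V/J composition — archetype identity lives in the interiors (which
    # the alignment kernel sees), not in the motif-usage counts (which the
    # k-mer features see).
    arch_library = []
    for a in range(n_arch):
        ancestors = [
            draw_interior(arch_profiles[a]) for _ in range(spec.motifs_per_archetype)
        ]
        lib = [
            spec.v_motifs[e % nv]
            + mutate(ancestors[e % len(ancestors)], int(rng.integers(3)))
            + spec.j_motifs[(e // nv + e) % nj]
            for e in range(per_arch)
        ]
        arch_library.append(lib)
    width = len(str(spec.n_individuals))
    pool: list[Repertoire] = []
    for i in range(spec.n_individuals):
        m = int(rng.integers(lo_c, hi_c + 1))
        a = int(rng.integers(n_arch))
        profile = rng.dirichlet(spec.profile_concentration * arch_profiles[a])
        v_usage = rng.dirichlet(np.full(nv, spec.usage_concentration))
        j_usage = rng.dirichlet(np.full(nj, spec.usage_concentration))
        library = arch_library[a]
        seqs: set[str] = set()
        tries = 0
        while len(seqs) < m:
            tries += 1
            if tries > 100 * m:
                raise SimulationError(
                    "cannot generate enough unique sequences; "
                    "enlarge cdr3_length or reduce clone counts"
                )
            if library and rng.random() < spec.public_fraction:
                seqs.add(library[int(rng.integers(len(library)))])
            else:
                seqs.add(draw_seq(profile, v_usage, j_usage))
        abund = np.minimum(rng.zipf(spec.abundance_zipf, size=m) + 1, spec.abundance_cap)
        clones = [(s, float(w)) for s, w in zip(sorted(seqs), abund)]
        pool.append(Repertoire(f"SYN{i:0{width}d}", clones))
    return pool


def _draw_hidden(lam: np.ndarray, U: np.ndarray, tau: float, rng) -> np.ndarray:
    z = rng.standard_normal(len(lam))
    return U @ (np.sqrt(np.clip(lam, 0.0, None) * tau) * z)


def simulate_dataset(
    cfg: SimulationConfig,
    pool: Sequence[Repertoire],
    seed: int | np.random.Generator = 0,
) -> SimulatedDataset:
    """Draw one train/test replicate from the generative model.

    Repertoires are sampled from the pool without replacement; Z and K are
    built jointly over train+test (the hidden effect must exist on the test
    side for evaluation).  For a binary outcome, (X, gamma, h, Y) are
    redrawn — keeping the sampled repertoires and kernel — until the case
    proportion falls inside ``cfg.case_prop_bounds``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = cfg.n_train + cfg.n_test
    if len(pool) < n:
        raise SimulationError(f"pool of {len(pool)} too small for n={n}")
    pick = rng.choice(len(pool), size=n, replace=False)
    reps = [pool[i] for i in pick]
    idx = np.arange(n)
    train_idx, test_idx = idx[: cfg.n_train], idx[cfg.n_train :]

    Z_raw = kf.build_feature_matrix(reps, cfg.k)
    Z = kf.quantile_scale(Z_raw, 0.75, nonzero_only=False)
    rank_src = Z_raw if cfg.rank_pre_scaling else Z
    colsum = rank_src.values.sum(axis=0)
    order = sorted(range(Z.p), key=lambda j: (-colsum[j], Z.feature_names[j]))
    causal_idx = order[: cfg.n_causal]
    causal = [Z.feature_names[j] for j in causal_idx]
    Zc = Z.values[:, causal_idx]

    K_raw = kernel_matrix(reps, cfg.substitution)
    K_proj = psd_project(K_raw)
    lam, U = np.linalg.eigh(K_proj.values)

    for attempt in range(cfg.max_redraws):
        X1 = rng.standard_normal(n)
        gamma = cfg.c0 * rng.uniform(-1.0, 1.0, size=cfg.n_causal)
        h = _draw_hidden(lam, U, cfg.tau, rng)
        eta = cfg.beta0 + cfg.beta1 * X1 + Zc @ gamma + h
        if cfg.outcome_type == "continuous":
            y = eta + rng.normal(0.0, cfg.continuous_noise_sd, size=n)
            break
        y = rng.binomial(1, sigmoid(eta)).astype(float)
        lo, hi = cfg.case_prop_bounds
        if lo <= y.mean() <= hi:
            break
    else:
        raise SimulationError(
            f"case proportion outside {cfg.case_prop_bounds} after "
            f"{cfg.max_redraws} redraws; adjust beta0/c0/tau"
        )
    return SimulatedDataset(
        reps, X1[:, None], y, train_idx, test_idx, Z, K_raw, K_proj,
        causal, gamma, h, eta, cfg.outcome_type,
    )


def export_dataset(data: SimulatedDataset, directory) -> dict[str, str]:
    """Write one simulated replicate as re-ingestable CSV files.

    Produces ``repertoires.csv`` (simple repertoire dialect),
    ``covariates.csv`` (individual_id, outcome, x1) and ``truth.csv``
    (per-individual hidden effect and linear predictor, with the causal
    k-mers and their coefficients in the header comment columns).
    Returns the mapping of file roles to paths.
    """
    import os

    os.makedirs(directory, exist_ok=True)
    paths = {
        "repertoires": os.path.join(directory, "repertoires.csv"),
        "covariates": os.path.join(directory, "covariates.csv"),
        "truth": os.path.join(directory, "truth.csv"),
    }
    from .repertoire_io import write_repertoires

    write_repertoires(data.reps, paths["repertoires"])
    ids = [r.individual_id for r in data.reps]
    pd.DataFrame(
        {"individual_id": ids, "outcome": data.y, "x1": data.X[:, 0]}
    ).to_csv(paths["covariates"], index=False)
    split = np.empty(len(ids), dtype=object)
    split[data.train_idx] = "train"
    split[data.test_idx] = "test"
    truth = pd.DataFrame(
        {
            "individual_id": ids,
            "split": split,
            "hidden_effect": data.h,
            "linear_predictor": data.eta,
        }
    )
    for name, g in zip(data.causal_features, data.gamma):
        truth[f"gamma_{name}"] = g
    truth.to_csv(paths["truth"], index=False)
    return paths


def _rows(fm: kf.FeatureMatrix, idx: np.ndarray) -> kf.FeatureMatrix:
    return fm.subset_rows(idx)


def screen_features(
    Z: kf.FeatureMatrix,
    y_train: np.ndarray,
    train_idx: np.ndarray,
    min_prevalence: float = 0.05,
    d: int | None = None,
) -> kf.FeatureMatrix:
    """Training-side feature screening: prevalence filter then SIS, both
    computed on the training rows only; returns the screened *joint* matrix."""
    Z_train = _rows(Z, train_idx)
    Z_train = kf.prevalence_filter(Z_train, min_prevalence)
    Z_train = kf.sis_screen(Z_train, y_train, d)
    return Z.subset_columns(Z_train.feature_names)


def _sub_kernel(K: HomologyKernel, idx: np.ndarray) -> HomologyKernel:
    return K.subset(idx)


def _fit_predict(
    method: str, data: SimulatedDataset, Z_s: kf.FeatureMatrix, seed: int
) -> np.ndarray:
    tr, te = data.train_idx, data.test_idx
    y_tr = data.y[tr]
    X_tr, X_te = data.X[tr], data.X[te]
    Z_tr, Z_te = Z_s.values[tr], Z_s.values[te]
    ot = data.outcome_type
    if method == "basic_glm":
        m = bl.fit_basic_glm(y_tr, X_tr, ot)
        return m.predict(X_te)
    if method in ("tcr_lasso", "tcr_ridge"):
        pen = "lasso" if method == "tcr_lasso" else "ridge"
        m = bl.fit_tcr_penalized(
            y_tr, X_tr, _rows(Z_s, tr), pen, ot, cv_seed=seed
        )
        return m.predict(X_te, Z_te)
    if method in ("tcrpred_B", "tcrpred_P"):
        sub = "BLOSUM62" if method.endswith("B") else "PAM250"
        if sub == data.K_raw.substitution:
            K_raw = data.K_raw
        else:
            K_raw = kernel_matrix(data.reps, sub)
        K_fit = psd_project(_sub_kernel(K_raw, tr))
        fit = md.fit_continuous if ot == "continuous" else md.fit_binary
        m = fit(y_tr, X_tr, _rows(Z_s, tr), K_fit, random_state=seed)
        sel = [Z_s.feature_names.index(c) for c in m.selected_features]
        res = md.predict(
            m, X_te, Z_new=Z_te[:, sel], K_cross=K_raw.values[np.ix_(te, tr)]
        )
        return res.values
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(
    cfg: SimulationConfig,
    methods: Sequence[str] = METHODS,
    pool: Sequence[Repertoire] | None = None,
    pool_spec: SyntheticPoolSpec | None = None,
) -> pd.DataFrame:
    """Replicate the generative design and score each method on the test set.

    Returns one row per (replicate, method) plus one aggregate ``mean`` row
    per method.  Fully deterministic given ``cfg.seed``.
    """
    for mname in methods:
        if mname not in METHODS:
            raise ValueError(f"unknown method {mname!r}; choose from {METHODS}")
    if pool is None:
        pool = generate_pool(pool_spec or SyntheticPoolSpec(), seed=cfg.seed + 1)
        pool, _ = filter_repertoires(pool)
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_replicates)
    rows = []
    for rep_i in range(cfg.n_replicates):
        rng = np.random.default_rng(children[rep_i])
        fit_seed = int(rng.integers(2**31 - 1))
        try:
            data = simulate_dataset(cfg, pool, rng)
            Z_s = screen_features(data.Z, data.y[data.train_idx], data.train_idx)
            for mname in methods:
                pred = _fit_predict(mname, data, Z_s, fit_seed)
                rep_report = bl.evaluate(pred, data.y[data.test_idx], cfg.outcome_type)
                rows.append(
                    {
                        "replicate": rep_i,
                        "method": mname,
                        "classification_error": rep_report.classification_error,
                        "auc": rep_report.auc,
                        "mse": rep_report.mse,
                        "n_test": rep_report.n_test,
                    }
                )
        except SimulationError as exc:
            raise SimulationError(f"replicate {rep_i}: {exc}") from exc
    df = pd.DataFrame(rows)
    agg = (
        df.groupby("method", sort=False)[["classification_error", "auc", "mse"]]
        .mean()
        .reset_index()
    )
    agg.insert(0, "replicate", "mean")
    agg["n_test"] = cfg.n_test
    return pd.concat([df, agg], ignore_index=True)
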