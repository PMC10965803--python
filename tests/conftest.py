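import numpy as np
import pytest

import tcrpred as t


@pytest.fixture(scope="session")
def small_pool():
    """A small synthetic pool for unit tests (fast kernels)."""
    spec = t.SyntheticPoolSpec(
        n_individuals=40,
        clones_per_individual=(4, 8),
        cdr3_length=(9, 13),
        n_archetypes=4,
        public_library_size=24,
    )
    pool, _ = t.filter_repertoires(t.generate_pool(spec, seed=5))
    return pool


@pytest.fixture(scope="session")
def bio_similarity():
    """Independent oracle: Biopython global affine-gap alignment similarity."""
    from Bio.Align import PairwiseAligner, substitution_matrices

    def sim(a, b, name="BLOSUM62", gap_open=10, gap_extend=1, normalize=True):
        al = PairwiseAligner()
        al.substitution_matrix = substitution_matrices.load(name)
        al.open_gap_score = -gap_open
        al.extend_gap_score = -gap_extend
        al.mode = "global"
        s = al.score(a, b)
        if normalize:
            s = s / np.sqrt(al.score(a, a) * al.score(b, b))
            s = max(s, -1.0)
        return float(s)

    return sim


@pytest.fixture(scope="session")
def naive_homology(bio_similarity):
    """Brute-force repertoire homology: double loop over all sequence pairs."""

    def hom(ri, rj, name="BLOSUM62"):
        wi = ri.abundances
        wj = rj.abundances
        S = np.array(
            [[bio_similarity(a, b, name) for b in rj.sequences] for a in ri.sequences]
        )
        num = float(wi @ S.max(axis=1) + wj @ S.max(axis=0))
        return num / (wi.sum() + wj.sum())

    return hom
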