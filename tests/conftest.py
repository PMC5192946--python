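import numpy as np
import pytest

from popdemog.seqdata import SiteMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_matrix(rows, L=100, polarized=True, positions=None):
    """SiteMatrix from a list of 0/1 strings, dropping nothing."""
    mat = np.array([[int(c) for c in r] for r in rows], dtype=np.uint8)
    S = mat.shape[1]
    pos = np.arange(S, dtype=float) if positions is None else np.asarray(positions, float)
    return SiteMatrix(
        matrix=mat,
        positions=pos,
        n=mat.shape[0],
        L=L,
        sample_labels=[f"s{i}" for i in range(mat.shape[0])],
        polarized=polarized,
        alignment_bp=L,
    )


def random_segregating_matrix(rng, n, S_target, L=100):
    """Random binary matrix with only segregating columns (S <= S_target)."""
    cols = []
    while len(cols) < S_target:
        c = rng.integers(0, 2, size=n, dtype=np.uint8)
        if 0 < c.sum() < n:
            cols.append(c)
    mat = np.column_stack(cols)
    return SiteMatrix(
        matrix=mat,
        positions=np.arange(S_target, dtype=float),
        n=n,
        L=L,
        sample_labels=[f"s{i}" for i in range(n)],
        polarized=True,
        alignment_bp=L,
    )
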