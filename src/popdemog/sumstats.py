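"""Per-locus and per-population summary statistics for site matrices.

Implements the classical frequency-spectrum estimators (S, pi, Watterson's
theta, Tajima's D, Fay & Wu's H), the Hudson-Kaplan minimum-recombination
count R_M from the four-gamete test, the largest non-recombining block, and
between-population divergence D_xy.  Per-population multilocus values are
pooled by site concatenation (sum of pairwise differences over summed
analyzed length), which reproduces the per-site definitions exactly; an
unweighted mean over loci is available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import PopdemogError
from .seqdata import SiteMatrix


@lru_cache(maxsize=None)
def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i; the Watterson normalizer for n sequences."""
    return float(sum(1.0 / i for i in range(1, n)))


@lru_cache(maxsize=None)
def harmonic_number_sq(n: int) -> float:
    """b_n = sum_{i=1}^{n-1} 1/i^2."""
    return float(sum(1.0 / (i * i) for i in range(1, n)))


@lru_cache(maxsize=None)
def tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) of Tajima's variance correction for sample size n."""
    a1 = harmonic_number(n)
    a2 = harmonic_number_sq(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return e1, e2


def segregating_sites(m: SiteMatrix) -> int:
    return m.S


def haplotype_count(m: SiteMatrix) -> int:
    """Number of distinct rows (monomorphic data have a single haplotype)."""
    if m.S == 0:
        return 1
    return len({row.tobytes() for row in np.ascontiguousarray(m.matrix)})


def pairwise_diversity(m: SiteMatrix) -> tuple[float, float]:
    """(pi_total, pi_site): mean pairwise differences per locus and per site."""
    if m.n < 2:
        raise PopdemogError("pairwise diversity needs at least 2 haplotypes")
    n = m.n
    c = m.matrix.sum(axis=0, dtype=np.int64)
    pi_total = float((2.0 * c * (n - c)).sum() / (n * (n - 1)))
    return pi_total, pi_total / m.L if m.L else 0.0


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's theta per site, S / (a_n * L)."""
    if n < 2:
        raise PopdemogError("Watterson's theta needs n >= 2")
    if L < 1:
        raise PopdemogError("Watterson's theta needs L >= 1")
    return S / (harmonic_number(n) * L)


def _tajimas_d_from_totals(pi_total: float, S: int, n: int) -> float:
    a1 = harmonic_number(n)
    e1, e2 = tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi_total - S / a1) / math.sqrt(var)


def tajimas_d(m: SiteMatrix) -> float:
    """Tajima's D; NaN when S = 0 (undefined, never reported as 0)."""
    if m.S == 0:
        return math.nan
    pi_total, _ = pairwise_diversity(m)
    return _tajimas_d_from_totals(pi_total, m.S, m.n)


def fay_wu_h(m: SiteMatrix) -> float:
    """Unnormalized Fay & Wu's H = theta_pi - theta_H over polarized columns.

    theta_H weights sites by the squared derived-allele count, so an excess of
    high-frequency derived alleles drives H negative.  Columns that could not
    be polarized are excluded from both estimators; with no polarized column
    and S > 0 the statistic is undefined (NaN).
    """
    if m.S == 0:
        return 0.0
    keep = m.col_polarized
    if not keep.any():
        return math.nan
    n = m.n
    c = m.matrix[:, keep].sum(axis=0, dtype=np.int64)
    denom = n * (n - 1)
    theta_pi = float((2.0 * c * (n - c)).sum() / denom)
    theta_h = float((2.0 * c * c).sum() / denom)
    return theta_pi - theta_h


def _incompatible_pairs(m: SiteMatrix) -> list[tuple[int, int]]:
    """All column pairs (i, j), i < j, showing all four gametes."""
    if m.S < 2:
        return []
    a = m.matrix.astype(bool)
    na = ~a
    c11 = a.T @ a
    c10 = a.T @ na
    c01 = na.T @ a
    c00 = na.T @ na
    bad = (c11 > 0) & (c10 > 0) & (c01 > 0) & (c00 > 0)
    i_idx, j_idx = np.nonzero(np.triu(bad, k=1))
    return list(zip(i_idx.tolist(), j_idx.tolist()))


def min_recombination_rm(m: SiteMatrix) -> tuple[int, list[tuple[int, int]]]:
    """Hudson-Kaplan R_M and the incompatible column-index pairs.

    R_M is the maximum number of pairwise-disjoint incompatible intervals;
    intervals sharing only an endpoint column are disjoint (the implied
    recombination events fall in different inter-site gaps).
    """
    pairs = _incompatible_pairs(m)
    rm = 0
    last_end = -1
    for i, j in sorted(pairs, key=lambda p: p[1]):
        if i >= last_end:
            rm += 1
            last_end = j
    return rm, pairs


def largest_nonrecombining_block(
    m: SiteMatrix, alignment_length: int | None = None
) -> float:
    """Longest contiguous stretch whose columns pass all four-gamete tests.

    Block boundaries are the midpoints between the flanking columns, clamped
    to [0, alignment_length], so a locus without any violation returns the
    full alignment length.
    """
    bp = alignment_length if alignment_length is not None else m.alignment_bp
    if m.S == 0:
        return float(bp)
    pos = m.positions * bp if m.unit_positions else m.positions
    S = m.S
    incompat = np.zeros((S, S), dtype=bool)
    for i, j in _incompatible_pairs(m):
        incompat[i, j] = incompat[j, i] = True

    def block_bp(j: int, k: int) -> float:
        start = 0.0 if j == 0 else 0.5 * (pos[j - 1] + pos[j])
        end = float(bp) if k == S - 1 else 0.5 * (pos[k] + pos[k + 1])
        return min(float(bp), max(0.0, end)) - max(0.0, min(float(bp), start))

    best = 0.0
    left = 0
    for k in range(S):
        for i in range(k - 1, left - 1, -1):
            if incompat[i, k]:
                left = i + 1
                break
        best = max(best, block_bp(left, k))
    return best


def dxy(m: SiteMatrix, popA_rows: Sequence[int], popB_rows: Sequence[int]) -> float:
    """Mean per-site pairwise differences between two populations."""
    rowsA = np.asarray(popA_rows, dtype=int)
    rowsB = np.asarray(popB_rows, dtype=int)
    if rowsA.size == 0 or rowsB.size == 0:
        raise PopdemogError("both populations must be non-empty")
    if np.intersect1d(rowsA, rowsB).size:
        raise PopdemogError("population row sets overlap")
    if m.S == 0:
        return 0.0
    cA = m.matrix[rowsA].sum(axis=0, dtype=np.int64)
    cB = m.matrix[rowsB].sum(axis=0, dtype=np.int64)
    nA, nB = rowsA.size, rowsB.size
    total = float((cA * (nB - cB) + cB * (nA - cA)).sum() / (nA * nB))
    return total / m.L


def dxy_multilocus(
    matrices: Sequence[SiteMatrix],
    popA_rows: Sequence[Sequence[int]],
    popB_rows: Sequence[Sequence[int]],
) -> float:
    """Multilocus D_xy: total between-pair differences over total length."""
    tot_diff = 0.0
    tot_L = 0
    for m, ra, rb in zip(matrices, popA_rows, popB_rows):
        tot_diff += dxy(m, ra, rb) * m.L
        tot_L += m.L
    return tot_diff / tot_L if tot_L else 0.0


@dataclass
class SummaryVector:
    """Named per-locus statistics (the ABC summary substrate)."""

    locus_id: str
    n: int
    L: int
    alignment_bp: int
    S: int
    h: int
    pi_total: float
    pi_site: float
    theta_w_site: float
    tajima_d: float
    fay_wu_h: float
    rm: int
    block_bp: float


def locus_summary(
    m: SiteMatrix,
    locus_id: str = "",
    alignment_length: int | None = None,
    compute_rm: bool = True,
) -> SummaryVector:
    pi_total, pi_site = pairwise_diversity(m)
    rm, _ = min_recombination_rm(m) if compute_rm else (0, [])
    block = (
        largest_nonrecombining_block(m, alignment_length) if compute_rm else math.nan
    )
    return SummaryVector(
        locus_id=locus_id,
        n=m.n,
        L=m.L,
        alignment_bp=int(alignment_length if alignment_length is not None else m.alignment_bp),
        S=m.S,
        h=haplotype_count(m),
        pi_total=pi_total,
        pi_site=pi_site,
        theta_w_site=watterson_theta(m.S, m.n, m.L),
        tajima_d=tajimas_d(m),
        fay_wu_h=fay_wu_h(m),
        rm=rm,
        block_bp=block,
    )


@dataclass
class PopulationSummary:
    population_id: str
    per_locus: list[SummaryVector]
    pi_site: float
    theta_w_site: float
    tajima_d: float
    n_loci: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_loci = len(self.per_locus)


def population_summary(
    matrices: Sequence[SiteMatrix],
    population_id: str = "",
    locus_ids: Sequence[str] | None = None,
    pooling: str = "concatenate",
) -> PopulationSummary:
    """Per-locus vectors plus multilocus pi, theta_W and D for one population.

    ``pooling="concatenate"`` treats all analyzed sites as one long locus
    (sums of pairwise differences, S and L); ``pooling="mean"`` averages the
    per-locus statistics instead.  With concatenation, D uses the pooled
    totals and the sample size shared across loci (rounded mean when loci
    differ in n).
    """
    if not matrices:
        raise PopdemogError(f"population {population_id!r}: no loci")
    ids = list(locus_ids) if locus_ids else [f"locus{i}" for i in range(len(matrices))]
    vectors = [
        locus_summary(m, locus_id=ids[i], compute_rm=False)
        for i, m in enumerate(matrices)
    ]
    if pooling == "mean":
        pi_site = float(np.mean([v.pi_site for v in vectors]))
        thw = float(np.mean([v.theta_w_site for v in vectors]))
        ds = [v.tajima_d for v in vectors if not math.isnan(v.tajima_d)]
        d = float(np.mean(ds)) if ds else math.nan
    elif pooling == "concatenate":
        tot_L = sum(v.L for v in vectors)
        tot_S = sum(v.S for v in vectors)
        tot_pi = sum(v.pi_total for v in vectors)
        pi_site = tot_pi / tot_L
        thw = sum(v.S / harmonic_number(v.n) for v in vectors) / tot_L
        n_pool = int(round(np.mean([v.n for v in vectors])))
        d = _tajimas_d_from_totals(tot_pi, tot_S, n_pool) if tot_S else math.nan
    else:
        raise PopdemogError(f"unknown pooling {pooling!r}")
    return PopulationSummary(
        population_id=population_id,
        per_locus=vectors,
        pi_site=pi_site,
        theta_w_site=thw,
        tajima_d=d,
    )


# --- multilocus reductions used as the ABC summary space ---------------------

ABC_SUMMARY_NAMES = (
    "S_mean", "S_var",
    "pi_mean", "pi_var",
    "thw_mean", "thw_var",
    "D_mean", "D_var",
    "h_mean", "h_var",
    "n_mono",
)


def dataset_summaries(matrices: Sequence[SiteMatrix]) -> np.ndarray:
    """Means and variances across loci of S, pi, theta_W (per-locus totals),
    Tajima's D and haplotype count, plus a monomorphic-locus counter.

    Undefined D values (monomorphic loci) enter as 0 and are counted by
    ``n_mono`` so that the summary vector stays finite without discarding
    simulations.
    """
    k = len(matrices)
    S = np.empty(k)
    pi = np.empty(k)
    thw = np.empty(k)
    D = np.empty(k)
    h = np.empty(k)
    n_mono = 0
    for i, m in enumerate(matrices):
        n = m.n
        S[i] = m.S
        if m.S == 0:
            pi[i] = thw[i] = D[i] = 0.0
            h[i] = 1
            n_mono += 1
            continue
        c = m.matrix.sum(axis=0, dtype=np.int64)
        pi[i] = (2.0 * c * (n - c)).sum() / (n * (n - 1))
        thw[i] = m.S / harmonic_number(n)
        d = _tajimas_d_from_totals(pi[i], m.S, n)
        D[i] = 0.0 if math.isnan(d) else d
        h[i] = len({row.tobytes() for row in np.ascontiguousarray(m.matrix)})
    out = np.empty(len(ABC_SUMMARY_NAMES))
    for j, arr in enumerate((S, pi, thw, D, h)):
        out[2 * j] = arr.mean()
        out[2 * j + 1] = arr.var(ddof=1) if k > 1 else 0.0
    out[10] = n_mono
    return out


PAIR_SUMMARY_NAMES = tuple(
    [f"A_{nm}" for nm in ABC_SUMMARY_NAMES]
    + [f"B_{nm}" for nm in ABC_SUMMARY_NAMES]
    + ["dxy_mean", "dxy_var"]
)


def pair_summaries(
    matrices: Sequence[SiteMatrix],
    rowsA: Sequence[np.ndarray],
    rowsB: Sequence[np.ndarray],
) -> np.ndarray:
    """Two-population summary vector: per-population reductions plus D_xy."""
    subA = [m.subset(r) for m, r in zip(matrices, rowsA)]
    subB = [m.subset(r) for m, r in zip(matrices, rowsB)]
    d = np.array([dxy(m, ra, rb) for m, ra, rb in zip(matrices, rowsA, rowsB)])
    k = len(matrices)
    dvar = d.var(ddof=1) if k > 1 else 0.0
    return np.concatenate(
        [dataset_summaries(subA), dataset_summaries(subB), [d.mean(), dvar]]
    )


def locus_table(summaries: Sequence[SummaryVector]) -> pd.DataFrame:
    """Per-locus report table (one row per locus)."""
    return pd.DataFrame(
        {
            "locus": [v.locus_id for v in summaries],
            "alignment_bp": [v.alignment_bp for v in summaries],
            "L_analyzed_bp": [v.L for v in summaries],
            "block_bp": [v.block_bp for v in summaries],
            "n": [v.n for v in summaries],
            "S": [v.S for v in summaries],
            "h": [v.h for v in summaries],
            "Rm": [v.rm for v in summaries],
            "pi": [round(v.pi_site, 4) for v in summaries],
            "D": [round(v.tajima_d, 3) for v in summaries],
            "H": [round(v.fay_wu_h, 3) for v in summaries],
        }
    )


def population_table(summaries: Sequence[PopulationSummary]) -> pd.DataFrame:
    """Per-population report table (one row per population)."""
    return pd.DataFrame(
        {
            "population": [p.population_id for p in summaries],
            "n_loci": [p.n_loci for p in summaries],
            "n": [int(round(np.mean([v.n for v in p.per_locus]))) for p in summaries],
            "pi": [round(p.pi_site, 4) for p in summaries],
            "thetaW": [round(p.theta_w_site, 4) for p in summaries],
            "D": [round(p.tajima_d, 3) for p in summaries],
        }
    )
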