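"""Simulation-based neutrality tests and the multilocus HKA test.

Tajima's D and Fay & Wu's H get empirical p-values from coalescent null
distributions under the standard neutral model.  The default conditions on
the observed number of segregating sites (exactly S mutations are placed on
each simulated genealogy); conditioning on theta (Poisson mutation counts)
is available by flag.  The HKA test fits the 1987 moment equations -- shared
divergence time T, per-locus thetas and (in the two-species variant) a
population-size ratio f -- and reports a chi-square goodness of fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .coalsim import sample_branch_spectrum
from .errors import EstimationError, FormatError, PopdemogError
from .sumstats import harmonic_number, harmonic_number_sq, tajima_constants


@dataclass
class NeutralityTestResult:
    statistic: float
    p_value: float
    n_reps: int
    tail: str


def fixed_s_null(
    n: int, S: int, n_reps: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Null distributions of D and H conditional on S segregating sites.

    Each replicate draws a constant-size genealogy and places exactly S
    mutations multinomially on branches by length; ancestral states are
    treated as perfectly known, so the derived-allele count of a mutation is
    the subtree size of its branch.
    """
    pi = np.empty(n_reps)
    theta_h = np.empty(n_reps)
    denom = n * (n - 1)
    for r in range(n_reps):
        sizes, lengths = sample_branch_spectrum(n, rng)
        counts = rng.multinomial(S, lengths / lengths.sum())
        pi[r] = (counts * 2.0 * sizes * (n - sizes)).sum() / denom
        theta_h[r] = (counts * 2.0 * sizes * sizes).sum() / denom
    a1 = harmonic_number(n)
    e1, e2 = tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    d = (pi - S / a1) / math.sqrt(var) if var > 0 else np.full(n_reps, np.nan)
    return {"D": d, "H": pi - theta_h, "pi": pi, "theta_h": theta_h}


def _fixed_theta_null(
    n: int, theta: float, n_reps: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    d = np.empty(n_reps)
    h = np.empty(n_reps)
    a1 = harmonic_number(n)
    e1, e2 = tajima_constants(n)
    denom = n * (n - 1)
    for r in range(n_reps):
        sizes, lengths = sample_branch_spectrum(n, rng)
        S = rng.poisson(theta * lengths.sum())
        if S == 0:
            d[r] = np.nan
            h[r] = 0.0
            continue
        counts = rng.multinomial(S, lengths / lengths.sum())
        pi = (counts * 2.0 * sizes * (n - sizes)).sum() / denom
        th = (counts * 2.0 * sizes * sizes).sum() / denom
        var = e1 * S + e2 * S * (S - 1)
        d[r] = (pi - S / a1) / math.sqrt(var) if var > 0 else np.nan
        h[r] = pi - th
    return {"D": d, "H": h}


def _null(n, S, n_reps, rng, conditioning, theta):
    if conditioning == "fixed_s":
        return fixed_s_null(n, S, n_reps, rng)
    if conditioning == "fixed_theta":
        if theta is None:
            raise PopdemogError("fixed_theta conditioning needs theta")
        return _fixed_theta_null(n, theta, n_reps, rng)
    raise PopdemogError(f"unknown conditioning {conditioning!r}")


def tajima_d_pvalue(
    observed_d: float,
    n: int,
    S: int,
    n_reps: int = 10_000,
    rng: np.random.Generator | None = None,
    conditioning: str = "fixed_s",
    theta: float | None = None,
) -> NeutralityTestResult:
    """Two-tailed empirical p-value for Tajima's D, 2*min(P<=, P>=) capped at 1.

    Uses the add-one correction (1 + #extreme) / (n_reps + 1) so p can never
    be exactly zero.
    """
    if S < 1:
        raise PopdemogError("Tajima's D is undefined when S = 0")
    if math.isnan(observed_d):
        raise PopdemogError("observed D is undefined")
    rng = rng if rng is not None else np.random.default_rng()
    null = _null(n, S, n_reps, rng, conditioning, theta)["D"]
    null = null[~np.isnan(null)]
    k = null.size
    p_le = (1 + (null <= observed_d).sum()) / (k + 1)
    p_ge = (1 + (null >= observed_d).sum()) / (k + 1)
    return NeutralityTestResult(
        statistic=observed_d,
        p_value=min(1.0, 2.0 * min(p_le, p_ge)),
        n_reps=int(k),
        tail="two-sided",
    )


def fay_wu_h_pvalue(
    observed_h: float,
    n: int,
    S: int,
    n_reps: int = 10_000,
    rng: np.random.Generator | None = None,
    conditioning: str = "fixed_s",
    theta: float | None = None,
    two_tailed: bool = False,
) -> NeutralityTestResult:
    """One-tailed (low-H) empirical p-value for unnormalized Fay & Wu's H.

    The default 10,000 replicates match common practice for outgroup-based H
    testing.  Requires polarized data; the observed H must be finite.
    """
    if S < 1:
        raise PopdemogError("Fay & Wu's H is undefined when S = 0")
    if math.isnan(observed_h):
        raise PopdemogError("observed H is undefined (unpolarized input?)")
    rng = rng if rng is not None else np.random.default_rng()
    null = _null(n, S, n_reps, rng, conditioning, theta)["H"]
    null = null[~np.isnan(null)]
    k = null.size
    p_le = (1 + (null <= observed_h).sum()) / (k + 1)
    if two_tailed:
        p_ge = (1 + (null >= observed_h).sum()) / (k + 1)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        tail = "two-sided"
    else:
        p = p_le
        tail = "low"
    return NeutralityTestResult(
        statistic=observed_h, p_value=p, n_reps=int(k), tail=tail
    )


# --- HKA ---------------------------------------------------------------------


@dataclass
class HkaLocus:
    """One locus of an HKA table: polymorphism in each species + divergence.

    ``s_a``/``s_b`` are segregating-site counts with sample sizes
    ``n_a``/``n_b``; ``d_ab`` is the mean number of pairwise differences
    between species (a per-locus total, like the S counts).
    """

    locus_id: str
    L: int
    n_a: int
    s_a: int
    d_ab: float
    n_b: int | None = None
    s_b: int | None = None


@dataclass
class HkaResult:
    x2: float
    df: int
    p_value: float
    variant: str
    theta: np.ndarray
    T: float
    f: float
    expected: pd.DataFrame


def _hka_solve_two(loci: list[HkaLocus]):
    sa = np.array([l.s_a for l in loci], dtype=float)
    sb = np.array([l.s_b for l in loci], dtype=float)
    d = np.array([l.d_ab for l in loci], dtype=float)
    aa = np.array([harmonic_number(l.n_a) for l in loci])
    ab = np.array([harmonic_number(l.n_b) for l in loci])
    nl = len(loci)

    # closed form for equal sample sizes; used as the start point in general
    theta_sum = sa.sum() / aa.mean()
    f0 = max(sb.sum() / (ab.mean() * theta_sum), 1e-6)
    t0 = max(d.sum() / theta_sum - (1 + f0) / 2.0, 1e-6)
    tot = sa + sb + d
    theta0 = np.maximum(tot / tot.sum() * theta_sum, 1e-8)

    def residuals(x):
        theta = np.exp(x[:nl])
        T = x[nl]
        f = math.exp(x[nl + 1])
        r = np.empty(nl + 2)
        r[:nl] = tot - theta * (aa + f * ab + T + (1 + f) / 2.0)
        r[nl] = sa.sum() - (theta * aa).sum()
        r[nl + 1] = sb.sum() - f * (theta * ab).sum()
        return r

    x0 = np.concatenate([np.log(theta0), [t0, math.log(f0)]])
    sol = optimize.least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success or np.abs(sol.fun).max() > 1e-6 * max(1.0, tot.sum()):
        raise EstimationError(
            f"HKA moment solver did not converge (max residual {np.abs(sol.fun).max():.3g})"
        )
    theta = np.exp(sol.x[:nl])
    T = float(sol.x[nl])
    f = float(math.exp(sol.x[nl + 1]))

    ba = np.array([harmonic_number_sq(l.n_a) for l in loci])
    bb = np.array([harmonic_number_sq(l.n_b) for l in loci])
    e_sa = theta * aa
    e_sb = f * theta * ab
    e_d = theta * (T + (1 + f) / 2.0)
    v_sa = e_sa + theta**2 * ba
    v_sb = e_sb + (f * theta) ** 2 * bb
    v_d = e_d + (theta * (1 + f) / 2.0) ** 2
    x2 = float(
        ((sa - e_sa) ** 2 / v_sa).sum()
        + ((sb - e_sb) ** 2 / v_sb).sum()
        + ((d - e_d) ** 2 / v_d).sum()
    )
    expected = pd.DataFrame(
        {
            "locus": [l.locus_id for l in loci],
            "E_S_a": e_sa, "E_S_b": e_sb, "E_D": e_d,
            "var_S_a": v_sa, "var_S_b": v_sb, "var_D": v_d,
        }
    )
    return x2, theta, T, f, expected


def _hka_solve_one(loci: list[HkaLocus]):
    sa = np.array([l.s_a for l in loci], dtype=float)
    d = np.array([l.d_ab for l in loci], dtype=float)
    aa = np.array([harmonic_number(l.n_a) for l in loci])
    nl = len(loci)
    theta_sum = sa.sum() / aa.mean()
    t0 = max(d.sum() / theta_sum - 1.0, 1e-6)
    tot = sa + d
    theta0 = np.maximum(tot / tot.sum() * theta_sum, 1e-8)

    def residuals(x):
        theta = np.exp(x[:nl])
        T = x[nl]
        r = np.empty(nl + 1)
        r[:nl] = tot - theta * (aa + T + 1.0)
        r[nl] = sa.sum() - (theta * aa).sum()
        return r

    x0 = np.concatenate([np.log(theta0), [t0]])
    sol = optimize.least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success or np.abs(sol.fun).max() > 1e-6 * max(1.0, tot.sum()):
        raise EstimationError("HKA moment solver did not converge")
    theta = np.exp(sol.x[:nl])
    T = float(sol.x[nl])
    ba = np.array([harmonic_number_sq(l.n_a) for l in loci])
    e_sa = theta * aa
    e_d = theta * (T + 1.0)
    v_sa = e_sa + theta**2 * ba
    v_d = e_d + theta**2
    x2 = float(((sa - e_sa) ** 2 / v_sa).sum() + ((d - e_d) ** 2 / v_d).sum())
    expected = pd.DataFrame(
        {
            "locus": [l.locus_id for l in loci],
            "E_S_a": e_sa, "E_D": e_d, "var_S_a": v_sa, "var_D": v_d,
        }
    )
    return x2, theta, T, 1.0, expected


def hka_test(loci: list[HkaLocus], variant: str = "two_species") -> HkaResult:
    """Multilocus HKA goodness-of-fit test.

    Under neutrality, polymorphism within species and divergence between
    species are proportional across loci.  The moment equations are solved
    for per-locus thetas, the divergence time T (in 2N_a generations) and,
    for ``two_species``, the size ratio f = N_b/N_a; X^2 sums
    (obs - exp)^2 / var over all cells, with df = L - 1 (one_species) or
    2L - 2 (two_species).
    """
    if len(loci) < 2:
        raise PopdemogError("HKA needs at least 2 loci")
    if variant == "two_species":
        if any(l.s_b is None or l.n_b is None for l in loci):
            raise PopdemogError("two_species variant needs s_b and n_b per locus")
        x2, theta, T, f, expected = _hka_solve_two(loci)
        df = 2 * len(loci) - 2
    elif variant == "one_species":
        x2, theta, T, f, expected = _hka_solve_one(loci)
        df = len(loci) - 1
    else:
        raise PopdemogError(f"unknown HKA variant {variant!r}")
    return HkaResult(
        x2=x2, df=df, p_value=float(stats.chi2.sf(x2, df)),
        variant=variant, theta=theta, T=T, f=f, expected=expected,
    )


def simulate_hka_null(
    thetas: np.ndarray,
    T: float,
    f: float,
    n_a: int,
    n_b: int,
    rng: np.random.Generator,
    L: int = 500,
) -> list[HkaLocus]:
    """Simulate one dataset from the HKA null model.

    Segregating sites come from neutral coalescent genealogies (theta and
    f*theta for the two species); divergence is Poisson around
    theta*(T + G) with G exponential of mean (1+f)/2, the ancestral
    coalescence contribution.
    """
    out = []
    for i, th in enumerate(np.atleast_1d(thetas)):
        _, len_a = sample_branch_spectrum(n_a, rng)
        s_a = int(rng.poisson(th * len_a.sum()))
        _, len_b = sample_branch_spectrum(n_b, rng)
        s_b = int(rng.poisson(f * th * len_b.sum()))
        g = rng.exponential((1 + f) / 2.0)
        d_ab = float(rng.poisson(th * (T + g)))
        out.append(
            HkaLocus(
                locus_id=f"locus{i}", L=L, n_a=n_a, s_a=s_a,
                d_ab=d_ab, n_b=n_b, s_b=s_b,
            )
        )
    return out


def read_hka_tsv(path: str | Path) -> list[HkaLocus]:
    """Read an HKA input table (locus, L, S_a, n_a, S_b, n_b, D_ab)."""
    df = pd.read_csv(path, sep="\t")
    required = {"locus", "L", "S_a", "n_a", "D_ab"}
    if not required.issubset(df.columns):
        raise FormatError(f"HKA table needs columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        s_b = getattr(row, "S_b", None)
        n_b = getattr(row, "n_b", None)
        out.append(
            HkaLocus(
                locus_id=str(row.locus), L=int(row.L),
                n_a=int(row.n_a), s_a=int(row.S_a), d_ab=float(row.D_ab),
                n_b=None if n_b is None or pd.isna(n_b) else int(n_b),
                s_b=None if s_b is None or pd.isna(s_b) else int(s_b),
            )
        )
    return out
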