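"""Coalescent simulation of genealogies and infinite-sites polymorphism.

Five demographic models are supported, all parameterized in the conventions
of standard coalescent simulators: time is measured in units of 4N0
generations, theta = 4*N*mu is the per-locus population mutation parameter,
and mutated positions are uniform on (0, 1).

* ``SNM``     constant population size (standard neutral model).
* ``EXP``     exponential growth toward the present: looking backwards the
              relative size is rho(t) = exp(-g*t).
* ``BOT``     instantaneous size reduction: forward in time the population
              dropped at time t_b from an ancestral size theta0/severity to
              the present size theta0 (severity = theta0/theta_A < 1 for a
              true reduction).
* ``BOT_EXP`` exponential growth after the instantaneous reduction: rho(t) =
              exp(-g*t) for t < t_b, then 1/severity.
* ``IM2``     two populations exchanging migrants that split from a single
              ancestor at t_split.  Deme sizes theta1, theta2 and thetaA are
              per-locus thetas; theta1 doubles as the 4N0 reference, and m12,
              m21 are scaled migration rates 4N0*M (each lineage in deme i
              migrates backwards at rate m_ij/2).

There is no intralocus recombination: loci are treated as non-recombining
blocks, with recombination handled upstream as a data-preprocessing concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .seqdata import SiteMatrix

MODELS = ("SNM", "EXP", "BOT", "BOT_EXP", "IM2")


@dataclass
class Demography:
    """Parameter bundle for one demographic model.

    ``theta0`` is the present-day per-locus mutation parameter and the 4N0
    reference for the time scale.  Model-specific fields are ignored by the
    other models.
    """

    model_id: str
    theta0: float = 1.0
    growth_g: float = 0.0          # EXP / BOT_EXP, per 4N0 generations
    t_b: float = 0.0               # BOT / BOT_EXP, in 4N0 units
    severity: float = 1.0          # theta0 / theta_ancestral
    theta1: float = 1.0            # IM2 deme sizes (per locus)
    theta2: float = 1.0
    thetaA: float = 1.0
    t_split: float = 0.0           # IM2 split time, 4N0 units
    m12: float = 0.0               # IM2 scaled migration rates 4N0*M
    m21: float = 0.0

    def __post_init__(self) -> None:
        if self.model_id not in MODELS:
            raise ParameterError(f"unknown model {self.model_id!r}")
        if self.theta0 <= 0:
            raise ParameterError("theta0 must be > 0")
        if self.severity <= 0:
            raise ParameterError("severity must be > 0")
        if self.t_b < 0 or self.t_split < 0:
            raise ParameterError("times must be >= 0")
        if self.m12 < 0 or self.m21 < 0:
            raise ParameterError("migration rates must be >= 0")
        if self.model_id == "IM2" and min(self.theta1, self.theta2, self.thetaA) <= 0:
            raise ParameterError("IM2 deme sizes must be > 0")


@dataclass
class Genealogy:
    """A single rooted genealogy over 2n-1 nodes.

    Leaves are nodes 0..n-1; internal nodes are appended in coalescence
    order, so node times are non-decreasing along the node index.  ``parent``
    is -1 at the root.  ``leaf_pop`` labels leaves by deme for two-population
    simulations.
    """

    n: int
    parent: np.ndarray
    time: np.ndarray
    leaf_pop: np.ndarray | None = None
    _leaf_sets: np.ndarray | None = field(default=None, repr=False)

    @property
    def total_length(self) -> float:
        t = self.time
        p = self.parent
        nonroot = p >= 0
        return float((t[p[nonroot]] - t[nonroot]).sum())

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (2n-2 values)."""
        return self.time[self.parent[:-1]] - self.time[:-1]

    def subtree_sizes(self) -> np.ndarray:
        sizes = np.ones(2 * self.n - 1, dtype=np.int64)
        sizes[self.n:] = 0
        for v in range(2 * self.n - 2):
            sizes[self.parent[v]] += sizes[v]
        return sizes

    def leaf_sets(self) -> np.ndarray:
        """(2n-1, n) boolean matrix: leaves below each node."""
        if self._leaf_sets is None:
            ls = np.zeros((2 * self.n - 1, self.n), dtype=bool)
            ls[np.arange(self.n), np.arange(self.n)] = True
            for v in range(2 * self.n - 2):
                ls[self.parent[v]] |= ls[v]
            self._leaf_sets = ls
        return self._leaf_sets


def _coal_waiting_time(t: float, k: int, d: Demography, x: float) -> float:
    """Time of the next coalescence given k lineages at time t.

    ``x`` is a standard-exponential hazard budget; the inhomogeneous rate
    k(k-1)/rho(t) is inverted analytically per epoch.
    """
    rate = k * (k - 1)
    model = d.model_id
    g = d.growth_g
    if model == "SNM" or (model == "EXP" and g == 0.0):
        return t + x / rate
    if model == "EXP":
        return t + math.log1p(g * x * math.exp(-g * t) / rate) / g
    if model == "BOT" or (model == "BOT_EXP" and g == 0.0):
        if t < d.t_b:
            tc = t + x / rate
            if tc <= d.t_b:
                return tc
            x -= (d.t_b - t) * rate
            t = d.t_b
        return t + x / (rate * d.severity)
    if model == "BOT_EXP":
        if t < d.t_b:
            hazard_to_tb = rate * (math.exp(g * d.t_b) - math.exp(g * t)) / g
            if x <= hazard_to_tb:
                return t + math.log1p(g * x * math.exp(-g * t) / rate) / g
            x -= hazard_to_tb
            t = d.t_b
        # ancestral epoch: constant relative size exp(-g*t_b)/severity
        rho_anc = math.exp(-g * d.t_b) / d.severity
        return t + x * rho_anc / rate
    raise ParameterError(f"model {model!r} is not a single-population model")


def _single_pop_genealogy(n: int, d: Demography,
                          rng: np.random.Generator) -> Genealogy:
    """Kingman coalescent with a deterministic size trajectory."""
    total = 2 * n - 1
    time = np.zeros(total)
    parent = np.full(total, -1, dtype=np.int64)
    active = list(range(n))
    next_node = n
    t = 0.0
    k = len(active)
    exps = rng.exponential(size=k - 1)
    us = rng.random(size=2 * (k - 1))
    for step in range(k - 1):
        kk = len(active)
        t = _coal_waiting_time(t, kk, d, exps[step])
        i = int(us[2 * step] * kk)
        j = int(us[2 * step + 1] * (kk - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = parent[b] = next_node
        time[next_node] = t
        # swap-pop removal keeps the list O(1) per event
        hi, lo = (i, j) if i > j else (j, i)
        active[hi] = active[-1]
        active.pop()
        active[lo] = next_node
        next_node += 1
    return Genealogy(n=n, parent=parent, time=time)


def _im2_genealogy(n1: int, n2: int, d: Demography,
                   rng: np.random.Generator) -> Genealogy:
    n = n1 + n2
    total = 2 * n - 1
    time = np.zeros(total)
    parent = np.full(total, -1, dtype=np.int64)
    rho1 = d.theta1 / d.theta0
    rho2 = d.theta2 / d.theta0
    rhoA = d.thetaA / d.theta0
    demes: list[list[int]] = [list(range(n1)), list(range(n1, n))]
    leaf_pop = np.concatenate([np.zeros(n1, np.int64), np.ones(n2, np.int64)])
    next_node = n
    t = 0.0
    while t < d.t_split and sum(len(dd) for dd in demes) > 1:
        k1, k2 = len(demes[0]), len(demes[1])
        r_c1 = k1 * (k1 - 1) / rho1
        r_c2 = k2 * (k2 - 1) / rho2
        r_m1 = k1 * d.m12 / 2.0
        r_m2 = k2 * d.m21 / 2.0
        total_rate = r_c1 + r_c2 + r_m1 + r_m2
        if total_rate == 0.0:
            break
        t_next = t + rng.exponential(1.0 / total_rate)
        if t_next >= d.t_split:
            break
        t = t_next
        u = rng.random() * total_rate
        if u < r_c1 or u < r_c1 + r_c2:
            deme = demes[0] if u < r_c1 else demes[1]
            kk = len(deme)
            i = rng.integers(kk)
            j = rng.integers(kk - 1)
            if j >= i:
                j += 1
            a, b = deme[int(i)], deme[int(j)]
            parent[a] = parent[b] = next_node
            time[next_node] = t
            hi, lo = max(int(i), int(j)), min(int(i), int(j))
            deme[hi] = deme[-1]
            deme.pop()
            deme[lo] = next_node
            next_node += 1
        elif u < r_c1 + r_c2 + r_m1:
            i = int(rng.integers(len(demes[0])))
            demes[1].append(demes[0][i])
            demes[0][i] = demes[0][-1]
            demes[0].pop()
        else:
            i = int(rng.integers(len(demes[1])))
            demes[0].append(demes[1][i])
            demes[1][i] = demes[1][-1]
            demes[1].pop()
    survivors = demes[0] + demes[1]
    if len(survivors) == 1:
        g = Genealogy(n=n, parent=parent, time=time, leaf_pop=leaf_pop)
        return g
    # merge into the ancestral deme of relative size rhoA
    t = max(t, d.t_split)
    k = len(survivors)
    exps = rng.exponential(size=k - 1)
    us = rng.random(size=2 * (k - 1))
    active = survivors
    for step in range(k - 1):
        kk = len(active)
        t += exps[step] * rhoA / (kk * (kk - 1))
        i = int(us[2 * step] * kk)
        j = int(us[2 * step + 1] * (kk - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = parent[b] = next_node
        time[next_node] = t
        hi, lo = max(i, j), min(i, j)
        active[hi] = active[-1]
        active.pop()
        active[lo] = next_node
        next_node += 1
    return Genealogy(n=n, parent=parent, time=time, leaf_pop=leaf_pop)


def sample_genealogy(
    n_per_pop: int | Sequence[int], d: Demography, rng: np.random.Generator
) -> Genealogy:
    """Draw one genealogy under the demography ``d``.

    ``n_per_pop`` is an integer for single-population models or a pair
    (n1, n2) for IM2.
    """
    if d.model_id == "IM2":
        if isinstance(n_per_pop, int):
            raise ParameterError("IM2 needs a (n1, n2) pair of sample sizes")
        n1, n2 = int(n_per_pop[0]), int(n_per_pop[1])
        if n1 + n2 < 2:
            raise ParameterError("need at least 2 sampled lineages")
        return _im2_genealogy(n1, n2, d, rng)
    n = int(n_per_pop) if isinstance(n_per_pop, (int, np.integer)) else int(sum(n_per_pop))
    if n < 2:
        raise ParameterError("need at least 2 sampled lineages")
    return _single_pop_genealogy(n, d, rng)


def drop_mutations(
    g: Genealogy,
    theta: float,
    rng: np.random.Generator,
    L: int = 1,
    sample_labels: Sequence[str] | None = None,
    fixed_s: int | None = None,
) -> SiteMatrix:
    """Place infinite-sites mutations on a genealogy.

    The mutation count is Poisson with mean ``theta * total_length`` (or
    exactly ``fixed_s`` when conditioning on S); each mutation picks a branch
    proportionally to its length and a unique position uniform on (0, 1).
    The matrix is polarized: 1 marks the derived allele.
    """
    if theta <= 0 and fixed_s is None:
        raise ParameterError("theta must be > 0")
    n = g.n
    labels = list(sample_labels) if sample_labels else [f"hap{i}" for i in range(n)]
    lengths = g.branch_lengths()
    total = lengths.sum()
    nmut = int(fixed_s) if fixed_s is not None else int(rng.poisson(theta * total))
    if nmut == 0:
        return SiteMatrix(
            matrix=np.zeros((n, 0), dtype=np.uint8),
            positions=np.empty(0),
            n=n, L=L, sample_labels=labels,
            polarized=True, unit_positions=True, alignment_bp=L,
        )
    branches = rng.choice(lengths.size, size=nmut, p=lengths / total)
    positions = np.sort(rng.random(nmut))
    leaf_sets = g.leaf_sets()
    matrix = leaf_sets[branches].T.astype(np.uint8)
    return SiteMatrix(
        matrix=matrix,
        positions=positions,
        n=n, L=L, sample_labels=labels,
        polarized=True, unit_positions=True, alignment_bp=L,
    )


def simulate_dataset(
    d: Demography,
    n_per_pop: int | Sequence[int],
    loci: Sequence[tuple[str, float, int]],
    rng: np.random.Generator,
    sample_labels: Sequence[str] | None = None,
) -> list[SiteMatrix]:
    """Independent genealogy + mutations per locus.

    ``loci`` is a sequence of (locus_id, theta_scale, L): the per-locus
    mutation parameter is ``d.theta0 * theta_scale``; ``L`` is carried on the
    matrix so per-site statistics can be formed.
    """
    if not loci:
        raise ParameterError("need at least one locus")
    out = []
    for _, scale, L in loci:
        g = sample_genealogy(n_per_pop, d, rng)
        out.append(
            drop_mutations(g, d.theta0 * scale, rng, L=L, sample_labels=sample_labels)
        )
    return out


def sample_branch_spectrum(
    n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(subtree sizes, branch lengths) of a constant-size coalescent genealogy.

    Lean path for null-distribution simulation: the frequency spectrum of a
    mutation placed on a branch depends only on the number of leaves below
    it, so no topology bookkeeping beyond subtree sizes is needed.
    """
    sizes = np.empty(2 * n - 2, dtype=np.int64)
    lengths = np.empty(2 * n - 2)
    birth = [0.0] * n
    size = [1] * n
    t = 0.0
    exps = rng.exponential(size=n - 1)
    us = rng.random(size=2 * (n - 1))
    idx = 0
    k = n
    for step in range(n - 1):
        t += exps[step] / (k * (k - 1))
        i = int(us[2 * step] * k)
        j = int(us[2 * step + 1] * (k - 1))
        if j >= i:
            j += 1
        sizes[idx] = size[i]
        lengths[idx] = t - birth[i]
        sizes[idx + 1] = size[j]
        lengths[idx + 1] = t - birth[j]
        idx += 2
        merged = size[i] + size[j]
        hi, lo = (i, j) if i > j else (j, i)
        size[hi] = size[-1]
        birth[hi] = birth[-1]
        size.pop(); birth.pop()
        size[lo] = merged
        birth[lo] = t
        k -= 1
    return sizes, lengths


def write_ms(matrices: Sequence[SiteMatrix], path, header: str = "popdemog") -> None:
    """Write simulated matrices in ms-style text format for cross-checking."""
    with open(path, "w") as fh:
        fh.write(f"{header}\n\n")
        for m in matrices:
            fh.write("//\n")
            fh.write(f"segsites: {m.S}\n")
            if m.S:
                pos = " ".join(f"{p:.5f}" for p in m.positions)
                fh.write(f"positions: {pos}\n")
                for row in m.matrix:
                    fh.write("".join(str(int(x)) for x in row) + "\n")
            fh.write("\n")
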