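"""Synthetic island-study datasets with known ground truth.

The generator emulates the shape of a multilocus continental-island survey:
a handful of nuclear loci a few hundred bp long, several island populations
with 14-16 phased haplotypes each, per-site diversity of a few parts per
thousand, and an outgroup sequence per locus divergent enough to polarize
derived alleles unambiguously.

Sequences are built by threading binary site-matrix columns onto a random
ancestral sequence: one substitution per segregating column at a unique
position, ancestral base uniform over ACGT, derived base uniform over the
other three (transition/transversion structure is not modeled -- the
downstream infinite-sites statistics are blind to base identity).
Populations without an explicit pair entry are simulated independently;
pairs are drawn jointly from a two-population isolation-with-migration
history so that between-population divergence is meaningful.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .coalsim import Demography, simulate_dataset
from .errors import ConfigError
from .seqdata import LocusAlignment, SiteMatrix, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# locus lengths spanning the 339-470 bp range typical of sequenced nuclear
# amplicons in this kind of survey
DEFAULT_LOCUS_LENGTHS = (461, 387, 387, 470, 407, 425, 464, 339)


@dataclass
class PopulationSpec:
    population_id: str
    island_id: str
    n_haplotypes: int = 16
    model_id: str = "SNM"
    theta_site: float = 0.004
    params: dict = field(default_factory=dict)  # growth_g, t_b, severity


@dataclass
class PairSpec:
    """Two populations drawn jointly from an IM2 history."""

    pop_a: str
    pop_b: str
    theta1_site: float = 0.004
    theta2_site: float = 0.004
    thetaA_site: float = 0.004
    t_split: float = 0.5
    m12: float = 0.0
    m21: float = 0.0


@dataclass
class StudyConfig:
    populations: list[PopulationSpec]
    loci: list[tuple[str, int]]
    pairs: list[PairSpec] = field(default_factory=list)
    outgroup_divergence: float | None = None  # per-site; default 10x max theta_site
    n_outgroup: int = 1

    def __post_init__(self) -> None:
        ids = [p.population_id for p in self.populations]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate population ids")
        paired = [p for pair in self.pairs for p in (pair.pop_a, pair.pop_b)]
        if len(set(paired)) != len(paired):
            raise ConfigError("a population may appear in at most one pair")
        for p in paired:
            if p not in ids:
                raise ConfigError(f"pair references unknown population {p!r}")
        if not self.loci:
            raise ConfigError("need at least one locus")

    @property
    def divergence(self) -> float:
        if self.outgroup_divergence is not None:
            return self.outgroup_divergence
        return 10.0 * max(p.theta_site for p in self.populations)


def default_island_config(
    n_populations: int = 4, n_haplotypes: int = 16, theta_site: float = 0.004
) -> StudyConfig:
    """Four island populations, eight loci, 16 haplotypes each."""
    pops = [
        PopulationSpec(
            population_id=f"P{i + 1}",
            island_id=f"I{i + 1}",
            n_haplotypes=n_haplotypes,
            theta_site=theta_site,
        )
        for i in range(n_populations)
    ]
    loci = [(f"L{i + 1}", L) for i, L in enumerate(DEFAULT_LOCUS_LENGTHS)]
    return StudyConfig(populations=pops, loci=loci)


@dataclass
class TruthRecord:
    """Everything needed to regenerate a dataset bit-for-bit."""

    seed: int
    config: dict
    files: dict[str, str]
    true_params: dict[str, dict]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))


def _pop_matrices(
    spec: PopulationSpec, loci: list[tuple[str, int]], rng: np.random.Generator
) -> list[SiteMatrix]:
    mean_L = float(np.mean([L for _, L in loci]))
    d = Demography(
        model_id=spec.model_id,
        theta0=spec.theta_site * mean_L,
        growth_g=spec.params.get("growth_g", 0.0),
        t_b=spec.params.get("t_b", 0.0),
        severity=spec.params.get("severity", 1.0),
    )
    labels = [f"{spec.population_id}_{i:02d}" for i in range(spec.n_haplotypes)]
    sim_loci = [(lid, L / mean_L, L) for lid, L in loci]
    return simulate_dataset(d, spec.n_haplotypes, sim_loci, rng, sample_labels=labels)


def _pair_matrices(
    pair: PairSpec,
    spec_a: PopulationSpec,
    spec_b: PopulationSpec,
    loci: list[tuple[str, int]],
    rng: np.random.Generator,
) -> list[SiteMatrix]:
    mean_L = float(np.mean([L for _, L in loci]))
    th1 = pair.theta1_site * mean_L
    d = Demography(
        model_id="IM2",
        theta0=th1,
        theta1=th1,
        theta2=pair.theta2_site * mean_L,
        thetaA=pair.thetaA_site * mean_L,
        t_split=pair.t_split,
        m12=pair.m12,
        m21=pair.m21,
    )
    labels = [f"{spec_a.population_id}_{i:02d}" for i in range(spec_a.n_haplotypes)]
    labels += [f"{spec_b.population_id}_{i:02d}" for i in range(spec_b.n_haplotypes)]
    sim_loci = [(lid, L / mean_L, L) for lid, L in loci]
    return simulate_dataset(
        d, (spec_a.n_haplotypes, spec_b.n_haplotypes), sim_loci, rng,
        sample_labels=labels,
    )


def _thread_sequences(
    locus_id: str,
    L: int,
    blocks: list[SiteMatrix],
    divergence: float,
    n_outgroup: int,
    rng: np.random.Generator,
) -> LocusAlignment:
    """Thread the columns of several site matrices onto one reference.

    Each matrix (one per independently simulated population or pair) claims
    its own set of alignment positions, so simulated unit-interval positions
    map to distinct integer sites.
    """
    total_S = sum(m.S for m in blocks)
    if total_S > L:
        raise ConfigError(
            f"locus {locus_id}: {total_S} segregating sites exceed length {L} "
            "(theta too high for the locus length)"
        )
    ancestral = _BASES[rng.integers(4, size=L)]
    all_pos = rng.choice(L, size=total_S, replace=False)
    rng.shuffle(all_pos)
    haplotypes: list[tuple[str, str]] = []
    cursor = 0
    seg_positions: list[int] = []
    for m in blocks:
        pos = np.sort(all_pos[cursor : cursor + m.S])
        cursor += m.S
        seg_positions.extend(pos.tolist())
        derived = np.empty(m.S, dtype=np.uint8)
        for j, p in enumerate(pos):
            choices = _BASES[_BASES != ancestral[p]]
            derived[j] = choices[rng.integers(3)]
        for i, label in enumerate(m.sample_labels):
            seq = ancestral.copy()
            carried = m.matrix[i].astype(bool)
            seq[pos[carried]] = derived[carried]
            haplotypes.append((label, seq.tobytes().decode()))
    outgroup: list[str] = []
    free = np.setdiff1d(np.arange(L), np.array(seg_positions, dtype=int))
    for _ in range(n_outgroup):
        seq = ancestral.copy()
        n_sub = rng.binomial(free.size, min(1.0, divergence))
        subs = rng.choice(free, size=n_sub, replace=False)
        for p in subs:
            choices = _BASES[_BASES != ancestral[p]]
            seq[p] = choices[rng.integers(3)]
        outgroup.append(seq.tobytes().decode())
    return LocusAlignment(
        locus_id=locus_id, haplotypes=haplotypes, length=L, outgroup=outgroup
    )


def generate_island_study(
    config: StudyConfig,
    rng: np.random.Generator | int,
    out_dir: str | Path,
) -> TruthRecord:
    """Write per-locus FASTA files, a population map and a truth record.

    Returns the TruthRecord; the same config and seed regenerate the files
    byte for byte.
    """
    seed = int(rng) if isinstance(rng, (int, np.integer)) else -1
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    paired = {p for pair in config.pairs for p in (pair.pop_a, pair.pop_b)}
    specs = {p.population_id: p for p in config.populations}

    # per-unit (population or pair) list of per-locus matrices
    unit_matrices: list[list[SiteMatrix]] = []
    true_params: dict[str, dict] = {}
    for pair in config.pairs:
        unit_matrices.append(
            _pair_matrices(pair, specs[pair.pop_a], specs[pair.pop_b], config.loci, rng)
        )
        true_params[f"{pair.pop_a}+{pair.pop_b}"] = asdict(pair)
    for spec in config.populations:
        if spec.population_id in paired:
            continue
        unit_matrices.append(_pop_matrices(spec, config.loci, rng))
        true_params[spec.population_id] = asdict(spec)

    files: dict[str, str] = {}
    for j, (locus_id, L) in enumerate(config.loci):
        blocks = [mats[j] for mats in unit_matrices]
        aln = _thread_sequences(
            locus_id, L, blocks, config.divergence, config.n_outgroup, rng
        )
        path = out_dir / f"{locus_id}.fasta"
        write_fasta(aln, path)
        files[locus_id] = path.name

    map_path = out_dir / "populations.tsv"
    with open(map_path, "w") as fh:
        fh.write("sample\tpopulation\tisland\n")
        for spec in config.populations:
            for i in range(spec.n_haplotypes):
                fh.write(f"{spec.population_id}_{i:02d}\t{spec.population_id}\t{spec.island_id}\n")
    files["population_map"] = map_path.name

    record = TruthRecord(
        seed=seed,
        config={
            "populations": [asdict(p) for p in config.populations],
            "loci": [list(l) for l in config.loci],
            "pairs": [asdict(p) for p in config.pairs],
            "outgroup_divergence": config.divergence,
            "n_outgroup": config.n_outgroup,
        },
        files=files,
        true_params=true_params,
    )
    record.to_json(out_dir / "truth.json")
    return record


@dataclass
class PanelItem:
    model_id: str
    params: dict[str, float]
    matrices: list[SiteMatrix]


DEFAULT_PANEL_GRIDS: dict[str, dict[str, tuple[float, float]]] = {
    # detectable, well-separated parameter regions for model-recovery checks
    "SNM": {"theta_site": (0.002, 0.008)},
    "EXP": {"theta_site": (0.002, 0.008), "growth_g": (5.0, 20.0)},
    "BOT": {"theta_site": (0.002, 0.008), "t_b": (0.1, 0.5), "severity": (0.01, 0.1)},
    "BOT_EXP": {
        "theta_site": (0.002, 0.008), "t_b": (0.1, 0.5),
        "severity": (0.01, 0.1), "growth_g": (5.0, 20.0),
    },
}


def generate_bottleneck_vs_constant_panel(
    n_per_model: int,
    rng: np.random.Generator,
    loci: list[tuple[str, int]] | None = None,
    n_haplotypes: int = 16,
    grids: dict[str, dict[str, tuple[float, float]]] | None = None,
) -> list[PanelItem]:
    """Balanced labeled panel of datasets from the four single-population models.

    Parameters are drawn uniformly (theta and severity log-uniformly) from
    per-model ranges chosen so the histories are distinguishable: severe
    recent bottlenecks, strong growth.
    """
    loci = loci or [(f"L{i + 1}", L) for i, L in enumerate(DEFAULT_LOCUS_LENGTHS)]
    grids = grids or DEFAULT_PANEL_GRIDS
    mean_L = float(np.mean([L for _, L in loci]))
    sim_loci = [(lid, L / mean_L, L) for lid, L in loci]
    items: list[PanelItem] = []
    for model_id, grid in grids.items():
        for _ in range(n_per_model):
            params: dict[str, float] = {}
            for name, (lo, hi) in grid.items():
                if name in ("theta_site", "severity"):
                    params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                else:
                    params[name] = float(rng.uniform(lo, hi))
            d = Demography(
                model_id=model_id,
                theta0=params["theta_site"] * mean_L,
                growth_g=params.get("growth_g", 0.0),
                t_b=params.get("t_b", 0.0),
                severity=params.get("severity", 1.0),
            )
            items.append(
                PanelItem(
                    model_id=model_id,
                    params=params,
                    matrices=simulate_dataset(d, n_haplotypes, sim_loci, rng),
                )
            )
    return items
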