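"""Phased haplotype alignments, population maps and binary site matrices.

Input conventions
-----------------
* One FASTA file per locus, containing every phased haplotype of the ingroup.
  Outgroup sequences live in the same file with record ids prefixed
  ``OUTGROUP|``.
* Population map: tab-separated file with a header row and three columns
  ``sample``, ``population``, ``island``.
* Optional column mask: BED-like TSV ``locus  start  end`` with 0-based
  half-open alignment coordinates; masked columns are treated like missing
  data (excluded from both the site matrix and the analyzed length).

Missing data are handled by complete deletion: an alignment column that
contains ``-`` or ``N`` in any ingroup sequence is dropped entirely and the
analyzed length ``L`` is reduced accordingly.  Columns with three or more
ingroup alleles are excluded from the site matrix (the downstream statistics
assume biallelic, infinite-sites variation) but still count toward ``L``;
their number is reported on the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, FormatError, ReconciliationError

OUTGROUP_PREFIX = "OUTGROUP|"

_MISSING = (ord("-"), ord("N"))


@dataclass
class LocusAlignment:
    """A phased haplotype alignment for one locus, plus optional outgroup rows."""

    locus_id: str
    haplotypes: list[tuple[str, str]]
    length: int
    outgroup: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.haplotypes) < 2:
            raise AlignmentError(
                f"locus {self.locus_id}: need at least 2 ingroup haplotypes, "
                f"got {len(self.haplotypes)}"
            )
        labels = [lab for lab, _ in self.haplotypes]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise AlignmentError(f"locus {self.locus_id}: duplicate labels {dupes}")
        for lab, seq in self.haplotypes:
            if len(seq) != self.length:
                raise AlignmentError(
                    f"locus {self.locus_id}: sequence {lab!r} has length "
                    f"{len(seq)}, expected {self.length}"
                )
        for i, seq in enumerate(self.outgroup):
            if len(seq) != self.length:
                raise AlignmentError(
                    f"locus {self.locus_id}: outgroup sequence {i} has length "
                    f"{len(seq)}, expected {self.length}"
                )

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.haplotypes]

    @property
    def n(self) -> int:
        return len(self.haplotypes)


def read_fasta(path: str | Path, locus_id: str | None = None) -> LocusAlignment:
    """Read one locus alignment from FASTA.

    Records whose id starts with ``OUTGROUP|`` become outgroup rows; all
    sequences are upper-cased and record order is preserved.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    haplotypes: list[tuple[str, str]] = []
    outgroup: list[str] = []
    for rec in records:
        seq = str(rec.seq).upper()
        if rec.id.startswith(OUTGROUP_PREFIX):
            outgroup.append(seq)
        else:
            haplotypes.append((rec.id, seq))
    length = len(records[0].seq)
    return LocusAlignment(
        locus_id=locus_id or path.stem,
        haplotypes=haplotypes,
        length=length,
        outgroup=outgroup,
    )


def write_fasta(alignment: LocusAlignment, path: str | Path) -> None:
    """Write an alignment (ingroup rows first, then outgroup rows) to FASTA."""
    records = [
        SeqRecord(Seq(seq), id=lab, description="")
        for lab, seq in alignment.haplotypes
    ]
    records += [
        SeqRecord(Seq(seq), id=f"{OUTGROUP_PREFIX}{alignment.locus_id}_og{i}", description="")
        for i, seq in enumerate(alignment.outgroup)
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class SiteMatrix:
    """Binary haplotype-by-segregating-site matrix.

    ``matrix[i, j] == 1`` means haplotype ``i`` carries the alternate allele at
    column ``j`` (the derived allele when the column is polarized).  ``L`` is
    the analyzed length in bp after complete deletion of missing columns;
    ``alignment_bp`` is the original alignment length, used for block-length
    bookkeeping.  ``positions`` are 0-based alignment column indices for real
    data, or numbers in (0, 1) for simulated loci (``unit_positions=True``).
    """

    matrix: np.ndarray
    positions: np.ndarray
    n: int
    L: int
    sample_labels: list[str]
    polarized: bool = False
    col_polarized: np.ndarray | None = None
    unit_positions: bool = False
    alignment_bp: int | None = None
    n_multiallelic: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[0] != self.n or self.n != len(self.sample_labels):
            raise ValueError("matrix rows, n and sample_labels must agree")
        if self.matrix.shape[1] != self.positions.size:
            raise ValueError("one position per matrix column required")
        if self.S and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")
        # real alignments cannot hold more segregating columns than sites;
        # infinite-sites simulations may (positions live on the unit interval)
        if self.L < self.S and not self.unit_positions:
            raise ValueError(f"L={self.L} smaller than S={self.S}")
        if self.S:
            csum = self.matrix.sum(axis=0)
            if (csum == 0).any() or (csum == self.n).any():
                raise ValueError("every column must be strictly segregating")
        if self.col_polarized is None:
            self.col_polarized = np.full(self.S, self.polarized, dtype=bool)
        else:
            self.col_polarized = np.asarray(self.col_polarized, dtype=bool)
        if self.alignment_bp is None:
            self.alignment_bp = self.L

    @property
    def S(self) -> int:
        return self.matrix.shape[1]

    def subset(self, rows: Sequence[int] | np.ndarray) -> "SiteMatrix":
        """Row subset, dropping columns that are no longer segregating.

        ``L`` and ``alignment_bp`` are preserved: the analyzed sites do not
        change when restricting to a subpopulation.
        """
        rows = np.asarray(rows, dtype=int)
        sub = self.matrix[rows]
        csum = sub.sum(axis=0)
        keep = (csum > 0) & (csum < rows.size)
        return SiteMatrix(
            matrix=sub[:, keep],
            positions=self.positions[keep],
            n=rows.size,
            L=self.L,
            sample_labels=[self.sample_labels[i] for i in rows],
            polarized=bool(self.col_polarized[keep].all()) if keep.any() else self.polarized,
            col_polarized=self.col_polarized[keep],
            unit_positions=self.unit_positions,
            alignment_bp=self.alignment_bp,
            n_multiallelic=self.n_multiallelic,
        )

    def rows_for(self, labels: Iterable[str]) -> np.ndarray:
        wanted = set(labels)
        return np.array(
            [i for i, lab in enumerate(self.sample_labels) if lab in wanted],
            dtype=int,
        )


def extract_site_matrix(
    alignment: LocusAlignment,
    use_outgroup: bool = False,
    mask: Sequence[tuple[int, int]] | None = None,
) -> SiteMatrix:
    """Reduce an alignment to its biallelic segregating columns.

    Parameters
    ----------
    use_outgroup
        Polarize columns against the outgroup rows: a column is oriented
        (0 = ancestral, 1 = derived) only when every outgroup sequence agrees
        and matches one of the two ingroup alleles.  Other columns stay in the
        matrix unpolarized.
    mask
        0-based half-open column intervals to exclude (treated as missing).
    """
    if alignment.n < 2:
        raise AlignmentError("need at least 2 ingroup sequences")
    if use_outgroup and not alignment.outgroup:
        raise AlignmentError(f"locus {alignment.locus_id}: no outgroup sequences")

    n, length = alignment.n, alignment.length
    arr = np.frombuffer(
        "".join(seq for _, seq in alignment.haplotypes).encode(), dtype=np.uint8
    ).reshape(n, length)
    og = (
        np.frombuffer("".join(alignment.outgroup).encode(), dtype=np.uint8).reshape(
            len(alignment.outgroup), length
        )
        if alignment.outgroup
        else None
    )

    missing = np.zeros(length, dtype=bool)
    for byte in _MISSING:
        missing |= (arr == byte).any(axis=0)
    if mask:
        for start, end in mask:
            missing[max(0, start) : min(length, end)] = True

    L = int((~missing).sum())
    variable = (~missing) & (arr != arr[0]).any(axis=0)

    cols: list[np.ndarray] = []
    positions: list[int] = []
    col_polarized: list[bool] = []
    n_multi = 0
    for j in np.flatnonzero(variable):
        col = arr[:, j]
        alleles, counts = np.unique(col, return_counts=True)
        if alleles.size > 2:
            n_multi += 1
            continue
        a0 = a1 = None
        polarized = False
        if og is not None and use_outgroup:
            og_col = og[:, j]
            anc = og_col[0]
            if anc not in _MISSING and (og_col == anc).all() and anc in alleles:
                a0 = anc
                polarized = True
        if a0 is None:
            # major-allele rule; ties go to the first haplotype's allele
            if counts[0] == counts[1]:
                a0 = col[0]
            else:
                a0 = alleles[np.argmax(counts)]
        cols.append((col != a0).astype(np.uint8))
        positions.append(j)
        col_polarized.append(polarized)

    matrix = (
        np.column_stack(cols) if cols else np.zeros((n, 0), dtype=np.uint8)
    )
    col_pol = np.asarray(col_polarized, dtype=bool)
    return SiteMatrix(
        matrix=matrix,
        positions=np.asarray(positions, dtype=float),
        n=n,
        L=L,
        sample_labels=alignment.labels,
        polarized=bool(col_pol.all()) if matrix.shape[1] else bool(use_outgroup),
        col_polarized=col_pol,
        unit_positions=False,
        alignment_bp=length,
        n_multiallelic=n_multi,
    )


@dataclass
class PopulationMap:
    """sample -> population and population -> island assignments."""

    assignments: dict[str, str]
    islands: dict[str, str]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop)
        return list(seen)

    def samples_in(self, population_id: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population_id]

    def population_of(self, sample: str) -> str:
        return self.assignments[sample]


def read_population_map(path: str | Path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "population", "island"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: population map needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    if df["sample"].duplicated().any():
        dupes = sorted(df.loc[df["sample"].duplicated(), "sample"].unique())
        raise ReconciliationError(f"duplicate sample rows in map: {dupes}")
    assignments = dict(zip(df["sample"], df["population"]))
    islands = dict(zip(df["population"], df["island"]))
    return PopulationMap(assignments=assignments, islands=islands)


def attach_population_map(
    dataset: list[LocusAlignment], map_path: str | Path
) -> tuple[list[LocusAlignment], PopulationMap]:
    """Resolve every haplotype label in `dataset` against a population map."""
    popmap = read_population_map(map_path)
    missing: set[str] = set()
    for aln in dataset:
        for lab in aln.labels:
            if lab not in popmap.assignments:
                missing.add(lab)
    if missing:
        raise ReconciliationError(
            f"labels missing from population map: {sorted(missing)}"
        )
    # every population represented in the data must keep >= 2 haplotypes
    seen = {lab for aln in dataset for lab in aln.labels}
    for pop in popmap.populations:
        present = [s for s in popmap.samples_in(pop) if s in seen]
        if present and len(present) < 2:
            raise ReconciliationError(
                f"population {pop!r} has fewer than 2 haplotypes in the data"
            )
    return dataset, popmap


def read_mask(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED-like mask TSV (locus, start, end) into per-locus intervals."""
    df = pd.read_csv(path, sep="\t", header=None, names=["locus", "start", "end"])
    out: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if end <= start:
            raise FormatError(f"mask interval for {row.locus}: end {end} <= start {start}")
        out.setdefault(str(row.locus), []).append((start, end))
    return out
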