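"""Sequence and marker-table I/O for hybrid-speciation diagnostics.

This module defines the in-memory containers shared by the rest of the
package — aligned loci with per-sequence metadata, polymorphism tables,
dominant (AFLP-style) marker matrices, and sample→population maps — and
the readers/writers that move them to and from FASTA, TSV and Newick.

FASTA header convention
-----------------------
Each record id is pipe-delimited: ``sampleID|population|sex|alleleIndex``,
e.g. ``app07|appalachiensis|M|1``.  ``sex`` is one of ``M``/``F``/``U``;
``alleleIndex`` distinguishes the two phased Z-chromosome copies of a
heterozygous (ZZ) male and is ``0`` otherwise.  Trailing fields may be
omitted; missing sex defaults to unknown, missing allele index to 0.

Missing bases are coded ``N`` and excluded site-wise downstream.
Alignment coordinates are 0-based half-open internally and 1-based in
human-readable reports.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

GAP = "-"
MISSING = "N"

__all__ = [
    "Inheritance",
    "Sex",
    "SequenceRecord",
    "AlignedLocus",
    "Site",
    "PolymorphismTable",
    "PopulationMap",
    "AFLPMatrix",
    "FormatError",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "expand_heterozygous_males",
    "extract_polymorphisms",
    "read_aflp_matrix",
    "write_aflp_matrix",
    "read_population_map",
    "write_population_map",
    "read_newick",
    "write_newick",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class Inheritance(str, enum.Enum):
    MITOCHONDRIAL = "mitochondrial"
    Z_LINKED = "z_linked"
    AUTOSOMAL = "autosomal"


class Sex(str, enum.Enum):
    MALE = "M"
    FEMALE = "F"
    UNKNOWN = "U"


@dataclass(frozen=True)
class SequenceRecord:
    sequence_id: str
    sample_id: str
    population: str
    sex: Sex
    seq: str


@dataclass
class AlignedLocus:
    """One gene's aligned sequences plus per-sequence sample metadata."""

    locus_name: str
    inheritance: Inheritance
    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError(f"locus {self.locus_name!r}: no sequences")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            bad = next(r for r in self.records if len(r.seq) != len(self.records[0].seq))
            raise FormatError(
                f"locus {self.locus_name!r}: ragged alignment at record {bad.sequence_id!r} "
                f"(length {len(bad.seq)}, expected {len(self.records[0].seq)})"
            )
        ids = [r.sequence_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError(f"locus {self.locus_name!r}: duplicate sequence ids")
        if self.inheritance is Inheritance.MITOCHONDRIAL:
            samples = [r.sample_id for r in self.records]
            if len(set(samples)) != len(samples):
                raise FormatError(
                    f"locus {self.locus_name!r}: mitochondrial locus with >1 sequence per sample"
                )

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].seq)

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def matrix(self) -> np.ndarray:
        """Character matrix (n_sequences, alignment_length) of single bases."""
        return np.array([list(r.seq) for r in self.records], dtype="U1")


def _parse_header(header: str) -> tuple[str, str, Sex, int]:
    parts = header.split("|")
    sample = parts[0]
    pop = parts[1] if len(parts) > 1 else ""
    sex = Sex(parts[2].upper()) if len(parts) > 2 and parts[2] else Sex.UNKNOWN
    allele = int(parts[3]) if len(parts) > 3 and parts[3] else 0
    return sample, pop, sex, allele


def read_fasta_alignment(path: str | Path, inheritance: Inheritance | str) -> AlignedLocus:
    """Read one locus alignment from FASTA.

    Headers follow the pipe-delimited convention described in the module
    docstring.  All records must share one length; a ragged alignment is a
    :class:`FormatError` naming the offending record.
    """
    inheritance = Inheritance(inheritance)
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sample, pop, sex, allele = _parse_header(rec.id)
        records.append(
            SequenceRecord(
                sequence_id=rec.id,
                sample_id=sample,
                population=pop,
                sex=sex,
                seq=str(rec.seq).upper(),
            )
        )
    if not records:
        raise FormatError(f"{path}: empty FASTA (no records)")
    return AlignedLocus(locus_name=path.stem, inheritance=inheritance, records=records)


def write_fasta_alignment(locus: AlignedLocus, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in locus.records:
            fh.write(f">{r.sequence_id}\n{r.seq}\n")


def expand_heterozygous_males(
    locus: AlignedLocus,
    phased_pairs: Mapping[str, tuple[str, str]],
) -> AlignedLocus:
    """Expand each heterozygous ZZ male into its two phased Z sequences.

    Males are diploid for Z-linked genes, so a heterozygous male
    contributes two sequences to the alignment while females (hemizygous
    ZW) and homozygous males contribute one; this is why published
    per-gene sequence counts can exceed sample counts.  ``phased_pairs``
    maps a male sample id to its two externally phased aligned sequences;
    phasing itself is out of scope here.
    """
    if locus.inheritance is not Inheritance.Z_LINKED:
        raise ValueError("heterozygous-male expansion applies to Z-linked loci only")
    out: list[SequenceRecord] = []
    seen = set()
    for r in locus.records:
        if r.sample_id in phased_pairs:
            if r.sex is Sex.FEMALE:
                raise ValueError(
                    f"sample {r.sample_id!r} is female: hemizygous, cannot carry a phased Z pair"
                )
            if r.sample_id in seen:
                continue
            seen.add(r.sample_id)
            a, b = phased_pairs[r.sample_id]
            if len(a) != locus.alignment_length or len(b) != locus.alignment_length:
                raise FormatError(f"phased pair for {r.sample_id!r} has wrong length")
            for i, s in enumerate((a, b)):
                out.append(
                    SequenceRecord(
                        sequence_id=f"{r.sample_id}|{r.population}|{r.sex.value}|{i}",
                        sample_id=r.sample_id,
                        population=r.population,
                        sex=r.sex,
                        seq=s.upper(),
                    )
                )
        else:
            out.append(r)
    return AlignedLocus(locus.locus_name, locus.inheritance, out)


@dataclass(frozen=True)
class Site:
    site_id: str
    kind: str  # "snp" | "indel"
    start: int  # 0-based, half-open
    end: int

    @property
    def label(self) -> str:
        """1-based human-readable position label."""
        if self.end - self.start == 1:
            return f"{self.start + 1}"
        return f"{self.start + 1}-{self.end}"


@dataclass
class PolymorphismTable:
    """Variable sites of one locus with per-sequence allele calls.

    ``calls`` is a DataFrame indexed by sequence_id with one column per
    site; entries are allele codes (a base for SNP sites, ``del``/``ins``
    for indel sites) or NaN for missing data.
    """

    locus_name: str
    sites: list[Site]
    calls: pd.DataFrame
    sample_ids: pd.Series  # sequence_id -> sample_id
    populations: pd.Series  # sequence_id -> population label

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site(self, site_id: str) -> Site:
        return next(s for s in self.sites if s.site_id == site_id)


def extract_polymorphisms(locus: AlignedLocus) -> PolymorphismTable:
    """Tabulate variable sites of an alignment.

    SNP sites are alignment columns showing ≥2 distinct non-gap, non-N
    bases.  Indels are collapsed to single sites: a maximal run of
    consecutive columns gapped in an identical (non-empty, proper) set of
    sequences is scored as one polymorphism regardless of its length, so a
    multi-base deletion event counts once.  Sequences gapped at a SNP
    column are coded missing there (the gap is already scored by its indel
    site); ``N`` is always missing.
    """
    if locus.n_sequences < 2:
        raise ValueError("need at least 2 sequences to call polymorphisms")
    M = locus.matrix()
    n, L = M.shape
    gap = M == GAP
    sites: list[Site] = []
    columns: dict[str, list] = {}

    # indel sites: maximal runs of columns with identical non-trivial gap pattern
    run_start = None
    prev_pattern: tuple | None = None
    def flush(run_start, run_end, pattern):
        idx = len([s for s in sites if s.kind == "indel"]) + 1
        site = Site(site_id=f"{locus.locus_name}:indel{idx}", kind="indel", start=run_start, end=run_end)
        sites.append(site)
        col = np.where(np.array(pattern), "del", "ins").astype(object)
        # sequences entirely N across the span are missing
        span = M[:, run_start:run_end]
        all_n = (span == MISSING).all(axis=1)
        col[all_n & ~np.array(pattern)] = np.nan
        columns[site.site_id] = col

    for j in range(L):
        pat = tuple(gap[:, j])
        nontrivial = any(pat) and not all(pat)
        if nontrivial and pat == prev_pattern:
            pass  # extend current run
        else:
            if prev_pattern is not None:
                flush(run_start, j, prev_pattern)
                prev_pattern, run_start = None, None
            if nontrivial:
                run_start, prev_pattern = j, pat
    if prev_pattern is not None:
        flush(run_start, L, prev_pattern)

    # SNP sites: >= 2 distinct observed bases ignoring gaps and N
    snp_idx = 0
    snp_entries = []
    for j in range(L):
        colchars = M[:, j]
        obs = colchars[(colchars != GAP) & (colchars != MISSING)]
        if len(set(obs.tolist())) >= 2:
            snp_idx += 1
            site = Site(site_id=f"{locus.locus_name}:snp{snp_idx}", kind="snp", start=j, end=j + 1)
            snp_entries.append((site, colchars))
    for site, colchars in snp_entries:
        sites.append(site)
        col = colchars.astype(object).copy()
        col[(colchars == GAP) | (colchars == MISSING)] = np.nan
        columns[site.site_id] = col

    sites.sort(key=lambda s: (s.start, s.kind))
    seq_ids = [r.sequence_id for r in locus.records]
    calls = pd.DataFrame(
        {s.site_id: columns[s.site_id] for s in sites}, index=pd.Index(seq_ids, name="sequence_id")
    )
    return PolymorphismTable(
        locus_name=locus.locus_name,
        sites=sites,
        calls=calls,
        sample_ids=pd.Series({r.sequence_id: r.sample_id for r in locus.records}),
        populations=pd.Series({r.sequence_id: r.population for r in locus.records}),
    )


@dataclass
class PopulationMap:
    """sample_id → (population, sex) assignments."""

    table: pd.DataFrame  # index sample_id, columns: population, sex

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids in population map: {dups}")

    @classmethod
    def from_pairs(cls, assignments: Mapping[str, tuple[str, str]]) -> "PopulationMap":
        df = pd.DataFrame.from_dict(assignments, orient="index", columns=["population", "sex"])
        df.index.name = "sample_id"
        return cls(df)

    def population(self, sample_id: str) -> str:
        try:
            return self.table.loc[sample_id, "population"]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in population map") from None

    def samples_of(self, population: str) -> list[str]:
        return self.table.index[self.table["population"] == population].tolist()

    def populations(self) -> list[str]:
        return pd.unique(self.table["population"]).tolist()

    def groups_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples absent from population map: {missing}")
        return self.table.loc[list(sample_ids), "population"].to_numpy()


def read_population_map(path: str | Path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "population"}
    if not required.issubset(df.columns):
        raise FormatError(f"population map needs columns {sorted(required)}; got {list(df.columns)}")
    if "sex" not in df.columns:
        df["sex"] = "U"
    df = df.set_index("sample_id")[["population", "sex"]]
    return PopulationMap(df)


def write_population_map(pmap: PopulationMap, path: str | Path) -> None:
    pmap.table.to_csv(path, sep="\t")


@dataclass
class AFLPMatrix:
    """Individuals × dominant binary markers (band present/absent).

    ``bands`` is a DataFrame indexed by sample id with marker-id columns;
    values 0/1, NaN for missing scores.
    """

    bands: pd.DataFrame

    def __post_init__(self) -> None:
        if self.bands.columns.duplicated().any():
            raise FormatError("duplicate marker ids in AFLP matrix")
        if self.bands.index.duplicated().any():
            raise FormatError("duplicate sample ids in AFLP matrix")

    @property
    def individuals(self) -> list[str]:
        return self.bands.index.tolist()

    @property
    def markers(self) -> list[str]:
        return self.bands.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape

    def polymorphic(self) -> "AFLPMatrix":
        """Drop monomorphic markers (band fixed present or fixed absent)."""
        vals = self.bands
        keep = [c for c in vals.columns if vals[c].dropna().nunique() >= 2]
        return AFLPMatrix(vals[keep].copy())

    def subset(self, sample_ids: Iterable[str] | None = None, markers: Iterable[str] | None = None) -> "AFLPMatrix":
        df = self.bands
        if sample_ids is not None:
            df = df.loc[list(sample_ids)]
        if markers is not None:
            df = df[list(markers)]
        return AFLPMatrix(df.copy())

    def concat(self, other: "AFLPMatrix") -> "AFLPMatrix":
        if list(other.markers) != list(self.markers):
            raise FormatError("marker sets differ; cannot concatenate AFLP matrices")
        return AFLPMatrix(pd.concat([self.bands, other.bands]))


def read_aflp_matrix(path: str | Path) -> AFLPMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return AFLPMatrix(df.astype(float))


def write_aflp_matrix(aflp: AFLPMatrix, path: str | Path) -> None:
    out = aflp.bands.copy()
    out.index.name = "sample_id"
    # write clean integers where not missing
    out.to_csv(path, sep="\t", float_format="%.0f")


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", suppress_internal_node_taxa=True)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
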