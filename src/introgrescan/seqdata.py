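"""Haplotype alignments, specimen metadata, and segregating-site classification.

The unit of analysis throughout the package is a per-locus alignment of
phased haplotype sequences, each tied to a specimen record (species, race,
colour phenotype, geographic region, locality).  Sites are classified
relative to a pair of populations into shared polymorphisms, exclusive
polymorphisms, fixed differences and monomorphic columns — the vocabulary
the shared-polymorphism LD gene-flow test is built on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignmentError",
    "InputError",
    "HaplotypeAlignment",
    "SpecimenMetadata",
    "SiteClass",
    "SiteClassification",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_metadata",
    "classify_sites",
    "classification_counts",
    "maf_filter",
    "SPECIES",
    "PHENOTYPES",
    "REGIONS",
]

VALID_BASES = frozenset("ACGTN-")
NUCLEOTIDES = frozenset("ACGT")

SPECIES = frozenset(
    {"melpomene", "cydno", "timareta", "heurippa", "numata_outgroup"}
)
PHENOTYPES = frozenset({"red_banded", "rayed", "non_red"})
REGIONS = frozenset(
    {
        "guiana_shield",
        "amazon",
        "pacific",
        "east_andes_foothills",
        "cauca_valley",
        "magdalena_valley",
    }
)

METADATA_COLUMNS = (
    "haplotype_id",
    "species",
    "race",
    "phenotype",
    "region",
    "locality",
)


class AlignmentError(ValueError):
    """Raised when sequences do not form a valid alignment."""


class InputError(ValueError):
    """Raised for malformed or inconsistent user input."""


@dataclass(frozen=True)
class HaplotypeAlignment:
    """Equal-length phased nucleotide sequences for one locus.

    Parameters
    ----------
    locus_name:
        Label for the locus (used in reports).
    ids:
        One unique identifier per haplotype.
    sequences:
        Aligned sequences over the alphabet ``{A,C,G,T,-,N}``; all the
        same length. Lowercase input is uppercased on construction.
    """

    locus_name: str
    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __init__(self, locus_name: str, ids: Sequence[str], sequences: Sequence[str]):
        ids = tuple(str(i) for i in ids)
        sequences = tuple(str(s).upper() for s in sequences)
        if len(ids) != len(sequences):
            raise AlignmentError(
                f"{len(ids)} ids but {len(sequences)} sequences"
            )
        if not sequences:
            raise InputError("alignment has no records")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate haplotype ids: {dupes}")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        if lengths == {0}:
            raise AlignmentError("alignment length must be >= 1")
        bad = set("".join(sequences)) - VALID_BASES
        if bad:
            raise InputError(f"invalid characters in sequences: {sorted(bad)}")
        object.__setattr__(self, "locus_name", locus_name)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "sequences", sequences)

    @property
    def n_haplotypes(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def matrix(self) -> np.ndarray:
        """Alignment as an (n_haplotypes, length) array of single characters."""
        return np.array([list(s) for s in self.sequences], dtype="U1")

    def index_of(self, haplotype_ids: Iterable[str]) -> np.ndarray:
        """Row indices for the given haplotype ids, in the given order."""
        lookup = {h: i for i, h in enumerate(self.ids)}
        try:
            return np.array([lookup[h] for h in haplotype_ids], dtype=int)
        except KeyError as exc:
            raise InputError(f"unknown haplotype id {exc.args[0]!r}") from None

    def subset(self, haplotype_ids: Sequence[str]) -> "HaplotypeAlignment":
        rows = self.index_of(haplotype_ids)
        return HaplotypeAlignment(
            self.locus_name,
            [self.ids[i] for i in rows],
            [self.sequences[i] for i in rows],
        )


def read_fasta_alignment(path: str | Path, locus_name: str | None = None) -> HaplotypeAlignment:
    """Read one locus alignment from FASTA.

    The locus name defaults to the file stem. Bases are uppercased;
    ragged alignments and duplicate ids are rejected.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return HaplotypeAlignment(
        locus_name if locus_name is not None else path.stem,
        [r.id for r in records],
        [str(r.seq) for r in records],
    )


def write_fasta_alignment(aln: HaplotypeAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=hid, description="")
        for hid, seq in zip(aln.ids, aln.sequences)
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


@dataclass(frozen=True)
class SpecimenMetadata:
    """Specimen labels keyed by haplotype id.

    Wraps a DataFrame indexed by ``haplotype_id`` with columns
    ``species``, ``race``, ``phenotype``, ``region``, ``locality``.
    Species, phenotype and region come from closed vocabularies.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS[1:] if c not in self.table.columns]
        if missing:
            raise InputError(f"metadata missing columns: {missing}")
        for col, vocab in (
            ("species", SPECIES),
            ("phenotype", PHENOTYPES),
            ("region", REGIONS),
        ):
            bad = set(self.table[col]) - vocab
            if bad:
                raise InputError(
                    f"unknown {col} token(s) {sorted(bad)}; allowed: {sorted(vocab)}"
                )
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise InputError(f"duplicate haplotype ids in metadata: {dupes}")

    def __len__(self) -> int:
        return len(self.table)

    def ids_where(self, predicate: str) -> list[str]:
        """Haplotype ids matching a predicate like
        ``"species=melpomene & phenotype=rayed"``.

        Clauses are joined with ``&`` (all must hold); within a clause,
        comma-separated values are alternatives
        (``species=timareta,heurippa``).
        """
        mask = pd.Series(True, index=self.table.index)
        for clause in predicate.split("&"):
            clause = clause.strip()
            if not clause:
                continue
            if "=" not in clause:
                raise InputError(f"malformed predicate clause {clause!r}")
            col, _, raw = clause.partition("=")
            col = col.strip()
            if col not in self.table.columns:
                raise InputError(f"unknown metadata column {col!r}")
            values = {v.strip() for v in raw.split(",")}
            mask &= self.table[col].isin(values)
        return self.table.index[mask].tolist()

    def phenotype_of(self, haplotype_id: str) -> str:
        return str(self.table.loc[haplotype_id, "phenotype"])


def read_metadata(path: str | Path, alignment: HaplotypeAlignment | None = None) -> SpecimenMetadata:
    """Read the specimen table (TSV with a header line) and, when an
    alignment is supplied, require a row for every haplotype in it."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise InputError(f"metadata file missing columns: {missing_cols}")
    df = df.set_index("haplotype_id")
    meta = SpecimenMetadata(df)
    if alignment is not None:
        absent = [h for h in alignment.ids if h not in df.index]
        if absent:
            raise InputError(
                f"metadata missing haplotype id(s): {absent[:10]}"
            )
    return meta


def write_metadata(meta: SpecimenMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="haplotype_id")


class SiteClass(str, enum.Enum):
    SHARED = "shared"
    EXCLUSIVE_POP1 = "exclusive_pop1"
    EXCLUSIVE_POP2 = "exclusive_pop2"
    FIXED_DIFFERENCE = "fixed_difference"
    MONOMORPHIC = "monomorphic"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class SiteClassification:
    """Classification of one alignment column relative to a population pair.

    ``position`` is 0-based; reports add 1.
    """

    position: int
    alleles: frozenset[str]
    klass: SiteClass


def classify_sites(
    aln: HaplotypeAlignment,
    pop1: Iterable[str],
    pop2: Iterable[str],
) -> list[SiteClassification]:
    """Classify every column relative to two disjoint populations.

    A column is *shared* when both populations segregate for the same two
    alleles, *exclusive* to a population when only that population
    segregates, and a *fixed difference* when each population is
    monomorphic for a different base.  Columns with a gap or ``N`` in
    either population, or more than two alleles pooled across the two
    populations, are *excluded* — gapped and multiallelic columns have no
    defined two-allele disequilibrium.
    """
    pop1 = list(pop1)
    pop2 = list(pop2)
    if not pop1 or not pop2:
        raise InputError("both populations must be non-empty")
    if set(pop1) & set(pop2):
        raise InputError("populations must be disjoint")
    mat = aln.matrix()
    rows1 = mat[aln.index_of(pop1)]
    rows2 = mat[aln.index_of(pop2)]

    out: list[SiteClassification] = []
    for j in range(aln.length):
        a1 = set(rows1[:, j])
        a2 = set(rows2[:, j])
        pooled = a1 | a2
        if pooled - NUCLEOTIDES or len(pooled) > 2:
            klass = SiteClass.EXCLUDED
        elif len(pooled) == 1:
            klass = SiteClass.MONOMORPHIC
        elif len(a1) == 2 and len(a2) == 2:
            klass = SiteClass.SHARED
        elif len(a1) == 2:
            klass = SiteClass.EXCLUSIVE_POP1
        elif len(a2) == 2:
            klass = SiteClass.EXCLUSIVE_POP2
        else:
            klass = SiteClass.FIXED_DIFFERENCE
        out.append(SiteClassification(j, frozenset(pooled), klass))
    return out


def classification_counts(classes: Sequence[SiteClassification]) -> dict[SiteClass, int]:
    counts = {k: 0 for k in SiteClass}
    for c in classes:
        counts[c.klass] += 1
    return counts


def classification_report(
    classes: Sequence[SiteClassification],
) -> pd.DataFrame:
    """Tabular site-classification report with 1-based positions."""
    return pd.DataFrame(
        {
            "position": [c.position + 1 for c in classes],
            "alleles": ["".join(sorted(c.alleles)) for c in classes],
            "class": [c.klass.value for c in classes],
        }
    )


def maf_filter(aln: HaplotypeAlignment, threshold: float) -> list[int]:
    """Indices of biallelic segregating columns whose minor-allele
    frequency strictly exceeds ``threshold``.

    Frequencies are computed over haplotypes carrying an unambiguous base
    at the column; gap/``N`` carriers do not count toward the denominator.
    The comparison is strict, so at ``threshold=0.05`` a singleton among
    20 haplotypes (frequency exactly 0.05) is dropped.
    """
    if not 0 <= threshold < 0.5:
        raise InputError(f"threshold must be in [0, 0.5), got {threshold}")
    mat = aln.matrix()
    keep: list[int] = []
    for j in range(aln.length):
        col = mat[:, j]
        col = col[np.isin(col, list(NUCLEOTIDES))]
        if col.size == 0:
            continue
        alleles, counts = np.unique(col, return_counts=True)
        if len(alleles) != 2:
            continue
        if counts.min() / col.size > threshold:
            keep.append(j)
    return keep
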