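"""Reading, writing and filtering of the pipeline's external artifacts.

Sequences and alignments travel as FASTA (via Bio.SeqIO); trait tables,
ortholog maps and reports are delimited text with a header (TSV by default).
Coordinates in reports are 1-based.  Missing trait values are explicit
markers, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, EmptyAlignmentError, TableError

NT_ALPHABET = frozenset("ACGTN-")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY") | frozenset("X-*")
#: cell contents read as "value absent"
MISSING_MARKERS = frozenset({"", "na", "nan", "none", "-", "—", "?"})

STATUSES = ("functional", "pseudogene", "lost")


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame codon-aware nucleotide alignment for one gene.

    Invariants: all sequences equal length, length divisible by 3, alphabet
    {A,C,G,T,-,N}, species identifiers unique.
    """

    gene_id: str
    entries: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.entries:
            raise AlignmentError(f"{self.gene_id}: alignment has no sequences")
        lengths = {len(seq) for _, seq in self.entries}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.gene_id}: unequal sequence lengths {sorted(lengths)}"
            )
        (length,) = lengths
        if length % 3 != 0:
            raise AlignmentError(
                f"{self.gene_id}: length {length} is not a multiple of 3"
            )
        for sp, seq in self.entries:
            bad = set(seq) - NT_ALPHABET
            if bad:
                raise AlignmentError(
                    f"{self.gene_id}/{sp}: illegal characters {sorted(bad)}"
                )
        ids = [sp for sp, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise AlignmentError(f"{self.gene_id}: duplicate species identifiers")

    @property
    def length(self) -> int:
        return len(self.entries[0][1])

    @property
    def n_codons(self) -> int:
        return self.length // 3

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sp for sp, _ in self.entries)

    def sequence(self, species_id: str) -> str:
        for sp, seq in self.entries:
            if sp == species_id:
                return seq
        raise KeyError(species_id)


@dataclass(frozen=True)
class ProteinAlignment:
    """An equal-length amino-acid alignment (e.g. one protein domain)."""

    name: str
    entries: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.entries:
            raise AlignmentError(f"{self.name}: alignment has no sequences")
        lengths = {len(seq) for _, seq in self.entries}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.name}: unequal sequence lengths {sorted(lengths)}"
            )
        for sp, seq in self.entries:
            bad = set(seq) - AA_ALPHABET
            if bad:
                raise AlignmentError(
                    f"{self.name}/{sp}: illegal residues {sorted(bad)}"
                )
        ids = [sp for sp, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise AlignmentError(f"{self.name}: duplicate species identifiers")

    @property
    def length(self) -> int:
        return len(self.entries[0][1])

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sp for sp, _ in self.entries)

    def sequence(self, species_id: str) -> str:
        for sp, seq in self.entries:
            if sp == species_id:
                return seq
        raise KeyError(species_id)


@dataclass(frozen=True)
class OrthologRecord:
    gene_id: str
    species_id: str
    status: str
    sequence_id: str = ""

    def __post_init__(self):
        if self.status not in STATUSES:
            raise TableError(f"unknown ortholog status {self.status!r}")
        if self.status == "functional" and not self.sequence_id:
            raise TableError(
                f"{self.gene_id}/{self.species_id}: functional record "
                "requires a sequence_id"
            )


@dataclass(frozen=True)
class OrthologMap:
    """Per-gene, per-species functional status bookkeeping."""

    records: tuple[OrthologRecord, ...]

    def __post_init__(self):
        keys = [(r.gene_id, r.species_id) for r in self.records]
        if len(set(keys)) != len(keys):
            raise TableError("duplicate (gene, species) pair in ortholog map")

    def status(self, gene_id: str, species_id: str) -> str | None:
        for r in self.records:
            if r.gene_id == gene_id and r.species_id == species_id:
                return r.status
        return None

    def functional_species(self, gene_id: str) -> tuple[str, ...]:
        return tuple(
            r.species_id
            for r in self.records
            if r.gene_id == gene_id and r.status == "functional"
        )


@dataclass(frozen=True)
class SpeciesTraits:
    """Life-history traits of one species.

    mrls: maximal reported lifespan in years; weight: typical adult body
    weight in grams; lq: longevity quotient (observed lifespan over the
    allometric expectation).  ``None`` marks a missing value.
    """

    species_id: str
    mrls: float | None = None
    weight: float | None = None
    lq: float | None = None
    order: str = ""
    superorder: str = ""

    def __post_init__(self):
        for name in ("mrls", "weight", "lq"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise TableError(
                    f"{self.species_id}: {name} must be positive, got {v}"
                )


class TraitTable:
    """Mapping of species_id -> :class:`SpeciesTraits`."""

    def __init__(self, traits: Iterable[SpeciesTraits]):
        self._traits: dict[str, SpeciesTraits] = {}
        for t in traits:
            if t.species_id in self._traits:
                raise TableError(f"duplicate species row: {t.species_id}")
            self._traits[t.species_id] = t

    def __getitem__(self, species_id: str) -> SpeciesTraits:
        return self._traits[species_id]

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._traits

    def __iter__(self):
        return iter(self._traits.values())

    def __len__(self) -> int:
        return len(self._traits)

    def get(self, species_id: str) -> SpeciesTraits | None:
        return self._traits.get(species_id)


# ---------------------------------------------------------------------------
# FASTA


def read_codon_alignment(path: str | Path, gene_id: str | None = None) -> CodonAlignment:
    """Read a codon-aware FASTA alignment; validates frame and alphabet."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records")
    entries = tuple((r.id, str(r.seq).upper()) for r in records)
    return CodonAlignment(gene_id=gene_id or path.stem, entries=entries)


def write_codon_alignment(aln: CodonAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sp, description="") for sp, seq in aln.entries
    ]
    SeqIO.write(records, str(path), "fasta")


def read_protein_alignment(path: str | Path, name: str | None = None) -> ProteinAlignment:
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records")
    entries = tuple((r.id, str(r.seq).upper()) for r in records)
    return ProteinAlignment(name=name or path.stem, entries=entries)


def write_protein_alignment(aln: ProteinAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sp, description="") for sp, seq in aln.entries
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Alignment filtering


def filter_alignment(
    aln: CodonAlignment, min_len: int | None = None
) -> CodonAlignment:
    """Drop short sequences, then remove codon columns with gaps or N.

    A sequence is "short" when its gap-free length is below *min_len*
    codons (default: half the alignment length in codons).  After dropping,
    every codon column in which any retained sequence carries a gap or an N
    at any of the three positions is removed — codon granularity preserves
    the reading frame.  Idempotent; never reorders sequences or retained
    columns.

    Raises :class:`EmptyAlignmentError` when no sequence or no column
    survives.
    """
    if min_len is None:
        min_len = math.ceil(aln.n_codons / 2)
    kept_entries = [
        (sp, seq)
        for sp, seq in aln.entries
        if (len(seq) - seq.count("-")) / 3.0 >= min_len
    ]
    if not kept_entries:
        raise EmptyAlignmentError(
            f"{aln.gene_id}: all sequences below {min_len} codons"
        )
    bad = set()
    for _, seq in kept_entries:
        for ci in range(len(seq) // 3):
            codon = seq[3 * ci: 3 * ci + 3]
            if "-" in codon or "N" in codon:
                bad.add(ci)
    kept_cols = [ci for ci in range(aln.n_codons) if ci not in bad]
    if not kept_cols:
        raise EmptyAlignmentError(f"{aln.gene_id}: every codon column removed")
    new_entries = tuple(
        (sp, "".join(seq[3 * ci: 3 * ci + 3] for ci in kept_cols))
        for sp, seq in kept_entries
    )
    return CodonAlignment(gene_id=aln.gene_id, entries=new_entries)


# ---------------------------------------------------------------------------
# Delimited tables


def _detect_sep(path: Path) -> str:
    header = path.open().readline()
    return "\t" if "\t" in header else ","


def _parse_cell(cell: object, column: str, species: str) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if text.lower() in MISSING_MARKERS:
        return None
    try:
        return float(text)
    except ValueError:
        raise TableError(
            f"{species}: non-numeric {column} cell {text!r}"
        ) from None


def read_trait_table(path: str | Path) -> TraitTable:
    """Read a species trait table (TSV/CSV with header).

    Required columns: ``species``, ``mrls``, ``weight``, ``lq``.  Optional:
    ``order``, ``superorder``.  Missing values may be empty cells or any of
    the markers in :data:`MISSING_MARKERS`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    required = {"species", "mrls", "weight", "lq"}
    missing = required - set(df.columns)
    if missing:
        raise TableError(f"{path}: missing columns {sorted(missing)}")
    traits = []
    for _, row in df.iterrows():
        sp = row["species"].strip()
        traits.append(
            SpeciesTraits(
                species_id=sp,
                mrls=_parse_cell(row["mrls"], "mrls", sp),
                weight=_parse_cell(row["weight"], "weight", sp),
                lq=_parse_cell(row["lq"], "lq", sp),
                order=row.get("order", "") or "",
                superorder=row.get("superorder", "") or "",
            )
        )
    return TraitTable(traits)


def write_trait_table(traits: TraitTable, path: str | Path) -> None:
    def cell(v: float | None) -> str:
        return "NA" if v is None else repr(float(v))

    lines = ["species\tmrls\tweight\tlq\torder\tsuperorder"]
    for t in traits:
        lines.append(
            f"{t.species_id}\t{cell(t.mrls)}\t{cell(t.weight)}\t{cell(t.lq)}"
            f"\t{t.order}\t{t.superorder}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read an ortholog/status map (columns: gene, species, status, sequence_id)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    required = {"gene", "species", "status"}
    missing = required - set(df.columns)
    if missing:
        raise TableError(f"{path}: missing columns {sorted(missing)}")
    records = tuple(
        OrthologRecord(
            gene_id=row["gene"].strip(),
            species_id=row["species"].strip(),
            status=row["status"].strip(),
            sequence_id=(row.get("sequence_id", "") or "").strip(),
        )
        for _, row in df.iterrows()
    )
    return OrthologMap(records)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    lines = ["gene\tspecies\tstatus\tsequence_id"]
    for r in omap.records:
        lines.append(f"{r.gene_id}\t{r.species_id}\t{r.status}\t{r.sequence_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_association_report(results: Sequence, path: str | Path) -> None:
    """Write association results as an 8-column TSV mirroring the study's
    summary-table layout: gene, n, r, p, slope, intercept, median_min,
    median_max.  One report per trait; the trait is part of the file name.
    """
    lines = ["gene\tn\tr\tp\tslope\tintercept\tmedian_min\tmedian_max"]
    for res in results:
        lines.append(
            f"{res.gene_id}\t{res.n}\t{res.r:.6g}\t{res.p:.6g}"
            f"\t{res.slope:.6g}\t{res.intercept:.6g}"
            f"\t{res.interval[0]:.6g}\t{res.interval[1]:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
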