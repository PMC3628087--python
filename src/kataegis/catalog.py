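"""Mutation catalogs and genome models.

The unit of data flowing through the pipeline is a per-clone somatic
substitution catalog: one row per single-base substitution with a clone
label, chromosome, 1-based position, reference and alternate base. The
companion :class:`GenomeModel` carries chromosome names, lengths and
(optionally) sequence, and is the coordinate authority for validation and
for sequence-context extraction.

Coordinates are 1-based, fully closed, on the forward (reference) strand
throughout; BED export converts to 0-based half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
_BASE_SET = frozenset(BASES)
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_COMPLEMENT_TRANS = str.maketrans("ACGTacgt", "TGCAtgca")

CATALOG_COLUMNS = ["clone", "chrom", "pos", "ref", "alt"]


def complement(base: str) -> str:
    """Watson-Crick complement of a single canonical base."""
    return COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT_TRANS)[::-1]


class CatalogValidationError(ValueError):
    """Raised when a mutation table fails validation.

    Carries the offending (1-based) line numbers in ``lines`` where they
    are known, so callers can report exactly which input rows are bad.
    """

    def __init__(self, message: str, lines: Sequence[int] | None = None):
        super().__init__(message)
        self.lines = list(lines) if lines is not None else []


class MutationRecord(NamedTuple):
    """A single somatic substitution (1-based, forward-strand)."""

    clone_id: str
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class GenomeModel:
    """Ordered chromosomes with lengths and optional sequence.

    Parameters
    ----------
    names : list of str
        Chromosome names, in genome order.
    lengths : dict
        Chromosome name -> length in bp.
    sequence : dict or None
        Chromosome name -> uppercase base string. When present, each
        sequence's length must equal the declared length.
    """

    names: list[str]
    lengths: dict[str, int]
    sequence: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate chromosome names in genome")
        if not self.names:
            raise ValueError("genome has no chromosomes")
        for name in self.names:
            length = self.lengths[name]
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}")
            if self.sequence is not None:
                seq = self.sequence[name]
                if len(seq) != length:
                    raise ValueError(
                        f"sequence length {len(seq)} != declared length "
                        f"{length} for chromosome {name!r}"
                    )

    @property
    def total_length(self) -> int:
        return sum(self.lengths[n] for n in self.names)

    @property
    def has_sequence(self) -> bool:
        return self.sequence is not None

    def length_array(self) -> np.ndarray:
        return np.array([self.lengths[n] for n in self.names], dtype=np.int64)

    def base_at(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position (requires sequence)."""
        if self.sequence is None:
            raise ValueError("genome model has no sequence")
        return self.sequence[chrom][pos - 1]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeModel":
        from Bio import SeqIO

        names: list[str] = []
        lengths: dict[str, int] = {}
        sequence: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in lengths:
                raise ValueError(f"duplicate chromosome name {rec.id!r} in FASTA")
            seq = str(rec.seq).upper()
            names.append(rec.id)
            lengths[rec.id] = len(seq)
            sequence[rec.id] = seq
        if not names:
            raise ValueError(f"no sequences found in {path}")
        return cls(names=names, lengths=lengths, sequence=sequence)

    @classmethod
    def from_length_table(cls, path: str | Path) -> "GenomeModel":
        """Read a two-column ``name<TAB>length`` table (``.fai``-compatible:
        extra columns are ignored)."""
        names: list[str] = []
        lengths: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 2:
                    raise ValueError(f"line {lineno}: expected name and length")
                name = parts[0]
                if name in lengths:
                    raise ValueError(f"duplicate chromosome name {name!r}")
                try:
                    length = int(parts[1])
                except ValueError:
                    raise ValueError(
                        f"line {lineno}: non-integer length {parts[1]!r}"
                    ) from None
                names.append(name)
                lengths[name] = length
        if not names:
            raise ValueError(f"empty length table {path}")
        return cls(names=names, lengths=lengths)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        if self.sequence is None:
            raise ValueError("genome model has no sequence to write")
        with open(path, "w") as fh:
            for name in self.names:
                fh.write(f">{name}\n")
                seq = self.sequence[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def to_length_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in self.names:
                fh.write(f"{name}\t{self.lengths[name]}\n")


def read_genome(path: str | Path) -> GenomeModel:
    """Read a genome from FASTA or a two-column length table.

    The format is sniffed from the first non-blank character: ``>`` means
    FASTA (sequence attached), anything else a length table.
    """
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line.lstrip()[0]
                break
        else:
            raise ValueError(f"empty genome file {path}")
    if first == ">":
        return GenomeModel.from_fasta(path)
    return GenomeModel.from_length_table(path)


@dataclass
class MutationCatalog:
    """Validated, canonically sorted collection of substitutions.

    ``df`` has columns ``clone, chrom, pos, ref, alt`` plus a derived
    boolean ``coalesced`` column marking substitutions whose neighbour
    within the same clone/chromosome sits at an immediately adjacent
    position (they are kept as separate records).
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.df = _canonicalize(self.df)

    @property
    def n_records(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def clone_ids(self) -> list[str]:
        return sorted(self.df["clone"].unique())

    def records(self) -> Iterator[MutationRecord]:
        for row in self.df.itertuples(index=False):
            yield MutationRecord(row.clone, row.chrom, int(row.pos), row.ref, row.alt)

    def subset(self, mask) -> "MutationCatalog":
        return MutationCatalog(self.df.loc[mask, CATALOG_COLUMNS].copy(), self.provenance)

    def for_clone(self, clone_id: str) -> "MutationCatalog":
        return self.subset(self.df["clone"] == clone_id)

    def validate(self, genome: GenomeModel | None = None) -> None:
        """Check field-level invariants, optionally against a genome.

        Unknown chromosomes and out-of-range positions are hard errors:
        silently dropping coordinates would corrupt IMD statistics.
        """
        df = self.df
        bad = ~df["ref"].isin(BASES) | ~df["alt"].isin(BASES)
        if bad.any():
            raise CatalogValidationError(
                f"{int(bad.sum())} records with non-canonical bases"
            )
        if (df["ref"] == df["alt"]).any():
            raise CatalogValidationError("records with ref == alt")
        if (df["pos"] < 1).any():
            raise CatalogValidationError("positions must be >= 1")
        dup = df.duplicated(subset=["clone", "chrom", "pos"])
        if dup.any():
            raise CatalogValidationError(
                f"{int(dup.sum())} duplicate (clone, chrom, pos) entries"
            )
        if genome is not None:
            unknown = set(df["chrom"]) - set(genome.names)
            if unknown:
                raise CatalogValidationError(
                    f"chromosomes absent from genome: {sorted(unknown)}"
                )
            lengths = df["chrom"].map(genome.lengths)
            if (df["pos"] > lengths).any():
                raise CatalogValidationError("positions beyond chromosome length")
            if genome.has_sequence:
                refs = [
                    genome.base_at(c, p)
                    for c, p in zip(df["chrom"], df["pos"])
                ]
                mismatch = df["ref"].to_numpy() != np.array(refs)
                if mismatch.any():
                    raise CatalogValidationError(
                        f"{int(mismatch.sum())} records whose ref does not match "
                        "the genome sequence"
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutationCatalog):
            return NotImplemented
        return self.df[CATALOG_COLUMNS].reset_index(drop=True).equals(
            other.df[CATALOG_COLUMNS].reset_index(drop=True)
        )


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogValidationError(f"missing columns: {missing}")
    df = df[CATALOG_COLUMNS].copy()
    df["clone"] = df["clone"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    df = df.sort_values(["clone", "chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )
    # adjacent substitutions at consecutive positions are flagged, not merged
    same_group = (df["clone"] == df["clone"].shift()) & (
        df["chrom"] == df["chrom"].shift()
    )
    prev_adjacent = same_group & (df["pos"] - df["pos"].shift() == 1)
    df["coalesced"] = (prev_adjacent | prev_adjacent.shift(-1, fill_value=False)).astype(
        bool
    )
    return df


def catalog_from_records(
    records: Iterable[MutationRecord | tuple], provenance: str = ""
) -> MutationCatalog:
    rows = list(records)
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    return MutationCatalog(df, provenance)


def _parse_tsv(path: str | Path) -> tuple[list[tuple], list[tuple[int, str]]]:
    rows: list[tuple] = []
    errors: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = CATALOG_COLUMNS
        if [h.strip() for h in header[: len(required)]] != required:
            raise CatalogValidationError(
                f"expected header {required!r}, got {header!r}", lines=[1]
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                errors.append((lineno, "fewer than 5 fields"))
                continue
            clone, chrom, pos_s, ref, alt = (p.strip() for p in parts[:5])
            try:
                pos = int(pos_s)
            except ValueError:
                errors.append((lineno, f"non-numeric pos {pos_s!r}"))
                continue
            if pos < 1:
                errors.append((lineno, f"pos {pos} < 1"))
                continue
            ref, alt = ref.upper(), alt.upper()
            if ref not in _BASE_SET or alt not in _BASE_SET:
                errors.append((lineno, f"invalid base {ref!r}>{alt!r}"))
                continue
            if ref == alt:
                errors.append((lineno, "ref equals alt"))
                continue
            rows.append((clone, chrom, pos, ref, alt))
    return rows, errors


def _parse_vcf(path: str | Path) -> tuple[list[tuple], list[tuple[int, str]]]:
    """VCF import: one clone per sample column; a record contributes a
    mutation to every sample carrying a non-reference genotype.
    Multi-allelic records and non-SNV records are rejected."""
    import pysam

    rows: list[tuple] = []
    errors: list[tuple[int, str]] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            if rec.alts is None or len(rec.alts) != 1:
                errors.append((i, "multi-allelic or ALT-less record rejected"))
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASE_SET or alt not in _BASE_SET:
                errors.append((i, f"not a canonical SNV: {ref}>{alt}"))
                continue
            if not samples:
                rows.append(("sample", rec.chrom, rec.pos, ref, alt))
                continue
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                if gt is not None and any(a not in (0, None) for a in gt):
                    rows.append((sample, rec.chrom, rec.pos, ref, alt))
    return rows, errors


def read_mutation_table(
    path: str | Path,
    dialect: str = "tsv",
    provenance: str | None = None,
    on_invalid: str = "raise",
) -> MutationCatalog | tuple[MutationCatalog, list[tuple[int, str]]]:
    """Read a mutation catalog from TSV (native) or VCF.

    The native TSV has header ``clone<TAB>chrom<TAB>pos<TAB>ref<TAB>alt``.
    Rows are validated individually; with ``on_invalid="raise"`` (default)
    any malformed row aborts with a :class:`CatalogValidationError` naming
    the offending line numbers, with ``on_invalid="collect"`` the valid
    catalog and the list of ``(line, reason)`` pairs are both returned, so
    input rows are never silently dropped.
    """
    if dialect == "tsv":
        rows, errors = _parse_tsv(path)
    elif dialect == "vcf":
        rows, errors = _parse_vcf(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'vcf')")
    if errors and on_invalid == "raise":
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in errors[:10])
        raise CatalogValidationError(
            f"{len(errors)} invalid rows in {path}: {detail}",
            lines=[ln for ln, _ in errors],
        )
    catalog = MutationCatalog(
        pd.DataFrame(rows, columns=CATALOG_COLUMNS),
        provenance if provenance is not None else str(path),
    )
    catalog.validate()
    if on_invalid == "collect":
        return catalog, errors
    return catalog


def write_mutation_table(catalog: MutationCatalog, path: str | Path) -> None:
    catalog.df[CATALOG_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_rainfall_table(
    catalog: MutationCatalog,
    imds,
    path: str | Path,
    cluster_labels: np.ndarray | None = None,
) -> None:
    """Export the per-mutation table underlying a rainfall plot.

    One row per mutation in genome order per clone with its IMD (distance
    to the next downstream mutation on the same chromosome; NA for the most
    downstream mutation of each chromosome and for chromosome singletons)
    and, when ``cluster_labels`` is given (one integer per catalog record,
    -1 for unclustered), the cluster id.
    """
    if imds.n_source_records != len(catalog):
        raise ValueError(
            "IMD series was not computed from this catalog "
            f"({imds.n_source_records} source records vs {len(catalog)})"
        )
    df = catalog.df[CATALOG_COLUMNS].copy()
    imd_col = np.full(len(df), np.nan)
    if len(imds.entries):
        key = pd.MultiIndex.from_frame(df[["clone", "chrom", "pos"]])
        ekey = pd.MultiIndex.from_frame(imds.entries[["clone", "chrom", "pos"]])
        imd_series = pd.Series(imds.entries["imd"].to_numpy(), index=ekey)
        imd_col = imd_series.reindex(key).to_numpy()
    df["imd"] = imd_col
    if cluster_labels is not None:
        labels = np.asarray(cluster_labels)
        df["cluster_id"] = [str(l) if l >= 0 else "NA" for l in labels]
    else:
        df["cluster_id"] = "NA"
    df["imd"] = df["imd"].map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_cluster_bed(calls, path: str | Path) -> None:
    """Export cluster calls as BED-like TSV.

    Columns: ``chrom, start0, end, clone:cluster_id, n_mutations,
    polarity``; start converted from internal 1-based closed to BED's
    0-based half-open convention.
    """
    with open(path, "w") as fh:
        for i, call in enumerate(calls):
            fh.write(
                f"{call.chrom}\t{call.start - 1}\t{call.end}\t"
                f"{call.clone_id}:{i}\t{call.n_mutations}\t{call.polarity:.4f}\n"
            )
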