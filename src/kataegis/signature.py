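"""Pyrimidine-oriented spectra, sequence contexts and motif similarity.

AID/APOBEC deaminases act on cytosine in single-stranded DNA, so every
mutation at a C:G pair is represented as a change at C: a G>A record on the
reference strand is the same deamination event as C>T read on the opposite
strand. Orientation determines the pyrimidine strand, the substitution
class (C>T transition vs C>G / C>A transversions) and the 5' flanking
context (positions -2, -1 relative to the mutated C, read on the
pyrimidine strand). Context preferences are summarized as position
frequency matrices (PFMs) and compared with the Sandelin-Wasserman
similarity, sum over aligned columns of 2 - sum_b (p1(b) - p2(b))^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    BASES,
    COMPLEMENT,
    GenomeModel,
    MutationCatalog,
    MutationRecord,
    complement,
)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

PYRIMIDINE_CHANGES = ("C>T", "C>G", "C>A")


class OrientedMutation(NamedTuple):
    record: MutationRecord
    pyr_strand: str | None  # "plus" / "minus"; None for A:T-pair mutations
    change: str | None  # "C>T" / "C>G" / "C>A"; None for A:T-pair
    at_pair: bool


def orient_to_pyrimidine(record: MutationRecord) -> OrientedMutation:
    """Map a substitution to its pyrimidine-strand representation.

    C>N records are already pyrimidine-oriented (plus strand); G>N records
    are complemented onto the minus strand (G>A becomes C>T). Mutations at
    A:T pairs carry no C change and are flagged instead.
    """
    if record.ref == "C":
        return OrientedMutation(record, "plus", f"C>{record.alt}", False)
    if record.ref == "G":
        return OrientedMutation(record, "minus", f"C>{complement(record.alt)}", False)
    return OrientedMutation(record, None, None, True)


def orient_catalog(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized orientation: adds ``pyr_strand``, ``change``, ``at_pair``."""
    out = df.copy()
    ref = df["ref"].to_numpy(dtype="U1")
    alt = df["alt"].to_numpy(dtype="U1")
    comp = np.array([COMPLEMENT[a] for a in alt], dtype="U1")
    is_c = ref == "C"
    is_g = ref == "G"
    out["at_pair"] = ~(is_c | is_g)
    out["pyr_strand"] = np.where(is_c, "plus", np.where(is_g, "minus", ""))
    change = np.where(is_c, np.char.add("C>", alt), np.char.add("C>", comp))
    out["change"] = np.where(is_c | is_g, change, "")
    return out


@dataclass
class SpectrumSummary:
    """Counts and percentages of C>T / C>G / C>A in one stratum."""

    stratum: str
    counts: dict[str, int]
    n_total: int
    n_at_pairs: int

    @property
    def n_c_pairs(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float] | None:
        n = self.n_c_pairs
        if n == 0:
            return None
        return {k: 100.0 * v / n for k, v in self.counts.items()}

    @property
    def transition_fraction(self) -> float | None:
        n = self.n_c_pairs
        return self.counts["C>T"] / n if n else None

    @property
    def transversion_fraction(self) -> float | None:
        n = self.n_c_pairs
        return (self.counts["C>G"] + self.counts["C>A"]) / n if n else None


def spectrum(records, stratum: str = "") -> SpectrumSummary:
    """Substitution spectrum at C:G pairs after pyrimidine orientation.

    ``records`` may be a MutationCatalog, a catalog DataFrame, or an
    iterable of MutationRecord. A:T-pair mutations are counted in
    ``n_at_pairs`` and excluded from the C-change percentages.
    """
    if isinstance(records, MutationCatalog):
        records = records.records()
    elif isinstance(records, pd.DataFrame):
        records = (
            MutationRecord(r.clone, r.chrom, int(r.pos), r.ref, r.alt)
            for r in records.itertuples(index=False)
        )
    counts = {c: 0 for c in PYRIMIDINE_CHANGES}
    n_total = 0
    n_at = 0
    for rec in records:
        n_total += 1
        oriented = orient_to_pyrimidine(rec)
        if oriented.at_pair:
            n_at += 1
        else:
            counts[oriented.change] += 1
    return SpectrumSummary(stratum, counts, n_total, n_at)


def strand_coordination(call) -> tuple[float, str]:
    """Polarity of one cluster: fraction of members at the majority base.

    A kataegic cluster arises from deamination of one exposed ssDNA strand,
    so its mutations fall predominantly at C or predominantly at G on the
    reference strand. Returns ``(polarity, majority_base)`` with polarity
    = max(#ref C, #ref G) / n_members.
    """
    refs = np.asarray(call.member_refs if hasattr(call, "member_refs") else call)
    if len(refs) < 2:
        raise ValueError("strand coordination requires >= 2 members")
    n_c = int(np.sum(refs == "C"))
    n_g = int(np.sum(refs == "G"))
    if n_c >= n_g:
        return n_c / len(refs), "C"
    return n_g / len(refs), "G"


def aggregate_strand_coordination(calls: Sequence) -> float:
    """Majority-strand members summed over clusters / total members."""
    num = 0
    den = 0
    for call in calls:
        refs = np.asarray(call.member_refs)
        num += max(int(np.sum(refs == "C")), int(np.sum(refs == "G")))
        den += len(refs)
    if den == 0:
        raise ValueError("no cluster members")
    return num / den


def extract_contexts(
    catalog: MutationCatalog | pd.DataFrame,
    genome: GenomeModel,
    offsets: Sequence[int] = (-2, -1),
) -> tuple[list[str], int]:
    """5'-flanking context strings of mutated C bases, pyrimidine-oriented.

    For a plus-strand C the context at offset ``o`` is the genome base at
    ``pos + o``; for a minus-strand C (reference G) it is the complement of
    the base at ``pos - o``, so offsets are always 5'-relative on the
    pyrimidine strand. Sites whose context would fall outside the
    chromosome are skipped and tallied in the returned count; A:T-pair
    mutations are ignored.
    """
    if not genome.has_sequence:
        raise ValueError("context extraction requires genome sequence")
    df = catalog.df if isinstance(catalog, MutationCatalog) else catalog
    contexts: list[str] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        if row.ref not in ("C", "G"):
            continue
        seq = genome.sequence[row.chrom]
        pos = int(row.pos)
        bases = []
        ok = True
        for o in offsets:
            idx = (pos + o) - 1 if row.ref == "C" else (pos - o) - 1
            if idx < 0 or idx >= len(seq):
                ok = False
                break
            b = seq[idx]
            bases.append(b if row.ref == "C" else COMPLEMENT[b])
        if ok:
            contexts.append("".join(bases))
        else:
            n_skipped += 1
    return contexts, n_skipped


@dataclass
class ContextPFM:
    """Position frequency matrix over bases at offsets relative to the
    mutated C (pyrimidine strand).

    ``matrix`` has one row per position (ordered as ``positions``) and one
    column per base in A, C, G, T order; each row sums to 1.
    """

    positions: tuple[int, ...]
    matrix: np.ndarray
    n_sites: int = 0
    normalized: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.positions), 4):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.positions)} positions x 4 bases"
            )
        if (self.matrix < 0).any():
            raise ValueError("PFM probabilities must be non-negative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each PFM position must sum to 1")

    @property
    def width(self) -> int:
        return len(self.positions)

    def column(self, offset: int) -> np.ndarray:
        return self.matrix[self.positions.index(offset)]

    def base_fraction(self, offset: int, base: str) -> float:
        return float(self.column(offset)[_BASE_INDEX[base]])


def build_pfm(
    contexts: Iterable[str],
    offsets: Sequence[int] = (-2, -1),
    background: np.ndarray | None = None,
    name: str = "",
) -> ContextPFM:
    """Tally context strings into a PFM, optionally background-normalized.

    With ``background`` (a length-4 composition, or one per position as a
    (w, 4) array), each observed frequency is divided by the genomic
    background frequency of that base and the position renormalized to 1,
    expressing enrichment over genomic availability.
    """
    contexts = list(contexts)
    if not contexts:
        raise ValueError("no contexts supplied")
    w = len(offsets)
    counts = np.zeros((w, 4))
    for ctx in contexts:
        if len(ctx) != w:
            raise ValueError(f"context {ctx!r} does not have width {w}")
        for i, b in enumerate(ctx):
            counts[i, _BASE_INDEX[b]] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    normalized = False
    if background is not None:
        bg = np.asarray(background, dtype=float)
        if bg.ndim == 1:
            bg = np.broadcast_to(bg, (w, 4))
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(bg > 0, freq / bg, 0.0)
        freq = freq / freq.sum(axis=1, keepdims=True)
        normalized = True
    return ContextPFM(
        positions=tuple(offsets),
        matrix=freq,
        n_sites=len(contexts),
        normalized=normalized,
        name=name,
    )


def genomic_background(
    genome: GenomeModel,
    offset: int = -2,
    condition: dict[int, str] | None = None,
) -> np.ndarray:
    """Genome-wide base composition at ``offset`` relative to C sites.

    Scans every C on both strands (i.e. C on plus and G on plus, read as C
    on minus), optionally restricted to sites whose other offsets match
    ``condition`` (e.g. ``{-1: "T"}`` restricts to TC dinucleotides, the
    A3A/A3B target). Both strands are counted because pyrimidine-oriented
    mutation targets exist on both. Returns the length-4 composition in
    A, C, G, T order.
    """
    if not genome.has_sequence:
        raise ValueError("background composition requires genome sequence")
    condition = condition or {}
    counts = np.zeros(4)
    for chrom in genome.names:
        seq = genome.sequence[chrom]
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        code = np.full(arr.shape, -1, dtype=np.int8)
        for b, i in _BASE_INDEX.items():
            code[arr == ord(b)] = i
        comp_code = np.full_like(code, -1)
        valid = code >= 0
        comp_code[valid] = 3 - code[valid]  # ACGT order makes complement 3-i

        for strand_code, sign in ((_BASE_INDEX["C"], +1), (_BASE_INDEX["G"], -1)):
            is_site = code == strand_code
            idx = np.flatnonzero(is_site)
            keep = np.ones(idx.shape, dtype=bool)
            for o, base in condition.items():
                j = idx + sign * o
                inb = (j >= 0) & (j < len(code))
                keep &= inb
                want = _BASE_INDEX[base]
                got = np.where(
                    inb, (code if sign > 0 else comp_code)[np.clip(j, 0, len(code) - 1)], -1
                )
                keep &= got == want
            j = idx[keep] + sign * offset
            inb = (j >= 0) & (j < len(code))
            vals = (code if sign > 0 else comp_code)[j[inb]]
            vals = vals[vals >= 0]
            counts += np.bincount(vals, minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("no sites in the genome match the stated condition")
    return counts / total


def sw_similarity(pfm1: ContextPFM, pfm2: ContextPFM) -> float:
    """Sandelin-Wasserman similarity between two aligned PFMs.

    Sum over columns of ``2 - sum_b (p1(b) - p2(b))^2``; ranges over
    [0, 2w] for width-w motifs, attaining 2w iff the motifs are identical.
    """
    if pfm1.positions != pfm2.positions:
        raise ValueError(
            f"PFMs have different positions: {pfm1.positions} vs {pfm2.positions}"
        )
    diff = pfm1.matrix - pfm2.matrix
    return float(np.sum(2.0 - np.sum(diff**2, axis=1)))


@dataclass
class SimilarityResult:
    score: float
    p_value: float
    n_perm: int
    seed: int | None = None


def _draw_null_pfm(
    background: np.ndarray,
    positions: tuple[int, ...],
    rng: np.random.Generator,
    concentration: float = 20.0,
) -> ContextPFM:
    """Random PFM whose columns are Dirichlet perturbations centred on the
    background composition (mean = background, spread set by the
    concentration parameter)."""
    bg = np.asarray(background, dtype=float)
    alpha = np.maximum(concentration * bg, 1e-3)
    matrix = rng.dirichlet(alpha, size=len(positions))
    return ContextPFM(positions=positions, matrix=matrix)


def sw_pvalue(
    pfm1: ContextPFM,
    pfm2: ContextPFM,
    background: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    concentration: float = 20.0,
) -> SimilarityResult:
    """Permutation p-value for the similarity of two context motifs.

    The null replaces ``pfm1`` with random motifs drawn around the genomic
    background composition; ``p = (1 + #{null >= observed}) / (n_perm +
    1)``. This is a fully specified, seedable stand-in for database-driven
    motif-comparison nulls, whose configuration is tool-dependent.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = sw_similarity(pfm1, pfm2)
    exceed = 0
    for _ in range(n_perm):
        null_pfm = _draw_null_pfm(background, pfm2.positions, rng, concentration)
        if sw_similarity(null_pfm, pfm2) >= observed:
            exceed += 1
    return SimilarityResult(
        score=observed, p_value=(1 + exceed) / (n_perm + 1), n_perm=n_perm, seed=seed
    )


def write_pfm(pfm: ContextPFM, path: str | Path) -> None:
    """Write the 4-row (A/C/G/T) by w-column text matrix format used by
    common motif tools, with a header line naming the positions."""
    with open(path, "w") as fh:
        fh.write("# positions: " + " ".join(str(p) for p in pfm.positions) + "\n")
        fh.write(f"# n_sites: {pfm.n_sites}\n")
        fh.write(f"# normalized: {pfm.normalized}\n")
        for i, b in enumerate(BASES):
            row = " ".join(f"{pfm.matrix[j, i]:.6f}" for j in range(pfm.width))
            fh.write(f"{b} {row}\n")


def read_pfm(path: str | Path, name: str = "") -> ContextPFM:
    positions: tuple[int, ...] | None = None
    n_sites = 0
    normalized = False
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("positions:"):
                    positions = tuple(int(x) for x in body.split(":", 1)[1].split())
                elif body.startswith("n_sites:"):
                    n_sites = int(body.split(":", 1)[1])
                elif body.startswith("normalized:"):
                    normalized = body.split(":", 1)[1].strip() == "True"
                continue
            parts = line.split()
            rows[parts[0]] = [float(x) for x in parts[1:]]
    if positions is None or set(rows) != set(BASES):
        raise ValueError(f"malformed PFM file {path}")
    matrix = np.array([[rows[b][j] for b in BASES] for j in range(len(positions))])
    matrix = matrix / matrix.sum(axis=1, keepdims=True)
    return ContextPFM(
        positions=positions, matrix=matrix, n_sites=n_sites,
        normalized=normalized, name=name,
    )


def _pfm(rows: list[list[float]], name: str) -> ContextPFM:
    return ContextPFM(positions=(-2, -1), matrix=np.array(rows), name=name)


#: Deaminase flanking-context preferences at (-2, -1), A/C/G/T order.
#: AID prefers 5'-WRC (W = A/T at -2, R = A/G at -1); APOBEC3G prefers
#: 5'-CCC; APOBEC3A and APOBEC3B both strongly prefer T at -1 (91%) and
#: differ in their mild -2 discrimination (A3A 25:26:7:42, A3B 35:14:20:31).
PRESET_PFMS: dict[str, ContextPFM] = {
    "AID": _pfm([[0.45, 0.05, 0.05, 0.45], [0.45, 0.05, 0.45, 0.05]], "AID"),
    "APOBEC3G": _pfm([[0.05, 0.85, 0.05, 0.05], [0.05, 0.85, 0.05, 0.05]], "APOBEC3G"),
    "APOBEC3A": _pfm([[0.25, 0.26, 0.07, 0.42], [0.03, 0.03, 0.03, 0.91]], "APOBEC3A"),
    "APOBEC3B": _pfm([[0.35, 0.14, 0.20, 0.31], [0.03, 0.03, 0.03, 0.91]], "APOBEC3B"),
}


def best_match(
    pfm: ContextPFM, library: dict[str, ContextPFM] | None = None
) -> tuple[str, dict[str, float]]:
    """Name of the library motif most similar to ``pfm`` (highest
    Sandelin-Wasserman score) plus the full score table."""
    library = library if library is not None else PRESET_PFMS
    if not library:
        raise ValueError("empty motif library")
    scores = {name: sw_similarity(pfm, ref) for name, ref in library.items()}
    return max(scores, key=scores.get), scores
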