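"""Synthetic yeast-like genomes and mutation catalogs with planted kataegis.

The generator emulates the statistical structure of deaminase-mutagenized
yeast clone genomes: a 16-chromosome ~12.1-Mb genome; per-clone singlet
mutations scattered uniformly over C/G sites (Poisson load, default mean
25); and planted kataegic clusters — runs of 5-26 same-strand C:G
mutations with log-normal intra-cluster gaps (default median 727 bp),
strand coordination (default 0.88), deaminase-specific -2/-1 flanking
context preferences, and stratum-specific substitution mixes (kataegic
stretches are transversion-rich relative to unclustered mutations in the
wild-type background; uracil-glycosylase-deficient presets are almost pure
C>T). Every catalog ships with its ground truth, so cluster-caller
sensitivity, polarity, spectra and context recovery are all testable
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import BASES, COMPLEMENT, GenomeModel, MutationCatalog, CATALOG_COLUMNS
from .signature import ContextPFM, PRESET_PFMS

#: sacCer3-style chromosome lengths (16 chromosomes, ~12.07 Mb total),
#: used so spacing statistics resemble the real genome without downloads.
SACCER3_LENGTHS: dict[str, int] = {
    "chrI": 230218, "chrII": 813184, "chrIII": 316620, "chrIV": 1531933,
    "chrV": 576874, "chrVI": 270161, "chrVII": 1090940, "chrVIII": 562643,
    "chrIX": 439888, "chrX": 745751, "chrXI": 666816, "chrXII": 1078177,
    "chrXIII": 924431, "chrXIV": 784333, "chrXV": 1091291, "chrXVI": 948066,
}

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_CHANGES = ("C>T", "C>G", "C>A")


@dataclass
class SyntheticParams:
    """Generator settings; defaults are the study-like conditions.

    ``spectrum_*`` are (C>T, C>G, C>A) percentages after pyrimidine
    orientation; ``gap_median_bp``/``gap_sigma_log10`` parameterize the
    log-normal intra-cluster spacing; ``cluster_rate`` is the Poisson mean
    number of planted clusters per clone.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(SACCER3_LENGTHS)
    )
    n_clones: int = 40
    singlet_load: float = 25.0
    cluster_rate: float = 0.65
    cluster_size_range: tuple[int, int] = (5, 26)
    cluster_size_mean_excess: float = 5.0
    # median 727 bp with sigma chosen so the log-normal mean is ~1220 bp,
    # the observed mean spacing within kataegic stretches
    gap_median_bp: float = 727.0
    gap_sigma_log10: float = 0.4418
    span_range_bp: tuple[int, int] = (1800, 30000)
    strand_coordination: float = 0.88
    context_pfm: str | ContextPFM = "AID"
    spectrum_kataegic: tuple[float, float, float] = (46.0, 47.0, 7.0)
    spectrum_unclustered: tuple[float, float, float] = (87.0, 11.0, 2.0)
    gc_content: float = 0.38
    name: str = "custom"

    def __post_init__(self) -> None:
        if not 0.0 <= self.strand_coordination <= 1.0:
            raise ValueError("strand_coordination must be in [0, 1]")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        for mix in (self.spectrum_kataegic, self.spectrum_unclustered):
            if abs(sum(mix) - 100.0) > 1e-6:
                raise ValueError(f"spectrum mix {mix} must sum to 100")
        lo, hi = self.cluster_size_range
        if not 2 <= lo <= hi:
            raise ValueError("cluster_size_range must satisfy 2 <= lo <= hi")
        if self.gap_median_bp <= 0 or self.gap_sigma_log10 < 0:
            raise ValueError("gap distribution parameters must be positive")
        if min(self.chrom_lengths.values(), default=0) <= 0:
            raise ValueError("chromosome lengths must be positive")

    @property
    def pfm(self) -> ContextPFM:
        if isinstance(self.context_pfm, ContextPFM):
            return self.context_pfm
        try:
            return PRESET_PFMS[self.context_pfm]
        except KeyError:
            raise ValueError(
                f"unknown context PFM {self.context_pfm!r}; "
                f"presets: {sorted(PRESET_PFMS)}"
            ) from None


_PRESETS: dict[str, dict] = {
    # wild-type hyperactive AID: median load 25, transversion-rich clusters
    "AID_star": dict(name="AID_star"),
    # UNG-deficient: ~4x load, nearly pure C>T, strongly diminished clustering
    "ung1_delta": dict(
        name="ung1_delta", singlet_load=50.0, cluster_rate=4 / 19,
        spectrum_kataegic=(99.3, 0.2, 0.5), spectrum_unclustered=(99.3, 0.2, 0.5),
    ),
    # REV1-deficient: reduced load, transitions only
    "rev1_delta": dict(
        name="rev1_delta", singlet_load=10.0, cluster_rate=0.3,
        spectrum_kataegic=(100.0, 0.0, 0.0), spectrum_unclustered=(100.0, 0.0, 0.0),
    ),
    "A3A": dict(
        name="A3A", cluster_rate=0.4, context_pfm="APOBEC3A",
        spectrum_kataegic=(79.0, 17.0, 4.0), spectrum_unclustered=(79.0, 17.0, 4.0),
    ),
    "A3B": dict(
        name="A3B", cluster_rate=0.4, context_pfm="APOBEC3B",
        spectrum_kataegic=(81.0, 16.0, 3.0), spectrum_unclustered=(81.0, 16.0, 3.0),
    ),
    "A3G_star": dict(
        name="A3G_star", cluster_rate=0.25, context_pfm="APOBEC3G",
        spectrum_kataegic=(78.0, 20.0, 2.0), spectrum_unclustered=(78.0, 20.0, 2.0),
    ),
}


def preset(name: str, **overrides) -> SyntheticParams:
    """Parameter bundle for a named genotype preset.

    Known presets: AID_star, ung1_delta, rev1_delta, A3A, A3B, A3G_star.
    Keyword overrides replace individual fields.
    """
    try:
        base = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return SyntheticParams(**{**base, **overrides})


def generate_genome(
    chrom_lengths: dict[str, int] | None = None,
    gc_content: float = 0.38,
    seed: int | np.random.Generator | None = None,
) -> GenomeModel:
    """I.i.d. random genome at the given GC content (deterministic under
    seed). Default chromosome lengths are the 16 yeast-like lengths."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = dict(chrom_lengths) if chrom_lengths else dict(SACCER3_LENGTHS)
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    alphabet = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    sequence = {}
    for name, length in lengths.items():
        codes = rng.choice(4, size=length, p=p)
        sequence[name] = alphabet[codes].tobytes().decode()
    return GenomeModel(names=list(lengths), lengths=lengths, sequence=sequence)


@dataclass
class SyntheticTruth:
    """Ground truth for a generated catalog.

    ``labels`` has one row per mutation: clone, chrom, pos, label
    ('singlet' or 'cluster'), cluster_id ('' for singlets). ``clusters``
    has one row per planted cluster: clone, cluster_id, chrom, start, end,
    strand ('+' = mutated C on plus strand), n_members.
    """

    labels: pd.DataFrame
    clusters: pd.DataFrame
    params: SyntheticParams

    def write(self, path: str | Path) -> None:
        self.labels.to_csv(path, sep="\t", index=False, lineterminator="\n")


class _ChromIndex:
    """Per-chromosome base codes for fast context-eligible site search."""

    def __init__(self, genome: GenomeModel):
        self.code: dict[str, np.ndarray] = {}
        for name in genome.names:
            arr = np.frombuffer(genome.sequence[name].encode(), dtype=np.uint8)
            code = np.full(arr.shape, -1, dtype=np.int8)
            for b, i in _BASE_INDEX.items():
                code[arr == ord(b)] = i
            self.code[name] = code


def _find_site(
    code: np.ndarray,
    lo: int,
    hi: int,
    nominal: int,
    strand: str,
    ctx: tuple[int, int] | None,
    taken: set[int],
) -> int | None:
    """Closest-to-nominal position in [lo, hi] (1-based) with the mutated
    base on ``strand`` and, if possible, the exact (-2, -1) pyrimidine
    context ``ctx``; falls back to ignoring the context."""
    lo = max(lo, 3)
    hi = min(hi, len(code) - 2)
    if lo > hi:
        return None
    window = code[lo - 1 : hi]
    if strand == "+":
        base_ok = window == _BASE_INDEX["C"]
        if ctx is not None:
            m2 = code[lo - 3 : hi - 2] == ctx[0]
            m1 = code[lo - 2 : hi - 1] == ctx[1]
            with_ctx = base_ok & m2 & m1
        else:
            with_ctx = base_ok
    else:
        base_ok = window == _BASE_INDEX["G"]
        if ctx is not None:
            # oriented offsets -2/-1 sit at pos+2/pos+1 on the plus strand,
            # complemented (A<->T, C<->G means code 3 - c)
            m2 = code[lo + 1 : hi + 2] == 3 - ctx[0]
            m1 = code[lo : hi + 1] == 3 - ctx[1]
            with_ctx = base_ok & m2 & m1
        else:
            with_ctx = base_ok
    for mask in (with_ctx, base_ok):
        cand = np.flatnonzero(mask) + lo
        if taken:
            cand = cand[~np.isin(cand, list(taken))]
        if cand.size:
            return int(cand[np.argmin(np.abs(cand - nominal))])
    return None


def _sample_change(rng: np.random.Generator, mix: tuple[float, float, float]) -> str:
    return _CHANGES[rng.choice(3, p=np.asarray(mix) / 100.0)]


def _alt_for(strand: str, change: str) -> tuple[str, str]:
    """(ref, alt) on the reference strand for a pyrimidine-strand change."""
    target = change[-1]
    if strand == "+":
        return "C", target
    return "G", COMPLEMENT[target]


def generate_catalog(
    genome: GenomeModel,
    params: SyntheticParams,
    seed: int | None = None,
) -> tuple[MutationCatalog, SyntheticTruth]:
    """Generate a multi-clone catalog with planted clusters and truth.

    Per clone: a Poisson(``singlet_load``) number of singlets at uniformly
    chosen C/G sites, and a Poisson(``cluster_rate``) number of clusters.
    Each cluster draws a majority strand, a member count, log-normal gaps,
    and then snaps each member to the nearest site carrying the mutated
    base on its strand with a -2/-1 context sampled from the deaminase
    PFM; members defect to the opposite strand with probability
    1 - ``strand_coordination``. Alternate alleles follow the stratum's
    substitution mix. Deterministic under (params, seed).
    """
    if not genome.has_sequence:
        raise ValueError("generator requires a genome with sequence")
    rng = np.random.default_rng(seed)
    index = _ChromIndex(genome)
    lengths = genome.length_array()
    chrom_p = lengths / lengths.sum()
    pfm = params.pfm
    if pfm.positions != (-2, -1):
        raise ValueError("generator expects a (-2, -1) context PFM")

    rows: list[tuple] = []
    label_rows: list[tuple] = []
    cluster_rows: list[tuple] = []
    kmin, kmax = params.cluster_size_range
    span_lo, span_hi = params.span_range_bp
    mu_ln = np.log(params.gap_median_bp)
    sigma_ln = params.gap_sigma_log10 * np.log(10)

    for c in range(params.n_clones):
        clone = f"clone{c + 1:03d}"
        taken: dict[str, set[int]] = {name: set() for name in genome.names}
        occupied: dict[str, list[tuple[int, int]]] = {
            name: [] for name in genome.names
        }

        # --- planted clusters ---
        n_clusters = rng.poisson(params.cluster_rate)
        for k in range(n_clusters):
            size = min(kmin + rng.geometric(1.0 / (1.0 + params.cluster_size_mean_excess)) - 1, kmax)
            for _ in range(20):
                gaps = np.exp(rng.normal(mu_ln, sigma_ln, size - 1))
                gaps = np.maximum(np.round(gaps).astype(np.int64), 2)
                if span_lo <= gaps.sum() <= span_hi:
                    break
            span = int(gaps.sum())
            majority = "+" if rng.random() < 0.5 else "-"
            placed = None
            for _attempt in range(50):
                ci = rng.choice(len(lengths), p=chrom_p)
                chrom = genome.names[ci]
                limit = int(lengths[ci]) - span - 600
                if limit < 600:
                    continue
                anchor = int(rng.integers(600, limit))
                if any(
                    not (anchor + span < s or anchor > e)
                    for s, e in occupied[chrom]
                ):
                    continue
                code = index.code[chrom]
                nominal = anchor + np.concatenate(([0], np.cumsum(gaps)))
                members = []
                prev = anchor - 1
                ok = True
                for nom in nominal:
                    strand = (
                        majority
                        if rng.random() < params.strand_coordination
                        else ("-" if majority == "+" else "+")
                    )
                    ctx = (
                        int(rng.choice(4, p=pfm.matrix[0])),
                        int(rng.choice(4, p=pfm.matrix[1])),
                    )
                    site = _find_site(
                        code, max(prev + 1, int(nom) - 300), int(nom) + 300,
                        int(nom), strand, ctx, taken[chrom],
                    )
                    if site is None:
                        ok = False
                        break
                    members.append((site, strand))
                    prev = site
                if ok and len(members) == size:
                    placed = (chrom, members)
                    break
            if placed is None:
                raise RuntimeError(
                    "could not place a synthetic cluster after bounded retries; "
                    "genome may be too small or too occupied"
                )
            chrom, members = placed
            cid = f"{clone}.k{k + 1}"
            for site, strand in members:
                taken[chrom].add(site)
                change = _sample_change(rng, params.spectrum_kataegic)
                ref, alt = _alt_for(strand, change)
                rows.append((clone, chrom, site, ref, alt))
                label_rows.append((clone, chrom, site, "cluster", cid))
            start = members[0][0]
            end = members[-1][0]
            occupied[chrom].append((start - 1, end + 1))
            cluster_rows.append(
                (clone, cid, chrom, start, end, majority, len(members))
            )

        # --- singlets at uniformly chosen C/G sites ---
        n_singlets = rng.poisson(params.singlet_load)
        placed_singlets = 0
        guard = 0
        while placed_singlets < n_singlets:
            guard += 1
            if guard > 200 * (n_singlets + 1):
                raise RuntimeError("could not place singlets; genome too small?")
            ci = rng.choice(len(lengths), p=chrom_p)
            chrom = genome.names[ci]
            pos = int(rng.integers(1, int(lengths[ci]) + 1))
            code = index.code[chrom]
            b = code[pos - 1]
            if b not in (_BASE_INDEX["C"], _BASE_INDEX["G"]):
                continue
            if pos in taken[chrom]:
                continue
            strand = "+" if b == _BASE_INDEX["C"] else "-"
            change = _sample_change(rng, params.spectrum_unclustered)
            ref, alt = _alt_for(strand, change)
            taken[chrom].add(pos)
            rows.append((clone, chrom, pos, ref, alt))
            label_rows.append((clone, chrom, pos, "singlet", ""))
            placed_singlets += 1

    catalog = MutationCatalog(
        pd.DataFrame(rows, columns=CATALOG_COLUMNS),
        provenance=f"synthetic:{params.name}",
    )
    labels = (
        pd.DataFrame(
            label_rows, columns=["clone", "chrom", "pos", "label", "cluster_id"]
        )
        .sort_values(["clone", "chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    clusters = pd.DataFrame(
        cluster_rows,
        columns=["clone", "cluster_id", "chrom", "start", "end", "strand", "n_members"],
    )
    return catalog, SyntheticTruth(labels=labels, clusters=clusters, params=params)
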