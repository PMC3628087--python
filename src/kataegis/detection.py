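"""Intermutational distances, IMD partitioning and kataegic cluster calling.

The detection pipeline is: (1) compute intermutational distances (IMDs),
the distance from each mutation to the next downstream mutation on the
same chromosome within the same clone; (2) split the pooled IMDs into a
proximal and a distal group with two-group k-means on log10(IMD); (3) set
the calling threshold at the IMD that excludes a stated fraction (default
99%) of the distal group; (4) call a kataegic cluster wherever at least
``min_mutations`` (default 5) adjacent mutations are each separated from
the next by less than the threshold.

The run-finding core (:func:`find_cluster_runs`) is shared verbatim by the
Monte Carlo null model, so null and real analyses use the identical code
path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import MutationCatalog
from . import signature


@dataclass
class IMDSeries:
    """Per-pair intermutational distances and exclusion bookkeeping.

    ``entries`` has one row per consecutive same-clone same-chromosome
    mutation pair, keyed by the upstream mutation: columns ``clone, chrom,
    pos, imd``. The most downstream mutation of each multiply-mutated
    chromosome has no IMD (``n_excluded_terminal``, one per such clone x
    chromosome) and mutations alone on their chromosome contribute nothing
    (``n_excluded_singleton_chrom``).
    """

    entries: pd.DataFrame
    n_excluded_terminal: int
    n_excluded_singleton_chrom: int
    n_source_records: int

    @property
    def values(self) -> np.ndarray:
        return self.entries["imd"].to_numpy(dtype=np.int64)

    def __len__(self) -> int:
        return len(self.entries)


def compute_imds(catalog: MutationCatalog) -> IMDSeries:
    """Distance from each mutation to the next downstream mutation on the
    same chromosome of the same clone."""
    df = catalog.df
    dup = df.duplicated(subset=["clone", "chrom", "pos"])
    if dup.any():
        raise ValueError(
            "duplicate (clone, chrom, pos) entries: IMD of 0 is undefined"
        )
    if len(df) == 0:
        entries = pd.DataFrame(columns=["clone", "chrom", "pos", "imd"])
        return IMDSeries(entries, 0, 0, 0)
    same = (df["clone"] == df["clone"].shift(-1)) & (
        df["chrom"] == df["chrom"].shift(-1)
    )
    imd = (df["pos"].shift(-1) - df["pos"]).where(same)
    entries = df.loc[same, ["clone", "chrom", "pos"]].copy()
    entries["imd"] = imd[same].astype(np.int64)
    entries = entries.reset_index(drop=True)
    group_sizes = df.groupby(["clone", "chrom"], sort=False).size()
    n_terminal = int((group_sizes >= 2).sum())
    n_singleton = int((group_sizes == 1).sum())
    return IMDSeries(entries, n_terminal, n_singleton, len(df))


@dataclass
class IMDPartition:
    """Two-group (proximal/distal) split of an IMD set.

    ``labels`` holds "proximal"/"distal" per entry; medians are in bp.
    ``threshold`` is populated by :func:`derive_threshold` as the IMD below
    which at least ``exclusion`` of the distal group does *not* fall
    (i.e. >= exclusion of distal IMDs strictly exceed it).
    """

    imds: np.ndarray
    labels: np.ndarray
    median_proximal: float
    median_distal: float
    threshold: float | None = None
    exclusion: float | None = None

    @property
    def proximal_values(self) -> np.ndarray:
        return self.imds[self.labels == "proximal"]

    @property
    def distal_values(self) -> np.ndarray:
        return self.imds[self.labels == "distal"]

    def summary(self) -> dict:
        return {
            "n_entries": int(len(self.imds)),
            "n_proximal": int((self.labels == "proximal").sum()),
            "n_distal": int((self.labels == "distal").sum()),
            "median_proximal_bp": float(self.median_proximal),
            "median_distal_bp": float(self.median_distal),
            "exclusion": self.exclusion,
            "threshold_bp": self.threshold,
        }


def partition_imds(imds: IMDSeries | np.ndarray, seed: int | None = None) -> IMDPartition:
    """Split IMDs into proximal and distal groups.

    Runs two-group k-means on log10(IMD) (deterministic percentile
    initialization, so ``seed`` has no effect and is accepted only for
    interface stability); the group with the smaller median is labelled
    proximal.
    """
    from .estimators import IMDPartitioner

    values = imds.values if isinstance(imds, IMDSeries) else np.asarray(imds)
    part = IMDPartitioner().fit(values.reshape(-1, 1))
    labels = np.where(part.labels_ == 0, "proximal", "distal")
    return IMDPartition(
        imds=np.asarray(values, dtype=np.int64),
        labels=labels,
        median_proximal=part.median_proximal_,
        median_distal=part.median_distal_,
    )


def derive_threshold(partition: IMDPartition, exclusion: float = 0.99) -> float:
    """Cluster-calling threshold: the empirical (1 - exclusion) quantile of
    the distal-group IMDs (linear interpolation between order statistics).

    With the default exclusion of 0.99, 99% of distal (singlet-like) IMDs
    exceed the threshold. The value is stored back into the partition.
    """
    if not 0.0 < exclusion < 1.0:
        raise ValueError("exclusion must be in (0, 1)")
    distal = partition.distal_values
    if len(distal) == 0:
        raise ValueError("distal group is empty")
    threshold = float(np.quantile(distal.astype(float), 1.0 - exclusion))
    partition.threshold = threshold
    partition.exclusion = exclusion
    return threshold


def find_cluster_runs(
    positions: np.ndarray,
    chrom_codes: np.ndarray,
    threshold: float,
    min_mutations: int,
) -> list[tuple[int, int]]:
    """Maximal runs of adjacent sub-threshold gaps.

    ``positions`` must be sorted ascending within each chromosome block
    and ``chrom_codes`` identifies the chromosome of each position. A gap
    participates iff it joins same-chromosome neighbours and is strictly
    below ``threshold`` (a gap equal to the threshold breaks the run).
    Returns inclusive member index ranges ``(first, last)`` for runs of at
    least ``min_mutations`` members. Shared by the real cluster caller and
    the Monte Carlo null.
    """
    n = positions.shape[0]
    if n < min_mutations:
        return []
    ok = (np.diff(positions) < threshold) & (chrom_codes[1:] == chrom_codes[:-1])
    padded = np.empty(ok.size + 2, dtype=np.int8)
    padded[0] = padded[-1] = 0
    padded[1:-1] = ok
    edges = np.flatnonzero(np.diff(padded))
    starts = edges[0::2]
    ends = edges[1::2]  # run covers gap indices [start, end) => members [start, end]
    need = min_mutations - 1
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= need]


@dataclass
class ClusterCall:
    """One called kataegic stretch within a clone."""

    clone_id: str
    chrom: str
    start: int  # 1-based position of the first member
    end: int  # 1-based position of the last member
    member_indices: np.ndarray  # row positions in the catalog DataFrame
    member_refs: np.ndarray
    member_alts: np.ndarray
    polarity: float
    majority_base: str
    spectrum: dict[str, int]
    mean_internal_imd: float

    @property
    def n_mutations(self) -> int:
        return len(self.member_indices)

    @property
    def length(self) -> int:
        """Span in bp, end - start (endpoint bases not double-counted)."""
        return self.end - self.start


def call_clusters(
    catalog: MutationCatalog,
    threshold: float,
    min_mutations: int = 5,
) -> list[ClusterCall]:
    """Call kataegic clusters: per clone and chromosome, every maximal run
    of >= ``min_mutations`` mutations whose successive gaps are all
    strictly below ``threshold``.

    Each call carries its span, strand polarity (fraction of members at
    the majority reference base, C or G) and pyrimidine-oriented
    substitution spectrum. Calls are returned sorted by
    (clone, chrom, start); clusters never cross clone or chromosome
    boundaries.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_mutations < 2:
        raise ValueError("min_mutations must be >= 2")
    df = catalog.df
    calls: list[ClusterCall] = []
    if len(df) == 0:
        return calls
    positions = df["pos"].to_numpy(dtype=np.int64)
    refs = df["ref"].to_numpy(dtype="U1")
    alts = df["alt"].to_numpy(dtype="U1")
    # canonical sort => (clone, chrom) blocks are contiguous
    codes, _ = pd.factorize(
        df["clone"].astype(str) + "\x00" + df["chrom"].astype(str), sort=False
    )
    codes = codes.astype(np.int64)
    clones = df["clone"].to_numpy()
    chroms = df["chrom"].to_numpy()
    for first, last in find_cluster_runs(positions, codes, threshold, min_mutations):
        idx = np.arange(first, last + 1)
        member_refs = refs[idx]
        member_alts = alts[idx]
        pol, majority = _polarity(member_refs)
        spec = _member_spectrum(member_refs, member_alts)
        gaps = np.diff(positions[idx])
        calls.append(
            ClusterCall(
                clone_id=str(clones[first]),
                chrom=str(chroms[first]),
                start=int(positions[first]),
                end=int(positions[last]),
                member_indices=idx,
                member_refs=member_refs,
                member_alts=member_alts,
                polarity=pol,
                majority_base=majority,
                spectrum=spec,
                mean_internal_imd=float(gaps.mean()),
            )
        )
    calls.sort(key=lambda c: (c.clone_id, c.chrom, c.start))
    return calls


def _polarity(refs: np.ndarray) -> tuple[float, str]:
    n_c = int(np.sum(refs == "C"))
    n_g = int(np.sum(refs == "G"))
    if n_c >= n_g:
        return n_c / len(refs), "C"
    return n_g / len(refs), "G"


def _member_spectrum(refs: np.ndarray, alts: np.ndarray) -> dict[str, int]:
    counts = {c: 0 for c in signature.PYRIMIDINE_CHANGES}
    for r, a in zip(refs, alts):
        if r == "C":
            counts[f"C>{a}"] += 1
        elif r == "G":
            counts[f"C>{signature.complement(a)}"] += 1
    return counts


def cluster_labels(catalog: MutationCatalog, calls: Sequence[ClusterCall]) -> np.ndarray:
    """Per-record cluster index (-1 for unclustered), aligned with the
    catalog DataFrame rows."""
    labels = np.full(len(catalog), -1, dtype=np.int64)
    for i, call in enumerate(calls):
        labels[call.member_indices] = i
    return labels


@dataclass
class BurdenSummary:
    """Per-genotype clustering burden."""

    genotype: str
    n_clones: int
    total_mutations: int
    clustered_mutations: int
    n_clusters: int
    clones_with_cluster: int
    mean_clustered_per_clone: float
    mean_internal_imd: float | None


def cluster_burden(
    calls: Sequence[ClusterCall],
    catalog: MutationCatalog,
    genotype_of: dict[str, str] | None = None,
) -> list[BurdenSummary]:
    """Summarize how much of the mutation load sits in clusters.

    With ``genotype_of`` (clone -> genotype label) summaries are stratified
    per genotype; otherwise all clones form a single stratum. The mean
    clustered mutations per clone divides by all clones of the stratum,
    including clones without clusters.
    """
    df = catalog.df
    geno = (
        df["clone"].map(lambda c: genotype_of.get(c, "unknown"))
        if genotype_of
        else pd.Series("all", index=df.index)
    )
    out: list[BurdenSummary] = []
    for g in sorted(geno.unique()):
        clones = df.loc[geno == g, "clone"].unique()
        clone_set = set(clones)
        g_calls = [c for c in calls if c.clone_id in clone_set]
        clustered = sum(c.n_mutations for c in g_calls)
        with_cluster = len({c.clone_id for c in g_calls})
        gaps = np.concatenate(
            [np.array([c.mean_internal_imd] * (c.n_mutations - 1)) for c in g_calls]
        ) if g_calls else np.array([])
        internal = (
            float(
                np.sum([c.mean_internal_imd * (c.n_mutations - 1) for c in g_calls])
                / np.sum([c.n_mutations - 1 for c in g_calls])
            )
            if g_calls
            else None
        )
        out.append(
            BurdenSummary(
                genotype=g,
                n_clones=len(clones),
                total_mutations=int((geno == g).sum()),
                clustered_mutations=clustered,
                n_clusters=len(g_calls),
                clones_with_cluster=with_cluster,
                mean_clustered_per_clone=clustered / len(clones) if len(clones) else 0.0,
                mean_internal_imd=internal,
            )
        )
    return out
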