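"""Monte Carlo null model of randomly scattered mutations.

Scatters per-clone mutation loads uniformly over the genome (chromosome
chosen proportional to length, positions distinct) to ask two questions:
what IMD distribution does random placement produce, and how often does
random placement alone yield a called cluster. The cluster question runs
through :func:`kataegis.detection.find_cluster_runs` — the identical code
path used on real catalogs — so the null estimate is an estimate for the
actual caller, not for an approximation of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import GenomeModel, MutationCatalog, CATALOG_COLUMNS
from .detection import find_cluster_runs

_TRANSITION = {"A": "G", "C": "T", "G": "A", "T": "C"}


def _genome_offsets(genome: GenomeModel) -> tuple[np.ndarray, np.ndarray]:
    lengths = genome.length_array()
    ends = np.cumsum(lengths)
    starts = ends - lengths
    return starts, ends


def _sample_position_matrix(
    rng: np.random.Generator, total_length: int, n: int, reps: int
) -> np.ndarray:
    """(reps, n) matrix of distinct global offsets in [0, total_length),
    sorted within each row. Rows with collisions are resampled."""
    if n > total_length:
        raise ValueError("more mutations requested than genome positions")
    out = rng.integers(0, total_length, size=(reps, n), dtype=np.int64)
    out.sort(axis=1)
    if n > 1:
        bad = np.flatnonzero((np.diff(out, axis=1) == 0).any(axis=1))
        while bad.size:
            out[bad] = rng.integers(0, total_length, size=(bad.size, n), dtype=np.int64)
            out[bad] = np.sort(out[bad], axis=1)
            bad = bad[(np.diff(out[bad], axis=1) == 0).any(axis=1)]
    return out


def simulate_random_catalog(
    genome: GenomeModel,
    n_mutations: int,
    clone_id: str = "sim",
    seed: int | np.random.Generator | None = None,
) -> MutationCatalog:
    """Uniformly scattered catalog: ``n_mutations`` distinct positions over
    the concatenated genome. When sequence is available the reference base
    is read from it and the alternate is its transition partner; otherwise
    a C>T placeholder is used (position statistics are what matter here).
    """
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_mutations == 0:
        return MutationCatalog(
            pd.DataFrame(columns=CATALOG_COLUMNS), provenance="null-simulation"
        )
    offsets = _sample_position_matrix(rng, genome.total_length, n_mutations, 1)[0]
    starts, ends = _genome_offsets(genome)
    chrom_idx = np.searchsorted(ends, offsets, side="right")
    pos = offsets - starts[chrom_idx] + 1
    chroms = [genome.names[i] for i in chrom_idx]
    if genome.has_sequence:
        refs = [genome.base_at(c, int(p)) for c, p in zip(chroms, pos)]
        alts = [_TRANSITION[r] for r in refs]
    else:
        refs = ["C"] * n_mutations
        alts = ["T"] * n_mutations
    df = pd.DataFrame(
        {"clone": clone_id, "chrom": chroms, "pos": pos, "ref": refs, "alt": alts}
    )
    return MutationCatalog(df, provenance="null-simulation")


@dataclass
class NullIMDDistribution:
    """Pooled IMDs from replicate random scatters."""

    imds: np.ndarray
    n_reps: int
    n_mutations: int
    genome_length: int

    def quantiles(self, q: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95)) -> dict:
        return {float(x): float(np.quantile(self.imds, x)) for x in q}

    @property
    def mean(self) -> float:
        return float(self.imds.mean())

    def ks_statistic(self, observed: np.ndarray) -> float:
        """Two-sample Kolmogorov-Smirnov distance to an observed IMD set."""
        return float(stats.ks_2samp(self.imds, np.asarray(observed)).statistic)

    def ks_vs_exponential(self) -> float:
        """KS distance to the large-genome limit Exp(rate = n/L)."""
        scale = self.genome_length / self.n_mutations
        return float(stats.kstest(self.imds, "expon", args=(0, scale)).statistic)


def imd_null_distribution(
    genome: GenomeModel,
    n_mutations: int,
    n_reps: int,
    seed: int | None = None,
) -> NullIMDDistribution:
    """IMD distribution of uniformly scattered mutations, pooled over
    ``n_reps`` independent clones."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    starts, ends = _genome_offsets(genome)
    mat = _sample_position_matrix(rng, genome.total_length, n_mutations, n_reps)
    chrom_idx = np.searchsorted(ends, mat, side="right")
    gaps = np.diff(mat, axis=1)
    same = chrom_idx[:, 1:] == chrom_idx[:, :-1]
    imds = gaps[same]
    return NullIMDDistribution(
        imds=imds.astype(np.int64),
        n_reps=n_reps,
        n_mutations=n_mutations,
        genome_length=genome.total_length,
    )


@dataclass
class NullEstimate:
    """Per-clone probability of at least one spurious cluster call."""

    probability: float
    n_hits: int
    n_reps: int
    ci95: tuple[float, float]
    params: dict

    def to_dict(self) -> dict:
        return {
            "probability": self.probability,
            "n_hits": self.n_hits,
            "n_reps": self.n_reps,
            "ci95": list(self.ci95),
            "params": self.params,
        }


def estimate_cluster_probability(
    genome: GenomeModel,
    n_mutations: int | Sequence[int],
    threshold: float,
    min_mutations: int = 5,
    n_reps: int = 100_000,
    seed: int | None = None,
    batch_size: int = 10_000,
) -> NullEstimate:
    """Monte Carlo probability that random scatter yields a cluster call.

    Each replicate scatters one clone's worth of mutations uniformly over
    the genome and runs the cluster caller's run-finding core at the given
    threshold. ``n_mutations`` may be a sequence of observed per-clone
    loads, in which case replicate ``i`` uses load ``i mod len`` —
    replicating the observed load distribution rather than a pooled mean,
    since IMDs are clone-conditional. The 95% CI is Clopper-Pearson.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    loads = np.atleast_1d(np.asarray(n_mutations, dtype=np.int64))
    if (loads < 0).any():
        raise ValueError("mutation loads must be >= 0")
    starts, ends = _genome_offsets(genome)
    hits = 0
    done = 0
    while done < n_reps:
        todo = min(batch_size, n_reps - done)
        batch_loads = loads[(done + np.arange(todo)) % len(loads)]
        for n in np.unique(batch_loads):
            reps_n = int((batch_loads == n).sum())
            if n < min_mutations:
                continue
            mat = _sample_position_matrix(rng, genome.total_length, int(n), reps_n)
            chrom_idx = np.searchsorted(ends, mat, side="right")
            for r in range(reps_n):
                runs = find_cluster_runs(
                    mat[r], chrom_idx[r], threshold, min_mutations
                )
                if runs:
                    hits += 1
        done += todo
    p = hits / n_reps
    ci = stats.binomtest(hits, n_reps).proportion_ci(confidence_level=0.95)
    return NullEstimate(
        probability=p,
        n_hits=hits,
        n_reps=n_reps,
        ci95=(float(ci.low), float(ci.high)),
        params={
            "genome_length": genome.total_length,
            "n_chromosomes": len(genome.names),
            "n_mutations": [int(x) for x in loads],
            "threshold": float(threshold),
            "min_mutations": int(min_mutations),
            "seed": seed,
        },
    )
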