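"""Population-level bookkeeping on the genotype matrix.

Minor allele frequency, per-group occurrence (carrier) frequency, and the
accession-subsampling saturation (rarefaction) curve showing how the
number of discovered variants grows with panel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sv_io import GenotypeMatrix


@dataclass
class RarefactionResult:
    sample_sizes: list
    reps: int
    seed: int
    mean_counts: np.ndarray
    sd_counts: np.ndarray


def maf(column) -> float:
    """Minor allele frequency of one variant column of dosages.

    ``min(p, 1-p)`` with p the alt-allele frequency among non-missing
    diploid genotypes.  All-missing columns are undefined and raise.
    """
    col = np.asarray(column)
    obs = col[col >= 0]
    if obs.size == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    p = obs.sum() / (2 * obs.size)
    return float(min(p, 1 - p))


def maf_all(matrix: GenotypeMatrix) -> np.ndarray:
    """Vectorised MAF per variant; NaN where all genotypes are missing."""
    geno = matrix.geno
    obs = geno >= 0
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, geno, 0).sum(axis=0) / (2 * n_obs)
    out = np.minimum(p, 1 - p)
    out[n_obs == 0] = np.nan
    return out


def occurrence_frequency(column, rows) -> float:
    """Carrier frequency: fraction of non-missing accessions in the group
    (given by row indices) carrying at least one alternate allele."""
    col = np.asarray(column)[np.asarray(rows, dtype=int)]
    obs = col[col >= 0]
    if obs.size == 0:
        raise ValueError("occurrence frequency undefined: group all missing")
    return float((obs >= 1).sum() / obs.size)


def group_carrier_counts(matrix: GenotypeMatrix, group: str):
    """(carriers, non-missing n) arrays over variants for one group."""
    rows = matrix.group_rows(group)
    sub = matrix.geno[rows]
    carriers = (sub >= 1).sum(axis=0)
    n = (sub >= 0).sum(axis=0)
    return carriers.astype(int), n.astype(int)


def rarefaction(matrix: GenotypeMatrix, sizes, reps: int, seed: int) -> RarefactionResult:
    """Mean/sd number of segregating variants discovered in random
    accession subsamples of each size (without replacement).

    A variant is discovered when at least one sampled accession carries an
    alternate allele; missing genotypes never count as carriers.
    Fully reproducible from ``seed``.
    """
    n_acc = len(matrix.accessions)
    sizes = list(sizes)
    if any(s > n_acc for s in sizes):
        raise ValueError(f"subsample size exceeds panel size {n_acc}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    carriers = matrix.geno >= 1  # bool (acc x var)
    means, sds = [], []
    for s in sizes:
        counts = np.empty(reps)
        for r in range(reps):
            rows = rng.choice(n_acc, size=s, replace=False)
            counts[r] = carriers[rows].any(axis=0).sum() if s > 0 else 0
        means.append(counts.mean())
        sds.append(counts.std(ddof=0))
    return RarefactionResult(
        sample_sizes=sizes, reps=reps, seed=seed,
        mean_counts=np.array(means), sd_counts=np.array(sds),
    )


def saturation_fraction(count_at_size: float, total: float) -> int:
    """Percentage of the total variant count discovered at a subsample
    size, rounded to the nearest integer for reporting."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(round(100.0 * count_at_size / total))
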