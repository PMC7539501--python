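"""Windowed nucleotide diversity and reduction-of-diversity sweep scans.

Per-site diversity is the unbiased pairwise-difference estimator
``2 j (n - j) / (n (n - 1))`` over n haplotypes carrying j alternate
alleles.  Diversity is summed over the variant sites inside each sliding
window (default 100 kb, step 10 kb) and divided by the full window length.
ROD is the ratio of earlier-group to later-group windowed diversity; the
top 5% of windows by ROD are flagged and merged into sweep regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .sv_io import GenotypeMatrix


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    n_sites: int
    pi: dict = field(default_factory=dict)  # group label -> per-bp diversity
    rod: float = math.nan
    is_sweep: bool = False
    truncated: bool = False


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    phase: str = ""
    source: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def site_pi(dosages) -> float:
    """Nucleotide diversity at one site from diploid dosages; equals the
    mean pairwise difference over all haplotype pairs."""
    d = np.asarray(dosages)
    obs = d[d >= 0]
    if obs.size < 2:
        raise ValueError("site diversity needs >= 2 non-missing genotypes")
    n = 2 * obs.size
    j = int(obs.sum())
    return 2.0 * j * (n - j) / (n * (n - 1))


def _window_grid(contig_length, window, step):
    starts = range(1, contig_length + 1, step)
    return [(s, min(s + window - 1, contig_length)) for s in starts
            if s <= contig_length]


def windowed_pi(matrix: GenotypeMatrix, group: str, contig_lengths: dict,
                window: int = 100_000, step: int = 10_000) -> list:
    """Per-window diversity for one group across all contigs.

    Sites contribute to every window containing them; the denominator is
    the full window length (truncated windows are flagged).  Sites where
    fewer than two group genotypes are observed contribute 0.
    """
    rows = matrix.group_rows(group)
    if rows.size < 1:
        raise ValueError(f"group {group!r} has no accessions")
    sub = matrix.geno[rows]
    obs = sub >= 0
    n_hap = 2 * obs.sum(axis=0)
    j = np.where(obs, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = np.where(
            n_hap >= 4, 2.0 * j * (n_hap - j) / (n_hap * (n_hap - 1)), 0.0
        )

    chroms = matrix.variants["chrom"].to_numpy()
    pos = matrix.variants["pos"].to_numpy()
    stats = []
    for chrom in sorted(contig_lengths):
        clen = contig_lengths[chrom]
        mask = chroms == chrom
        cpos = pos[mask]
        cpi = pi_site[mask]
        order = np.argsort(cpos, kind="stable")
        cpos, cpi = cpos[order], cpi[order]
        cum = np.concatenate([[0.0], np.cumsum(cpi)])
        for s, e in _window_grid(clen, window, step):
            lo = np.searchsorted(cpos, s, side="left")
            hi = np.searchsorted(cpos, e, side="right")
            stats.append(WindowStat(
                chrom=chrom, start=s, end=e, n_sites=int(hi - lo),
                pi={group: float(cum[hi] - cum[lo]) / window},
                truncated=(e - s + 1) < window,
            ))
    return stats


def rod_sweeps(stats_earlier, stats_later, top_fraction: float = 0.05,
               step: int = 10_000):
    """Flag the top-fraction windows by ROD and assemble sweep regions.

    ROD = pi_earlier / pi_later.  Windows where the later group retains no
    diversity but the earlier does rank above every finite ratio; windows
    with zero diversity in both groups are excluded from ranking.  Ties at
    the quantile boundary resolve in genomic order.  Flagged windows that
    overlap or are step-contiguous merge into one region.
    """
    if len(stats_earlier) != len(stats_later):
        raise ValueError("window lists differ in length")
    combined = []
    for we, wl in zip(stats_earlier, stats_later):
        if (we.chrom, we.start, we.end) != (wl.chrom, wl.start, wl.end):
            raise ValueError("window grids differ between groups")
        w = WindowStat(
            chrom=we.chrom, start=we.start, end=we.end,
            n_sites=max(we.n_sites, wl.n_sites),
            pi={**we.pi, **wl.pi}, truncated=we.truncated,
        )
        pe = next(iter(we.pi.values()))
        pl = next(iter(wl.pi.values()))
        if pl > 0:
            w.rod = pe / pl
        elif pe > 0:
            w.rod = math.inf
        combined.append(w)

    ranked = [w for w in combined if not math.isnan(w.rod)]
    n_flag = math.ceil(top_fraction * len(ranked))
    order = sorted(
        range(len(ranked)),
        key=lambda i: (-ranked[i].rod, ranked[i].chrom, ranked[i].start),
    )
    for i in order[:n_flag]:
        ranked[i].is_sweep = True

    flagged = sorted(
        (w for w in combined if w.is_sweep), key=lambda w: (w.chrom, w.start)
    )
    regions = []
    for w in flagged:
        last = regions[-1] if regions else None
        if (last is not None and last.chrom == w.chrom
                and w.start <= last.end + step):
            last.end = max(last.end, w.end)
            last.n_windows += 1
        else:
            regions.append(SweepRegion(
                chrom=w.chrom, start=w.start, end=w.end, n_windows=1
            ))
    return combined, regions


def region_overlap(a, b) -> int:
    """Total shared bp between two internally non-overlapping region sets."""
    total = 0
    for ra in a:
        for rb in b:
            if ra.chrom != rb.chrom:
                continue
            lo = max(ra.start, rb.start)
            hi = min(ra.end, rb.end)
            if hi >= lo:
                total += hi - lo + 1
    return total


def sweep_summary(regions, genome_length: int) -> dict:
    """Region count, cumulative Mb and genome fraction, for reporting."""
    total_bp = sum(r.length for r in regions)
    return {
        "n_regions": len(regions),
        "total_mb": total_bp / 1e6,
        "pct_genome": 100.0 * total_bp / genome_length if genome_length else 0.0,
    }
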