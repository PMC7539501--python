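"""Functional-impact classification of consensus SVs against gene models.

Each SV is intersected with the CDS, intron, and 2-kb promoter intervals
of every gene on its chromosome.  Insertions act as 1-bp points at their
start; breakends contribute their two breakpoint loci as 1-bp points.  At
the gene level a precedence rule (CDS > intron > promoter) assigns each
affected gene exactly one category, so category counts are mutually
exclusive and sum to the affected-gene count.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

CATEGORIES = ("CDS", "intron", "promoter")
_PRECEDENCE = {"CDS": 0, "intron": 1, "promoter": 2}


@dataclass
class ImpactCall:
    event_id: str
    gene_id: str
    category: str
    overlap_bp: int


def _sv_intervals(sv):
    """1-based closed intervals an SV occupies for overlap purposes."""
    if sv.svtype == "INS":
        return [(sv.chrom, sv.start, sv.start)]
    if sv.svtype == "BND":
        loci = [(sv.chrom, sv.start, sv.start)]
        mate = None
        if getattr(sv, "mate_chrom", ""):
            mate = (sv.mate_chrom, sv.mate_pos)
        else:  # consensus breakend: mate locus lives on its member calls
            for m in getattr(sv, "members", []):
                if m.mate_chrom:
                    mate = (m.mate_chrom, m.mate_pos)
                    break
        if mate is not None:
            loci.append((mate[0], mate[1], mate[1]))
        return loci
    return [(sv.chrom, sv.start, sv.end)]


def _gene_trees(genes):
    """chrom → IntervalTree of (gene_id, category) annotated intervals.

    Trees use half-open [start, end+1) coordinates internally; query
    results are converted back to closed-interval overlap lengths.
    """
    trees: dict = {}
    for g in genes:
        t = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.cds:
            t[s:e + 1] = (g.gene_id, "CDS")
        for s, e in g.introns:
            t[s:e + 1] = (g.gene_id, "intron")
        if g.promoter is not None:
            s, e = g.promoter
            t[s:e + 1] = (g.gene_id, "promoter")
    return trees


def sv_gene_overlaps(merged, genes) -> list:
    """One :class:`ImpactCall` per (SV, gene, category) with >= 1 bp
    intersection; multiple CDS exons of one gene hit by one SV are summed
    into a single call."""
    trees = _gene_trees(genes)
    agg: dict = {}
    for sv in merged:
        for chrom, start, end in _sv_intervals(sv):
            tree = trees.get(chrom)
            if tree is None:
                continue
            for iv in tree.overlap(start, end + 1):
                gene_id, category = iv.data
                ov = min(end + 1, iv.end) - max(start, iv.begin)
                key = (sv.event_id, gene_id, category)
                agg[key] = agg.get(key, 0) + ov
    return [
        ImpactCall(event_id=e, gene_id=g, category=c, overlap_bp=bp)
        for (e, g, c), bp in sorted(agg.items())
    ]


def gene_level_summary(calls, genes):
    """Assign each gene at most one category by precedence
    CDS > intron > promoter and tally.

    Returns ``(per_gene, counts)`` where ``per_gene`` maps gene_id → its
    category and ``counts`` has the three category counts plus
    ``affected``, ``unaffected``, ``total`` and ``pct_affected``.
    """
    per_gene: dict = {}
    for call in calls:
        cur = per_gene.get(call.gene_id)
        if cur is None or _PRECEDENCE[call.category] < _PRECEDENCE[cur]:
            per_gene[call.gene_id] = call.category
    counts = {c: 0 for c in CATEGORIES}
    for cat in per_gene.values():
        counts[cat] += 1
    total = len(genes)
    affected = len(per_gene)
    counts.update({
        "affected": affected,
        "unaffected": total - affected,
        "total": total,
        "pct_affected": int(round(100.0 * affected / total)) if total else 0,
    })
    return per_gene, counts


def affected_gene_table(calls):
    """Per-gene rows mirroring a supplementary-table layout:
    gene_id, category (precedence-resolved), n_svs, sv_ids."""
    import pandas as pd

    by_gene: dict = {}
    for c in calls:
        by_gene.setdefault(c.gene_id, []).append(c)
    rows = []
    for gene_id in sorted(by_gene):
        gcalls = by_gene[gene_id]
        cat = min((c.category for c in gcalls), key=_PRECEDENCE.get)
        svs = sorted({c.event_id for c in gcalls})
        rows.append({
            "gene_id": gene_id, "category": cat,
            "n_svs": len(svs), "sv_ids": ",".join(svs),
        })
    return pd.DataFrame(rows, columns=["gene_id", "category", "n_svs", "sv_ids"])
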