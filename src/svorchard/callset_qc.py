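"""Per-caller SV filtering and GATK-style small-variant hard filters.

The LUMPY-style filter keeps a call only when quality exceeds 20, total
read support exceeds 5, and a deletion shorter than 340 bp has at least one
split read.  Small variants are dropped when any of their class's hard
thresholds fires (e.g. a SNP with FS > 60).  All comparators are strict, so
values exactly at a cutoff fail the ">" rules and survive the "<" ones
exactly as the inequalities read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

SNP_THRESHOLDS = {
    "QUAL": ("<", 40.0),
    "QD": ("<", 2.0),
    "FS": (">", 60.0),
    "MQ": ("<", 40.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
}
INDEL_THRESHOLDS = {
    "QD": ("<", 2.0),
    "FS": (">", 200.0),
    "ReadPosRankSum": ("<", -20.0),
}


@dataclass
class FilterPolicy:
    """Cutoffs for both filter families; defaults are the pipeline's
    standard values."""

    min_qual: float = 20.0
    min_su: int = 5
    del_sr_min_size: int = 340
    snp_thresholds: dict = field(default_factory=lambda: dict(SNP_THRESHOLDS))
    indel_thresholds: dict = field(default_factory=lambda: dict(INDEL_THRESHOLDS))


def filter_lumpy_like(records, policy: FilterPolicy | None = None):
    """Apply the read-evidence filter used for LUMPY-style call sets.

    Returns ``(kept, dropped)`` where ``dropped`` is a list of
    ``(record, reason)`` pairs carrying the first failing rule.  Missing
    su/sr are treated as 0 (conservative) and logged.
    """
    policy = policy or FilterPolicy()
    kept, dropped = [], []
    for r in records:
        if r.su is None or r.sr is None:
            log.warning("record %s missing read-evidence fields; treated as 0", r.id)
        qual = r.qual or 0.0
        su = r.su or 0
        sr = r.sr or 0
        if not qual > policy.min_qual:
            dropped.append((r, f"quality {qual} not > {policy.min_qual}"))
        elif not su > policy.min_su:
            dropped.append((r, f"support {su} not > {policy.min_su}"))
        elif r.svtype == "DEL" and r.svlen < policy.del_sr_min_size and sr == 0:
            dropped.append((r, "short deletion without split-read support"))
        else:
            kept.append(r)
    return kept, dropped


def _fails(value, comparator, cutoff):
    return value < cutoff if comparator == "<" else value > cutoff


def hard_filter_small_variants(records, policy: FilterPolicy | None = None):
    """GATK-style hard filtering: drop a record iff ANY of its class's
    threshold conditions holds; absent annotations are not evaluated."""
    policy = policy or FilterPolicy()
    kept, dropped = [], []
    for r in records:
        thresholds = (policy.snp_thresholds if r.vclass == "SNP"
                      else policy.indel_thresholds)
        reason = None
        for key, (cmp_, cutoff) in thresholds.items():
            value = r.qual if key == "QUAL" else r.info.get(key)
            if value is None:
                log.debug("record %s:%s lacks %s; condition skipped",
                          r.chrom, r.pos, key)
                continue
            if _fails(value, cmp_, cutoff):
                reason = f"{key} {cmp_} {cutoff} (value {value})"
                break
        if reason is None:
            kept.append(r)
        else:
            dropped.append((r, reason))
    return kept, dropped


def size_gate(records, min_size: int = 50, max_size: int = 10_000_000):
    """Keep non-BND records with min_size <= svlen <= max_size (inclusive);
    breakends are exempt from the size gate."""
    return [
        r for r in records
        if r.svtype == "BND" or min_size <= r.svlen <= max_size
    ]
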