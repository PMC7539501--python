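"""Multi-caller consensus merging of SV call sets.

Two calls are compatible when they lie on the same chromosome(s), share the
SV type and strand orientation (both requirements can be relaxed), and both
breakpoints are within ``max_dist`` (default 1000 bp).  Clusters are the
connected components of the compatibility graph — single-linkage chaining,
the semantics of SURVIVOR-style merging — built with a sliding window over
start positions, which is exact because a start distance beyond
``max_dist`` already breaks compatibility.  A cluster becomes a consensus
SV only when it contains calls from at least ``min_callers`` distinct
callers; representative coordinates are the lower median of member
breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .callset_qc import size_gate


@dataclass
class MergeParams:
    max_dist: int = 1000
    min_callers: int = 2
    require_type: bool = True
    require_strand: bool = True
    min_size: int = 50
    max_size: int = 10_000_000

    def __post_init__(self):
        if self.max_dist < 0:
            raise ValueError("max_dist must be >= 0")
        if self.min_callers < 1:
            raise ValueError("min_callers must be >= 1")


@dataclass
class MergedSV:
    """A consensus SV: representative coordinates plus member calls."""

    event_id: str
    chrom: str
    start: int
    end: int
    svtype: str
    svlen: int
    strands: str
    members: list = field(default_factory=list)
    callers: set = field(default_factory=set)


def compatible(a, b, params: MergeParams | None = None) -> bool:
    """SURVIVOR-style pairwise compatibility predicate.

    For breakends both mate loci must match chromosomes and lie within
    ``max_dist``; for all other types the start and end coordinates are
    compared.
    """
    params = params or MergeParams()
    if a.chrom != b.chrom:
        return False
    if params.require_type and a.svtype != b.svtype:
        return False
    if params.require_strand and a.strands != b.strands:
        return False
    if a.svtype == "BND" or b.svtype == "BND":
        if a.svtype != b.svtype:
            return False
        if a.mate_chrom != b.mate_chrom:
            return False
        return (abs(a.start - b.start) <= params.max_dist
                and abs(a.mate_pos - b.mate_pos) <= params.max_dist)
    return (abs(a.start - b.start) <= params.max_dist
            and abs(a.end - b.end) <= params.max_dist)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _lower_median(values):
    v = sorted(values)
    return v[(len(v) - 1) // 2]


def _check_sorted(records, caller):
    prev = None
    for r in records:
        key = (r.chrom, r.start)
        if prev is not None and key < prev:
            raise ValueError(
                f"call set {caller!r} is not sorted by (chrom, start); "
                "sort the records before merging"
            )
        prev = key


def _primary_bnd(records):
    """Keep one mate per breakend event (the lexicographically smaller
    locus) so a translocation enters clustering once."""
    out = []
    for r in records:
        if r.svtype != "BND":
            out.append(r)
        elif (r.chrom, r.start, r.id) <= (r.mate_chrom, r.mate_pos, r.mate_id):
            out.append(r)
    return out


def merge_callsets(callsets: dict, params: MergeParams | None = None) -> list:
    """Merge per-caller call sets into consensus SVs.

    ``callsets`` maps caller label → QC-filtered records sorted by
    (chrom, start).  Output is sorted by (chrom, start, end) with
    sequential event ids; the result is invariant to caller order.
    """
    params = params or MergeParams()
    for caller, recs in callsets.items():
        _check_sorted(recs, caller)

    pool = []
    for caller in sorted(callsets):
        pool.extend(_primary_bnd(callsets[caller]))
    # deterministic global order; tie-break by caller label then record id
    pool.sort(key=lambda r: (r.chrom, r.start, r.end, r.caller, r.id))

    # partition so that only potentially-compatible records are clustered
    partitions: dict = {}
    for r in pool:
        key = [r.chrom]
        if r.svtype == "BND":
            key.append(r.mate_chrom)
        if params.require_type:
            key.append(r.svtype)
        if params.require_strand:
            key.append(r.strands)
        partitions.setdefault(tuple(key), []).append(r)

    merged = []
    for recs in partitions.values():
        uf = _UnionFind(len(recs))
        lo = 0
        for i, r in enumerate(recs):
            while recs[lo].start < r.start - params.max_dist:
                lo += 1
            for j in range(lo, i):
                if compatible(recs[j], r, params):
                    uf.union(j, i)
        components: dict = {}
        for i in range(len(recs)):
            components.setdefault(uf.find(i), []).append(recs[i])
        for members in components.values():
            callers = {m.caller for m in members}
            if len(callers) < params.min_callers:
                continue
            merged.append(_make_merged(members, callers))

    merged = size_gate(merged, params.min_size, params.max_size)
    merged.sort(key=lambda m: (m.chrom, m.start, m.end, m.svtype))
    for k, m in enumerate(merged, 1):
        m.event_id = f"MSV{k:06d}"
    return merged


def _make_merged(members, callers):
    start = _lower_median([m.start for m in members])
    svtype = members[0].svtype
    if svtype == "BND":
        end = start
        svlen = 0
    elif svtype == "INS":
        end = start
        svlen = _lower_median([m.svlen for m in members])
    else:
        end = _lower_median([m.end for m in members])
        svlen = end - start
    return MergedSV(
        event_id="", chrom=members[0].chrom, start=start, end=end,
        svtype=svtype, svlen=svlen, strands=members[0].strands,
        members=sorted(members, key=lambda m: (m.caller, m.id)),
        callers=callers,
    )


def combine_type_counts(counts: dict) -> dict:
    """Attach the ``total`` (sum of per-category counts) to a dict of SV
    counts by reported category."""
    out = dict(counts)
    out["total"] = sum(counts.values())
    return out


def summarize_map(merged) -> dict:
    """Counts by reported category: DEL and INS are tallied together as
    "indel", breakend pairs count once (they enter merging as single
    events).  ``total`` is the sum of the category counts."""
    counts = {"indel": 0, "DUP": 0, "INV": 0, "BND": 0}
    for m in merged:
        if m.svtype in ("DEL", "INS"):
            counts["indel"] += 1
        else:
            counts[m.svtype] += 1
    return combine_type_counts(counts)
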