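"""Ground-truth simulator for every input the pipeline consumes.

The generator emulates a resequenced crop panel in three population groups
(wild, landrace, improved): a toy genome with gene models, a set of truth
SVs with type proportions and log-uniform size ranges shaped like an
empirical SV map (indels and duplications mostly 100 bp-10 kb, inversions
heavier above 10 kb, translocations as reciprocal breakend pairs between
contigs), noisy per-caller call sets (breakpoint jitter, per-caller false
negatives, caller-private false calls, a LUMPY-like caller whose quality
and read-support fields partly fail QC on purpose), population genotypes
with drifted group frequencies and planted frequency-shifted (selected)
SVs, dense SNPs whose later-group diversity is scaled down inside planted
sweep regions, and a phenotype with one causal marker at a configured
heritability.

Randomness flows from a single seed through named sub-streams, so the same
seed yields byte-identical output files and any one component can be
regenerated without perturbing the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sv_io import (
    AccessionPanel, GeneModel, GenotypeMatrix, SVRecord,
    write_genotype_vcf, write_gff3, write_panel_tsv, write_sv_vcf,
)

DEFAULT_TYPE_MIX = {"DEL": 0.35, "INS": 0.25, "DUP": 0.05, "INV": 0.05, "BND": 0.30}
DEFAULT_SIZE_RANGES = {
    "DEL": (100, 10_000),
    "INS": (100, 10_000),
    "DUP": (100, 10_000),
    "INV": (1_000, 100_000),
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated panel.

    Group sizes default to 13 wild / 70 landrace / 233 improved, the
    composition of the panel the pipeline is designed around.  Selected
    SVs are planted per phase with a carrier-frequency shift between the
    phase's two groups; sweep regions scale the later group's SNP
    diversity by ``sweep_pi_scale``.
    """

    seed: int
    n_contigs: int = 2
    contig_length: int = 2_000_000
    n_genes: int = 100
    n_truth_svs: int = 300
    type_mix: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_MIX))
    size_ranges: dict = field(default_factory=lambda: dict(DEFAULT_SIZE_RANGES))
    callers: tuple = ("lumpy", "manta", "gridss", "delly")
    breakpoint_jitter_sd: float = 50.0
    caller_fnr: float = 0.1
    caller_fpr: float = 0.1
    qc_fail_fraction: float = 0.05  # lumpy calls engineered to fail QC
    group_sizes: tuple = (13, 70, 233)  # wild, landrace, improved
    n_selected_svs: int = 20  # per phase
    selection_shift: float = 0.8
    drift_sd: float = 0.03
    missing_rate: float = 0.05
    snp_spacing: int = 200
    snp_drift_sd: float = 0.02
    sweep_regions: tuple = (("contig1", 900_001, 1_050_000, "domestication"),)
    sweep_pi_scale: float = 0.1
    causal_effect: float = 1.0
    heritability: float = 0.3

    def __post_init__(self):
        if abs(sum(self.type_mix.values()) - 1.0) > 1e-9:
            raise ValueError("type_mix proportions must sum to 1")
        for name, rate in (("caller_fnr", self.caller_fnr),
                           ("caller_fpr", self.caller_fpr),
                           ("missing_rate", self.missing_rate),
                           ("heritability", self.heritability)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def contigs(self) -> dict:
        return {f"contig{i + 1}": self.contig_length
                for i in range(self.n_contigs)}


@dataclass
class TruthSet:
    """Everything the tests need to score the pipeline against."""

    svs: list  # dicts: id, chrom, start, end, svtype, svlen, strands, freqs
    selected: dict  # phase -> {sv_id: "positive" | "negative"}
    sweep_regions: list  # (chrom, start, end, phase)
    causal_id: str
    false_call_ids: dict  # caller -> list of planted-false-call ids

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulationResult:
    config: SimulationConfig
    contigs: dict
    genes: list
    truth: TruthSet
    callsets: dict  # caller -> sorted list of SVRecord
    sv_matrix: GenotypeMatrix
    snp_matrix: GenotypeMatrix
    panel: AccessionPanel

    def write(self, out_dir) -> dict:
        """Write every pipeline input below ``out_dir``; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for caller, recs in self.callsets.items():
            p = out / f"{caller}.vcf"
            write_sv_vcf(recs, p, self.contigs)
            paths[f"caller:{caller}"] = p
        write_genotype_vcf(self.sv_matrix, out / "sv_genotypes.vcf", self.contigs)
        write_genotype_vcf(self.snp_matrix, out / "snp_genotypes.vcf", self.contigs)
        write_gff3(self.genes, out / "genes.gff3", self.contigs)
        write_panel_tsv(self.panel, out / "panel.tsv")
        self.truth.to_json(out / "truth.json")
        paths.update({
            "sv_genotypes": out / "sv_genotypes.vcf",
            "snp_genotypes": out / "snp_genotypes.vcf",
            "genes": out / "genes.gff3",
            "panel": out / "panel.tsv",
            "truth": out / "truth.json",
        })
        return paths


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named deterministic sub-stream of the global seed."""
    digest = hashlib.sha256(name.encode()).digest()
    child = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng([seed % (2**31), child])


# ---------------------------------------------------------------------------
# Genome and truth SVs
# ---------------------------------------------------------------------------

def _simulate_genes(cfg: SimulationConfig, rng) -> list:
    """Non-overlapping genes with 2-4 CDS exons, random strand, spread
    evenly over the contigs (promoter space left between neighbours)."""
    genes = []
    contig_names = sorted(cfg.contigs)
    per_contig = cfg.n_genes // cfg.n_contigs
    slot = cfg.contig_length // (per_contig + 1)
    if slot - 4_200 <= 2_000:
        raise ValueError(
            "infeasible config: too many genes for the contig length "
            f"(per-gene slot {slot} bp)"
        )
    k = 0
    for chrom in contig_names:
        for i in range(per_contig):
            k += 1
            anchor = (i + 1) * slot
            span = int(rng.integers(2_000, min(8_000, slot - 4_200)))
            start = anchor + int(rng.integers(0, max(1, slot - span - 4_200)))
            end = start + span - 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 5))
            bounds = np.sort(rng.choice(
                np.arange(1, span - 1), size=2 * n_exons - 2, replace=False))
            edges = [0, *bounds.tolist(), span - 1]
            cds = [(start + edges[2 * j], start + edges[2 * j + 1])
                   for j in range(n_exons)]
            introns = [(cds[j][1] + 1, cds[j + 1][0] - 1)
                       for j in range(n_exons - 1)
                       if cds[j + 1][0] > cds[j][1] + 1]
            if strand == "+":
                promoter = (max(1, start - 2000), start - 1)
            else:
                promoter = (end + 1, min(cfg.contig_length, end + 2000))
            genes.append(GeneModel(
                gene_id=f"gene{k:04d}", chrom=chrom, strand=strand,
                start=start, end=end, cds=cds, introns=introns,
                promoter=promoter,
            ))
    return genes


def _type_counts(cfg: SimulationConfig) -> dict:
    counts = {t: int(round(p * cfg.n_truth_svs))
              for t, p in cfg.type_mix.items()}
    # absorb rounding drift into the most abundant type
    top = max(counts, key=counts.get)
    counts[top] += cfg.n_truth_svs - sum(counts.values())
    return counts


def _log_uniform(rng, lo, hi):
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def _simulate_truth_svs(cfg: SimulationConfig, rng) -> list:
    """Truth SVs as dicts; within a type, intervals do not overlap.

    BND events carry both loci (chrom/start and chrom2/pos2) and are one
    event each.  Raises when the requested SV mass cannot fit.
    """
    counts = _type_counts(cfg)
    contig_names = sorted(cfg.contigs)
    for t, (lo, hi) in cfg.size_ranges.items():
        expected = counts.get(t, 0) * np.exp((np.log(lo) + np.log(hi)) / 2)
        if expected > 0.8 * cfg.n_contigs * cfg.contig_length:
            raise ValueError(
                f"infeasible config: expected {t} mass {expected:.0f} bp "
                f"exceeds genome capacity"
            )
    svs = []
    occupied = {t: {c: [] for c in contig_names} for t in cfg.size_ranges}
    k = 0
    for svtype in sorted(counts):
        for _ in range(counts[svtype]):
            k += 1
            sv_id = f"T{k:05d}"
            if svtype == "BND":
                if cfg.n_contigs >= 2:
                    c1, c2 = rng.choice(len(contig_names), size=2, replace=False)
                else:
                    c1 = c2 = 0
                p1 = int(rng.integers(10_000, cfg.contig_length - 10_000))
                p2 = int(rng.integers(10_000, cfg.contig_length - 10_000))
                strands = ["+-", "-+", "++", "--"][int(rng.integers(4))]
                svs.append({
                    "id": sv_id, "chrom": contig_names[c1], "start": p1,
                    "end": p1, "svtype": "BND", "svlen": 0, "strands": strands,
                    "chrom2": contig_names[c2], "pos2": p2,
                })
                continue
            lo, hi = cfg.size_ranges[svtype]
            for _attempt in range(200):
                size = _log_uniform(rng, lo, hi)
                chrom = contig_names[int(rng.integers(cfg.n_contigs))]
                start = int(rng.integers(5_000, cfg.contig_length - size - 5_000))
                end = start if svtype == "INS" else start + size
                span = (start - 2_500, end + 2_500)  # keep same-type calls apart
                if all(span[1] < s or span[0] > e
                       for s, e in occupied[svtype][chrom]):
                    occupied[svtype][chrom].append((start, end))
                    svs.append({
                        "id": sv_id, "chrom": chrom, "start": start, "end": end,
                        "svtype": svtype, "svlen": size,
                        "strands": ("++" if svtype == "INV" and rng.random() < 0.5
                                    else "--" if svtype == "INV"
                                    else {"DEL": "+-", "INS": "+-", "DUP": "-+"}[svtype]),
                        "chrom2": "", "pos2": 0,
                    })
                    break
            else:
                raise ValueError("could not place truth SVs without overlap; "
                                 "reduce n_truth_svs or grow the genome")
    svs.sort(key=lambda s: (s["chrom"], s["start"], s["id"]))
    return svs


# ---------------------------------------------------------------------------
# Caller call sets
# ---------------------------------------------------------------------------

def _caller_evidence(rng, caller, fail_qc: bool):
    """qual/su/sr/pe fields; LUMPY-like callers get realistic evidence,
    a ``fail_qc`` fraction engineered to trip one of the QC rules."""
    if fail_qc:
        mode = int(rng.integers(2))
        if mode == 0:
            return round(float(rng.uniform(0, 20)), 2), int(rng.integers(8, 40)), 3, 5
        return round(float(rng.uniform(30, 90)), 2), int(rng.integers(0, 6)), 0, 1
    qual = round(float(rng.uniform(30, 95)), 2)
    su = int(rng.integers(8, 60))
    sr = int(rng.integers(1, max(2, su // 2)))
    return qual, su, sr, su - sr


def _simulate_callset(cfg: SimulationConfig, caller: str, truth_svs,
                      rng) -> tuple:
    """One caller's noisy view of the truth set.

    Returns ``(records, false_ids)``; call ids embed the truth id
    (``{caller}_{truth_id}``) or an FP tag, keeping every emitted call
    traceable.
    """
    records, false_ids = [], []
    jit = cfg.breakpoint_jitter_sd
    is_lumpy = caller == "lumpy"
    for sv in truth_svs:
        if rng.random() < cfg.caller_fnr:
            continue
        fail = is_lumpy and rng.random() < cfg.qc_fail_fraction
        qual, su, sr, pe = _caller_evidence(rng, caller, fail)
        base = f"{caller}_{sv['id']}"
        if sv["svtype"] == "BND":
            p1 = max(1, sv["start"] + int(round(rng.normal(0, jit))))
            p2 = max(1, sv["pos2"] + int(round(rng.normal(0, jit))))
            a, b = f"{base}_a", f"{base}_b"
            common = dict(svtype="BND", svlen=0, strands=sv["strands"],
                          caller=caller, qual=qual, su=su, sr=sr, pe=pe,
                          event_id=base)
            records.append(SVRecord(id=a, chrom=sv["chrom"], start=p1, end=p1,
                                    mate_id=b, mate_chrom=sv["chrom2"],
                                    mate_pos=p2, **common))
            records.append(SVRecord(id=b, chrom=sv["chrom2"], start=p2, end=p2,
                                    mate_id=a, mate_chrom=sv["chrom"],
                                    mate_pos=p1, **common))
            continue
        start = max(1, sv["start"] + int(round(rng.normal(0, jit))))
        if sv["svtype"] == "INS":
            end = start
            svlen = max(50, sv["svlen"] + int(round(rng.normal(0, jit / 5))))
        else:
            end = max(start, sv["end"] + int(round(rng.normal(0, jit))))
            svlen = end - start
        records.append(SVRecord(
            id=base, chrom=sv["chrom"], start=start, end=end,
            svtype=sv["svtype"], svlen=svlen, strands=sv["strands"],
            caller=caller, qual=qual, su=su, sr=sr, pe=pe,
        ))
    records.sort(key=lambda r: (r.chrom, r.start, r.id))
    return records, false_ids


def _simulate_false_calls(cfg: SimulationConfig, n_truth: int, rng) -> dict:
    """Caller-private false calls for every caller, drawn from one shared
    stream so that same-type false calls of different callers always sit
    further apart than the merge distance — planted false positives are
    unreplicated by construction."""
    n_false = int(round(cfg.caller_fpr * n_truth))
    contig_names = sorted(cfg.contigs)
    taken: dict = {}  # svtype -> chrom -> list of starts
    out = {c: [] for c in cfg.callers}
    min_gap = 2_500  # > max merge distance with jitter headroom
    for caller in sorted(cfg.callers):
        for k in range(n_false):
            for _attempt in range(200):
                svtype = ["DEL", "INS", "DUP", "INV"][int(rng.integers(4))]
                lo, hi = cfg.size_ranges[svtype]
                size = _log_uniform(rng, lo, hi)
                chrom = contig_names[int(rng.integers(cfg.n_contigs))]
                start = int(rng.integers(5_000, cfg.contig_length - size - 5_000))
                near = taken.setdefault(svtype, {}).setdefault(chrom, [])
                if all(abs(start - s) > min_gap for s in near):
                    near.append(start)
                    break
            else:
                raise ValueError("could not place private false calls; "
                                 "reduce caller_fpr or grow the genome")
            qual, su, sr, pe = _caller_evidence(rng, caller, fail_qc=False)
            out[caller].append(SVRecord(
                id=f"{caller}_FP{k + 1:04d}", chrom=chrom, start=start,
                end=start if svtype == "INS" else start + size,
                svtype=svtype, svlen=size,
                strands=("++" if svtype == "INV" else
                         {"DEL": "+-", "INS": "+-", "DUP": "-+"}[svtype]),
                caller=caller, qual=qual, su=su, sr=sr, pe=pe,
            ))
    return out


# ---------------------------------------------------------------------------
# Population genotypes, SNPs, phenotype
# ---------------------------------------------------------------------------

def _accession_names(cfg: SimulationConfig):
    n_w, n_l, n_i = cfg.group_sizes
    names, groups = [], {}
    for prefix, group, n in (("W", "wild", n_w), ("L", "landrace", n_l),
                             ("I", "improved", n_i)):
        for i in range(n):
            a = f"{prefix}{i + 1:03d}"
            names.append(a)
            groups[a] = group
    return names, groups


def _plant_frequencies(cfg: SimulationConfig, truth_svs, rng):
    """Per-group carrier frequencies: neutral SVs share a drifted base
    frequency; selected SVs shift by ``selection_shift`` between the
    phase's groups; the causal marker sits at intermediate frequency in
    every group so the phenotype marker is common."""
    n = len(truth_svs)
    base = rng.beta(0.3, 3.0, size=n).clip(0.005, 0.9)
    freqs = {}
    for g in ("wild", "landrace", "improved"):
        freqs[g] = (base + rng.normal(0, cfg.drift_sd, size=n)).clip(0.0, 0.95)

    order = rng.permutation(n)
    needed = 2 * cfg.n_selected_svs + 1
    if needed > n:
        raise ValueError("n_selected_svs too large for n_truth_svs")
    sel_dom = order[:cfg.n_selected_svs]
    sel_imp = order[cfg.n_selected_svs:2 * cfg.n_selected_svs]
    causal_idx = int(order[2 * cfg.n_selected_svs])

    # Selected SVs mirror the empirical pattern of strong selection:
    # near-absent in the earlier group, near-fixed in the later one.
    selected = {"domestication": {}, "improvement": {}}
    shift = cfg.selection_shift
    for j in sel_dom:
        low = rng.uniform(0.01, 0.05)
        positive = rng.random() < 0.5
        early, late = (low, min(0.95, low + shift)) if positive else (min(0.95, low + shift), low)
        freqs["wild"][j] = early
        freqs["landrace"][j] = late
        freqs["improved"][j] = np.clip(late + rng.normal(0, cfg.drift_sd), 0, 0.95)
        selected["domestication"][truth_svs[j]["id"]] = (
            "positive" if positive else "negative")
    for j in sel_imp:
        low = rng.uniform(0.01, 0.05)
        positive = rng.random() < 0.5
        early, late = (low, min(0.95, low + shift)) if positive else (min(0.95, low + shift), low)
        freqs["wild"][j] = np.clip(early + rng.normal(0, cfg.drift_sd), 0, 0.95)
        freqs["landrace"][j] = early
        freqs["improved"][j] = late
        selected["improvement"][truth_svs[j]["id"]] = (
            "positive" if positive else "negative")

    # carrier frequency 0.51 <=> allele frequency 0.3
    for g in freqs:
        freqs[g][causal_idx] = 0.51
    return freqs, selected, truth_svs[causal_idx]["id"]


def _genotypes_from_carrier_freq(freqs_by_group, accessions, groups, cfg, rng):
    """Dosages ~ Binomial(2, p) with p = 1 - sqrt(1 - carrier frequency)
    (Hardy-Weinberg), then masked at ``missing_rate``."""
    n_var = len(next(iter(freqs_by_group.values())))
    geno = np.empty((len(accessions), n_var), dtype=np.int8)
    for i, a in enumerate(accessions):
        f = freqs_by_group[groups[a]]
        p = 1.0 - np.sqrt(1.0 - np.clip(f, 0.0, 0.99))
        geno[i] = rng.binomial(2, p).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(geno.shape) < cfg.missing_rate
        geno[mask] = -1
    return geno


def _simulate_snps(cfg: SimulationConfig, accessions, groups, rng):
    """SNP matrix dense enough for 100-kb windows; inside each planted
    sweep region the later group of the region's phase keeps only a
    ``sweep_pi_scale`` fraction of polymorphic sites (expected diversity
    scaled accordingly)."""
    later_of = {"domestication": "landrace", "improvement": "improved"}
    if cfg.snp_spacing <= 0:  # SNP stage disabled
        empty = pd.DataFrame(columns=["id", "chrom", "pos", "end", "svtype"])
        return GenotypeMatrix(
            accessions=list(accessions),
            variants=empty,
            geno=np.zeros((len(accessions), 0), dtype=np.int8),
            groups=dict(groups),
        )
    meta = []
    p_group = {g: [] for g in ("wild", "landrace", "improved")}
    for chrom in sorted(cfg.contigs):
        pos = 0
        while True:
            pos += 1 + int(rng.exponential(cfg.snp_spacing))
            if pos > cfg.contig_length:
                break
            base = rng.uniform(0.05, 0.5)
            ps = {g: float(np.clip(base + rng.normal(0, cfg.snp_drift_sd), 0, 1))
                  for g in p_group}
            for region in cfg.sweep_regions:
                rchrom, rstart, rend, phase = region
                if chrom == rchrom and rstart <= pos <= rend:
                    if rng.random() > cfg.sweep_pi_scale:
                        ps[later_of[phase]] = 0.0
            meta.append({"id": f"snp_{chrom}_{pos}", "chrom": chrom,
                         "pos": pos, "end": pos, "svtype": "SNP"})
            for g in p_group:
                p_group[g].append(ps[g])
    for g in p_group:
        p_group[g] = np.asarray(p_group[g])
    n_var = len(meta)
    geno = np.empty((len(accessions), n_var), dtype=np.int8)
    for i, a in enumerate(accessions):
        geno[i] = rng.binomial(2, p_group[groups[a]]).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(geno.shape) < cfg.missing_rate
        geno[mask] = -1
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "end", "svtype"])
    return GenotypeMatrix(accessions=list(accessions), variants=variants,
                          geno=geno, groups=dict(groups))


def _simulate_phenotype(cfg: SimulationConfig, sv_matrix: GenotypeMatrix,
                        causal_id: str, rng) -> pd.Series:
    """trait = effect * causal dosage + Gaussian noise calibrated so the
    causal marker explains ``heritability`` of the trait variance."""
    j = sv_matrix.variants.index[sv_matrix.variants["id"] == causal_id][0]
    d = sv_matrix.geno[:, j].astype(float)
    d[d < 0] = np.nanmean(d[d >= 0])  # phenotype exists for every accession
    g = cfg.causal_effect * d
    var_g = g.var()
    h2 = cfg.heritability
    sigma_e = np.sqrt(var_g * (1 - h2) / h2) if 0 < h2 < 1 and var_g > 0 else 1.0
    y = g + rng.normal(0, sigma_e, size=g.size)
    return pd.Series(y, index=sv_matrix.accessions, name="trait")


# ---------------------------------------------------------------------------
# Top-level
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate the full study: genome, truth SVs, caller call sets,
    population genotypes, SNPs, panel and phenotype.

    Deterministic: the same config (same seed) yields identical objects
    and, via :meth:`SimulationResult.write`, byte-identical files.
    """
    seed = config.seed
    genes = _simulate_genes(config, _stream(seed, "genes"))
    truth_svs = _simulate_truth_svs(config, _stream(seed, "svs"))

    false_calls = _simulate_false_calls(
        config, len(truth_svs), _stream(seed, "false_calls"))
    callsets, false_ids = {}, {}
    for caller in config.callers:
        recs, _ = _simulate_callset(
            config, caller, truth_svs, _stream(seed, f"caller:{caller}"))
        recs = recs + false_calls[caller]
        recs.sort(key=lambda r: (r.chrom, r.start, r.id))
        callsets[caller] = recs
        false_ids[caller] = [r.id for r in false_calls[caller]]

    accessions, groups = _accession_names(config)
    freqs, selected, causal_id = _plant_frequencies(
        config, truth_svs, _stream(seed, "frequencies"))
    geno = _genotypes_from_carrier_freq(
        freqs, accessions, groups, config, _stream(seed, "genotypes"))
    variants = pd.DataFrame(
        [{"id": s["id"], "chrom": s["chrom"], "pos": s["start"],
          "end": s["end"], "svtype": s["svtype"]} for s in truth_svs],
        columns=["id", "chrom", "pos", "end", "svtype"])
    sv_matrix = GenotypeMatrix(accessions=accessions, variants=variants,
                               geno=geno, groups=groups)

    snp_matrix = _simulate_snps(config, accessions, groups,
                                _stream(seed, "snps"))
    pheno = _simulate_phenotype(config, sv_matrix, causal_id,
                                _stream(seed, "phenotype"))

    for j, sv in enumerate(truth_svs):
        sv["freq"] = {g: float(freqs[g][j]) for g in freqs}

    truth = TruthSet(
        svs=truth_svs, selected=selected,
        sweep_regions=[list(r) for r in config.sweep_regions],
        causal_id=causal_id, false_call_ids=false_ids,
    )
    panel = AccessionPanel(groups=groups, phenotypes=pheno.to_frame())
    return SimulationResult(
        config=config, contigs=config.contigs, genes=genes, truth=truth,
        callsets=callsets, sv_matrix=sv_matrix, snp_matrix=snp_matrix,
        panel=panel,
    )
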