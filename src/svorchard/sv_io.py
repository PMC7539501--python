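"""Readers and writers for the formats the pipeline touches.

VCF carries structural variants (symbolic ALTs plus breakend notation for
translocations), small variants, and the population genotype matrix; GFF3
carries gene models; BED carries windows and sweep regions; TSV carries the
accession panel and phenotypes.

All internal coordinates are 1-based, fully closed (VCF/GFF3 native).  The
BED writer is the single place where conversion to 0-based half-open
happens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

SV_TYPES = ("DEL", "INS", "DUP", "INV", "BND")
VALID_GROUPS = ("wild", "ornamental", "landrace", "improved")

#: default breakpoint-orientation pair per symbolic SV type
DEFAULT_STRANDS = {"DEL": "+-", "INS": "+-", "DUP": "-+", "INV": "++"}


class VcfFormatError(ValueError):
    """A VCF record violates the conventions the pipeline relies on."""


class ValidationError(ValueError):
    """Parsed input is structurally inconsistent (e.g. unpaired breakends)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SVRecord:
    """One caller's structural-variant call.

    ``start``/``end`` are 1-based inclusive; for insertions ``end == start``
    and ``svlen`` is the inserted length; for breakends (BND) the record
    describes one side of a reciprocal pair, ``mate_chrom``/``mate_pos``
    hold the partner locus once mates are linked, and the pair shares one
    ``event_id`` so a translocation is counted as a single event.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    svlen: int
    strands: str
    caller: str
    qual: float = 0.0
    su: int = 0
    sr: int = 0
    pe: int = 0
    mate_id: str = ""
    mate_chrom: str = ""
    mate_pos: int = 0
    event_id: str = ""

    def __post_init__(self):
        if self.svtype not in SV_TYPES:
            raise ValidationError(f"unknown SVTYPE {self.svtype!r} for record {self.id}")
        if self.svtype != "BND":
            if self.end < self.start:
                raise ValidationError(f"end < start for record {self.id}")
            if self.svtype == "INS" and self.end != self.start:
                raise ValidationError(f"INS record {self.id} must have end == start")


@dataclass
class SmallVariantRecord:
    """A SNP or short indel with its GATK-style filter annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str  # SNP | INDEL
    qual: float
    info: dict = field(default_factory=dict)


@dataclass
class GeneModel:
    """Gene span with representative-transcript CDS, derived introns, and
    the 2-kb strand-aware upstream promoter interval.

    ``promoter`` is ``None`` when the gene starts at a contig edge and no
    upstream sequence exists; otherwise it is truncated to the contig.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds: list
    introns: list
    promoter: tuple | None


@dataclass
class AccessionPanel:
    """Accession → group assignment plus optional phenotype table."""

    groups: dict
    phenotypes: pd.DataFrame | None = None

    def __post_init__(self):
        bad = {g for g in self.groups.values() if g not in VALID_GROUPS}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")

    @property
    def accessions(self):
        return list(self.groups)


@dataclass
class GenotypeMatrix:
    """Accessions x variants alt-allele dosage matrix.

    ``geno`` is int8 with codes 0/1/2 and -1 for missing.  ``variants`` is a
    DataFrame with at least columns id, chrom, pos, end, svtype.
    """

    accessions: list
    variants: pd.DataFrame
    geno: np.ndarray
    groups: dict

    def __post_init__(self):
        if self.geno.shape != (len(self.accessions), len(self.variants)):
            raise ValidationError(
                f"genotype matrix shape {self.geno.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.variants)} variants"
            )

    def group_rows(self, group: str) -> np.ndarray:
        """Row indices of accessions belonging to ``group``."""
        return np.array(
            [i for i, a in enumerate(self.accessions) if self.groups.get(a) == group],
            dtype=int,
        )

    def subset_variants(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            accessions=self.accessions,
            variants=self.variants.loc[mask].reset_index(drop=True),
            geno=self.geno[:, mask],
            groups=self.groups,
        )


# ---------------------------------------------------------------------------
# VCF headers
# ---------------------------------------------------------------------------

def _sv_header(contigs: dict) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for name, length in contigs.items():
        h.contigs.add(name, length=int(length))
    h.info.add("SVTYPE", 1, "String", "Type of structural variant")
    h.info.add("SVLEN", 1, "Integer", "Length of the variant (negative for deletions)")
    h.info.add("STRANDS", 1, "String", "Breakpoint strand orientation pair")
    h.info.add("SU", 1, "Integer", "Total supporting reads")
    h.info.add("SR", 1, "Integer", "Split-read support")
    h.info.add("PE", 1, "Integer", "Paired-end support")
    h.info.add("MATEID", 1, "String", "ID of mate breakend")
    h.info.add("EVENT", 1, "String", "Event identifier shared by breakend mates")
    return h


_BND_RE = re.compile(r"[\[\]]([^\[\]:]+):(\d+)[\[\]]")


def _bnd_alt(strands: str, mate_chrom: str, mate_pos: int) -> str:
    """Encode a breakend ALT from a strand pair (LUMPY convention)."""
    p = f"{mate_chrom}:{mate_pos}"
    return {
        "+-": f"N[{p}[",
        "++": f"N]{p}]",
        "-+": f"]{p}]N",
        "--": f"[{p}[N",
    }[strands]


def _bnd_strands(alt: str) -> str:
    if alt.endswith("[") and not alt.startswith(("[", "]")):
        return "+-"
    if alt.endswith("]") and not alt.startswith(("[", "]")):
        return "++"
    if alt.startswith("]"):
        return "-+"
    if alt.startswith("["):
        return "--"
    raise VcfFormatError(f"unrecognised breakend ALT {alt!r}")


# ---------------------------------------------------------------------------
# SV VCF
# ---------------------------------------------------------------------------

def read_sv_vcf(path, caller: str) -> list:
    """Read a single-caller SV VCF into :class:`SVRecord` objects.

    BND mates are linked via MATEID (both directions checked); each mate
    pair shares an event id.  Raises :class:`VcfFormatError` naming the
    offending record when SVTYPE is absent, and :class:`ValidationError`
    when a breakend lacks its partner.
    """
    records: list[SVRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for lineno, rec in enumerate(vf, start=1):
            info = dict(rec.info)
            svtype = info.get("SVTYPE")
            if svtype is None:
                raise VcfFormatError(
                    f"record {lineno} ({rec.chrom}:{rec.pos}): missing SVTYPE"
                )
            # QUAL travels through htslib as float32; 2 decimals is the
            # precision the pipeline guarantees round-trip stable
            qual = round(float(rec.qual), 2) if rec.qual is not None else 0.0
            su = int(info.get("SU", 0))
            sr = int(info.get("SR", 0))
            pe = int(info.get("PE", 0))
            if svtype == "BND":
                alt = rec.alts[0]
                m = _BND_RE.search(alt)
                if m is None:
                    raise VcfFormatError(
                        f"record {lineno} ({rec.chrom}:{rec.pos}): bad breakend ALT {alt!r}"
                    )
                records.append(SVRecord(
                    id=rec.id, chrom=rec.chrom, start=rec.pos, end=rec.pos,
                    svtype="BND", svlen=0, strands=_bnd_strands(alt),
                    caller=caller, qual=qual, su=su, sr=sr, pe=pe,
                    mate_id=str(info.get("MATEID", "")),
                    mate_chrom=m.group(1), mate_pos=int(m.group(2)),
                    event_id=str(info.get("EVENT", "")),
                ))
            else:
                svlen = info.get("SVLEN")
                if svtype == "INS":
                    end = rec.pos
                    svlen = abs(int(svlen)) if svlen is not None else 0
                else:
                    end = rec.stop
                    svlen = end - rec.pos
                strands = str(info.get("STRANDS", DEFAULT_STRANDS[svtype]))
                records.append(SVRecord(
                    id=rec.id, chrom=rec.chrom, start=rec.pos, end=end,
                    svtype=svtype, svlen=svlen, strands=strands,
                    caller=caller, qual=qual, su=su, sr=sr, pe=pe,
                ))
    _link_bnd_mates(records)
    return records


def _link_bnd_mates(records):
    """Check MATEID symmetry and assign shared event ids to BND pairs."""
    bnds = {r.id: r for r in records if r.svtype == "BND"}
    for r in bnds.values():
        mate = bnds.get(r.mate_id)
        if mate is None or mate.mate_id != r.id:
            raise ValidationError(f"unpaired breakend {r.id} (MATEID {r.mate_id!r})")
        if not r.event_id:
            eid = min(r.id, mate.id)
            r.event_id = eid
            mate.event_id = eid


def write_sv_vcf(records, path, contigs: dict) -> None:
    """Write :class:`SVRecord` objects as a VCF 4.2 file."""
    header = _sv_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            if r.svtype == "BND":
                rec = out.new_record(
                    contig=r.chrom, start=r.start - 1, stop=r.start,
                    alleles=("N", _bnd_alt(r.strands, r.mate_chrom, r.mate_pos)),
                    id=r.id, qual=round(r.qual, 2),
                )
                rec.info["MATEID"] = r.mate_id
                if r.event_id:
                    rec.info["EVENT"] = r.event_id
            else:
                rec = out.new_record(
                    contig=r.chrom, start=r.start - 1, stop=r.end,
                    alleles=("N", f"<{r.svtype}>"), id=r.id, qual=r.qual,
                )
                rec.info["SVLEN"] = -r.svlen if r.svtype == "DEL" else r.svlen
            rec.info["SVTYPE"] = r.svtype
            rec.info["STRANDS"] = r.strands
            rec.info["SU"] = r.su
            rec.info["SR"] = r.sr
            rec.info["PE"] = r.pe
            out.write(rec)


def vcf_contigs(path) -> dict:
    """Contig name → length from a VCF header."""
    with pysam.VariantFile(str(path)) as vf:
        return {name: c.length for name, c in vf.header.contigs.items()}


# ---------------------------------------------------------------------------
# Small-variant VCF
# ---------------------------------------------------------------------------

_SMALL_INFO_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")


def read_small_variant_vcf(path) -> list:
    """Read SNPs and short indels with their filter annotations."""
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            ref, alt = rec.ref, rec.alts[0]
            vclass = "SNP" if len(ref) == len(alt) else "INDEL"
            info = {k: float(rec.info[k]) for k in _SMALL_INFO_KEYS if k in rec.info}
            out.append(SmallVariantRecord(
                chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt, vclass=vclass,
                qual=float(rec.qual) if rec.qual is not None else 0.0, info=info,
            ))
    return out


def write_small_variant_vcf(records, path, contigs: dict) -> None:
    h = pysam.VariantHeader()
    for name, length in contigs.items():
        h.contigs.add(name, length=int(length))
    for key in _SMALL_INFO_KEYS:
        h.info.add(key, 1, "Float", key)
    with pysam.VariantFile(str(path), "w", header=h) as out:
        for r in records:
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1,
                alleles=(r.ref, r.alt), qual=r.qual,
            )
            for k, v in r.info.items():
                rec.info[k] = v
            out.write(rec)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path, promoter_len: int = 2000) -> list:
    """Parse gene models from GFF3.

    One representative transcript per gene: the mRNA with the longest total
    CDS (ties broken by feature id).  Introns are the gaps between
    consecutive CDS intervals of the representative transcript.  The
    promoter is the ``promoter_len`` bp immediately upstream of the
    strand-aware gene start, truncated at contig edges (contig lengths are
    taken from ``##sequence-region`` directives when present).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    contig_len = {}
    for d in db.directives:
        m = re.match(r"sequence-region\s+(\S+)\s+(\d+)\s+(\d+)", d)
        if m:
            contig_len[m.group(1)] = int(m.group(3))

    genes = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if mrnas:
            def cds_total(m):
                return sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))
            rep = max(mrnas, key=lambda m: (cds_total(m), m.id))
            cds_feats = list(db.children(rep, featuretype="CDS"))
        else:
            cds_feats = list(db.children(gene, featuretype="CDS"))
        cds = sorted((c.start, c.end) for c in cds_feats)
        for s, e in cds:
            if s < gene.start or e > gene.end:
                raise ValidationError(
                    f"CDS {s}-{e} outside span of gene {gene.id} "
                    f"({gene.start}-{gene.end})"
                )
        introns = [
            (cds[i][1] + 1, cds[i + 1][0] - 1)
            for i in range(len(cds) - 1)
            if cds[i + 1][0] > cds[i][1] + 1
        ]
        promoter = _promoter(
            gene.strand, gene.start, gene.end, promoter_len,
            contig_len.get(gene.seqid),
        )
        genes.append(GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            start=gene.start, end=gene.end, cds=cds, introns=introns,
            promoter=promoter,
        ))
    return genes


def _promoter(strand, start, end, length, contig_len):
    if strand == "+":
        lo, hi = start - length, start - 1
        lo = max(lo, 1)
    else:
        lo, hi = end + 1, end + length
        if contig_len is not None:
            hi = min(hi, contig_len)
    if hi < lo:
        return None
    return (lo, hi)


def write_gff3(genes, path, contigs: dict) -> None:
    """Write gene models (gene/mRNA/CDS) with ##sequence-region directives."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in contigs.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsvorchard\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tsvorchard\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chrom}\tsvorchard\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# Genotype VCF
# ---------------------------------------------------------------------------

_GT_TO_DOSAGE = {
    (0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2,
    (None, None): -1, (None,): -1,
}


def read_genotype_vcf(path, panel: AccessionPanel) -> GenotypeMatrix:
    """Read a multi-sample VCF into a dosage matrix ordered as the file.

    Samples absent from the panel raise :class:`ValidationError` listing
    them.  All-missing columns are preserved.
    """
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        unknown = [s for s in samples if s not in panel.groups]
        if unknown:
            raise ValidationError(f"samples not in panel: {unknown}")
        rows = {s: i for i, s in enumerate(samples)}
        meta, cols = [], []
        for rec in vf:
            info = dict(rec.info)
            svtype = info.get("SVTYPE", "SNP")
            end = rec.stop if svtype not in ("SNP", "INS", "BND") else rec.pos
            meta.append({
                "id": rec.id or f"{rec.chrom}:{rec.pos}",
                "chrom": rec.chrom, "pos": rec.pos, "end": end, "svtype": svtype,
            })
            col = np.full(len(samples), -1, dtype=np.int8)
            for s, call in rec.samples.items():
                gt = call.get("GT")
                d = _GT_TO_DOSAGE.get(tuple(gt) if gt is not None else (None,), -1)
                col[rows[s]] = d
            cols.append(col)
    geno = (np.stack(cols, axis=1) if cols
            else np.zeros((len(samples), 0), dtype=np.int8))
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "end", "svtype"])
    return GenotypeMatrix(
        accessions=samples, variants=variants, geno=geno,
        groups={s: panel.groups[s] for s in samples},
    )


_DOSAGE_TO_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}


def write_genotype_vcf(matrix: GenotypeMatrix, path, contigs: dict) -> None:
    header = _sv_header(contigs)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in matrix.accessions:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, v in matrix.variants.iterrows():
            svtype = v["svtype"]
            if svtype == "SNP":
                rec = out.new_record(
                    contig=v["chrom"], start=v["pos"] - 1,
                    alleles=("A", "T"), id=v["id"],
                )
            else:
                stop = v["pos"] if svtype in ("INS", "BND") else int(v["end"])
                rec = out.new_record(
                    contig=v["chrom"], start=v["pos"] - 1, stop=stop,
                    alleles=("N", f"<{svtype}>"), id=v["id"],
                )
                rec.info["SVTYPE"] = svtype
            for i, s in enumerate(matrix.accessions):
                rec.samples[s]["GT"] = _DOSAGE_TO_GT[int(matrix.geno[i, j])]
            out.write(rec)


# ---------------------------------------------------------------------------
# TSV / BED
# ---------------------------------------------------------------------------

def read_panel_tsv(path) -> AccessionPanel:
    """Read the accession table: columns ``accession``, ``group``, then any
    number of phenotype columns."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    groups = dict(zip(df["accession"], df["group"]))
    pheno_cols = [c for c in df.columns if c not in ("accession", "group")]
    phenotypes = df.set_index("accession")[pheno_cols] if pheno_cols else None
    return AccessionPanel(groups=groups, phenotypes=phenotypes)


def write_panel_tsv(panel: AccessionPanel, path) -> None:
    df = pd.DataFrame({
        "accession": list(panel.groups),
        "group": list(panel.groups.values()),
    })
    if panel.phenotypes is not None:
        df = df.merge(
            panel.phenotypes, left_on="accession", right_index=True, how="left"
        )
    df.to_csv(path, sep="\t", index=False)


def write_bed(intervals, path) -> None:
    """Write (chrom, start, end, *extra) 1-based closed intervals as BED
    (0-based half-open) — the only coordinate conversion in the package."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end, *extra = iv
            fields = [chrom, str(start - 1), str(end)] + [str(x) for x in extra]
            fh.write("\t".join(fields) + "\n")
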