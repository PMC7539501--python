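"""GWAS support: MAF filtering, Bonferroni threshold, a single-marker
regression test, and pairwise LD r^2 for regional plots.

The association test is a simple linear regression of phenotype on
alt-allele dosage (F test on the slope, df = n - 2) with no population
structure correction; mixed models are deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .population_matrix import maf_all
from .sv_io import GenotypeMatrix


@dataclass
class AssociationResult:
    variant_id: str
    chrom: str
    pos: int
    p: float
    neg_log10_p: float
    passed: bool


def bonferroni_threshold(n_markers: int, alpha: float = 0.05) -> float:
    """Genome-wide significance cutoff -log10(alpha / n_markers),
    reported to 2 decimals."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return round(-math.log10(alpha / n_markers), 2)


def maf_filter(matrix: GenotypeMatrix, min_maf: float = 0.01):
    """Remove variants with MAF < min_maf (strict; a variant at exactly
    min_maf is kept).  Returns the filtered matrix plus a report of
    kept/removed counts by variant class."""
    if len(matrix.variants) == 0:
        return matrix, {"kept": {}, "removed": {}, "n_kept": 0, "n_removed": 0}
    m = maf_all(matrix)
    keep = ~(m < min_maf)  # NaN (all-missing) columns are kept, flagged upstream
    classes = matrix.variants["svtype"].fillna("SNP")
    report = {
        "kept": classes[keep].value_counts().to_dict(),
        "removed": classes[~keep].value_counts().to_dict(),
        "n_kept": int(keep.sum()),
        "n_removed": int((~keep).sum()),
    }
    return matrix.subset_variants(keep), report


def single_marker_test(dosages, phenotype) -> float:
    """P value of the simple linear regression of phenotype on dosage.

    Pairs with missing dosage or phenotype are dropped; needs >= 3
    complete pairs and non-zero dosage variance.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    ok = (d >= 0) & np.isfinite(d) & np.isfinite(y)
    d, y = d[ok], y[ok]
    if d.size < 3:
        raise ValueError("need >= 3 complete dosage/phenotype pairs")
    if np.ptp(d) == 0:
        raise ValueError("zero dosage variance; test undefined")
    return float(stats.linregress(d, y).pvalue)


def ld_r2(dosages_x, dosages_y) -> float:
    """Composite LD: squared Pearson correlation of two dosage vectors on
    their shared non-missing accessions."""
    x = np.asarray(dosages_x, dtype=float)
    y = np.asarray(dosages_y, dtype=float)
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on shared non-missing accessions")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def gwas(matrix: GenotypeMatrix, phenotype, min_maf: float = 0.01,
         alpha: float = 0.05):
    """MAF-filter the matrix, test every variant, and apply the Bonferroni
    cutoff computed from the number of markers actually tested.

    ``phenotype`` maps accession → trait value.  Monomorphic markers after
    missingness are skipped.  Returns ``(results, threshold)``.
    """
    filtered, _ = maf_filter(matrix, min_maf)
    y = np.array([phenotype.get(a, np.nan) for a in filtered.accessions])
    results = []
    for j, v in filtered.variants.iterrows():
        try:
            p = single_marker_test(filtered.geno[:, j], y)
        except ValueError:
            continue
        results.append((v["id"], v["chrom"], int(v["pos"]), p))
    if not results:
        return [], bonferroni_threshold(1, alpha)
    threshold = bonferroni_threshold(len(results), alpha)
    out = []
    for vid, chrom, pos, p in results:
        nlp = -math.log10(p) if p > 0 else math.inf
        out.append(AssociationResult(
            variant_id=vid, chrom=chrom, pos=pos, p=p,
            neg_log10_p=nlp, passed=nlp >= threshold,
        ))
    return out, threshold
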