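"""Occurrence-frequency selection scan over domestication and improvement.

For each SV the carrier counts of the two groups of a phase (domestication:
wild vs landrace; improvement: landrace vs improved) form a 2x2 table of
carriers/non-carriers x group tested with the two-sided Fisher exact test.
P values are Benjamini-Hochberg adjusted within the phase; an SV is
classified as positively (later-group frequency higher) or negatively
selected when q < 0.001 and the smoothed fold change exceeds 2.

Fold change uses Haldane-style +0.5 smoothing on carrier counts so it stays
finite when one group has no carriers; the test itself uses raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .population_matrix import group_carrier_counts
from .sv_io import GenotypeMatrix

PHASES = {
    "domestication": ("wild", "landrace"),
    "improvement": ("landrace", "improved"),
}


@dataclass
class SelectionResult:
    event_id: str
    phase: str
    fA: float
    fB: float
    carriersA: int
    nA: int
    carriersB: int
    nB: int
    p: float
    q: float
    fold_change: float
    selection: str  # positive | negative | none


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table: the sum of
    hypergeometric probabilities of all tables with the same margins whose
    probability does not exceed the observed table's."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("negative cell count")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_selection(carriersA, nA, carriersB, nB, q,
                       fdr: float = 0.001, fc: float = 2.0):
    """Smoothed fold change and selection class for one SV.

    Returns ``(fold_change, class)``; the direction compares the raw
    later-group frequency fB against the earlier fA.
    """
    fA = carriersA / nA
    fB = carriersB / nB
    sA = (carriersA + 0.5) / (nA + 1)
    sB = (carriersB + 0.5) / (nB + 1)
    fold = max(sA, sB) / min(sA, sB)
    if q < fdr and fold > fc:
        if fB > fA:
            return fold, "positive"
        if fB < fA:
            return fold, "negative"
    return fold, "none"


def scan(matrix: GenotypeMatrix, phase: str,
         fdr: float = 0.001, fc: float = 2.0) -> list:
    """Run the selection scan for one phase over every variant.

    FDR adjustment is computed across all tested variants of the phase;
    results come back in matrix variant order.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {list(PHASES)}")
    group_a, group_b = PHASES[phase]
    ca, na = group_carrier_counts(matrix, group_a)
    cb, nb = group_carrier_counts(matrix, group_b)
    if (na == 0).any() or (nb == 0).any():
        raise ValueError(f"phase {phase}: a group is empty after missingness")
    pvals = np.array([
        fisher_exact_2x2([[ca[j], na[j] - ca[j]], [cb[j], nb[j] - cb[j]]])
        for j in range(len(na))
    ])
    qvals = bh_fdr(pvals)
    results = []
    ids = matrix.variants["id"].tolist()
    for j in range(len(na)):
        fold, cls = classify_selection(ca[j], na[j], cb[j], nb[j], qvals[j], fdr, fc)
        results.append(SelectionResult(
            event_id=ids[j], phase=phase,
            fA=ca[j] / na[j], fB=cb[j] / nb[j],
            carriersA=int(ca[j]), nA=int(na[j]),
            carriersB=int(cb[j]), nB=int(nb[j]),
            p=float(pvals[j]), q=float(qvals[j]),
            fold_change=float(fold), selection=cls,
        ))
    return results


def selected_genes(results, impact_calls) -> set:
    """Gene ids hit by any selected SV (join of scan output with the
    SV-gene impact calls)."""
    selected_ids = {r.event_id for r in results if r.selection != "none"}
    return {c.gene_id for c in impact_calls if c.event_id in selected_ids}
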