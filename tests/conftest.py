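import numpy as np
import pandas as pd
import pytest

from svorchard import GenotypeMatrix, SimulationConfig, SVRecord, simulate


def make_matrix(geno, groups_per_row, chrom="contig1", positions=None,
                svtype="DEL"):
    """Build a GenotypeMatrix from a raw dosage array for unit tests."""
    geno = np.asarray(geno, dtype=np.int8)
    n_acc, n_var = geno.shape
    accessions = [f"a{i:03d}" for i in range(n_acc)]
    groups = {a: g for a, g in zip(accessions, groups_per_row)}
    if positions is None:
        positions = [1000 * (j + 1) for j in range(n_var)]
    variants = pd.DataFrame({
        "id": [f"v{j:04d}" for j in range(n_var)],
        "chrom": chrom,
        "pos": positions,
        "end": [p + 100 for p in positions],
        "svtype": svtype,
    })
    return GenotypeMatrix(accessions=accessions, variants=variants,
                         geno=geno, groups=groups)


def make_sv(id="sv1", chrom="contig1", start=10_000, end=12_000,
            svtype="DEL", caller="lumpy", qual=50.0, su=20, sr=5, pe=10,
            strands=None, svlen=None, **kw):
    if strands is None:
        strands = {"DEL": "+-", "INS": "+-", "DUP": "-+",
                   "INV": "++", "BND": "+-"}[svtype]
    if svlen is None:
        svlen = 0 if svtype == "BND" else (end - start if svtype != "INS" else 500)
    return SVRecord(id=id, chrom=chrom, start=start, end=end, svtype=svtype,
                    svlen=svlen, strands=strands, caller=caller, qual=qual,
                    su=su, sr=sr, pe=pe, **kw)


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated study shared by read-only tests."""
    cfg = SimulationConfig(seed=11, n_truth_svs=80, n_genes=20,
                           snp_spacing=2_000, n_selected_svs=5)
    return simulate(cfg)
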