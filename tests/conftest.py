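import numpy as np
import pytest

from metageno import genodata, simulate
from metageno.genodata import DISEASES, Variant, VariantPanel


@pytest.fixture
def small_panel():
    """Nine variants spread over chromosomes 1, 2, 3 and 7."""
    rows = [
        ("rs1", 1, 100, "T", "A", 0.10),
        ("rs2", 1, 250, "G", "C", -0.20),
        ("rs3", 2, 50, "A", "G", 0.05),
        ("rs4", 2, 900, "C", "T", 0.30),
        ("rs5", 3, 10, "T", "C", -0.15),
        ("rs6", 3, 500, "G", "A", 0.25),
        ("rs7", 3, 700, "A", "T", 0.12),
        ("rs8", 7, 123, "C", "G", -0.08),
        ("rs9", 7, 456, "T", "A", 0.40),
    ]
    return VariantPanel([
        Variant(r, c, p, ea, oa, w, frozenset({"IS"}))
        for r, c, p, ea, oa, w in rows
    ])


@pytest.fixture
def small_geno(small_panel):
    rng = np.random.default_rng(7)
    dosages = rng.integers(0, 3, size=(20, len(small_panel)))
    ids = [f"S{i}" for i in range(20)]
    return genodata.GenotypeMatrix(dosages, ids, small_panel)


def write_scoring_file(path, rows, extra_comment=True):
    """rows: (rsid, chrom, pos, ea, oa, weight)."""
    with open(path, "w") as fh:
        if extra_comment:
            fh.write("# comment line\n#another\n")
        fh.write("rsID\tchr_name\tchr_position\teffect_allele\t"
                 "other_allele\teffect_weight\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    return path


@pytest.fixture
def null_cohort():
    """Small no-signal cohort shared by several metric tests."""
    spec = simulate.make_null_spec(n_variants=44, seed=3)
    G = simulate.simulate_genotypes(400, spec)
    cohort = simulate.simulate_multitask_phenotypes(G, spec)
    cohort = simulate.simulate_ages_and_events(cohort, seed=3)
    return G, cohort
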