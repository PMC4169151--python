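import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import isoqtl as q
from isoqtl.evaluate import _index_of, run_demo

settings.register_profile("ci", deadline=None, derandomize=True, database=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """Two families (one isogenic, one from unrelated parents), one QTL
    with an allelic difference (a=5 vs a=15), GBS missingness, both encoded
    datasets.  The causal locus sits exactly on a marker."""
    genome = q.default_genome(3, 6_000_000, 1.0, 60)
    families = (
        q.FamilySpec("A", 80, "isogenic", segments=(("1", 1_000_000, 2_000_000),)),
        q.FamilySpec("B", 80, "unrelated", density=0.7),
    )
    qtl = (q.QtlSpec("L1", "1", 1_500_000, "Y", {"A": 5.0, "B": 15.0}),)
    truth = q.simulate_study(genome, families, qtl, 3)
    raw = q.apply_gbs_missingness(truth.marker_genotypes(), 0.03, 5)
    pheno = q.simulate_phenotypes(truth, {"Y": {"A": 50.0, "B": 60.0}}, {"Y": 3.0}, 7)
    trimmed, trim_log = q.trim_snps(raw)
    keep = _index_of(raw.snp_map, trimmed.snp_map)
    parents = {f.name: tuple(v[keep] for v in truth.parent_genotypes(f.name))
               for f in families}
    return {
        "genome": genome, "truth": truth, "raw": raw, "pheno": pheno,
        "trimmed": trimmed, "trim_log": trim_log, "parents": parents,
        "gwas": q.build_gwas_dataset(trimmed),
        "linkage": q.build_linkage_dataset(trimmed, parents),
    }


@pytest.fixture(scope="session")
def demo_abcde():
    """The packaged demonstration scenario mapped with all five families."""
    return run_demo(subsets=("ABCDE",))


@pytest.fixture()
def two_family_example():
    """A two-family, five-equidistant-SNP worked example.

    Raw GWAS-coded progeny, homozygous parents, SNP spacing of one unit
    (1 kb); SNPs 2 and 4 are monomorphic in family A, SNPs 2 and 3 in
    family B.
    """
    smap = q.SnpMap.from_positions({"1": np.array([1000, 2000, 3000, 4000, 5000])})
    gwas_codes = np.array([
        [2, 0, 2, 0, 1],   # A1
        [1, 0, 1, 0, 1],   # A2
        [0, 0, 1, 0, 1],   # A3
        [1, 0, 2, 2, 2],   # B1
        [1, 0, 2, 1, 2],   # B2
        [0, 0, 2, 0, 0],   # B3
    ], dtype=float)
    linkage_expected = np.array([
        [2, 2.0, 2, 1.5, 1],
        [1, 1.0, 1, 1.0, 1],
        [0, 0.5, 1, 1.0, 1],
        [1, 4 / 3, 5 / 3, 2, 2],   # often quoted rounded as 1.34; the weighting formula gives 4/3
        [1, 1.0, 1, 1, 2],
        [0, 0.0, 0, 0, 0],
    ])
    gm = q.GenotypeMatrix(
        gwas_codes,
        np.array([f"{f}{i}" for f in "AB" for i in (1, 2, 3)], dtype=object),
        np.array(list("AAABBB"), dtype=object), smap, "raw",
    )
    parents = {
        "A": (np.array([0, 0, 0, 0, 0.0]), np.array([2, 0, 2, 0, 2.0])),
        "B": (np.array([0, 0, 2, 0, 0.0]), np.array([2, 0, 2, 2, 2.0])),
    }
    return {"matrix": gm, "parents": parents, "linkage_expected": linkage_expected,
            "snp_map": smap}


def make_phenotypes(line_id, family, values, trait="Y"):
    return pd.DataFrame({"line_id": line_id, "family": family, trait: values})
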