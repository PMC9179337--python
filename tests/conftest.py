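import numpy as np
import pandas as pd
import pytest

import xeprof as xp


@pytest.fixture(scope="session")
def standard_cohort():
    """The default multi-study cohort: 3 studies x (10 naive + 10 primed + 2 male)."""
    return xp.simulate_cohort(xp.multi_study_config(seed=11))


@pytest.fixture(scope="session")
def standard_tpm(standard_cohort):
    return xp.compute_tpm(standard_cohort.counts, standard_cohort.annotation)


@pytest.fixture(scope="session")
def cohort_dir(standard_cohort, tmp_path_factory):
    """The same cohort written to disk in the standard TSV/VCF dialects."""
    outdir = tmp_path_factory.mktemp("cohort")
    return xp.write_cohort(standard_cohort, outdir)


@pytest.fixture(scope="session")
def small_cohort():
    """One XIST+ study, 3 naive + 3 primed + 1 male, for cheap stage tests."""
    cfg = xp.multi_study_config(seed=7, n_studies=1, n_naive=3, n_primed=3,
                                 n_male=1, n_xist_neg_studies=0)
    return xp.simulate_cohort(cfg)


@pytest.fixture
def toy_annotation():
    """Ten chrX genes plus 2x5 autosomal genes with fixed coordinates."""
    genes = [xp.GeneModel(f"x{i}", "chrX", i * 1000, i * 1000 + 500, 300)
             for i in range(10)]
    genes += [xp.GeneModel(f"a{i}", "chr1", i * 1000, i * 1000 + 500, 300)
              for i in range(5)]
    genes += [xp.GeneModel(f"b{i}", "chr2", i * 1000, i * 1000 + 500, 300)
              for i in range(5)]
    return xp.GeneAnnotation(genes)


def make_snps(rows):
    """rows: (chrom, pos, sample, gene, ref, alt)."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "sample_id", "gene_id",
                                       "ref_depth", "alt_depth"])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
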