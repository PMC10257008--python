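import numpy as np
import pandas as pd
import pytest

import transcore as tc


@pytest.fixture(scope="session")
def tiny_config() -> tc.SimulationConfig:
    """A scaled-down study: fast enough for unit tests, same structure."""
    return tc.SimulationConfig(
        seed=7, n_reference=800, n_gwas=4_000, n_cases=400, n_controls=400,
        n_blocks=40, n_genes=6, n_core_genes=2, n_hla_driven_genes=1,
        trans_eqtls_per_gene=8)


@pytest.fixture(scope="session")
def tiny_result(tiny_config) -> tc.PipelineResult:
    return tc.run_pipeline(tiny_config)


@pytest.fixture(scope="session")
def pipe_config() -> tc.PipelineConfig:
    return tc.PipelineConfig()


def make_sumstats(positions, pvalues, chrom="1", target="GENE", betas=None):
    """Minimal single-target summary-statistics frame for clumping tests."""
    n = len(positions)
    betas = betas if betas is not None else np.full(n, 0.1)
    return pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n)],
        "chrom": chrom, "pos": list(positions),
        "effect_allele": "A", "other_allele": "G",
        "beta": betas, "se": 0.02, "pvalue": list(pvalues),
        "target_id": target, "n": 10_000,
    })
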