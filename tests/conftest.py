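import numpy as np
import pytest

import cescore as ces
from cescore.model import PermutationPlan


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at the reference study conditions."""
    return ces.generate(ces.SimulationConfig())


@pytest.fixture(scope="session")
def normalized_default(default_dataset):
    d = default_dataset
    return (
        ces.zscore_normalize(d.crispr),
        ces.zscore_normalize(d.shrna),
        ces.zscore_normalize(d.features),
        d.truth,
    )


@pytest.fixture(scope="session")
def default_fit(normalized_default):
    crispr, shrna, features, _ = normalized_default
    return ces.fit_ces(crispr, shrna, features)


@pytest.fixture(scope="session")
def default_fits(normalized_default, default_fit):
    """Full, null and permuted fits on the shared dataset."""
    crispr, shrna, features, _ = normalized_default
    null = ces.fit_ces_null(crispr, shrna)
    plan = PermutationPlan.generate(crispr.n_genes, crispr.n_cell_lines, seed=99)
    perm = ces.fit_ces_perm(crispr, shrna, features, plan)
    return {"CES": default_fit, "CES_null": null, "CES_perm": perm}


def random_instance(rng, n_genes, n_lines, missing_frac=0.0):
    """A random aligned (crispr, shrna, features) triple, z-score scale."""
    from cescore.containers import FEATURE_NAMES, FeaturePanel, ScreenMatrix

    genes = [f"G{i}" for i in range(n_genes)]
    lines = [f"L{j}" for j in range(n_lines)]

    def mat():
        v = rng.normal(size=(n_genes, n_lines))
        if missing_frac:
            v[rng.random(v.shape) < missing_frac] = np.nan
        return v

    crispr = ScreenMatrix(genes, lines, mat())
    shrna = ScreenMatrix(list(genes), list(lines), mat(), "shRNA")
    features = FeaturePanel(
        gene_ids=list(genes), cell_line_ids=list(lines), normalized=True,
        **{name: mat() for name in FEATURE_NAMES},
    )
    return crispr, shrna, features
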