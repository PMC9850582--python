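import numpy as np
import pandas as pd
import pytest

import ferroscore as fs


@pytest.fixture(scope="session")
def default_cohort():
    """One draw of the reference study conditions (80 samples, 150-gene
    panel + 500 background, planted shifts of 1.0 log2 units)."""
    config = fs.CohortConfig(seed=20)
    matrix, phenotypes, truth = fs.generate_survival_cohort(config)
    return config, matrix, phenotypes, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Downsized cohort for stages where the full one is unnecessary."""
    config = fs.CohortConfig(n_case=20, n_control=20, n_background=100, seed=5)
    matrix, phenotypes, truth = fs.generate_cohort(config)
    return config, matrix, phenotypes, truth


@pytest.fixture(scope="session")
def fitted_model(default_cohort):
    """Signatures + scoring model fitted on the reference cohort, with the
    contrast taken between the true case/control groups."""
    config, matrix, phenotypes, truth = default_cohort
    diagnosis = phenotypes.diagnosis_of()
    result = fs.moderated_t_test(matrix.subset_genes(
        [g for g in matrix.gene_ids if not g.startswith("BGD")]),
        diagnosis, case_group="TCMR")
    signatures = fs.derive_signatures(result)
    model = fs.fit_score_model(matrix, signatures, labels=diagnosis)
    return signatures, model


def make_expression(genes, samples, values):
    return fs.ExpressionMatrix(list(genes), list(samples),
                               np.asarray(values, dtype=float))
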