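"""Shared fixtures: expensive simulated datasets are session-scoped."""

import warnings

import numpy as np
import pytest

from hyposig.io import log2_transform, normalize_chain
from hyposig.l1l2 import L1L2Config, LabeledDataset
from hyposig.pipeline import DerivationConfig, EvaluationConfig, run_derivation, run_evaluation
from hyposig.signature import Signature
from hyposig.simulate import CellLineSimConfig, CohortSimConfig, simulate_cell_line_pairs, simulate_tumor_cohort


@pytest.fixture(scope="session")
def planted_cellline():
    """Planted cell-line dataset at the reference study conditions."""
    cfg = CellLineSimConfig(
        n_lines=11, n_probesets=2000, n_responsive=50, effect_log2=1.5, noise_sd=0.5, seed=1
    )
    E, design, truth = simulate_cell_line_pairs(cfg)
    return E, design, truth


@pytest.fixture(scope="session")
def derivation_bundle(planted_cellline):
    """Full derivation (normalize -> l1l2 nested LOO -> DE -> intersection)."""
    E, design, _ = planted_cellline
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_derivation(E, design, DerivationConfig())


@pytest.fixture(scope="session")
def labeled_dataset(planted_cellline):
    E, design, _ = planted_cellline
    return LabeledDataset.from_expression(log2_transform(normalize_chain(E)), design)


@pytest.fixture(scope="session")
def sig62():
    return Signature("sig62", [f"PS{i:05d}" for i in range(62)])


@pytest.fixture(scope="session")
def planted_cohort(sig62):
    """Planted 88-patient cohort with a strong hypoxia signature effect."""
    cfg = CohortSimConfig(signature=sig62, seed=5)
    E, clin, H = simulate_tumor_cohort(cfg)
    return E, clin, H


@pytest.fixture(scope="session")
def evaluation_bundle(planted_cohort, sig62):
    E, clin, _ = planted_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_evaluation(E, clin, sig62, EvaluationConfig(n_perm=60, restarts=25, seed=1))
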