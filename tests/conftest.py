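import numpy as np
import pytest

from plkd.data_io import normalize_log1p
from plkd.navigator import build_knowledge_mask
from plkd.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 400-cell, 200-gene planted-module dataset."""
    return simulate(SimulationConfig(n_genes=200, n_cells=400, n_pathways=8,
                                     genes_per_pathway=20, seed=7))


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    return normalize_log1p(small_dataset.expression)


@pytest.fixture(scope="session")
def small_mask(small_dataset, small_normalized):
    return build_knowledge_mask(small_normalized.gene_names,
                                small_dataset.planted_sets)


@pytest.fixture(scope="session")
def small_trained(small_dataset, small_normalized, small_mask):
    """Teacher + Student trained on the small dataset (shared across tests)."""
    from plkd.trainer import TrainConfig, train_student, train_teacher

    cfg = TrainConfig(seed=7, batch_size=128)
    teacher, tlog = train_teacher(small_normalized, cfg, mask=small_mask)
    student, slog = train_student(small_normalized, teacher, cfg)
    return {"teacher": teacher, "student": student, "teacher_log": tlog,
            "student_log": slog, "config": cfg}


def rng(seed=0):
    return np.random.default_rng(seed)
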