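import numpy as np
import pytest

import scalemarks as sm
from scalemarks.design import build_design, extract_counts
from scalemarks.model import ModelConfig, fit_model


@pytest.fixture(scope="session")
def small_bundle():
    """A modest synthetic dataset used across unit tests."""
    truth = sm.species_preset("curema", n_individuals=25)
    return sm.simulate_dataset(truth, seed=101)


@pytest.fixture(scope="session")
def small_fit(small_bundle):
    """One cheap hierarchical Poisson fit shared by the posterior-facing tests."""
    readable = sm.filter_readable(small_bundle.dataset)
    design = build_design(readable, centre="auto")
    counts = extract_counts(readable)
    config = ModelConfig(
        chains=2, tune=500, draws=500, seed=31, max_retries=0, ess_threshold=100.0
    )
    draws = fit_model(design, counts, config)
    return design, counts, draws


def make_dataset(rows):
    """Build a ScaleDataset from terse row tuples:
    (specimen, sex, sl, area, lsc, status, marks[, locality])."""
    records = []
    for row in rows:
        loc = row[7] if len(row) > 7 else "LM"
        records.append(
            sm.ScaleRecord(
                specimen_id=row[0],
                species="curema",
                locality=loc,
                sex=row[1],
                standard_length=row[2],
                area=row[3],
                scale_length=row[4],
                status=row[5],
                marks=row[6],
            )
        )
    return sm.ScaleDataset(records)
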