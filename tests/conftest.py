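"""Shared fixtures: a measured synthetic cohort reused by the slower tests.

The cohort is generated once per session at desk scale (96 genomes of
20–200 kb) with the package defaults for all coupling parameters, and its
compression ratios are measured with the built-in context coders.
"""

import numpy as np
import pytest

from grc.pipeline import composition_table, compression_table
from grc.synthetic import CohortSpec, generate_cohort

COHORT_SPEC = CohortSpec(
    n_genera=12,
    genomes_per_genus=8,
    size_range=(2e4, 2e5),
    seed=11,
)


@pytest.fixture(scope="session")
def measured_cohort():
    """(records, truth, analysis table) for the session's reference cohort."""
    records, truth = generate_cohort(COHORT_SPEC)
    table = composition_table(records).merge(
        compression_table(records, ("ctx", "ctx-rc")), on="genome_id"
    )
    return records, truth, table


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
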