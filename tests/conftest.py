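import numpy as np
import pytest

from chrompen import (
    GenomicInterval,
    ContactRecord,
    ContactSet,
    NormalizedProfile,
    PenaltyParams,
    PowerLawComponent,
)


@pytest.fixture
def single_alpha_params():
    """Single power-law penalty, alpha=1, raw scale (no normalization)."""
    return PenaltyParams(
        species_label="toy",
        components=(PowerLawComponent(alpha=1.0, beta=1.0, pi=1.0),),
        fit_range_bp=(35_000.0, 500_000.0),
        normalization="none",
    )


@pytest.fixture
def three_component_params():
    comps = (
        PowerLawComponent(alpha=6.0, beta=1.5e27, pi=0.2, x_range=(4.5, 4.9), r_squared=0.99),
        PowerLawComponent(alpha=0.31, beta=0.8, pi=0.5, x_range=(4.9, 5.6), r_squared=0.95),
        PowerLawComponent(alpha=1.5, beta=120.0, pi=0.3, x_range=(5.6, 6.3), r_squared=0.97),
    )
    return PenaltyParams(
        species_label="rice-like",
        components=comps,
        fit_range_bp=(35_000.0, 2_000_000.0),
        normalization="max_one_on_fit_range",
        selection_table=({"n": 1, "bic": 10.0, "aic": 9.0, "converged": True},
                         {"n": 3, "bic": -5.0, "aic": -7.0, "converged": True}),
        transitions_bp=(61_000.0, 1_000_000.0),
        seed=42,
    )


def make_contacts(distances_bp, counts=None, chrom="chr1"):
    counts = counts if counts is not None else [1.0] * len(distances_bp)
    records = []
    for i, (d, c) in enumerate(zip(distances_bp, counts)):
        a1 = GenomicInterval(chrom, 1000 + i * 10_000, 3000 + i * 10_000)
        a2 = GenomicInterval(chrom, a1.start + int(d), a1.end + int(d))
        records.append(ContactRecord(a1, a2, count=c))
    return ContactSet(records, source_label="toy")


@pytest.fixture
def contacts_factory():
    return make_contacts


def profile_on(mids, values):
    values = np.asarray(values, dtype=float)
    return NormalizedProfile(np.asarray(mids, dtype=float), values / values.max())


@pytest.fixture
def profile_factory():
    return profile_on
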