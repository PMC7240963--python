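import pandas as pd
import pytest
from hypothesis import settings

from ilnet import (
    SyntheticConfig,
    TraitAnnotation,
    aggregate_replicates,
    generate_population,
    log_standardize,
)

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


SMALL_CONFIG = SyntheticConfig(
    n_lines=40,
    class_spec=(
        ("lipid", "TAG", "storage-lipid", 4),
        ("secondary", "flavonoids", "polar-secondary", 4),
    ),
    replicate_range=(2, 4),
    intra_class_rho=0.7,
    missing_rate=0.02,
    n_transcripts=4,
    seed=42,
)


@pytest.fixture(scope="session")
def small_population():
    """A compact two-class panel reused across modules."""
    return generate_population(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_matrix(small_population):
    table, _, _ = small_population
    return log_standardize(aggregate_replicates(table))


@pytest.fixture(scope="session")
def small_annotation(small_population):
    _, ann_df, _ = small_population
    return TraitAnnotation(ann_df)


def transcript_annotation(ann_df: pd.DataFrame, transcripts) -> TraitAnnotation:
    """Extend a trait annotation frame with transcript rows."""
    extra = pd.DataFrame(
        {"group": "transcript", "class": "gene", "subclass": "lipid-related"},
        index=pd.Index(list(transcripts), name="trait"),
    )
    return TraitAnnotation(pd.concat([ann_df, extra]))
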