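import pandas as pd
import pytest

import seafood_audit as sa


@pytest.fixture(scope="session")
def invertebrates():
    return sa.load_fixture("invertebrates")


@pytest.fixture(scope="session")
def finfish():
    return sa.load_fixture("finfish")


@pytest.fixture(scope="session")
def classified_invertebrates(invertebrates):
    return sa.classify_all(
        invertebrates.records,
        invertebrates.authority,
        invertebrates.status_registry,
    )


@pytest.fixture(scope="session")
def classified_finfish(finfish):
    return sa.classify_all(
        finfish.records, finfish.authority, finfish.status_registry
    )


@pytest.fixture(scope="session")
def classified_all(classified_invertebrates, classified_finfish):
    return pd.concat(
        [classified_invertebrates, classified_finfish], ignore_index=True
    )
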