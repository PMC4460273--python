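import pytest

from genassoc import datasets


@pytest.fixture(scope="session")
def leeds():
    """The 350-case / 3781-control exudative-AMD genotype count table."""
    return datasets.leeds_amd_counts()


@pytest.fixture(scope="session")
def zurdel():
    """Summary estimates of the 167/517 AMD study (SEs recovered from p-values)."""
    return datasets.zurdel_amd_summary()


@pytest.fixture(scope="session")
def ad_meta():
    """Summary estimates of the AD meta-analysis (SEs recovered from p-values)."""
    return datasets.ad_meta_summary()
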