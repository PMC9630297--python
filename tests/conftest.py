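import io

import pytest

from dsgd.otp import reset_wc_usage


@pytest.fixture(autouse=True)
def _fresh_wc_registry():
    """Each test starts with a clean one-time-key usage registry."""
    reset_wc_usage()
    yield
    reset_wc_usage()


@pytest.fixture
def small_vcf_text():
    """A 3,000-record synthetic VCF (the 1:1000-scale disclosure input)."""
    from dsgd.fixtures import gen_vcf

    return gen_vcf(3000, n_chroms=2, seed=11)


@pytest.fixture
def vcf_stream(small_vcf_text):
    return io.StringIO(small_vcf_text)
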