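import pytest

from exomir import LibraryProfile, ReferenceConfig, build_reference


@pytest.fixture(scope="session")
def small_bundle():
    """Eight-hairpin toy reference shared across read-level tests."""
    return build_reference(ReferenceConfig(n_hairpins=8, seed=11))


@pytest.fixture(scope="session")
def mirna_only_profile():
    """Pure-miRNA library: no trimming, no tails, no other ncRNA classes."""
    from exomir import TailModel

    return LibraryProfile(
        read_count=400,
        trim_probs=(1.0,),
        tail=TailModel(length_probs=(1.0,)),
        class_fractions={},
        unmappable_fraction=0.0,
        seed=5,
    )
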