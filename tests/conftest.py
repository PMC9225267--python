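import pytest

import f13meta as fm


@pytest.fixture(scope="session")
def is_set() -> fm.StudySet:
    return fm.load_is_studies()


@pytest.fixture(scope="session")
def mi_set() -> fm.StudySet:
    return fm.load_mi_studies()


@pytest.fixture(scope="session")
def mi_report(mi_set) -> fm.MetaReport:
    """Random-effects report on the MI fixture (the published analysis used
    random effects for every MI model)."""
    return fm.run_meta(mi_set, policy="force_random")


@pytest.fixture(scope="session")
def is_report(is_set) -> fm.MetaReport:
    return fm.run_meta(is_set, policy="auto")
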