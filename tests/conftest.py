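import pytest
from hypothesis import HealthCheck, settings

from ethnosurvey.records import CitationRecord, InterviewSet, UseCategory

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def _rec(iid, area, taxon, rank, cat, **kw):
    return CitationRecord(
        interview_id=iid,
        area=area,
        taxon=taxon,
        rank=rank,
        use_category=UseCategory(cat),
        **kw,
    )


@pytest.fixture
def make_record():
    return _rec


@pytest.fixture
def tiny_set():
    """Two areas, three interviews, four taxa with hand-checkable indices."""
    records = [
        # interview K1 (Komen): list of 3 taxa
        _rec("K1", "Komen", "Taraxacum officinale", 1, "E"),
        _rec("K1", "Komen", "Taraxacum officinale", 1, "M"),
        _rec("K1", "Komen", "Urtica dioica", 2, "E"),
        _rec("K1", "Komen", "Rosa canina", 3, "A"),
        # interview K2 (Komen): list of 2 taxa
        _rec("K2", "Komen", "Taraxacum officinale", 1, "E"),
        _rec("K2", "Komen", "Salvia officinalis", 2, "M"),
        # interview I1 (Izola): list of 2 taxa
        _rec("I1", "Izola", "Rosa canina", 1, "E"),
        _rec("I1", "Izola", "Taraxacum officinale", 2, "E"),
    ]
    return InterviewSet(records)


@pytest.fixture(scope="session")
def fixture_data():
    from ethnosurvey.simulate import benchmark_fixture

    return benchmark_fixture()


@pytest.fixture(scope="session")
def sim_data():
    from ethnosurvey.simulate import SimConfig, generate

    return generate(SimConfig(seed=11))
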