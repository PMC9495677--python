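import pytest

from synermix import InteractionAnalyzer, build_study_panel, load_fixtures


@pytest.fixture(scope="session")
def panel():
    return build_study_panel()


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def fitted_analyzer(fixtures):
    """Analyzer fitted on the published individual activities."""
    return InteractionAnalyzer().fit(fixtures.individual_summary())


@pytest.fixture(scope="session")
def study_results(fixtures, fitted_analyzer):
    """All published mixture measurements scored against additivity."""
    summary = fixtures.mixture_summary()
    results = fitted_analyzer.transform(summary)
    results["table"] = summary["table"].to_numpy()
    return results
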