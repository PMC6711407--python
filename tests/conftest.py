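"""Shared fixtures: the four study scenarios, run once per session."""

import pytest

from circwave.pipeline import SCENARIOS, analyze_result, scenario_config
from circwave.simulator import simulate_scenario


@pytest.fixture(scope="session")
def scenario_runs():
    """Simulate all four scenarios once; return {name: SimulationResult}."""
    return {name: simulate_scenario(scenario_config(name))
            for name in SCENARIOS}


@pytest.fixture(scope="session")
def scenario_reports(scenario_runs):
    """Derived index reports of the four scenarios."""
    return {name: analyze_result(res) for name, res in scenario_runs.items()}


@pytest.fixture(scope="session")
def ref_run(scenario_runs):
    return scenario_runs["ref"]


@pytest.fixture(scope="session")
def ref_report(scenario_reports):
    return scenario_reports["ref"]
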