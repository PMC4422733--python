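import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from gstmine.domains import load_profiles
from gstmine.pipeline import analyze_assembly, compare_assemblies
from gstmine.simulate import FamilySpec, default_scenario


@pytest.fixture(scope="session")
def profiles():
    return load_profiles()


@pytest.fixture(scope="session")
def scenario1():
    """The default two-population synthetic dataset at seed 1."""
    return default_scenario(1)


@pytest.fixture(scope="session")
def analyzed1(scenario1, profiles):
    """Both assemblies of the seed-1 scenario analyzed plus the comparison."""
    res_a = analyze_assembly(scenario1.assembly_a, scenario1.panel, profiles)
    res_b = analyze_assembly(scenario1.assembly_b, scenario1.panel, profiles)
    comparison = compare_assemblies(res_a, res_b, scenario1.assembly_a,
                                    scenario1.assembly_b)
    return res_a, res_b, comparison


@pytest.fixture(scope="session")
def small_scenario():
    """A fast two-subclass scenario for determinism/CLI-level tests."""
    specs = [FamilySpec("Delta", 2), FamilySpec("Sigma", 2)]
    return default_scenario(5, n_decoys=8, specs=specs, replicates=2,
                            depth=200_000)
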