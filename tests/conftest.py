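import pytest

import circfood as cf


@pytest.fixture(scope="session")
def default_instance():
    """The standard synthetic instance: 3 zones, 2 countries, 10 food crops
    (plus the fodder backbone), 4 animal systems."""
    return cf.generate_instance(seed=1)


@pytest.fixture(scope="session")
def known_optimum():
    return cf.generate_known_optimum_instance(7)


@pytest.fixture(scope="session")
def solved_presets(default_instance):
    """All four scenario presets solved on the default instance."""
    out = {}
    for name, preset in cf.PRESETS.items():
        scen = preset()
        sol = cf.solve(cf.build_problem(default_instance, scen))
        out[name] = (scen, sol)
    return out


@pytest.fixture()
def instance_file(tmp_path, default_instance):
    path = tmp_path / "instance.yaml"
    cf.write_instance(default_instance, path)
    return path
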