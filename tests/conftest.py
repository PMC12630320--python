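import numpy as np
import pytest
import sympy as sp

from factorlik import catalog, core


@pytest.fixture(scope="session")
def models():
    """All catalog models, built once."""
    return {name: catalog.make_model(name) for name in catalog.catalog_names()}


@pytest.fixture(scope="session")
def continuous_models(models):
    return {k: m for k, m in models.items() if not m.discrete}


def level_set_equivalent(s1, s2, outcomes) -> bool:
    """True when two statistics carry the same information (shared level sets)."""
    byname = {str(y): y for y in outcomes}
    s2 = sp.sympify(s2)
    s2 = s2.subs({sym: byname[str(sym)] for sym in s2.free_symbols
                  if str(sym) in byname})
    return core.functionally_dependent(sp.sympify(s1), s2, outcomes)
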