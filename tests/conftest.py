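import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from stdmat.binding_thermo import solve_binding
from stdmat.full_matrix_oracle import ExchangeKinetics, initial_slope_fd, solve_buildup
from stdmat.relaxation_core import RelaxationParams
from stdmat.spin_system import apply_cutoff, parse_complex, select_saturated
from stdmat.synthetic_fixtures import FixtureSpec, make_spin_fixture


@pytest.fixture
def params():
    """600 MHz spectrometer, protein-sized complex (slow tumbling)."""
    return RelaxationParams(larmor_frequency=600.0, tau_c_bound=34.5)


@pytest.fixture
def binding():
    """Weak-binding conditions: 20 uM protein, 1 mM ligand, Kd 2 mM."""
    return solve_binding(20.0, 1000.0, 2000.0)


@pytest.fixture
def spin_fixture(tmp_path):
    """Factory: template name/params -> pruned, saturation-tagged SpinSystem."""

    def build(template, fixture_params=None, cutoff=12.0, seed=0):
        res = make_spin_fixture(
            FixtureSpec(template, params=fixture_params or {}, seed=seed),
            tmp_path / template,
        )
        system = parse_complex(res["protein"], res["ligand"])
        system = select_saturated(system, res["truth"]["saturation_list"])
        return apply_cutoff(system, cutoff), res["truth"]

    return build


def oracle_relative(system, params, binding, koff=1e4):
    """Relative epitope from the full-matrix solver's FD initial slopes."""
    kin = ExchangeKinetics.from_koff_kd(koff, binding.kd)
    probe = solve_buildup(system, params, binding, kin, np.array([0.0]))
    t1 = 0.005 / probe.max_eigenvalue
    sol = solve_buildup(system, params, binding, kin, np.array([0.0, t1, 2 * t1]))
    slopes = initial_slope_fd(sol)
    peak = max(slopes.values())
    return {k: 100.0 * v / peak for k, v in slopes.items()}
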