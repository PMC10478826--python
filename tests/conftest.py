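import numpy as np
import pytest

from rmdose import BloodModel, CompartmentFit, Tissue, TimeActivityCurve

# the study's nominal 4-point imaging schedule (hours post-injection)
SCAN_TIMES = np.array([4.0, 19.0, 53.0, 170.0])


@pytest.fixture
def scan_times():
    return SCAN_TIMES.copy()


@pytest.fixture
def blood_model():
    """A blood input function with a fast distribution phase and slow tail."""
    return BloodModel(A1=50.0, A2=5.0, lambda1=0.5, lambda2=0.008)


@pytest.fixture
def physio_blood():
    """Blood model in the package's standard units (MBq/cm^3 per GBq)."""
    return BloodModel(A1=0.24, A2=0.0025, lambda1=np.log(2) / 1.5,
                      lambda2=np.log(2) / 11.0)


@pytest.fixture
def compartment_params():
    return CompartmentFit(k1=0.05, k2=0.01, f=0.2)


def make_curve(times, concentrations, tissue=Tissue.VERTEBRAE, patient_id="p1"):
    return TimeActivityCurve(
        patient_id=patient_id,
        tissue=tissue,
        times=tuple(float(t) for t in times),
        concentrations=tuple(float(c) for c in concentrations),
    )


@pytest.fixture
def curve_factory():
    return make_curve


def ode_specific(blood, params, t_eval):
    """Stiff numerical integration of the uptake-release ODE (oracle)."""
    from scipy.integrate import solve_ivp

    from rmdose import eval_blood

    def rhs(t, y):
        return [params.k1 * params.f * eval_blood(blood, t) - params.k2 * y[0]]

    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), [0.0], method="Radau",
                    rtol=1e-11, atol=1e-18, t_eval=t_eval, dense_output=False)
    assert sol.success
    return sol.y[0]
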