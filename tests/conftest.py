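import numpy as np
import pytest

from hypermet import AcquisitionScheme, ExchangeParams, simulate_exchange


@pytest.fixture(scope="session")
def scheme():
    """Study-like acquisition: 15/40 degrees, TR 2 s, 4 s frames."""
    return AcquisitionScheme(n_frames=20)


@pytest.fixture(scope="session")
def baseline_params():
    """Exchange parameters at the cohort-baseline exchange rate."""
    return ExchangeParams(k_pl=0.0064)


@pytest.fixture(scope="session")
def noiseless_series(scheme, baseline_params):
    return simulate_exchange(baseline_params, scheme)


def euler_exchange(params, scheme, dt=1e-3, m0=(0.0, 0.0)):
    """Independent fine-step explicit-Euler oracle for the two-pool model.

    Vectorised over an array of parameter sets: ``params`` may hold
    k_pl/r1 values as arrays of shape (m,).  Pulse events are snapped to
    the Euler grid (dt must divide tr).
    """
    from hypermet.hp_simulator import gamma_variate
    import math

    k_pl = np.atleast_1d(np.asarray(params["k_pl"], dtype=float))
    r1p = np.atleast_1d(np.asarray(params["r1_pyr"], dtype=float))
    r1l = np.atleast_1d(np.asarray(params["r1_lac"], dtype=float))
    amp = float(params.get("aif_amplitude", 1.0))
    arrival = float(params.get("aif_arrival", 8.0))
    shape_p = float(params.get("aif_shape", 3.0))
    rate = float(params.get("aif_rate", 4.0))
    m = k_pl.size

    sin_p = math.sin(math.radians(scheme.flip_pyr))
    cos_p = math.cos(math.radians(scheme.flip_pyr))
    sin_l = math.sin(math.radians(scheme.flip_lac))
    cos_l = math.cos(math.radians(scheme.flip_lac))

    events = {}
    for i, t in enumerate(scheme.frame_times):
        events[round(t / dt)] = ("pyr", i)
        events[round((t + scheme.tr) / dt)] = ("lac", i)
    n_steps = max(events) + 1

    mp = np.full(m, float(m0[0]))
    ml = np.full(m, float(m0[1]))
    pyr_sig = np.zeros((m, scheme.n_frames))
    lac_sig = np.zeros((m, scheme.n_frames))
    for step in range(n_steps + 1):
        ev = events.get(step)
        if ev is not None:
            met, idx = ev
            if met == "pyr":
                pyr_sig[:, idx] = sin_p * mp
                mp = mp * cos_p
            else:
                lac_sig[:, idx] = sin_l * ml
                ml = ml * cos_l
        t = step * dt
        u = gamma_variate(t, amp, arrival, shape_p, rate)
        dmp = -(k_pl + r1p) * mp + u
        dml = k_pl * mp - r1l * ml
        mp = mp + dt * dmp
        ml = ml + dt * dml
    return pyr_sig, lac_sig
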