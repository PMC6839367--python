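"""Shared fixtures and independent numerical oracles.

The oracles here deliberately re-derive the model predictions by a
different route than the package (direct ODE/PDE integration, brute-force
fine-grid convolution, one-line formula scripts) so that agreement is a
genuine cross-check, not a tautology.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.signal import fftconvolve

from dualflow.aif import AIFModelParams, DualInputSpec, net_plasma_input
from dualflow.kinetics import KineticFitParams
from dualflow.phantom import default_pulmonary_aif, default_systemic_aif


@pytest.fixture(scope="session")
def pa_aif():
    return default_pulmonary_aif()


@pytest.fixture(scope="session")
def ao_aif():
    return default_systemic_aif()


@pytest.fixture(scope="session")
def dual_spec(pa_aif, ao_aif):
    return DualInputSpec(mode="dual", pulmonary=pa_aif, systemic=ao_aif, h_lv=0.45)


@pytest.fixture(scope="session")
def t_frames():
    """130 frames at 2 s, in minutes."""
    return np.arange(130) * 2.0 / 60.0


# ---------------------------------------------------------------------------
# oracles


def ode_residue_2cx(params: KineticFitParams, t):
    """2CX residue by direct stiff ODE integration of the mass balance."""
    f, ps, vp, vi = params.f_t, params.ps_t, params.v_p, params.v_i

    def rhs(_, y):
        cp, ci = y
        return [(-(f + ps) * cp + ps * ci) / vp, ps * (cp - ci) / max(vi, 1e-300)]

    t = np.asarray(t, dtype=float)
    sol = solve_ivp(rhs, [0.0, t[-1] if t[-1] > 0 else 1.0], [1.0 / vp, 0.0],
                    t_eval=t, method="LSODA", rtol=1e-11, atol=1e-13)
    return vp * sol.y[0] + vi * sol.y[1]


def pde_residue_dp(params: KineticFitParams, t_eval, n_segments=200):
    """DP residue by upwind finite-volume integration of the plug-flow PDE.

    The time step is matched to the cell size (CFL = 1) so advection is
    an exact one-cell shift and the sharp vascular front is preserved;
    the exchange terms use the exact 2x2 matrix exponential in a Strang
    splitting.
    """
    f, ps, vp, vi = params.f_t, params.ps_t, params.v_p, params.v_i
    ds = 1.0 / n_segments
    dt = ds / (f / vp)
    if ps > 0 and vi > 0:
        A = np.array([[-ps / vp, ps / vp], [ps / vi, -ps / vi]])
        mh = expm(A * dt / 2.0)
    else:
        mh = np.eye(2)
    cp = np.zeros(n_segments)
    ci = np.zeros(n_segments)
    cp[0] = 1.0 / (vp * ds)
    t_eval = np.asarray(t_eval, dtype=float)
    nst = int(np.ceil(t_eval[-1] / dt)) + 1
    ts = np.empty(nst + 1)
    rs = np.empty(nst + 1)
    ts[0], rs[0] = 0.0, 1.0
    for k in range(nst):
        cp, ci = mh[0, 0] * cp + mh[0, 1] * ci, mh[1, 0] * cp + mh[1, 1] * ci
        cp = np.concatenate(([0.0], cp[:-1]))
        cp, ci = mh[0, 0] * cp + mh[0, 1] * ci, mh[1, 0] * cp + mh[1, 1] * ci
        ts[k + 1] = (k + 1) * dt
        rs[k + 1] = vp * cp.sum() * ds + vi * ci.sum() * ds
    return np.interp(t_eval, ts, rs), dt


def brute_force_tissue_curve(residue_on, params: KineticFitParams,
                             spec: DualInputSpec, t_grid, dt=2e-5,
                             add_etk_delta=False):
    """Trapezoid convolution of an externally supplied residue function
    with the net plasma input on a very fine uniform grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    tf = np.arange(0.0, t_grid[-1] + 0.6, dt)
    cin = net_plasma_input(spec, params.gamma, tf)
    kern = params.f_t * np.asarray(residue_on(tf), dtype=float)
    y = fftconvolve(kern, cin)[: tf.size] * dt
    y -= 0.5 * dt * (kern[0] * cin + kern[: tf.size] * cin[0])
    if add_etk_delta:
        y = y + params.v_p * cin
    return np.interp(t_grid - params.t_lag, tf, y, left=0.0)


@pytest.fixture(scope="session")
def oracles():
    return {
        "ode_2cx": ode_residue_2cx,
        "pde_dp": pde_residue_dp,
        "brute_conv": brute_force_tissue_curve,
    }
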