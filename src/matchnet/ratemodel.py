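"""Simplified population-rate dynamics.

Instead of tracking single neurons, the network's transient behaviour is
described by the mean currents of its populations. Each population K carries
three current channels with the synaptic kinetics of the spiking model,

    tau_N dI_N/dt = -I_N + X_K * mu_rec_E(K),
    tau_A dI_A/dt = -I_A + (1 - X_K) * mu_rec_E(K),
    tau_G dI_G/dt = -I_G + mu_rec_I(K),

where mu_rec_E/mu_rec_I are the excitatory/inhibitory mean recurrent drives
implied by the instantaneous population rates, and the rate of population K
is the quenched-averaged transfer of its total mean current

    nu_K = PhiBar(I_N + I_A - I_G + mu_ext_K + stimulus_K).

Stimuli enter as population-mean current steps: alpha + beta to the
representation of the presented stimulus, beta to the other representations
(within-population quenched heterogeneity is not represented here; it lives
in the spiking model). The dynamics is integrated with the Euler method at
dt = 1 ms and converges to the fixed points of the stationary mean-field
equations.

All p selective representations are integrated individually (p + 2
populations in total); the four-population foreground/background description
of the delay period is the special case in which the p - 1 non-stimulated
representations share a common rate, which they do under the protocols used
here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import meanfield as mf
from .inputs import StimulusParameters, STANDARD_STIMULI
from .parameters import NetworkParameters

__all__ = [
    "RateState",
    "spontaneous_rate_state",
    "integrate_rate_trial",
    "epoch_response",
    "rate_trace_columns",
]

_tables: dict = {}


def _phi_tables(params: NetworkParameters):
    # PhiBar depends only on the noise, threshold and membrane constants —
    # not on efficacies or network size — so scans over J_plus reuse it
    key = (params.sigma, params.sigma_BG, params.theta, params.V_R,
           params.tau_arp, params.tau_E, params.tau_I)
    if key not in _tables:
        _tables[key] = (mf.PhiBarTable(params, params.tau_E),
                        mf.PhiBarTable(params, params.tau_I))
    return _tables[key]


def rate_trace_columns(params: NetworkParameters) -> list[str]:
    return [f"sel_{k + 1}" for k in range(params.p)] + ["ns", "inh"]


@dataclass
class RateState:
    """Population currents (mV) of the p+2 populations; rates are derived."""

    I_N: np.ndarray
    I_A: np.ndarray
    I_G: np.ndarray
    t: float = 0.0

    def copy(self) -> "RateState":
        return RateState(self.I_N.copy(), self.I_A.copy(), self.I_G.copy(), self.t)


def _x_fraction(params: NetworkParameters) -> np.ndarray:
    return np.array([params.X_E] * (params.p + 1) + [params.X_I])


def _mu_ext(params: NetworkParameters) -> np.ndarray:
    return np.array([params.mu_ext_E] * (params.p + 1) + [params.mu_ext_I])


def rates_from_state(state: RateState, params: NetworkParameters,
                     stim_drive: np.ndarray | float = 0.0) -> np.ndarray:
    phiE, phiI = _phi_tables(params)
    mu = state.I_N + state.I_A - state.I_G + _mu_ext(params) + stim_drive
    nu = np.empty(params.p + 2)
    nu[:-1] = phiE(mu[:-1])
    nu[-1] = phiI(mu[-1])
    return nu


def spontaneous_rate_state(params: NetworkParameters) -> RateState:
    """Rate state positioned at the spontaneous mean-field fixed point."""
    sol = mf.solve_spontaneous(params)
    nu = sol.rate_vector()
    mu_E, mu_I = mf.recurrent_currents_full(nu[:params.p], nu[params.p],
                                            nu[params.p + 1], params)
    X = _x_fraction(params)
    return RateState(I_N=X * mu_E, I_A=(1.0 - X) * mu_E, I_G=mu_I.copy(), t=0.0)


def state_from_rates(nu, params: NetworkParameters, t: float = 0.0) -> RateState:
    """Currents consistent with a given rate vector (used to seed fixed points)."""
    nu = np.asarray(nu, dtype=float)
    mu_E, mu_I = mf.recurrent_currents_full(nu[:params.p], nu[params.p],
                                            nu[params.p + 1], params)
    X = _x_fraction(params)
    return RateState(I_N=X * mu_E, I_A=(1.0 - X) * mu_E, I_G=mu_I.copy(), t=t)


def _stimulus_drive(params: NetworkParameters, stim: StimulusParameters,
                    active: int | None) -> np.ndarray:
    drive = np.zeros(params.p + 2)
    if active is not None:
        if not 0 <= active < params.p:
            raise ValueError(f"unknown stimulus id {active}")
        drive[:params.p] = stim.beta
        drive[active] = stim.alpha + stim.beta
    return drive


def integrate_rate_trial(params: NetworkParameters,
                         epochs: list[tuple[int | None, float]],
                         stim: StimulusParameters = STANDARD_STIMULI,
                         initial: RateState | None = None,
                         dt: float | None = None) -> pd.DataFrame:
    """Euler-integrate the rate dynamics through a schedule of epochs.

    ``epochs`` is a list of (active_stimulus or None, duration_s) pairs.
    Returns a DataFrame with the time stamp and the p+2 population rates at
    every step. The default initial condition is the spontaneous fixed point.
    """
    if not params.is_calibrated:
        raise RuntimeError("parameters must be calibrated before integration")
    q = params
    dt = q.dt_rate if dt is None else dt
    phiE, phiI = _phi_tables(q)
    state = spontaneous_rate_state(q) if initial is None else initial.copy()
    X = _x_fraction(q)
    mu_ext = _mu_ext(q)
    p = q.p

    rows_t: list[float] = []
    rows_nu: list[np.ndarray] = []
    I_N, I_A, I_G = state.I_N, state.I_A, state.I_G
    t_start = state.t
    step_total = 0
    for active, duration in epochs:
        if duration < 0:
            raise ValueError("epoch duration must be non-negative")
        drive = _stimulus_drive(q, stim, active)
        n_steps = int(round(duration / dt))
        for _ in range(n_steps):
            mu = I_N + I_A - I_G + mu_ext + drive
            nu = np.empty(p + 2)
            nu[:-1] = phiE(mu[:-1])
            nu[-1] = phiI(mu[-1])
            mu_E, mu_I = mf.recurrent_currents_full(nu[:p], nu[p], nu[p + 1], q)
            I_N += dt / q.tau_NMDA * (-I_N + X * mu_E)
            I_A += dt / q.tau_AMPA * (-I_A + (1.0 - X) * mu_E)
            I_G += dt / q.tau_GABA * (-I_G + mu_I)
            step_total += 1
            # timestamp by multiplication, so epoch boundaries are exact
            t = t_start + step_total * dt
            rows_t.append(t)
            rows_nu.append(nu)
            if not np.isfinite(mu).all():
                raise FloatingPointError(f"non-finite rate-model state at t = {t:.4f} s")
    state.t = t_start + step_total * dt
    traces = pd.DataFrame(np.array(rows_nu) if rows_nu else np.zeros((0, p + 2)),
                          columns=rate_trace_columns(q))
    traces.insert(0, "time", np.array(rows_t))
    return traces


def epoch_response(traces: pd.DataFrame, onset: float, window: float = 0.2,
                   epoch_end: float | None = None) -> pd.Series:
    """Mean rate of every population over [onset, onset + window).

    Trace rows are end-of-step samples: the row stamped t carries the rates
    of the step covering (t - dt, t], so the window mean uses rows with
    onset < t <= onset + window. ``epoch_end`` (if given) guards against a
    window spilling outside its epoch.
    """
    if epoch_end is not None and onset + window > epoch_end + 1e-9:
        raise ValueError(
            f"response window [{onset}, {onset + window}) exceeds epoch end {epoch_end}")
    t = traces["time"].values
    m = (t > onset + 1e-9) & (t <= onset + window + 1e-9)
    if not m.any():
        raise ValueError("response window contains no samples")
    return traces.loc[m].drop(columns="time").mean()
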