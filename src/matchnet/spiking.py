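"""Spiking simulation of the all-to-all LIF attractor network.

Membrane potentials follow tau_m dV/dt = -V + I with threshold theta, reset
V_R and absolute refractory period tau_arp. The recurrent current of every
neuron is carried by three exponentially-decaying channels: a slow NMDA-like
and a fast AMPA-like channel for excitatory input (charge split X vs 1 - X,
with X depending on the target class) and a GABA channel for inhibitory
input. A pre-synaptic spike of efficacy J (mV) deposits total charge
tau_m * J on its target, as instantaneous kicks

    dI_N = X * tau_m * J / tau_NMDA,
    dI_A = (1 - X) * tau_m * J / tau_AMPA     (excitatory source),
    dI_G = tau_m * J / tau_GABA               (inhibitory source),

each followed by exponential decay, so each channel integrates to its charge
share. Everything is integrated with the Euler method at dt = 0.1 ms; spikes
emitted in a step reach their targets at the end of that step (a one-step
transmission delay).

Because connectivity is all-to-all with block-structured efficacies, the
recurrent input to a neuron depends on pre-synaptic activity only through the
per-population spike counts of the current step, which keeps the per-step
cost O(N) instead of O(N^2); self-connections are excluded by subtracting a
neuron's own contribution when it fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inputs import QuenchedInputs
from .parameters import NetworkParameters

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:     # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(fn):
            return fn
        return deco

__all__ = [
    "SpikingState",
    "SpikeRaster",
    "build_connectivity",
    "dense_connectivity",
    "initial_state",
    "run_epoch",
    "SpikingNetwork",
]


@dataclass
class SpikingState:
    """Instantaneous simulator state (arrays of length N_E + N_I)."""

    V: np.ndarray               # membrane potentials, mV
    I_N: np.ndarray             # NMDA-channel current, mV
    I_A: np.ndarray             # AMPA-channel current, mV
    I_G: np.ndarray             # GABA-channel current, mV (enters with minus sign)
    refractory_until: np.ndarray  # absolute time (s) until which each neuron is held
    t: float = 0.0

    def copy(self) -> "SpikingState":
        return SpikingState(self.V.copy(), self.I_N.copy(), self.I_A.copy(),
                            self.I_G.copy(), self.refractory_until.copy(), self.t)


@dataclass
class SpikeRaster:
    """Recorded spikes with population labels."""

    times: np.ndarray           # (n_spikes,) seconds, non-decreasing
    neurons: np.ndarray         # (n_spikes,) neuron ids
    labels: np.ndarray          # (N,) per-neuron population label

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times,
            "neuron_id": self.neurons,
            "population_label": self.labels[self.neurons],
        })

    @staticmethod
    def concatenate(rasters: list["SpikeRaster"]) -> "SpikeRaster":
        if not rasters:
            raise ValueError("no rasters to concatenate")
        return SpikeRaster(
            times=np.concatenate([r.times for r in rasters]),
            neurons=np.concatenate([r.neurons for r in rasters]),
            labels=rasters[0].labels,
        )


def build_connectivity(params: NetworkParameters) -> np.ndarray:
    """Block efficacy map J[target_population, source_population] (mV).

    Populations 0..p-1 are the selective representations, p the non-selective
    excitatory pool, p+1 the inhibitory pool. Selective targets receive
    J_plus from their own representation and J_minus from every other
    excitatory source; non-selective targets receive the baseline J_EE from
    all excitatory sources; inhibitory efficacies are unstructured.
    """
    q = params
    p = q.p
    J = np.zeros((p + 2, p + 2))
    J[:p, :p + 1] = q.J_minus
    J[np.arange(p), np.arange(p)] = q.J_plus
    J[p, :p + 1] = q.J_EE
    J[:p + 1, p + 1] = q.J_EI
    J[p + 1, :p + 1] = q.J_IE
    J[p + 1, p + 1] = q.J_II
    return J


def dense_connectivity(params: NetworkParameters, labels: np.ndarray) -> np.ndarray:
    """Per-synapse efficacy matrix W[target, source] (mV) for tiny fixtures.

    All-to-all with no self-connections; used as the naive-summation oracle
    against the block-summed recurrent computation.
    """
    J = build_connectivity(params)
    W = J[np.ix_(labels, labels)].copy()
    np.fill_diagonal(W, 0.0)
    return W


def initial_state(params: NetworkParameters, rng: np.random.Generator) -> SpikingState:
    """Fresh trial state: V uniform in [V_R, theta), currents at zero."""
    n = params.N_E + params.N_I
    V = rng.uniform(params.V_R, params.theta, size=n)
    z = np.zeros(n)
    return SpikingState(V=V, I_N=z.copy(), I_A=z.copy(), I_G=z.copy(),
                        refractory_until=np.full(n, -np.inf), t=0.0)


@_njit(cache=True)
def _chunk_kernel(V, I_N, I_A, I_G, refr, labels, mu_ext, noise, bins,
                  bin_counts, Jblock, kick_N, kick_A, kick_G, self_J,
                  dN, dA, dG, euler, noise_amp, theta, V_R, tau_arp,
                  t0, dt, step0, spike_steps, spike_ids, spiked):
    """Advance one chunk of Euler steps; returns the number of spikes stored."""
    n = V.size
    n_pops = Jblock.shape[0]
    n_exc = n_pops - 1
    counts = np.zeros(n_pops)
    exc_by_pop = np.zeros(n_pops)
    count = 0
    for s in range(noise.shape[0]):
        t_prev = t0 + (step0 + s) * dt
        t = t_prev + dt
        for q in range(n_pops):
            counts[q] = 0.0
        start = count
        for i in range(n):
            I_N[i] -= dN * I_N[i]
            I_A[i] -= dA * I_A[i]
            I_G[i] -= dG * I_G[i]
            if refr[i] <= t_prev:
                I_tot = I_N[i] + I_A[i] - I_G[i] + mu_ext[i]
                V[i] += euler[i] * (I_tot - V[i]) + noise_amp[i] * noise[s, i]
            else:
                V[i] = V_R
            if V[i] >= theta:
                V[i] = V_R
                refr[i] = t + tau_arp
                spike_steps[count] = step0 + s
                spike_ids[count] = i
                spiked[i] = True
                counts[labels[i]] += 1.0
                count += 1
        if count > start:
            b = bins[s]
            for q in range(n_pops):
                bin_counts[b, q] += counts[q]
                e = 0.0
                for r in range(n_exc):
                    e += Jblock[q, r] * counts[r]
                exc_by_pop[q] = e
            n_inh_spikes = counts[n_pops - 1]
            for i in range(n):
                lab = labels[i]
                e = exc_by_pop[lab]
                g = Jblock[lab, n_pops - 1] * n_inh_spikes
                if spiked[i]:
                    if lab < n_exc:
                        e -= self_J[i]
                    else:
                        g -= self_J[i]
                I_N[i] += kick_N[i] * e
                I_A[i] += kick_A[i] * e
                I_G[i] += kick_G[i] * g
            for k in range(start, count):
                spiked[spike_ids[k]] = False
    return count


def _chunk_numpy(V, I_N, I_A, I_G, refr, labels, mu_ext, noise, bins,
                 bin_counts, Jblock, kick_N, kick_A, kick_G, self_J,
                 dN, dA, dG, euler, noise_amp, theta, V_R, tau_arp,
                 t0, dt, step0, spike_steps, spike_ids, spiked):
    """Vectorized numpy reference path, semantically identical to the kernel."""
    n_pops = Jblock.shape[0]
    is_exc_source = labels < n_pops - 1
    count = 0
    for s in range(noise.shape[0]):
        t_prev = t0 + (step0 + s) * dt
        t = t_prev + dt
        I_N -= dN * I_N
        I_A -= dA * I_A
        I_G -= dG * I_G
        I_tot = I_N + I_A - I_G + mu_ext
        active = refr <= t_prev
        dV = euler * (I_tot - V) + noise_amp * noise[s]
        V[:] = np.where(active, V + dV, V_R)
        spiking = V >= theta
        if spiking.any():
            ids = np.nonzero(spiking)[0]
            V[ids] = V_R
            refr[ids] = t + tau_arp
            spike_steps[count:count + ids.size] = step0 + s
            spike_ids[count:count + ids.size] = ids
            count += ids.size
            pops = labels[ids]
            counts = np.bincount(pops, minlength=n_pops).astype(float)
            np.add.at(bin_counts[bins[s]], pops, 1)
            exc_by_pop = Jblock[:, :n_pops - 1] @ counts[:n_pops - 1]
            inh_by_pop = Jblock[:, n_pops - 1] * counts[n_pops - 1]
            exc_in = exc_by_pop[labels]
            inh_in = inh_by_pop[labels]
            exc_self = spiking & is_exc_source
            inh_self = spiking & ~is_exc_source
            if exc_self.any():
                exc_in = exc_in - np.where(exc_self, self_J, 0.0)
            if inh_self.any():
                inh_in = inh_in - np.where(inh_self, self_J, 0.0)
            I_N += kick_N * exc_in
            I_A += kick_A * exc_in
            I_G += kick_G * inh_in
    return count


def run_epoch(state: SpikingState, inputs: QuenchedInputs,
              active_stimulus: int | None, duration: float,
              params: NetworkParameters, rng: np.random.Generator,
              record_raster: bool = True, rate_bin: float = 0.01,
              use_numba: bool | None = None,
              ) -> tuple[SpikingState, SpikeRaster, pd.DataFrame]:
    """Advance the network for ``duration`` seconds under a fixed drive.

    Returns the final state, the spikes emitted during the epoch, and the
    per-population mean rate traces binned at ``rate_bin`` seconds. The state
    is modified in place (and also returned). The compiled and the vectorized
    integration paths consume the noise stream identically and give the same
    trajectories up to floating-point summation order.
    """
    q = params
    if duration < 0:
        raise ValueError("duration must be non-negative")
    n = q.N_E + q.N_I
    labels = inputs.labels
    dt = q.dt_spiking
    n_steps = int(round(duration / dt))
    Jblock = build_connectivity(q)
    p = q.p

    tau_m = np.where(np.arange(n) < q.N_E, q.tau_E, q.tau_I)
    X = np.where(np.arange(n) < q.N_E, q.X_E, q.X_I)
    # per-neuron kick scale factors for a unit-efficacy pre-synaptic spike
    kick_N = X * tau_m / q.tau_NMDA
    kick_A = (1.0 - X) * tau_m / q.tau_AMPA
    kick_G = tau_m / q.tau_GABA
    euler = dt / tau_m
    noise_amp = q.sigma * np.sqrt(dt / tau_m)

    mu_ext = inputs.drive_vector(active_stimulus)
    # self-connection correction: a neuron that spiked must not receive its own kick
    self_J = Jblock[labels, labels]

    V, I_N, I_A, I_G = state.V, state.I_N, state.I_A, state.I_G
    refr = state.refractory_until
    t0 = state.t

    n_bins = max(1, int(np.ceil(n_steps * dt / rate_bin))) if n_steps else 0
    bin_counts = np.zeros((n_bins, p + 2))
    pop_sizes = np.bincount(labels, minlength=p + 2)

    if use_numba is None:
        use_numba = _HAVE_NUMBA
    chunk_fn = _chunk_kernel if use_numba else _chunk_numpy

    spike_t: list[np.ndarray] = []
    spike_i: list[np.ndarray] = []
    spiked = np.zeros(n, dtype=np.bool_)
    chunk = 2000
    # refractoriness caps the per-chunk spike count
    cap = n * (int(chunk * dt / q.tau_arp) + 2)
    spike_steps = np.empty(cap, dtype=np.int64)
    spike_ids = np.empty(cap, dtype=np.int64)
    for step0 in range(0, n_steps, chunk):
        m = min(chunk, n_steps - step0)
        noise = rng.standard_normal((m, n))
        bins = np.minimum(((step0 + np.arange(m)) * dt / rate_bin).astype(np.int64),
                          n_bins - 1)
        cnt = chunk_fn(V, I_N, I_A, I_G, refr, labels, mu_ext, noise, bins,
                       bin_counts, Jblock, kick_N, kick_A, kick_G, self_J,
                       dt / q.tau_NMDA, dt / q.tau_AMPA, dt / q.tau_GABA,
                       euler, noise_amp, q.theta, q.V_R, q.tau_arp,
                       t0, dt, step0, spike_steps, spike_ids, spiked)
        if not np.isfinite(V).all():
            raise FloatingPointError(
                f"non-finite membrane potential at t = {t0 + (step0 + m) * dt:.4f} s")
        if record_raster and cnt:
            spike_t.append(t0 + (spike_steps[:cnt] + 1) * dt)
            spike_i.append(spike_ids[:cnt].copy())

    state.V, state.I_N, state.I_A, state.I_G = V, I_N, I_A, I_G
    state.refractory_until = refr
    state.t = t0 + n_steps * dt

    if spike_t:
        raster = SpikeRaster(np.concatenate(spike_t), np.concatenate(spike_i), labels)
    else:
        raster = SpikeRaster(np.empty(0), np.empty(0, dtype=np.int64), labels)

    times = t0 + rate_bin * (np.arange(n_bins) + 0.5)
    widths = np.full(n_bins, rate_bin)
    if n_bins:
        # last bin may be shorter when duration is not a multiple of rate_bin
        widths[-1] = n_steps * dt - rate_bin * (n_bins - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = bin_counts / (pop_sizes[None, :] * widths[:, None])
    cols = [f"sel_{k + 1}" for k in range(p)] + ["ns", "inh"]
    traces = pd.DataFrame(rates, columns=cols)
    traces.insert(0, "time", times)
    return state, raster, traces


class SpikingNetwork:
    """Convenience wrapper binding parameters and quenched inputs.

    Separates the two seed streams: the quenched structure lives in
    ``inputs`` (drawn once), while each call to :meth:`run` consumes an
    independent fast-noise generator, so repeated trials share the same
    frozen network but differ in membrane noise.
    """

    def __init__(self, params: NetworkParameters, inputs: QuenchedInputs):
        if not params.is_calibrated:
            raise RuntimeError("parameters must be calibrated before simulation")
        self.params = params
        self.inputs = inputs

    def run(self, epochs: list[tuple[int | None, float]], noise_seed: int,
            record_raster: bool = True, rate_bin: float = 0.01,
            use_numba: bool | None = None,
            ) -> tuple[SpikeRaster, pd.DataFrame, list[tuple[float, float]]]:
        """Run a sequence of (active_stimulus, duration) epochs from scratch.

        Returns the full-trial raster, concatenated rate traces and the
        absolute (start, end) times of each epoch.
        """
        rng = np.random.default_rng(noise_seed)
        state = initial_state(self.params, rng)
        rasters, trace_parts, bounds = [], [], []
        for stim, dur in epochs:
            t_start = state.t
            state, raster, traces = run_epoch(
                state, self.inputs, stim, dur, self.params, rng,
                record_raster=record_raster, rate_bin=rate_bin,
                use_numba=use_numba)
            bounds.append((t_start, state.t))
            rasters.append(raster)
            trace_parts.append(traces)
        raster = SpikeRaster.concatenate(rasters)
        traces = pd.concat(trace_parts, ignore_index=True)
        return raster, traces, bounds
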