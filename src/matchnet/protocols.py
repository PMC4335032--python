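"""Delayed match-to-sample protocols and multi-trial experiments.

Every trial starts with a 1 s pre-stimulus interval, followed by alternating
0.5 s stimulus presentations and 0.7 s delays. Variants:

* match:      sample s ... test s
* nonmatch:   sample s ... test b != s
* abba:       sample A, distractor B, repeated distractor B, match A
* distractors (n = 1, 2): sample s, n distinct non-sample distractors, then a
  test that either matches the sample or not.

Epoch roles follow the analysis conventions of single-unit DMS studies: the
first presentation of a non-sample stimulus is a "nonmatch" presentation, its
repetition a "repeated_nonmatch", and the final presentation of the sample a
"match". Trials can be run on either engine — the spiking network (per-neuron
rasters, trial-to-trial variability from the fast membrane noise) or the
deterministic population-rate dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ratemodel as rm
from .inputs import QuenchedInputs, StimulusParameters, STANDARD_STIMULI
from .parameters import NetworkParameters
from .spiking import SpikeRaster, SpikingNetwork

__all__ = [
    "Epoch",
    "ProtocolSpec",
    "TrialResult",
    "build_protocol",
    "run_experiment",
    "DEFAULT_DURATIONS",
]

#: Default epoch durations (s): pre-stimulus, stimulus presentation, delay.
DEFAULT_DURATIONS = {"pre": 1.0, "stimulus": 0.5, "delay": 0.7}

_PRESENTATION_ROLES = ("sample", "match", "nonmatch", "repeated_nonmatch", "distractor")


@dataclass(frozen=True)
class Epoch:
    role: str                   # pre | delay | sample | match | nonmatch | ...
    stimulus: int | None
    duration: float


@dataclass(frozen=True)
class ProtocolSpec:
    """A validated trial schedule."""

    kind: str
    sample: int
    epochs: tuple[Epoch, ...]
    stim_params: StimulusParameters = STANDARD_STIMULI

    @property
    def duration(self) -> float:
        return sum(e.duration for e in self.epochs)

    def epoch_bounds(self) -> list[tuple[Epoch, float, float]]:
        out, t = [], 0.0
        for e in self.epochs:
            out.append((e, t, t + e.duration))
            t += e.duration
        return out

    def engine_schedule(self) -> list[tuple[int | None, float]]:
        return [(e.stimulus, e.duration) for e in self.epochs]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "sample": self.sample,
            "epochs": [(e.role, e.stimulus, e.duration) for e in self.epochs],
            "alpha": self.stim_params.alpha,
            "beta": self.stim_params.beta,
            "sigma_S": self.stim_params.sigma_S,
        }


def build_protocol(kind: str, sample: int, foils=None,
                   durations: dict | None = None, n_stimuli: int = 6,
                   stim_params: StimulusParameters = STANDARD_STIMULI,
                   test: str = "match", rng=None) -> ProtocolSpec:
    """Build a validated epoch schedule.

    ``kind``: "match", "nonmatch", "abba" or "distractors_n" with n in {0,1,2}.
    ``foils`` supplies the non-sample stimuli where the protocol needs them
    (the nonmatch test, the ABBA distractor, the intervening distractors); if
    omitted they are sampled without replacement from the non-sample stimuli
    using ``rng``. For distractor protocols ``test`` selects whether the final
    stimulus matches the sample ("match") or is yet another stimulus
    ("nonmatch").
    """
    if not 0 <= sample < n_stimuli:
        raise ValueError(f"sample id {sample} out of range [0, {n_stimuli})")
    dur = dict(DEFAULT_DURATIONS)
    if durations:
        dur.update(durations)
    pre, st, de = dur["pre"], dur["stimulus"], dur["delay"]

    if foils is None:
        foils = []
    elif np.isscalar(foils):
        foils = [int(foils)]
    else:
        foils = [int(x) for x in foils]
    pool = [s for s in range(n_stimuli) if s != sample and s not in foils]

    def draw(k):
        if rng is None:
            raise ValueError(f"protocol '{kind}' needs {k} foil(s); pass foils or rng")
        picked = list(np.random.default_rng(rng).choice(pool, size=k, replace=False)
                      if not isinstance(rng, np.random.Generator)
                      else rng.choice(pool, size=k, replace=False))
        return [int(x) for x in picked]

    def check_foils(fs, k):
        if len(fs) != k:
            raise ValueError(f"protocol '{kind}' needs exactly {k} foil(s), got {len(fs)}")
        if len(set(fs)) != len(fs) or sample in fs:
            raise ValueError("foil ids must be distinct and differ from the sample")
        if any(not 0 <= x < n_stimuli for x in fs):
            raise ValueError("foil id out of range")

    E = []
    E.append(Epoch("pre", None, pre))
    E.append(Epoch("sample", sample, st))

    if kind in ("match", "distractors_0"):
        E += [Epoch("delay", None, de), Epoch("match", sample, st)]
        kind_out = "match" if kind == "match" else kind
    elif kind == "nonmatch":
        fs = foils or draw(1)
        check_foils(fs, 1)
        E += [Epoch("delay", None, de), Epoch("nonmatch", fs[0], st)]
        kind_out = kind
    elif kind == "abba":
        fs = foils or draw(1)
        check_foils(fs, 1)
        b = fs[0]
        E += [Epoch("delay", None, de), Epoch("nonmatch", b, st),
              Epoch("delay", None, de), Epoch("repeated_nonmatch", b, st),
              Epoch("delay", None, de), Epoch("match", sample, st)]
        kind_out = kind
    elif kind.startswith("distractors_"):
        n = int(kind.split("_")[1])
        if n not in (1, 2):
            raise ValueError("distractor count must be 0, 1 or 2")
        need = n + (1 if test == "nonmatch" else 0)
        fs = foils or draw(need)
        check_foils(fs, need)
        for d in fs[:n]:
            E += [Epoch("delay", None, de), Epoch("distractor", d, st)]
        if test == "match":
            E += [Epoch("delay", None, de), Epoch("match", sample, st)]
        elif test == "nonmatch":
            E += [Epoch("delay", None, de), Epoch("nonmatch", fs[n], st)]
        else:
            raise ValueError(f"unknown test kind {test!r}")
        kind_out = kind
    else:
        raise ValueError(f"unknown protocol kind {kind!r}")
    return ProtocolSpec(kind=kind_out, sample=sample, epochs=tuple(E),
                        stim_params=stim_params)


@dataclass
class TrialResult:
    """One simulated trial with epoch bookkeeping.

    ``raster`` is None for rate-engine trials; ``traces`` always holds the
    per-population rate time courses. ``memory_survived`` flags, one per delay
    epoch, say whether the most recently cued representation was still active
    (rate over the last 100 ms of the delay above ``survival_factor`` times the
    spontaneous rate) at the delay's end.
    """

    protocol: ProtocolSpec
    engine: str
    noise_seed: int | None
    epochs: list[tuple[Epoch, float, float]]
    traces: pd.DataFrame
    raster: SpikeRaster | None = None
    memory_survived: list[bool] = field(default_factory=list)

    def presentation_epochs(self):
        return [(e, t0, t1) for e, t0, t1 in self.epochs
                if e.role in _PRESENTATION_ROLES]

    def sample_delay_bounds(self):
        """(t0, t1) of the delay immediately following the sample."""
        for i, (e, t0, t1) in enumerate(self.epochs):
            if e.role == "sample":
                nxt = self.epochs[i + 1]
                if nxt[0].role == "delay":
                    return nxt[1], nxt[2]
        raise ValueError("trial has no sample-delay epoch")


def _survival_flags(traces: pd.DataFrame, epochs, sample: int,
                    params: NetworkParameters,
                    survival_factor: float) -> list[bool]:
    """Per delay epoch: is the sample's representation still active at its end?

    "Active" means its mean rate over the last 100 ms of the delay exceeds
    ``survival_factor`` times the calibrated spontaneous rate.
    """
    flags = []
    t = traces["time"].values
    for e, t0, t1 in epochs:
        if e.role == "delay":
            m = (t >= t1 - 0.1) & (t < t1)
            fg = traces.loc[m, f"sel_{sample + 1}"].mean()
            flags.append(bool(fg > survival_factor * params.nu_E_sp))
    return flags


def run_trial(engine: str, protocol: ProtocolSpec, params: NetworkParameters,
              inputs: QuenchedInputs | None = None, noise_seed: int | None = None,
              survival_factor: float = 5.0, record_raster: bool = True) -> TrialResult:
    """Simulate one trial on the chosen engine ("spiking" or "rate")."""
    bounds = protocol.epoch_bounds()
    if engine == "spiking":
        if inputs is None:
            raise ValueError("the spiking engine needs QuenchedInputs")
        net = SpikingNetwork(params, inputs)
        raster, traces, _ = net.run(protocol.engine_schedule(),
                                    noise_seed=noise_seed if noise_seed is not None else 0,
                                    record_raster=record_raster)
    elif engine == "rate":
        traces = rm.integrate_rate_trial(params, protocol.engine_schedule(),
                                         stim=protocol.stim_params)
        raster = None
    else:
        raise ValueError(f"unknown engine {engine!r}")
    flags = _survival_flags(traces, bounds, protocol.sample, params, survival_factor)
    return TrialResult(protocol=protocol, engine=engine, noise_seed=noise_seed,
                       epochs=bounds, traces=traces, raster=raster,
                       memory_survived=flags)


def run_experiment(engine: str, protocols: list[ProtocolSpec], n_trials: int,
                   params: NetworkParameters, inputs: QuenchedInputs | None = None,
                   seed: int = 0, survival_factor: float = 5.0,
                   record_raster: bool = True) -> list[TrialResult]:
    """Run ``n_trials`` trials of every protocol.

    Trials share the quenched input structure and differ only in the
    fast-noise stream; per-trial seeds are spawned deterministically from
    ``seed``, so identical arguments give identical results.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be non-negative")
    results = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   ss.spawn(len(protocols) * n_trials)]
    i = 0
    for proto in protocols:
        for _ in range(n_trials):
            results.append(run_trial(engine, proto, params, inputs,
                                     noise_seed=child_seeds[i],
                                     survival_factor=survival_factor,
                                     record_raster=record_raster))
            i += 1
    return results
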