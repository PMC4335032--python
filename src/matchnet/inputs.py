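"""Quenched external-input structure.

Every neuron receives a noisy external current whose mean is drawn once —
and frozen thereafter — from a Gaussian centred on the calibrated class mean
(mu_ext_E for excitatory, mu_ext_I for inhibitory cells) with SD sigma_BG.
On top of this, presenting stimulus s adds a frozen selective current to each
neuron of the memory representations: drawn from N(alpha + beta, sigma_S^2)
for neurons in representation s (the selective foreground) and from
N(beta, sigma_S^2) for neurons in the other representations (the selective
background). Non-selective excitatory neurons and inhibitory neurons receive
no stimulus current. Because the draws are quenched, a given stimulus always
elicits the same current in a given neuron, across trials and epochs; only
the fast temporal noise (amplitude sigma) differs between trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import NetworkParameters

__all__ = [
    "StimulusParameters",
    "QuenchedInputs",
    "draw_quenched_inputs",
    "population_labels",
    "STANDARD_STIMULI",
    "DISTRACTOR_REGIME_STIMULI",
]


@dataclass(frozen=True)
class StimulusParameters:
    """Statistics of the stimulus-evoked currents (mV)."""

    alpha: float = 1.5      # extra mean drive to the foreground representation
    beta: float = 1.8       # mean drive to every memory representation
    sigma_S: float = 2.0    # quenched SD of the selective currents
    n_stimuli: int = 6

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")
        if self.sigma_S < 0:
            raise ValueError("sigma_S must be non-negative")


#: Stimulus statistics of the standard match/non-match experiments.
STANDARD_STIMULI = StimulusParameters(alpha=1.5, beta=1.8)
#: Weaker-input regime in which persistent activity usually, but not always,
#: survives a distractor (used for the intervening-stimulus protocols).
DISTRACTOR_REGIME_STIMULI = StimulusParameters(alpha=0.84, beta=1.7)


def population_labels(params: NetworkParameters) -> np.ndarray:
    """Per-neuron population label for the full network of N_E + N_I cells.

    Labels 0..p-1: selective representations (contiguous blocks of f*N_E
    excitatory neurons), p: non-selective excitatory, p+1: inhibitory.
    """
    q = params
    labels = np.full(q.N_E + q.N_I, q.p, dtype=np.int64)
    block = q.n_selective_per_pop
    for k in range(q.p):
        labels[k * block:(k + 1) * block] = k
    labels[q.N_E:] = q.p + 1
    return labels


@dataclass
class QuenchedInputs:
    """Frozen external-input structure for one realization of the network."""

    params: NetworkParameters
    mu_ext_background: np.ndarray       # (N_E + N_I,) per-neuron mean current, mV
    mu_sel: np.ndarray                  # (n_selective, p) selective currents, mV
    labels: np.ndarray                  # (N_E + N_I,) population labels
    stimulus: StimulusParameters
    seed: int

    def __post_init__(self):
        n_sel = self.params.n_selective
        if self.mu_sel.shape != (n_sel, self.params.p):
            raise ValueError("mu_sel has wrong shape")

    def total_drive(self, neuron: int, active_stimulus: int | None = None
                    ) -> tuple[float, float]:
        """Mean external current and fast-noise amplitude for one neuron (mV).

        With no stimulus every neuron sees its quenched background mean; during
        a presentation, selective neurons additionally see their frozen
        per-stimulus current. The noise amplitude is sigma in all cases.
        """
        n = self.mu_ext_background.size
        if not 0 <= neuron < n:
            raise IndexError(f"neuron index {neuron} out of range [0, {n})")
        mu = float(self.mu_ext_background[neuron])
        if active_stimulus is not None:
            if not 0 <= active_stimulus < self.params.p:
                raise ValueError(f"unknown stimulus id {active_stimulus}")
            if neuron < self.params.n_selective:
                mu += float(self.mu_sel[neuron, active_stimulus])
        return mu, self.params.sigma

    def drive_vector(self, active_stimulus: int | None = None) -> np.ndarray:
        """Vectorized mean external current for all neurons (mV)."""
        mu = self.mu_ext_background.copy()
        if active_stimulus is not None:
            if not 0 <= active_stimulus < self.params.p:
                raise ValueError(f"unknown stimulus id {active_stimulus}")
            mu[:self.params.n_selective] += self.mu_sel[:, active_stimulus]
        return mu

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (one row per neuron) for serialization."""
        n = self.mu_ext_background.size
        df = pd.DataFrame({
            "neuron": np.arange(n),
            "population": self.labels,
            "mu_ext_background": self.mu_ext_background,
        })
        for s in range(self.params.p):
            col = np.full(n, np.nan)
            col[:self.params.n_selective] = self.mu_sel[:, s]
            df[f"mu_sel_{s}"] = col
        return df


def draw_quenched_inputs(params: NetworkParameters,
                         stim: StimulusParameters | None = None,
                         seed: int = 0) -> QuenchedInputs:
    """Draw the frozen input structure; deterministic for a given seed.

    Requires calibrated external means (they are the centres of the quenched
    background distribution).
    """
    if not params.is_calibrated:
        raise RuntimeError(
            "external current means are uncalibrated; calibrate mu_ext_E/mu_ext_I "
            "before drawing quenched inputs")
    if stim is None:
        stim = STANDARD_STIMULI
    if stim.n_stimuli != params.p:
        raise ValueError(f"n_stimuli={stim.n_stimuli} must equal p={params.p}")
    rng = np.random.default_rng(seed)
    labels = population_labels(params)
    n = params.N_E + params.N_I
    means = np.where(np.arange(n) < params.N_E, params.mu_ext_E, params.mu_ext_I)
    mu_bg = rng.normal(means, params.sigma_BG)
    n_sel = params.n_selective
    # background-level selective current everywhere, foreground mean on own block
    mu_sel = rng.normal(stim.beta, stim.sigma_S, size=(n_sel, params.p))
    own = labels[:n_sel][:, None] == np.arange(params.p)[None, :]
    mu_sel = mu_sel + own * stim.alpha
    return QuenchedInputs(params=params, mu_ext_background=mu_bg, mu_sel=mu_sel,
                          labels=labels, stimulus=stim, seed=seed)
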