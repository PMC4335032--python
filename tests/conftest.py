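"""Shared fixtures.

Expensive spiking experiments are session-scoped and shared between the
behavioural tests and the acceptance tests; everything is generated
programmatically from seeds, no stored data.
"""

from __future__ import annotations

import numpy as np
import pytest

from matchnet import (
    DISTRACTOR_REGIME_STIMULI,
    STANDARD_STIMULI,
    StimulusParameters,
    analysis,
    build_protocol,
    calibrated,
    draw_quenched_inputs,
    fixture_scale,
    load_parameters,
    run_experiment,
)


@pytest.fixture(scope="session")
def params():
    """Canonical parameter set, uncalibrated."""
    return load_parameters()


@pytest.fixture(scope="session")
def cal(params):
    """Canonical parameters with mean-field-calibrated external currents."""
    return calibrated(params)


@pytest.fixture(scope="session")
def tiny(cal):
    """4x-reduced network (N_E=400, N_I=100, efficacies rescaled) for fast runs."""
    return calibrated(fixture_scale(cal, 4))


@pytest.fixture(scope="session")
def bifurcation(cal):
    """Delay-state continuation over a J_plus grid spanning the critical point."""
    from matchnet import scan_bifurcation
    return scan_bifurcation(cal, np.arange(0.132, 0.1701, 0.004))


@pytest.fixture(scope="session")
def standard_inputs(cal):
    return draw_quenched_inputs(cal, STANDARD_STIMULI, seed=11)


@pytest.fixture(scope="session")
def match_experiment(cal, standard_inputs):
    """Match trials for all 6 stimuli, 15 fast-noise seeds each (spiking)."""
    protos = [build_protocol("match", s) for s in range(cal.p)]
    return run_experiment("spiking", protos, 15, cal, standard_inputs, seed=5)


@pytest.fixture(scope="session")
def match_nonmatch_experiment(cal, standard_inputs):
    """Nonmatch trials for all 6 stimuli (3 seeds each, spiking)."""
    protos = [build_protocol("nonmatch", s, foils=[(s + 1) % cal.p])
              for s in range(cal.p)]
    return run_experiment("spiking", protos, 3, cal, standard_inputs, seed=6)


@pytest.fixture(scope="session")
def match_table(match_experiment):
    return analysis.count_responses(match_experiment)


@pytest.fixture(scope="session")
def full_table(match_experiment, match_nonmatch_experiment):
    return analysis.count_responses(match_experiment + match_nonmatch_experiment)


@pytest.fixture(scope="session")
def distractor_inputs(cal):
    return draw_quenched_inputs(cal, DISTRACTOR_REGIME_STIMULI, seed=7)


@pytest.fixture(scope="session")
def distractor_experiments(cal, distractor_inputs):
    """Weak-input-regime experiments keyed by distractor count.

    For each n in {0, 1, 2}: match- and nonmatch-test protocols for all 6
    samples, 4 noise seeds each (24 trials per test condition).
    """
    rng = np.random.default_rng(3)
    exps = {}
    for n in (0, 1, 2):
        protos = []
        for s in range(cal.p):
            for test in ("match", "nonmatch"):
                if n == 0:
                    protos.append(build_protocol(
                        "match" if test == "match" else "nonmatch", s,
                        stim_params=DISTRACTOR_REGIME_STIMULI, rng=rng))
                else:
                    protos.append(build_protocol(
                        f"distractors_{n}", s, test=test,
                        stim_params=DISTRACTOR_REGIME_STIMULI, rng=rng))
        exps[n] = run_experiment("spiking", protos, 4, cal, distractor_inputs,
                                 seed=100 + n)
    return exps


@pytest.fixture(scope="session")
def abba_trials(cal, distractor_inputs):
    """ABBA protocol, weak-input regime, all 6 samples x 4 seeds."""
    rng = np.random.default_rng(9)
    protos = [build_protocol("abba", s, stim_params=DISTRACTOR_REGIME_STIMULI,
                             rng=rng) for s in range(cal.p)]
    return run_experiment("spiking", protos, 4, cal, distractor_inputs, seed=55)


@pytest.fixture(scope="session")
def heterogeneity_tables(cal):
    """Response tables of match experiments at sigma_S in {2, 3, 4} mV."""
    tables = {}
    for sigma_s in (2.0, 3.0, 4.0):
        stim = StimulusParameters(alpha=STANDARD_STIMULI.alpha,
                                  beta=STANDARD_STIMULI.beta,
                                  sigma_S=sigma_s, n_stimuli=cal.p)
        inputs = draw_quenched_inputs(cal, stim, seed=7)
        protos = [build_protocol("match", s, stim_params=stim)
                  for s in range(cal.p)]
        trials = run_experiment("spiking", protos, 2, cal, inputs, seed=200)
        tables[sigma_s] = analysis.count_responses(trials)
    return tables
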