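import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from matchnet import analysis as an
from matchnet import StimulusParameters, build_protocol
from matchnet.analysis import ResponseTable
from matchnet.protocols import TrialResult
from matchnet.spiking import SpikeRaster


# --------------------------------------------------------------------------
# Sparseness
# --------------------------------------------------------------------------

def test_sparseness_trivial_cases_exact():
    assert an.sparseness_index([3.0] * 6) == pytest.approx(0.0, abs=1e-15)
    assert an.sparseness_index([5.0, 0, 0, 0, 0, 0]) == pytest.approx(1.0, abs=1e-15)


def test_sparseness_worked_example():
    # A = (16/6)^2 / (126/6); S = (1 - A) / (1 - 1/6)
    assert an.sparseness_index([10, 5, 1, 0, 0, 0]) == pytest.approx(0.7936507936507937)


def test_sparseness_degenerate_and_invalid():
    assert np.isnan(an.sparseness_index([0.0, 0.0, 0.0]))
    with pytest.raises(ValueError):
        an.sparseness_index([1.0])
    with pytest.raises(ValueError):
        an.sparseness_index([1.0, -1.0])


@given(st.lists(st.floats(0.0, 100.0), min_size=2, max_size=8),
       st.floats(0.01, 50.0))
@settings(max_examples=60, deadline=None)
def test_sparseness_invariant_under_uniform_rescaling(rates, c):
    a = an.sparseness_index(rates)
    b = an.sparseness_index([c * r for r in rates])
    if np.isnan(a):
        assert np.isnan(b)
    else:
        assert b == pytest.approx(a, rel=1e-9, abs=1e-9)


# --------------------------------------------------------------------------
# Synthetic response tables
# --------------------------------------------------------------------------

def synth_table(**roles):
    """6 neurons, one per representation; role -> 6x6 rate matrix."""
    rates = {k: np.asarray(v, dtype=float) for k, v in roles.items()}
    n_trials = {k: np.ones_like(v, dtype=int) for k, v in rates.items()}
    return ResponseTable(rates=rates, n_trials=n_trials, rep=np.arange(6),
                         window=0.2)


def test_match_effect_indices_on_synthetic_counts():
    fg = np.eye(6, dtype=bool)
    sample = np.full((6, 6), 10.0)
    match = np.where(fg, 20.0, 5.0)
    nonmatch = np.full((6, 6), 10.0)
    idx = an.match_effect_indices(synth_table(sample=sample, match=match,
                                              nonmatch=nonmatch))
    assert idx.enhancement == pytest.approx(2.0)
    assert idx.suppression == pytest.approx(0.5)
    assert idx.match_nonmatch_foreground == pytest.approx(2.0)
    assert idx.match_nonmatch_background == pytest.approx(0.5)
    assert np.allclose(idx.per_representation["m_nm_index"], 2.0)


def test_indices_flag_zero_denominators():
    idx = an.match_effect_indices(synth_table(sample=np.zeros((6, 6)),
                                              match=np.ones((6, 6))))
    assert np.isnan(idx.enhancement) and np.isnan(idx.suppression)


def test_fraction_suppressed_enumeration_oracle():
    """4 cells x 2 stimuli, 3 suppressed pairs by construction -> 3/8."""
    sample = np.array([[2.0, 1.0], [3.0, 0.0], [1.0, 1.0], [5.0, 5.0]])
    match = np.array([[1.0, 1.5], [2.0, 0.0], [0.5, 2.0], [5.0, 6.0]])
    table = ResponseTable(rates={"sample": sample, "match": match},
                          n_trials={"sample": np.ones((4, 2), int),
                                    "match": np.ones((4, 2), int)},
                          rep=np.array([0, 0, 1, 1]), window=0.2)
    b = an.suppression_breakdown(table)
    assert an.fraction_suppressed(table) == pytest.approx(3 / 8)
    assert b["suppressed"] + b["enhanced"] + b["tied"] == pytest.approx(1.0)
    assert b["tied"] == pytest.approx(2 / 8)       # the (0,0) and (5,5) pairs
    assert b["suppressed_among_classified"] == pytest.approx(3 / 6)


def test_tuning_curves_ranking():
    sample = np.tile(np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0]), (6, 1))
    match = np.tile(np.arange(6, dtype=float), (6, 1))
    curves = an.tuning_curves(synth_table(sample=sample, match=match))
    assert np.allclose(curves["sample"], sample)       # already ranked
    assert np.allclose(curves["match"], match)         # re-indexed by identity
    # permuting the stimulus axis leaves ranked curves unchanged
    perm = np.array([3, 1, 5, 0, 2, 4])
    curves2 = an.tuning_curves(synth_table(sample=sample[:, perm],
                                           match=match[:, perm]))
    assert np.allclose(curves2["sample"], curves["sample"])
    assert np.allclose(curves2["match"], curves["match"])
    # ties broken by stimulus id
    tied = an.tuning_curves(synth_table(sample=np.ones((6, 6)),
                                        match=match))
    assert np.allclose(tied["match"], match)


def test_pearson_correlation_matches_manual_computation():
    sample = np.tile(np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]), (6, 1))
    delay = np.tile(np.array([2.0, 1.0, 5.0, 3.0, 7.0, 6.0]), (6, 1))
    out = an.sample_delay_correlation(synth_table(sample=sample, delay=delay))
    x, y = sample[0], delay[0]
    manual = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
    assert out["mean_r"] == pytest.approx(manual)
    assert out["n_neurons"] == 6 and out["n_excluded"] == 0
    # identical vectors correlate perfectly
    out = an.sample_delay_correlation(synth_table(sample=sample, delay=sample))
    assert out["mean_r"] == pytest.approx(1.0)
    # zero-variance neurons are excluded and counted
    flat = sample.copy()
    flat[0] = 3.0
    out = an.sample_delay_correlation(synth_table(sample=flat, delay=delay))
    assert out["n_excluded"] == 1 and out["n_neurons"] == 5


# --------------------------------------------------------------------------
# Synthetic trials (raster plumbing)
# --------------------------------------------------------------------------

def make_trial(spikes, n=30, p=6):
    """Match trial over a 30-neuron network with a hand-written raster."""
    proto = build_protocol("match", 0,
                           stim_params=StimulusParameters(n_stimuli=p))
    labels = np.concatenate([np.arange(p), np.full(n - p - 5, p),
                             np.full(5, p + 1)])
    times = np.array([t for t, _ in spikes])
    ids = np.array([i for _, i in spikes], dtype=np.int64)
    raster = SpikeRaster(times, ids, labels)
    return TrialResult(protocol=proto, engine="spiking", noise_seed=0,
                       epochs=proto.epoch_bounds(), traces=None, raster=raster,
                       memory_survived=[True])


def test_count_responses_direct_counting():
    # neuron 0: 4 spikes in the first 200 ms of the sample epoch (onset 1.0)
    spikes = [(1.01, 0), (1.05, 0), (1.1, 0), (1.19, 0),
              (1.35, 0),                   # outside the counting window
              (2.25, 1), (2.30, 1)]        # neuron 1, match epoch (onset 2.2)
    table = an.count_responses([make_trial(spikes)])
    assert table.counts("sample")[0, 0] == pytest.approx(4.0)
    assert table.rates["sample"][0, 0] == pytest.approx(20.0)
    assert table.counts("match")[1, 0] == pytest.approx(2.0)
    assert table.counts("match")[0, 0] == 0.0


def test_count_responses_empty_raster_gives_zeros():
    table = an.count_responses([make_trial([])])
    assert np.all(table.rates["sample"][:, 0] == 0.0)
    assert np.all(table.rates["match"][:, 0] == 0.0)
    assert np.all(np.isnan(table.rates["sample"][:, 1]))   # unseen stimulus


def test_count_responses_window_validation():
    with pytest.raises(ValueError, match="exceeds"):
        an.count_responses([make_trial([])], window=0.9)
    with pytest.raises(ValueError, match="no trials"):
        an.count_responses([])


def test_distractor_decay_forced_survival_control():
    """If the trial sets are identical at every distractor count, the
    suppression magnitude cannot depend on the count."""
    trials = [make_trial([(1.05, 2), (2.25, 3)])]
    nm = build_protocol("nonmatch", 0, foils=[1],
                        stim_params=StimulusParameters(n_stimuli=6))
    nm_trial = make_trial([(2.25, 4)])
    nm_trial.protocol = nm
    nm_trial.epochs = nm.epoch_bounds()
    exps = {n: trials + [nm_trial] for n in (0, 1, 2)}
    df = an.distractor_decay(exps)
    assert df["suppression_magnitude"].nunique() == 1
    with pytest.raises(ValueError, match="missing experiment"):
        an.distractor_decay({0: trials, 1: trials})


# --------------------------------------------------------------------------
# Directional checks on simulated experiments
# --------------------------------------------------------------------------

def test_foreground_enhanced_background_suppressed_dominantly(match_table):
    """In match trials nearly all classified foreground pairs are enhanced
    and nearly all classified background pairs suppressed."""
    fg = match_table.rep[:, None] == np.arange(match_table.p)[None, :]
    m, s = match_table.rates["match"], match_table.rates["sample"]
    fg_cls = fg & (m != s)
    bg_cls = ~fg & (m != s)
    assert np.mean(m[fg_cls] > s[fg_cls]) > 0.9
    assert np.mean(m[bg_cls] < s[bg_cls]) > 0.9


def test_repetition_sharpens_tuning(match_table):
    """The response to the best (rank-1) stimulus grows on repetition while
    responses to the other stimuli shrink."""
    curves = an.tuning_curves(match_table, roles=("sample", "match"))
    fg_neurons = np.arange(match_table.n_neurons)
    rank1_gain = np.nanmean(curves["match"][:, 0] - curves["sample"][:, 0])
    rest_gain = np.nanmean(curves["match"][:, 1:] - curves["sample"][:, 1:])
    assert rank1_gain > 0 > rest_gain
    # sharpening raises the sparseness of the repeated-stimulus responses
    s_sample = [an.sparseness_index(r) for r in np.nan_to_num(curves["sample"])
                if r.sum() > 0]
    s_match = [an.sparseness_index(r) for r in np.nan_to_num(curves["match"])
               if r.sum() > 0]
    assert np.mean(s_match) > np.mean(s_sample)


def test_heterogeneity_scan_structure(cal):
    """The sigma_S orchestration returns one well-formed row per grid value
    (direction checks run at full scale elsewhere; this uses the reduced
    fixture network)."""
    from matchnet import calibrated, fixture_scale
    tiny = calibrated(fixture_scale(cal, 4))
    df = an.heterogeneity_correlations(tiny, [2.0, 4.0], n_trials=1, seed=3)
    assert list(df["sigma_s"]) == [2.0, 4.0]
    assert ((df["sample_delay_r"].abs() <= 1.0).all()
            and (df["match_delay_r"].abs() <= 1.0).all())
    assert (df["n_neurons"] + df["n_excluded"] == tiny.n_selective).all()


def test_match_enhancement_and_suppression_coexist(full_table):
    idx = an.match_effect_indices(full_table)
    assert idx.enhancement > 1.0
    assert idx.suppression < 1.0
    assert idx.match_nonmatch_foreground > 1.0
    assert idx.match_nonmatch_background < 1.0
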