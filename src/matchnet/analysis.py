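"""Statistics of simulated delayed match-to-sample experiments.

All response measures mirror the conventions of single-unit DMS studies:
stimulus responses are spike counts of selective neurons in the first 200 ms
of a presentation (reported in Hz after dividing by the window), delay
activity is the rate over the last 200 ms of a delay, and effects are
summarized by

* the enhancement index — population-averaged match / sample response of the
  active (foreground) representation;
* the suppression index — match / sample response of the inactive
  (background) representations;
* the match-nonmatch index — match / nonmatch response, per group;
* the sparseness index S = (1 - A) / (1 - 1/n), A = (sum nu / n)^2 /
  (sum nu^2 / n), 0 for uniform responses and 1 for one-hot responses;
* per-neuron Pearson correlations between epoch-response vectors across the
  stimulus set (e.g. sample vs delay), averaged over selective neurons.

"Suppressed" means the mean match response is strictly below the mean sample
response; ties are counted separately and reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import NetworkParameters
from .protocols import TrialResult

__all__ = [
    "ResponseTable",
    "IndexSet",
    "count_responses",
    "sparseness_index",
    "match_effect_indices",
    "rate_engine_indices",
    "fraction_suppressed",
    "suppression_breakdown",
    "tuning_curves",
    "sample_delay_correlation",
    "heterogeneity_correlations",
    "response_by_role_and_group",
    "distractor_decay",
]

RESPONSE_WINDOW = 0.2   # s, counting window from stimulus onset
DELAY_WINDOW = 0.2      # s, measured backwards from delay end


# --------------------------------------------------------------------------
# Response counting
# --------------------------------------------------------------------------

@dataclass
class ResponseTable:
    """Trial-averaged responses of selective neurons.

    ``rates[role]`` is an (n_selective, p) array of mean rates in Hz (NaN
    where a neuron/stimulus/role combination was never observed);
    ``n_trials[role]`` the matching observation counts. ``rep`` holds each
    selective neuron's representation id.
    """

    rates: dict[str, np.ndarray]
    n_trials: dict[str, np.ndarray]
    rep: np.ndarray
    window: float

    @property
    def n_neurons(self) -> int:
        return self.rep.size

    @property
    def p(self) -> int:
        return next(iter(self.rates.values())).shape[1]

    def counts(self, role: str) -> np.ndarray:
        """Mean spike counts (rate * window)."""
        return self.rates[role] * self.window

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for role, mat in self.rates.items():
            n_obs = self.n_trials[role]
            for s in range(mat.shape[1]):
                rows.append(pd.DataFrame({
                    "neuron": np.arange(mat.shape[0]),
                    "representation": self.rep,
                    "stimulus": s,
                    "role": role,
                    "rate_hz": mat[:, s],
                    "n_trials": n_obs[:, s],
                }))
        return pd.concat(rows, ignore_index=True)


def count_responses(trials: list[TrialResult], window: float = RESPONSE_WINDOW,
                    delay_window: float = DELAY_WINDOW) -> ResponseTable:
    """Per-neuron, per-stimulus, per-role trial-averaged responses.

    Presentation responses are spike counts of the selective neurons in the
    first ``window`` seconds of the epoch; the "delay" role is the rate over
    the last ``delay_window`` seconds of the delay that follows the sample,
    attributed to the sample stimulus. Requires spiking-engine trials.
    """
    if not trials:
        raise ValueError("no trials to analyze")
    params = trials[0].protocol.stim_params
    p = params.n_stimuli
    first = trials[0]
    if first.raster is None:
        raise ValueError("count_responses needs spiking trials (with rasters)")
    n_sel_per = np.count_nonzero(first.raster.labels == 0)
    n_sel = n_sel_per * p
    rep = first.raster.labels[:n_sel]

    sums: dict[str, np.ndarray] = {}
    obs: dict[str, np.ndarray] = {}

    def acc(role, s, values):
        if role not in sums:
            sums[role] = np.zeros((n_sel, p))
            obs[role] = np.zeros((n_sel, p), dtype=int)
        sums[role][:, s] += values
        obs[role][:, s] += 1

    for tr in trials:
        if tr.raster is None:
            raise ValueError("count_responses needs spiking trials (with rasters)")
        times, neurons = tr.raster.times, tr.raster.neurons
        sel = neurons < n_sel
        times, neurons = times[sel], neurons[sel]
        for e, t0, t1 in tr.presentation_epochs():
            if window > e.duration + 1e-9:
                raise ValueError(
                    f"window {window} s exceeds the {e.duration} s {e.role} epoch")
            m = (times >= t0) & (times < t0 + window)
            counts = np.bincount(neurons[m], minlength=n_sel)[:n_sel]
            acc(e.role, e.stimulus, counts / window)
        d0, d1 = tr.sample_delay_bounds()
        m = (times >= d1 - delay_window) & (times < d1)
        counts = np.bincount(neurons[m], minlength=n_sel)[:n_sel]
        acc("delay", tr.protocol.sample, counts / delay_window)

    rates = {}
    for role in sums:
        with np.errstate(invalid="ignore"):
            rates[role] = np.where(obs[role] > 0, sums[role] / np.maximum(obs[role], 1),
                                   np.nan)
    return ResponseTable(rates=rates, n_trials=obs, rep=rep, window=window)


# --------------------------------------------------------------------------
# Sparseness
# --------------------------------------------------------------------------

def sparseness_index(rates, n: int | None = None) -> float:
    """Selectivity of a response vector: 0 uniform, 1 one-hot.

    Returns NaN (flagged missing) for an all-zero vector, for which the index
    is undefined.
    """
    nu = np.asarray(rates, dtype=float)
    if n is None:
        n = nu.size
    if n < 2:
        raise ValueError("sparseness needs at least 2 stimuli")
    if np.any(nu < 0):
        raise ValueError("rates must be non-negative")
    denom = np.sum(nu ** 2) / n
    if denom == 0.0:
        return float("nan")
    A = (np.sum(nu) / n) ** 2 / denom
    return float((1.0 - A) / (1.0 - 1.0 / n))


# --------------------------------------------------------------------------
# Match-effect indices
# --------------------------------------------------------------------------

@dataclass
class IndexSet:
    """Population-averaged response ratios quantifying match effects."""

    enhancement: float                 # foreground match / sample
    suppression: float                 # background match / sample
    match_nonmatch_foreground: float   # foreground match / nonmatch
    match_nonmatch_background: float   # background match / nonmatch
    per_representation: pd.DataFrame | None = field(default=None, repr=False)

    def as_dict(self) -> dict[str, float]:
        return {
            "enhancement": self.enhancement,
            "suppression": self.suppression,
            "match_nonmatch_foreground": self.match_nonmatch_foreground,
            "match_nonmatch_background": self.match_nonmatch_background,
        }


def _ratio(num: float, den: float) -> float:
    return float(num / den) if den > 0 else float("nan")


def match_effect_indices(table: ResponseTable) -> IndexSet:
    """Match-effect indices from per-neuron responses (spiking engine).

    Foreground pairs are (neuron, stimulus) combinations where the neuron
    belongs to the stimulus's representation; background pairs are the rest.
    Each index is the ratio of the pair-averaged responses.
    """
    fg = table.rep[:, None] == np.arange(table.p)[None, :]

    def group_mean(role, mask):
        if role not in table.rates:
            return float("nan")
        m = table.rates[role]
        valid = mask & ~np.isnan(m)
        return float(np.nanmean(m[valid])) if valid.any() else float("nan")

    S_fg, S_bg = group_mean("sample", fg), group_mean("sample", ~fg)
    M_fg, M_bg = group_mean("match", fg), group_mean("match", ~fg)
    # background pairs for the nonmatch role include cells of the trial's
    # persistently-active representation: their strong transient response to
    # the nonmatch is what drives the background M/NM index below one
    NM_fg, NM_bg = group_mean("nonmatch", fg), group_mean("nonmatch", ~fg)

    per_rep = None
    if "match" in table.rates and "nonmatch" in table.rates:
        rows = []
        for r in range(table.p):
            mask = table.rep == r
            with np.errstate(invalid="ignore"):
                m = np.nanmean(table.rates["match"][mask, r])
                nm = np.nanmean(table.rates["nonmatch"][mask, r])
            rows.append({"representation": r, "match": m, "nonmatch": nm,
                         "m_nm_index": _ratio(m, nm)})
        per_rep = pd.DataFrame(rows)

    return IndexSet(
        enhancement=_ratio(M_fg, S_fg),
        suppression=_ratio(M_bg, S_bg),
        match_nonmatch_foreground=_ratio(M_fg, NM_fg),
        match_nonmatch_background=_ratio(M_bg, NM_bg),
        per_representation=per_rep,
    )


def rate_engine_indices(match_trial: TrialResult, nonmatch_trial: TrialResult,
                        window: float = RESPONSE_WINDOW) -> IndexSet:
    """Match-effect indices from one rate-engine match + nonmatch trial pair.

    The rate model is population-symmetric, so a single pair determines the
    indices: sample and match responses come from the match trial; nonmatch
    responses come from the test epoch of the nonmatch trial, read from the
    test stimulus's representation (foreground) and from the representations
    that are neither sample nor test (background).
    """
    from . import ratemodel as rm

    def resp(trial, role):
        for e, t0, t1 in trial.epochs:
            if e.role == role:
                return rm.epoch_response(trial.traces, t0, window, epoch_end=t1), e
        raise ValueError(f"trial has no {role!r} epoch")

    p = match_trial.protocol.stim_params.n_stimuli
    S, sample_e = resp(match_trial, "sample")
    M, match_e = resp(match_trial, "match")
    fg = f"sel_{match_e.stimulus + 1}"
    bg_cols = [f"sel_{k + 1}" for k in range(p) if k != match_e.stimulus]
    NM, nm_e = resp(nonmatch_trial, "nonmatch")
    nm_fg = f"sel_{nm_e.stimulus + 1}"
    # background includes the sample's (persistently active) representation
    nm_bg_cols = [f"sel_{k + 1}" for k in range(p) if k != nm_e.stimulus]
    return IndexSet(
        enhancement=_ratio(M[fg], S[fg]),
        suppression=_ratio(float(M[bg_cols].mean()), float(S[bg_cols].mean())),
        match_nonmatch_foreground=_ratio(M[fg], NM[nm_fg]),
        match_nonmatch_background=_ratio(float(M[bg_cols].mean()),
                                         float(NM[nm_bg_cols].mean())),
    )


# --------------------------------------------------------------------------
# Suppression dominance
# --------------------------------------------------------------------------

def suppression_breakdown(table: ResponseTable) -> dict[str, float]:
    """Fractions of (cell, stimulus) pairs with match <, >, or == sample.

    Ties are almost exclusively combinations that emitted no spike in either
    response window — cells that never responded and therefore cannot be
    classified as suppressed or enhanced. ``suppressed_among_classified``
    restricts the denominator to the classifiable (non-tied) combinations,
    the convention of the single-unit studies these statistics mirror.
    """
    if "match" not in table.rates or "sample" not in table.rates:
        raise ValueError("need both match and sample responses")
    m, s = table.rates["match"], table.rates["sample"]
    valid = ~np.isnan(m) & ~np.isnan(s)
    if not valid.any():
        raise ValueError("no (cell, stimulus) pair has both match and sample responses")
    n = valid.sum()
    n_sup = int(np.sum(m[valid] < s[valid]))
    n_enh = int(np.sum(m[valid] > s[valid]))
    return {
        "suppressed": float(n_sup / n),
        "enhanced": float(n_enh / n),
        "tied": float(np.sum(m[valid] == s[valid]) / n),
        "suppressed_among_classified": (float(n_sup / (n_sup + n_enh))
                                        if n_sup + n_enh else float("nan")),
        "n_pairs": int(n),
    }


def fraction_suppressed(table: ResponseTable) -> float:
    """Fraction of (cell, stimulus) pairs whose mean match response is
    strictly below the mean sample response."""
    return suppression_breakdown(table)["suppressed"]


# --------------------------------------------------------------------------
# Tuning curves
# --------------------------------------------------------------------------

def tuning_curves(table: ResponseTable, roles=("sample", "match"),
                  rank_by: str = "sample") -> dict[str, np.ndarray]:
    """Per-neuron responses with stimuli ranked best-to-worst by the
    ``rank_by`` role; ties broken by stimulus id. Other roles are re-indexed
    by the same per-neuron ordering."""
    ref = table.rates[rank_by]
    # stable descending sort: ties keep ascending stimulus id; NaN ranks last
    order = np.argsort(-ref, axis=1, kind="stable")
    out = {}
    rows = np.arange(table.n_neurons)[:, None]
    for role in roles:
        out[role] = table.rates[role][rows, order]
    return out


# --------------------------------------------------------------------------
# Heterogeneity: epoch-response correlations
# --------------------------------------------------------------------------

def sample_delay_correlation(table: ResponseTable,
                             pair: tuple[str, str] = ("sample", "delay"),
                             min_valid: int = 3) -> dict[str, float]:
    """Mean per-neuron Pearson correlation between two epoch-response vectors.

    For every selective neuron, the responses across the stimulus set in the
    two roles are correlated; neurons with fewer than ``min_valid`` jointly
    observed stimuli or zero variance in either vector are excluded and
    counted.
    """
    a, b = (table.rates[r] for r in pair)
    rs, excluded = [], 0
    for i in range(table.n_neurons):
        valid = ~np.isnan(a[i]) & ~np.isnan(b[i])
        x, y = a[i, valid], b[i, valid]
        if valid.sum() < min_valid or x.std() == 0 or y.std() == 0:
            excluded += 1
            continue
        rs.append(np.corrcoef(x, y)[0, 1])
    return {
        "mean_r": float(np.mean(rs)) if rs else float("nan"),
        "n_neurons": len(rs),
        "n_excluded": excluded,
    }


def heterogeneity_correlations(params, sigma_s_values, n_trials: int = 2,
                               seed: int = 0,
                               alpha: float | None = None,
                               beta: float | None = None) -> pd.DataFrame:
    """Mean sample-delay and match-delay correlations across a sigma_S grid.

    For every stimulus-input SD in ``sigma_s_values``, draws a fresh quenched
    input structure (same seed, so only the heterogeneity changes), runs
    match trials for every stimulus on the spiking engine, and computes the
    neuron-averaged Pearson correlations between the per-stimulus response
    vectors of the sample (and match) epochs and the delay activity.
    """
    from .inputs import STANDARD_STIMULI, StimulusParameters, draw_quenched_inputs
    from .protocols import build_protocol, run_experiment

    if alpha is None:
        alpha = STANDARD_STIMULI.alpha
    if beta is None:
        beta = STANDARD_STIMULI.beta
    rows = []
    for sigma_s in sigma_s_values:
        stim = StimulusParameters(alpha=alpha, beta=beta, sigma_S=float(sigma_s),
                                  n_stimuli=params.p)
        inputs = draw_quenched_inputs(params, stim, seed=seed)
        protos = [build_protocol("match", s, stim_params=stim)
                  for s in range(params.p)]
        trials = run_experiment("spiking", protos, n_trials, params, inputs,
                                seed=seed)
        table = count_responses(trials)
        sd = sample_delay_correlation(table, ("sample", "delay"))
        md = sample_delay_correlation(table, ("match", "delay"))
        rows.append({"sigma_s": float(sigma_s),
                     "sample_delay_r": sd["mean_r"],
                     "match_delay_r": md["mean_r"],
                     "n_neurons": sd["n_neurons"],
                     "n_excluded": sd["n_excluded"]})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Grouped responses (repeating / non-repeating distractor protocols)
# --------------------------------------------------------------------------

def response_by_role_and_group(trials: list[TrialResult],
                               window: float = RESPONSE_WINDOW) -> pd.DataFrame:
    """Mean response per epoch role, split into the enhancement group (cells
    of the presented stimulus's representation) and the suppression group
    (cells of the other representations), with s.e.m. over trial-epochs."""
    obs: dict[tuple[str, str], list[float]] = {}
    for tr in trials:
        if tr.raster is None:
            raise ValueError("grouped responses need spiking trials")
        labels = tr.raster.labels
        p = tr.protocol.stim_params.n_stimuli
        n_sel = np.count_nonzero(labels < p)
        times, neurons = tr.raster.times, tr.raster.neurons
        for e, t0, t1 in tr.presentation_epochs():
            m = (times >= t0) & (times < t0 + window) & (neurons < n_sel)
            counts = np.bincount(neurons[m], minlength=n_sel)[:n_sel] / window
            in_rep = labels[:n_sel] == e.stimulus
            obs.setdefault((e.role, "enhancement"), []).append(counts[in_rep].mean())
            obs.setdefault((e.role, "suppression"), []).append(counts[~in_rep].mean())
    rows = []
    for (role, group), vals in sorted(obs.items()):
        v = np.asarray(vals)
        rows.append({"role": role, "group": group, "mean_rate": v.mean(),
                     "sem": v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0,
                     "n": v.size})
    return pd.DataFrame(rows)


def distractor_decay(experiments: dict[int, list[TrialResult]],
                     window: float = RESPONSE_WINDOW,
                     required=(0, 1, 2)) -> pd.DataFrame:
    """Mean match and nonmatch test responses of the suppressed populations
    as a function of the number of intervening distractors.

    For every trial the suppressed population is the set of selective cells
    outside the test stimulus's representation; its response in the first
    ``window`` of the test epoch is averaged within each trial, then across
    trials. The suppression magnitude is nonmatch minus match mean.
    """
    for n in required:
        if n not in experiments:
            raise ValueError(f"missing experiment for n_distractors = {n}")
    rows = []
    for n in sorted(experiments):
        per_kind: dict[str, list[float]] = {"match": [], "nonmatch": []}
        for tr in experiments[n]:
            if tr.raster is None:
                raise ValueError("distractor analysis needs spiking trials")
            labels = tr.raster.labels
            p = tr.protocol.stim_params.n_stimuli
            n_sel = np.count_nonzero(labels < p)
            times, neurons = tr.raster.times, tr.raster.neurons
            for e, t0, t1 in tr.presentation_epochs():
                if e.role not in ("match", "nonmatch"):
                    continue
                m = (times >= t0) & (times < t0 + window) & (neurons < n_sel)
                counts = np.bincount(neurons[m], minlength=n_sel)[:n_sel] / window
                out_rep = labels[:n_sel] != e.stimulus
                per_kind[e.role].append(counts[out_rep].mean())
        row = {"n_distractors": n}
        for kind, vals in per_kind.items():
            v = np.asarray(vals)
            row[f"{kind}_mean"] = v.mean() if v.size else np.nan
            row[f"{kind}_sem"] = (v.std(ddof=1) / np.sqrt(v.size)
                                  if v.size > 1 else np.nan)
            row[f"{kind}_n"] = v.size
        row["suppression_magnitude"] = row["nonmatch_mean"] - row["match_mean"]
        rows.append(row)
    return pd.DataFrame(rows)
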