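"""Stationary mean-field theory of the attractor network.

The stationary firing rate of a white-noise-driven LIF neuron with mean input
current mu and noise amplitude sigma is the Ricciardi transfer function

    Phi(mu, sigma) = 1 / ( tau_arp + tau_m * sqrt(pi) * int_b^a erfcx(-u) du ),
    a = (theta - mu)/sigma,  b = (V_R - mu)/sigma,

where erfcx(x) = exp(x^2) erfc(x) is the scaled complementary error function;
exp(u^2)(1 + erf(u)) = erfcx(-u), which keeps the integrand finite deep into
the subthreshold regime. Because external currents are quenched (drawn once
per neuron from a Gaussian with SD sigma_BG), population rates are Gaussian
averages of Phi over the external current. The self-consistency problem — the
rate of each population equals the quenched-averaged transfer of the mean
current the other populations impose on it — is solved by a damped
Newton-Raphson iteration with a finite-difference Jacobian.

Two parameterizations are used, mirroring the two stationary regimes:

* spontaneous: p + 2 populations (p selective, non-selective, inhibitory),
  all selective populations symmetric;
* delay: 4 populations (selective foreground sf, selective background sb,
  non-selective, inhibitory), where gamma representations (default 1) are in
  the foreground.

The noise entering Phi is the external fast-noise amplitude only; recurrent
spiking fluctuations are neglected, so the theory matches the spiking network
approximately, not exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss
from scipy.special import erfcx

from .parameters import NetworkParameters

__all__ = [
    "phi_transfer",
    "quenched_average_rate",
    "recurrent_currents_spontaneous",
    "recurrent_currents_delay",
    "recurrent_currents_full",
    "calibrate_external_currents",
    "solve_spontaneous",
    "solve_delay_state",
    "find_critical_j_plus",
    "scan_bifurcation",
    "MeanFieldSolution",
    "BifurcationBranch",
    "PhiBarTable",
    "SolverError",
    "calibrated",
    "population_rates",
]

_GL_ORDER = 96      # fixed-order Gauss-Legendre for the Phi integral
_GH_ORDER = 201     # fixed-order Gauss-Hermite for the quenched average

_gl_nodes, _gl_weights = leggauss(_GL_ORDER)
_gh_nodes, _gh_weights = hermgauss(_GH_ORDER)
_gh_weights = _gh_weights / np.sqrt(np.pi)   # weights of E[f(Z)], Z ~ N(0,1) at sqrt(2)*nodes


class SolverError(RuntimeError):
    """A fixed-point solver failed to converge."""


# --------------------------------------------------------------------------
# Transfer function and quenched averaging
# --------------------------------------------------------------------------

def phi_transfer(mu, sigma: float, tau_m: float, theta: float, V_R: float,
                 tau_arp: float):
    """Stationary LIF firing rate (Hz) at mean current ``mu`` (mV).

    Vectorized over ``mu``. ``sigma`` is the amplitude of the temporal
    fluctuations of the input current (mV) and must be positive.
    """
    if sigma <= 0:
        raise ValueError(f"phi_transfer requires sigma > 0, got {sigma}")
    mu = np.asarray(mu, dtype=float)
    a = (theta - mu) / sigma
    b = (V_R - mu) / sigma
    mid = 0.5 * (a + b)
    half = 0.5 * (a - b)          # = (theta - V_R) / (2 sigma) > 0, scalar spread
    # u grid: shape mu.shape + (order,)
    u = mid[..., None] + half[..., None] * _gl_nodes
    with np.errstate(over="ignore"):
        integrand = np.sqrt(np.pi) * erfcx(-u)
        integral = half[..., None] * integrand @ _gl_weights
        rate = 1.0 / (tau_arp + tau_m * integral)
    # deep subthreshold: integral overflows to inf -> rate underflows to 0
    rate = np.where(np.isfinite(integral), rate, 0.0)
    return rate if rate.ndim else float(rate)


def quenched_average_rate(mu_rec, mu_ext_mean, sigma_BG: float, sigma: float,
                          tau_m: float, theta: float, V_R: float, tau_arp: float):
    """Population rate with the external current Gaussian-averaged (Hz).

    Averages :func:`phi_transfer` over mu_ext ~ N(mu_ext_mean, sigma_BG^2)
    using fixed-order Gauss-Hermite quadrature; degenerates to a plain
    transfer-function evaluation when sigma_BG == 0. Vectorized over
    ``mu_rec``/``mu_ext_mean``.
    """
    if sigma_BG < 0:
        raise ValueError("sigma_BG must be non-negative")
    mu_rec = np.asarray(mu_rec, dtype=float)
    mu_ext_mean = np.asarray(mu_ext_mean, dtype=float)
    base = mu_rec + mu_ext_mean
    if sigma_BG == 0.0:
        return phi_transfer(base, sigma, tau_m, theta, V_R, tau_arp)
    mu = base[..., None] + np.sqrt(2.0) * sigma_BG * _gh_nodes
    rates = phi_transfer(mu, sigma, tau_m, theta, V_R, tau_arp)
    out = rates @ _gh_weights
    return out if np.ndim(out) else float(out)


# --------------------------------------------------------------------------
# Recurrent currents
# --------------------------------------------------------------------------

def recurrent_currents_full(nu_sel, nu_0: float, nu_I: float,
                            params: NetworkParameters):
    """Per-population mean recurrent currents, excitatory/inhibitory split.

    ``nu_sel`` holds the p selective-population rates (Hz). Returns two arrays
    of length p + 2 (ordering: selective 1..p, non-selective, inhibitory):
    the excitatory drive ``mu_E`` and the inhibitory drive ``mu_I`` (both mV,
    positive); the net recurrent current is ``mu_E - mu_I``.

    Synaptic structure: a selective target receives J_plus from its own
    representation and J_minus from every other excitatory source (other
    representations and non-selective cells); non-selective and inhibitory
    targets receive the unstructured baseline efficacies.
    """
    q = params
    nu_sel = np.asarray(nu_sel, dtype=float)
    if nu_sel.shape != (q.p,):
        raise ValueError(f"expected {q.p} selective rates, got shape {nu_sel.shape}")
    gp, gm = q.g_plus, q.g_minus
    f, p = q.f, q.p
    total_sel = nu_sel.sum()
    kEE = q.N_E * q.J_EE * q.tau_E
    mu_E = np.empty(p + 2)
    mu_I = np.empty(p + 2)
    # selective targets
    mu_E[:p] = kEE * (f * gp * nu_sel + f * gm * (total_sel - nu_sel)
                      + (1.0 - p * f) * gm * nu_0)
    mu_I[:p] = q.N_I * q.J_EI * q.tau_E * nu_I
    # non-selective target
    mu_E[p] = kEE * (f * total_sel + (1.0 - p * f) * nu_0)
    mu_I[p] = q.N_I * q.J_EI * q.tau_E * nu_I
    # inhibitory target
    mu_E[p + 1] = q.N_E * q.J_IE * q.tau_I * (f * total_sel + (1.0 - p * f) * nu_0)
    mu_I[p + 1] = q.N_I * q.J_II * q.tau_I * nu_I
    return mu_E, mu_I


def recurrent_currents_spontaneous(rates, params: NetworkParameters):
    """Net mean recurrent currents for the p+2 spontaneous-state populations.

    ``rates``: array (p+2,) ordered selective 1..p, non-selective, inhibitory.
    """
    rates = np.asarray(rates, dtype=float)
    mu_E, mu_I = recurrent_currents_full(rates[:params.p], rates[params.p],
                                         rates[params.p + 1], params)
    return mu_E - mu_I


def recurrent_currents_delay(rates, params: NetworkParameters, gamma: int = 1):
    """Net mean recurrent currents for the 4 delay-state populations.

    ``rates``: array (4,) ordered (sf, sb, non-selective, inhibitory); gamma
    representations are in the foreground, p - gamma in the background.
    """
    q = params
    nu_sf, nu_sb, nu_0, nu_I = np.asarray(rates, dtype=float)
    gp, gm = q.g_plus, q.g_minus
    f, p = q.f, q.p
    kEE = q.N_E * q.J_EE * q.tau_E
    inh_E = q.N_I * q.J_EI * q.tau_E * nu_I
    mu_sf = kEE * (f * nu_sf * (gp + (gamma - 1) * gm) + f * nu_sb * (p - gamma) * gm
                   + (1.0 - p * f) * gm * nu_0) - inh_E
    mu_sb = kEE * (f * nu_sf * gamma * gm + f * nu_sb * (gp + (p - gamma - 1) * gm)
                   + (1.0 - p * f) * gm * nu_0) - inh_E
    mu_0 = kEE * (f * nu_sf * gamma + f * nu_sb * (p - gamma)
                  + (1.0 - p * f) * nu_0) - inh_E
    mu_I = (q.N_E * q.J_IE * q.tau_I * (f * nu_sf * gamma + f * nu_sb * (p - gamma)
                                        + (1.0 - p * f) * nu_0)
            - q.N_I * q.J_II * q.tau_I * nu_I)
    return np.array([mu_sf, mu_sb, mu_0, mu_I])


# --------------------------------------------------------------------------
# Solutions and solvers
# --------------------------------------------------------------------------

@dataclass
class MeanFieldSolution:
    """A converged (or classified) fixed point of the self-consistency map."""

    rates: dict[str, float]
    mu_rec: dict[str, float]
    branch: str                  # "spontaneous" | "memory" | "unstable"
    residual_norm: float
    stable: bool = True

    def rate_vector(self) -> np.ndarray:
        return np.array(list(self.rates.values()))


@dataclass
class BifurcationBranch:
    """Delay-state fixed points along a grid of potentiation values."""

    j_plus: np.ndarray
    spontaneous: list[MeanFieldSolution]
    memory: list[MeanFieldSolution | None]
    unstable: list[MeanFieldSolution | None]
    critical_j_plus: float = field(default=float("nan"))

    def memory_rates(self) -> np.ndarray:
        return np.array([np.nan if s is None else s.rates["sf"] for s in self.memory])


def _damped_newton(F, x0, tol=1e-10, max_iter=200, fd_eps=1e-6):
    """Solve F(x) = 0 by Newton-Raphson with step halving; returns (x, ||F||_inf)."""
    x = np.asarray(x0, dtype=float).copy()
    fx = F(x)
    norm = np.max(np.abs(fx))
    for _ in range(max_iter):
        if norm < tol:
            return x, norm
        n = x.size
        J = np.empty((n, n))
        for j in range(n):
            dx = fd_eps * max(1.0, abs(x[j]))
            xp = x.copy()
            xp[j] += dx
            J[:, j] = (F(xp) - fx) / dx
        try:
            step = np.linalg.solve(J, -fx)
        except np.linalg.LinAlgError:
            raise SolverError("singular Jacobian in Newton-Raphson")
        lam = 1.0
        for _ in range(40):
            x_new = x + lam * step
            f_new = F(x_new)
            n_new = np.max(np.abs(f_new))
            if n_new < norm:
                break
            lam *= 0.5
        else:
            # no descent found: accept the full step once, may still converge
            x_new, f_new = x + step, F(x + step)
            n_new = np.max(np.abs(f_new))
        x, fx, norm = x_new, f_new, n_new
    if norm < tol:
        return x, norm
    raise SolverError(f"Newton-Raphson did not converge: last residual {norm:.3e} Hz")


def _phi_bar_E(params, mu_total_mean):
    return quenched_average_rate(0.0, mu_total_mean, params.sigma_BG, params.sigma,
                                 params.tau_E, params.theta, params.V_R, params.tau_arp)


def _phi_bar_I(params, mu_total_mean):
    return quenched_average_rate(0.0, mu_total_mean, params.sigma_BG, params.sigma,
                                 params.tau_I, params.theta, params.V_R, params.tau_arp)


def population_rates(params: NetworkParameters, mu_rec, mu_ext):
    """Quenched-averaged rates of the p+2 populations (last one inhibitory)."""
    q = params
    mu_rec = np.asarray(mu_rec, float)
    mu_ext = np.asarray(mu_ext, float)
    out = np.empty(mu_rec.shape)
    out[..., :-1] = quenched_average_rate(mu_rec[..., :-1], mu_ext[..., :-1],
                                          q.sigma_BG, q.sigma, q.tau_E,
                                          q.theta, q.V_R, q.tau_arp)
    out[..., -1] = quenched_average_rate(mu_rec[..., -1], mu_ext[..., -1],
                                         q.sigma_BG, q.sigma, q.tau_I,
                                         q.theta, q.V_R, q.tau_arp)
    return out


def calibrate_external_currents(params: NetworkParameters,
                                nu_E_sp: float | None = None,
                                nu_I_sp: float | None = None,
                                tol: float = 1e-10) -> tuple[float, float]:
    """Mean external currents (mu_ext_E, mu_ext_I) pinning the spontaneous rates.

    In the symmetric spontaneous state all excitatory populations fire at
    nu_E_sp and the inhibitory population at nu_I_sp; with the rates pinned,
    the recurrent currents are fixed numbers and the external means are the
    solution of two transfer-function inversions, solved here by
    Newton-Raphson (bracketed initial guess from a coarse scan).
    """
    q = params
    nu_E = q.nu_E_sp if nu_E_sp is None else nu_E_sp
    nu_I = q.nu_I_sp if nu_I_sp is None else nu_I_sp
    rates = np.array([nu_E] * (q.p + 1) + [nu_I])
    mu_rec = recurrent_currents_spontaneous(rates, q)
    mu_rec_E, mu_rec_I = mu_rec[0], mu_rec[-1]

    def F(x):
        return np.array([
            _phi_bar_E(q, mu_rec_E + x[0]) - nu_E,
            _phi_bar_I(q, mu_rec_I + x[1]) - nu_I,
        ])

    # coarse scan for a sensible starting point (Phi-bar is monotone in mu)
    grid = np.linspace(-5.0, q.theta + 10.0, 121)
    rE = _phi_bar_E(q, mu_rec_E + grid)
    rI = _phi_bar_I(q, mu_rec_I + grid)
    x0 = np.array([
        grid[np.argmin(np.abs(rE - nu_E))],
        grid[np.argmin(np.abs(rI - nu_I))],
    ])
    x, _ = _damped_newton(F, x0, tol=tol)
    return float(x[0]), float(x[1])


def _require_calibrated(params: NetworkParameters):
    if not params.is_calibrated:
        raise SolverError(
            "external currents are uncalibrated; run calibrate_external_currents "
            "and set mu_ext_E / mu_ext_I first"
        )


def _solution_from(rates, mu_rec, names, branch, residual, stable=True):
    return MeanFieldSolution(
        rates=dict(zip(names, map(float, rates))),
        mu_rec=dict(zip(names, map(float, mu_rec))),
        branch=branch, residual_norm=float(residual), stable=stable,
    )


def _spontaneous_map(params):
    q = params
    mu_ext = np.array([q.mu_ext_E] * (q.p + 1) + [q.mu_ext_I])

    def G(nu):
        mu_rec = recurrent_currents_spontaneous(nu, q)
        return population_rates(q, mu_rec, mu_ext) - nu

    return G, mu_ext


def solve_spontaneous(params: NetworkParameters, tol: float = 1e-10) -> MeanFieldSolution:
    """Symmetric spontaneous fixed point of the p+2 population system."""
    _require_calibrated(params)
    q = params
    G, _ = _spontaneous_map(q)
    x0 = np.array([q.nu_E_sp] * (q.p + 1) + [q.nu_I_sp])
    x, res = _damped_newton(G, x0, tol=tol)
    mu_rec = recurrent_currents_spontaneous(x, q)
    names = [f"sel_{k + 1}" for k in range(q.p)] + ["ns", "inh"]
    stable = _is_stable(G, x)
    return _solution_from(x, mu_rec, names, "spontaneous", res, stable)


def _delay_map(params, gamma):
    q = params
    mu_ext = np.array([q.mu_ext_E] * 3 + [q.mu_ext_I])

    def G(nu):
        mu_rec = recurrent_currents_delay(nu, q, gamma)
        return population_rates(q, mu_rec, mu_ext) - nu

    return G


def _is_stable(G, x, fd_eps=1e-6):
    """Stability of a fixed point of the surrogate dynamics nu_dot = G(nu)."""
    n = x.size
    J = np.empty((n, n))
    gx = G(x)
    for j in range(n):
        dx = fd_eps * max(1.0, abs(x[j]))
        xp = x.copy()
        xp[j] += dx
        J[:, j] = (G(xp) - gx) / dx
    return bool(np.all(np.linalg.eigvals(J).real < 0))


_DELAY_NAMES = ("sf", "sb", "ns", "inh")


def solve_delay_state(params: NetworkParameters, gamma: int = 1,
                      initial_guess=None, tol: float = 1e-10) -> MeanFieldSolution:
    """One fixed point of the 4-population delay system from a given guess.

    With the default memory-like guess the solver lands on the memory branch
    when it exists and otherwise falls back to the spontaneous solution; the
    returned solution's ``branch`` tag says which. Pass an explicit
    ``initial_guess`` to target a specific fixed point (e.g. the unstable one).
    """
    _require_calibrated(params)
    q = params
    G = _delay_map(q, gamma)
    if initial_guess is None:
        initial_guess = np.array([40.0, q.nu_E_sp, q.nu_E_sp, q.nu_I_sp])
    x, res = _damped_newton(G, np.asarray(initial_guess, float), tol=tol)
    mu_rec = recurrent_currents_delay(x, q, gamma)
    stable = _is_stable(G, x)
    if x[0] > 5.0 * q.nu_E_sp:
        branch = "memory" if stable else "unstable"
    else:
        branch = "spontaneous" if stable else "unstable"
    return _solution_from(x, mu_rec, _DELAY_NAMES, branch, res, stable)


def _memory_solution(params, gamma=1):
    """Memory-branch solution, or None when only the spontaneous state exists."""
    for guess_sf in (40.0, 80.0, 20.0, 120.0):
        try:
            sol = solve_delay_state(
                params, gamma,
                initial_guess=np.array([guess_sf, params.nu_E_sp,
                                        params.nu_E_sp, params.nu_I_sp]))
        except SolverError:
            continue
        if sol.branch == "memory":
            return sol
    return None


def find_critical_j_plus(params: NetworkParameters, lo: float | None = None,
                         hi: float | None = None, tol: float = 1e-5) -> float:
    """Smallest J_plus (mV) at which the memory branch exists, by bisection."""
    _require_calibrated(params)
    lo = params.J_EE if lo is None else lo
    hi = params.J_plus if hi is None else hi
    if _memory_solution(params.replace(J_plus=hi)) is None:
        raise SolverError(f"no memory state at the upper end J_plus = {hi}")
    if _memory_solution(params.replace(J_plus=lo)) is not None:
        raise SolverError(f"memory state already present at the lower end J_plus = {lo}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _memory_solution(params.replace(J_plus=mid)) is None:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def scan_bifurcation(params: NetworkParameters, j_plus_grid,
                     gamma: int = 1) -> BifurcationBranch:
    """Continuation of the delay-state fixed points along a J_plus grid.

    For each grid point the spontaneous solution, the memory solution (seeded
    from the previous grid point where available) and — where both exist — the
    intermediate unstable solution are computed. The critical J_plus is
    refined by bisection between the last absent and first present grid point.
    """
    _require_calibrated(params)
    j_plus_grid = np.asarray(j_plus_grid, dtype=float)
    spont, mem, unst = [], [], []
    prev_mem = None
    for jp in j_plus_grid:
        pj = params.replace(J_plus=float(jp))
        G = _delay_map(pj, gamma)
        s = solve_delay_state(pj, gamma,
                              initial_guess=np.array([pj.nu_E_sp] * 3 + [pj.nu_I_sp]))
        spont.append(s)
        guess = None if prev_mem is None else prev_mem.rate_vector()
        m = None
        if guess is not None:
            try:
                cand = solve_delay_state(pj, gamma, initial_guess=guess)
                m = cand if cand.branch == "memory" else None
            except SolverError:
                m = None
        if m is None:
            m = _memory_solution(pj, gamma)
        mem.append(m)
        prev_mem = m
        u = None
        if m is not None:
            # unstable saddle between the two stable branches
            midpoint = 0.5 * (m.rate_vector() + s.rate_vector())
            try:
                cand = solve_delay_state(pj, gamma, initial_guess=midpoint)
                if not cand.stable and cand.rates["sf"] > s.rates["sf"] + 1e-6:
                    u = cand
            except SolverError:
                u = None
        unst.append(u)
    branch = BifurcationBranch(j_plus_grid, spont, mem, unst)
    present = [jp for jp, m in zip(j_plus_grid, mem) if m is not None]
    absent = [jp for jp, m in zip(j_plus_grid, mem) if m is None]
    if present and absent and max(absent) < max(present):
        try:
            branch.critical_j_plus = find_critical_j_plus(
                params, lo=max(absent), hi=min(p for p in present if p > max(absent)))
        except SolverError:
            branch.critical_j_plus = min(present)
    elif present:
        branch.critical_j_plus = min(present)
    return branch


class PhiBarTable:
    """Cubic-spline tabulation of the quenched-averaged transfer function.

    The quenched average is a smooth 1-D function of the total mean current
    for a fixed neuron class; tabulating it once (interpolation error well
    below 1e-7 Hz at the default grid spacing) makes the rate-model inner
    loop cheap without changing the quadrature the fixed-point solvers use.
    Inputs outside the tabulated range fall back to direct quadrature.
    """

    def __init__(self, params: NetworkParameters, tau_m: float,
                 lo: float = -40.0, hi: float = 90.0, step: float = 0.04):
        from scipy.interpolate import CubicSpline
        q = params
        self._q = q
        self._tau_m = tau_m
        self._lo, self._hi = lo, hi
        grid = np.arange(lo, hi + step, step)
        vals = np.empty_like(grid)
        chunk = 2000
        for i in range(0, grid.size, chunk):
            g = grid[i:i + chunk]
            vals[i:i + chunk] = quenched_average_rate(
                0.0, g, q.sigma_BG, q.sigma, tau_m, q.theta, q.V_R, q.tau_arp)
        self._spline = CubicSpline(grid, vals)

    def __call__(self, mu_total_mean):
        mu = np.asarray(mu_total_mean, dtype=float)
        out = self._spline(np.clip(mu, self._lo, self._hi))
        oob = (mu < self._lo) | (mu > self._hi)
        if np.any(oob):
            q = self._q
            out = np.where(
                oob,
                quenched_average_rate(0.0, mu, q.sigma_BG, q.sigma, self._tau_m,
                                      q.theta, q.V_R, q.tau_arp),
                out,
            )
        return np.maximum(out, 0.0)


def calibrated(params: NetworkParameters) -> NetworkParameters:
    """Convenience: return a copy of ``params`` with mu_ext_E/I calibrated."""
    mu_E, mu_I = calibrate_external_currents(params)
    return params.replace(mu_ext_E=mu_E, mu_ext_I=mu_I)
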