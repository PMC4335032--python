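"""Model parameters and their validation.

The network is characterised by a small set of biophysical and architectural
constants: membrane and synaptic time constants, threshold/reset potentials,
synaptic efficacies (in mV, interpreted as the total post-synaptic charge a
single pre-synaptic spike deposits divided by the membrane time constant),
the architecture of the excitatory sub-network (p non-overlapping memory
representations, each a fraction f of the N_E excitatory cells), and the
target spontaneous rates used to calibrate the mean external drive.

Structured synaptic efficacies obey the balance constraint

    f * J_plus + (1 - f) * J_minus = J_EE

so that the depressed efficacy J_minus is derived, never set directly; the
constraint keeps the spontaneous state independent of the potentiation level.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "NetworkParameters",
    "ParameterError",
    "load_parameters",
    "fixture_scale",
    "TABLE1_PATH",
]

TABLE1_PATH = Path(__file__).with_name("table1.toml")

#: Fields that must be present in a configuration file (mu_ext_* are optional:
#: they are produced by mean-field calibration, not chosen by the user).
_REQUIRED_FIELDS = (
    "p", "f", "N_E", "N_I",
    "tau_E", "tau_I", "theta", "V_R", "tau_arp",
    "sigma", "sigma_BG", "sigma_S",
    "tau_AMPA", "tau_NMDA", "tau_GABA",
    "X_E", "X_I",
    "J_EE", "J_IE", "J_EI", "J_II", "J_plus",
    "nu_E_sp", "nu_I_sp",
    "dt_spiking", "dt_rate",
)


class ParameterError(ValueError):
    """A configuration is missing a key or violates a model invariant."""


@dataclass(frozen=True)
class NetworkParameters:
    """Full parameter set of the model.

    Units: potentials and currents in mV, times in s, rates in Hz.
    ``mu_ext_E``/``mu_ext_I`` are the mean external currents to excitatory and
    inhibitory cells; they default to ``None`` ("uncalibrated") and are set by
    :func:`matchnet.meanfield.calibrate_external_currents`.
    """

    p: int = 6                  # number of selective populations / stimuli
    f: float = 0.05             # coding level (fraction of N_E per representation)
    N_E: int = 1600
    N_I: int = 400
    tau_E: float = 0.02         # membrane time constants (s)
    tau_I: float = 0.01
    theta: float = 20.0         # firing threshold (mV)
    V_R: float = 10.0           # reset potential (mV)
    tau_arp: float = 0.0025     # absolute refractory period (s)
    sigma: float = 0.75         # fast (temporal) noise amplitude (mV)
    sigma_BG: float = 1.0       # quenched SD of the background external current (mV)
    sigma_S: float = 2.0        # quenched SD of the stimulus-evoked current (mV)
    tau_AMPA: float = 0.005     # synaptic decay constants (s)
    tau_NMDA: float = 0.05
    tau_GABA: float = 0.005
    X_E: float = 0.7            # NMDA charge fraction onto excitatory targets
    X_I: float = 0.002          # NMDA charge fraction onto inhibitory targets
    J_EE: float = 0.025         # baseline efficacies (mV)
    J_IE: float = 0.0625        # = 2.5 J_EE at defaults
    J_EI: float = 0.075         # = 3 J_EE
    J_II: float = 0.1           # = 4 J_EE
    J_plus: float = 0.156       # potentiated efficacy within a representation (mV)
    nu_E_sp: float = 0.75       # target spontaneous rates (Hz)
    nu_I_sp: float = 5.0
    dt_spiking: float = 1e-4    # Euler step of the spiking simulation (s)
    dt_rate: float = 1e-3       # Euler step of the rate dynamics (s)
    mu_ext_E: float | None = None   # mean external currents (mV), set by calibration
    mu_ext_I: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    # ---- derived quantities -------------------------------------------------

    @property
    def J_minus(self) -> float:
        """Depressed efficacy, from f*J_plus + (1-f)*J_minus = J_EE."""
        return (self.J_EE - self.J_plus * self.f) / (1.0 - self.f)

    @property
    def g_plus(self) -> float:
        return self.J_plus / self.J_EE

    @property
    def g_minus(self) -> float:
        return self.J_minus / self.J_EE

    @property
    def n_selective_per_pop(self) -> int:
        return round(self.f * self.N_E)

    @property
    def n_selective(self) -> int:
        """Total count of selective excitatory neurons (p*f*N_E; 480 at defaults)."""
        return self.p * self.n_selective_per_pop

    @property
    def rate_max(self) -> float:
        """Refractory-limited maximum firing rate 1/tau_arp (Hz)."""
        return 1.0 / self.tau_arp

    @property
    def is_calibrated(self) -> bool:
        return self.mu_ext_E is not None and self.mu_ext_I is not None

    # ---- validation ---------------------------------------------------------

    def validate(self) -> None:
        if not 0.0 < self.f < 1.0:
            raise ParameterError(f"coding level f must lie in (0, 1), got {self.f}")
        if self.p < 1 or self.p * self.f > 1.0 + 1e-12:
            raise ParameterError(
                f"p*f = {self.p * self.f:.4g} must not exceed 1 (non-overlapping representations)"
            )
        for name in ("tau_E", "tau_I", "tau_arp", "tau_AMPA", "tau_NMDA", "tau_GABA",
                     "dt_spiking", "dt_rate"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"time constant {name} must be positive")
        if self.theta <= self.V_R:
            raise ParameterError(f"threshold theta={self.theta} must exceed reset V_R={self.V_R}")
        for name in ("X_E", "X_I"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ParameterError(f"NMDA fraction {name}={x} must lie in [0, 1]")
        if self.sigma < 0:
            raise ParameterError("fast-noise amplitude sigma must be non-negative")
        if self.sigma_BG < 0 or self.sigma_S < 0:
            raise ParameterError("quenched noise SDs must be non-negative")
        if self.N_E < 1 or self.N_I < 1:
            raise ParameterError("N_E and N_I must be positive")
        nsel = self.f * self.N_E
        if abs(nsel - round(nsel)) > 1e-9:
            raise ParameterError(
                f"f*N_E = {nsel:.6g} must be an integer (whole neurons per representation)"
            )
        # balance constraint holds by construction; check it is consistent
        resid = self.f * self.J_plus + (1.0 - self.f) * self.J_minus - self.J_EE
        if abs(resid) > 1e-12 * max(1.0, abs(self.J_EE)):
            raise ParameterError("synaptic balance constraint violated")

    # ---- (de)serialization --------------------------------------------------

    def replace(self, **changes) -> "NetworkParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["mu_ext_E"] is None:
            del d["mu_ext_E"]
        if d.get("mu_ext_I") is None:
            d.pop("mu_ext_I", None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParameters":
        missing = [k for k in _REQUIRED_FIELDS if k not in d]
        if missing:
            raise ParameterError(f"configuration missing required key(s): {', '.join(missing)}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known - {"J_minus"}
        if unknown:
            raise ParameterError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
        kwargs = {k: v for k, v in d.items() if k in known}
        return cls(**kwargs)

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for k, v in self.to_dict().items():
            if isinstance(v, bool):
                lines.append(f"{k} = {str(v).lower()}")
            elif isinstance(v, int):
                lines.append(f"{k} = {v}")
            else:
                lines.append(f"{k} = {float(v)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    def digest(self) -> str:
        """Stable hex digest of the parameter values (for run manifests)."""
        import hashlib
        items = sorted(self.to_dict().items())
        blob = ";".join(f"{k}={v!r}" for k, v in items).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_parameters(source: str | Path | dict | None = None) -> NetworkParameters:
    """Load a validated :class:`NetworkParameters`.

    ``source`` may be a TOML file path, a dict of key/values, or ``None`` for
    the canonical defaults (shipped as ``table1.toml``).
    """
    if source is None:
        source = TABLE1_PATH
    if isinstance(source, dict):
        return NetworkParameters.from_dict(source)
    with open(source, "rb") as fh:
        data = tomllib.load(fh)
    return NetworkParameters.from_dict(data)


def fixture_scale(params: NetworkParameters, factor: int) -> NetworkParameters:
    """Shrink the network by an integer ``factor`` for fast tests.

    N_E and N_I are divided by ``factor`` while every synaptic efficacy is
    multiplied by it, keeping the products N*J — and therefore all mean-field
    rates — unchanged. f and p are preserved. Finite-size fluctuations grow
    roughly as sqrt(factor), so fixture networks are noisier than the full one.
    """
    if factor < 1:
        raise ParameterError("fixture scale factor must be >= 1")
    if params.N_E % factor or params.N_I % factor:
        raise ParameterError(f"factor {factor} must divide N_E={params.N_E} and N_I={params.N_I}")
    nsel = params.f * params.N_E / factor
    if abs(nsel - round(nsel)) > 1e-9:
        raise ParameterError(f"factor {factor} breaks whole-neuron representations")
    return params.replace(
        N_E=params.N_E // factor,
        N_I=params.N_I // factor,
        J_EE=params.J_EE * factor,
        J_IE=params.J_IE * factor,
        J_EI=params.J_EI * factor,
        J_II=params.J_II * factor,
        J_plus=params.J_plus * factor,
    )
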