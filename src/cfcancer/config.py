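"""Run configuration and the documented baseline fixture.

A :class:`RunConfig` bundles everything one solver run needs: the 16 model
rates, the 5-component initial state, the fractional order ``theta``, the
scheme name and the step/horizon. Configs serialize to a flat key-value
mapping (YAML or JSON) whose keys are exactly the field names, so files
round-trip bitwise.

The baseline fixture is an *assumed* parameter set: the source study prints
no baseline table, only the values swept in its figure captions. Where a
swept parameter has printed values the fixture takes the middle one; every
other rate is an assumed, documented choice of plausible magnitude. All
outputs label these values as assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .model import PARAM_NAMES, STATE_NAMES, ModelParameters, StateVector

__all__ = ["RunConfig", "ConfigError", "SCHEMES", "baseline_fixture", "config_to_dict", "config_from_dict"]

SCHEMES = ("ab2", "picard", "exact", "rk4")

_INITIAL_KEYS = tuple(f"{name}0" for name in STATE_NAMES)  # C_A0 .. C_E0


class ConfigError(ValueError):
    """Invalid run configuration; the message lists every violation."""


@dataclass(frozen=True)
class RunConfig:
    """A complete, validated solver-run specification."""

    params: ModelParameters
    y0: StateVector
    theta: float = 0.9
    scheme: str = "ab2"
    h: float = 0.01
    T: float = 50.0
    outdir: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        problems = []
        if self.scheme not in SCHEMES:
            problems.append(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if not 0.0 < self.theta <= 1.0:
            problems.append(
                f"theta = {self.theta} violates the fractional-order bound 0 < theta <= 1"
            )
        if not self.h > 0:
            problems.append(f"step h must be > 0, got {self.h}")
        if not self.T > 0:
            problems.append(f"horizon T must be > 0, got {self.T}")
        if problems:
            raise ConfigError("; ".join(problems))

    def replace(self, **changes) -> "RunConfig":
        return replace(self, **changes)


def baseline_fixture() -> RunConfig:
    """The documented default configuration (assumed values).

    Swept rates sit at the middle printed sweep value (delta_AD = 0.0651,
    delta_BD = 0.442, delta_BE = 0.631, delta_CD = 0.458, delta_CE = 0.396,
    delta_DE = 0.422); the remaining rates and the initial cohort are
    assumed. The fixture satisfies the contraction condition
    (mu1 = 0.1151 < 1) and its system matrix is nonsingular with all
    eigenvalue real parts negative.
    """
    params = ModelParameters(
        eta1=5.0,
        eta2=3.0,
        eta3=2.0,
        delta_AB=0.05,
        delta_AD=0.0651,
        delta_BC=0.1,
        delta_BD=0.442,
        delta_BE=0.631,
        delta_CD=0.458,
        delta_CE=0.396,
        delta_DB=0.02,
        delta_DC=0.02,
        delta_DE=0.422,
        gamma1=0.1,
        gamma2=0.05,
        gamma3=0.1,
    )
    y0 = StateVector(C_A=60.0, C_B=40.0, C_C=20.0, C_D=0.0, C_E=0.0)
    return RunConfig(params=params, y0=y0, theta=0.9, scheme="ab2", h=0.01, T=50.0)


def config_to_dict(config: RunConfig) -> dict:
    """Flatten a RunConfig to the serialized key-value form."""
    d: dict = dict(config.params.as_dict())
    d.update({f"{name}0": float(getattr(config.y0, name)) for name in STATE_NAMES})
    d.update(theta=config.theta, scheme=config.scheme, h=config.h, T=config.T)
    return d


def config_from_dict(d: dict) -> RunConfig:
    """Build and validate a RunConfig from its flat key-value form.

    Collects *all* violations (missing keys, extra keys, negative rates,
    theta out of range, bad scheme) into one :class:`ConfigError`.
    """
    expected = set(PARAM_NAMES) | set(_INITIAL_KEYS) | {"theta", "scheme", "h", "T"}
    got = set(d)
    problems = []
    missing = sorted(expected - got)
    extra = sorted(got - expected)
    if missing:
        problems.append(f"missing keys: {', '.join(missing)}")
    if extra:
        problems.append(f"unknown keys: {', '.join(extra)}")
    if problems:
        raise ConfigError("; ".join(problems))
    try:
        params = ModelParameters.from_dict(d)
    except ValueError as exc:
        problems.append(str(exc))
        params = None
    try:
        y0 = StateVector(**{name: float(d[f"{name}0"]) for name in STATE_NAMES})
    except ValueError as exc:
        problems.append(str(exc))
        y0 = None
    if params is not None and y0 is not None:
        try:
            return RunConfig(
                params=params, y0=y0,
                theta=float(d["theta"]), scheme=str(d["scheme"]),
                h=float(d["h"]), T=float(d["T"]),
            )
        except ConfigError as exc:
            problems.append(str(exc))
    raise ConfigError("; ".join(problems))
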