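"""Scenario sweeps over the fractional order and the transition rates.

The source study's simulation section varies one quantity at a time around
an unstated baseline: the fractional order ``theta`` (two value triples)
and six transition rates, each over three printed values, plus a
classical-vs-fractional comparison at ``theta = 0.9``. The sweeps are
reproduced here as presets named after the figures they correspond to
(``fig3`` .. ``fig11``, with ``fig8`` being the comparison); the non-swept
quantities are held at the assumed baseline fixture, which every result
records in its metadata.

The narrative claims about parameter influence are qualitative. The only
quantitative reading available is the sign of the equilibrium sensitivity
``sign(d C_i* / d rate)``, so they are encoded as an expectation table and
checked by central finite differences of the linear-solve equilibrium;
disagreements on a given parameter set are reported, never suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig, baseline_fixture
from .model import (
    PARAM_NAMES,
    STATE_NAMES,
    equilibrium_linear_solve,
    stability_eigenvalues,
)
from .solver import (
    Trajectory,
    solve_cf_ab2,
    solve_classical_ab2,
    solve_classical_rk4,
)

__all__ = [
    "SweepSpec",
    "SweepResult",
    "ComparisonResult",
    "SignTable",
    "SWEEP_PRESETS",
    "EXPECTED_DIRECTIONS",
    "sweep_preset",
    "run_sweep",
    "compare_orders",
    "equilibrium_sensitivity_signs",
]

# the printed sweep values, keyed by preset name (fig8 is the
# classical-vs-fractional comparison, handled by compare_orders)
SWEEP_PRESETS: dict[str, tuple[str, tuple[float, ...]]] = {
    "fig3": ("theta", (0.6, 0.8, 1.0)),
    "fig4": ("theta", (0.4, 0.5, 0.7)),
    "fig5": ("delta_AD", (0.0351, 0.0651, 0.0951)),
    "fig6": ("delta_BD", (0.242, 0.442, 0.642)),
    "fig7": ("delta_BE", (0.531, 0.631, 0.731)),
    "fig9": ("delta_CD", (0.358, 0.458, 0.558)),
    "fig10": ("delta_CE", (0.296, 0.396, 0.496)),
    "fig11": ("delta_DE", (0.311, 0.422, 0.533)),
}

# Directional narrative claims, encoded as expected signs of
# d C_i* / d rate. Comments record ambiguities of the narrative itself.
EXPECTED_DIRECTIONS: dict[str, dict[str, int]] = {
    "delta_AD": {"C_A": -1, "C_B": -1, "C_C": +1, "C_D": +1, "C_E": +1},
    # The narrative first states C_B decreases with delta_BD, then that
    # "the population level of C_B and C_E increases slightly" — mutually
    # contradictory for C_B; the first statement is kept here.
    "delta_BD": {"C_B": -1, "C_D": +1},
    "delta_BE": {"C_B": -1, "C_C": -1, "C_E": +1},
    # delta_CD: cardiac deaths up (C_E up), cancer deaths down (C_C down).
    "delta_CD": {"C_C": -1, "C_E": +1},
    "delta_CE": {"C_C": -1, "C_E": +1},
    # delta_DE drains the disease-free pool towards cardiotoxicity, cutting
    # the D->B and D->C backflow: cancer stages down, cardiotoxic up.
    "delta_DE": {"C_B": -1, "C_C": -1, "C_E": +1},
}


@dataclass(frozen=True)
class SweepSpec:
    """One-at-a-time sweep of ``theta`` or a named rate over given values."""

    target: str
    values: tuple[float, ...]
    base: RunConfig
    preset: str | None = None

    def __post_init__(self) -> None:
        if self.target != "theta" and self.target not in PARAM_NAMES:
            raise ValueError(f"unknown sweep target {self.target!r}")
        if len(self.values) == 0:
            raise ValueError("sweep needs at least one value")
        for v in self.values:
            if self.target == "theta":
                if not 0.0 < v <= 1.0:
                    raise ValueError(f"swept theta value {v} outside (0, 1]")
            elif v < 0:
                raise ValueError(f"swept rate {self.target} value {v} is negative")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))


@dataclass(frozen=True)
class SweepResult:
    """Per-value trajectories, terminal states and equilibria of a sweep."""

    spec: SweepSpec
    trajectories: tuple[Trajectory, ...]
    terminal_states: np.ndarray  # (n_values, 5)
    equilibria: np.ndarray  # (n_values, 5)
    sign_table: "SignTable | None"
    meta: dict = field(default_factory=dict, compare=False)


def sweep_preset(name: str, base: RunConfig | None = None) -> SweepSpec:
    """Build the SweepSpec for a named figure preset."""
    if name == "fig8":
        raise ValueError(
            "fig8 is the classical-vs-fractional comparison; use compare_orders()"
        )
    if name not in SWEEP_PRESETS:
        raise ValueError(f"unknown preset {name!r}; known: {sorted(SWEEP_PRESETS)} (+ fig8)")
    target, values = SWEEP_PRESETS[name]
    return SweepSpec(target=target, values=values, base=base or baseline_fixture(), preset=name)


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Integrate the model once per swept value with the CF-AB2 scheme.

    Everything not swept is held at the base configuration; the result
    metadata records that those values are assumed. For a rate sweep the
    equilibrium-sensitivity sign table of the swept rate is attached.
    """
    base = spec.base
    trajectories = []
    equilibria = []
    for v in spec.values:
        if spec.target == "theta":
            params, theta = base.params, v
        else:
            params, theta = base.params.replace(**{spec.target: v}), base.theta
        trajectories.append(solve_cf_ab2(params, base.y0, theta, h=base.h, T=base.T))
        equilibria.append(equilibrium_linear_solve(params))
    sign_table = None
    if spec.target != "theta":
        sign_table = equilibrium_sensitivity_signs(base.params, [spec.target])
    return SweepResult(
        spec=spec,
        trajectories=tuple(trajectories),
        terminal_states=np.array([t.terminal_state for t in trajectories]),
        equilibria=np.array(equilibria),
        sign_table=sign_table,
        meta={
            "preset": spec.preset,
            "target": spec.target,
            "values": list(spec.values),
            "non_swept": "held at the assumed baseline fixture",
            "eigenvalues_A_real": np.real(stability_eigenvalues(base.params)).tolist(),
        },
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Classical vs fractional run on identical inputs."""

    classical: Trajectory
    fractional: Trajectory
    sup_norm_diff: np.ndarray  # per compartment, shape (5,)
    terminal_diff: np.ndarray  # per compartment, shape (5,)


def compare_orders(
    params,
    y0,
    theta: float = 0.9,
    h: float = 0.01,
    T: float = 50.0,
    classical_scheme: str = "rk4",
) -> ComparisonResult:
    """Run the ordinary and the order-``theta`` fractional model side by side.

    The classical leg integrates the ordinary system with RK4 by default
    (``classical_scheme="ab2"`` selects classical two-step Adams-Bashforth,
    which at ``theta = 1`` reproduces the fractional leg bitwise). Reports
    per-compartment sup-norm and terminal differences; the difference at
    ``t = 0`` is exactly zero since both legs share the initial state.
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError(f"compare_orders requires 0 < theta <= 1, got {theta}")
    if classical_scheme == "rk4":
        classical = solve_classical_rk4(params, y0, h=h, T=T)
    elif classical_scheme == "ab2":
        classical = solve_classical_ab2(params, y0, h=h, T=T)
    else:
        raise ValueError(f"classical_scheme must be 'rk4' or 'ab2', got {classical_scheme!r}")
    fractional = solve_cf_ab2(params, y0, theta, h=h, T=T)
    diff = np.abs(classical.states - fractional.states)
    return ComparisonResult(
        classical=classical,
        fractional=fractional,
        sup_norm_diff=diff.max(axis=0),
        terminal_diff=classical.terminal_state - fractional.terminal_state,
    )


@dataclass(frozen=True)
class SignTable:
    """Signs of equilibrium sensitivities and their match to expectations.

    ``signs[target][compartment]`` is the sign (−1, 0, +1) of the central
    finite difference of the equilibrium with respect to the target rate.
    ``mismatches`` lists every (target, compartment, expected, observed)
    where an encoded narrative expectation disagrees — reported, never
    forced.
    """

    signs: dict[str, dict[str, int]]
    derivatives: dict[str, np.ndarray]
    mismatches: tuple[tuple[str, str, int, int], ...]

    @property
    def agrees(self) -> bool:
        return len(self.mismatches) == 0


def equilibrium_sensitivity_signs(
    params, targets, rel_step: float = 1e-6
) -> SignTable:
    """Signs of ``d C_i* / d rate`` by central differences of the linear solve.

    The stencil uses a relative step (absolute ``rel_step`` when the rate
    is zero). Raises if the system is singular anywhere on the stencil or
    if ``rel_step <= 0``.
    """
    if rel_step <= 0:
        raise ValueError(f"rel_step must be > 0, got {rel_step}")
    signs: dict[str, dict[str, int]] = {}
    derivatives: dict[str, np.ndarray] = {}
    mismatches: list[tuple[str, str, int, int]] = []
    for target in targets:
        if target not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {target!r}")
        v = getattr(params, target)
        step = rel_step * (abs(v) if v != 0 else 1.0)
        lo = max(v - step, 0.0)  # rates must stay nonnegative
        hi = v + step
        e_hi = equilibrium_linear_solve(params.replace(**{target: hi}))
        e_lo = equilibrium_linear_solve(params.replace(**{target: lo}))
        deriv = (e_hi - e_lo) / (hi - lo)
        derivatives[target] = deriv
        scale = np.maximum(np.abs(equilibrium_linear_solve(params)), 1.0)
        sig = {
            name: (0 if abs(d) <= 1e-9 * s else (1 if d > 0 else -1))
            for name, d, s in zip(STATE_NAMES, deriv, scale)
        }
        signs[target] = sig
        for comp, expected in EXPECTED_DIRECTIONS.get(target, {}).items():
            if sig[comp] != expected:
                mismatches.append((target, comp, expected, sig[comp]))
    return SignTable(signs=signs, derivatives=derivatives, mismatches=tuple(mismatches))
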