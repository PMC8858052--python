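"""Compartmental model of breast-cancer stage progression under chemotherapy.

Patients in a treatment cohort are partitioned into five compartments:

========  =====================================================
``C_A``   stages 1-2 (pooled: early-stage counts are smallest)
``C_B``   stage 3
``C_C``   stage 4
``C_D``   disease-free (responding to treatment)
``C_E``   cardiotoxic (chemotherapy-induced heart damage)
========  =====================================================

New patients enter the three cancer stages at recruitment rates
``eta1, eta2, eta3``; ten first-order transition rates ``delta_XY`` move
patients between compartments (e.g. ``delta_BE`` is the stage-3 ->
cardiotoxic rate); ``gamma2, gamma3`` are cancer death rates from stages 3
and 4 and ``gamma1`` is the cardiac death rate from the cardiotoxic state.
All rates are per unit time and nonnegative. The resulting vector field is
affine, ``dC/dt = A C + b``, with ``A`` Metzler (nonnegative off-diagonal),
so the flow preserves the nonnegative orthant.

The same right-hand side is used for the classical ODE system and for its
Caputo-Fabrizio fractional generalisation of order ``theta``; the fractional
system's fixed-point (Picard) analysis runs through the Lipschitz constants
of the five kernels, which for this linear field are exactly the
self-coupling magnitudes ``mu_1 .. mu_5`` computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from math import inf

import numpy as np

from .cf_core import cf_coefficients

__all__ = [
    "PARAM_NAMES",
    "STATE_NAMES",
    "ModelParameters",
    "StateVector",
    "LinearSystem",
    "EquilibriumExpansion",
    "ConditionReport",
    "EquilibriumError",
    "DegenerateEquilibriumError",
    "TranscriptionWarning",
    "vector_field",
    "build_linear_system",
    "equilibrium_linear_solve",
    "equilibrium_closed_form",
    "lipschitz_constants",
    "existence_uniqueness_check",
    "stability_eigenvalues",
]

STATE_NAMES = ("C_A", "C_B", "C_C", "C_D", "C_E")


class EquilibriumError(ValueError):
    """Raised when the model admits no unique equilibrium (singular A)."""


class DegenerateEquilibriumError(ZeroDivisionError):
    """Raised when a closed-form equilibrium denominator vanishes."""


class TranscriptionWarning(UserWarning):
    """The closed-form equilibrium expansion disagrees with the linear solve.

    The printed scalar expansions for the equilibrium are typeset without
    grouping and contain at least one apparent typo, so the transcription
    implemented here is advisory; the linear solve is the ground truth.
    """


@dataclass(frozen=True)
class ModelParameters:
    """The 16 nonnegative rates of the compartmental model.

    ``eta1..eta3`` are recruitment rates (patients per unit time) into
    ``C_A``, ``C_B``, ``C_C``; the ``delta_XY`` are transition rates from
    compartment X to Y; ``gamma1`` is the cardiac death rate from ``C_E``
    and ``gamma2, gamma3`` the cancer death rates from ``C_B``, ``C_C``.
    """

    eta1: float
    eta2: float
    eta3: float
    delta_AB: float
    delta_AD: float
    delta_BC: float
    delta_BD: float
    delta_BE: float
    delta_CD: float
    delta_CE: float
    delta_DB: float
    delta_DC: float
    delta_DE: float
    gamma1: float
    gamma2: float
    gamma3: float

    def __post_init__(self) -> None:
        bad = [
            f.name
            for f in fields(self)
            if not np.isfinite(getattr(self, f.name)) or getattr(self, f.name) < 0
        ]
        if bad:
            raise ValueError(f"model rates must be finite and >= 0; invalid: {', '.join(bad)}")

    # total outflow rates of the three cancer-stage compartments
    @property
    def k1(self) -> float:
        return self.delta_AD + self.delta_AB

    @property
    def k2(self) -> float:
        return self.delta_BD + self.delta_BC + self.delta_BE + self.gamma2

    @property
    def k3(self) -> float:
        return self.delta_CD + self.delta_CE + self.gamma3

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**{f.name: float(d[f.name]) for f in fields(cls)})

    def replace(self, **overrides) -> "ModelParameters":
        d = self.as_dict()
        d.update(overrides)
        return ModelParameters.from_dict(d)


PARAM_NAMES: tuple[str, ...] = tuple(f.name for f in fields(ModelParameters))


@dataclass(frozen=True)
class StateVector:
    """Patient counts per compartment; nonnegative at construction."""

    C_A: float
    C_B: float
    C_C: float
    C_D: float
    C_E: float

    def __post_init__(self) -> None:
        bad = [
            name
            for name in STATE_NAMES
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0
        ]
        if bad:
            raise ValueError(f"state components must be finite and >= 0; invalid: {', '.join(bad)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.C_A, self.C_B, self.C_C, self.C_D, self.C_E], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "StateVector":
        return cls(*(float(x) for x in np.asarray(arr, dtype=float)))

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in STATE_NAMES}


def as_state_array(state) -> np.ndarray:
    """Coerce a StateVector or 5-sequence to a float array of length 5."""
    if isinstance(state, StateVector):
        return state.as_array()
    arr = np.asarray(state, dtype=float)
    if arr.shape != (5,):
        raise ValueError(f"state must have 5 components, got shape {arr.shape}")
    return arr


def vector_field(state, params: ModelParameters) -> np.ndarray:
    """Right-hand sides (dC_A/dt, ..., dC_E/dt) of the compartmental model.

    These five affine expressions are also the kernels of the fractional
    system's Volterra reformulation. Written out term by term (not via the
    matrix form) so the two routes can be cross-checked.
    """
    ca, cb, cc, cd, ce = as_state_array(state)
    p = params
    return np.array(
        [
            p.eta1 - p.delta_AD * ca - p.delta_AB * ca,
            p.eta2 + p.delta_AB * ca + p.delta_DB * cd
            - p.delta_BD * cb - p.delta_BC * cb - p.delta_BE * cb - p.gamma2 * cb,
            p.eta3 + p.delta_BC * cb + p.delta_DC * cd
            - p.delta_CD * cc - p.delta_CE * cc - p.gamma3 * cc,
            p.delta_AD * ca + p.delta_BD * cb + p.delta_CD * cc
            - p.delta_DB * cd - p.delta_DC * cd - p.delta_DE * cd,
            p.delta_DE * cd + p.delta_CE * cc + p.delta_BE * cb - p.gamma1 * ce,
        ]
    )


@dataclass(frozen=True)
class LinearSystem:
    """Matrix/offset pair with ``vector_field(s) = A s + b``."""

    A: np.ndarray
    b: np.ndarray

    def __call__(self, state) -> np.ndarray:
        return self.A @ as_state_array(state) + self.b


def build_linear_system(params: ModelParameters) -> LinearSystem:
    """Affine restatement of the vector field: ``A`` Metzler, ``b >= 0``.

    Column sums of ``A`` are (0, -gamma2, -gamma3, 0, -gamma1): every
    internal transfer appears once with + and once with -, so only the
    death rates leak out of the total population balance.
    """
    p = params
    mu4 = p.delta_DB + p.delta_DC + p.delta_DE
    A = np.array(
        [
            [-p.k1, 0.0, 0.0, 0.0, 0.0],
            [p.delta_AB, -p.k2, 0.0, p.delta_DB, 0.0],
            [0.0, p.delta_BC, -p.k3, p.delta_DC, 0.0],
            [p.delta_AD, p.delta_BD, p.delta_CD, -mu4, 0.0],
            [0.0, p.delta_BE, p.delta_CE, p.delta_DE, -p.gamma1],
        ]
    )
    b = np.array([p.eta1, p.eta2, p.eta3, 0.0, 0.0])
    return LinearSystem(A=A, b=b)


def equilibrium_linear_solve(params: ModelParameters) -> np.ndarray:
    """Ground-truth equilibrium ``-A^{-1} b`` of the affine vector field.

    Raises :class:`EquilibriumError` naming the rank deficiency when ``A``
    is singular (no unique equilibrium).
    """
    sys = build_linear_system(params)
    rank = np.linalg.matrix_rank(sys.A)
    if rank < 5:
        raise EquilibriumError(
            f"no unique equilibrium: system matrix has rank {rank} < 5 (singular A)"
        )
    x = np.linalg.solve(sys.A, -sys.b)
    residual = np.linalg.norm(sys.A @ x + sys.b, ord=inf)
    if residual >= 1e-12 * (1.0 + np.linalg.norm(sys.b, ord=inf)):
        raise EquilibriumError(
            f"equilibrium solve is ill-conditioned: residual {residual:.3e}"
        )
    return x


@dataclass(frozen=True)
class EquilibriumExpansion:
    """Scalar combinations entering the printed closed-form equilibrium.

    ``k1, k2, k3`` are the stage outflow totals; ``alpha, beta, xi, v``
    are the numerators of the closed forms for ``C_B*, C_C*, C_D*, C_E*``
    and ``lam`` their shared denominator factor. ``discrepancy`` holds the
    per-component relative error against the linear-solve equilibrium
    (None when the cross-check could not run) and ``consistent`` is True
    when every component agrees within 1e-8 relative.
    """

    k1: float
    k2: float
    k3: float
    alpha: float
    beta: float
    xi: float
    v: float
    lam: float
    discrepancy: np.ndarray | None = field(default=None, compare=False)
    consistent: bool | None = field(default=None, compare=False)


def _expansion_scalars(p: ModelParameters) -> tuple[float, float, float, float, float]:
    """One literal reading of the printed equilibrium expansion.

    The source typesets these scalars without any grouping symbols and the
    ``v`` expression contains a bare ``eta`` (read here as ``eta1``), so the
    bracketing below is a documented best-effort reading, not an authority:
    :func:`equilibrium_closed_form` always cross-checks it against the
    linear solve and warns on disagreement.
    """
    d = p  # terse aliases keep the long products readable
    # recurring kernel of the alpha expression
    R = (d.delta_DE + d.delta_DC) * d.gamma3 + (d.delta_DE + d.delta_DC) * d.delta_CE \
        + d.delta_DE * d.delta_CD
    alpha = (
        (d.k3 * d.delta_BD + R) * (d.eta2 * d.delta_AB + d.k3 * d.eta1 + d.delta_CD * d.eta3 * d.delta_DB)
        + d.eta1 * R * d.delta_AB
        + d.delta_AD * ((d.k3 * d.delta_DB + R) * d.eta2 + (d.k3 * d.eta1 + d.delta_CD * d.eta3) * d.delta_DB)
    )
    beta = (
        (
            d.k2 * d.delta_DC
            + (d.delta_DB + d.delta_DE) * d.delta_BC
            + (d.gamma2 + d.delta_BD + d.delta_BE) * d.delta_DE
            + d.delta_DB * (d.gamma2 + d.delta_BE)
        )
        * d.k1
        * d.eta3
        + ((d.eta1 + d.eta2) * d.delta_BC + (d.gamma2 + d.delta_BD + d.delta_BE) * d.eta1 + d.delta_BD * d.eta2)
        * d.delta_DC
        + (d.eta2 * d.delta_DE + d.delta_DB * (d.eta1 + d.eta2) * d.delta_BC) * d.delta_AD
        + ((d.delta_BC + d.delta_BD) * d.delta_DC + (d.delta_DB + d.delta_DE) * d.delta_BC)
        * (d.eta1 + d.eta2)
        * d.delta_AB
    )
    xi = (
        (d.k2 * d.eta1 + (d.eta1 + d.eta3) * d.delta_BD + d.delta_BC * (d.eta2 + d.eta3))
        * (d.gamma2 + d.delta_BC + d.delta_BE)
        * d.delta_CD
        + (d.k2 * d.eta1 + d.delta_BD * d.eta2) * (d.gamma3 + d.delta_CE) * d.delta_AD
        + d.delta_AB
        * (
            (d.delta_BC + d.delta_BD) * (d.eta1 + d.eta2 + d.eta3) * d.delta_BD
            + d.delta_BC * (d.eta2 + d.eta3) * (d.gamma2 + d.delta_BC + d.delta_BE) * d.delta_CD
            + d.delta_BD * (d.eta1 + d.eta2) * (d.gamma3 + d.delta_CE)
        )
    )
    dd = d.delta_DB + d.delta_DC
    v = (
        (
            (d.eta1 + d.eta2 + d.eta3) * d.delta_BE
            + (d.gamma2 + d.delta_BC + d.delta_BD) * d.eta1
            + (d.delta_BC + d.delta_BD) * (d.eta2 + d.eta3) * d.gamma2
            + (d.delta_BC + d.delta_BD) * d.delta_DE
        )
        * d.delta_AD
        * d.delta_CE
        + (
            dd * (d.eta1 + d.eta2 + d.eta3) * d.delta_BE
            + dd * (d.delta_BC + d.delta_DC * d.gamma2 + d.delta_BD) * d.eta1
            + (d.delta_BD + d.delta_DC) * (d.delta_BC + d.delta_BD) * d.delta_DC * d.eta2
            + dd * (d.delta_BC + d.gamma2) * dd * d.gamma2
            + d.delta_BD * d.eta3
        )
        * d.delta_AD
        * d.delta_CE
        + (
            (d.eta1 + d.eta2 + d.eta3) * d.delta_BE  # bare "eta" in print, read as eta1
            + (d.delta_BC + d.delta_BD) * d.eta1
            + (d.delta_BC + d.delta_BD) * (d.eta2 + d.eta3) * d.gamma2
            + (d.delta_BC + d.delta_BD) * d.delta_DE
        )
        * d.delta_AB
        * d.delta_CE
        + (
            dd * (d.eta1 + d.eta2 + d.eta3) * d.delta_BE
            + dd * (d.delta_BC + d.delta_BD) * d.delta_DC * d.eta1
        )
        * d.delta_AB
        * d.delta_CE
        + (
            dd * (d.delta_BC + d.delta_BD) * d.delta_DC * d.eta2
            + dd * (d.delta_BC + d.gamma2) * dd * d.gamma2
            + d.delta_BD * d.eta3
        )
        * d.delta_AB
        * d.delta_CE
        + d.delta_DE
        * d.delta_AD
        * (
            (d.gamma3 + d.delta_CD) * d.eta1
            + (d.gamma3 + d.delta_CD) * d.eta2
            + d.eta3 * d.delta_CD * d.delta_BE
            + (d.gamma3 + d.delta_CD) * (d.gamma2 + d.delta_BC + d.delta_BD) * d.eta1
            + (d.delta_BC + d.delta_BD) * (d.delta_DC + d.gamma3) * d.delta_BD * d.eta2
            + d.eta3 * d.delta_CD * (d.gamma2 + d.delta_BC + d.delta_BD)
        )
        + d.delta_BE
        * (d.gamma3 + d.delta_CD)
        * d.delta_DB
        * d.eta1
        + (d.delta_DB * d.delta_CD + d.gamma3 * (d.delta_DB + d.delta_DC)) * d.eta2 * d.delta_AD
        + d.eta3 * d.delta_CD * d.delta_DB * d.delta_AD
        + d.delta_AB
        * d.delta_DE
        * (
            (d.gamma3 + d.delta_CD) * d.eta1
            + (d.gamma3 + d.delta_CD) * d.eta2
            + d.eta3 * d.delta_CD * d.delta_BE * (d.delta_BC + d.delta_BD)
            + (d.delta_CD + d.gamma3) * d.delta_BD * d.eta1
        )
        + d.delta_AB
        * d.delta_DE
        * (
            (d.delta_BC + d.delta_BD) * (d.delta_CD + d.gamma3) * d.delta_BD * d.eta2
            + d.eta3 * d.delta_CD * (d.gamma2 + d.delta_BC + d.delta_BD + d.delta_BE)
        )
        + d.delta_AB
        * d.delta_BD
        * (
            (d.delta_CD + d.gamma3) * (d.delta_DB + d.delta_DC) * d.eta1
            + (d.delta_DB * d.delta_CD + d.gamma3 * (d.delta_DB + d.delta_DC)) * d.eta2
            + d.eta3 * d.delta_CD * d.delta_DB
        )
    )
    # shared denominator factor; P is the recurring inner bracket
    P = (
        d.k2 * d.delta_DE
        + (d.delta_DB + d.delta_DC) * d.gamma2
        + (d.delta_DB + d.delta_DC) * d.delta_BE
        + d.delta_BC * d.delta_DB
        + (d.delta_BC + d.delta_BD) * d.delta_DC
    )
    lam = d.k1 * (
        P * d.gamma3
        + (P - d.k2 * d.delta_DE) * d.delta_CE
        + d.delta_CD * d.delta_DB * (d.gamma2 + d.delta_BE)
    )
    return alpha, beta, xi, v, lam


def equilibrium_closed_form(
    params: ModelParameters,
) -> tuple[np.ndarray, EquilibriumExpansion]:
    """Closed-form equilibrium from the printed scalar expansion.

    Returns ``(C_A*, ..., C_E*)`` with ``C_A* = eta1/k1`` (this first
    component follows from the decoupled stage-1/2 balance and is exact)
    and the remaining components from the transcribed expansion. The
    result is cross-checked against :func:`equilibrium_linear_solve`; a
    :class:`TranscriptionWarning` with per-component relative errors is
    emitted when any component disagrees by more than 1e-8 relative.
    """
    p = params
    if p.k1 == 0.0:
        raise DegenerateEquilibriumError("k1 = delta_AD + delta_AB = 0: C_A* undefined")
    if p.gamma1 == 0.0:
        raise DegenerateEquilibriumError("gamma1 = 0: C_E* undefined (division by zero)")
    alpha, beta, xi, v, lam = _expansion_scalars(p)
    if lam == 0.0:
        raise DegenerateEquilibriumError("lambda = 0: closed-form equilibrium undefined")
    state = np.array(
        [
            p.eta1 / p.k1,
            alpha / (p.k1 * lam),
            beta / (p.k1 * lam),
            xi / (p.k1 * lam),
            v / (p.k1 * lam * p.gamma1),
        ]
    )
    discrepancy = None
    consistent = None
    try:
        reference = equilibrium_linear_solve(p)
    except EquilibriumError:
        reference = None
    if reference is not None:
        scale = np.maximum(np.abs(reference), 1.0)
        discrepancy = np.abs(state - reference) / scale
        consistent = bool(np.all(discrepancy <= 1e-8))
        if not consistent:
            per_comp = ", ".join(
                f"{name}: {err:.2e}" for name, err in zip(STATE_NAMES, discrepancy)
            )
            warnings.warn(
                "closed-form equilibrium transcription disagrees with the linear "
                f"solve (relative errors {per_comp}); trust the linear solve",
                TranscriptionWarning,
                stacklevel=2,
            )
    expansion = EquilibriumExpansion(
        k1=p.k1, k2=p.k2, k3=p.k3, alpha=alpha, beta=beta, xi=xi, v=v, lam=lam,
        discrepancy=discrepancy, consistent=consistent,
    )
    return state, expansion


@dataclass(frozen=True)
class ConditionReport:
    """Lipschitz constants and fixed-point existence/uniqueness flags.

    ``mu1..mu5`` are the Lipschitz constants of the five Volterra kernels
    in their own state argument. The contraction analysis is driven by
    ``mu1``: ``t0_max`` is the largest horizon on which the Picard map is
    a guaranteed contraction, ``existence_ok`` requires the evaluation
    horizon ``t`` to lie strictly inside it, and ``uniqueness_ok`` checks
    ``1 - c1 mu1 - c2 mu1 t > 0`` with ``(c1, c2) = (1-theta, theta)``.
    """

    mu1: float
    mu2: float
    mu3: float
    mu4: float
    mu5: float
    theta: float | None = None
    t: float | None = None
    contraction_ok: bool | None = None
    t0_max: float | None = None
    existence_ok: bool | None = None
    uniqueness_ok: bool | None = None

    @property
    def mus(self) -> np.ndarray:
        return np.array([self.mu1, self.mu2, self.mu3, self.mu4, self.mu5])


def lipschitz_constants(params: ModelParameters) -> ConditionReport:
    """Lipschitz constants ``mu_i`` of the five kernels.

    The kernels are affine, so the exact Lipschitz constant of kernel ``i``
    in its own state is the magnitude of its self-coupling coefficient:
    ``mu1 = delta_AD + delta_AB = k1``, ``mu2 = k2``, ``mu3 = k3``,
    ``mu4 = delta_DB + delta_DC + delta_DE`` and ``mu5 = gamma1``.
    """
    p = params
    return ConditionReport(
        mu1=p.k1,
        mu2=p.k2,
        mu3=p.k3,
        mu4=p.delta_DB + p.delta_DC + p.delta_DE,
        mu5=p.gamma1,
    )


def existence_uniqueness_check(
    params: ModelParameters, theta: float, t: float
) -> ConditionReport:
    """Evaluate the fixed-point existence and uniqueness conditions.

    With ``c1 = 1 - theta`` and ``c2 = theta``: the Picard kernels are
    contractions iff ``mu1 < 1``; the guaranteed-existence horizon is
    ``t0_max = (1 - c1 mu1) / (c2 mu1)`` (infinite when ``mu1 = 0``, zero
    when ``c1 mu1 >= 1``); existence holds for ``t < t0_max`` and
    uniqueness for ``1 - c1 mu1 - c2 mu1 t > 0`` (the same threshold,
    strictly).
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError(f"existence check requires 0 < theta <= 1, got {theta}")
    if t < 0:
        raise ValueError(f"time horizon must be >= 0, got {t}")
    base = lipschitz_constants(params)
    c1, c2 = 1.0 - theta, theta
    mu1 = base.mu1
    if mu1 == 0.0:
        t0_max = inf
    elif c1 * mu1 < 1.0:
        t0_max = (1.0 - c1 * mu1) / (c2 * mu1)
    else:
        t0_max = 0.0
    return ConditionReport(
        mu1=base.mu1,
        mu2=base.mu2,
        mu3=base.mu3,
        mu4=base.mu4,
        mu5=base.mu5,
        theta=theta,
        t=t,
        contraction_ok=bool(0.0 <= mu1 < 1.0),
        t0_max=t0_max,
        existence_ok=bool(t < t0_max),
        uniqueness_ok=bool(1.0 - c1 * mu1 - c2 * mu1 * t > 0.0),
    )


def stability_eigenvalues(params: ModelParameters) -> np.ndarray:
    """Eigenvalues of the system matrix ``A`` (supplementary diagnostic).

    Linear stability of the equilibrium is not part of the fixed-point
    analysis above; this is extra metadata for scenario reporting. All
    real parts negative means every trajectory relaxes to the unique
    equilibrium.
    """
    return np.linalg.eigvals(build_linear_system(params).A)


def _check_coefficient_identity(theta: float) -> float:
    """|c1 + c2 - 1| for the unsimplified CF coefficients (test hook)."""
    c1, c2 = cf_coefficients(theta)
    return abs(c1 + c2 - 1.0)
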