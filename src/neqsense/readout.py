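"""Time integration of sensor states by a finite readout population.

The two-sensor complex is extended with a pool of ``r in {0, ..., r0}``
readout molecules whose activation (``r -> r+1``) and decay (``r -> r-1``)
rates depend on the sensor states through the differential readout
potentials ``dmu_i``:

    Gamma(S -> S^i | r, H) = exp[-beta s_i (h_i - b_i + J_ij s_j + dmu_i r)]
    Gamma(r -> r±1 | S, H) = exp[±(beta/2) (dmu_1 s_1 + dmu_2 s_2)]

with the reparametrisation ``dmu_1 = (Delta + delta)/2``,
``dmu_2 = (Delta - delta)/2``: ``Delta`` sets how different the correlated
states ``++`` and ``--`` look to the readout, ``delta`` distinguishes the
anticorrelated states ``+-`` and ``-+``.  The sensor biases are fixed to
``b_i = dmu_i r0 / 2``, centring the readout feedback on the middle of the
population range so that the full range of readout states is used.

Moves that would leave ``[0, r0]`` carry zero rate (reflecting boundaries),
the unique probability-conserving choice on a finite population without
extra states.  The readout performs time integration: in steady state the
population is a stochastic running record of past sensor states.  For a
symmetric coupling (t = 0) the joint chain is in equilibrium, the
conditional ``P(r | S, H)`` is independent of ``H``, and the data-processing
inequality ``I(S; H) >= I(r; H)`` binds; a nonzero drive breaks the Markov
chain ``H -> S -> r`` and lets the readout exceed the equilibrium optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .core import (
    STATES,
    Signal,
    SensorParams,
    state_index,
    steady_state_numeric,
    _softmax,
)
from .information import SignalPrior, entropy

__all__ = [
    "ReadoutParams",
    "build_joint_rate_matrix",
    "joint_steady_state",
    "equilibrium_closed_form",
    "joint_conditionals",
    "readout_mutual_information",
    "conditional_mean_readout",
    "factorization_deviation",
    "dpi_check",
    "DPIReport",
    "optimize_readout_strategy",
]

_S1 = np.array([s for s, _ in STATES], dtype=float)
_S2 = np.array([s for _, s in STATES], dtype=float)


@dataclass(frozen=True)
class ReadoutParams:
    """Readout population size and differential potentials.

    ``r0`` is the maximum population, ``Delta`` and ``delta`` parametrise
    the potentials ``dmu_1 = (Delta + delta)/2``, ``dmu_2 = (Delta -
    delta)/2`` so that the effective chemical potential ``mu_S = dmu_1 s_1 +
    dmu_2 s_2`` takes the values ``mu_++ = -mu_-- = Delta`` and ``mu_+- =
    -mu_-+ = delta``.  The derived sensor biases ``b_i = dmu_i r0 / 2``
    centre the readout feedback term.
    """

    r0: int = 10
    Delta: float = 1.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.r0 < 1 or self.r0 != int(self.r0):
            raise ValueError("r0 must be a positive integer")

    @property
    def dmu1(self) -> float:
        return 0.5 * (self.Delta + self.delta)

    @property
    def dmu2(self) -> float:
        return 0.5 * (self.Delta - self.delta)

    @property
    def biases(self) -> tuple[float, float]:
        return (0.5 * self.dmu1 * self.r0, 0.5 * self.dmu2 * self.r0)

    @property
    def n_states(self) -> int:
        return 4 * (self.r0 + 1)

    def joint_index(self, r: int, s: tuple[int, int]) -> int:
        """Canonical index of joint state (r, S): ``4 r + state_index(S)``."""
        return 4 * r + state_index(*s)


def _check_sensor_params(params: SensorParams) -> None:
    if params.b1 != 0.0 or params.b2 != 0.0:
        raise ValueError(
            "sensor biases in the readout model are fixed to b_i = dmu_i r0/2 "
            "by ReadoutParams; leave SensorParams biases at zero"
        )


def build_joint_rate_matrix(
    signal: Signal, params: SensorParams, readout: ReadoutParams
) -> np.ndarray:
    """Generator on the ``4 (r0 + 1)`` joint states (column convention).

    Sensor flips act within each readout level with the feedback term
    ``dmu_i r``; readout steps couple adjacent levels with rates set by the
    current sensor state.  Moves out of ``[0, r0]`` have zero rate.  As in
    the sensor-only generator, all rates share one overall timescale chosen
    so that the largest rate is 1.
    """
    _check_sensor_params(params)
    r0 = readout.r0
    b1, b2 = readout.biases
    dmu1, dmu2 = readout.dmu1, readout.dmu2
    n = readout.n_states
    logW = np.full((n, n), -np.inf)
    for r in range(r0 + 1):
        for k, (s1, s2) in enumerate(STATES):
            j = 4 * r + k
            # sensor flips within readout level r
            i = 4 * r + state_index(-s1, s2)
            logW[i, j] = -params.beta * s1 * (
                signal.h1 - b1 + params.J12 * s2 + dmu1 * r
            )
            i = 4 * r + state_index(s1, -s2)
            logW[i, j] = -params.beta * s2 * (
                signal.h2 - b2 + params.J21 * s1 + dmu2 * r
            )
            # readout activation / decay, reflecting at the boundaries
            mu = dmu1 * s1 + dmu2 * s2
            if r < r0:
                logW[4 * (r + 1) + k, j] = 0.5 * params.beta * mu
            if r > 0:
                logW[4 * (r - 1) + k, j] = -0.5 * params.beta * mu
    shift = np.max(logW[np.isfinite(logW)])
    W = np.exp(logW - shift)
    np.fill_diagonal(W, 0.0)
    np.fill_diagonal(W, -W.sum(axis=0))
    return W


def joint_steady_state(W: np.ndarray) -> np.ndarray:
    """Stationary joint distribution from the SVD null space of ``W``."""
    return steady_state_numeric(W)


def _joint_log_weights_eq(
    h1: np.ndarray, h2: np.ndarray, params: SensorParams, readout: ReadoutParams
) -> np.ndarray:
    """Equilibrium log weights, shape (..., r0+1, 4)."""
    b1, b2 = readout.biases
    r = np.arange(readout.r0 + 1, dtype=float)[:, None]
    h1 = np.asarray(h1, dtype=float)[..., None, None]
    h2 = np.asarray(h2, dtype=float)[..., None, None]
    mu = readout.dmu1 * _S1 + readout.dmu2 * _S2
    return params.beta * (
        (h1 - b1) * _S1 + (h2 - b2) * _S2 + params.J * _S1 * _S2 + mu * r
    )


def equilibrium_closed_form(
    signal: Signal, params: SensorParams, readout: ReadoutParams
) -> np.ndarray:
    """Boltzmann joint distribution ``exp(-beta F(r, S))/Z`` at ``t = 0``.

    The free energy separates into a signal-sensor part and a
    sensor-readout part, so ``P(r | S, H)`` is independent of ``H`` — the
    Markov-chain structure behind the data-processing inequality.
    """
    _check_sensor_params(params)
    if params.t != 0.0:
        raise ValueError("equilibrium closed form requires t = 0")
    logw = _joint_log_weights_eq(signal.h1, signal.h2, params, readout)
    flat = logw.reshape(-1)
    return _softmax(flat)


def joint_conditionals(
    prior: SignalPrior,
    params: SensorParams,
    readout: ReadoutParams,
    force_numeric: bool = False,
) -> np.ndarray:
    """Joint conditionals ``P(r, S | h)`` at every prior node.

    Shape ``(n_nodes, r0+1, 4)``.  At ``t = 0`` the Boltzmann form is
    evaluated vectorised over nodes; otherwise (or with ``force_numeric``)
    each node is solved by the null-space method on the full joint chain.
    """
    _check_sensor_params(params)
    n = len(prior.weights)
    if params.t == 0.0 and not force_numeric:
        logw = _joint_log_weights_eq(
            prior.nodes[:, 0], prior.nodes[:, 1], params, readout
        )
        flat = _softmax(logw.reshape(n, -1))
        return flat.reshape(n, readout.r0 + 1, 4)
    out = np.empty((n, readout.r0 + 1, 4))
    for k, (h1, h2) in enumerate(prior.nodes):
        W = build_joint_rate_matrix(Signal(float(h1), float(h2)), params, readout)
        out[k] = joint_steady_state(W).reshape(readout.r0 + 1, 4)
    return out


class ReadoutMI(NamedTuple):
    I_rH: float
    I_SH: float


def _marginal_mi(weights: np.ndarray, conditionals: np.ndarray) -> float:
    p_out = weights @ conditionals
    return float(entropy(p_out) - weights @ entropy(conditionals, axis=-1))


def readout_mutual_information(
    prior: SignalPrior,
    params: SensorParams,
    readout: ReadoutParams,
    conditionals: Optional[np.ndarray] = None,
) -> ReadoutMI:
    """Mutual informations I(r; H) and I(S; H) of the joint steady state.

    Both are computed from marginals of the same joint conditionals, so in
    equilibrium they satisfy the data-processing inequality
    ``I(S; H) >= I(r; H)`` exactly (up to quadrature round-off).
    """
    if conditionals is None:
        conditionals = joint_conditionals(prior, params, readout)
    p_r = conditionals.sum(axis=2)   # (n, r0+1)
    p_s = conditionals.sum(axis=1)   # (n, 4)
    return ReadoutMI(
        I_rH=max(_marginal_mi(prior.weights, p_r), 0.0),
        I_SH=max(_marginal_mi(prior.weights, p_s), 0.0),
    )


def conditional_mean_readout(
    h_values: np.ndarray, params: SensorParams, readout: ReadoutParams
) -> np.ndarray:
    """Mean readout population E[r | h] along perfectly correlated signals."""
    from .information import custom_prior

    h = np.asarray(h_values, dtype=float)
    prior = custom_prior(
        np.column_stack([h, h]), np.full(h.shape, 1.0 / h.size)
    )
    cond = joint_conditionals(prior, params, readout)
    p_r = cond.sum(axis=2)
    r = np.arange(readout.r0 + 1, dtype=float)
    return p_r @ r


def factorization_deviation(
    prior: SignalPrior, params: SensorParams, readout: ReadoutParams
) -> float:
    """Max deviation of ``P(r | S, h)`` from its signal average.

    Zero (to solver precision) in equilibrium, where the joint free energy
    separates; a nonzero drive couples readout statistics to the signal
    beyond the sensor state and the factorisation fails.  Conditionals are
    obtained from the numeric null-space solver so the check also exercises
    the solver itself.  States with negligible probability (< 1e-10) are
    excluded from the comparison.
    """
    cond = joint_conditionals(prior, params, readout, force_numeric=True)
    p_s = cond.sum(axis=1)  # (n, 4)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_r_given_s = cond / p_s[:, None, :]
    mask = p_s > 1e-10
    ref = np.nanmean(np.where(mask[:, None, :], p_r_given_s, np.nan), axis=0)
    dev = np.abs(p_r_given_s - ref)
    dev = np.where(mask[:, None, :], dev, 0.0)
    return float(np.nanmax(dev))


@dataclass(frozen=True)
class DPIReport:
    """Result of a randomized data-processing-inequality audit."""

    n_draws: int
    passed: bool
    min_margin_bits: float          # min over draws of I(S;H) - I(r;H)
    max_factorization_dev: float
    failures: tuple[dict, ...] = ()


def dpi_check(
    prior: SignalPrior,
    n_draws: int = 100,
    seed: int = 0,
    r0: int = 10,
    margin_tol: float = 1e-9,
    factorization_tol: float = 1e-9,
    n_factorization_draws: int = 5,
) -> DPIReport:
    """Audit ``I(S; H) >= I(r; H)`` over random equilibrium complexes.

    Draws ``(beta, J, Delta, delta)`` at ``t = 0`` and checks the inequality
    on each; for a subset of draws the factorisation ``P(r | S, H) =
    P(r | S)`` is verified through the numeric solver.  Any violation is
    reported with the offending parameters (it would indicate a solver bug,
    since the inequality is an identity of the equilibrium model).
    """
    rng = np.random.default_rng(seed)
    failures = []
    min_margin = np.inf
    max_dev = 0.0
    for k in range(n_draws):
        beta = rng.uniform(0.2, 5.0)
        J = rng.uniform(-3.0, 3.0)
        Delta = rng.uniform(-2.0, 2.0)
        delta = rng.uniform(-2.0, 2.0)
        params = SensorParams(beta=beta, J=J, t=0.0)
        ro = ReadoutParams(r0=r0, Delta=Delta, delta=delta)
        mi = readout_mutual_information(prior, params, ro)
        margin = mi.I_SH - mi.I_rH
        min_margin = min(min_margin, margin)
        ok = margin >= -margin_tol
        dev = None
        if k < n_factorization_draws:
            # factorisation holds pointwise in h, so a handful of signal
            # values suffices; the numeric solve per node is the costly part
            from .information import custom_prior

            h = np.linspace(-2.0, 2.0, 5)
            small = custom_prior(
                np.column_stack([h, h]), np.full(h.shape, 1.0 / h.size)
            )
            dev = factorization_deviation(small, params, ro)
            max_dev = max(max_dev, dev)
            ok = ok and dev < factorization_tol
        if not ok:
            failures.append({
                "beta": beta, "J": J, "Delta": Delta, "delta": delta,
                "margin_bits": margin, "factorization_dev": dev,
            })
    return DPIReport(
        n_draws=n_draws,
        passed=not failures,
        min_margin_bits=float(min_margin),
        max_factorization_dev=float(max_dev),
        failures=tuple(failures),
    )


def optimize_readout_strategy(
    prior: SignalPrior,
    beta: float,
    Delta: float = 1.0,
    r0: int = 10,
    mode: str = "equilibrium",
    J_max: float = 20.0,
):
    """Maximise the readout information I(r; H) under a strategy constraint.

    Modes: ``noninteracting`` (J = t = delta = 0), ``equilibrium``
    (t = 0, J and delta free) and ``full`` (J, t and delta free).  ``Delta``
    and ``r0`` are held fixed.  The search mirrors the sensor-only
    optimiser: a fixed multi-start Nelder-Mead lattice, a coupling bound
    ``J_max`` with a divergence flag, and ``t*`` reported as ``|t*|``.
    """
    from scipy.optimize import minimize

    from .optimization import OptimizationResult, StrategyMode

    # search box: beyond these the exponentials underflow double precision
    # long before the information surface moves
    t_max, delta_max = 20.0, 5.0

    def I_r(J: float, t: float, delta: float) -> float:
        params = SensorParams(
            beta=beta,
            J=float(np.clip(J, -J_max, J_max)),
            t=float(np.clip(t, -t_max, t_max)),
        )
        ro = ReadoutParams(
            r0=r0, Delta=Delta, delta=float(np.clip(delta, -delta_max, delta_max))
        )
        return readout_mutual_information(prior, params, ro).I_rH

    if mode == "noninteracting":
        return OptimizationResult(
            StrategyMode.NONINTERACTING, I_r(0.0, 0.0, 0.0), 0.0, delta_star=0.0
        )

    if mode == "equilibrium":
        def neg(x):
            J, delta = x
            pen = 1e-4 * (
                max(0.0, abs(J) - J_max) ** 2
                + max(0.0, abs(delta) - delta_max) ** 2
            )
            return -I_r(J, 0.0, delta) + pen

        starts = [(J0, d0) for J0 in (-3.0, 0.0, 3.0) for d0 in (-1.0, 0.0, 1.0)]
        dim_t = False
    elif mode == "full":
        def neg(x):
            J, t, delta = x
            pen = 1e-4 * (
                max(0.0, abs(J) - J_max) ** 2
                + max(0.0, abs(t) - t_max) ** 2
                + max(0.0, abs(delta) - delta_max) ** 2
            )
            return -I_r(J, t, delta) + pen

        starts = [
            (J0, t0, d0)
            for J0 in (-3.0, 0.0, 3.0)
            for t0, d0 in ((0.0, 0.0), (5.0, -0.5), (5.0, 0.5))
        ]
        dim_t = True
    else:
        raise ValueError("mode must be noninteracting, equilibrium or full")

    best, n_ok = None, 0
    for x0 in starts:
        res = minimize(neg, np.asarray(x0, dtype=float), method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-10, "maxiter": 600})
        n_ok += bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    J_star = float(np.clip(best.x[0], -J_max, J_max))
    t_star = float(min(abs(best.x[1]), t_max)) if dim_t else 0.0
    delta_star = float(np.clip(best.x[-1], -delta_max, delta_max))
    I_star = float(-best.fun)
    side = J_max if J_star >= 0 else -J_max
    divergent = (
        I_r(side, t_star if dim_t else 0.0, delta_star) >= I_star - 1e-9
        and abs(J_star) > 1.0
    )
    if divergent:
        J_star = side
    return OptimizationResult(
        StrategyMode.FULL if dim_t else StrategyMode.EQUILIBRIUM,
        I_star, J_star, t_star, delta_star=delta_star,
        divergent=divergent, n_starts=len(starts), converged=n_ok > 0,
    )
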