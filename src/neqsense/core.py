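"""Two coupled binary sensors with possibly asymmetric coupling.

The model is a continuous-time Markov chain on the four states of a pair of
binary sensors (spins) ``s_1, s_2 = ±1``.  A signal ``H = (h_1, h_2)`` acts as
a pair of local fields; the sensors interact through directed couplings

    J_12 = J + t/2,      J_21 = J - t/2,

where ``J`` is the symmetric (equilibrium) coupling and ``t`` is the
nonequilibrium drive.  A sensor flips one at a time with inversion rate

    Gamma_i(S | H) = exp[-beta * s_i * (h_i - b_i + J_ij * s_j)],

with ``beta`` the sensor reliability (inverse intrinsic noise) and ``b_i`` an
optional signal-independent bias.  For ``t = 0`` the chain satisfies detailed
balance and the stationary law is the Boltzmann distribution of the free
energy ``F = -sum_i (h_i - b_i) s_i - J s_1 s_2``; any ``t != 0`` breaks
Kolmogorov's cycle criterion and drives a steady probability current around
the cycle ``-- -> -+ -> ++ -> +- -> --``, dissipating free energy ``4 t`` per
completed loop.

The stationary distribution is available both from the null space of the
generator (any state-space size) and from an exact closed form for the
unbiased two-sensor complex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STATE_LABELS",
    "STATES",
    "CYCLE_EDGES",
    "Signal",
    "SensorParams",
    "state_index",
    "free_energy_eq",
    "inversion_rate",
    "build_rate_matrix",
    "steady_state_numeric",
    "steady_state_closed_form",
    "boltzmann_distribution",
    "kolmogorov_ratio",
    "cycle_current",
    "cycle_dissipation",
    "cycle_free_energy_drop",
]

#: Canonical state order; "cyclic" means increasing index modulo 4.
STATE_LABELS: tuple[str, ...] = ("--", "-+", "++", "+-")
STATES: tuple[tuple[int, int], ...] = ((-1, -1), (-1, 1), (1, 1), (1, -1))

#: Directed edges of the cycle -- -> -+ -> ++ -> +- -> --.
CYCLE_EDGES: tuple[tuple[int, int], ...] = ((0, 1), (1, 2), (2, 3), (3, 0))

_S1 = np.array([s for s, _ in STATES], dtype=float)
_S2 = np.array([s for _, s in STATES], dtype=float)


@dataclass(frozen=True)
class Signal:
    """Pair of local fields (dimensionless energy units)."""

    h1: float
    h2: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.h2 is None:
            object.__setattr__(self, "h2", self.h1)
        if not (np.isfinite(self.h1) and np.isfinite(self.h2)):
            raise ValueError("signal fields must be finite")


@dataclass(frozen=True)
class SensorParams:
    """Couplings and noise level of the two-sensor complex.

    Parameters
    ----------
    beta:
        Sensor reliability (inverse intrinsic noise), ``beta >= 0``.
    J:
        Symmetric coupling; ``J > 0`` favours correlated states.
    t:
        Nonequilibrium drive, the antisymmetric part of the coupling.
        ``t = 0`` if and only if detailed balance holds.
    b1, b2:
        Signal-independent biases, entering the rates as ``h_i - b_i``.
    """

    beta: float
    J: float = 0.0
    t: float = 0.0
    b1: float = 0.0
    b2: float = 0.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")

    @property
    def J12(self) -> float:
        return self.J + 0.5 * self.t

    @property
    def J21(self) -> float:
        return self.J - 0.5 * self.t

    @property
    def is_equilibrium(self) -> bool:
        return self.t == 0.0

    @property
    def biases(self) -> tuple[float, float]:
        return (self.b1, self.b2)


def state_index(s1: int, s2: int) -> int:
    """Canonical index of the state ``(s1, s2)``."""
    return STATES.index((int(np.sign(s1)), int(np.sign(s2))))


def free_energy_eq(state: tuple[int, int], signal: Signal, params: SensorParams) -> float:
    """Equilibrium free energy ``-(h1-b1)s1 - (h2-b2)s2 - J s1 s2``.

    Only the symmetric coupling enters; the drive ``t`` does not contribute
    to the equilibrium free energy.
    """
    s1, s2 = state
    return (
        -(signal.h1 - params.b1) * s1
        - (signal.h2 - params.b2) * s2
        - params.J * s1 * s2
    )


def inversion_rate(
    state: tuple[int, int], sensor_index: int, signal: Signal, params: SensorParams
) -> float:
    """Rate at which sensor ``sensor_index`` (1 or 2) flips out of ``state``.

    The overall timescale constant is fixed to 1; it drops out of every
    steady-state quantity.  Flipping sensor 1 uses the directed coupling
    ``J_12``, sensor 2 uses ``J_21``.
    """
    s1, s2 = state
    if sensor_index == 1:
        exponent = -params.beta * s1 * (signal.h1 - params.b1 + params.J12 * s2)
    elif sensor_index == 2:
        exponent = -params.beta * s2 * (signal.h2 - params.b2 + params.J21 * s1)
    else:
        raise ValueError(f"sensor_index must be 1 or 2, got {sensor_index}")
    return float(np.exp(exponent))


def _log_rate_matrix(signal: Signal, params: SensorParams) -> np.ndarray:
    """Log off-diagonal rates; -inf marks forbidden (double-flip) transitions."""
    logW = np.full((4, 4), -np.inf)
    for j, (s1, s2) in enumerate(STATES):
        # flip sensor 1: (s1, s2) -> (-s1, s2)
        i = state_index(-s1, s2)
        logW[i, j] = -params.beta * s1 * (signal.h1 - params.b1 + params.J12 * s2)
        # flip sensor 2
        i = state_index(s1, -s2)
        logW[i, j] = -params.beta * s2 * (signal.h2 - params.b2 + params.J21 * s1)
    return logW


def build_rate_matrix(signal: Signal, params: SensorParams) -> np.ndarray:
    """Generator of the two-sensor Markov chain in the canonical state order.

    Off-diagonal entry ``W[i, j]`` is the rate of the transition ``j -> i``;
    the diagonal makes every column sum to zero.  Only single-sensor flips
    are allowed, so the two double-flip entries vanish.  All rates share a
    common timescale constant, chosen here as ``exp(-max log-rate)`` so that
    the largest rate is 1; this keeps the matrix finite for large ``beta``
    and leaves the stationary distribution untouched.
    """
    logW = _log_rate_matrix(signal, params)
    shift = np.max(logW)
    W = np.exp(logW - shift)
    np.fill_diagonal(W, 0.0)
    np.fill_diagonal(W, -W.sum(axis=0))
    return W


def _steady_state_gth(W: np.ndarray) -> np.ndarray:
    """Stationary distribution by GTH state reduction.

    The Grassmann-Taksar-Heyman algorithm eliminates states one by one
    using only additions, multiplications and divisions of nonnegative
    quantities — no cancellation — so it attains entrywise *relative*
    accuracy even when the rates span hundreds of orders of magnitude,
    where any null-space method in fixed precision breaks down.  Cost is
    O(n^3), same as the SVD.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    # A[i, j] = rate i -> j (row convention used by the classic algorithm)
    A = W.T.copy()
    np.fill_diagonal(A, 0.0)
    for k in range(n - 1, 0, -1):
        s = A[k, :k].sum()
        if s <= 0.0:
            raise ValueError(
                "GTH reduction hit a state with no numerically representable "
                "exit rate; chain is reducible at this precision"
            )
        A[:k, :k] += np.outer(A[:k, k], A[k, :k]) / s
    p = np.zeros(n)
    p[0] = 1.0
    for k in range(1, n):
        s = A[k, :k].sum()
        p[k] = (p[:k] @ A[:k, k]) / s
        if not np.isfinite(p[k]):
            raise ValueError("GTH back-substitution overflowed")
        if p[k] > 1e250:  # renormalise on the fly to dodge overflow
            p[: k + 1] /= p[k]
    return p / p.sum()


def steady_state_numeric(
    W: np.ndarray, precision_gap: float = 1e-6
) -> np.ndarray:
    """Stationary distribution of a generator ``W`` from its SVD null space.

    Works for any state-space size (the readout-extended chain reuses it).
    When the second-smallest singular value falls below ``precision_gap``
    relative to the largest, the double-precision null vector is
    contaminated by near-null directions (its error grows like eps/gap):
    stiff-but-irreducible generators are then re-solved by
    cancellation-free GTH state reduction, while structurally reducible
    chains (transition graph not strongly connected) raise.
    """
    W = np.asarray(W, dtype=float)
    _, s, Vt = np.linalg.svd(W)
    p = Vt[-1]
    p = p * np.sign(p.sum())
    # a weak gap or visibly negative entries both mean the double-precision
    # null vector is contaminated by near-null junk of a stiff generator
    stiff = s[-2] <= precision_gap * s[0] or np.any(
        p < -1e-12 * max(1.0, np.abs(p).max())
    )
    if stiff:
        # a structurally reducible chain (transition graph not strongly
        # connected) has a genuinely non-unique or degenerate stationary
        # law and cannot be rescued by precision
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        offdiag = W - np.diag(np.diag(W))
        n_comp, _ = connected_components(
            csr_matrix(offdiag.T > 0), directed=True, connection="strong"
        )
        if n_comp > 1:
            raise ValueError(
                "degenerate null space: second-smallest singular value "
                f"{s[-2]:.3e} vs largest {s[0]:.3e}; chain is reducible"
            )
        return _steady_state_gth(W)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def _log_cosh(x: np.ndarray) -> np.ndarray:
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax)) - np.log(2.0)


def closed_form_log_weights(
    h1: np.ndarray, h2: np.ndarray, beta: float, J: float, t: float
) -> np.ndarray:
    """Unnormalised log stationary weights, broadcast over signal arrays.

    Returns an array with a trailing axis of length 4 (canonical order).
    The weight of state ``S`` is ``exp[-beta (F_S + dF_S)]`` where ``dF`` is
    the drive-induced correction

        dF_S = -(1/beta) log[ e^{beta t s1 s2 / 2} cosh(beta (h1 - t s2))
                              + e^{-beta t s1 s2 / 2} cosh(beta (h2 + t s1)) ]
               (up to an S-independent constant absorbed in the normaliser),

    which vanishes as ``t -> 0``.  Everything is evaluated in the log domain
    so large ``beta`` (up to ~30) stays finite.
    """
    h1 = np.asarray(h1, dtype=float)[..., None]
    h2 = np.asarray(h2, dtype=float)[..., None]
    minus_beta_F = beta * (h1 * _S1 + h2 * _S2 + J * _S1 * _S2)
    a = 0.5 * beta * t * _S1 * _S2 + _log_cosh(beta * (h1 - t * _S2))
    b = -0.5 * beta * t * _S1 * _S2 + _log_cosh(beta * (h2 + t * _S1))
    return minus_beta_F + np.logaddexp(a, b)


def _softmax(logw: np.ndarray) -> np.ndarray:
    logw = logw - logw.max(axis=-1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=-1, keepdims=True)


def steady_state_closed_form(signal: Signal, params: SensorParams) -> np.ndarray:
    """Exact stationary distribution of the unbiased two-sensor complex.

    Valid for any drive ``t``; reduces to the Boltzmann distribution at
    ``t = 0``.  Refuses nonzero biases (use :func:`steady_state_numeric` or
    :func:`boltzmann_distribution` there).
    """
    if params.b1 != 0.0 or params.b2 != 0.0:
        raise ValueError(
            "closed form is stated for the unbiased complex; "
            "use steady_state_numeric for b != 0"
        )
    logw = closed_form_log_weights(signal.h1, signal.h2, params.beta, params.J, params.t)
    return _softmax(logw)


def boltzmann_distribution(signal: Signal, params: SensorParams) -> np.ndarray:
    """Equilibrium (t = 0) stationary law ``exp(-beta F)/Z``; biases allowed."""
    if params.t != 0.0:
        raise ValueError("Boltzmann form requires t = 0")
    logw = np.array(
        [-params.beta * free_energy_eq(S, signal, params) for S in STATES]
    )
    return _softmax(logw)


def kolmogorov_ratio(params: SensorParams) -> float:
    """Ratio of cyclic to anticyclic rate products around the four-state loop.

    Equals ``exp(4 beta (J12 - J21)) = exp(4 beta t)``; the chain satisfies
    detailed balance if and only if this is 1, i.e. ``t = 0``.
    """
    return float(np.exp(4.0 * params.beta * (params.J12 - params.J21)))


def cycle_current(dist: np.ndarray, W: np.ndarray, atol: float = 1e-8) -> float:
    """Net stationary probability current along the cycle -- -> -+ -> ++ -> +-.

    At stationarity the net flow is identical on all four edges; the four
    edge flows are checked for consistency and their mean returned.  The
    current is zero iff detailed balance holds and its sign follows the sign
    of the drive ``t`` (for the generator convention of
    :func:`build_rate_matrix` the magnitude carries the same overall
    timescale factor as the rates).
    """
    p = np.asarray(dist, dtype=float)
    flows = np.array([W[b, a] * p[a] - W[a, b] * p[b] for a, b in CYCLE_EDGES])
    if flows.max() - flows.min() > atol:
        raise ValueError(
            f"edge flows disagree (spread {flows.max() - flows.min():.3e}); "
            "distribution is not stationary for this generator"
        )
    return float(flows.mean())


def cycle_dissipation(params: SensorParams) -> float:
    """Free energy dissipated per completed cycle: ``4 t``.

    The equilibrium free-energy changes telescope to zero around the loop
    while each of the four cyclic transitions contributes ``-t``, so one
    full cycle releases ``4 t`` (consumed from the drive to conserve energy).
    """
    return 4.0 * params.t


def cycle_free_energy_drop(signal: Signal, params: SensorParams) -> float:
    """Sum of effective free-energy changes over the four cyclic transitions.

    Each transition rate obeys ``Gamma = exp(-beta dF_eff / 2)`` with
    ``dF_eff = dF_eq -/+ t`` for cyclic/anticyclic moves, so the effective
    change is recovered from the rate as ``-(2/beta) log Gamma``.  Summed
    around the loop the equilibrium parts cancel exactly and the result is
    ``-4 t`` for any signal and coupling.  Requires ``beta > 0``.
    """
    if params.beta <= 0:
        raise ValueError("effective free-energy changes need beta > 0")
    total = 0.0
    for a, b in CYCLE_EDGES:
        sa, sb = STATES[a], STATES[b]
        sensor = 1 if sa[0] != sb[0] else 2
        rate = inversion_rate(sa, sensor, signal, params)
        total += -(2.0 / params.beta) * np.log(rate)
    return float(total)
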