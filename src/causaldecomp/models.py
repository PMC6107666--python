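"""Benchmark systems and robustness manipulations for causal decomposition.

Three coupled pairs with known ground-truth interaction, plus white-noise
null ensembles:

* a chaotic coupled two-species logistic difference system where x couples
  into y ten times more strongly than y into x (x→y dominant);
* a linear stochastic autoregressive pair where y is a pure lagged response
  to x (period-8 oscillator driving y at lag 2);
* the classical Lotka–Volterra predator–prey ordinary differential
  equations, integrated with fourth-order Runge–Kutta;
* seeded iid Gaussian white-noise pairs for null calibration.

Down-sampling and temporal-shift helpers reproduce the robustness
manipulations: decimation destroys the causal dynamics (strengths should
collapse to 0.5) while moderate temporal shifts should leave the phase
measure unaffected.
"""

from __future__ import annotations

import numpy as np

from .emd import MIN_LENGTH, TimeSeries

__all__ = [
    "coupled_logistic",
    "ar_stochastic",
    "lotka_volterra",
    "white_noise_pairs",
    "downsample",
    "time_shift",
]


def coupled_logistic(
    length: int = 400, x1: float = 0.2, y1: float = 0.4
) -> tuple[TimeSeries, TimeSeries]:
    """Coupled two-species nonlinear logistic difference system.

        x(t+1) = x(t) [3.8 − 3.8 x(t) − 0.02 y(t)]
        y(t+1) = y(t) [3.5 − 3.5 y(t) − 0.1  x(t)]

    Chaotic at these parameters; x drives y (coupling 0.1) five times more
    strongly than y drives x (0.02).  Trajectories must stay inside the
    unit interval — escaping indicates wrong parameters or initial values.
    """
    if not (0.0 < x1 < 1.0 and 0.0 < y1 < 1.0):
        raise ValueError("initial values must lie in (0, 1)")
    if length < MIN_LENGTH:
        raise ValueError(f"length must be at least {MIN_LENGTH}")
    x = np.empty(length)
    y = np.empty(length)
    x[0], y[0] = x1, y1
    for t in range(length - 1):
        x[t + 1] = x[t] * (3.8 - 3.8 * x[t] - 0.02 * y[t])
        y[t + 1] = y[t] * (3.5 - 3.5 * y[t] - 0.1 * x[t])
        if not (0.0 < x[t + 1] < 1.0 and 0.0 < y[t + 1] < 1.0):
            raise ValueError(
                f"trajectory escaped the unit interval at step {t + 1}; "
                "check parameters and initial values"
            )
    return TimeSeries(x, "logistic_x"), TimeSeries(y, "logistic_y")


def ar_stochastic(
    length: int = 1000, seed: int = 0, burn_in: int = 100
) -> tuple[TimeSeries, TimeSeries]:
    """Stochastic autoregressive pair with unidirectional coupling x → y.

        x(t+1) = 0.95·√2·x(t) − 0.9025·x(t−1) + w1(t)
        y(t+1) = 0.5·x(t−1) + w2(t)

    The AR(2) skeleton of x has complex roots 0.95·e^{±iπ/4}: a damped
    oscillation of period 8 samples.  y is x delayed by two samples plus
    independent noise, so y never feeds back into x.  Initial values are
    standard-normal draws and ``burn_in`` samples are discarded.
    """
    if length < 20:
        raise ValueError("length must be at least 20")
    rng = np.random.default_rng(seed)
    n = length + burn_in
    x = np.zeros(n)
    y = np.zeros(n)
    x[:2] = rng.standard_normal(2)
    y[:2] = rng.standard_normal(2)
    w1 = rng.standard_normal(n)
    w2 = rng.standard_normal(n)
    for t in range(1, n - 1):
        x[t + 1] = 0.95 * np.sqrt(2.0) * x[t] - 0.9025 * x[t - 1] + w1[t]
        y[t + 1] = 0.5 * x[t - 1] + w2[t]
    return TimeSeries(x[burn_in:], "ar_x"), TimeSeries(y[burn_in:], "ar_y")


def lotka_volterra(
    duration: float = 200.0,
    dt: float = 0.01,
    alpha: float = 1.0,
    beta: float = 0.05,
    delta: float = 0.02,
    gamma: float = 0.5,
    x0: float = 30.0,
    y0: float = 10.0,
    sample_interval: float = 1.0,
) -> tuple[TimeSeries, TimeSeries]:
    """Lotka–Volterra predator–prey model, RK4-integrated and resampled.

        dx/dt = α x − β x y      (prey)
        dy/dt = δ x y − γ y      (predator)

    Defaults: α = 1, β = 0.05, δ = 0.02, γ = 0.5, so the coexistence
    equilibrium is x* = γ/δ = 25, y* = α/β = 20.  Integration uses
    classical 4th-order Runge–Kutta at step ``dt`` and the trajectory is
    sampled every ``sample_interval`` model-time units.  Abundances must
    stay positive; a non-positive value suggests the step is too large.
    """
    if min(alpha, beta, delta, gamma, x0, y0, dt, sample_interval) <= 0:
        raise ValueError("parameters, initial abundances, dt and sampling must be positive")

    def rhs(x: float, y: float) -> tuple[float, float]:
        return alpha * x - beta * x * y, delta * x * y - gamma * y

    n_steps = int(round(duration / dt))
    stride = max(1, int(round(sample_interval / dt)))
    xs, ys = [x0], [y0]
    x, y = x0, y0
    for step in range(1, n_steps + 1):
        k1x, k1y = rhs(x, y)
        k2x, k2y = rhs(x + 0.5 * dt * k1x, y + 0.5 * dt * k1y)
        k3x, k3y = rhs(x + 0.5 * dt * k2x, y + 0.5 * dt * k2y)
        k4x, k4y = rhs(x + dt * k3x, y + dt * k3y)
        x += dt * (k1x + 2 * k2x + 2 * k3x + k4x) / 6.0
        y += dt * (k1y + 2 * k2y + 2 * k3y + k4y) / 6.0
        if x <= 0.0 or y <= 0.0:
            raise ValueError(
                f"abundance became non-positive at t={step * dt:.3f}; "
                "use a smaller dt"
            )
        if step % stride == 0:
            xs.append(x)
            ys.append(y)
    return TimeSeries(np.array(xs), "prey"), TimeSeries(np.array(ys), "predator")


def white_noise_pairs(
    n_pairs: int, length: int, seed: int = 0
) -> list[tuple[TimeSeries, TimeSeries]]:
    """Independent standard-Gaussian pairs for null calibration."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = []
    for k in range(n_pairs):
        pairs.append((
            TimeSeries(rng.standard_normal(length), f"noise_{k}_a"),
            TimeSeries(rng.standard_normal(length), f"noise_{k}_b"),
        ))
    return pairs


def downsample(x: TimeSeries, factor: int) -> TimeSeries:
    """Keep every ``factor``-th sample, starting at the first."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    out = x.values[::factor]
    if out.size < MIN_LENGTH:
        raise ValueError(f"down-sampled length {out.size} below minimum {MIN_LENGTH}")
    return TimeSeries(out, f"{x.label}/ds{factor}")


def time_shift(
    a: TimeSeries, b: TimeSeries, k: int, circular: bool = False
) -> tuple[TimeSeries, TimeSeries]:
    """Shift ``b`` by ``k`` samples relative to ``a`` (positive = b lagged).

    By default both series are trimmed to the overlapping support (no
    wrap-around); ``circular=True`` rolls ``b`` instead, preserving length.
    """
    n = min(len(a), len(b))
    if abs(k) > n // 4:
        raise ValueError(f"|shift| must be at most length/4 = {n // 4}")
    if circular:
        return a, TimeSeries(np.roll(b.values, k), f"{b.label}>>{k}")
    if k >= 0:
        av, bv = a.values[k:n], b.values[: n - k]
    else:
        av, bv = a.values[: n + k], b.values[-k:n]
    if av.size < MIN_LENGTH:
        raise ValueError(f"overlap length {av.size} below minimum {MIN_LENGTH}")
    return TimeSeries(av, a.label), TimeSeries(bv, f"{b.label}>>{k}")
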