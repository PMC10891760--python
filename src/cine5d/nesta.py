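"""Staged NESTA solver for the Huber-smoothed CS objective.

NESTA runs Nesterov-accelerated gradient descent on the smoothed objective

    f(m) = 1/2 ||E m - y||^2 + lambda f_mu(Phi m)

and refines the l1 approximation across stages by shrinking the smoothing
width mu (continuation).  Each stage warm-starts from the previous stage's
solution, runs up to ``max_iter_per_stage`` iterations, and halts early when
the progress quotient

    qp = (fbar - f_k) / fbar,   fbar = mean of the last tau objective values

drops to the tolerance, once at least ``tau`` iterations have been recorded.

Iterates within a stage (k = 0, 1, ...):

    g_k = grad f(x_k)
    y_k = x_k - g_k / L
    z_k = x_init - (1/L) sum_{i<=k} alpha_i g_i,   alpha_i = (i + 1) / 2
    x_{k+1} = tau_k z_k + (1 - tau_k) y_k,          tau_k = 2 / (k + 3)

with L = ||E||^2 + lambda ||Phi||^2 / mu = 1 + 8 lambda / mu for normalized
coils, orthonormal DFT and unit tTV weights.  The stage solution is the
final y_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cine5d.data_model import (
    CoilSet,
    ImageSeries5D,
    KSpace5D,
    ObjectiveHistory,
    ReconConfig,
)
from cine5d.operators import (
    HuberParams,
    apply_encoding_adjoint,
    objective_and_gradient,
    phi_norm_sq_bound,
    ttv_forward,
)

__all__ = [
    "StageSchedule",
    "SolverState",
    "DivergenceError",
    "build_schedule",
    "progress_quotient",
    "run_stage",
    "run_reconstruction",
    "zero_filled",
    "default_mu0",
    "default_lambda",
    "histories_to_csv",
]


class DivergenceError(RuntimeError):
    """The objective became non-finite; names the stage and iteration."""

    def __init__(self, stage: int, iteration: int, device: int | None = None):
        self.stage = stage
        self.iteration = iteration
        self.device = device
        where = f"stage {stage}, iteration {iteration}"
        if device is not None:
            where += f", device {device}"
        super().__init__(f"objective diverged (non-finite) at {where}")


@dataclass
class StageSchedule:
    """Per-stage smoothing widths (strictly decreasing) and Lipschitz constants."""

    mus: list[float]
    lipschitz: list[float]

    def __post_init__(self) -> None:
        if len(self.mus) != len(self.lipschitz):
            raise ValueError("mus and lipschitz must have equal length")
        if any(b >= a for a, b in zip(self.mus, self.mus[1:])):
            raise ValueError(f"stage mus must be strictly decreasing, got {self.mus}")

    def __len__(self) -> int:
        return len(self.mus)

    def __iter__(self):
        return iter(zip(self.mus, self.lipschitz))


def build_schedule(
    mu0: float,
    mu_final: float,
    n_stages: int,
    lambda_reg: float,
    phi_norm_sq: float = 8.0,
) -> StageSchedule:
    """Geometric mu-continuation: mu_s = mu0 * gamma^(s-1), gamma = (mu_final/mu0)^(1/(n_stages-1)).

    The per-stage Lipschitz constant is L_s = 1 + phi_norm_sq * lambda / mu_s.
    A single-stage schedule requires mu0 == mu_final (there is nothing to
    interpolate); otherwise mu0 must strictly exceed mu_final.
    """
    if mu_final <= 0 or mu0 <= 0:
        raise ValueError(f"mu values must be positive, got mu0={mu0}, mu_final={mu_final}")
    if lambda_reg < 0:
        raise ValueError(f"lambda_reg must be nonnegative, got {lambda_reg}")
    if n_stages < 1:
        raise ValueError(f"n_stages must be >= 1, got {n_stages}")
    if n_stages == 1:
        if mu0 != mu_final:
            raise ValueError(
                f"a single-stage schedule requires mu0 == mu_final, "
                f"got mu0={mu0}, mu_final={mu_final}"
            )
        mus = [float(mu0)]
    else:
        if mu0 <= mu_final:
            raise ValueError(f"need mu0 > mu_final, got mu0={mu0}, mu_final={mu_final}")
        gamma = (mu_final / mu0) ** (1.0 / (n_stages - 1))
        mus = [float(mu0 * gamma**s) for s in range(n_stages)]
    lips = [1.0 + phi_norm_sq * lambda_reg / mu for mu in mus]
    return StageSchedule(mus=mus, lipschitz=lips)


def progress_quotient(history: ObjectiveHistory, tau: int) -> float:
    """qp = (fbar - f_k) / fbar with fbar the mean of the last tau values.

    Requires at least tau recorded iterations (the stopping rule activates
    only then).  A zero fbar (identically zero objective) reports qp = 0, so
    a stationary all-zero problem halts as soon as the rule activates.
    """
    if len(history) < tau:
        raise ValueError(
            f"progress quotient needs >= tau={tau} iterations, history has {len(history)}"
        )
    window = history.values[-tau:]
    fbar = float(np.mean(window))
    fk = history.values[-1]
    if fbar == 0.0:
        return 0.0
    return (fbar - fk) / fbar


@dataclass
class SolverState:
    """Mutable per-stage NESTA state over a (possibly device-local) array.

    ``x`` is the current iterate x_k, ``x_stage_init`` the stage warm start,
    ``accum`` the weighted gradient sum sum_i alpha_i g_i, ``y_last`` the
    latest gradient-step iterate (the stage solution on exit).
    """

    x: np.ndarray
    x_stage_init: np.ndarray = field(init=False)
    accum: np.ndarray = field(init=False)
    y_last: np.ndarray = field(init=False)
    k: int = field(default=0, init=False)
    history: ObjectiveHistory = field(default=None)  # type: ignore[assignment]
    stage_index: int = 1

    def __post_init__(self) -> None:
        self.x = np.array(self.x, dtype=np.complex128)
        self.x_stage_init = self.x.copy()
        self.accum = np.zeros_like(self.x)
        self.y_last = self.x.copy()
        if self.history is None:
            self.history = ObjectiveHistory(stage_index=self.stage_index)

    def step(self, f: float, g: np.ndarray, lipschitz: float) -> None:
        """Record f(x_k) and advance one accelerated iteration to x_{k+1}."""
        self.history.append(f)
        y = self.x - g / lipschitz
        self.accum += (0.5 * (self.k + 1)) * g
        z = self.x_stage_init - self.accum / lipschitz
        tk = 2.0 / (self.k + 3.0)
        self.x = tk * z + (1.0 - tk) * y
        self.y_last = y
        self.k += 1

    def should_stop(self, tau: int, tol: float) -> bool:
        if len(self.history) < tau:
            return False
        return progress_quotient(self.history, tau) <= tol


def run_stage(
    x0: np.ndarray,
    mu: float,
    lipschitz: float,
    y: KSpace5D,
    coils: CoilSet,
    lambda_reg: float,
    config: ReconConfig,
    stage_index: int = 1,
) -> tuple[np.ndarray, ObjectiveHistory]:
    """Run one NESTA stage; returns (stage solution y_k, objective history)."""
    params = HuberParams(mu=mu)
    state = SolverState(x=x0, stage_index=stage_index)
    for k in range(config.max_iter_per_stage):
        f, g = objective_and_gradient(
            ImageSeries5D._unchecked(state.x),
            y,
            coils,
            lambda_reg,
            params,
            config.ttv_weights,
        )
        try:
            state.step(f, g.data, lipschitz)
        except ValueError as exc:
            raise DivergenceError(stage_index, k + 1) from exc
        if state.should_stop(config.tau, config.tol):
            break
    return state.y_last, state.history


def zero_filled(y: KSpace5D, coils: CoilSet) -> ImageSeries5D:
    """The zero-filled adjoint reconstruction E^H y (solver init and baseline)."""
    return apply_encoding_adjoint(y, coils)


def default_mu0(m0: ImageSeries5D, ttv_weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """Continuation start mu0 = 0.9 * max |Phi m0|_inf (1.0 if the series is flat)."""
    mu0 = 0.9 * ttv_forward(m0, ttv_weights).max_abs()
    return mu0 if mu0 > 0 else 1.0


def default_lambda(m0: ImageSeries5D) -> float:
    """Data-scaled regularization default 0.01 * max |E^H y|."""
    return 0.01 * float(np.abs(m0.data).max())


def resolve_schedule(
    m0: ImageSeries5D, config: ReconConfig
) -> tuple[StageSchedule, float]:
    """Build the (schedule, lambda) pair for a problem from its zero-filled init."""
    lam = config.lambda_reg if config.lambda_reg is not None else default_lambda(m0)
    mu0 = default_mu0(m0, config.ttv_weights)
    return _schedule_from_constants(mu0, lam, config), lam


def _schedule_from_constants(mu0: float, lam: float, config: ReconConfig) -> StageSchedule:
    if config.n_stages == 1:
        mu_final = config.mu_final if config.mu_final is not None else mu0
        if mu_final != mu0:
            mu0 = mu_final  # single stage runs directly at the target smoothing
    else:
        mu_final = config.mu_final if config.mu_final is not None else mu0 * 1e-3
    return build_schedule(
        mu0, mu_final, config.n_stages, lam, phi_norm_sq_bound(config.ttv_weights)
    )


def run_reconstruction(
    y: KSpace5D, coils: CoilSet, config: ReconConfig | None = None
) -> tuple[ImageSeries5D, list[ObjectiveHistory]]:
    """Full staged reconstruction from undersampled multicoil k-space.

    Initializes from the zero-filled adjoint m0 = E^H y, derives the
    continuation schedule (mu0 = 0.9 max |Phi m0|, geometric decay to
    mu_final) and the data-scaled lambda unless configured explicitly, and
    runs the stages sequentially with warm starts.  Returns the final image
    and the per-stage objective histories.
    """
    config = config or ReconConfig()
    m0 = zero_filled(y, coils)
    schedule, lam = resolve_schedule(m0, config)
    x = m0.data.copy()
    histories: list[ObjectiveHistory] = []
    for s, (mu, lips) in enumerate(schedule, start=1):
        x, hist = run_stage(x, mu, lips, y, coils, lam, config, stage_index=s)
        histories.append(hist)
    return ImageSeries5D(data=x), histories


def histories_to_csv(histories: list[ObjectiveHistory], path: str | Path) -> None:
    """Write per-stage objective histories as CSV (stage, iteration, f)."""
    with open(path, "w") as fh:
        fh.write("stage,iteration,objective\n")
        for hist in histories:
            for it, val in enumerate(hist.values, start=1):
                fh.write(f"{hist.stage_index},{it},{val!r}\n")
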