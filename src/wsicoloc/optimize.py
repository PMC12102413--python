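"""Adaptive stochastic gradient descent (ASGD).

Minimizes a (possibly stochastically sampled) objective with the step
schedule ``gamma(t) = a / (A + t)**alpha``, where the artificial time ``t``
is adapted from the inner product of successive gradients: correlated
gradients (consistent descent direction) decrease ``t`` and so enlarge the
step, anti-correlated gradients (overshooting) increase ``t`` and shrink
it.  The gain ``a`` is auto-scaled from probe gradients at the start point
so that the first step moves at most ``delta`` parameter units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ASGDConfig", "ASGDResult", "asgd_minimize"]


@dataclass
class ASGDConfig:
    max_iterations: int = 500
    a: float | None = None  # gain; auto-scaled from probe gradients if None
    A: float = 20.0
    alpha: float = 1.0
    delta: float = 1.0  # target maximum first-step length (parameter units)
    max_step: float | None = None  # per-iteration step clip; defaults to delta
    step_tolerance: float = 1e-5  # stop when mean recent step norm drops below
    # sigmoid of normalized gradient correlation, time update in [f_min, f_max]
    f_max: float = 2.0
    f_min: float = -0.5
    omega: float = 0.2
    n_probe: int = 3  # gradient probes used for gain auto-scaling


@dataclass
class ASGDResult:
    x: np.ndarray
    value: float
    n_iterations: int
    converged: bool
    status: str
    trace: list = field(default_factory=list)


def asgd_minimize(objective, x0, config: ASGDConfig | None = None, seed: int = 0) -> ASGDResult:
    """Minimize ``objective(x, k) -> (value, gradient)`` starting at ``x0``.

    ``k`` is the iteration index; stochastic objectives should derive their
    sample set from it (and from their own seed) so that gradient and value
    share common random numbers within one iteration.
    """
    cfg = config or ASGDConfig()
    x = np.asarray(x0, dtype=float).copy()
    rng = np.random.default_rng(seed)

    a = cfg.a
    if a is None:
        # probe gradient magnitude at x0 to target a first step of delta
        norms = []
        for j in range(cfg.n_probe):
            _, g = objective(x, int(rng.integers(1 << 30)))
            if not np.all(np.isfinite(g)):
                return ASGDResult(x, np.inf, 0, False, "non-finite gradient at start", [])
            norms.append(np.max(np.abs(g)))
        gmax = float(np.median(norms))
        a = cfg.delta * (cfg.A + 1.0) ** cfg.alpha / max(gmax, 1e-12)

    t = 0.0
    g_prev = None
    trace = []
    steps: list[float] = []
    status, converged = "max-iterations", False
    f, k = np.inf, 0
    for k in range(cfg.max_iterations):
        f, g = objective(x, k)
        if not (np.isfinite(f) and np.all(np.isfinite(g))):
            return ASGDResult(x, float(f), k, False, "non-finite objective", trace)
        gamma = a / (cfg.A + t) ** cfg.alpha
        step = gamma * g
        clip = cfg.max_step if cfg.max_step is not None else cfg.delta
        norm_inf = np.max(np.abs(step))
        if norm_inf > clip:
            step = step * (clip / norm_inf)
        x = x - step
        trace.append((float(f), x.copy()))
        if g_prev is not None:
            denom = np.linalg.norm(g) * np.linalg.norm(g_prev)
            corr = float(g @ g_prev) / denom if denom > 0 else 0.0
            sig = 1.0 / (1.0 + np.exp(corr / cfg.omega))
            t = max(0.0, t + cfg.f_min + (cfg.f_max - cfg.f_min) * sig)
        g_prev = g
        steps.append(float(np.linalg.norm(step)))
        if len(steps) >= 10 and np.mean(steps[-10:]) < cfg.step_tolerance:
            status, converged = "step-tolerance", True
            break
    return ASGDResult(x, float(f), k + 1, converged, status, trace)
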