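"""Steady-state approximation, stability testing and attractor classification.

A steady state is approximated by integrating forward in fixed-length
checkpoint windows until the max-norm change between consecutive checkpoints
falls below a tolerance.  Stability follows the perturbation protocol: add
small uniform noise to every component (clipped at zero), re-converge, and
check return to the unperturbed state.  Enumeration runs the procedure from a
family of sampled initial conditions and deduplicates the converged profiles
by normalised L2 distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .pde import Grid, IntegrationError, ModelSpec, apply_dirichlet, integrate

__all__ = [
    "SteadyStateResult",
    "find_steady_state",
    "assess_stability",
    "enumerate_steady_states",
    "classify_steady_state",
    "state_distance",
]


@dataclass
class SteadyStateResult:
    """A converged (or timed-out) profile with stability flag and features."""

    profile: np.ndarray  # (S, N)
    t_reached: float
    converged: bool
    residual: float
    stable: bool | None = None
    features: dict = field(default_factory=dict)
    label: str = "other"
    multiplicity: int = 1
    initial_state: np.ndarray | None = None
    member_times: list = field(default_factory=list)


def state_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Normalised (root-mean-square) L2 distance between two field states."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def find_steady_state(
    model: ModelSpec,
    grid: Grid,
    state0: np.ndarray,
    check_interval: float = 1.0,
    tol: float = 1e-10,
    t_max: float = 200.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    divergence_bound: float = 1e3,
) -> SteadyStateResult:
    """Integrate in checkpoint windows until the state stops changing.

    Converged when ``max|state(t+dt) - state(t)| < tol`` between consecutive
    checkpoints spaced ``check_interval`` apart; ``t_reached`` is the first
    checkpoint time at which this holds.  An unconverged result (flag False)
    is returned once ``t_max`` is exceeded; norm growth beyond
    ``divergence_bound`` raises :class:`~twoscale.pde.IntegrationError`.
    """
    state = apply_dirichlet(model, grid, np.asarray(state0, dtype=float))
    initial = state.copy()
    t = 0.0
    residual = np.inf
    while t < t_max:
        traj = integrate(
            model, grid, state, (0.0, check_interval), rtol=rtol, atol=atol
        )
        new = traj.state(-1)
        t += check_interval
        residual = float(np.max(np.abs(new - state)))
        state = new
        if np.max(np.abs(state)) > divergence_bound:
            raise IntegrationError(f"solution diverged at t={t}")
        if residual < tol:
            return SteadyStateResult(
                profile=state,
                t_reached=t,
                converged=True,
                residual=residual,
                initial_state=initial,
            )
    return SteadyStateResult(
        profile=state,
        t_reached=t,
        converged=False,
        residual=residual,
        initial_state=initial,
    )


def assess_stability(
    model: ModelSpec,
    grid: Grid,
    ss: SteadyStateResult,
    noise_amp: float = 0.001,
    n_trials: int = 10,
    seed: int | None = None,
    return_tol: float = 1e-3,
    **find_kwargs,
) -> bool:
    """Perturb-and-return stability test.

    Each trial adds i.i.d. uniform noise ``U(-noise_amp, noise_amp)`` to every
    component, clips at zero, re-runs :func:`find_steady_state` and checks the
    normalised L2 distance to the unperturbed profile.  Stable iff every trial
    returns within ``return_tol``.
    """
    if not ss.converged:
        raise ValueError("stability assessment requires a converged steady state")
    if noise_amp == 0:
        ss.stable = True
        return True
    rng = np.random.default_rng(seed)
    for _ in range(n_trials):
        noise = rng.uniform(-noise_amp, noise_amp, size=ss.profile.shape)
        perturbed = np.clip(ss.profile + noise, 0.0, None)
        res = find_steady_state(model, grid, perturbed, **find_kwargs)
        if not res.converged or state_distance(res.profile, ss.profile) > return_tol:
            ss.stable = False
            return False
    ss.stable = True
    return True


def enumerate_steady_states(
    model: ModelSpec,
    grid: Grid,
    ic_sampler: Callable[[int], np.ndarray],
    n_samples: int,
    dedup_tol: float = 1e-3,
    seed: int | None = None,
    check_stability: bool = True,
    stability_trials: int = 10,
    noise_amp: float = 0.001,
    **find_kwargs,
) -> list[SteadyStateResult]:
    """Distinct steady states reachable from ``n_samples`` sampled ICs.

    ``ic_sampler(i)`` returns the i-th initial field state.  Converged states
    closer than ``dedup_tol`` (normalised L2) are merged, counting
    multiplicity; unconverged runs are dropped.  Distinct states are labelled
    via :func:`classify_steady_state`, with the widest/narrowest non-trivial
    En domain tagged ``SS1-wide`` / ``SS2-narrow``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    distinct: list[SteadyStateResult] = []
    for i in range(n_samples):
        res = find_steady_state(model, grid, ic_sampler(i), **find_kwargs)
        if not res.converged:
            continue
        for known in distinct:
            if state_distance(res.profile, known.profile) < dedup_tol:
                known.multiplicity += 1
                known.member_times.append(res.t_reached)
                break
        else:
            res.member_times.append(res.t_reached)
            distinct.append(res)

    for res in distinct:
        classify_steady_state(res)
    _assign_width_labels(distinct)

    if check_stability:
        for k, res in enumerate(distinct):
            assess_stability(
                model,
                grid,
                res,
                noise_amp=noise_amp,
                n_trials=stability_trials,
                seed=None if seed is None else seed + k,
                **find_kwargs,
            )
    return distinct


def _assign_width_labels(states: Sequence[SteadyStateResult]) -> None:
    nontrivial = [
        s
        for s in states
        if s.label not in ("trivial", "spotted") and "en_pax_width" in s.features
    ]
    if not nontrivial:
        return
    widths = [s.features["en_pax_width"] for s in nontrivial]
    wide = nontrivial[int(np.argmax(widths))]
    narrow = nontrivial[int(np.argmin(widths))]
    wide.label = "SS1-wide"
    if narrow is not wide:
        narrow.label = "SS2-narrow"


def _components(mask: np.ndarray) -> int:
    """Number of disjoint runs of True in a boolean vector."""
    m = mask.astype(int)
    return int(np.sum(np.diff(np.concatenate(([0], m))) == 1))


def classify_steady_state(
    ss: SteadyStateResult,
    half_max_fraction: float = 0.5,
    grid: Grid | None = None,
) -> SteadyStateResult:
    """Compute phenotype features and a provisional label.

    Features: width of the En and Pax expression domains (measure of the set
    above ``half_max_fraction`` of the species maximum), maximal discrete
    gradient of the Fgf8 mRNA on the posterior half (``x > 0``), and the
    number of disjoint super-threshold En components (spots).
    """
    if not ss.converged:
        raise ValueError("classification requires a converged profile")
    profile = ss.profile
    S, N = profile.shape
    if np.max(profile) < 1e-8:
        ss.features = {"en_pax_width": 0.0, "fgf8_posterior_sharpness": 0.0, "spots": 0}
        ss.label = "trivial"
        return ss
    if S < 6:  # not an MHB-layout state: no phenotype features to extract
        ss.features = {}
        ss.label = "other"
        return ss
    g = grid or Grid(N=N)
    x, h = g.x, g.h
    en, pax, fgf8 = profile[4], profile[5], profile[2]

    feats = {}
    for name, prof in (("en", en), ("pax", pax)):
        peak = prof.max()
        mask = prof >= half_max_fraction * peak if peak > 0 else np.zeros(N, bool)
        feats[f"{name}_width"] = float(h * mask.sum())
        feats[f"{name}_spots"] = _components(mask)
    feats["en_pax_width"] = 0.5 * (feats["en_width"] + feats["pax_width"])
    post = x > 0
    grad = np.gradient(fgf8, x)
    feats["fgf8_posterior_sharpness"] = float(np.max(np.abs(grad[post]))) if post.any() else 0.0
    feats["spots"] = feats["en_spots"]
    ss.features = feats
    ss.label = "spotted" if feats["en_spots"] > 1 else "other"
    return ss
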