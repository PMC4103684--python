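"""The mid-hindbrain-boundary (isthmic organizer) model instance.

Eight species on ``[-L, L]``: six cell-bound transcription activities
(*Otx2*, *Gbx2*, *Fgf8* mRNA, *Wnt1* mRNA, *En*, *Pax*) and two diffusive
morphogen proteins (Fgf8, Wnt1) sourced proportionally to their encoding
genes with zero-Dirichlet far-field boundaries::

    du_i/dt = alpha_i B_i(u, v) - beta_i u_i              i = 1..6
    dv_j/dt = alpha_{6+j} u_src(j) - beta_{6+j} v_j + d_j v_j,xx   j = 1,2

Spatial convention: the mid-hindbrain region (MHR) is ``[-1, 1]`` inside the
larger domain ``[-L, L]`` (default ``L = 2``), the boundary (MHB) sits at
``x* = 0``, anterior is negative ``x`` (Otx2 side) and posterior positive
(Gbx2 side).

Besides the model builder this module provides E8.5-like initial-condition
generators and the closed-form analytics of the Otx2/Gbx2 toggle switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grn import GENE_NAMES, HillParams, regulation_all
from .pde import Grid, ModelSpec

__all__ = [
    "MHBParams",
    "SPECIES",
    "build_mhb_model",
    "make_initial_conditions",
    "toggle_bistability_threshold",
    "toggle_boundary_position",
]

#: full species order: six genes then the two morphogen proteins
SPECIES = GENE_NAMES + ("Fgf8", "Wnt1")


@dataclass(frozen=True)
class MHBParams:
    """Kinetic parameters of the MHB model.

    ``alpha``/``beta`` are the eight synthesis/degradation rates (genes 1..6,
    then Fgf8 and Wnt1 protein), all per time unit; ``hill`` the shared Hill
    interaction parameters; ``d_fgf8``/``d_wnt1`` the morphogen diffusion
    coefficients (space^2 per time).
    """

    alpha: tuple[float, ...] = (1.0,) * 8
    beta: tuple[float, ...] = (1.0,) * 8
    hill: HillParams = field(default_factory=HillParams)
    d_fgf8: float = 0.001
    d_wnt1: float = 0.001

    def __post_init__(self) -> None:
        if len(self.alpha) != 8 or len(self.beta) != 8:
            raise ValueError("alpha and beta must each have 8 entries")
        if any(a <= 0 for a in self.alpha) or any(b <= 0 for b in self.beta):
            raise ValueError("all rates must be positive")
        if self.d_fgf8 < 0 or self.d_wnt1 < 0:
            raise ValueError("diffusion coefficients must be nonnegative")


def build_mhb_model(p: MHBParams | None = None) -> ModelSpec:
    """Assemble the 8-species :class:`~twoscale.pde.ModelSpec`."""
    p = p or MHBParams()
    alpha = np.asarray(p.alpha, dtype=float)
    beta = np.asarray(p.beta, dtype=float)
    hp = p.hill

    def reaction(x, U, params):
        # integrator trial steps may dip infinitesimally below zero
        U = np.maximum(U, 0.0)
        u, v = U[:6], U[6:8]
        dU = np.empty_like(U)
        dU[:6] = alpha[:6, None] * regulation_all(u, v, hp) - beta[:6, None] * u
        dU[6] = alpha[6] * u[2] - beta[6] * v[0]  # Fgf8 protein from Fgf8 mRNA
        dU[7] = alpha[7] * u[3] - beta[7] * v[1]  # Wnt1 protein from Wnt1 mRNA
        return dU

    dirichlet = {
        name: (0.0, 0.0)
        for name, d in (("Fgf8", p.d_fgf8), ("Wnt1", p.d_wnt1))
        if d > 0
    }
    return ModelSpec(
        species=SPECIES,
        reaction=reaction,
        diffusion={"Fgf8": p.d_fgf8, "Wnt1": p.d_wnt1},
        dirichlet=dirichlet,
        params={"mhb": p},
    )


def _plateau(x, center, half_width, amp, edge=0.02):
    """Flat-topped expression domain with steep logistic edges."""
    left = 1.0 / (1.0 + np.exp(-(x - (center - half_width)) / edge))
    right = 1.0 / (1.0 + np.exp((x - (center + half_width)) / edge))
    return amp * left * right


def make_initial_conditions(
    kind: str,
    xstar: float,
    grid: Grid,
    widths=None,
    amplitudes=None,
    centers=None,
    ramp_width: float = 0.1,
    edge_width: float = 0.02,
    morphogen_scale: float = 0.1,
    seed: int | None = None,
) -> np.ndarray:
    """E8.5-like initial expression pattern.

    Otx2/Gbx2 are opposing logistic ramps crossing exactly once at ``xstar``
    (Otx2 high anterior, ``x < xstar``); the remaining genes start as
    flat-topped expression domains with steep edges near ``xstar`` — one
    domain each for ``kind='unimodal'`` (half-width ``widths``, per gene or
    shared), several disjoint domains for ``kind='multimodal'`` — and the
    morphogens start at ``morphogen_scale`` times their source gene.
    Deterministic given identical arguments; a seed only randomises
    multimodal domain placement when ``centers`` is not given.
    """
    if not (-grid.L < xstar < grid.L):
        raise ValueError(f"xstar={xstar} outside the open domain (-L, L)")
    if kind not in ("unimodal", "multimodal"):
        raise ValueError(f"kind must be 'unimodal' or 'multimodal', got {kind!r}")

    x = grid.x
    state = np.zeros((8, grid.N))
    ramp = 1.0 / (1.0 + np.exp((x - xstar) / ramp_width))
    state[0] = ramp  # Otx2 anterior
    state[1] = 1.0 - ramp  # Gbx2 posterior

    if kind == "unimodal":
        widths = np.broadcast_to(
            np.asarray(0.18 if widths is None else widths, dtype=float), (4,)
        )
        amplitudes = np.broadcast_to(
            np.asarray(1.0 if amplitudes is None else amplitudes, dtype=float), (4,)
        )
        # Fgf8 mRNA domain posterior of the boundary, Wnt1 mRNA anterior,
        # En/Pax astride it
        offsets = (0.1, -0.1, 0.0, 0.0)
        for row, (w, a, off) in enumerate(zip(widths, amplitudes, offsets), start=2):
            state[row] = _plateau(x, xstar + off, w, a, edge_width)
    else:
        rng = np.random.default_rng(seed)
        if centers is None:
            centers = xstar + rng.uniform(-0.8, 0.8, size=2)
        centers = np.atleast_1d(np.asarray(centers, dtype=float))
        widths = np.broadcast_to(
            np.asarray(0.08 if widths is None else widths, dtype=float),
            centers.shape,
        )
        amplitudes = np.broadcast_to(
            np.asarray(1.0 if amplitudes is None else amplitudes, dtype=float),
            centers.shape,
        )
        for row in range(2, 6):
            bump = np.zeros_like(x)
            for c, w, a in zip(centers, widths, amplitudes):
                bump = np.maximum(bump, _plateau(x, c, w, a, edge_width))
            state[row] = bump

    state[6] = morphogen_scale * state[2]
    state[7] = morphogen_scale * state[3]
    np.clip(state, 0.0, 1.0, out=state)
    # far-field Dirichlet values
    state[6, [0, -1]] = 0.0
    state[7, [0, -1]] = 0.0
    return state


def sample_unimodal_family(
    grid: Grid,
    n: int,
    xstar: float = 0.0,
    seed: int | None = None,
    restricted_width: tuple[float, float] = (0.15, 0.20),
    broad_width: tuple[float, float] = (1.8, 2.4),
    amplitude_range: tuple[float, float] = (0.4, 1.0),
):
    """Low-discrepancy family of unimodal E8.5-like initial conditions.

    The family spans the two qualitative classes of primordial pattern the
    model distinguishes: *restricted* domains confined to the boundary
    neighbourhood and *broad* domains spanning the mid-hindbrain region.
    Within each class the domain half-width and the four gene amplitudes are
    sampled space-fillingly (Halton); the class itself alternates with the
    first Halton coordinate.  Returns a list of ``(8, N)`` field states.
    """
    from scipy.stats import qmc

    sampler = qmc.Halton(d=6, scramble=True, seed=seed)
    pts = sampler.random(n)
    states = []
    for row in pts:
        broad = row[0] >= 0.5
        lo, hi = broad_width if broad else restricted_width
        w = lo + (hi - lo) * row[1]
        a_lo, a_hi = amplitude_range
        amps = a_lo + (a_hi - a_lo) * row[2:6]
        states.append(
            make_initial_conditions(
                "unimodal", xstar, grid, widths=w, amplitudes=amps
            )
        )
    return states


def toggle_bistability_threshold(n: float) -> float:
    """Critical ratio ``beta/alpha = (n-1)^(1+1/n) / n`` of the symmetric toggle.

    For ``beta/alpha`` above this value the Otx2/Gbx2 mutual-inhibition system
    is bistable and separated expression domains can form; requires ``n > 1``.
    """
    if not n > 1:
        raise ValueError("the bistability threshold requires Hill exponent n > 1")
    return (n - 1.0) ** (1.0 + 1.0 / n) / n


def toggle_boundary_position(u01: np.ndarray, u02: np.ndarray, grid: Grid) -> float:
    """Position ``x*`` where the initial Otx2/Gbx2 profiles cross.

    ``u01 > u02`` anterior of ``x*`` and ``u01 < u02`` posterior of it; the
    crossing is located by linear interpolation between the bracketing nodes.
    Raises if the difference changes sign zero times or more than once.
    """
    u01 = np.asarray(u01, dtype=float)
    u02 = np.asarray(u02, dtype=float)
    if u01.shape != (grid.N,) or u02.shape != (grid.N,):
        raise ValueError("profiles must match the grid size")
    diff = u01 - u02
    sign = np.sign(diff)
    nz = sign != 0
    change = np.where(np.diff(sign[nz]) != 0)[0]
    if len(change) != 1:
        raise ValueError(
            f"profiles must cross exactly once, found {len(change)} crossings"
        )
    idx = np.flatnonzero(nz)
    i0, i1 = idx[change[0]], idx[change[0] + 1]
    x = grid.x
    d0, d1 = diff[i0], diff[i1]
    return float(x[i0] + (x[i1] - x[i0]) * d0 / (d0 - d1))
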