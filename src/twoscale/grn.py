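"""Hill-type regulation functions of the isthmic-organizer gene network.

The six IsO genes (*Otx2*, *Gbx2*, *Fgf8*, *Wnt1*, *En*, *Pax*) regulate each
other through sigmoidal, saturating interactions.  Each gene ``i`` carries a
production term ``alpha_i * B_i(u, v)`` where ``B_i`` is a continuous
transcriptional activation in ``[0, 1]`` obtained from the Boolean regulatory
logic of the network by multi-affine (HillCube) interpolation: every Boolean
input is replaced by a Hill activation (or inhibition), a Boolean AND of
independent inputs becomes a product and an OR is combined by
inclusion-exclusion, so that the continuous function agrees with the Boolean
one at all saturating corner inputs.

Regulatory logic implemented (activating edges ``->``, inhibiting ``-|``)::

    Gbx2 -| Otx2                 B1 = inh(Gbx2)
    Otx2 -| Gbx2                 B2 = inh(Otx2)
    Otx2 -| Fgf8;  Wnt1p -> Fgf8;  (En AND Pax) -> Fgf8
                                 B3 = inh(Otx2) * [act(Wnt1p) OR act(En)act(Pax)]
    Gbx2 -| Wnt1;  Fgf8p -> Wnt1
                                 B4 = inh(Gbx2) * act(Fgf8p)
    Pax -> En;  (Fgf8p OR Wnt1p) -> En
                                 B5 = act(Pax) * [act(Fgf8p) OR act(Wnt1p)]
    En -> Pax                    B6 = act(En)

``Fgf8p``/``Wnt1p`` denote the diffusive morphogen proteins; all other inputs
are cell-bound transcription activities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HillParams",
    "hill_activation",
    "hill_inhibition",
    "regulation_B",
    "boolean_update",
    "N_GENES",
    "GENE_NAMES",
]

N_GENES = 6
GENE_NAMES = ("Otx2", "Gbx2", "Fgf8_rna", "Wnt1_rna", "En", "Pax")


@dataclass(frozen=True)
class HillParams:
    """Shared Hill interaction parameters.

    Parameters
    ----------
    k : activation threshold (> 0); an input equal to ``k`` gives half-maximal
        activation.
    n : Hill exponent (>= 1); steepness of the sigmoid.
    """

    k: float = 0.1
    n: float = 2.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"Hill threshold k must be > 0, got {self.k}")
        if not self.n >= 1:
            raise ValueError(f"Hill exponent n must be >= 1, got {self.n}")


def _check_nonneg(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hill functions are defined for nonnegative inputs only")
    return x


def hill_activation(x, hp: HillParams):
    """Hill activation ``x^n / (k^n + x^n)``; monotone nondecreasing, in [0, 1)."""
    x = _check_nonneg(x)
    xn = x ** hp.n
    return xn / (hp.k ** hp.n + xn)


def hill_inhibition(x, hp: HillParams):
    """Hill inhibition ``k^n / (k^n + x^n) = 1 - hill_activation``; in (0, 1]."""
    x = _check_nonneg(x)
    kn = hp.k ** hp.n
    return kn / (kn + x ** hp.n)


def _lor(a, b):
    # inclusion-exclusion OR of two unit-interval activations
    return a + b - a * b


def regulation_B(i: int, u, v, hp: HillParams):
    """Continuous transcriptional activation ``B_i`` of gene ``i`` (1-based).

    Parameters
    ----------
    i : gene index in 1..6 ordered as ``GENE_NAMES``.
    u : array-like, shape (6,) or (6, N) — transcription activities.
    v : array-like, shape (2,) or (2, N) — morphogen concentrations
        (Fgf8 protein, Wnt1 protein).
    hp : shared Hill parameters.

    Returns the activation in [0, 1], elementwise over trailing axes.
    """
    u = _check_nonneg(u)
    v = _check_nonneg(v)
    if u.shape[0] != 6 or v.shape[0] != 2:
        raise ValueError("u must have 6 rows and v 2 rows")
    if i == 1:
        return hill_inhibition(u[1], hp)
    if i == 2:
        return hill_inhibition(u[0], hp)
    if i == 3:
        return hill_inhibition(u[0], hp) * _lor(
            hill_activation(v[1], hp),
            hill_activation(u[4], hp) * hill_activation(u[5], hp),
        )
    if i == 4:
        return hill_inhibition(u[1], hp) * hill_activation(v[0], hp)
    if i == 5:
        return hill_activation(u[5], hp) * _lor(
            hill_activation(v[0], hp), hill_activation(v[1], hp)
        )
    if i == 6:
        return hill_activation(u[4], hp)
    raise ValueError(f"gene index must be in 1..6, got {i}")


def regulation_all(u, v, hp: HillParams) -> np.ndarray:
    """Stack ``B_1..B_6``; shape (6,) + trailing axes of the inputs."""
    return np.stack([regulation_B(i, u, v, hp) for i in range(1, 7)])


def boolean_update(i: int, u_bool, v_bool) -> bool:
    """Boolean regulatory function underlying ``B_i`` (corner-value oracle).

    ``u_bool``/``v_bool`` are length-6/length-2 sequences of truth values.
    """
    o, g, _f, _w, e, p = (bool(b) for b in u_bool)
    fp, wp = (bool(b) for b in v_bool)
    table = {
        1: not g,
        2: not o,
        3: (not o) and (wp or (e and p)),
        4: (not g) and fp,
        5: p and (fp or wp),
        6: e,
    }
    if i not in table:
        raise ValueError(f"gene index must be in 1..6, got {i}")
    return table[i]
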