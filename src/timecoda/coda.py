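"""Compositional geometry for 3-part time-use data.

A day of accelerometer wear splits into sedentary behavior (SB), light
physical activity (LPA) and moderate-to-vigorous physical activity (MVPA).
Only the relative shares carry information, so the triple lives on the
2-simplex and is analysed in Aitchison geometry: closure, multiplicative
zero replacement, pivot isometric log-ratio (ilr) coordinates and their
inverse, the compositional (geometric-mean) center, and the variation
matrix of pairwise log-ratio variances.

Compositions are plain NumPy arrays in the canonical part order
``PARTS = ("sb", "lpa", "mvpa")``; every function accepts a single
composition of shape ``(3,)`` or a stack of shape ``(n, 3)``.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np

PARTS: tuple[str, str, str] = ("sb", "lpa", "mvpa")

#: Pivot ordering used throughout the MVPA analysis: the first ilr
#: coordinate isolates MVPA against the geometric mean of SB and LPA.
MVPA_FIRST: tuple[str, str, str] = ("mvpa", "sb", "lpa")
SB_FIRST: tuple[str, str, str] = ("sb", "lpa", "mvpa")
LPA_FIRST: tuple[str, str, str] = ("lpa", "mvpa", "sb")

PIVOT_ORDERS: dict[str, tuple[str, str, str]] = {
    "sb": SB_FIRST,
    "lpa": LPA_FIRST,
    "mvpa": MVPA_FIRST,
}

_CLOSE_TOL = 1e-12


class IlrPair(NamedTuple):
    """Pivot ilr coordinates of one composition.

    ``z1`` contrasts the pivot-first part against the geometric mean of the
    other two; ``z2`` contrasts the third against the second part of
    ``pivot_order``.
    """

    z1: float
    z2: float
    pivot_order: tuple[str, str, str]


def _as_parts(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape[-1] != 3:
        raise ValueError(f"expected 3 parts in the last axis, got shape {a.shape}")
    return a


def close(parts) -> np.ndarray:
    """Closure: rescale non-negative parts to proportions summing to 1.

    Raises ``ValueError`` on negative parts or an all-zero row.
    """
    a = _as_parts(parts)
    if np.any(a < 0):
        raise ValueError("parts must be non-negative")
    tot = a.sum(axis=-1, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError("closure undefined for an all-zero set of parts")
    return a / tot


def replace_zeros(comp, delta=None, *, strategy: str = "multiplicative") -> np.ndarray:
    """Multiplicative replacement of zero parts.

    Each zero part is set to ``delta`` and the non-zero parts are shrunk by
    the factor ``1 - (number of zeros) * delta`` so the row still sums to 1.
    ``delta`` may be a scalar or one value per part; when omitted it defaults
    to 0.65 times the smallest observed non-zero proportion of that part
    across the input rows (falling back to 1e-5 for a part that is zero
    everywhere, i.e. below any plausible detection floor).

    ``strategy="fail"`` raises on any zero instead of imputing.
    """
    a = close(comp)
    zeros = a == 0.0
    if not zeros.any():
        return a.copy()
    if strategy == "fail":
        raise ValueError("composition contains zero parts and strategy is 'fail'")
    if strategy != "multiplicative":
        raise ValueError(f"unknown zero-replacement strategy {strategy!r}")

    stacked = a.reshape(-1, 3)
    if delta is None:
        delta_vec = np.empty(3)
        for j in range(3):
            nz = stacked[:, j][stacked[:, j] > 0]
            delta_vec[j] = 0.65 * nz.min() if nz.size else 1e-5
    else:
        delta_vec = np.broadcast_to(np.asarray(delta, dtype=float), (3,)).copy()
    if np.any(delta_vec <= 0) or np.any(delta_vec >= 1):
        raise ValueError("delta must lie strictly between 0 and 1")

    out = stacked.copy()
    zmask = out == 0.0
    for i in np.nonzero(zmask.any(axis=1))[0]:
        row_delta = np.where(zmask[i], delta_vec, 0.0)
        out[i] = np.where(zmask[i], row_delta, out[i] * (1.0 - row_delta.sum()))
    out = out.reshape(a.shape)
    if np.any(out <= 0):
        raise ValueError("zero replacement produced non-positive parts; delta too large")
    return out


def pivot_basis(pivot_order: Sequence[str] = MVPA_FIRST) -> np.ndarray:
    """Orthonormal pivot ilr basis as a 3x2 matrix of clr coefficients.

    Columns are the basis vectors for (z1, z2), rows follow the canonical
    ``PARTS`` order.  z1 = sqrt(2/3)*ln(p1 / sqrt(p2*p3)) and
    z2 = sqrt(1/2)*ln(p3 / p2) for parts (p1, p2, p3) in ``pivot_order``.
    """
    order = tuple(pivot_order)
    if sorted(order) != sorted(PARTS):
        raise ValueError(f"pivot_order must be a permutation of {PARTS}, got {order}")
    idx = [PARTS.index(p) for p in order]
    V = np.zeros((3, 2))
    V[idx[0], 0] = np.sqrt(2.0 / 3.0)
    V[idx[1], 0] = -np.sqrt(2.0 / 3.0) / 2.0
    V[idx[2], 0] = -np.sqrt(2.0 / 3.0) / 2.0
    V[idx[1], 1] = -np.sqrt(1.0 / 2.0)
    V[idx[2], 1] = np.sqrt(1.0 / 2.0)
    return V


def ilr_pivot(comp, pivot_order: Sequence[str] = MVPA_FIRST) -> np.ndarray:
    """Map strictly positive composition(s) to pivot ilr coordinates.

    Returns shape ``(..., 2)``.  Zero parts are a domain error: route the
    data through :func:`replace_zeros` first.
    """
    a = close(comp)
    if np.any(a <= 0):
        raise ValueError("ilr requires strictly positive parts (see replace_zeros)")
    return np.log(a) @ pivot_basis(pivot_order)


def ilr_inverse(z, pivot_order: Sequence[str] = MVPA_FIRST) -> np.ndarray:
    """Inverse pivot ilr: coordinates ``(..., 2)`` back to composition(s)."""
    zz = np.asarray(z, dtype=float)
    if zz.shape[-1] != 2:
        raise ValueError("expected 2 ilr coordinates in the last axis")
    clr = zz @ pivot_basis(pivot_order).T
    # guard against overflow for extreme coordinates; closure cancels the shift
    clr = clr - clr.max(axis=-1, keepdims=True)
    return close(np.exp(clr))


def ilr_pair(comp, pivot_order: Sequence[str] = MVPA_FIRST) -> IlrPair:
    """Single-composition convenience wrapper returning an :class:`IlrPair`."""
    z = ilr_pivot(comp, pivot_order)
    if z.ndim != 1:
        raise ValueError("ilr_pair expects a single composition")
    return IlrPair(float(z[0]), float(z[1]), tuple(pivot_order))


def variation_matrix(comps) -> np.ndarray:
    """Variances of all pairwise log-ratios across compositions.

    Entry (i, j) is the sample variance (n-1 divisor) of ln(x_i/x_j) over the
    rows.  Symmetric with a zero diagonal; small entries mean the two
    behaviors are nearly proportional across participants.
    """
    a = close(comps)
    a = np.atleast_2d(a)
    if a.shape[0] < 2:
        raise ValueError("variation matrix needs at least 2 compositions")
    if np.any(a <= 0):
        raise ValueError("variation matrix requires strictly positive parts")
    logs = np.log(a)
    T = np.zeros((3, 3))
    for i in range(3):
        for j in range(i + 1, 3):
            T[i, j] = T[j, i] = np.var(logs[:, i] - logs[:, j], ddof=1)
    return T


def compositional_mean(comps) -> np.ndarray:
    """Center of a compositional sample: closure of part-wise geometric means."""
    a = np.atleast_2d(close(comps))
    if np.any(a <= 0):
        raise ValueError("compositional mean requires strictly positive parts")
    return close(np.exp(np.log(a).mean(axis=0)))


def clr_cov_from_variation(T) -> np.ndarray:
    """clr covariance matrix implied by a variation matrix.

    Uses the identity t_ij = s_ii + s_jj - 2 s_ij together with the zero-sum
    constraint of clr coordinates: S = -0.5 * G T G with G the centering
    matrix.  Used to calibrate simulations to a published variation matrix.
    """
    T = np.asarray(T, dtype=float)
    if T.shape != (3, 3):
        raise ValueError("expected a 3x3 variation matrix")
    G = np.eye(3) - np.ones((3, 3)) / 3.0
    return -0.5 * G @ T @ G


def ilr_cov_from_variation(T, pivot_order: Sequence[str] = MVPA_FIRST) -> np.ndarray:
    """2x2 covariance of pivot ilr coordinates implied by a variation matrix."""
    V = pivot_basis(pivot_order)
    return V.T @ clr_cov_from_variation(T) @ V


def write_variation_tsv(T, path) -> None:
    """Write the lower triangle of a variation matrix as a labelled TSV."""
    T = np.asarray(T, dtype=float)
    labels = [p.upper() for p in PARTS]
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for i, lab in enumerate(labels):
            cells = [f"{T[i, j]:.2f}" if j < i else ("0" if j == i else "") for j in range(3)]
            fh.write(lab + "\t" + "\t".join(cells) + "\n")
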