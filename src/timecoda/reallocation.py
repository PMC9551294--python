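"""Time-reallocation (isotemporal substitution) prediction.

Given a fitted compositional effect (as a zero-sum log-contrast vector) and
a base composition, predict the outcome difference when a fixed number of
percentage points of wear time moves into or out of one behavior while the
remainder is redistributed to the other two — either equally (the default)
or proportionally to their base shares.  Because the model is linear in
log-parts, the predicted difference is

    delta_y = sum_k a_k * (ln new_k - ln base_k)

which equals beta . (ilr(new) - ilr(base)) in any pivot; both routes are
computed and cross-checked on every call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import coda
from .regression import LogContrastVector


@dataclass(frozen=True)
class ReallocationScenario:
    """A shift of ``delta`` (signed, in proportion units: 0.03 = 3 percentage
    points of wear time) into/out of ``focal``, the rest redistributed."""

    focal: str
    delta: float
    rule: str = "equal"  # or "proportional"

    def __post_init__(self) -> None:
        if self.focal not in coda.PARTS:
            raise ValueError(f"focal behavior must be one of {coda.PARTS}")
        if self.rule not in ("equal", "proportional"):
            raise ValueError("rule must be 'equal' or 'proportional'")


@dataclass(frozen=True)
class ReallocationPrediction:
    scenario: ReallocationScenario
    base: np.ndarray
    new_composition: np.ndarray
    predicted_diff: float
    minutes_equivalent: float


def reallocate(base, focal: str, delta: float, rule: str = "equal") -> np.ndarray:
    """New composition after shifting ``delta`` proportion units into ``focal``.

    Under ``equal`` the two remaining parts each absorb -delta/2; under
    ``proportional`` they absorb -delta in proportion to their base shares
    (which leaves their ratio, hence the second pivot coordinate, unchanged).
    Raises with the feasible delta range if any part would hit zero.
    """
    b = coda.close(base)
    if b.ndim != 1:
        raise ValueError("reallocate expects a single composition")
    i = coda.PARTS.index(focal)
    others = [j for j in range(3) if j != i]
    new = b.copy()
    new[i] += delta
    if rule == "equal":
        for j in others:
            new[j] -= delta / 2.0
    elif rule == "proportional":
        w = b[others] / b[others].sum()
        for j, wj in zip(others, w):
            new[j] -= delta * wj
    else:
        raise ValueError("rule must be 'equal' or 'proportional'")
    if np.any(new <= 0.0) or new[i] >= 1.0:
        lo, hi = _feasible_range(b, i, rule)
        raise ValueError(
            f"delta {delta:+.4f} infeasible for {focal} from base {np.round(b, 4)}; "
            f"feasible open range is ({lo:.4f}, {hi:.4f})"
        )
    return new


def _feasible_range(b: np.ndarray, i: int, rule: str) -> tuple[float, float]:
    others = [j for j in range(3) if j != i]
    if rule == "equal":
        hi = 2.0 * min(b[j] for j in others)
    else:
        hi = b[others].sum()  # proportional can never exhaust one side first
    return -b[i], min(hi, 1.0 - b[i])


def predict_difference(
    fit: LogContrastVector,
    base,
    scenario: ReallocationScenario,
    wear_minutes: float | None = None,
) -> ReallocationPrediction:
    """Predicted outcome difference for one reallocation scenario.

    Computed as the log-contrast inner product and cross-checked against the
    ilr-difference route (they agree to 1e-10 by construction; a mismatch
    indicates numerical corruption of the inputs).
    """
    b = coda.close(base)
    if np.any(b <= 0):
        raise ValueError("base composition must be strictly positive")
    new = reallocate(b, scenario.focal, scenario.delta, scenario.rule)
    a = fit.as_array()
    diff = float(a @ (np.log(new) - np.log(b)))
    # independent route: beta in the MVPA-first pivot applied to ilr difference
    beta = coda.pivot_basis(coda.MVPA_FIRST).T @ a
    diff_ilr = float(
        beta @ (coda.ilr_pivot(new, coda.MVPA_FIRST) - coda.ilr_pivot(b, coda.MVPA_FIRST))
    )
    if abs(diff - diff_ilr) > 1e-10 * max(1.0, abs(diff)):
        raise AssertionError("log-contrast and ilr routes disagree")
    minutes = abs(scenario.delta) * wear_minutes if wear_minutes is not None else float("nan")
    return ReallocationPrediction(
        scenario=scenario, base=b, new_composition=new,
        predicted_diff=diff, minutes_equivalent=minutes,
    )


def reallocation_curve(
    fit: LogContrastVector,
    base,
    focal: str,
    deltas,
    wear_minutes: float,
    rule: str = "equal",
) -> pd.DataFrame:
    """One prediction per grid point; infeasible points are dropped with a warning.

    Columns: delta_pp (percentage points), minutes_equiv, new_sb, new_lpa,
    new_mvpa, predicted_diff_mm3.
    """
    import warnings

    rows = []
    for d in np.asarray(deltas, dtype=float):
        try:
            pred = predict_difference(
                fit, base, ReallocationScenario(focal, d, rule), wear_minutes
            )
        except ValueError as exc:
            warnings.warn(f"dropping infeasible grid point delta={d:+.4f}: {exc}")
            continue
        rows.append(
            {
                "delta_pp": 100.0 * d,
                "minutes_equiv": pred.minutes_equivalent,
                "new_sb": pred.new_composition[0],
                "new_lpa": pred.new_composition[1],
                "new_mvpa": pred.new_composition[2],
                "predicted_diff_mm3": pred.predicted_diff,
            }
        )
    return pd.DataFrame(rows)


def plot_curve(curve: pd.DataFrame, ax=None, ylabel: str = "Predicted difference (mm³)"):
    """Optional matplotlib rendering of a reallocation curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve["delta_pp"], curve["predicted_diff_mm3"], marker="o")
    ax.axhline(0.0, lw=0.8, color="grey")
    ax.axvline(0.0, lw=0.8, color="grey")
    ax.set_xlabel("Reallocation of focal behavior (percentage points of wear time)")
    ax.set_ylabel(ylabel)
    return ax
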