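"""Calibration of temperature-correction parameters from kinetic data.

Three estimation procedures live here:

1. :func:`fit_eyring` — nonlinear least-squares fit of the Eyring curve
   ln(k/T) = C2 - dCp_act/(R*T)*[T - T_H - T*ln(T/T_H)] to a series of
   (T, ln k) measurements, yielding (C2, dCp_act, T_H) for one protein.
2. :func:`calibrate_folding_panel` — averages per-protein (T_H, beta)
   over a panel of proteins into a single :class:`CorrectionParams` with
   standard errors, the quantity the correction pipeline consumes.
3. :func:`optimize_t_hu` — a one-parameter RMSD minimization that places
   the unfolding T_H, which lies far below any observable temperature and
   therefore cannot be read off an Eyring plot directly.  It searches the
   T_H that best maps rate constants measured at off-standard temperatures
   onto their independently measured 25 C values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .thermo import (
    R_GAS,
    T_STANDARD,
    EyringParams,
    Temperature,
    TemperatureLike,
    as_kelvin,
    beta_from_activation,
    correct_rate,
    delta_cp_from_length,
    ln_k_over_t,
    t_h_from_enthalpy,
)

__all__ = [
    "Direction",
    "FoldClass",
    "EyringSeries",
    "CorrectionParams",
    "PairedRateObservation",
    "fit_eyring",
    "panel_mean_se",
    "calibrate_folding_panel",
    "screen_overlarge_activation",
    "optimize_t_hu",
    "read_eyring_series",
]


class Direction(str, Enum):
    """Reaction direction of a rate constant."""

    FOLDING = "folding"
    UNFOLDING = "unfolding"


class FoldClass(str, Enum):
    """Kinetic folding class.

    ``TWO_STATE_HIDDEN`` (2S*) marks two-state folders whose chevron-limb
    curvature suggests a high-energy intermediate; for every correction
    purpose it behaves as two-state.
    """

    TWO_STATE = "2S"
    TWO_STATE_HIDDEN = "2S*"
    NON_TWO_STATE = "N2S"

    @property
    def effective_two_state(self) -> bool:
        return self is not FoldClass.NON_TWO_STATE


@dataclass(frozen=True)
class EyringSeries:
    """Rate measurements of one protein/reaction across temperatures."""

    protein_id: str
    direction: Direction
    temperatures_k: Tuple[float, ...]
    ln_k: Tuple[float, ...]

    def __post_init__(self) -> None:
        temps = tuple(as_kelvin(t) for t in self.temperatures_k)
        lnk = tuple(float(v) for v in self.ln_k)
        if len(temps) != len(lnk):
            raise ValueError("temperatures and ln_k must be the same length")
        if len(set(temps)) != len(temps):
            raise ValueError("temperatures must be pairwise distinct")
        object.__setattr__(self, "temperatures_k", temps)
        object.__setattr__(self, "ln_k", lnk)
        object.__setattr__(self, "direction", Direction(self.direction))

    def __len__(self) -> int:
        return len(self.temperatures_k)


@dataclass(frozen=True)
class CorrectionParams:
    """Panel-level (T_H, beta) pair with uncertainty.

    Standard errors are present only when the panel had >= 2 proteins.
    """

    direction: Direction
    fold_class: FoldClass
    t_h: Temperature
    beta: float
    t_h_se: Optional[float] = None
    beta_se: Optional[float] = None
    n_proteins: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))
        object.__setattr__(self, "fold_class", FoldClass(self.fold_class))
        if isinstance(self.t_h, (int, float)):
            object.__setattr__(self, "t_h", Temperature(float(self.t_h)))
        if self.n_proteins < 1:
            raise ValueError("a panel needs at least one protein")
        if self.n_proteins < 2 and (self.t_h_se is not None or self.beta_se is not None):
            raise ValueError("standard errors require >= 2 proteins")


@dataclass(frozen=True)
class PairedRateObservation:
    """One protein with ln k measured both at T_x and at the standard T_0.

    Used to validate the correction and to calibrate the unfolding T_H.
    ``t_target_k`` allows a per-record standard temperature (one entry in
    the validation panels was observed at 26 C rather than 25 C).
    """

    protein_id: str
    ln_k_x: float
    t_x_k: float
    ln_k_0_observed: float
    delta_cp_eq: float
    t_target_k: float = T_STANDARD.kelvin

    def __post_init__(self) -> None:
        object.__setattr__(self, "t_x_k", as_kelvin(self.t_x_k))
        object.__setattr__(self, "t_target_k", as_kelvin(self.t_target_k))
        if self.t_x_k == T_STANDARD.kelvin:
            raise ValueError(
                "paired observation requires T_x different from the standard 298.15 K"
            )
        if self.delta_cp_eq <= 0.0:
            raise ValueError("equilibrium heat capacity must be positive")


def _eyring_model(t: np.ndarray, c2: float, delta_cp_act: float, t_h: float) -> np.ndarray:
    return c2 - delta_cp_act / (R_GAS * t) * (t - t_h - t * np.log(t / t_h))


def fit_eyring(series: EyringSeries) -> EyringParams:
    """Fit (C2, dCp_act, T_H) to one Eyring series by least squares.

    The fit is performed on y = ln(k/T) against T.  Initial guesses are
    analytic: C2 from the extremal y, T_H from its location, and dCp_act
    from a quadratic pre-fit (the curvature at the extremum equals
    dCp_act / (R * T_H^2)).  On noiseless model data the parameters are
    recovered to ~1e-8 relative error.

    Raises
    ------
    ValueError
        For fewer than 3 points, or for a degenerate series (all ln k
        equal over a sub-Kelvin temperature span) where the curvature is
        unidentifiable.
    """
    if len(series) < 3:
        raise ValueError(
            f"Eyring fit needs >= 3 points, got {len(series)} for {series.protein_id}"
        )
    t = np.asarray(series.temperatures_k, dtype=float)
    y = np.asarray(series.ln_k, dtype=float) - np.log(t)
    span = t.max() - t.min()
    if span < 1.0 and np.allclose(series.ln_k, series.ln_k[0]):
        raise ValueError(
            f"series {series.protein_id} is degenerate (flat ln k over a {span:.3f} K span); "
            "curvature is not identifiable"
        )

    # analytic initial guesses
    coeffs = np.polyfit(t, y, 2)  # y ~ a2*T^2 + a1*T + a0
    a2 = coeffs[0]
    if a2 < 0:  # convex Eyring plot: folding-like, maximum at T_H
        i0 = int(np.argmax(y))
    else:  # concave: unfolding-like, minimum at T_H
        i0 = int(np.argmin(y))
    t_h0 = float(np.clip(-coeffs[1] / (2 * a2) if a2 != 0 else t[i0], 150.0, 400.0))
    c2_0 = float(y[i0])
    dcp0 = float(2.0 * a2 * R_GAS * t_h0**2)
    if dcp0 == 0.0:
        dcp0 = -1.0 if a2 <= 0 else 1.0

    popt, _ = curve_fit(
        _eyring_model,
        t,
        y,
        p0=(c2_0, dcp0, t_h0),
        maxfev=20000,
        xtol=1e-14,
        ftol=1e-14,
        bounds=((-np.inf, -np.inf, 1.0), (np.inf, np.inf, 2000.0)),
    )
    c2, dcp, t_h = (float(v) for v in popt)
    return EyringParams(delta_cp_act=dcp, t_h=Temperature(t_h), intercept=c2)


def panel_mean_se(values: Sequence[float]) -> Tuple[float, Optional[float]]:
    """Arithmetic mean and standard error of a panel column.

    The SE is the n-1 sample standard deviation over sqrt(n); it is absent
    (``None``) for a single value.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot average an empty panel")
    mean = float(arr.mean())
    if arr.size == 1:
        return mean, None
    se = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return mean, se


PanelEntry = Union[EyringParams, Tuple[float, float, float]]


def calibrate_folding_panel(
    panel: Sequence[PanelEntry],
    lengths: Sequence[int],
    fold_class: FoldClass = FoldClass.TWO_STATE,
    delta_cp_model: str = "with_intercept",
) -> CorrectionParams:
    """Average per-protein folding (T_H, beta) into panel-level parameters.

    Each panel entry is either an :class:`EyringParams` from
    :func:`fit_eyring` or a literature triple ``(t_a_k, delta_h_act,
    delta_cp_act)`` from which T_H follows as T_a - dH_act/dCp_act.  The
    per-protein beta is dCp_act over the chain-length dCp of the aligned
    entry in ``lengths``.

    Anomalous proteins with |dCp_act| exceeding the equilibrium dCp must
    be screened out *before* calling (see
    :func:`screen_overlarge_activation`); this function averages exactly
    what it is given.
    """
    if len(panel) != len(lengths):
        raise ValueError(f"{len(panel)} panel entries but {len(lengths)} lengths")
    if not panel:
        raise ValueError("empty calibration panel")
    t_hs: List[float] = []
    betas: List[float] = []
    for entry, l_pdb in zip(panel, lengths):
        if isinstance(entry, EyringParams):
            t_h = entry.t_h.kelvin
            dcp_act = entry.delta_cp_act
        else:
            t_a, dh, dcp_act = entry
            t_h = t_h_from_enthalpy(t_a, dh, dcp_act).kelvin
        if dcp_act >= 0.0:
            raise ValueError(
                f"folding activation heat capacity must be negative, got {dcp_act}"
            )
        t_hs.append(t_h)
        betas.append(beta_from_activation(dcp_act, delta_cp_from_length(l_pdb, delta_cp_model)))
    t_h_mean, t_h_se = panel_mean_se(t_hs)
    beta_mean, beta_se = panel_mean_se(betas)
    return CorrectionParams(
        direction=Direction.FOLDING,
        fold_class=fold_class,
        t_h=Temperature(t_h_mean),
        beta=beta_mean,
        t_h_se=t_h_se,
        beta_se=beta_se,
        n_proteins=len(panel),
    )


def screen_overlarge_activation(
    candidates: Iterable[Tuple[str, float, int]],
    delta_cp_model: str = "with_intercept",
) -> Tuple[List[Tuple[str, float, int]], List[Tuple[str, float, int]]]:
    """Partition (id, dCp_act, L_PDB) candidates by physical plausibility.

    An activation heat capacity cannot exceed the equilibrium unfolding
    heat capacity in magnitude; candidates with |dCp_act| > dCp(L_PDB) are
    excluded from calibration panels.  Returns ``(kept, excluded)``, an
    exhaustive and disjoint partition in input order.
    """
    kept: List[Tuple[str, float, int]] = []
    excluded: List[Tuple[str, float, int]] = []
    for cand in candidates:
        _, dcp_act, l_pdb = cand
        if abs(dcp_act) > delta_cp_from_length(l_pdb, delta_cp_model):
            excluded.append(cand)
        else:
            kept.append(cand)
    return kept, excluded


def _t_hu_rmsd(
    t_h: float, observations: Sequence[PairedRateObservation], beta_u: float
) -> float:
    sq = 0.0
    for obs in observations:
        pred = correct_rate(
            obs.ln_k_x,
            obs.t_x_k,
            beta_u * obs.delta_cp_eq,
            t_h,
            obs.t_target_k,
        )
        sq += (pred - obs.ln_k_0_observed) ** 2
    return math.sqrt(sq / len(observations))


def optimize_t_hu(
    observations: Sequence[PairedRateObservation],
    beta_u: float,
    search: Tuple[float, float, float] = (50.0, 298.0, 0.1),
) -> Tuple[Temperature, float]:
    """Place the unfolding T_H by RMSD minimization over paired observations.

    For each candidate T_H the rate measured at T_x is corrected to the
    standard temperature with dCp_act = beta_u * dCp and compared with the
    independently measured value there; the RMSD over the panel is
    minimized by a dense grid of spacing ``search[2]`` over
    ``[search[0], search[1]]`` followed by bounded local refinement.  Grid
    ties break toward the lower T_H.  Multiple rows of one protein count
    per-row.

    With a single observation the problem is underdetermined (a whole
    curve of T_H values reproduces one number exactly); the returned value
    is then simply the in-range minimizer.

    Returns
    -------
    (Temperature, float)
        The optimal T_H and the RMSD achieved there (ln-units).
    """
    observations = list(observations)
    if not observations:
        raise ValueError("at least one paired observation is required")
    if beta_u <= 0.0:
        raise ValueError(f"beta_u must be positive for unfolding, got {beta_u}")
    lo, hi, step = search
    if not (lo < hi) or step <= 0.0:
        raise ValueError(f"invalid search window {search}")

    grid = np.arange(lo, hi + step / 2, step)
    rmsds = np.array([_t_hu_rmsd(t, observations, beta_u) for t in grid])
    i_best = int(np.argmin(rmsds))  # argmin returns first minimum -> lower T_H on ties

    # local refinement inside the bracketing grid cells
    a = grid[max(i_best - 1, 0)]
    b = grid[min(i_best + 1, len(grid) - 1)]
    if a < b:
        res = minimize_scalar(
            _t_hu_rmsd,
            args=(observations, beta_u),
            bounds=(a, b),
            method="bounded",
            options={"xatol": min(step * 1e-4, 1e-6)},
        )
        if res.fun <= rmsds[i_best]:
            return Temperature(float(res.x)), float(res.fun)
    return Temperature(float(grid[i_best])), float(rmsds[i_best])


def read_eyring_series(
    path: Union[str, Path],
    protein_id: Optional[str] = None,
    direction: Direction = Direction.FOLDING,
) -> EyringSeries:
    """Read an Eyring series from a 2-column delimited text file.

    The file must declare its units in ``#`` header comments before any
    data row::

        # temperature: K          (or C)
        # rate: ln_k              (or k)
        280.0  5.71
        285.0, 6.02

    Columns may be separated by whitespace or a comma.  Malformed rows are
    errors, never silently skipped.
    """
    path = Path(path)
    temp_unit: Optional[str] = None
    rate_kind: Optional[str] = None
    temps: List[float] = []
    lnks: List[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip().lower()
            if body.startswith("temperature:"):
                temp_unit = body.split(":", 1)[1].strip().upper()
            elif body.startswith("rate:"):
                rate_kind = body.split(":", 1)[1].strip()
            continue
        if temp_unit not in ("K", "C"):
            raise ValueError(f"{path}:{lineno}: temperature unit not declared (expected '# temperature: K' or C)")
        if rate_kind not in ("k", "ln_k"):
            raise ValueError(f"{path}:{lineno}: rate kind not declared (expected '# rate: k' or ln_k)")
        fields = [f for f in line.replace(",", " ").split() if f]
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}: {raw!r}")
        try:
            t_val, r_val = float(fields[0]), float(fields[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric row {raw!r}") from exc
        t_k = t_val if temp_unit == "K" else t_val + 273.15
        ln_k = r_val if rate_kind == "ln_k" else math.log(r_val)
        temps.append(t_k)
        lnks.append(ln_k)
    if not temps:
        raise ValueError(f"{path}: no data rows found")
    return EyringSeries(
        protein_id=protein_id or path.stem,
        direction=direction,
        temperatures_k=tuple(temps),
        ln_k=tuple(lnks),
    )
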