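"""Three-compartment lysine-recycling kinetics.

After a diet switch from heavy (Lys8) to light (Lys0) food, unlabeled lysine
moves through three pools: the free amino-acid pool, the bulk ("all proteins")
pool, and each protein of interest. Writing the *unlabeled fraction* of each
pool as ``A(t)``, ``B(t)`` and ``F_i(t)``, the model is the linear system

    dA/dt = k_st * (1 - A) + k_a0 * (B - A)
    dB/dt = k_bt * (A - B)
    dF_i/dt = k_bi * (A - F_i)

with ``A(0) = B(0) = F_i(0) = 0``.  ``k_st`` is dietary influx of new lysine
into the free pool, ``k_bt`` is bulk-protein turnover (the source of recycled
labeled lysine), ``k_a0`` is the exchange of recycled lysine back into the
free pool, and ``k_bi`` is the replacement rate of the protein of interest.
All rates are per day; half-life is ``ln 2 / k_bi``.

The free-pool solution is biexponential, ``A(t) = 1 - c1 e^{-l1 t} -
c2 e^{-l2 t}`` where ``l1, l2`` are the roots of
``l^2 - (k_st + k_a0 + k_bt) l + k_st k_bt = 0`` and ``c1 + c2 = 1``.
``F_i`` follows by convolving ``A`` against the exponential age distribution
of protein molecules; everything below is evaluated in closed form with
numerically stable confluent limits for near-equal rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TissueCoefficients",
    "ModelCurves",
    "LabelCombinationPrediction",
    "K_MIN",
    "K_MAX",
    "precursor_fraction",
    "protein_fraction",
    "missed_cleavage_fractions",
    "half_life_from_rate",
    "rate_from_half_life",
    "flag_impossible_observations",
    "exogenous_suspect",
    "curve_table",
]

LN2 = math.log(2.0)

#: Bounds on the peptide replacement rate (per day).  They bracket half-lives
#: from about 15 minutes to ~14 years, well beyond what a 60-day chase can
#: resolve on either end.
K_MIN = LN2 / 5000.0
K_MAX = LN2 / 0.01


class InvalidCoefficientsError(ValueError):
    """Raised for non-positive or non-finite kinetic coefficients."""


class UndefinedHalfLifeError(ValueError):
    """Raised when converting a non-positive rate to a half-life."""


@dataclass(frozen=True)
class TissueCoefficients:
    """Tissue-level kinetic coefficients (per day).

    Attributes
    ----------
    k_st : float
        Dietary influx rate of unlabeled lysine into the free pool.
    k_bt : float
        Turnover rate of the bulk ("all proteins") pool.
    k_a0 : float
        Exchange rate of recycled lysine from the bulk pool into the
        free pool.
    """

    k_st: float
    k_bt: float
    k_a0: float

    def __post_init__(self) -> None:
        for name in ("k_st", "k_bt", "k_a0"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidCoefficientsError(
                    f"{name} must be strictly positive and finite, got {v!r}"
                )

    def eigen(self) -> "ModelCurves":
        """Diagonalize the free/bulk subsystem.

        Returns the decay rates and weights of the biexponential precursor
        solution.  With ``k_a0 > 0`` the discriminant is strictly positive,
        so the rates are always distinct.
        """
        s = self.k_st + self.k_a0 + self.k_bt
        p = self.k_st * self.k_bt
        disc = s * s - 4.0 * p
        root = math.sqrt(max(disc, 0.0))
        lam1 = 0.5 * (s + root)
        lam2 = p / lam1  # stable for small lam2
        if lam1 == lam2:
            c1, c2 = 0.5, 0.5
        else:
            c1 = (self.k_st - lam2) / (lam1 - lam2)
            c2 = 1.0 - c1
        return ModelCurves(lam1=lam1, lam2=lam2, c1=c1, c2=c2)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.k_st, self.k_bt, self.k_a0)

    def scaled(self, f_st: float, f_bt: float, f_a0: float) -> "TissueCoefficients":
        return TissueCoefficients(self.k_st * f_st, self.k_bt * f_bt, self.k_a0 * f_a0)


@dataclass(frozen=True)
class ModelCurves:
    """Eigen-decomposition of the precursor curve: A(t) = 1 - c1 e^{-l1 t} - c2 e^{-l2 t}."""

    lam1: float
    lam2: float
    c1: float
    c2: float


@dataclass(frozen=True)
class LabelCombinationPrediction:
    """Expected fractions of the three label combinations of a two-lysine peptide."""

    p00: float  # Lys0-Lys0, fully unlabeled
    p08: float  # Lys0-Lys8, mixed
    p88: float  # Lys8-Lys8, fully labeled


def _check_time(t: np.ndarray) -> None:
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("time must be finite and non-negative (days)")


def _phi(x: np.ndarray) -> np.ndarray:
    """(e^x - 1)/x with the removable singularity at 0 filled in."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0.0
    out[nz] = np.expm1(x[nz]) / x[nz]
    return out


def precursor_fraction(coeffs: TissueCoefficients, t) -> np.ndarray | float:
    """Unlabeled fraction A(t) of the free lysine pool.

    Monotone non-decreasing from A(0) = 0 toward 1.  Accepts scalar or
    array times (days).
    """
    t_arr = np.asarray(t, dtype=float)
    _check_time(t_arr)
    e = coeffs.eigen()
    delta = e.lam1 - e.lam2
    # 1 - A = e^{-l2 t} (1 - (k_st - l2) * t * phi(-delta t)); exact for
    # delta -> 0 as well.
    labeled = np.exp(-e.lam2 * t_arr) * (
        1.0 - (coeffs.k_st - e.lam2) * t_arr * _phi(-delta * t_arr)
    )
    a = np.clip(1.0 - labeled, 0.0, 1.0)
    return float(a) if np.isscalar(t) or a.ndim == 0 else a


def _conv_exp(k, mu, t):
    """G(mu) = int_0^t k e^{-k (t-s)} e^{-mu s} ds, elementwise and stable.

    This is the convolution of an exponential age distribution (rate ``k``)
    with a decaying exponential of the synthesis time.  Broadcasts ``k``,
    ``mu`` and ``t``.
    """
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    t = np.asarray(t, dtype=float)
    k, mu, t = np.broadcast_arrays(k, mu, t)
    x = (k - mu) * t
    small = np.abs(x) < 1e-7
    denom = np.where(small, 1.0, k - mu)
    direct = k * (np.exp(-mu * t) - np.exp(-k * t)) / denom
    # confluent limit k -> mu: k t e^{-k t} (1 + x/2 + x^2/6)
    conf = k * t * np.exp(-k * t) * (1.0 + x / 2.0 + x * x / 6.0)
    out = np.where(small, conf, direct)
    return out


def protein_fraction(coeffs: TissueCoefficients, k_bi, t) -> np.ndarray | float:
    """Unlabeled fraction F_i(t) of a protein with replacement rate ``k_bi``.

    Equals the convolution of the precursor curve with the exponential
    age distribution of the protein's molecules:
    ``F_i(t) = int_0^t k_bi e^{-k_bi (t-s)} A(s) ds``.
    ``k_bi`` and ``t`` broadcast; ``k_bi = 0`` gives 0 (no turnover).
    """
    t_arr = np.asarray(t, dtype=float)
    _check_time(t_arr)
    k_arr = np.asarray(k_bi, dtype=float)
    if np.any(k_arr < 0) or not np.all(np.isfinite(k_arr)):
        raise ValueError("k_bi must be finite and non-negative (per day)")
    e = coeffs.eigen()
    f = (
        _conv_exp(k_arr, 0.0, t_arr)
        - e.c1 * _conv_exp(k_arr, e.lam1, t_arr)
        - e.c2 * _conv_exp(k_arr, e.lam2, t_arr)
    )
    f = np.clip(f, 0.0, 1.0)
    if np.isscalar(t) and np.isscalar(k_bi):
        return float(f)
    return f


def missed_cleavage_fractions(
    coeffs: TissueCoefficients, k_bi: float, t
) -> LabelCombinationPrediction:
    """Expected Lys0Lys0 / Lys0Lys8 / Lys8Lys8 fractions of a two-lysine peptide.

    Both lysines of a molecule are drawn independently from the precursor
    pool at the molecule's synthesis time ``s``, so

        p00 = int_0^t k_bi e^{-k_bi (t-s)} A(s)^2 ds
        p08 = int_0^t k_bi e^{-k_bi (t-s)} 2 A(s) (1 - A(s)) ds
        p88 = 1 - p00 - p08   (molecules made before the switch are 8/8).

    Exact identities: ``p00 + p08 + p88 = 1`` and
    ``p00 + p08/2 = protein_fraction(coeffs, k_bi, t)``.
    """
    t_arr = np.asarray(t, dtype=float)
    _check_time(t_arr)
    if not (np.isfinite(k_bi) and k_bi >= 0):
        raise ValueError("k_bi must be finite and non-negative")
    e = coeffs.eigen()
    g = lambda mu: _conv_exp(k_bi, mu, t_arr)  # noqa: E731
    f = g(0.0) - e.c1 * g(e.lam1) - e.c2 * g(e.lam2)
    # A^2 expands into exponentials with rates 0, l1, l2, 2 l1, l1+l2, 2 l2.
    p00 = (
        g(0.0)
        - 2.0 * e.c1 * g(e.lam1)
        - 2.0 * e.c2 * g(e.lam2)
        + e.c1 * e.c1 * g(2.0 * e.lam1)
        + 2.0 * e.c1 * e.c2 * g(e.lam1 + e.lam2)
        + e.c2 * e.c2 * g(2.0 * e.lam2)
    )
    p00 = np.clip(p00, 0.0, 1.0)
    p08 = np.clip(2.0 * (f - p00), 0.0, 1.0)
    p88 = np.clip(1.0 - p00 - p08, 0.0, 1.0)
    if np.isscalar(t):
        return LabelCombinationPrediction(float(p00), float(p08), float(p88))
    return LabelCombinationPrediction(p00, p08, p88)


def half_life_from_rate(k_bi: float) -> float:
    """Half-life in days, ``ln 2 / k_bi``, for a strictly positive rate."""
    if not (np.isfinite(k_bi) and k_bi > 0):
        raise UndefinedHalfLifeError(f"half-life undefined for k_bi={k_bi!r}")
    return LN2 / k_bi


def rate_from_half_life(half_life: float) -> float:
    """Replacement rate per day, ``ln 2 / t_half``."""
    if not (np.isfinite(half_life) and half_life > 0):
        raise UndefinedHalfLifeError(f"rate undefined for half-life={half_life!r}")
    return LN2 / half_life


def flag_impossible_observations(
    t: Sequence[float],
    ratio: Sequence[float],
    coeffs: TissueCoefficients,
    tol: float = 0.05,
) -> np.ndarray:
    """Flag observations lying above the free-lysine curve.

    No endogenous protein can incorporate unlabeled lysine faster than the
    free pool supplies it, so a ratio above ``A(t) + tol`` indicates an
    exogenous protein (e.g. plasma albumin diffused into a solid tissue)
    synthesized with access to a different precursor pool.

    Returns a boolean array aligned with the input observations.
    """
    t_arr = np.asarray(t, dtype=float)
    r_arr = np.asarray(ratio, dtype=float)
    if t_arr.size == 0:
        return np.zeros(0, dtype=bool)
    a = precursor_fraction(coeffs, t_arr)
    return r_arr > np.asarray(a) + tol


def exogenous_suspect(
    t: Sequence[float],
    ratio: Sequence[float],
    coeffs: TissueCoefficients,
    tol: float = 0.05,
    min_fraction: float = 0.5,
) -> bool:
    """A peptide is exogenous-suspect when >= ``min_fraction`` of its
    observations lie in the impossible region above the precursor curve."""
    flags = flag_impossible_observations(t, ratio, coeffs, tol)
    if flags.size == 0:
        return False
    return float(flags.mean()) >= min_fraction


def curve_table(
    coeffs: TissueCoefficients,
    k_bi_values: Iterable[float],
    t_max: float,
    n_points: int = 200,
):
    """Plot-ready table of the precursor and protein curves.

    Grid spans 0 to ``1.2 * t_max`` with ``n_points`` points. Columns:
    ``t_d``, ``precursor``, then one ``F_<half-life>d`` column per rate.
    Returns a pandas DataFrame.
    """
    import pandas as pd

    grid = np.linspace(0.0, 1.2 * t_max, n_points)
    out = {"t_d": grid, "precursor": np.asarray(precursor_fraction(coeffs, grid))}
    for k in k_bi_values:
        label = f"F_{half_life_from_rate(k):.4g}d" if k > 0 else "F_inf"
        out[label] = np.asarray(protein_fraction(coeffs, k, grid))
    return pd.DataFrame(out)
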