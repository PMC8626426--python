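"""Cross-tissue and proteoform half-life comparisons.

Observed ratios from two tissues cannot be compared directly because the
tissues sit at different points of their labeling curves at any calendar
timepoint.  Comparison therefore shifts each ratio onto a common
*normalization timepoint* ``t*``: with ``kbar`` the mean of the two
replacement rates, ``t*`` is where the mean predicted fraction of the two
tissues crosses 0.5, and each observed ratio ``r`` at time ``t`` in tissue
``x`` becomes ``r - F_x(t; kbar) + F_x(t*; kbar)``.  The shift is constant
within a tissue-timepoint, so all per-timepoint standard deviations are
preserved.  A two-tailed t-test (Welch by default) on the normalized sets
gives the p-value; the fold change is ``log2`` of the half-life ratio.

Proteoform comparisons pair a modified peptidoform with its unmodified twin
(same base sequence, protein and tissue) and apply the same machinery;
a difference is called significant at |log2 FC| > 0.25 and p < 1e-4, and
pairs involving methionine oxidation or a half-life under 3 days are
omitted before testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .io import PeptideSeries, modification_tokens
from .model import TissueCoefficients, protein_fraction, rate_from_half_life

__all__ = [
    "ComparisonResult",
    "NormalizationError",
    "normalization_timepoint",
    "normalize_ratios",
    "compare_groups",
    "compare_protein",
    "compare_proteoforms",
]

PROTEOFORM_LOG2FC_THRESHOLD = 0.25
PROTEOFORM_P_THRESHOLD = 1e-4
PROTEOFORM_MIN_HALF_LIFE = 3.0


class NormalizationError(RuntimeError):
    """No normalization timepoint exists for the given kinetics."""


@dataclass
class ComparisonResult:
    """One half-life comparison (protein across tissues, or peptidoform pair)."""

    identifier: str
    group_a: str
    group_b: str
    half_life_a: float
    half_life_b: float
    log2_fold_change: float
    p_value: float
    n_a: int
    n_b: int
    significant: bool | None = None
    omitted_reason: str | None = None

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_value) if self.p_value > 0 else math.inf


def normalization_timepoint(
    k_mean: float,
    coeffs_a: TissueCoefficients,
    coeffs_b: TissueCoefficients,
    t_max: float = 1e4,
    tol: float = 1e-9,
) -> float:
    """Timepoint ``t*`` where the mean predicted fraction of the two tissues
    reaches 0.5, found by bracketed root solving on [0, t_max] days."""

    def g(t: float) -> float:
        fa = float(protein_fraction(coeffs_a, k_mean, t))
        fb = float(protein_fraction(coeffs_b, k_mean, t))
        return 0.5 * (fa + fb) - 0.5

    if g(t_max) <= 0.0:
        raise NormalizationError(
            f"mean predicted fraction never reaches 0.5 by t={t_max} d "
            f"(k_mean={k_mean:.3g}/d)"
        )
    return float(optimize.brentq(g, 0.0, t_max, xtol=tol))


def normalize_ratios(
    t: np.ndarray,
    ratios: np.ndarray,
    coeffs: TissueCoefficients,
    k_mean: float,
    t_star: float,
) -> np.ndarray:
    """Shift observed ratios onto the normalization timepoint:
    ``r - F(t; k_mean) + F(t*; k_mean)``."""
    f_t = np.asarray(protein_fraction(coeffs, k_mean, np.asarray(t, dtype=float)))
    f_star = float(protein_fraction(coeffs, k_mean, t_star))
    return np.asarray(ratios, dtype=float) - f_t + f_star


def compare_groups(
    identifier: str,
    group_a: str,
    half_life_a: float,
    t_a: np.ndarray,
    r_a: np.ndarray,
    coeffs_a: TissueCoefficients,
    group_b: str,
    half_life_b: float,
    t_b: np.ndarray,
    r_b: np.ndarray,
    coeffs_b: TissueCoefficients,
    welch: bool = True,
) -> ComparisonResult:
    """Normalize both ratio sets and run the two-tailed t-test.

    With fewer than two ratios on either side the p-value is undefined
    (reported as NaN, no significance call).
    """
    k_a = rate_from_half_life(half_life_a)
    k_b = rate_from_half_life(half_life_b)
    k_mean = 0.5 * (k_a + k_b)
    t_star = normalization_timepoint(k_mean, coeffs_a, coeffs_b)
    na, nb = len(r_a), len(r_b)
    log2fc = math.log2(half_life_a / half_life_b)
    if na < 2 or nb < 2:
        p = math.nan
    else:
        norm_a = normalize_ratios(t_a, r_a, coeffs_a, k_mean, t_star)
        norm_b = normalize_ratios(t_b, r_b, coeffs_b, k_mean, t_star)
        res = stats.ttest_ind(norm_a, norm_b, equal_var=not welch)
        p = float(res.pvalue)
        if not np.isfinite(p):
            p = 1.0
        p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return ComparisonResult(
        identifier=identifier,
        group_a=group_a,
        group_b=group_b,
        half_life_a=half_life_a,
        half_life_b=half_life_b,
        log2_fold_change=log2fc,
        p_value=p,
        n_a=na,
        n_b=nb,
    )


def compare_protein(
    protein_id: str,
    tissue_a: str,
    half_life_a: float,
    series_a: list[PeptideSeries],
    coeffs_a: TissueCoefficients,
    tissue_b: str,
    half_life_b: float,
    series_b: list[PeptideSeries],
    coeffs_b: TissueCoefficients,
    welch: bool = True,
) -> ComparisonResult:
    """Compare one protein's half-life between two tissues.

    The observed ratios of all constituent peptides in each tissue are
    pooled, normalized to the common timepoint, and t-tested.
    """
    t_a, r_a = _pool_points(series_a)
    t_b, r_b = _pool_points(series_b)
    return compare_groups(
        protein_id, tissue_a, half_life_a, t_a, r_a, coeffs_a,
        tissue_b, half_life_b, t_b, r_b, coeffs_b, welch=welch,
    )


def _pool_points(series_list: list[PeptideSeries]) -> tuple[np.ndarray, np.ndarray]:
    ts, rs = [], []
    for s in series_list:
        t, r = s.valid_points()
        ts.append(t)
        rs.append(r)
    if not ts:
        return np.empty(0), np.empty(0)
    return np.concatenate(ts), np.concatenate(rs)


def _is_met_oxidation(token: str) -> bool:
    low = token.lower()
    return "oxidation" in low and ("m" in low.split(" on ")[-1] if " on " in low else "m" in low)


def compare_proteoforms(
    peptide_results: list[dict],
    coeffs_by_tissue: dict[str, TissueCoefficients],
    welch: bool = True,
) -> list[ComparisonResult]:
    """Pair modified peptidoforms with their unmodified twins and test them.

    ``peptide_results`` entries need keys: ``tissue``, ``series``
    (PeptideSeries) and ``half_life``.  Pairing is within (tissue, protein,
    base sequence): the unmodified twin is the peptidoform whose full
    sequence equals the base sequence.  Pairs involving methionine
    oxidation, or where either half-life is under 3 days, are reported as
    omitted without a test.  Significant requires |log2 FC| > 0.25 and
    p < 1e-4.
    """
    by_key: dict[tuple[str, str, str], list[dict]] = {}
    for entry in peptide_results:
        s: PeptideSeries = entry["series"]
        key = (entry["tissue"], s.protein_id, s.base_sequence)
        by_key.setdefault(key, []).append(entry)
    out: list[ComparisonResult] = []
    for (tissue, protein_id, base), entries in sorted(by_key.items()):
        unmodified = [e for e in entries if e["series"].full_sequence == base]
        modified = [e for e in entries if e["series"].full_sequence != base]
        if not unmodified or not modified:
            continue
        twin = unmodified[0]
        coeffs = coeffs_by_tissue[tissue]
        for mod in sorted(modified, key=lambda e: e["series"].full_sequence):
            ident = f"{protein_id}:{mod['series'].full_sequence}"
            tokens = modification_tokens(mod["series"].full_sequence)
            reason = None
            if any(_is_met_oxidation(tok) for tok in tokens):
                reason = "methionine-oxidation"
            elif (
                mod["half_life"] < PROTEOFORM_MIN_HALF_LIFE
                or twin["half_life"] < PROTEOFORM_MIN_HALF_LIFE
            ):
                reason = "half-life-below-3d"
            if reason is not None:
                out.append(
                    ComparisonResult(
                        identifier=ident,
                        group_a=f"{tissue}:modified",
                        group_b=f"{tissue}:unmodified",
                        half_life_a=mod["half_life"],
                        half_life_b=twin["half_life"],
                        log2_fold_change=math.log2(
                            mod["half_life"] / twin["half_life"]
                        ),
                        p_value=math.nan,
                        n_a=mod["series"].n_valid,
                        n_b=twin["series"].n_valid,
                        significant=None,
                        omitted_reason=reason,
                    )
                )
                continue
            t_m, r_m = mod["series"].valid_points()
            t_u, r_u = twin["series"].valid_points()
            res = compare_groups(
                ident,
                f"{tissue}:modified", mod["half_life"], t_m, r_m, coeffs,
                f"{tissue}:unmodified", twin["half_life"], t_u, r_u, coeffs,
                welch=welch,
            )
            res.significant = bool(
                abs(res.log2_fold_change) > PROTEOFORM_LOG2FC_THRESHOLD
                and np.isfinite(res.p_value)
                and res.p_value < PROTEOFORM_P_THRESHOLD
            )
            out.append(res)
    return out
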