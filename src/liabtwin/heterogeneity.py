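"""Stratified heritability and between-stratum Z-tests.

Fits the biometric model separately within levels of a stratifier (sex,
birth-cohort band, education, income, ...) and compares heritability
estimates between strata with a two-sample Z statistic

    z = (a2_a - a2_b) / sqrt(se_a^2 + se_b^2),   p = 2 * (1 - Phi(|z|)).

Sex-stratified fits need the twin_sibling design: within one sex there is
no opposite-sex twin group, so same-sex twins are contrasted with
same-sex sibling pairs instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .biometric import BiometricModel, BiometricResults, WeinbergAdjustment, weinberg
from .data import aggregate

__all__ = ["StratumComparison", "fit_stratified", "compare_strata", "forest_plot"]


@dataclass(frozen=True)
class StratumComparison:
    """Two-sample Z-test for a heritability difference between strata."""

    stratum_a: str
    stratum_b: str
    a2_a: float
    a2_b: float
    se_a: float
    se_b: float
    z: float
    p: float
    significant_05: bool
    reliable: bool = True


def fit_stratified(
    records: pd.DataFrame,
    stratify_by: str,
    model: str = "ACE",
    design: str = "twin",
    gamma: str | float = "global",
    **model_kwargs,
) -> dict[str, BiometricResults]:
    """One biometric fit per stratum level.

    Parameters
    ----------
    records : DataFrame
        Pair-level records including the stratifier column.
    gamma : {"global", "auto"} or float
        "global" (default) computes the Weinberg adjustment once from the
        full sample's same-sex/opposite-sex counts and reuses it in every
        stratum; "auto" recomputes it within each stratum; a float fixes
        the same-sex genetic correlation directly.

    Strata whose tables cannot identify the model are reported as skipped
    with a warning rather than silently dropped.
    """
    if stratify_by not in records.columns:
        raise ValueError(f"stratifier {stratify_by!r} not found in records")
    levels = records[stratify_by].dropna().unique()
    if len(levels) < 2:
        raise ValueError(
            f"stratifier {stratify_by!r} has a single level; nothing to compare"
        )

    adjustment = _resolve_gamma(records, gamma)
    tables = aggregate(records, stratify_by=stratify_by)

    fits: dict[str, BiometricResults] = {}
    for level in sorted(map(str, levels)):
        sub = [t for t in tables if t.stratum == level]
        groups_present = {t.group for t in sub}
        if design == "twin" and "opposite_sex" not in groups_present:
            raise ValueError(
                f"stratum {level!r} has no opposite-sex twin pairs under "
                "design='twin' (e.g. a sex-stratified fit); use "
                "design='twin_sibling', which contrasts same-sex twins with "
                "same-sex sibling pairs"
            )
        adj = adjustment
        if adj is None:  # per-stratum recomputation
            n_ss = sum(t.n_total for t in sub if t.group == "same_sex")
            n_os = sum(t.n_total for t in sub if t.group == "opposite_sex")
            adj = weinberg(n_ss, n_os) if n_ss >= 1 else None
        try:
            mod = BiometricModel(
                sub, model=model, adjustment=adj, design=design, **model_kwargs
            )
            fits[level] = mod.fit()
            fits[level].stratum = level
        except ValueError as err:
            warnings.warn(
                f"stratum {level!r} skipped: {err}", RuntimeWarning, stacklevel=2
            )
    return fits


def _resolve_gamma(records, gamma) -> WeinbergAdjustment | None:
    if gamma == "auto":
        return None
    if gamma == "global":
        n_ss = float((records["group"] == "same_sex").sum())
        n_os = float((records["group"] == "opposite_sex").sum())
        if n_ss < 1:
            raise ValueError("no same-sex pairs; cannot compute Weinberg adjustment")
        return weinberg(n_ss, n_os)
    g = float(gamma)
    if not 0.5 <= g <= 1.0:
        raise ValueError(f"gamma must lie in [0.5, 1], got {g}")
    p_mz = 2.0 * g - 1.0
    return WeinbergAdjustment(np.nan, np.nan, p_mz, g, p_mz + 0.25 * (1 - p_mz))


def compare_strata(
    fit_a: BiometricResults, fit_b: BiometricResults
) -> StratumComparison:
    """Z-test for equality of heritability between two stratified fits."""
    if fit_a.model != fit_b.model:
        raise ValueError("fits use different models; comparison undefined")
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged")
    se2 = fit_a.se_a2**2 + fit_b.se_a2**2
    if se2 <= 0:
        raise ValueError("degenerate variance: both standard errors are zero")
    reliable = not (fit_a.boundary or fit_b.boundary)
    if not reliable:
        warnings.warn(
            "a component sits at the zero boundary; Z-test standard errors "
            "may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    z = (fit_a.a2 - fit_b.a2) / np.sqrt(se2)
    p = 2.0 * (1.0 - ndtr(abs(z)))
    return StratumComparison(
        stratum_a=fit_a.stratum,
        stratum_b=fit_b.stratum,
        a2_a=fit_a.a2,
        a2_b=fit_b.a2,
        se_a=fit_a.se_a2,
        se_b=fit_b.se_a2,
        z=float(z),
        p=float(p),
        significant_05=bool(p < 0.05),
        reliable=reliable,
    )


def forest_plot(fits: dict[str, BiometricResults], ax=None):
    """Point estimates of a2 with 95% CIs per stratum (forest layout)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.6 * len(fits) + 1.5))
    labels = list(fits)
    for i, lab in enumerate(labels):
        f = fits[lab]
        lo, hi = f.conf_int()["a2"]
        ax.errorbar(
            f.a2, i, xerr=[[f.a2 - lo], [hi - f.a2]],
            fmt="o", color="k", capsize=3,
        )
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels)
    ax.set_xlabel("heritability $a^2$ (liability scale)")
    ax.set_xlim(0, 1)
    ax.invert_yaxis()
    return ax
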