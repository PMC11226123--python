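"""Biometric variance decomposition for binary phenotypes with unknown zygosity.

The classical twin design contrasts MZ and DZ pair correlations.  When a
registry records no zygosity, twin sex stands in for it: opposite-sex
pairs are certainly DZ (genetic correlation 1/2), while the same-sex
group is a mixture of MZ and DZ pairs.  Weinberg's differential rule
estimates the MZ proportion among same-sex pairs from the same-sex /
opposite-sex count imbalance (DZ sexes assort independently, so DZ pairs
split evenly), and the same-sex group is assigned the mixture-averaged
genetic correlation

    gamma = p_MZ * 1 + (1 - p_MZ) * 1/2.

The ACE (or ADE) liability-threshold model is then fitted by joint
maximum likelihood on the per-group 2x2 concordance tables: the expected
liability correlation in group g is

    r_g = kappa_g * a^2 + c^2          (ACE)
    r_g = kappa_g * a^2 + delta_g * d^2  (ADE)

with kappa = gamma (same-sex twins) or 1/2 (opposite-sex twins,
siblings), and cell probabilities from the shared-threshold bivariate
normal.  Components are parameterized through path coefficients
(a, c or d) so they are non-negative by construction, and e^2 is the
standardization remainder 1 - a^2 - c^2(or d^2).

A closed-form method-of-moments solver (`mom_oracle`) inverts the
two-group correlation equations directly and serves as an independent
cross-check of the ML route.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtr

from .data import ConcordanceTable, aggregate
from .tetrachoric import _num_hessian, cell_probabilities, fit_tetrachoric

__all__ = [
    "WeinbergAdjustment",
    "GroupCoefficients",
    "weinberg",
    "expected_pair_correlation",
    "mom_oracle",
    "BiometricModel",
    "BiometricResults",
    "fit_biometric",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class WeinbergAdjustment:
    """MZ proportion and mixture-adjusted sharing coefficients for the
    same-sex twin group."""

    n_same_sex: float
    n_opposite_sex: float
    p_mz: float
    gamma: float
    delta_same_sex: float


def weinberg(n_same_sex: float, n_opposite_sex: float) -> WeinbergAdjustment:
    """Weinberg's differential rule.

    p_MZ = (N_ss - N_os) / N_ss; the adjusted genetic correlation of the
    same-sex group is gamma = p_MZ + (1 - p_MZ)/2, equivalently
    (N_ss - N_os)/N_ss + 0.5 * N_os/N_ss.  The dominance analogue uses
    the DZ coefficient 1/4.  A negative p_MZ (more opposite-sex than
    same-sex pairs) is clipped to 0 with a warning.
    """
    if n_same_sex < 1:
        raise ValueError("need at least one same-sex pair")
    p_mz = (n_same_sex - n_opposite_sex) / n_same_sex
    if p_mz < 0:
        warnings.warn(
            "more opposite-sex than same-sex pairs; MZ proportion clipped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        p_mz = 0.0
    gamma = p_mz + 0.5 * (1.0 - p_mz)
    delta_ss = p_mz + 0.25 * (1.0 - p_mz)
    return WeinbergAdjustment(n_same_sex, n_opposite_sex, p_mz, gamma, delta_ss)


@dataclass(frozen=True)
class GroupCoefficients:
    """Sharing coefficients entering the expected pair correlation."""

    group: str
    kappa: float
    delta: float
    c_coef: float = 1.0


def group_coefficients(
    adjustment: WeinbergAdjustment, sibling_c_coef: float = 1.0
) -> dict[str, GroupCoefficients]:
    """Coefficient table for the three observable groups."""
    return {
        "same_sex": GroupCoefficients(
            "same_sex", adjustment.gamma, adjustment.delta_same_sex, 1.0
        ),
        "opposite_sex": GroupCoefficients("opposite_sex", 0.5, 0.25, 1.0),
        "sibling": GroupCoefficients("sibling", 0.5, 0.25, sibling_c_coef),
    }


def expected_pair_correlation(
    model: str, a2: float, c2_or_d2: float, coeffs: GroupCoefficients
) -> float:
    """Expected liability correlation for one group under ACE or ADE."""
    if model == "ACE":
        r = coeffs.kappa * a2 + coeffs.c_coef * c2_or_d2
    elif model == "ADE":
        r = coeffs.kappa * a2 + coeffs.delta * c2_or_d2
    else:
        raise ValueError(f"model must be 'ACE' or 'ADE', got {model!r}")
    return float(r)


def mom_oracle(
    r_ss: float,
    r_other: float,
    adjustment: WeinbergAdjustment,
    model: str = "ACE",
) -> tuple[float, float, float]:
    """Closed-form method-of-moments solution from two group correlations.

    ACE:  a2 = (r_ss - r_os) / (gamma - 1/2);  c2 = r_os - a2/2.
    ADE:  solve [[gamma, delta_ss], [1/2, 1/4]] (a2, d2)' = (r_ss, r_os)'.

    The raw algebraic solution is returned without truncation; values can
    fall outside [0, 1] under sampling noise.
    """
    g = adjustment.gamma
    d_ss = adjustment.delta_same_sex
    if model == "ACE":
        if abs(g - 0.5) < 1e-12:
            raise ValueError("gamma = 1/2: ACE components not identified")
        a2 = (r_ss - r_other) / (g - 0.5)
        c2 = r_other - 0.5 * a2
    elif model == "ADE":
        coef = np.array([[g, d_ss], [0.5, 0.25]])
        if abs(np.linalg.det(coef)) < 1e-12:
            raise ValueError("singular coefficient matrix: ADE not identified")
        a2, c2 = np.linalg.solve(coef, [r_ss, r_other])
    else:
        raise ValueError(f"model must be 'ACE' or 'ADE', got {model!r}")
    return float(a2), float(c2), float(1.0 - a2 - c2)


_DESIGN_GROUPS = {
    "twin": ("same_sex", "opposite_sex"),
    "twin_sibling": ("same_sex", "sibling"),
}


@dataclass
class BiometricResults:
    """Fitted standardized variance components on the liability scale.

    a2, c2_or_d2 and e2 sum to one exactly; standard errors are
    delta-method transforms of the observed information of the path
    coefficients, and 95% Wald intervals are truncated to [0, 1].  When a
    component sits at the zero boundary its Wald SE is unreliable and
    ``boundary`` is set; `conf_int(method="profile")` gives
    likelihood-based intervals instead.
    """

    model: str
    design: str
    a2: float
    c2_or_d2: float
    e2: float
    se_a2: float
    se_c2_or_d2: float
    tau: float
    llf: float
    n_pairs_by_group: dict[str, float]
    converged: bool
    boundary: bool
    gamma: float
    stratum: str = "all"
    _model_obj: "BiometricModel | None" = None

    @property
    def component_label(self) -> str:
        return "c2" if self.model == "ACE" else "d2"

    def conf_int(self, method: str = "auto") -> dict[str, tuple[float, float]]:
        """95% confidence intervals for a2 and c2 (or d2).

        method="auto" (default) uses Wald intervals in the interior and
        switches to profile-likelihood intervals when a component sits at
        the zero boundary, where the observed information decouples and
        Wald SEs understate uncertainty.  "wald" and "profile" force one
        route.
        """
        if method == "auto":
            method = "profile" if self.boundary else "wald"
        if method == "wald":
            lo_a = max(0.0, self.a2 - _Z95 * self.se_a2)
            hi_a = min(1.0, self.a2 + _Z95 * self.se_a2)
            lo_c = max(0.0, self.c2_or_d2 - _Z95 * self.se_c2_or_d2)
            hi_c = min(1.0, self.c2_or_d2 + _Z95 * self.se_c2_or_d2)
            return {"a2": (lo_a, hi_a), self.component_label: (lo_c, hi_c)}
        if method == "profile":
            if self._model_obj is None:
                raise ValueError("profile intervals need the originating model")
            return {
                "a2": self._model_obj._profile_ci(self, "a2"),
                self.component_label: self._model_obj._profile_ci(self, "c2_or_d2"),
            }
        raise ValueError(f"unknown method {method!r}")

    def summary(self) -> str:
        ci = self.conf_int()
        comp = self.component_label
        lines = [
            f"Liability-threshold {self.model} model ({self.design} design)",
            f"  stratum          : {self.stratum}",
            f"  gamma (same-sex) : {self.gamma:.4f}",
            "  pairs by group   : "
            + ", ".join(f"{g}={n:.0f}" for g, n in self.n_pairs_by_group.items()),
            f"  a2  (A)          : {self.a2:.4f}  SE {self.se_a2:.4f}  "
            f"95% CI [{ci['a2'][0]:.4f}, {ci['a2'][1]:.4f}]",
            f"  {comp}  ({'C' if comp == 'c2' else 'D'})          : "
            f"{self.c2_or_d2:.4f}  SE {self.se_c2_or_d2:.4f}  "
            f"95% CI [{ci[comp][0]:.4f}, {ci[comp][1]:.4f}]",
            f"  e2  (E)          : {self.e2:.4f}",
            f"  threshold tau    : {self.tau:.4f}",
            f"  log-likelihood   : {self.llf:.3f}",
            f"  converged        : {self.converged}",
        ]
        if self.boundary:
            lines.append(
                "  note: component at the zero boundary; Wald SEs unreliable, "
                "reported CIs are profile-likelihood"
            )
        return "\n".join(lines)


class BiometricModel:
    """Joint ML fit of an ACE or ADE liability-threshold model across
    twin/sibling groups.

    Parameters
    ----------
    tables : sequence of ConcordanceTable
        One symmetrized table per group; at least two groups with
        distinct genetic-sharing coefficients are required.
    model : {"ACE", "ADE"}
    adjustment : WeinbergAdjustment, optional
        Same-sex mixture adjustment.  When omitted it is computed from
        the same-sex / opposite-sex table weights; the twin_sibling
        design has no opposite-sex group, so it must be supplied there.
    design : {"twin", "twin_sibling"}
        Which two groups identify the decomposition.
    shared_tau : bool
        Single threshold across groups (default) or one per group.
    sibling_c_coef : float
        Shared-environment coefficient for sibling pairs; 1 by default,
        exposed as a sensitivity knob for sibling designs.
    """

    def __init__(
        self,
        tables,
        model: str = "ACE",
        adjustment: WeinbergAdjustment | None = None,
        design: str = "twin",
        shared_tau: bool = True,
        sibling_c_coef: float = 1.0,
    ):
        if model not in ("ACE", "ADE"):
            raise ValueError(f"model must be 'ACE' or 'ADE', got {model!r}")
        if design not in _DESIGN_GROUPS:
            raise ValueError(f"design must be one of {tuple(_DESIGN_GROUPS)}")
        wanted = _DESIGN_GROUPS[design]
        by_group: dict[str, ConcordanceTable] = {}
        for t in tables:
            if t.group in wanted:
                if t.group in by_group:
                    raise ValueError(f"multiple tables for group {t.group!r}")
                by_group[t.group] = t
        missing = [g for g in wanted if g not in by_group]
        if missing:
            raise ValueError(
                f"design {design!r} needs groups {wanted}; missing {missing}"
            )
        if adjustment is None:
            if design != "twin":
                raise ValueError(
                    "Weinberg adjustment must be supplied for the "
                    "twin_sibling design (no opposite-sex group to infer it from)"
                )
            adjustment = weinberg(
                by_group["same_sex"].n_total, by_group["opposite_sex"].n_total
            )
        coeffs = group_coefficients(adjustment, sibling_c_coef)
        kappas = {coeffs[g].kappa for g in wanted}
        deltas = {coeffs[g].delta for g in wanted}
        if model == "ACE" and len(kappas) == 1:
            raise ValueError(
                "all groups share the same genetic correlation; "
                "ACE components are not identified"
            )
        if model == "ADE" and len(kappas) == 1 and len(deltas) == 1:
            raise ValueError("ADE components are not identified")

        self.model = model
        self.design = design
        self.adjustment = adjustment
        self.shared_tau = shared_tau
        self.groups = list(wanted)
        self.tables = by_group
        self.coeffs = {g: coeffs[g] for g in wanted}

    @classmethod
    def from_pairs(cls, records, **kwargs):
        """Build the model from pair-level records (see `data.read_pairs`)."""
        return cls(aggregate(records), **kwargs)

    # --- likelihood -----------------------------------------------------

    def _taus(self, theta: np.ndarray) -> dict[str, float]:
        if self.shared_tau:
            return {g: theta[2] for g in self.groups}
        return {g: theta[2 + i] for i, g in enumerate(self.groups)}

    def _n_params(self) -> int:
        return 3 if self.shared_tau else 2 + len(self.groups)

    def loglike(self, theta: np.ndarray) -> float:
        """Summed multinomial log-likelihood; theta = (a, b, tau...)."""
        a, b = theta[0], theta[1]
        a2, b2 = a * a, b * b
        if a2 + b2 > 1.0:
            return -np.inf
        taus = self._taus(theta)
        total = 0.0
        for g in self.groups:
            r = expected_pair_correlation(self.model, a2, b2, self.coeffs[g])
            if not -1.0 <= r <= 1.0:
                return -np.inf
            p = np.asarray(cell_probabilities(r, taus[g]))
            n = self.tables[g].counts
            with np.errstate(divide="ignore", invalid="ignore"):
                logp = np.log(p)
                terms = np.where(n > 0, n * logp, 0.0)
            if np.any(np.isneginf(terms)) or np.any(np.isnan(terms)):
                return -np.inf
            total += terms.sum()
        return float(total)

    def _start(self) -> np.ndarray:
        # thresholds from pooled marginal prevalence
        ntot = sum(t.n_total for t in self.tables.values())
        n1 = sum(t.n01 + t.n11 for t in self.tables.values())  # symmetrized marginal
        prev = min(max(n1 / ntot, 1e-4), 1 - 1e-4)
        tau0 = float(-stats.norm.ppf(prev))
        # moment start from per-group tetrachorics
        try:
            rhos = {g: fit_tetrachoric(self.tables[g]).rho for g in self.groups}
            other = self.groups[1]
            a2, b2, _ = mom_oracle(
                rhos["same_sex"], rhos[other], self.adjustment, self.model
            )
            a2 = min(max(a2, 0.0), 0.95)
            b2 = min(max(b2, 0.0), 0.95 - a2)
        except (ValueError, np.linalg.LinAlgError):
            a2, b2 = 0.3, 0.1
        theta0 = [np.sqrt(a2), np.sqrt(b2), tau0]
        if not self.shared_tau:
            theta0 = [theta0[0], theta0[1]] + [tau0] * len(self.groups)
        return np.asarray(theta0)

    def fit(self) -> BiometricResults:
        k = self._n_params()
        bounds = [(0.0, 1.0), (0.0, 1.0)] + [(-6.0, 6.0)] * (k - 2)
        cons = [{"type": "ineq",
                 "fun": lambda th: 1.0 - th[0] ** 2 - th[1] ** 2}]

        def nll(th):
            v = self.loglike(th)
            return 1e12 if not np.isfinite(v) else -v

        res = optimize.minimize(
            nll,
            x0=self._start(),
            method="SLSQP",
            bounds=bounds,
            constraints=cons,
            options={"ftol": 1e-12, "maxiter": 400},
        )
        theta = res.x
        a, b = float(theta[0]), float(theta[1])
        a2, b2 = a * a, b * b
        e2 = 1.0 - a2 - b2
        llf = -float(nll(theta))

        boundary = a < 1e-4 or b < 1e-4 or e2 < 1e-4
        se_a2, se_b2 = self._delta_method_ses(theta)
        taus = self._taus(theta)
        return BiometricResults(
            model=self.model,
            design=self.design,
            a2=a2,
            c2_or_d2=b2,
            e2=e2,
            se_a2=se_a2,
            se_c2_or_d2=se_b2,
            tau=float(taus[self.groups[0]]),
            llf=llf,
            n_pairs_by_group={g: self.tables[g].n_total for g in self.groups},
            converged=bool(res.success),
            boundary=boundary,
            gamma=self.adjustment.gamma,
            _model_obj=self,
        )

    def _delta_method_ses(self, theta: np.ndarray) -> tuple[float, float]:
        """SEs of (a2, c2_or_d2) via observed information of (a, b, tau...).

        The full-parameter observed information is used even when a path
        coefficient sits at the zero boundary: the likelihood retains
        curvature in b there (through the group derivatives of the pair
        correlation), and the marginal variance of a must reflect its
        correlation with b.  If the full matrix is not invertible,
        boundary coordinates are profiled out as a fallback; a
        squared-scale SE of 0 then flags the unidentified direction.
        """
        a, b = theta[0], theta[1]

        def _cov_for(free):
            def nll_free(x):
                th = np.array(theta, float)
                th[free] = x
                v = self.loglike(th)
                return 1e12 if not np.isfinite(v) else -v

            hess = _num_hessian(nll_free, theta[free], h=1e-4)
            cov = np.linalg.inv(hess)
            var = {i: cov[k, k] for k, i in enumerate(free)}
            if any(v <= 0 for v in var.values()):
                raise np.linalg.LinAlgError("non-positive variance")
            return var

        all_free = list(range(len(theta)))
        interior = [
            i for i in range(len(theta)) if not (i < 2 and theta[i] < 1e-4)
        ]
        for free in (all_free, interior):
            try:
                var = _cov_for(free)
            except np.linalg.LinAlgError:
                continue
            se_a2 = 2.0 * a * np.sqrt(var[0]) if 0 in var else 0.0
            se_b2 = 2.0 * b * np.sqrt(var[1]) if 1 in var else 0.0
            return float(se_a2), float(se_b2)
        return float("nan"), float("nan")

    # --- profile likelihood ---------------------------------------------

    def _max_loglike_fixed(self, component: str, value: float) -> float:
        """Profile log-likelihood with a2 (or c2/d2) fixed at `value`."""
        fixed_path = np.sqrt(max(value, 0.0))
        k = self._n_params()

        def nll(x):
            if component == "a2":
                th = np.concatenate([[fixed_path], x])
            else:
                th = np.concatenate([[x[0], fixed_path], x[1:]])
            v = self.loglike(th)
            return 1e12 if not np.isfinite(v) else -v

        x0 = self._start()
        x0 = np.delete(x0, 0 if component == "a2" else 1)
        bounds = [(0.0, 1.0)] + [(-6.0, 6.0)] * (k - 2)
        res = optimize.minimize(
            nll, x0, method="SLSQP", bounds=bounds,
            options={"ftol": 1e-12, "maxiter": 300},
        )
        return -float(res.fun)

    def _profile_ci(
        self, fit: BiometricResults, component: str, level: float = 0.95
    ) -> tuple[float, float]:
        """Likelihood-ratio interval by bisection on the profile deviance."""
        crit = stats.chi2.ppf(level, df=1) / 2.0
        mle = fit.a2 if component == "a2" else fit.c2_or_d2
        target = fit.llf - crit

        def deficit(v):
            return self._max_loglike_fixed(component, v) - target

        lo = 0.0
        if mle > 1e-6 and deficit(0.0) < 0:
            lo = optimize.brentq(deficit, 0.0, mle, xtol=1e-5)
        hi = 1.0
        if deficit(1.0) < 0:
            hi = optimize.brentq(deficit, mle, 1.0, xtol=1e-5)
        return (float(lo), float(hi))


def fit_biometric(tables, model="ACE", adjustment=None, design="twin",
                  **kwargs) -> BiometricResults:
    """Convenience wrapper: ``BiometricModel(...).fit()``."""
    return BiometricModel(
        tables, model=model, adjustment=adjustment, design=design, **kwargs
    ).fit()
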