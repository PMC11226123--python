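"""Synthetic twin-registry generator.

Emulates the statistical structure of a population twin registry in which
zygosity is unknown: MZ pairs are hidden inside the same-sex group, DZ
pairs split between same-sex and opposite-sex labels, and an optional
same-sex (non-twin) sibling group supports sex-specific designs.

Each pair draws a bivariate standard-normal latent liability with
correlation kappa*a2 + delta*d2 + c2 (kappa, delta the genetic and
dominance sharing coefficients of the true pair type); the binary
phenotype is 1 when liability exceeds the prevalence threshold
tau = Phi^{-1}(1 - K).  Sampling uses numpy's default PCG64 generator
through Cholesky factorization of the 2x2 correlation matrix, so fixed
seeds are portable across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

__all__ = [
    "GenerativeConfig",
    "StratumSpec",
    "liability_threshold",
    "pair_liability_correlation",
    "simulate_pairs",
]

#: genetic / dominance sharing coefficients by true pair type
SHARING = {"MZ": (1.0, 1.0), "DZ": (0.5, 0.25), "SIB": (0.5, 0.25)}


def liability_threshold(prevalence: float) -> float:
    """Threshold tau on the standard-normal liability scale.

    The phenotype is 1 iff liability > tau, so tau = Phi^{-1}(1 - K)
    for prevalence K.  Strictly decreasing in K; tau = 0 at K = 1/2.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must lie in (0, 1), got {prevalence}")
    return float(ndtri(1.0 - prevalence))


def pair_liability_correlation(
    a2: float, c2: float, d2: float = 0.0, kappa: float = 1.0, delta: float | None = None
) -> float:
    """Expected liability correlation for a pair sharing fraction kappa of
    additive and delta of dominance genetic variance.

    r = kappa*a2 + delta*d2 + c2.  For MZ pairs kappa = delta = 1; for DZ
    twins and full siblings kappa = 1/2, delta = 1/4.
    """
    if delta is None:
        delta = 0.25 if kappa == 0.5 else kappa
    r = kappa * a2 + delta * d2 + c2
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"implied pair correlation {r} outside [0, 1]")
    return r


@dataclass(frozen=True)
class StratumSpec:
    """Per-stratum overrides of the generating parameters.

    Only heritability, shared environment and prevalence may differ by
    stratum; the group composition (pair counts) is shared so that strata
    are comparable.
    """

    label: str
    a2: float | None = None
    c2: float | None = None
    prevalence: float | None = None


@dataclass
class GenerativeConfig:
    """Generating parameters for a synthetic twin registry.

    Parameters
    ----------
    n_mz_pairs, n_dz_pairs, n_sib_pairs : int
        True pair counts per type.  MZ pairs always appear as
        ``same_sex``; each DZ pair is labeled ``opposite_sex`` with
        probability ``dz_opposite_sex_prob`` (independent sexes within a
        DZ pair make this 1/2), else ``same_sex``.
    a2, c2, d2 : float
        Standardized additive-genetic, shared-environment and dominance
        variance fractions; e2 = 1 - a2 - c2 - d2 must be >= 0.
    prevalence : float
        Population frequency K of the binary phenotype.
    strata_specs : list of StratumSpec, optional
        When given, each stratum is generated with the full group
        composition and its own (a2, c2, K) overrides.
    seed : int
        Seed for the PCG64 generator.
    """

    n_mz_pairs: int = 0
    n_dz_pairs: int = 0
    n_sib_pairs: int = 0
    a2: float = 0.5
    c2: float = 0.0
    d2: float = 0.0
    prevalence: float = 0.17
    dz_opposite_sex_prob: float = 0.5
    strata_specs: list[StratumSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_mz_pairs, self.n_dz_pairs, self.n_sib_pairs) < 0:
            raise ValueError("pair counts must be non-negative")
        for name in ("a2", "c2", "d2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.a2 + self.c2 + self.d2 > 1.0 + 1e-12:
            raise ValueError("a2 + c2 + d2 must not exceed 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0.0 <= self.dz_opposite_sex_prob <= 1.0:
            raise ValueError("dz_opposite_sex_prob must lie in [0, 1]")

    @property
    def e2(self) -> float:
        return 1.0 - self.a2 - self.c2 - self.d2


def _draw_pairs(rng, n: int, r: float, tau: float):
    """Draw n latent liability pairs with correlation r; return liabilities
    and thresholded phenotypes."""
    z = rng.standard_normal((n, 2))
    # Cholesky of [[1, r], [r, 1]]
    l1 = z[:, 0]
    l2 = r * z[:, 0] + np.sqrt(1.0 - r * r) * z[:, 1]
    return l1, l2, (l1 > tau).astype(np.int8), (l2 > tau).astype(np.int8)


def simulate_pairs(config: GenerativeConfig, debug: bool = False) -> pd.DataFrame:
    """Generate pair-level records under the liability-threshold model.

    Returns a DataFrame with columns pair_id, group, pheno_1, pheno_2,
    sex_pair and, when strata are configured, a ``stratum`` column.  With
    ``debug=True`` the true zygosity and latent liabilities are appended;
    estimation code never reads them.
    """
    rng = np.random.default_rng(config.seed)
    total = config.n_mz_pairs + config.n_dz_pairs + config.n_sib_pairs
    if total == 0:
        warnings.warn("configuration yields zero pairs", RuntimeWarning, stacklevel=2)

    strata = config.strata_specs or [StratumSpec("all")]
    frames = []
    counter = 0
    for spec in strata:
        a2 = config.a2 if spec.a2 is None else spec.a2
        c2 = config.c2 if spec.c2 is None else spec.c2
        prev = config.prevalence if spec.prevalence is None else spec.prevalence
        if a2 + c2 + config.d2 > 1.0 + 1e-12:
            raise ValueError(f"stratum {spec.label!r}: a2 + c2 + d2 exceeds 1")
        tau = liability_threshold(prev)
        for ztype, n in (
            ("MZ", config.n_mz_pairs),
            ("DZ", config.n_dz_pairs),
            ("SIB", config.n_sib_pairs),
        ):
            if n == 0:
                continue
            kappa, delta = SHARING[ztype]
            r = pair_liability_correlation(a2, c2, config.d2, kappa, delta)
            l1, l2, y1, y2 = _draw_pairs(rng, n, r, tau)
            if ztype == "MZ":
                group = np.full(n, "same_sex")
                sex = np.where(rng.random(n) < 0.5, "MM", "FF")
            elif ztype == "DZ":
                opp = rng.random(n) < config.dz_opposite_sex_prob
                group = np.where(opp, "opposite_sex", "same_sex")
                same_sex_draw = np.where(rng.random(n) < 0.5, "MM", "FF")
                sex = np.where(opp, "MF", same_sex_draw)
            else:
                group = np.full(n, "sibling")
                sex = np.where(rng.random(n) < 0.5, "MM", "FF")
            df = pd.DataFrame(
                {
                    "pair_id": [f"p{counter + i:07d}" for i in range(n)],
                    "group": group,
                    "pheno_1": y1,
                    "pheno_2": y2,
                    "sex_pair": sex,
                }
            )
            counter += n
            if config.strata_specs:
                df["stratum"] = spec.label
            if debug:
                df["true_zygosity"] = ztype
                df["liab_1"] = l1
                df["liab_2"] = l2
            frames.append(df)

    if not frames:
        cols = ["pair_id", "group", "pheno_1", "pheno_2", "sex_pair"]
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)
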