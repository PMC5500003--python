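"""Cooperative binding analysis of gel-shift titrations.

Fraction of RNA bound as a function of free protein concentration x is
modeled with the Hill equation

    y = 1 / (1 + (K_d / x)**n)

where K_d is the apparent dissociation constant and n the Hill coefficient
(n > 1 indicates cooperative binding of multiple proteins per RNA).  The
direct-titration design keeps the RNA at trace concentration so total protein
approximates free protein.

Also provided: the family of tight-binding ("stoichiometric") saturation
curves used to bracket stoichiometric titrations, giving the fraction of
protein bound at a protein:RNA molar ratio r when each RNA carries m protein
sites — min(1, m/r) in the infinitely tight limit, or the per-site
mass-balance quadratic at finite K_d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

DEFAULT_KD_BOUNDS = (1.0, 1e5)  # nM
DEFAULT_N_BOUNDS = (0.2, 8.0)


@dataclass
class HillParams:
    kd_nM: float
    n: float
    kd_se: float = np.nan
    n_se: float = np.nan
    converged: bool = True

    def __post_init__(self) -> None:
        if self.kd_nM <= 0:
            raise ValueError("K_d must be positive")
        if self.n <= 0:
            raise ValueError("Hill coefficient must be positive")


@dataclass
class TitrationCurve:
    """Concentration / fraction-bound pairs from a gel-shift titration."""

    conc_nM: np.ndarray
    fraction_bound: np.ndarray
    trace_rna_nM: float = 26.0

    def __post_init__(self) -> None:
        self.conc_nM = np.asarray(self.conc_nM, dtype=float)
        self.fraction_bound = np.asarray(self.fraction_bound, dtype=float)
        if self.conc_nM.shape != self.fraction_bound.shape:
            raise ValueError("concentration and fraction arrays must match")
        if np.any(self.conc_nM <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.conc_nM) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any((self.fraction_bound < 0) | (self.fraction_bound > 1)):
            raise ValueError("fractions bound must lie in [0, 1]")


def hill_fraction(x, kd_nM: float, n: float):
    """Evaluate the Hill equation; strictly increasing in x."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("protein concentration must be positive")
    if kd_nM <= 0 or n <= 0:
        raise ValueError("K_d and n must be positive")
    out = 1.0 / (1.0 + (kd_nM / x) ** n)
    return out if out.ndim else float(out)


def fit_hill(
    curve: TitrationCurve,
    init: HillParams | None = None,
    kd_bounds: tuple[float, float] = DEFAULT_KD_BOUNDS,
    n_bounds: tuple[float, float] = DEFAULT_N_BOUNDS,
    bootstrap: int = 0,
    seed: int | None = None,
) -> HillParams:
    """Least-squares Hill fit of a titration curve.

    Standard errors come from the Jacobian at the optimum; pass
    ``bootstrap > 0`` for residual-resampling errors instead (seeded).
    Degenerate inputs: an all-zero or all-one curve carries no information
    and is rejected; a flat (constant) curve is non-identifiable and is
    returned with ``converged=False``.
    """
    x, y = curve.conc_nM, curve.fraction_bound
    if x.size < 4:
        raise ValueError("need at least 4 points to fit the Hill equation")
    if np.all(y == 0) or np.all(y == 1):
        raise ValueError("titration carries no information (all 0 or all 1)")

    if init is None:
        # K_d ~ concentration at the point nearest half-saturation.
        kd0 = float(x[np.argmin(np.abs(y - 0.5))])
        init = HillParams(kd_nM=np.clip(kd0, *kd_bounds), n=1.0)

    if np.ptp(y) < 1e-3:
        return HillParams(
            kd_nM=init.kd_nM, n=init.n, kd_se=np.nan, n_se=np.nan,
            converged=False,
        )

    lo = [kd_bounds[0], n_bounds[0]]
    hi = [kd_bounds[1], n_bounds[1]]
    try:
        popt, pcov = optimize.curve_fit(
            hill_fraction, x, y,
            p0=[init.kd_nM, init.n], bounds=(lo, hi), maxfev=10000,
        )
        converged = np.all(np.isfinite(pcov))
    except RuntimeError:
        return HillParams(init.kd_nM, init.n, converged=False)

    kd_se, n_se = np.sqrt(np.diag(pcov)) if converged else (np.nan, np.nan)
    # A fit pinned at a box boundary is silently divergent, not an estimate.
    at_edge = any(
        np.isclose(popt[i], b, rtol=1e-6)
        for i, pair in enumerate((kd_bounds, n_bounds)) for b in pair
    )
    if at_edge:
        converged = False

    if bootstrap > 0 and converged:
        rng = np.random.default_rng(seed)
        resid = y - hill_fraction(x, *popt)
        reps = []
        for _ in range(bootstrap):
            y_star = np.clip(
                hill_fraction(x, *popt) + rng.choice(resid, size=resid.size),
                0.0, 1.0,
            )
            try:
                p_star, _ = optimize.curve_fit(
                    hill_fraction, x, y_star,
                    p0=popt, bounds=(lo, hi), maxfev=10000,
                )
                reps.append(p_star)
            except RuntimeError:
                continue
        if reps:
            kd_se, n_se = np.std(np.asarray(reps), axis=0, ddof=1)

    return HillParams(
        kd_nM=float(popt[0]), n=float(popt[1]),
        kd_se=float(kd_se), n_se=float(n_se), converged=bool(converged),
    )


def saturation_bound_fraction(r, m: int, kd_nM: float | None = None,
                              rna_nM: float | None = None):
    """Fraction of protein bound at protein:RNA molar ratio r with
    stoichiometry m (m protein sites per RNA).

    Default is the tight-binding limit min(1, m/r).  Supplying ``kd_nM`` and
    ``rna_nM`` switches to the finite-affinity per-site mass-balance
    quadratic: with total protein P = r*R and total sites S = m*R,

        PB**2 - PB*(P + S + K_d) + P*S = 0,   fraction = PB / P.
    """
    if not 1 <= int(m) <= 6 or m != int(m):
        raise ValueError("stoichiometry m must be an integer in 1..6")
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("molar ratio must be positive")
    if kd_nM is None:
        out = np.minimum(1.0, m / r)
    else:
        if rna_nM is None or rna_nM <= 0:
            raise ValueError("finite-affinity curves need a positive rna_nM")
        p = r * rna_nM
        s = float(m) * rna_nM
        b = p + s + kd_nM
        pb = (b - np.sqrt(b * b - 4.0 * p * s)) / 2.0
        out = pb / p
    return out if out.ndim else float(out)


@dataclass
class StoichiometricCurve:
    m: int
    ratios: np.ndarray
    bound_fraction: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.bound_fraction = saturation_bound_fraction(self.ratios, self.m)


def stoichiometric_family(ratios, m_values=range(1, 7)) -> list[StoichiometricCurve]:
    """The 1:1 through 6:1 theoretical saturation curves on a shared grid."""
    return [StoichiometricCurve(m=m, ratios=ratios) for m in m_values]
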