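"""Independent (one-set-of-sites) binding model for incremental-titration ITC.

An RNA titrant at syringe concentration X0 is injected in small volumes dV
into a perfusion cell of volume V0 containing the protein at M0.  Each
injection displaces cell volume, so concentrations follow the standard
displacement bookkeeping

    M_i = M0 * prod_j (1 - dV_j / V0)
    X_i = X_{i-1} * (1 - dV_i / V0) + X0 * dV_i / V0

With n independent, identical sites per macromolecule (here n is titrant
bound per macromolecule at saturation; a protein-dimer:RNA stoichiometry
appears as n ~ 0.5 on the titrant:macromolecule axis), the bound fraction of
sites Theta_i after injection i solves

    Theta**2 - Theta * (1 + X/(n*M) + K_d/(n*M)) + X/(n*M) = 0

(the root in [0, 1]).  The cumulative heat is Q_i = n * Theta_i * M_i * dH *
V0 (uM * ml * kcal/mol = ucal) and the observed per-injection heat is

    dQ_i = Q_i - Q_{i-1} + (dV_i / V0) * (Q_i + Q_{i-1}) / 2

where the last term corrects for heat content displaced out of the cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

DEFAULT_INJECTIONS = 25


@dataclass(frozen=True)
class ITCProtocol:
    """Injection schedule for a perfusion-cell titration.

    Defaults follow the tau/tRNA design: 300 uM titrant injected in 5 ul
    steps into 1 ml of 30 uM macromolecule.
    """

    cell_volume_ml: float = 1.0
    cell_uM: float = 30.0
    syringe_uM: float = 300.0
    injection_volumes_ul: tuple[float, ...] = (5.0,) * DEFAULT_INJECTIONS
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        if self.cell_volume_ml <= 0:
            raise ValueError("cell volume must be positive")
        if self.cell_uM <= 0 or self.syringe_uM <= 0:
            raise ValueError("concentrations must be positive")
        if len(self.injection_volumes_ul) == 0:
            raise ValueError("at least one injection required")
        for dv in self.injection_volumes_ul:
            if dv <= 0:
                raise ValueError("injection volumes must be positive")
            if dv >= self.cell_volume_ml * 1000.0:
                raise ValueError("injection volume must be below cell volume")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_ul)

    def concentrations_after_injection(self, i: int) -> tuple[float, float]:
        """Cell (macromolecule, titrant) concentrations in uM after
        injection ``i`` (1-based); ``i = 0`` gives the pre-titration state."""
        if not 0 <= i <= self.n_injections:
            raise ValueError(f"injection index {i} out of range")
        m, x = self.cell_uM, 0.0
        v0_ul = self.cell_volume_ml * 1000.0
        for dv in self.injection_volumes_ul[:i]:
            f = 1.0 - dv / v0_ul
            m *= f
            x = x * f + self.syringe_uM * dv / v0_ul
        return m, x

    def concentration_series(self) -> tuple[np.ndarray, np.ndarray]:
        pairs = [
            self.concentrations_after_injection(i)
            for i in range(1, self.n_injections + 1)
        ]
        m, x = np.asarray(pairs).T
        return m, x

    def molar_ratios(self) -> np.ndarray:
        """Titrant:macromolecule molar ratio after each injection."""
        m, x = self.concentration_series()
        return x / m


@dataclass
class Thermogram:
    """Integrated per-injection heats (ucal), optionally with a
    titrant-into-buffer blank to subtract."""

    heats_ucal: np.ndarray
    blank_ucal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if self.blank_ucal is not None:
            self.blank_ucal = np.asarray(self.blank_ucal, dtype=float)
            if self.blank_ucal.shape != self.heats_ucal.shape:
                raise ValueError("blank and sample heats must have equal length")

    def corrected(self) -> np.ndarray:
        if self.blank_ucal is None:
            return self.heats_ucal.copy()
        return self.heats_ucal - self.blank_ucal


@dataclass
class ITCParams:
    kd_nM: float
    dH_kcal_mol: float
    n: float
    kd_se: float = np.nan
    dH_se: float = np.nan
    n_se: float = np.nan
    converged: bool = True

    def __post_init__(self) -> None:
        if self.kd_nM <= 0:
            raise ValueError("K_d must be positive")
        if self.n <= 0:
            raise ValueError("stoichiometry n must be positive")


def _bound_fraction(x_uM, m_uM, kd_uM: float, n: float):
    """Root in [0, 1] of the one-set-of-sites quadratic."""
    nm = n * m_uM
    b = 1.0 + x_uM / nm + kd_uM / nm
    disc = b * b - 4.0 * x_uM / nm
    if np.any(disc < -1e-12):  # pragma: no cover - internal guard
        raise FloatingPointError("one-set-of-sites quadratic has no real root")
    theta = (b - np.sqrt(np.maximum(disc, 0.0))) / 2.0
    return np.clip(theta, 0.0, 1.0)


def cumulative_heats(protocol: ITCProtocol, params: ITCParams) -> np.ndarray:
    m, x = protocol.concentration_series()
    theta = _bound_fraction(x, m, params.kd_nM / 1000.0, params.n)
    return params.n * theta * m * params.dH_kcal_mol * protocol.cell_volume_ml


def predicted_heats(protocol: ITCProtocol, params: ITCParams) -> np.ndarray:
    """Per-injection heats (ucal) under the independent binding model."""
    q = cumulative_heats(protocol, params)
    q_prev = np.concatenate(([0.0], q[:-1]))
    dv = np.asarray(protocol.injection_volumes_ul) / (protocol.cell_volume_ml * 1000.0)
    return q - q_prev + dv * (q + q_prev) / 2.0


def _initial_guess(heats: np.ndarray, protocol: ITCProtocol) -> ITCParams:
    ratios = protocol.molar_ratios()
    # nmol injected per shot: uM * ul / 1000; ucal / nmol = kcal/mol.
    nmol_first = protocol.syringe_uM * protocol.injection_volumes_ul[0] / 1000.0
    dh0 = float(heats[0] / nmol_first)
    if dh0 == 0:
        dh0 = -1.0
    cum = np.cumsum(heats)
    half = cum[-1] / 2.0
    idx = int(np.argmin(np.abs(cum - half)))
    n0 = float(np.clip(ratios[idx], 0.05, 10.0))
    return ITCParams(kd_nM=1000.0, dH_kcal_mol=dh0, n=n0)


def fit_independent_model(
    thermogram: Thermogram,
    protocol: ITCProtocol,
    init: ITCParams | None = None,
    *,
    drop_first: bool = False,
    noise_floor_ucal: float = 0.05,
) -> ITCParams:
    """Least-squares (K_d, dH, n) fit of blank-corrected heats.

    ``drop_first`` excludes the first injection (the usual anomalous-first-
    point practice).  Heats whose largest magnitude sits below
    ``noise_floor_ucal`` carry essentially no enthalpic signal; the fit is
    still attempted but flagged unconverged with a low-enthalpy warning,
    since no binding model is identifiable from such data.  Cooperative or
    two-independent-site models are deliberately not offered: with the
    shallow heats typical of this system their extra parameters are not
    identifiable (errors exceeding the estimates themselves).
    """
    heats = thermogram.corrected()
    if heats.shape[0] != protocol.n_injections:
        raise ValueError("thermogram length must match the injection count")
    if np.all(heats == 0):
        raise ValueError("thermogram carries no information (all zeros)")

    low_signal = float(np.max(np.abs(heats))) < noise_floor_ucal
    if low_signal:
        warnings.warn(
            "heats are below the noise floor; the low enthalpy of the binding "
            "event precludes a reliable fit", UserWarning, stacklevel=2,
        )

    mask = np.ones(protocol.n_injections, dtype=bool)
    if drop_first:
        mask[0] = False

    if init is None:
        init = _initial_guess(heats, protocol)

    def residuals(p):
        kd_nM, dh, n = p
        model = predicted_heats(
            protocol, ITCParams(kd_nM=kd_nM, dH_kcal_mol=dh, n=n)
        )
        return (model - heats)[mask]

    lower = [1e-2, -100.0, 0.02]
    upper = [1e7, 100.0, 20.0]
    x0 = np.clip([init.kd_nM, init.dH_kcal_mol, init.n],
                 lower, upper)
    result = optimize.least_squares(
        residuals, x0, bounds=(lower, upper), method="trf", xtol=1e-12,
        ftol=1e-12, gtol=1e-12,
    )
    kd, dh, n = result.x

    dof = int(mask.sum()) - 3
    ses = (np.nan, np.nan, np.nan)
    converged = bool(result.success) and not low_signal
    if converged and dof > 0:
        jtj = result.jac.T @ result.jac
        try:
            cov = np.linalg.inv(jtj) * (2.0 * result.cost / dof)
            ses = tuple(np.sqrt(np.maximum(np.diag(cov), 0.0)))
        except np.linalg.LinAlgError:
            converged = False

    return ITCParams(
        kd_nM=float(kd), dH_kcal_mol=float(dh), n=float(n),
        kd_se=float(ses[0]), dH_se=float(ses[1]), n_se=float(ses[2]),
        converged=converged,
    )
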