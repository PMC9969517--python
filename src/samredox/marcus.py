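"""Marcus linear-response estimation from vertical energy-gap ensembles.

Under the linear-response assumption the oxidation free energy is the
symmetric average of the two vertical gaps,

    dA = (<VIE>_N + <VAE>_N+) / 2,

with the reorganization energy available two ways: the Stokes-shift form
lambda = (<VIE> - <VAE>)/2, and the fluctuation form
lambda_s = sigma_s^2 / (2 kB T) for each sampling state s. Validity
requires (i) Gaussian gap distributions, (ii) equal widths
sigma_VIE = sigma_VAE, and (iii) agreement of the Stokes and variance
routes. When the diagnostics fail, the symmetric second-order cumulant
(Matyushov-Voth-type quadratic) correction

    dA = (<VIE> + <VAE>)/2 + (sigma_N+^2 - sigma_N^2) / (4 kB T)

is applied; it reduces exactly to the linear estimate for equal widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .constants import Constants, DEFAULT_CONSTANTS
from .model import GapEnsemble, MarcusResult

__all__ = [
    "estimate_free_energy",
    "reorganization_energies",
    "diagnostics",
    "quadratic_correction",
    "potential_from_marcus",
    "analyze",
    "DiagnosticThresholds",
]


def _check_nonempty(ens: GapEnsemble, minimum: int = 1) -> None:
    if ens.vie_samples.size < minimum or ens.vae_samples.size < minimum:
        raise ValueError(
            f"gap ensemble needs at least {minimum} samples per state "
            f"(got {ens.vie_samples.size} VIE / {ens.vae_samples.size} VAE)"
        )


def estimate_free_energy(ens: GapEnsemble) -> float:
    """Linear-response oxidation free energy dA = (<VIE> + <VAE>)/2, eV."""
    _check_nonempty(ens)
    return 0.5 * (float(np.mean(ens.vie_samples)) + float(np.mean(ens.vae_samples)))


def reorganization_energies(
    ens: GapEnsemble, constants: Constants = DEFAULT_CONSTANTS
) -> tuple[float, float, float]:
    """(lambda_Stokes, lambda_var_N, lambda_var_N+), all in eV.

    Variance-route estimates use the sample variance divided by the
    thermal factor 2 kB T at the ensemble temperature. Single-sample or
    constant ensembles yield lambda_var = 0 without error.
    """
    _check_nonempty(ens)
    lam_stokes = 0.5 * (
        float(np.mean(ens.vie_samples)) - float(np.mean(ens.vae_samples))
    )
    kbt2 = 2.0 * constants.k_b * ens.temperature

    def lam_var(x: np.ndarray) -> float:
        if x.size < 2:
            return 0.0
        return float(np.var(x, ddof=1)) / kbt2

    return lam_stokes, lam_var(ens.vie_samples), lam_var(ens.vae_samples)


@dataclass
class DiagnosticThresholds:
    """Configurable pass/fail thresholds for the Marcus validity checks."""

    alpha: float = 0.05
    sigma_ratio_bounds: tuple[float, float] = (0.8, 1.25)
    lambda_rel_tol: float = 0.2
    normality_test: str = "omnibus"  # "omnibus" (D'Agostino) or "shapiro"


@dataclass
class MarcusDiagnostics:
    skewness_n: float
    skewness_ncat: float
    kurtosis_n: float
    kurtosis_ncat: float
    normality_p_n: float
    normality_p_ncat: float
    sigma_n: float
    sigma_ncat: float
    sigma_ratio: float
    lambda_stokes: float
    lambda_var_n: float
    lambda_var_ncat: float
    passed_normality: bool = field(default=False)
    passed_sigma_ratio: bool = field(default=False)
    passed_lambda_consistency: bool = field(default=False)

    @property
    def all_passed(self) -> bool:
        return (
            self.passed_normality
            and self.passed_sigma_ratio
            and self.passed_lambda_consistency
        )

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["all_passed"] = self.all_passed
        return d


def _normality_p(x: np.ndarray, test: str) -> float:
    if test == "shapiro":
        return float(stats.shapiro(x).pvalue)
    if test == "omnibus":
        return float(stats.normaltest(x).pvalue)
    raise ValueError(f"unknown normality test {test!r}")


def diagnostics(
    ens: GapEnsemble,
    thresholds: Optional[DiagnosticThresholds] = None,
    constants: Constants = DEFAULT_CONSTANTS,
) -> MarcusDiagnostics:
    """Evaluate the three Marcus validity conditions on a gap ensemble.

    Condition (i): each gap distribution passes a normality test at level
    alpha. Condition (ii): the width ratio sigma_VIE/sigma_VAE lies inside
    the configured bounds. Condition (iii): both variance-route
    reorganization energies agree with the Stokes-shift route within a
    relative tolerance.
    """
    thresholds = thresholds or DiagnosticThresholds()
    _check_nonempty(ens, minimum=8)
    vie, vae = ens.vie_samples, ens.vae_samples
    sigma_n = float(np.std(vie, ddof=1))
    sigma_ncat = float(np.std(vae, ddof=1))
    lam_stokes, lam_n, lam_ncat = reorganization_energies(ens, constants)

    # degenerate (zero-width) samples: normality is vacuous, ratio exact
    degenerate = sigma_n == 0.0 and sigma_ncat == 0.0
    p_n = 1.0 if sigma_n == 0.0 else _normality_p(vie, thresholds.normality_test)
    p_ncat = (
        1.0 if sigma_ncat == 0.0 else _normality_p(vae, thresholds.normality_test)
    )
    ratio = 1.0 if degenerate else (
        np.inf if sigma_ncat == 0.0 else sigma_n / sigma_ncat
    )

    lo, hi = thresholds.sigma_ratio_bounds
    if degenerate:
        lam_ok = True
    else:
        ref = max(abs(lam_stokes), abs(lam_n), abs(lam_ncat), 1e-30)
        lam_ok = (
            abs(lam_n - lam_stokes) <= thresholds.lambda_rel_tol * ref
            and abs(lam_ncat - lam_stokes) <= thresholds.lambda_rel_tol * ref
        )

    return MarcusDiagnostics(
        skewness_n=float(stats.skew(vie)) if sigma_n else 0.0,
        skewness_ncat=float(stats.skew(vae)) if sigma_ncat else 0.0,
        kurtosis_n=float(stats.kurtosis(vie)) if sigma_n else 0.0,
        kurtosis_ncat=float(stats.kurtosis(vae)) if sigma_ncat else 0.0,
        normality_p_n=p_n,
        normality_p_ncat=p_ncat,
        sigma_n=sigma_n,
        sigma_ncat=sigma_ncat,
        sigma_ratio=float(ratio),
        lambda_stokes=lam_stokes,
        lambda_var_n=lam_n,
        lambda_var_ncat=lam_ncat,
        passed_normality=(p_n >= thresholds.alpha and p_ncat >= thresholds.alpha),
        passed_sigma_ratio=bool(lo <= ratio <= hi),
        passed_lambda_consistency=bool(lam_ok),
    )


def quadratic_correction(
    ens: GapEnsemble, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Second-order-cumulant (quadratic-model) free energy, eV.

    dA = (<VIE> + <VAE>)/2 + (sigma_N+^2 - sigma_N^2)/(4 kB T); identical
    to the linear estimate when the two widths coincide.
    """
    _check_nonempty(ens)
    base = estimate_free_energy(ens)
    var_n = float(np.var(ens.vie_samples, ddof=1)) if ens.vie_samples.size > 1 else 0.0
    var_ncat = (
        float(np.var(ens.vae_samples, ddof=1)) if ens.vae_samples.size > 1 else 0.0
    )
    return base + (var_ncat - var_n) / (4.0 * constants.k_b * ens.temperature)


def potential_from_marcus(
    delta_a: float, e_ref: Optional[float] = None,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """E_red = dA (eV per electron, numerically V) - E_ref, one electron."""
    if e_ref is None:
        e_ref = constants.e_she
    return delta_a - e_ref


def analyze(
    ens: GapEnsemble,
    thresholds: Optional[DiagnosticThresholds] = None,
    constants: Constants = DEFAULT_CONSTANTS,
    e_ref: Optional[float] = None,
) -> MarcusResult:
    """Full Marcus analysis of one gap ensemble.

    Runs the linear estimator, both reorganization routes and the validity
    diagnostics; applies the quadratic correction if (and only if) any
    diagnostic fails. The reported potential uses the (possibly corrected)
    free energy.
    """
    diag = diagnostics(ens, thresholds, constants)
    delta_a_linear = estimate_free_energy(ens)
    correction_applied = not diag.all_passed
    delta_a = (
        quadratic_correction(ens, constants) if correction_applied else delta_a_linear
    )
    return MarcusResult(
        delta_a=delta_a,
        potential=potential_from_marcus(delta_a, e_ref, constants),
        lambda_stokes=diag.lambda_stokes,
        lambda_var_n=diag.lambda_var_n,
        lambda_var_ncat=diag.lambda_var_ncat,
        skewness_n=diag.skewness_n,
        skewness_ncat=diag.skewness_ncat,
        sigma_ratio=diag.sigma_ratio,
        normality_p_n=diag.normality_p_n,
        normality_p_ncat=diag.normality_p_ncat,
        correction_applied=correction_applied,
        delta_a_linear=delta_a_linear,
        diagnostics=diag.to_dict(),
    )
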