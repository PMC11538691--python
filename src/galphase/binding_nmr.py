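"""NMR observables: chemical-shift perturbation, K_D and R2 fitting.

Three quantities drive the solution-NMR side of the analysis:

* the combined amide chemical-shift perturbation
  ``CSP = sqrt((dH^2 + (dN/5)^2) / 2)``, with the nitrogen shift
  down-weighted by the standard 1/5 factor (configurable);

* the one-site ligand-depletion binding isotherm

  .. math::

     \\Delta\\delta^{obs} = \\Delta\\delta^{max}
        \\frac{(K_D + [L] + [P]) - \\sqrt{(K_D + [L] + [P])^2 - 4[P][L]}}
             {2[P]}

  the exact quadratic solution of single-site binding, required because
  protein concentrations here (tens to hundreds of micromolar) are
  comparable to K_D, so the free-ligand approximation fails;

* mono-exponential transverse relaxation ``I(t) = I0 exp(-R2 t)``, with
  a Monte Carlo fitting-error estimate: refit synthetic datasets in which
  the intensities are perturbed by Gaussian noise at the spectrum noise
  level, and report the spread of the refitted R2.

Least-squares fitting goes through lmfit; parameter uncertainties for the
binding fit come from the estimated covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from lmfit import Model

#: Standard down-weighting of the amide nitrogen shift relative to 1H.
DEFAULT_N_SCALING = 0.2


class ConvergenceError(RuntimeError):
    """A nonlinear fit failed to converge; carries diagnostics in args."""


class FitDomainError(ValueError):
    """Data incompatible with the model family (e.g. non-decaying series)."""


@dataclass(frozen=True)
class ShiftPerturbation:
    """Per-residue 1H/15N shift changes and their combined CSP (ppm)."""

    residue_id: str
    delta_h: float
    delta_n: float
    delta_av: float


@dataclass(frozen=True)
class TitrationSeries:
    """Observed CSP versus added ligand at fixed total protein (µM, ppm)."""

    protein_conc: float
    ligand_concs: tuple[float, ...]
    observed: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ligand_concs) != len(self.observed):
            raise ValueError("ligand and observation lists differ in length")
        if len(self.ligand_concs) < 3:
            raise ValueError("need at least 3 titration points")
        if self.protein_conc <= 0:
            raise ValueError("protein concentration must be positive")
        if any(l < 0 for l in self.ligand_concs):
            raise ValueError("ligand concentrations must be non-negative")


@dataclass(frozen=True)
class BindingFit:
    """Fitted (K_D, Δδmax) with 1-sigma uncertainties from the covariance."""

    kd: float
    delta_max: float
    kd_err: float
    delta_max_err: float
    residual_norm: float
    non_binding: bool = False


@dataclass(frozen=True)
class RelaxationSeries:
    """Peak intensities at increasing relaxation delays (s, a.u.)."""

    peak_id: str
    delays: tuple[float, ...]
    intensities: tuple[float, ...]
    noise_sd: float

    def __post_init__(self) -> None:
        if len(self.delays) != len(self.intensities):
            raise ValueError("delay and intensity lists differ in length")
        if len(self.delays) < 2:
            raise ValueError("need at least 2 relaxation points")
        d = np.asarray(self.delays)
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("delays must be positive and strictly increasing")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class R2Fit:
    """Fitted transverse relaxation rate with Monte Carlo error."""

    r2: float
    i0: float
    r2_err: float
    n_mc: int
    seed: int


def csp(delta_h: float, delta_n: float,
        n_scaling: float = DEFAULT_N_SCALING) -> float:
    """Combined amide CSP: sqrt((dH^2 + (s*dN)^2) / 2), s = 1/5 by default."""
    if not (math.isfinite(delta_h) and math.isfinite(delta_n)):
        raise ValueError("shift differences must be finite")
    return math.sqrt((delta_h ** 2 + (n_scaling * delta_n) ** 2) / 2.0)


def binding_isotherm(kd: float, delta_max: float, p: float,
                     l: float | np.ndarray) -> float | np.ndarray:
    """Ligand-depletion one-site isotherm; exact for [P] comparable to K_D."""
    if p <= 0:
        raise ValueError("protein concentration must be positive")
    if kd < 0:
        raise ValueError("K_D must be non-negative")
    l = np.asarray(l, dtype=float)
    if np.any(l < 0):
        raise ValueError("ligand concentration must be non-negative")
    b = kd + l + p
    # the discriminant b^2 - 4pl rewritten as (kd + p - l)^2 + 4*kd*l:
    # identical algebraically, manifestly non-negative, and free of the
    # cancellation that b^2 - 4pl suffers near stoichiometric [L] = [P]
    disc = (kd + p - l) ** 2 + 4.0 * kd * l
    if np.any(disc < 0.0):
        raise ArithmeticError("negative discriminant in binding isotherm")
    # likewise (b - sqrt(disc)) / (2p) as 2l / (b + sqrt(disc)): the same
    # root without cancellation at large [L]
    bound_fraction = 2.0 * l / (b + np.sqrt(disc))
    out = delta_max * bound_fraction
    return float(out) if out.ndim == 0 else out


def _kd_init(series: TitrationSeries) -> tuple[float, float]:
    """Starting values: Δδmax0 = max observed; K_D0 = [L] at half-max."""
    obs = np.asarray(series.observed)
    lig = np.asarray(series.ligand_concs)
    dmax0 = float(obs.max())
    half = dmax0 / 2.0
    order = np.argsort(lig)
    kd0 = float(np.interp(half, obs[order], lig[order]))
    if kd0 <= 0:
        kd0 = float(np.median(lig[lig > 0])) if np.any(lig > 0) else 1.0
    return kd0, dmax0


def fit_kd(series: TitrationSeries,
           init: tuple[float, float] | None = None,
           non_binding_tol: float = 1e-6) -> BindingFit:
    """Least-squares (K_D, Δδmax) under the ligand-depletion isotherm.

    ``init`` optionally supplies (kd0, delta_max0); otherwise Δδmax
    starts at the largest observed shift and K_D at the interpolated
    half-saturation ligand concentration.  A series whose observations
    are all below ``non_binding_tol`` is flagged non-binding and not fit.
    Deterministic given identical inputs.
    """
    obs = np.asarray(series.observed, dtype=float)
    lig = np.asarray(series.ligand_concs, dtype=float)
    if np.unique(lig[lig > 0]).size < 2:
        raise ValueError("need at least two distinct nonzero ligand points")
    if np.all(np.abs(obs) < non_binding_tol):
        return BindingFit(kd=math.nan, delta_max=math.nan, kd_err=math.nan,
                          delta_max_err=math.nan, residual_norm=0.0,
                          non_binding=True)
    kd0, dmax0 = init if init is not None else _kd_init(series)

    model = Model(lambda l, kd, delta_max:
                  binding_isotherm(kd, delta_max, series.protein_conc, l),
                  independent_vars=["l"])
    params = model.make_params(kd=kd0, delta_max=dmax0)
    params["kd"].set(min=0.0)
    params["delta_max"].set(min=1e-12)
    result = model.fit(obs, params, l=lig)
    if not result.success:
        raise ConvergenceError("binding fit did not converge", result.message)
    kd_err = result.params["kd"].stderr
    dmax_err = result.params["delta_max"].stderr
    return BindingFit(
        kd=float(result.params["kd"].value),
        delta_max=float(result.params["delta_max"].value),
        kd_err=float(kd_err) if kd_err is not None else math.nan,
        delta_max_err=float(dmax_err) if dmax_err is not None else math.nan,
        residual_norm=float(np.linalg.norm(result.residual)),
    )


def _fit_exponential(delays: np.ndarray, intensities: np.ndarray,
                     ) -> tuple[float, float]:
    """Nonlinear LSQ of I0*exp(-r2*t), seeded by the log-linear fit."""
    if np.any(intensities <= 0):
        raise FitDomainError("intensities must be positive for decay fitting")
    slope, icpt = np.polyfit(delays, np.log(intensities), 1)
    r2_0, i0_0 = -slope, math.exp(icpt)
    if r2_0 <= 0:
        raise FitDomainError("best-fit relaxation rate is not positive "
                             "(non-decaying data)")
    model = Model(lambda t, i0, r2: i0 * np.exp(-r2 * t),
                  independent_vars=["t"])
    params = model.make_params(i0=i0_0, r2=r2_0)
    params["r2"].set(min=1e-12)
    params["i0"].set(min=1e-12)
    result = model.fit(intensities, params, t=delays)
    if not result.success:
        raise ConvergenceError("relaxation fit did not converge", result.message)
    r2 = float(result.params["r2"].value)
    if r2 <= 0:
        raise FitDomainError("best-fit relaxation rate is not positive")
    return r2, float(result.params["i0"].value)


def fit_r2(series: RelaxationSeries, n_mc: int = 1000,
           seed: int = 0) -> R2Fit:
    """Mono-exponential R2 fit with Monte Carlo error estimation.

    The point estimate is the least-squares fit of the raw data and is
    independent of ``n_mc`` and ``seed``.  The error is the standard
    deviation of R2 over ``n_mc`` refits of the best-fit curve perturbed
    by Gaussian noise of sd ``series.noise_sd`` (parametric bootstrap at
    the spectrum noise level).
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    t = np.asarray(series.delays, dtype=float)
    y = np.asarray(series.intensities, dtype=float)
    r2, i0 = _fit_exponential(t, y)

    rng = np.random.default_rng(seed)
    best = i0 * np.exp(-r2 * t)
    replicates = []
    for _ in range(n_mc):
        perturbed = best + rng.normal(0.0, series.noise_sd, size=t.size)
        try:
            r2_k, _ = _fit_exponential(t, np.maximum(perturbed, 1e-12))
        except (FitDomainError, ConvergenceError):
            continue  # pathological replicate at very high noise; drop it
        replicates.append(r2_k)
    r2_err = float(np.std(replicates)) if len(replicates) > 1 else 0.0
    return R2Fit(r2=r2, i0=i0, r2_err=r2_err, n_mc=n_mc, seed=seed)


def csp_series(spectrum_a: Mapping[str, tuple[float, float]],
               spectrum_b: Mapping[str, tuple[float, float]],
               n_scaling: float = DEFAULT_N_SCALING,
               ) -> tuple[list[ShiftPerturbation], list[str]]:
    """Per-residue CSPs between two assigned spectra.

    Returns the perturbation list over the shared residues (sorted by
    residue id) and the list of residues present in only one spectrum.
    """
    shared = sorted(set(spectrum_a) & set(spectrum_b))
    if not shared:
        raise ValueError("spectra share no residues")
    unmatched = sorted(set(spectrum_a) ^ set(spectrum_b))
    perturbations = []
    for rid in shared:
        dh = spectrum_b[rid][0] - spectrum_a[rid][0]
        dn = spectrum_b[rid][1] - spectrum_a[rid][1]
        perturbations.append(ShiftPerturbation(
            residue_id=rid, delta_h=dh, delta_n=dn,
            delta_av=csp(dh, dn, n_scaling)))
    return perturbations, unmatched


def normalize_csp(perturbations: Sequence[ShiftPerturbation],
                  reference: Sequence[ShiftPerturbation],
                  ) -> dict[str, float | None]:
    """Elementwise ratio of CSPs to a reference perturbation set.

    Mirrors normalizing a full-length construct's pH-induced CSPs to
    those measured for the isolated folded domain under the same pH
    change.  Where the reference CSP is zero the ratio is undefined and
    reported as ``None``, never as infinity.
    """
    ref_by_id = {p.residue_id: p.delta_av for p in reference}
    out: dict[str, float | None] = {}
    for p in perturbations:
        if p.residue_id not in ref_by_id:
            continue
        ref = ref_by_id[p.residue_id]
        out[p.residue_id] = (p.delta_av / ref) if ref != 0.0 else None
    return out
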