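"""Forward models and fitters for SPR kinetics, stoichiometry and titrations.

SPR sensorgrams are modelled with the closed-form 1:1 Langmuir solution
(association ``R(t) = Req (1 - exp(-(ka C + kd) t))`` with
``Req = Rmax ka C / (ka C + kd)``; exponential decay after injection stop).
The binding stoichiometry follows the mass-proportionality of the SPR
response::

    S = Rmax / ((MW_A / MW_L) * R_L)

with ``MW_A`` the analyte (ParA monomer) mass, ``MW_L`` and ``R_L`` the mass
and immobilized amount of the DNA ligand; ``S`` counts analyte monomers per
DNA molecule and halves to dimers.

Equilibrium titrations are fit with either a Hill curve (apparent KD = EC50,
cooperativity h) or, when the dissociation constant approaches the probe
concentration, the quadratic ligand-depletion ("tight binding") model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Sensorgram",
    "BindingIsotherm",
    "KineticParams",
    "StoichiometryResult",
    "IsothermFit",
    "FitError",
    "langmuir_forward",
    "fit_kinetics",
    "stoichiometry",
    "hill_model",
    "fit_hill",
    "depletion_model",
    "fit_depletion",
    "fold_stimulation",
    "read_sensorgrams_csv",
    "read_isotherm_csv",
]


class FitError(RuntimeError):
    """Raised when input data cannot support a meaningful fit."""


@dataclass
class Sensorgram:
    """One SPR injection: response (RU) vs time (s) at a fixed analyte
    concentration, with association phase ``[t_inject, t_stop]``."""

    times: np.ndarray
    response: np.ndarray
    conc: float  # M
    t_inject: float = 0.0
    t_stop: float = 180.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.times.shape != self.response.shape:
            raise ValueError("times and response must have equal shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.t_stop <= self.t_inject:
            raise ValueError("t_stop must follow t_inject")
        if self.conc < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class BindingIsotherm:
    """Fraction of probe bound vs total protein concentration (nM)."""

    conc_nM: np.ndarray
    fraction_bound: np.ndarray
    probe_conc_nM: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.conc_nM = np.asarray(self.conc_nM, dtype=float)
        self.fraction_bound = np.asarray(self.fraction_bound, dtype=float)
        if self.conc_nM.shape != self.fraction_bound.shape:
            raise ValueError("conc and fraction_bound must have equal shape")


@dataclass
class KineticParams:
    """1:1 Langmuir kinetic parameters; ``KD = kd / ka`` by identity."""

    ka: float  # M^-1 s^-1
    kd: float  # s^-1
    rmax: float  # RU

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd <= 0 or self.rmax <= 0:
            raise ValueError("ka, kd and Rmax must be positive")

    @property
    def KD(self) -> float:
        return self.kd / self.ka


@dataclass
class KineticFitResult:
    """Aggregated kinetic fit plus the per-curve ("local") parameters."""

    params: KineticParams
    per_curve: list[KineticParams]
    residual_norm: float
    mode: str


@dataclass
class StoichiometryResult:
    s_monomers: float
    rmax: float
    mw_analyte: float
    mw_ligand: float
    r_l: float

    @property
    def s_dimers(self) -> float:
        return self.s_monomers / 2.0


@dataclass
class IsothermFit:
    kd_app_nM: float
    hill_h: float
    model_kind: Literal["hill", "depletion"]
    residual_norm: float
    stderr: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Forward models


def langmuir_forward(
    params: KineticParams,
    conc: float,
    times: np.ndarray,
    t_inject: float = 0.0,
    t_stop: float = 180.0,
) -> np.ndarray:
    """Closed-form 1:1 Langmuir response curve.

    Association (t_inject <= t <= t_stop)::

        R(t) = Req * (1 - exp(-(ka*C + kd) * (t - t_inject)))
        Req  = Rmax * ka*C / (ka*C + kd)

    Dissociation (t > t_stop)::

        R(t) = R(t_stop) * exp(-kd * (t - t_stop))

    The curve is continuous at the phase boundary and identically zero for
    C = 0 or before the injection.
    """
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    t = np.asarray(times, dtype=float)
    r = np.zeros_like(t)
    if conc == 0:
        return r
    kobs = params.ka * conc + params.kd
    req = params.rmax * params.ka * conc / kobs
    assoc = (t >= t_inject) & (t <= t_stop)
    r[assoc] = req * (1.0 - np.exp(-kobs * (t[assoc] - t_inject)))
    r_off = req * (1.0 - math.exp(-kobs * (t_stop - t_inject)))
    dissoc = t > t_stop
    r[dissoc] = r_off * np.exp(-params.kd * (t[dissoc] - t_stop))
    return r


def hill_model(p_nM, kd_app_nM: float, h: float):
    """Hill isotherm: theta = P^h / (KD^h + P^h).

    ``kd_app_nM`` is the EC50 of the curve (the titration midpoint), not a
    microscopic constant.  Reduces to the simple Langmuir isotherm
    P/(KD + P) at h = 1.
    """
    if kd_app_nM <= 0:
        raise ValueError("kd_app must be positive")
    p = np.asarray(p_nM, dtype=float)
    with np.errstate(divide="ignore"):
        theta = np.where(p > 0, 1.0 / (1.0 + (kd_app_nM / np.maximum(p, 1e-300)) ** h), 0.0)
    return theta if theta.ndim else float(theta)


def depletion_model(p0_nM, d0_nM: float, kd_nM: float):
    """Quadratic ligand-depletion isotherm (tight binding).

    Fraction of probe bound when the probe concentration D0 is not
    negligible relative to KD::

        theta = [(P0 + D0 + KD) - sqrt((P0 + D0 + KD)^2 - 4 P0 D0)] / (2 D0)
    """
    if d0_nM <= 0:
        raise ValueError("probe concentration D0 must be positive")
    if kd_nM < 0:
        raise ValueError("KD must be >= 0")
    p0 = np.asarray(p0_nM, dtype=float)
    b = p0 + d0_nM + kd_nM
    disc = np.maximum(b * b - 4.0 * p0 * d0_nM, 0.0)
    theta = (b - np.sqrt(disc)) / (2.0 * d0_nM)
    return theta if theta.ndim else float(theta)


# ---------------------------------------------------------------------------
# Kinetic fitting


def _fit_single_curve(sg: Sensorgram) -> tuple[KineticParams, float]:
    """Deterministic multi-start least-squares fit of one sensorgram."""
    resp_scale = float(np.max(np.abs(sg.response)))
    if resp_scale <= 0:
        raise FitError("all-zero response: kinetics not identifiable")

    def model(logp: np.ndarray) -> np.ndarray:
        ka, kd, rmax = np.exp(logp)
        return langmuir_forward(
            KineticParams(ka, kd, rmax), sg.conc, sg.times, sg.t_inject, sg.t_stop
        )

    def residuals(logp: np.ndarray) -> np.ndarray:
        return model(logp) - sg.response

    # 3 x 3 x 3 log-spaced multi-start grid in fixed order: screen all 27
    # starts by SSE, refine the best three, keep the overall best.
    ka_grid = [1e3, 3e4, 1e6]
    kd_grid = [1e-4, 3e-3, 1e-1]
    rmax_grid = [resp_scale, 2 * resp_scale, 4 * resp_scale]
    starts = [
        np.log([ka, kd, rm])
        for ka in ka_grid
        for kd in kd_grid
        for rm in rmax_grid
    ]
    screened = sorted(
        enumerate(starts), key=lambda it: (float(np.sum(residuals(it[1]) ** 2)), it[0])
    )
    best: tuple[float, np.ndarray] | None = None
    for _, x0 in screened[:3]:
        sol = least_squares(residuals, x0, method="lm", max_nfev=2000)
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, sol.x)
    assert best is not None
    ka, kd, rmax = np.exp(best[1])
    return KineticParams(ka, kd, rmax), math.sqrt(best[0])


def fit_kinetics(
    sensorgrams: Sequence[Sensorgram],
    mode: Literal["local", "global"] = "local",
) -> KineticFitResult:
    """Fit the 1:1 Langmuir model to a set of dose-response sensorgrams.

    ``local`` mode (default) fits ka, kd and Rmax per concentration and
    aggregates by the median — the per-curve analysis used for SPR dose
    series whose kinetics vary between injections.  ``global`` mode refines
    a single shared parameter set against all curves simultaneously,
    starting from the local medians.

    Raises
    ------
    FitError
        On empty input or when every curve is flat zero (non-identifiable).
    """
    if not sensorgrams:
        raise FitError("no sensorgrams supplied")
    if all(float(np.max(np.abs(sg.response))) == 0.0 for sg in sensorgrams):
        raise FitError("all sensorgrams are flat zero: kinetics not identifiable")

    per_curve: list[KineticParams] = []
    norms: list[float] = []
    for sg in sensorgrams:
        if sg.conc == 0 or float(np.max(np.abs(sg.response))) == 0.0:
            continue  # uninformative for a local fit
        p, norm = _fit_single_curve(sg)
        per_curve.append(p)
        norms.append(norm)
    if not per_curve:
        raise FitError("no informative sensorgrams (non-zero conc and response)")

    agg = KineticParams(
        ka=float(np.median([p.ka for p in per_curve])),
        kd=float(np.median([p.kd for p in per_curve])),
        rmax=float(np.median([p.rmax for p in per_curve])),
    )
    residual_norm = float(np.sqrt(np.sum(np.square(norms))))

    if mode == "global":

        def residuals(logp: np.ndarray) -> np.ndarray:
            ka, kd, rmax = np.exp(logp)
            pr = KineticParams(ka, kd, rmax)
            return np.concatenate(
                [
                    langmuir_forward(pr, sg.conc, sg.times, sg.t_inject, sg.t_stop)
                    - sg.response
                    for sg in sensorgrams
                ]
            )

        sol = least_squares(
            residuals, np.log([agg.ka, agg.kd, agg.rmax]), method="lm", max_nfev=4000
        )
        ka, kd, rmax = np.exp(sol.x)
        agg = KineticParams(ka, kd, rmax)
        residual_norm = float(np.linalg.norm(sol.fun))
    elif mode != "local":
        raise ValueError(f"unknown mode {mode!r}")

    return KineticFitResult(
        params=agg, per_curve=per_curve, residual_norm=residual_norm, mode=mode
    )


def stoichiometry(
    rmax: float, mw_analyte: float, mw_ligand: float, r_l: float
) -> StoichiometryResult:
    """Analyte monomers bound per immobilized DNA from the SPR saturation
    response: ``S = Rmax / ((MW_A / MW_L) * R_L)``.

    ``S`` is invariant to rescaling both molecular weights by a common
    factor and linear in Rmax.  ``s_dimers`` is S/2.
    """
    if mw_analyte <= 0 or mw_ligand <= 0 or r_l <= 0:
        raise ValueError("molecular weights and R_L must be positive")
    if rmax < 0:
        raise ValueError("Rmax must be >= 0")
    s = rmax / ((mw_analyte / mw_ligand) * r_l)
    return StoichiometryResult(
        s_monomers=s, rmax=rmax, mw_analyte=mw_analyte, mw_ligand=mw_ligand, r_l=r_l
    )


# ---------------------------------------------------------------------------
# Isotherm fitting


def _isotherm_stderr(residuals_fn, x: np.ndarray, names: list[str]) -> dict[str, float]:
    """Asymptotic parameter standard errors from the Jacobian at the optimum."""
    eps = 1e-6
    r0 = residuals_fn(x)
    n, k = r0.size, x.size
    if n <= k:
        return {name: float("nan") for name in names}
    J = np.empty((n, k))
    for j in range(k):
        dx = np.zeros_like(x)
        dx[j] = eps * max(1.0, abs(x[j]))
        J[:, j] = (residuals_fn(x + dx) - r0) / dx[j]
    sigma2 = float(np.sum(r0**2)) / (n - k)
    try:
        cov = sigma2 * np.linalg.inv(J.T @ J)
        return {name: float(np.sqrt(max(cov[j, j], 0.0))) for j, name in enumerate(names)}
    except np.linalg.LinAlgError:
        return {name: float("nan") for name in names}


def fit_hill(iso: BindingIsotherm) -> IsothermFit:
    """Least-squares Hill fit with bounds h in [0.5, 6], KD in (0, 10*max P].

    Deterministic multi-start over a fixed log-spaced KD x h grid.  The
    reported ``kd_app_nM`` is the EC50 of the fitted curve.
    """
    p = iso.conc_nM
    theta = iso.fraction_bound
    if p.size == 0:
        raise FitError("empty isotherm")
    if np.all(theta == 0):
        raise FitError("all-zero fraction bound: KD not identifiable")
    kd_hi = 10.0 * float(np.max(p))

    def residuals(x: np.ndarray) -> np.ndarray:
        return hill_model(p, x[0], x[1]) - theta

    pos = p[p > 0]
    starts = [
        np.array([kd0, h0])
        for kd0 in np.geomspace(max(pos.min(), 1e-3), pos.max(), 3)
        for h0 in (1.0, 2.0, 4.0)
    ]
    best: tuple[float, np.ndarray] | None = None
    for x0 in starts:
        sol = least_squares(
            residuals, x0, bounds=([1e-9, 0.5], [kd_hi, 6.0]), max_nfev=2000
        )
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, sol.x)
    assert best is not None
    sse, x = best
    return IsothermFit(
        kd_app_nM=float(x[0]),
        hill_h=float(x[1]),
        model_kind="hill",
        residual_norm=math.sqrt(sse),
        stderr=_isotherm_stderr(residuals, x, ["kd_app_nM", "hill_h"]),
    )


def fit_depletion(iso: BindingIsotherm, probe_conc_nM: float | None = None) -> IsothermFit:
    """Fit KD of the quadratic depletion model at known probe concentration."""
    d0 = probe_conc_nM if probe_conc_nM is not None else iso.probe_conc_nM
    if d0 is None or d0 <= 0:
        raise ValueError("probe concentration D0 must be positive")
    p = iso.conc_nM
    theta = iso.fraction_bound
    if p.size == 0:
        raise FitError("empty isotherm")
    if np.all(theta == 0):
        raise FitError("all-zero fraction bound: KD not identifiable")
    kd_hi = 10.0 * float(np.max(p))

    def residuals(x: np.ndarray) -> np.ndarray:
        return depletion_model(p, d0, x[0]) - theta

    best: tuple[float, np.ndarray] | None = None
    for kd0 in np.geomspace(1e-2, kd_hi / 10.0, 5):
        sol = least_squares(residuals, np.array([kd0]), bounds=([1e-9], [kd_hi]), max_nfev=2000)
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, sol.x)
    assert best is not None
    sse, x = best
    return IsothermFit(
        kd_app_nM=float(x[0]),
        hill_h=1.0,
        model_kind="depletion",
        residual_norm=math.sqrt(sse),
        stderr=_isotherm_stderr(residuals, x, ["kd_app_nM"]),
    )


def fold_stimulation(kd_ref_nM: float, kd_test_nM: float) -> float:
    """Affinity gain of a test condition over a reference: kd_ref / kd_test.

    Values > 1 mean the test condition binds tighter (e.g. the ParB-assisted
    promoter binding); values < 1 indicate destabilization.
    """
    if kd_ref_nM <= 0 or kd_test_nM <= 0:
        raise ValueError("dissociation constants must be positive")
    return kd_ref_nM / kd_test_nM


# ---------------------------------------------------------------------------
# I/O (long-format CSVs matching the synthetic writers)


def read_sensorgrams_csv(path: str | Path, t_stop: float | None = None) -> list[Sensorgram]:
    """Read a long-format sensorgram CSV (time_s, response_RU, conc_M, phase).

    The association stop time is inferred from the last time point labelled
    ``association`` unless given explicitly.
    """
    df = pd.read_csv(path)
    out: list[Sensorgram] = []
    for conc, grp in df.groupby("conc_M", sort=True):
        grp = grp.sort_values("time_s")
        stop = t_stop
        if stop is None:
            assoc = grp[grp["phase"] == "association"]
            stop = float(assoc["time_s"].max()) if len(assoc) else float(grp["time_s"].max())
        out.append(
            Sensorgram(
                times=grp["time_s"].to_numpy(),
                response=grp["response_RU"].to_numpy(),
                conc=float(conc),
                t_inject=0.0,
                t_stop=stop,
            )
        )
    return out


def read_isotherm_csv(path: str | Path, probe_conc_nM: float | None = None) -> BindingIsotherm:
    """Read an isotherm CSV with columns conc_nM, fraction_bound."""
    df = pd.read_csv(path).sort_values("conc_nM")
    return BindingIsotherm(
        conc_nM=df["conc_nM"].to_numpy(),
        fraction_bound=df["fraction_bound"].to_numpy(),
        probe_conc_nM=probe_conc_nM,
    )
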