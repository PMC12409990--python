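"""Equilibrium-unfolding thermodynamics and proteolysis kinetics.

Implements the linear-extrapolation-method (LEM) forward models for monomeric
two-state (N <-> U) and three-state (N <-> I <-> U) equilibrium unfolding,
global multi-probe multi-concentration fitting of conformational free
energies and m-values, a concentration-dependence (monomer-consistency)
check, and single-exponential fits of limited-proteolysis band intensities.

Sign convention: dG(urea) = dG_H2O - m*[urea] and K = exp(-dG/RT), so a
positive dG_H2O means the more folded species is stable in water.  All free
energies are kcal/mol and m-values kcal/mol/M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

#: Gas constant in kcal/(mol K)
R_KCAL = 1.9872e-3

TWO_STATE = "two_state"
THREE_STATE = "three_state"


@dataclass(frozen=True)
class ProbeBaselines:
    """Linear species baselines for one spectroscopic probe.

    The native and unfolded baselines are linear in urea; the intermediate
    baseline (three-state only) is a urea-independent constant, the standard
    identifiability choice for three-state fits.
    """

    n_intercept: float
    n_slope: float
    u_intercept: float
    u_slope: float
    i_value: float | None = None


@dataclass
class ThermoParams:
    """Thermodynamic parameters of an equilibrium-unfolding model.

    ``dG_list`` and ``m_list`` hold one entry per transition in unfolding
    order: N->U for the two-state model, (N->I, I->U) for the three-state
    model.
    """

    model: str
    dG_list: list[float]
    m_list: list[float]
    temperature: float = 298.15
    baselines: dict[str, ProbeBaselines] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in (TWO_STATE, THREE_STATE):
            raise ValueError(f"unknown model {self.model!r}")
        n_trans = 1 if self.model == TWO_STATE else 2
        if len(self.dG_list) != n_trans or len(self.m_list) != n_trans:
            raise ValueError(
                f"{self.model} expects {n_trans} transition(s); got "
                f"{len(self.dG_list)} dG and {len(self.m_list)} m values"
            )
        if any(m <= 0 for m in self.m_list):
            raise ValueError("m-values must be positive")
        for probe, b in self.baselines.items():
            if self.model == TWO_STATE and b.i_value is not None:
                raise ValueError(
                    f"probe {probe!r}: intermediate baseline supplied for a "
                    "two-state model"
                )
            if self.model == THREE_STATE and b.i_value is None:
                raise ValueError(
                    f"probe {probe!r}: three-state model requires an "
                    "intermediate baseline"
                )

    @property
    def rt(self) -> float:
        return R_KCAL * self.temperature

    @property
    def midpoints(self) -> list[float]:
        """Transition midpoints Cm_i = dG_i / m_i in M urea."""
        return [dg / m for dg, m in zip(self.dG_list, self.m_list)]


def _equilibrium_constant(dG: float, m: float, urea: np.ndarray, rt: float) -> np.ndarray:
    return np.exp(-(dG - m * np.asarray(urea, dtype=float)) / rt)


def fractions_two_state(params: ThermoParams, urea) -> tuple[np.ndarray, np.ndarray]:
    """Species fractions (fN, fU) of the two-state model at the given urea."""
    if params.model != TWO_STATE:
        raise ValueError("params are not two-state")
    k1 = _equilibrium_constant(params.dG_list[0], params.m_list[0], urea, params.rt)
    f_u = k1 / (1.0 + k1)
    return 1.0 - f_u, f_u


def fractions_three_state(
    params: ThermoParams, urea
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Species fractions (fN, fI, fU) of the three-state monomer model.

    fN = 1/(1 + K1 + K1*K2), fI = K1*fN, fU = K1*K2*fN; the fractions are the
    normalized Boltzmann weights of the three species and sum to 1 exactly.
    """
    if params.model != THREE_STATE:
        raise ValueError("params are not three-state")
    rt = params.rt
    k1 = _equilibrium_constant(params.dG_list[0], params.m_list[0], urea, rt)
    k2 = _equilibrium_constant(params.dG_list[1], params.m_list[1], urea, rt)
    f_n = 1.0 / (1.0 + k1 + k1 * k2)
    return f_n, k1 * f_n, k1 * k2 * f_n


def signal_model(params: ThermoParams, urea, probe: str) -> np.ndarray:
    """Population-weighted observable signal for one probe.

    signal = fN*(aN + bN*urea) + [fI*cI] + fU*(aU + bU*urea).
    """
    if probe not in params.baselines:
        raise KeyError(f"no baselines for probe {probe!r}")
    b = params.baselines[probe]
    u = np.asarray(urea, dtype=float)
    if params.model == TWO_STATE:
        f_n, f_u = fractions_two_state(params, u)
        return f_n * (b.n_intercept + b.n_slope * u) + f_u * (b.u_intercept + b.u_slope * u)
    f_n, f_i, f_u = fractions_three_state(params, u)
    return (
        f_n * (b.n_intercept + b.n_slope * u)
        + f_i * b.i_value
        + f_u * (b.u_intercept + b.u_slope * u)
    )


@dataclass
class EquilibriumFoldingDataset:
    """One unfolding or refolding curve for a single probe and concentration."""

    urea: np.ndarray
    signal: np.ndarray
    probe: str
    conc_uM: float
    replicate: int = 0
    direction: str = "unfolding"

    def __post_init__(self) -> None:
        self.urea = np.asarray(self.urea, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.urea.shape != self.signal.shape:
            raise ValueError("urea and signal must have the same shape")
        if np.any(self.urea < 0):
            raise ValueError("urea concentrations must be non-negative")
        if len(self.urea) < 8:
            raise ValueError("a dataset needs at least 8 points")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signals must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "urea_M": self.urea,
                "signal": self.signal,
                "probe": self.probe,
                "conc_uM": self.conc_uM,
                "replicate": self.replicate,
                "direction": self.direction,
            }
        )


def datasets_to_frame(datasets: list[EquilibriumFoldingDataset]) -> pd.DataFrame:
    return pd.concat([d.to_frame() for d in datasets], ignore_index=True)


def datasets_from_frame(frame: pd.DataFrame) -> list[EquilibriumFoldingDataset]:
    """Rebuild dataset objects from a tidy table (as written by the generator)."""
    out = []
    keys = ["probe", "conc_uM", "replicate", "direction"]
    for (probe, conc, rep, direction), grp in frame.groupby(keys, sort=True):
        out.append(
            EquilibriumFoldingDataset(
                grp["urea_M"].to_numpy(),
                grp["signal"].to_numpy(),
                probe=str(probe),
                conc_uM=float(conc),
                replicate=int(rep),
                direction=str(direction),
            )
        )
    return out


# --------------------------------------------------------------------------
# Global fitting
# --------------------------------------------------------------------------


@dataclass
class FoldingFitResult:
    """Result of a global equilibrium-unfolding fit."""

    params: ThermoParams
    stderr: dict[str, float] | None
    rss: float
    aic: float
    n_parameters: int
    n_points: int
    converged: bool
    n_starts: int
    seed: int | None

    @property
    def total_dG(self) -> float:
        return float(sum(self.params.dG_list))


def _pack_names(model: str, probes: list[str], native_slope: bool) -> list[str]:
    n_trans = 1 if model == TWO_STATE else 2
    names = [f"dG{i + 1}" for i in range(n_trans)] + [f"m{i + 1}" for i in range(n_trans)]
    for p in probes:
        names += [f"{p}:aN"] + ([f"{p}:bN"] if native_slope else [])
        if model == THREE_STATE:
            names += [f"{p}:cI"]
        names += [f"{p}:aU", f"{p}:bU"]
    return names


def _unpack(
    theta: np.ndarray,
    model: str,
    probes: list[str],
    temperature: float,
    native_slope: bool,
) -> ThermoParams:
    n_trans = 1 if model == TWO_STATE else 2
    dG = list(theta[:n_trans])
    m = list(theta[n_trans : 2 * n_trans])
    baselines = {}
    i = 2 * n_trans
    for p in probes:
        a_n = theta[i]
        i += 1
        b_n = 0.0
        if native_slope:
            b_n = theta[i]
            i += 1
        c_i = None
        if model == THREE_STATE:
            c_i = theta[i]
            i += 1
        a_u, b_u = theta[i : i + 2]
        i += 2
        baselines[p] = ProbeBaselines(a_n, b_n, a_u, b_u, c_i)
    return ThermoParams(model, dG, m, temperature, baselines)


def global_fit(
    datasets: list[EquilibriumFoldingDataset],
    model: str,
    n_starts: int = 25,
    seed: int | None = None,
    temperature: float = 298.15,
    dG_bounds: tuple[float, float] = (0.0, 15.0),
    m_bounds: tuple[float, float] = (1e-3, 3.0),
    native_slope: bool = False,
) -> FoldingFitResult:
    """Globally fit dG and m values shared across all datasets.

    Thermodynamic parameters are shared across probes, concentrations and
    directions; baselines are shared per probe.  Residuals are weighted per
    probe by the inverse of a successive-difference noise estimate, so
    probes reported in different units (fluorescence intensity, CD
    ellipticity) contribute comparably to the global objective.  The
    nonlinear objective is minimized from ``n_starts`` Latin-hypercube
    initial values, sampled as transition midpoints over the urea window
    (with m-values over their bounds), keeping the best converged solution.

    Because the baselines enter the signal model linearly, the multistart
    search uses variable projection: only (dG, m) are optimized nonlinearly
    and the baselines are profiled out by an inner linear least-squares
    solve per probe.  A final full-parameter refinement from the best
    projected solution supplies the covariance-based standard errors.

    With ``native_slope=False`` (default) the native baseline is treated as
    urea-independent: when the native state is only marginally stable there
    is no extended pre-transition region from which a slope could be
    estimated, and leaving it free makes the first transition's free energy
    unidentifiable.  Set ``native_slope=True`` to fit it.
    """
    if not datasets:
        raise ValueError("no datasets supplied")
    if model not in (TWO_STATE, THREE_STATE):
        raise ValueError(f"unknown model {model!r}")
    probes = sorted({d.probe for d in datasets})
    for p in probes:
        pts = sum(len(d.urea) for d in datasets if d.probe == p)
        if pts < 8:
            raise ValueError(f"probe {p!r} has fewer than 8 points")
    max_urea = max(d.urea.max() for d in datasets)
    if max_urea < 6.0:
        warnings.warn(
            f"urea only spans up to {max_urea:.1f} M; the unfolded baseline "
            "may be poorly determined",
            stacklevel=2,
        )

    n_trans = 1 if model == TWO_STATE else 2
    names = _pack_names(model, probes, native_slope)
    n_params = len(names)
    n_points = sum(len(d.urea) for d in datasets)
    # group points per probe; datasets of one probe share baselines
    urea_by_probe = {
        p: np.concatenate([d.urea for d in datasets if d.probe == p]) for p in probes
    }
    sig_by_probe = {
        p: np.concatenate([d.signal for d in datasets if d.probe == p]) for p in probes
    }
    rt = R_KCAL * temperature
    # per-probe inverse-noise weights (successive-difference estimator)
    weight_by_probe = {}
    for p in probes:
        sds = [
            np.std(np.diff(d.signal)) / np.sqrt(2.0)
            for d in datasets
            if d.probe == p and len(d.signal) > 2
        ]
        sd = float(np.median(sds)) if sds else 0.0
        weight_by_probe[p] = 1.0 / sd if sd > 0 else 1.0

    def _design(theta_nl: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Linear design matrix of the species-baseline coefficients."""
        dG = theta_nl[:n_trans]
        m = theta_nl[n_trans:]
        if model == TWO_STATE:
            k1 = np.exp(-(dG[0] - m[0] * u) / rt)
            f_u = k1 / (1.0 + k1)
            f_n = 1.0 - f_u
            cols = [f_n] + ([f_n * u] if native_slope else []) + [f_u, f_u * u]
        else:
            k1 = np.exp(-(dG[0] - m[0] * u) / rt)
            k2 = np.exp(-(dG[1] - m[1] * u) / rt)
            f_n = 1.0 / (1.0 + k1 + k1 * k2)
            f_i = k1 * f_n
            f_u = k1 * k2 * f_n
            cols = [f_n] + ([f_n * u] if native_slope else []) + [f_i, f_u, f_u * u]
        return np.column_stack(cols)

    def _profiled(theta_nl: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Residuals with baselines solved by linear least squares per probe."""
        res = []
        coeffs = {}
        for p in probes:
            a = _design(theta_nl, urea_by_probe[p])
            y = sig_by_probe[p]
            c, *_ = np.linalg.lstsq(a, y, rcond=None)
            coeffs[p] = c
            res.append((a @ c - y) * weight_by_probe[p])
        return np.concatenate(res), coeffs

    lo_nl = np.array([dG_bounds[0]] * n_trans + [m_bounds[0]] * n_trans)
    hi_nl = np.array([dG_bounds[1]] * n_trans + [m_bounds[1]] * n_trans)

    # Multistart in (midpoint, m) space: transition midpoints Cm = dG/m must
    # lie inside the experimental urea window, so Latin-hypercube sample the
    # midpoints over that window (sorted so transitions stay ordered) and the
    # m-values over their bounds, then recover dG = m * Cm.
    u_min = min(d.urea.min() for d in datasets)
    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=2 * n_trans, seed=rng)
    unit = sampler.random(n=n_starts)
    cms = np.sort(u_min + unit[:, :n_trans] * (max_urea - u_min), axis=1)
    ms = m_bounds[0] + unit[:, n_trans:] * (m_bounds[1] - m_bounds[0])
    dgs = np.clip(ms * cms, *dG_bounds)
    starts = np.hstack([dgs, ms])

    best = None
    for theta0 in starts:
        try:
            sol = least_squares(
                lambda t: _profiled(t)[0], theta0, bounds=(lo_nl, hi_nl),
                method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
        except Exception:  # numerical failure of one start is not fatal
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol

    if best is not None:
        # full-parameter polish from the projected optimum (for the covariance)
        _, coeffs = _profiled(best.x)
        # design-column order matches the packed baseline order per probe
        theta_full0 = np.concatenate([best.x] + [coeffs[p] for p in probes])
        lo = np.full(n_params, -np.inf)
        hi = np.full(n_params, np.inf)
        lo[: 2 * n_trans], hi[: 2 * n_trans] = lo_nl, hi_nl

        def residuals(theta: np.ndarray) -> np.ndarray:
            par = _unpack(theta, model, probes, temperature, native_slope)
            return np.concatenate(
                [
                    (signal_model(par, urea_by_probe[p], p) - sig_by_probe[p])
                    * weight_by_probe[p]
                    for p in probes
                ]
            )

        try:
            best = least_squares(
                residuals, np.clip(theta_full0, lo, hi), bounds=(lo, hi),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            best = None

    if best is None:
        return FoldingFitResult(
            params=ThermoParams(model, [np.nan] * n_trans, [1.0] * n_trans, temperature, {}),
            stderr=None, rss=np.inf, aic=np.inf, n_parameters=n_params,
            n_points=n_points, converged=False, n_starts=n_starts, seed=seed,
        )

    rss = float(2 * best.cost)  # weighted residual sum of squares
    # AIC for Gaussian errors with the variance profiled out
    aic = n_points * np.log(max(rss, 1e-300) / n_points) + 2 * n_params
    stderr = None
    try:
        jtj = best.jac.T @ best.jac
        dof = max(n_points - n_params, 1)
        cov = np.linalg.pinv(jtj) * (rss / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderr = dict(zip(names, se.tolist()))
    except np.linalg.LinAlgError:
        pass

    return FoldingFitResult(
        params=_unpack(best.x, model, probes, temperature, native_slope),
        stderr=stderr, rss=rss, aic=float(aic), n_parameters=n_params,
        n_points=n_points, converged=True, n_starts=n_starts, seed=seed,
    )


# --------------------------------------------------------------------------
# Concentration dependence (monomer consistency)
# --------------------------------------------------------------------------


@dataclass
class ConcentrationDependenceReport:
    """Outcome of the protein-concentration overlay check.

    For a monomeric folding mechanism the normalized unfolding curves at
    different protein concentrations superimpose; a systematic spread across
    concentrations indicates an oligomeric (concentration-dependent)
    equilibrium.
    """

    statistic: float
    threshold: float
    concentration_independent: bool
    per_probe: dict[str, float]


def concentration_dependence_test(
    datasets: list[EquilibriumFoldingDataset],
    threshold: float | None = None,
) -> ConcentrationDependenceReport:
    """Overlay min-max-normalized curves across concentrations per probe.

    The statistic is the maximum, over probes and urea points, of the range
    of mean normalized signal across concentrations.  The default threshold
    is three times the pooled noise standard deviation estimated from
    successive differences of the normalized curves.
    """
    concs = sorted({d.conc_uM for d in datasets})
    if len(concs) < 2:
        raise ValueError("need at least two distinct protein concentrations")

    per_probe: dict[str, float] = {}
    noise_estimates = []
    for probe in sorted({d.probe for d in datasets}):
        sub = [d for d in datasets if d.probe == probe]
        # mean normalized signal per concentration on a shared urea grid
        curves = {}
        for conc in concs:
            rows = [d for d in sub if d.conc_uM == conc]
            if not rows:
                continue
            frames = []
            for d in rows:
                lo, hi = d.signal.min(), d.signal.max()
                span = hi - lo if hi > lo else 1.0
                norm = (d.signal - lo) / span
                frames.append(pd.Series(norm, index=np.round(d.urea, 6)))
                noise_estimates.append(np.std(np.diff(norm)) / np.sqrt(2))
            curves[conc] = pd.concat(frames).groupby(level=0).mean()
        table = pd.DataFrame(curves).dropna()
        spread = (table.max(axis=1) - table.min(axis=1)).max() if not table.empty else 0.0
        per_probe[probe] = float(spread)

    statistic = max(per_probe.values())
    if threshold is None:
        pooled_sd = float(np.median(noise_estimates)) if noise_estimates else 0.0
        threshold = max(3.0 * pooled_sd, 1e-12)
    return ConcentrationDependenceReport(
        statistic=statistic,
        threshold=float(threshold),
        concentration_independent=statistic < threshold,
        per_probe=per_probe,
    )


# --------------------------------------------------------------------------
# Proteolysis kinetics
# --------------------------------------------------------------------------


@dataclass
class ExponentialFit:
    """Single-exponential decay fit I(t) = A*exp(-k*t) + C."""

    k_app: float
    amplitude: float
    offset: float
    rss: float
    degenerate: bool = False


def fit_exponential(time, intensity) -> ExponentialFit:
    """Fit a band-intensity time course to a single-exponential decay.

    The apparent rate constant ``k_app`` (1/min for times in minutes) is
    constrained non-negative.  Non-decaying data yield k_app ~ 0 with a
    degenerate flag and a warning.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 time points")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")

    span = y.max() - y.min()
    if span <= 0:
        warnings.warn("constant intensity: returning degenerate k_app=0", stacklevel=2)
        return ExponentialFit(0.0, 0.0, float(y[0]), 0.0, degenerate=True)

    # log-linear seed for k from the positive part of the decay
    t_span = t.max() - t.min() if t.max() > t.min() else 1.0
    k0 = 1.0 / t_span
    guesses = [k0, 5 * k0, 0.2 * k0]

    def residuals(theta):
        a, k, c = theta
        return a * np.exp(-k * t) + c - y

    best = None
    for k_guess in guesses:
        theta0 = np.array([y[0] - y[-1], k_guess, y[-1]])
        sol = least_squares(
            residuals, theta0,
            bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    a, k, c = best.x
    rss = float(2 * best.cost)
    degenerate = abs(a) < 1e-8 * span or k < 1e-10
    if degenerate:
        warnings.warn("data do not decay: k_app ~ 0", stacklevel=2)
    return ExponentialFit(float(k), float(a), float(c), rss, degenerate=degenerate)
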