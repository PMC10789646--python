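"""One-site ITC binding model: forward simulation and nonlinear least-squares fit.

The model is the standard one-set-of-sites (Wiseman) isotherm for a
perfusion cell.  After injection *i* with cumulative injected volume
``dV``, the displaced-volume correction gives the active concentrations

    Mt = M0 (1 - dV/2V0) / (1 + dV/2V0)      (macromolecule, decreasing)
    Xt = X0 (dV/V0)      / (1 + dV/2V0)      (titrant, increasing)

The bound fraction Θ of sites is the physical root of the mass-action
quadratic, the cumulative heat is Q = N Θ Mt ΔH V0, and the per-injection
heat corrects for the heat carried out with the displaced volume:

    ΔQ_i = Q_i − Q_{i−1} + (v_i / V0) (Q_i + Q_{i−1}) / 2

plus a constant molar dilution-heat offset per mole of injectant.  Fitting
minimizes the sum of squared residuals of molar heats over the
non-discarded injections (the initial small injection is discarded, the
usual instrument practice).

Units: volumes μl, concentrations μM, raw heats μcal, molar heats and
enthalpies kcal/mol, temperatures K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

R_KCAL = 1.9872e-3  # gas constant, kcal/mol/K

# default titration geometry: one 0.4 μl priming injection then 18 × 2 μl
# into a 200 μl cell at 15 °C; syringe/cell concentrations mid-range of the
# usual bromodomain setup (1.6 mM peptide into 90 μM protein)
DEFAULT_INJECTIONS = (0.4,) + (2.0,) * 18


@dataclass(frozen=True)
class ITCProtocol:
    cell_volume_ul: float = 200.0
    injection_volumes_ul: tuple[float, ...] = DEFAULT_INJECTIONS
    syringe_conc_uM: float = 1600.0
    cell_conc_uM: float = 90.0
    temperature_K: float = 288.15

    def __post_init__(self) -> None:
        if self.cell_volume_ul <= 0 or self.syringe_conc_uM <= 0 or self.cell_conc_uM <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if not self.injection_volumes_ul or any(v <= 0 for v in self.injection_volumes_ul):
            raise ValueError("injection volumes must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_ul)


@dataclass(frozen=True)
class OneSiteParams:
    """Thermodynamic parameters of the one-site model.

    N: sites per macromolecule; Kd_uM: dissociation constant; dH_kcal:
    binding enthalpy; offset_kcal: constant dilution heat per mole injected.
    """

    N: float
    Kd_uM: float
    dH_kcal: float
    offset_kcal: float = 0.0

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.Kd_uM <= 0:
            raise ValueError("Kd must be positive")


@dataclass
class Isotherm:
    molar_ratio: np.ndarray      # Xt/Mt after each injection
    molar_heat: np.ndarray       # kcal per mol of injectant
    raw_heat_ucal: np.ndarray
    discarded: np.ndarray        # boolean mask; first injection flagged

    def __post_init__(self) -> None:
        n = len(self.molar_ratio)
        if not (len(self.molar_heat) == len(self.raw_heat_ucal) == len(self.discarded) == n):
            raise ValueError("isotherm arrays must have equal length")
        if np.any(np.diff(self.molar_ratio) <= 0):
            raise ValueError("molar ratios must be strictly increasing")

    @property
    def n_fit_points(self) -> int:
        return int((~self.discarded).sum())


@dataclass
class OneSiteFitResult:
    params: OneSiteParams
    sse: float
    dG_kcal: float
    minus_TdS_kcal: float
    converged: bool
    stderr: dict[str, float]


def concentrations_after_injection(protocol: ITCProtocol, i: int) -> tuple[float, float]:
    """Active cell concentrations (Mt, Xt) in μM after injection i (1-based)."""
    if not (1 <= i <= protocol.n_injections):
        raise ValueError(f"injection index {i} out of range 1..{protocol.n_injections}")
    dv = float(sum(protocol.injection_volumes_ul[:i]))
    v0 = protocol.cell_volume_ul
    if dv >= 2 * v0:
        raise ValueError("cumulative injected volume exceeds model validity (dV >= 2 V0)")
    d = dv / (2 * v0)
    mt = protocol.cell_conc_uM * (1 - d) / (1 + d)
    xt = protocol.syringe_conc_uM * (dv / v0) / (1 + d)
    return mt, xt


def bound_fraction(xt: float, mt: float, N: float, Kd_uM: float) -> float:
    """Fraction Θ of sites occupied, the physical root of the binding quadratic."""
    ka = 1.0 / Kd_uM
    r = xt / (N * mt)
    b = 1.0 + r + 1.0 / (N * ka * mt)
    disc = b * b - 4.0 * r
    assert disc >= 0, "binding quadratic has no real root (invalid inputs)"
    return 0.5 * (b - math.sqrt(disc))


def _model_heats(params: OneSiteParams, protocol: ITCProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free per-injection raw heats (μcal) and molar ratios."""
    v0 = protocol.cell_volume_ul
    n_inj = protocol.n_injections
    raw = np.empty(n_inj)
    ratios = np.empty(n_inj)
    q_prev = 0.0
    for i in range(1, n_inj + 1):
        mt, xt = concentrations_after_injection(protocol, i)
        theta = bound_fraction(xt, mt, params.N, params.Kd_uM)
        # Q in μcal: μM * μl * kcal/mol = 1e-3 μcal
        q = params.N * theta * mt * params.dH_kcal * v0 * 1e-3
        v_i = protocol.injection_volumes_ul[i - 1]
        dq = q - q_prev + (v_i / v0) * (q + q_prev) / 2.0
        # moles injected = X0[μM]·v[μl]·1e-12 mol; offset[kcal/mol] → μcal: ×1e9
        dq += params.offset_kcal * protocol.syringe_conc_uM * v_i * 1e-3
        raw[i - 1] = dq
        ratios[i - 1] = xt / mt
        q_prev = q
    return raw, ratios


def _molar_heats(raw_ucal: np.ndarray, protocol: ITCProtocol) -> np.ndarray:
    vols = np.asarray(protocol.injection_volumes_ul)
    # μcal → kcal/mol of injectant: ΔQ·1e-9 / (X0·v·1e-12)
    return raw_ucal * 1e3 / (protocol.syringe_conc_uM * vols)


def simulate_isotherm(
    params: OneSiteParams,
    protocol: ITCProtocol,
    noise_sd_ucal: float = 0.0,
    seed: int | None = None,
) -> Isotherm:
    """Forward-simulate an isotherm; Gaussian noise on raw heats, first injection flagged."""
    raw, ratios = _model_heats(params, protocol)
    if noise_sd_ucal > 0:
        rng = np.random.default_rng(seed)
        raw = raw + rng.normal(0.0, noise_sd_ucal, size=raw.shape)
    discarded = np.zeros(protocol.n_injections, dtype=bool)
    discarded[0] = True
    return Isotherm(
        molar_ratio=ratios,
        molar_heat=_molar_heats(raw, protocol),
        raw_heat_ucal=raw,
        discarded=discarded,
    )


def thermodynamics(params: OneSiteParams, temperature_K: float) -> tuple[float, float]:
    """Derived free energy and entropy term: dG = RT ln(Kd in molar); −TΔS = dG − dH."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    dg = R_KCAL * temperature_K * math.log(params.Kd_uM * 1e-6)
    return dg, dg - params.dH_kcal


class FlatIsothermError(ValueError):
    """Raised when the isotherm amplitude is indistinguishable from noise."""


def _self_initialize(y: np.ndarray, ratios: np.ndarray, protocol: ITCProtocol) -> list[OneSiteParams]:
    """Heuristic starts: plateaus give dH and offset, half-amplitude crossing
    gives N; Kd is scanned over a small grid (the transition steepness alone
    is a weak Kd estimator at low c)."""
    offset0 = float(y[-1])
    dh0 = float(y[0] - y[-1])
    half = offset0 + dh0 / 2.0
    crossings = np.nonzero(np.diff(np.sign(y - half)))[0]
    n0 = float(ratios[crossings[0]]) if len(crossings) else 1.0
    n0 = min(max(n0, 0.2), 5.0)
    mt_mid = concentrations_after_injection(protocol, protocol.n_injections // 2)[0]
    starts = []
    for c in (50.0, 5.0, 0.5):  # tight, moderate, shallow regimes
        starts.append(OneSiteParams(N=n0, Kd_uM=max(n0 * mt_mid / c, 1e-3), dH_kcal=dh0, offset_kcal=offset0))
    return starts


def fit_one_site(
    isotherm: Isotherm,
    protocol: ITCProtocol,
    init: OneSiteParams | None = None,
) -> OneSiteFitResult:
    """Fit (N, Kd, ΔH, offset) to the molar heats of the non-discarded injections.

    Bounded trust-region least squares on (N, log10 Kd, ΔH, offset);
    self-initializes from the isotherm shape when ``init`` is absent, with
    multi-start over binding-regime guesses.  Refuses isotherms whose
    amplitude is below three times the point-noise estimate.
    """
    mask = ~isotherm.discarded
    if mask.sum() < 6:
        raise ValueError("need at least 6 non-discarded injections to fit")
    y = isotherm.molar_heat[mask]

    amplitude = float(np.ptp(y))
    # point noise from the median absolute second difference (trend-insensitive)
    noise_est = float(np.median(np.abs(np.diff(y, n=2)))) / math.sqrt(6) * 1.4826 if y.size >= 3 else 0.0
    if amplitude < max(3.0 * noise_est, 1e-9):
        raise FlatIsothermError(
            f"flat isotherm: amplitude {amplitude:.3g} kcal/mol below 3x noise estimate {noise_est:.3g}"
        )

    # restrict the protocol to the simulated geometry for residual evaluation
    def residuals(x: np.ndarray) -> np.ndarray:
        p = OneSiteParams(N=x[0], Kd_uM=10.0 ** x[1], dH_kcal=x[2], offset_kcal=x[3])
        raw, _ = _model_heats(p, protocol)
        return _molar_heats(raw, protocol)[mask] - y

    lo = [0.1, -3.0, -np.inf, -np.inf]
    hi = [10.0, 5.0, np.inf, np.inf]

    if init is not None:
        starts = [init]
    else:
        starts = _self_initialize(y, isotherm.molar_ratio[mask], protocol)

    best = None
    for p0 in starts:
        x0 = np.array(
            [
                min(max(p0.N, lo[0]), hi[0]),
                min(max(math.log10(p0.Kd_uM), lo[1]), hi[1]),
                p0.dH_kcal,
                p0.offset_kcal,
            ]
        )
        sol = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000)
        if best is None or sol.cost < best.cost:
            best = sol

    x = best.x
    params = OneSiteParams(N=float(x[0]), Kd_uM=float(10.0 ** x[1]), dH_kcal=float(x[2]), offset_kcal=float(x[3]))
    sse = float(2 * best.cost)
    converged = bool(best.status > 0)

    stderr = _stderr_from_jacobian(best.jac, sse, y.size, x[1])
    dg, mtds = thermodynamics(params, protocol.temperature_K)
    return OneSiteFitResult(
        params=params,
        sse=sse,
        dG_kcal=dg,
        minus_TdS_kcal=mtds,
        converged=converged,
        stderr=stderr,
    )


def _stderr_from_jacobian(jac: np.ndarray, sse: float, n_obs: int, log10_kd: float) -> dict[str, float]:
    """Parameter standard errors from the local quadratic approximation."""
    names = ("N", "Kd_uM", "dH_kcal", "offset_kcal")
    dof = max(n_obs - jac.shape[1], 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * (sse / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        # delta method: fitted variable is log10 Kd
        se[1] = se[1] * (10.0 ** log10_kd) * math.log(10.0)
        return dict(zip(names, (float(v) for v in se)))
    except np.linalg.LinAlgError:
        return {k: float("nan") for k in names}


def write_isotherm_csv(isotherm: Isotherm, protocol: ITCProtocol, path: str | Path) -> None:
    pd.DataFrame(
        {
            "injection_index": np.arange(1, len(isotherm.raw_heat_ucal) + 1),
            "volume_ul": list(protocol.injection_volumes_ul),
            "raw_heat_ucal": [repr(float(v)) for v in isotherm.raw_heat_ucal],
            "molar_ratio": [repr(float(v)) for v in isotherm.molar_ratio],
            "discarded": isotherm.discarded.astype(int),
        }
    ).to_csv(path, index=False)


def read_isotherm_csv(path: str | Path, protocol: ITCProtocol) -> Isotherm:
    """Read an isotherm CSV (injection_index, volume_ul, raw_heat_ucal[, molar_ratio]).

    Molar ratios are recomputed from the protocol when absent; the first
    injection is flagged discarded unless a ``discarded`` column says otherwise.
    """
    df = pd.read_csv(path)
    if "raw_heat_ucal" not in df.columns:
        raise ValueError(f"{path}: missing raw_heat_ucal column")
    n = len(df)
    if n != protocol.n_injections:
        raise ValueError(f"{path}: {n} rows but protocol has {protocol.n_injections} injections")
    raw = df["raw_heat_ucal"].to_numpy(dtype=float)
    if "molar_ratio" in df.columns:
        ratios = df["molar_ratio"].to_numpy(dtype=float)
    else:
        ratios = np.array([
            (lambda mt_xt: mt_xt[1] / mt_xt[0])(concentrations_after_injection(protocol, i))
            for i in range(1, n + 1)
        ])
    if "discarded" in df.columns:
        discarded = df["discarded"].to_numpy(dtype=bool)
    else:
        discarded = np.zeros(n, dtype=bool)
        discarded[0] = True
    return Isotherm(
        molar_ratio=ratios,
        molar_heat=_molar_heats(raw, protocol),
        raw_heat_ucal=raw,
        discarded=discarded,
    )
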