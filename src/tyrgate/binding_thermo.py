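"""Binding and stability thermodynamics.

Closed-form state functions from ITC observables (ΔG = RT ln Kd,
TΔS = ΔH − ΔG, relative affinities, Wiseman c-value), the exact
single-site ITC isotherm fit, the four-parameter-logistic competitive
IC50 fit with relative IC50, and the two-state linear-extrapolation
(LEM) unfolding fit with its transition midpoint D½ = |ΔG_fold|/m.

Energies are kJ·mol⁻¹, concentrations molar, temperatures kelvin. The
default temperature is 298.15 K (25 °C) and is overridable everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .structure_io import TyrgateError

#: Universal gas constant, J·mol⁻¹·K⁻¹.
R_GAS = 8.314

#: Default absolute temperature (25 °C), K.
T_DEFAULT = 298.15


class FitError(TyrgateError):
    """A curve fit failed or the data are degenerate."""


class FitQualityWarning(UserWarning):
    """The data look ill-conditioned for the requested fit."""


# ---------------------------------------------------------------------------
# Closed-form state functions


def dG_from_Kd(Kd: float, T: float = T_DEFAULT) -> float:
    """Binding free energy ΔG = RT ln Kd, in kJ·mol⁻¹ (Kd in molar)."""
    if not (Kd > 0 and T > 0):
        raise TyrgateError(f"Kd and T must be positive (Kd={Kd}, T={T})")
    return R_GAS * T * np.log(Kd) / 1000.0


def Kd_from_dG(dG: float, T: float = T_DEFAULT) -> float:
    """Inverse of :func:`dG_from_Kd`: Kd = exp(1000·ΔG / RT), molar."""
    if not T > 0:
        raise TyrgateError("T must be positive")
    return float(np.exp(1000.0 * dG / (R_GAS * T)))


def TdS(dH: float, dG: float) -> float:
    """Entropic term TΔS = ΔH − ΔG (kJ·mol⁻¹)."""
    if not (np.isfinite(dH) and np.isfinite(dG)):
        raise TyrgateError("dH and dG must be finite")
    return dH - dG


def relative_Kd(Kd: float, Kd_ref: float) -> float:
    """Relative dissociation constant rKd = Kd / Kd_ref (dimensionless)."""
    if not (Kd > 0 and Kd_ref > 0):
        raise TyrgateError("Kd values must be positive")
    return Kd / Kd_ref


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, as in the printed report tables."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass
class BindingThermo:
    """Thermodynamic fingerprint of one ligand/variant binding measurement.

    ``dG`` and ``TdS`` are derived from (Kd, dH, T) on construction via
    :meth:`from_measurement`; the decomposition dG = dH − TdS holds
    exactly by construction.
    """

    ligand: str
    variant: str
    n: float
    Kd: float  # molar
    dH: float  # kJ/mol
    T: float = T_DEFAULT
    dG: float = field(default=np.nan)
    TdS: float = field(default=np.nan)

    @classmethod
    def from_measurement(
        cls, ligand: str, variant: str, n: float, Kd: float, dH: float,
        T: float = T_DEFAULT,
    ) -> "BindingThermo":
        if not Kd > 0:
            raise TyrgateError(f"Kd must be positive, got {Kd}")
        dG = dG_from_Kd(Kd, T)
        return cls(ligand, variant, n, Kd, dH, T, dG=dG, TdS=TdS(dH, dG))


@dataclass
class CValue:
    """Wiseman c-value c = Mt(0)/Kd with a fittable-range flag."""

    Mt0: float
    Kd: float
    c: float
    reliable: bool
    bounds: tuple[float, float] = (10.0, 600.0)


def c_value(Mt0: float, Kd: float, bounds: tuple[float, float] = (10.0, 600.0)) -> CValue:
    """Wiseman c = Mt(0)/Kd; flagged reliable when within ``bounds``.

    The default 10–600 window is the conventional range over which an
    ITC titration constrains Kd well.
    """
    if not (Mt0 > 0 and Kd > 0):
        raise TyrgateError("Mt0 and Kd must be positive")
    c = Mt0 / Kd
    return CValue(Mt0, Kd, c, bounds[0] <= c <= bounds[1], bounds)


# ---------------------------------------------------------------------------
# Single-site ITC isotherm (Wiseman)


def wiseman_total_heat(
    molar_ratio: np.ndarray, n: float, Kd: float, dH: float, Mt0: float, V0: float
) -> np.ndarray:
    """Cumulative heat (kJ) after titrating to the given molar ratios.

    Exact single-site 1:1 binding heat content of the cell:
    Q = n·Mt0·ΔH·V0/2 · [1 + Xr/n + 1/(n·c) − √((1 + Xr/n + 1/(n·c))² − 4·Xr/n)]
    with Xr the ligand:protein molar ratio and c = Mt0/Kd.
    """
    Xr = np.asarray(molar_ratio, dtype=float)
    c = Mt0 / Kd
    b = 1.0 + Xr / n + 1.0 / (n * c)
    disc = np.maximum(b * b - 4.0 * Xr / n, 0.0)
    return n * Mt0 * dH * V0 / 2.0 * (b - np.sqrt(disc))


def itc_injection_heats(
    molar_ratio: np.ndarray,
    n: float,
    Kd: float,
    dH: float,
    Mt0: float,
    V0: float = 1.4523e-3,
    offset: float = 0.0,
) -> np.ndarray:
    """Per-injection heats normalised per mole of injectant (kJ·mol⁻¹).

    ``molar_ratio`` is the cumulative ligand:protein ratio after each
    injection; differencing the total heat and dividing by the moles
    injected gives the quantity an ITC instrument reports. ``offset``
    models a constant residual dilution heat.
    """
    Xr = np.asarray(molar_ratio, dtype=float)
    if np.any(np.diff(Xr) <= 0) or Xr[0] <= 0:
        raise TyrgateError("molar-ratio grid must be positive and strictly increasing")
    Q = wiseman_total_heat(np.concatenate([[0.0], Xr]), n, Kd, dH, Mt0, V0)
    dXr = np.diff(np.concatenate([[0.0], Xr]))
    return np.diff(Q) / (dXr * Mt0 * V0) + offset


@dataclass
class ITCFit:
    """Point estimates of a single-site ITC isotherm fit."""

    n: float
    Kd: float  # molar
    dH: float  # kJ/mol
    offset: float
    residual_norm: float


def fit_itc_isotherm(
    molar_ratio: np.ndarray,
    heats: np.ndarray,
    Mt0: float,
    V0: float = 1.4523e-3,
    fit_offset: bool = False,
) -> ITCFit:
    """Least-squares fit of (n, Kd, ΔH) to normalised injection heats.

    ``heats`` are kJ per mol injectant on the cumulative molar-ratio
    grid. Flat curves (no transition) raise :class:`FitError`; a c-value
    outside the fittable range at the solution triggers a
    :class:`FitQualityWarning`.
    """
    Xr = np.asarray(molar_ratio, dtype=float)
    q = np.asarray(heats, dtype=float)
    if Xr.size != q.size:
        raise TyrgateError("molar_ratio and heats must have equal length")
    if Xr.size < 10:
        raise FitError("need at least 10 injections spanning the transition")
    span = np.ptp(q)
    if span < 1e-12 or np.max(np.abs(q)) < 1e-12:
        raise FitError("no transition in the injection heats (flat curve)")

    dH0 = q[0]
    # molar ratio at the half-height crossing approximates the stoichiometry
    half = (q[0] + q[-1]) / 2.0
    crossings = np.nonzero(np.diff(np.sign(q - half)))[0]
    n0 = float(Xr[crossings[0]]) if crossings.size else 1.0
    n0 = min(max(n0, 0.2), 5.0)
    logKd0 = np.log10(Mt0 / 100.0)

    def residuals(p):
        n_, logKd, dH_ = p[0], p[1], p[2]
        off = p[3] if fit_offset else 0.0
        model = itc_injection_heats(Xr, n_, 10.0**logKd, dH_, Mt0, V0, off)
        return model - q

    p0 = [n0, logKd0, dH0] + ([0.0] if fit_offset else [])
    lower = [0.05, np.log10(Mt0) - 8.0, -1e4] + ([-np.inf] if fit_offset else [])
    upper = [10.0, np.log10(Mt0) + 4.0, 1e4] + ([np.inf] if fit_offset else [])
    result = least_squares(residuals, p0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14)
    if not result.success:
        raise FitError(f"ITC fit did not converge; last iterate {result.x}")
    n_, Kd_, dH_ = result.x[0], 10.0 ** result.x[1], result.x[2]
    off = result.x[3] if fit_offset else 0.0
    c = Mt0 / Kd_
    if not 1.0 <= c <= 5000.0:
        warnings.warn(
            f"c-value {c:.3g} outside a well-conditioned range; "
            "Kd is weakly constrained",
            FitQualityWarning,
            stacklevel=2,
        )
    return ITCFit(float(n_), float(Kd_), float(dH_), float(off), float(np.linalg.norm(result.fun)))


# ---------------------------------------------------------------------------
# Four-parameter logistic IC50


def logistic_4pl(conc, top: float, bottom: float, ic50: float, hill: float):
    """4PL response: bottom + (top − bottom)/(1 + (x/IC50)^hill).

    With hill > 0 this is a decreasing (inhibition) curve.
    """
    x = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


@dataclass
class DoseResponseFit:
    """4PL competition-curve parameters and the relative IC50."""

    ic50: float  # molar
    hill: float
    top: float
    bottom: float
    r_ic50: float = np.nan
    residual_norm: float = np.nan


def fit_ic50(
    conc: np.ndarray,
    response: np.ndarray,
    reference_ic50: float | None = None,
) -> DoseResponseFit:
    """Fit a four-parameter logistic to a competition dose–response table.

    Replicate wells (repeated concentrations) are averaged before
    fitting. ``reference_ic50`` sets the denominator-free convention
    rIC50 = IC50 / IC50(reference); a compound fitted against its own
    IC50 gives rIC50 = 1.
    """
    df = pd.DataFrame({"conc": np.asarray(conc, float), "resp": np.asarray(response, float)})
    if np.any(df["conc"] <= 0):
        raise TyrgateError("concentrations must be positive")
    mean = df.groupby("conc", sort=True)["resp"].mean()
    x = mean.index.to_numpy()
    y = mean.to_numpy()
    if x.size < 5:
        raise FitError("need at least 5 distinct concentrations spanning the inflection")
    span = np.ptp(y)
    if span < 0.02 * max(np.max(np.abs(y)), 1e-12):
        raise FitError("no inhibition: response is constant across concentrations")
    rho = np.corrcoef(np.log(x), y)[0, 1]
    if rho > 0.3:
        warnings.warn(
            "response increases with concentration; not an inhibition curve?",
            FitQualityWarning,
            stacklevel=2,
        )

    top0, bottom0 = float(y.max()), float(y.min())
    half = (top0 + bottom0) / 2.0
    ic50_0 = float(x[np.argmin(np.abs(y - half))])

    def residuals(p):
        top, bottom, logic50, hill = p
        return logistic_4pl(x, top, bottom, 10.0**logic50, hill) - y

    result = least_squares(
        residuals,
        [top0, bottom0, np.log10(ic50_0), 1.0],
        bounds=([-np.inf, -np.inf, np.log10(x.min()) - 4, 0.05],
                [np.inf, np.inf, np.log10(x.max()) + 4, 20.0]),
        xtol=1e-14, ftol=1e-14,
    )
    if not result.success:
        raise FitError(f"IC50 fit did not converge; last iterate {result.x}")
    top, bottom, ic50, hill = result.x[0], result.x[1], 10.0 ** result.x[2], result.x[3]
    if not bottom < top:
        raise FitError("fitted bottom plateau is not below the top plateau")
    r = ic50 / reference_ic50 if reference_ic50 else np.nan
    return DoseResponseFit(
        float(ic50), float(hill), float(top), float(bottom), float(r),
        float(np.linalg.norm(result.fun)),
    )


# ---------------------------------------------------------------------------
# Two-state unfolding, linear extrapolation method


def lem_signal(
    D, dG_fold: float, m: float, a_n: float, b_n: float, a_u: float, b_u: float,
    T: float = T_DEFAULT,
):
    """Observed two-state unfolding signal at denaturant concentration D.

    The native and unfolded baselines are linear in D; the unfolded
    fraction follows ΔG_unf(D) = −ΔG_fold − m·D (linear extrapolation),
    f_U = exp(−ΔG_unf/RT) / (1 + exp(−ΔG_unf/RT)).
    """
    D = np.asarray(D, dtype=float)
    dG_unf = -dG_fold - m * D  # kJ/mol, positive below the midpoint
    K = np.exp(-1000.0 * dG_unf / (R_GAS * T))
    f_u = K / (1.0 + K)
    return (1.0 - f_u) * (a_n + b_n * D) + f_u * (a_u + b_u * D)


def unfolded_fraction(D, dG_fold: float, m: float, T: float = T_DEFAULT):
    """Normalised (0–1) unfolding curve implied by (ΔG_fold, m)."""
    D = np.asarray(D, dtype=float)
    K = np.exp(-1000.0 * (-dG_fold - m * D) / (R_GAS * T))
    return K / (1.0 + K)


@dataclass
class UnfoldingFit:
    """Two-state LEM fit: folding free energy, m-value and midpoint.

    ``dG_fold`` uses the folding convention (negative for a stable
    protein); ``m`` is the cooperativity slope (kJ·mol⁻¹·M⁻¹) and
    ``D_half = |dG_fold|/m`` the transition midpoint (M), an identity
    that holds exactly for every successful fit.
    """

    dG_fold: float
    m: float
    D_half: float
    baselines: dict
    normalized: np.ndarray
    residual_norm: float
    T: float = T_DEFAULT


def fit_unfolding_lem(
    denaturant: np.ndarray, signal: np.ndarray, T: float = T_DEFAULT
) -> UnfoldingFit:
    """Fit a denaturant–signal curve with the two-state LEM model.

    The curve must span both baselines and the transition; sparse
    baseline coverage triggers a :class:`FitQualityWarning`. Returns the
    folding free energy (negative), the m-value, D½ and the normalised
    unfolded-fraction curve on the input grid.
    """
    D = np.asarray(denaturant, dtype=float)
    y = np.asarray(signal, dtype=float)
    if D.size != y.size or D.size < 8:
        raise FitError("need at least 8 (denaturant, signal) points")
    order = np.argsort(D)
    D, y = D[order], y[order]

    k = max(3, D.size // 6)
    a_n0, b_n0 = _line_fit(D[:k], y[:k])
    a_u0, b_u0 = _line_fit(D[-k:], y[-k:])
    yn = a_n0 + b_n0 * D
    yu = a_u0 + b_u0 * D
    denom = yn - yu
    if np.max(np.abs(denom)) < 1e-12:
        raise FitError("baselines coincide: no unfolding transition")
    fu_emp = np.clip((yn - y) / np.where(np.abs(denom) < 1e-12, np.nan, denom), 1e-6, 1 - 1e-6)
    mid = (fu_emp > 0.05) & (fu_emp < 0.95)
    if mid.sum() < 2:
        warnings.warn(
            "transition region barely sampled; LEM fit may be ill-conditioned",
            FitQualityWarning,
            stacklevel=2,
        )
        mid = np.ones_like(fu_emp, dtype=bool)
    logit = np.log(fu_emp[mid] / (1 - fu_emp[mid]))
    # logit(f_U) = (dG_fold + m D)/RT in our convention
    slope, intercept = np.polyfit(D[mid], logit, 1)
    RT = R_GAS * T / 1000.0
    m0 = max(slope * RT, 1e-3)
    dG0 = min(intercept * RT, -1e-3)

    def residuals(p):
        return lem_signal(D, p[0], p[1], p[2], p[3], p[4], p[5], T) - y

    result = least_squares(
        residuals,
        [dG0, m0, a_n0, b_n0, a_u0, b_u0],
        bounds=([-1e4, 1e-6] + [-np.inf] * 4, [0.0, 1e4] + [np.inf] * 4),
        xtol=1e-14, ftol=1e-14,
    )
    if not result.success:
        raise FitError(f"LEM fit did not converge; last iterate {result.x}")
    dG_fold, m = float(result.x[0]), float(result.x[1])
    baselines = {
        "native": (float(result.x[2]), float(result.x[3])),
        "unfolded": (float(result.x[4]), float(result.x[5])),
    }
    return UnfoldingFit(
        dG_fold=dG_fold,
        m=m,
        D_half=abs(dG_fold) / m,
        baselines=baselines,
        normalized=unfolded_fraction(D, dG_fold, m, T),
        residual_norm=float(np.linalg.norm(result.fun)),
        T=T,
    )


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


# ---------------------------------------------------------------------------
# Report tables


def binding_report(
    table: pd.DataFrame,
    T: float = T_DEFAULT,
    reference_variant: str = "WT",
) -> pd.DataFrame:
    """Derive ΔG, TΔS and rKd columns from a (ligand, variant, n, Kd, dH) table.

    ``table`` needs columns ``ligand``, ``variant``, ``n``, ``Kd_nM``
    and ``dH_kJ_mol``. rKd is computed against each ligand's
    ``reference_variant`` row (the per-ligand wild-type convention).
    Full-precision columns are accompanied by 1-d.p. report columns
    (rounded half away from zero).
    """
    required = {"ligand", "variant", "n", "Kd_nM", "dH_kJ_mol"}
    missing = required - set(table.columns)
    if missing:
        raise TyrgateError(f"binding table missing columns: {sorted(missing)}")
    out = table.copy()
    bad = ~(out["Kd_nM"] > 0)
    if bad.any():
        raise TyrgateError(
            f"non-positive Kd in rows {list(out.index[bad])}"
        )
    Kd_M = out["Kd_nM"] * 1e-9
    out["dG_kJ_mol"] = [dG_from_Kd(kd, T) for kd in Kd_M]
    out["TdS_kJ_mol"] = out["dH_kJ_mol"] - out["dG_kJ_mol"]
    ref = out[out["variant"] == reference_variant].set_index("ligand")["Kd_nM"]
    out["rKd"] = [
        relative_Kd(row.Kd_nM, ref[row.ligand]) if row.ligand in ref.index else np.nan
        for row in out.itertuples()
    ]
    for col in ("dG_kJ_mol", "TdS_kJ_mol", "rKd"):
        out[col + "_1dp"] = out[col].map(lambda v: round_half_away(v, 1))
    return out


def load_reference_binding_table() -> pd.DataFrame:
    """ITC binding parameters (n, Kd, ΔH) of AM/HM/BF against WT, Y48A
    and Y137A FimH, with the published derived cells as ``*_printed``
    reference columns."""
    from importlib.resources import files

    with files("tyrgate.data").joinpath("fimh_mannoside_itc.csv").open() as fh:
        return pd.read_csv(fh)


def load_reference_unfolding_params() -> pd.DataFrame:
    """Two-state LEM folding parameters (ΔG_fold, m) of WT/Y48A/Y137A
    FimH from GdmCl unfolding, with published midpoints."""
    from importlib.resources import files

    with files("tyrgate.data").joinpath("fimh_unfolding_params.csv").open() as fh:
        return pd.read_csv(fh)
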