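"""Endocast-to-brain conversion and Manger encephalization quotients.

Proboscidean endocasts overestimate brain volume because unusually thick
meninges line the endocranial cavity.  Brain mass is therefore obtained as

    M = V * (1 - m(V)) * rho

where ``m(V)`` is the meningeal fraction and ``rho`` = 1.036 g/cm3 is the
average specific gravity of brain tissue.  Outgroup taxa (the sirenian and
hyracoid comparators) receive no meningeal correction: M = V * rho.

The encephalization quotient follows Manger's reference allometry,

    EQ = M_brain / (a * M_body**b),

with constants recovered by log-log least squares from the packaged trait
table (the reference publication's constants are accepted as an override).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treedata import SpecimenTable

log = logging.getLogger(__name__)

__all__ = [
    "RHO_BRAIN",
    "BrainConversionParams",
    "EQParams",
    "DEFAULT_CONVERSION",
    "DEFAULT_EQ",
    "endocast_to_brain_mass",
    "fit_meningeal_params",
    "manger_eq",
    "fit_eq_params",
    "compute_eq_table",
]

#: average specific gravity of brain tissue, g/cm3
RHO_BRAIN = 1.036


@dataclass(frozen=True)
class BrainConversionParams:
    """Meningeal correction and tissue density.

    ``mode="constant"`` uses a fixed fraction ``fraction``; ``mode="allometric"``
    uses m(V) = coeff * V**exponent, capturing the mild decrease of the
    fraction with endocast size seen between the smallest and largest taxa.
    """

    fraction: float | None = None
    coeff: float | None = None
    exponent: float | None = None
    rho: float = RHO_BRAIN
    mode: str = "allometric"
    residual_sd: float | None = None  # spread of log fraction residuals from the fit

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.mode not in ("constant", "allometric"):
            raise ValueError("mode must be 'constant' or 'allometric'")
        if self.mode == "constant" and self.fraction is None:
            raise ValueError("constant mode requires a fraction")
        if self.mode == "allometric" and (self.coeff is None or self.exponent is None):
            raise ValueError("allometric mode requires coeff and exponent")
        if self.fraction is not None and not (0.0 <= self.fraction < 1.0):
            raise ValueError("meningeal fraction must lie in [0, 1)")

    def meningeal_fraction(self, volume_cm3: float | np.ndarray) -> float | np.ndarray:
        v = np.asarray(volume_cm3, dtype=float)
        if self.mode == "constant":
            m = np.full_like(v, self.fraction, dtype=float)
        else:
            m = self.coeff * v ** self.exponent
        if np.any((m < 0) | (m >= 1)):
            raise ValueError("meningeal fraction left [0, 1) over the requested volumes")
        return m if m.ndim else float(m)


@dataclass(frozen=True)
class EQParams:
    """Reference allometry M_expected = a * M_body**b (masses in g)."""

    a: float
    b: float
    residual_sd: float | None = None

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("coefficient a must be > 0")
        if not (0.0 < self.b < 1.0):
            raise ValueError("exponent b must lie in (0, 1)")


def endocast_to_brain_mass(
    volume_cm3: float | np.ndarray,
    group: str = "proboscidean",
    params: BrainConversionParams | None = None,
) -> float | np.ndarray:
    """Convert endocast volume (cm3) to brain mass (g)."""
    params = params or DEFAULT_CONVERSION
    v = np.asarray(volume_cm3, dtype=float)
    if np.any(v <= 0):
        raise ValueError("endocast volume must be > 0")
    if group == "outgroup":
        out = v * params.rho
    else:
        out = v * (1.0 - params.meningeal_fraction(v)) * params.rho
    return out if out.ndim else float(out)


def fit_meningeal_params(table: SpecimenTable, rho: float = RHO_BRAIN) -> BrainConversionParams:
    """Recover the meningeal correction from printed (volume, mass) pairs.

    Uses proboscidean rows carrying both columns.  The per-row implied
    fraction is m_i = 1 - M_i/(V_i*rho); the constant mode stores its mean,
    the allometric mode fits log m = log(coeff) + exponent*log V.
    """
    df = table.df
    use = (df["group"] == "proboscidean") & df["endocast_cm3"].notna() & df["brain_g"].notna()
    if use.sum() < 2:
        raise ValueError("need at least 2 proboscidean rows with endocast volume and brain mass")
    v = df.loc[use, "endocast_cm3"].to_numpy(float)
    m_frac = 1.0 - df.loc[use, "brain_g"].to_numpy(float) / (v * rho)
    if np.any(m_frac <= 0) or np.any(m_frac >= 1):
        raise ValueError("implied meningeal fraction outside (0, 1); check units")
    X = np.column_stack([np.ones_like(v), np.log(v)])
    coefs, *_ = np.linalg.lstsq(X, np.log(m_frac), rcond=None)
    resid = np.log(m_frac) - X @ coefs
    return BrainConversionParams(
        fraction=float(np.mean(m_frac)),
        coeff=float(np.exp(coefs[0])),
        exponent=float(coefs[1]),
        rho=rho,
        mode="allometric",
        residual_sd=float(np.std(resid, ddof=2)) if len(v) > 2 else 0.0,
    )


def manger_eq(brain_g: float | np.ndarray, body_g: float | np.ndarray, params: EQParams | None = None) -> float | np.ndarray:
    """EQ = observed brain mass over the mass expected from body mass."""
    params = params or DEFAULT_EQ
    mbr = np.asarray(brain_g, dtype=float)
    mbd = np.asarray(body_g, dtype=float)
    if np.any(mbr <= 0) or np.any(mbd <= 0):
        raise ValueError("brain and body mass must be > 0")
    out = mbr / (params.a * mbd ** params.b)
    return out if out.ndim else float(out)


def fit_eq_params(table: SpecimenTable, include_outgroups: bool = False) -> EQParams:
    """Recover (a, b) of the reference allometry from printed EQ triples.

    Least squares of log(M_brain/EQ) on log(M_body) over every row carrying
    brain mass, body mass and EQ.  Outgroup rows are excluded by default:
    their printed brain masses are tiny integers (5 g), so printing
    resolution alone perturbs the recovered constants visibly.
    """
    df = table.df
    use = df["brain_g"].notna() & df["body_g"].notna() & df["eq"].notna()
    if not include_outgroups:
        use &= df["group"] == "proboscidean"
    if use.sum() < 3:
        raise ValueError("need at least 3 rows with brain mass, body mass and EQ")
    mbr = df.loc[use, "brain_g"].to_numpy(float)
    mbd = df.loc[use, "body_g"].to_numpy(float)
    eq = df.loc[use, "eq"].to_numpy(float)
    y = np.log(mbr / eq)
    X = np.column_stack([np.ones_like(y), np.log(mbd)])
    coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coefs
    return EQParams(
        a=float(np.exp(coefs[0])),
        b=float(coefs[1]),
        residual_sd=float(np.std(resid, ddof=2)) if use.sum() > 2 else 0.0,
    )


def compute_eq_table(
    table: SpecimenTable,
    conv: BrainConversionParams | None = None,
    eqp: EQParams | None = None,
) -> SpecimenTable:
    """Fill recomputed brain-mass and EQ columns for every row.

    ``brain_g_recomputed`` is the endocast conversion where a volume exists
    (NaN otherwise); the EQ uses the printed brain mass when present, else the
    conversion, so rows that already carry a mass skip the conversion step.
    Printed columns are retained untouched for comparison.  Idempotent.
    """
    conv = conv or DEFAULT_CONVERSION
    eqp = eqp or DEFAULT_EQ
    df = table.df.copy()
    if df.empty:
        for col in ("brain_g_recomputed", "eq_recomputed"):
            df[col] = pd.Series(dtype=float)
        return SpecimenTable(df)
    rec = np.full(len(df), np.nan)
    for i, row in df.reset_index(drop=True).iterrows():
        if pd.notna(row["endocast_cm3"]):
            rec[i] = endocast_to_brain_mass(row["endocast_cm3"], row["group"], conv)
    df["brain_g_recomputed"] = rec
    used = df["brain_g"].to_numpy(float)
    used = np.where(np.isnan(used), rec, used)
    if np.any(np.isnan(used)):
        raise ValueError("rows with neither brain mass nor endocast volume")
    df["eq_recomputed"] = manger_eq(used, df["body_g"].to_numpy(float), eqp)
    return SpecimenTable(df)


# Defaults frozen from the packaged trait table via the two fit procedures
# (see docs/methods.md); regenerate with fit_meningeal_params / fit_eq_params.
DEFAULT_CONVERSION = BrainConversionParams(
    fraction=0.11344537860959306,
    coeff=0.13662987227647377,
    exponent=-0.022445002641201847,
    mode="allometric",
    residual_sd=0.006910863592900927,
)
DEFAULT_EQ = EQParams(
    a=0.05395292335321567,
    b=0.728169893702835,
    residual_sd=0.0037360560321161736,
)
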