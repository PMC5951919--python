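"""Hill-equation modelling of binding titrations.

Used for RNase-protection titrations of fluorophore-labelled aminoacyl-
tRNA against EF-Tu:GTP: the protected fraction follows
f(c) = plateau * c^n / (Kd^n + c^n), with the Hill coefficient fixed at
n = 1 for non-cooperative binding.  The plateau is free by default
because filter-based protection assays rarely reach 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

__all__ = ["HillFit", "hill_fraction", "fit_hill", "validate_titration"]


@dataclass
class HillFit:
    kd_nM: float
    n: float
    plateau: float
    kd_se: float
    plateau_se: float
    residual_norm: float
    poor_fit: bool = False


def hill_fraction(c, kd, n: float = 1.0, plateau: float = 1.0):
    """Hill binding curve f = plateau * c^n / (kd^n + c^n).

    Monotone increasing in c; f = plateau/2 at c = kd for any n.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0) or kd <= 0 or n <= 0 or plateau <= 0:
        raise ValueError("concentrations, kd, n and plateau must be > 0")
    cn = c**n
    out = plateau * cn / (kd**n + cn)
    return float(out) if out.ndim == 0 else out


def validate_titration(table: pd.DataFrame) -> pd.DataFrame:
    """Check a titration table (conc_nM, fraction) for fitting."""
    if not {"conc_nM", "fraction"}.issubset(table.columns):
        raise ValueError("titration table needs columns conc_nM, fraction")
    if len(table) < 4:
        raise ValueError("need >= 4 titration points")
    c = table["conc_nM"].to_numpy(dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    return table.sort_values("conc_nM").reset_index(drop=True)


def fit_hill(
    table: pd.DataFrame,
    n_fixed: float = 1.0,
    plateau_free: bool = True,
    n_bootstrap: int = 200,
    seed: int | None = None,
) -> HillFit:
    """Least-squares Hill fit with fixed Hill coefficient.

    Fits Kd (and the plateau unless ``plateau_free`` is False) on the
    linear concentration scale.  Grossly non-monotone data is fitted
    anyway but flagged ``poor_fit``.  Standard errors are a seeded
    bootstrap over titration points.
    """
    table = validate_titration(table)
    c = table["conc_nM"].to_numpy(dtype=float)
    f = table["fraction"].to_numpy(dtype=float)

    rho = spearmanr(c, f).statistic
    poor = bool(np.isnan(rho) or rho < 0.5)

    def _fit_once(cc, ff):
        if plateau_free:
            def model(x, kd, plateau):
                return plateau * x**n_fixed / (kd**n_fixed + x**n_fixed)
            p0 = [float(np.median(cc)), float(max(ff.max(), 0.1))]
            popt, _ = curve_fit(
                model, cc, ff, p0=p0, bounds=([1e-6, 1e-3], [np.inf, 1.5]), maxfev=20000
            )
            return float(popt[0]), float(popt[1])
        def model1(x, kd):
            return x**n_fixed / (kd**n_fixed + x**n_fixed)
        p0 = [float(np.median(cc))]
        popt, _ = curve_fit(model1, cc, ff, p0=p0, bounds=(1e-6, np.inf), maxfev=20000)
        return float(popt[0]), 1.0

    kd, plateau = _fit_once(c, f)
    resid = f - hill_fraction(c, kd, n_fixed, plateau)
    residual_norm = float(np.linalg.norm(resid))

    kd_se = plateau_se = 0.0
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        kds, plats = [], []
        for _ in range(n_bootstrap):
            idx = rng.choice(len(c), size=len(c), replace=True)
            if len(np.unique(c[idx])) < 3:
                continue
            try:
                kb, pb = _fit_once(c[idx], f[idx])
            except RuntimeError:
                continue
            kds.append(kb)
            plats.append(pb)
        if kds:
            kd_se = float(np.std(kds))
            plateau_se = float(np.std(plats))

    return HillFit(
        kd_nM=kd,
        n=n_fixed,
        plateau=plateau,
        kd_se=kd_se,
        plateau_se=plateau_se,
        residual_norm=residual_norm,
        poor_fit=poor,
    )
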