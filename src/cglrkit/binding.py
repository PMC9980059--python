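"""Single-site binding isotherm fits for EMSA titrations.

STING-ligand affinity is quantified from electrophoretic mobility shift
assays: fraction bound (shifted/total probe signal) is measured across a
protein titration and fit to the single-site isotherm

    f(c) = c / (c + Kd),

the trace-ligand approximation appropriate when the labeled cyclic
dinucleotide probe (tens of nM) is far below the protein range (up to tens
of uM), so free protein equals total protein. No Hill coefficient and no
depletion correction are applied.

Kd is found by deterministic least squares on log10(Kd): a coarse grid over
[min conc / 100, max conc x 100] followed by bounded scalar refinement.
The log parameterization enforces positivity and makes the fit equivariant
under rescaling of the concentration axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar


@dataclass
class BindingCurve:
    """One titration: protein concentrations (M) vs fraction bound."""

    ligand_id: str
    protein_concentrations: np.ndarray
    fraction_bound: np.ndarray
    replicate_id: str = "0"
    clipped: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.protein_concentrations, dtype=float)
        f = np.asarray(self.fraction_bound, dtype=float)
        if c.shape != f.shape or c.ndim != 1:
            raise ValueError("concentrations and fractions must be equal-length 1-D")
        if not np.all(c > 0):
            raise ValueError("concentrations must be strictly positive")
        if not np.all(np.diff(c) > 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(f < 0) or np.any(f > 1):
            f = np.clip(f, 0.0, 1.0)
            self.clipped = True
        self.protein_concentrations = c
        self.fraction_bound = f


@dataclass
class IsothermFit:
    Kd: float | None
    residual_sum_squares: float | None
    converged: bool
    n_points: int
    diagnostic: str | None = None


def fraction_bound(concentration: float, Kd: float) -> float:
    """Equilibrium fraction bound c/(c+Kd) of a trace ligand."""
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = c / (c + Kd)
    return float(out) if out.ndim == 0 else out


def fit_isotherm(curve: BindingCurve, grid_points: int = 400) -> IsothermFit:
    """Least-squares Kd for one titration (deterministic).

    Degenerate curves (all fractions identical, e.g. no binding over the
    tested range) return ``converged=False`` with a diagnostic rather than
    raising.
    """
    c = curve.protein_concentrations
    f = curve.fraction_bound
    n = len(c)
    if n < 3:
        raise ValueError("need at least 3 titration points")
    if np.allclose(f, f[0]):
        if np.allclose(f, 0.0):
            diag = "no binding detected (all fractions zero)"
        elif np.allclose(f, 1.0):
            diag = "saturated at every concentration (Kd below tested range)"
        else:
            diag = "flat titration; Kd not identifiable"
        return IsothermFit(None, None, False, n, diag)

    def sse(log_kd: float) -> float:
        kd = 10.0 ** log_kd
        r = f - c / (c + kd)
        return float(r @ r)

    lo = np.log10(c.min()) - 2.0
    hi = np.log10(c.max()) + 2.0
    grid = np.linspace(lo, hi, grid_points)
    values = np.array([sse(x) for x in grid])
    i = int(values.argmin())
    left = grid[max(i - 1, 0)]
    right = grid[min(i + 1, grid_points - 1)]
    res = minimize_scalar(
        sse, bounds=(left, right), method="bounded",
        options={"xatol": 1e-12, "maxiter": 500},
    )
    kd = float(10.0 ** res.x)
    return IsothermFit(
        Kd=kd,
        residual_sum_squares=float(res.fun),
        converged=True,
        n_points=n,
    )


def fit_table(df) -> "pandas.DataFrame":  # noqa: F821 - annotation only
    """Fit every ligand x replicate in a tidy table, plus a pooled fit.

    Expects columns ligand_id, replicate_id, concentration_M, fraction_bound.
    """
    import pandas as pd

    rows = []

    def one(ligand, replicate, sub):
        sub = sub.sort_values("concentration_M")
        curve = BindingCurve(
            ligand_id=str(ligand),
            protein_concentrations=sub["concentration_M"].to_numpy(),
            fraction_bound=sub["fraction_bound"].to_numpy(),
            replicate_id=str(replicate),
        )
        fit = fit_isotherm(curve)
        rows.append(
            {
                "ligand_id": ligand,
                "replicate_id": replicate,
                "Kd_M": fit.Kd,
                "rss": fit.residual_sum_squares,
                "converged": fit.converged,
                "n_points": fit.n_points,
                "diagnostic": fit.diagnostic or "",
            }
        )

    for (ligand, replicate), sub in df.groupby(["ligand_id", "replicate_id"]):
        one(ligand, replicate, sub)
    for ligand, sub in df.groupby("ligand_id"):
        pooled = (
            sub.groupby("concentration_M", as_index=False)["fraction_bound"].mean()
        )
        if len(pooled) >= 3:
            one(ligand, "pooled", pooled)
    return pd.DataFrame(rows)
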