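"""Calibration of the per-gene phenotype models from polarisation data.

Bone-marrow-derived macrophages polarised in vitro at pH 7.4 or 6.8 under
inflammatory (e = -1) or anti-inflammatory (e = +1) stimulation yield, for
each marker gene, expression observations on the design {7.4, 6.8} x
{-1, +1}.  An ordinary least-squares fit on the basis (1, p, e, p*e) gives
the coefficients (alpha, beta, gamma, delta) used by the macrophage agents.

Raw qPCR readouts are converted to fold change relative to a housekeeping
reference via FC = 2**(-(Ct_target - Ct_reference)); fitting is done on the
fold-change scale (a log-scale option exists behind a flag).

Because the underlying raw expression tables are experiment-specific, the
module also ships a synthetic-expression generator whose default true
coefficients reproduce the qualitative polarisation pattern: the
anti-tumour marker (Ccl2) falls and the pro-tumour marker (Arg1) rises
under acidosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FittingError, ParameterError
from .macrophage import ANTI_TUMOUR, PRO_TUMOUR, PhenotypeModel, TraitModel

#: the 2x2 polarisation design used in vitro: pH {7.4, 6.8} x stimulus {-1, +1}
DEFAULT_DESIGN = [(7.4, -1.0), (7.4, 1.0), (6.8, -1.0), (6.8, 1.0)]

_BASIS_NAMES = ("intercept", "pH", "e", "pH*e")

#: expression (fold change) at the four design corners for the default pair
#: of marker genes; chosen so acidosis suppresses the inflammatory marker
#: and amplifies the alternative-activation marker.
DEFAULT_TRAIT_CORNERS = {
    # trait: (polarity, {(pH, e): value})
    "Ccl2": (ANTI_TUMOUR, {(7.4, -1.0): 10.0, (7.4, 1.0): 2.0,
                           (6.8, -1.0): 4.0, (6.8, 1.0): 1.0}),
    "Arg1": (PRO_TUMOUR, {(7.4, -1.0): 1.0, (7.4, 1.0): 8.0,
                          (6.8, -1.0): 3.0, (6.8, 1.0): 16.0}),
}

OBS_COLUMNS = ["trait", "pH", "e_code", "value", "replicate"]


@dataclass
class TraitFit:
    """OLS result for one trait on the basis (1, p, e, p*e)."""

    trait: str
    alpha: float
    beta: float
    gamma: float
    delta: float
    rss: float
    std_errors: dict
    n_obs: int

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.delta])


def ct_to_foldchange(ct_target, ct_reference):
    """Fold change FC = 2**(-dCt) with dCt = Ct_target - Ct_reference."""
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(ct_target)) and np.all(np.isfinite(ct_reference))):
        raise ParameterError("Ct values must be finite")
    out = 2.0 ** (-(ct_target - ct_reference))
    return float(out) if out.ndim == 0 else out


def design_matrix(ph, e):
    """Basis (1, p, e, p*e) evaluated at paired pH / ecology values."""
    ph = np.asarray(ph, dtype=float)
    e = np.asarray(e, dtype=float)
    return np.column_stack([np.ones_like(ph), ph, e, ph * e])


def fit_trait_model(observations: pd.DataFrame, log_scale: bool = False) -> TraitFit:
    """Ordinary least squares for one trait's linear model.

    ``observations`` must hold one trait and the columns pH, e_code, value.
    With exactly the four 2x2 design corners observed once each the fit
    interpolates the data exactly (4 equations, 4 unknowns).  A singular
    design raises :class:`FittingError` naming the unidentifiable basis
    direction(s).
    """
    traits = observations["trait"].unique() if "trait" in observations else ["?"]
    if len(traits) != 1:
        raise ParameterError(f"fit_trait_model expects a single trait, got {list(traits)}")
    y = observations["value"].to_numpy(dtype=float)
    if log_scale:
        if np.any(y <= 0):
            raise ParameterError("log-scale fitting requires strictly positive values")
        y = np.log(y)
    X = design_matrix(observations["pH"], observations["e_code"])
    n = len(y)
    if n < 4:
        raise FittingError(f"trait {traits[0]!r}: need >= 4 observations, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < 4:
        # name the basis directions lost to the deficient design
        _, s, vt = np.linalg.svd(X)
        null = vt[rank:]
        deficient = sorted({
            _BASIS_NAMES[j]
            for row in null
            for j in np.nonzero(np.abs(row) > 1e-8)[0]
        })
        raise FittingError(
            f"trait {traits[0]!r}: singular design; "
            f"unidentifiable basis direction(s): {', '.join(deficient)}"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    dof = n - 4
    sigma2 = rss / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return TraitFit(
        trait=str(traits[0]),
        alpha=float(coef[0]), beta=float(coef[1]),
        gamma=float(coef[2]), delta=float(coef[3]),
        rss=rss,
        std_errors=dict(zip(("alpha", "beta", "gamma", "delta"), se)),
        n_obs=n,
    )


def fit_all_traits(observations: pd.DataFrame, log_scale: bool = False) -> dict:
    """Fit every trait present in a long-format observation table."""
    return {
        trait: fit_trait_model(sub, log_scale=log_scale)
        for trait, sub in observations.groupby("trait", sort=True)
    }


def _coeffs_from_corners(corners: dict) -> np.ndarray:
    pts = list(corners)
    X = design_matrix([p for p, _ in pts], [e for _, e in pts])
    return np.linalg.solve(X, np.array([corners[k] for k in pts], dtype=float))


def default_true_model() -> PhenotypeModel:
    """The default generating truth: Ccl2 (anti-tumour) and Arg1 (pro-tumour).

    Coefficients are defined through expression values at the four
    polarisation corners, so that acidosis (pH 6.8) lowers Ccl2 and raises
    Arg1 at matched stimulation.  Reference ranges for behaviour
    normalisation span the corner values.
    """
    traits = []
    for name, (polarity, corners) in DEFAULT_TRAIT_CORNERS.items():
        a, b, c, d = _coeffs_from_corners(corners)
        vals = list(corners.values())
        traits.append(TraitModel(
            name=name, polarity=polarity,
            alpha=float(a), beta=float(b), gamma=float(c), delta=float(d),
            ref_min=float(min(vals)), ref_max=float(max(vals)),
        ))
    return PhenotypeModel(traits)


def build_phenotype_model(
    fits: dict,
    polarities: dict,
    design: list | None = None,
) -> PhenotypeModel:
    """Assemble a :class:`PhenotypeModel` from per-trait fits.

    Reference ranges (used to normalise expression into behaviour) span the
    fitted predictions over the calibration design corners.
    """
    design = design or DEFAULT_DESIGN
    traits = []
    for name, fit in fits.items():
        if name not in polarities:
            raise ParameterError(f"no polarity given for trait {name!r}")
        X = design_matrix([p for p, _ in design], [e for _, e in design])
        preds = X @ fit.coefficients
        lo, hi = float(preds.min()), float(preds.max())
        if hi <= lo:
            hi = lo + 1.0
        traits.append(TraitModel(
            name=name, polarity=polarities[name],
            alpha=fit.alpha, beta=fit.beta, gamma=fit.gamma, delta=fit.delta,
            ref_min=lo, ref_max=hi,
        ))
    return PhenotypeModel(traits)


def generate_synthetic_expression(
    true_model: PhenotypeModel,
    design: list | None = None,
    replicates: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic long-format expression table from known true coefficients.

    ``noise_sd`` is the Gaussian noise standard deviation expressed as a
    fraction of each trait's mean predicted expression over the design
    (so 0.1 means sigma = 10% of the mean); values are truncated at zero.
    Deterministic for a fixed seed.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    design = design or DEFAULT_DESIGN
    rng = np.random.default_rng(seed)
    rows = []
    for name in true_model.trait_names():
        t = true_model.traits[name]
        preds = np.array([t.predict(p, e) for p, e in design])
        sigma = noise_sd * float(np.mean(np.abs(preds)))
        for rep in range(replicates):
            for (p, e), mu in zip(design, preds):
                val = mu + (sigma * rng.standard_normal() if sigma > 0 else 0.0)
                rows.append([name, p, e, max(0.0, val), rep])
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def prediction_heatmap(
    model: PhenotypeModel,
    trait: str,
    ph_grid: np.ndarray,
    e_grid: np.ndarray,
) -> np.ndarray:
    """Matrix of predicted expression over the Cartesian (pH x e) grid.

    Rows index ``ph_grid``, columns ``e_grid``; entry (i, j) equals
    ``trait_expression`` at ``(ph_grid[i], e_grid[j])``.
    """
    if trait not in model.traits:
        raise KeyError(f"unknown trait {trait!r}")
    t = model.traits[trait]
    P, E = np.meshgrid(np.asarray(ph_grid, float), np.asarray(e_grid, float), indexing="ij")
    return t.alpha + t.beta * P + t.gamma * E + t.delta * P * E
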