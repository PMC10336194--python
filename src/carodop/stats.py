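"""Hierarchical TAV ~ MAP analysis.

Fits a two-level linear mixed model of time-averaged velocity on mean
arterial pressure (polynomial up to degree 2) with animal and
sequence-within-animal random intercepts, optionally adding per-animal random
slopes for MAP and MAP^2.  The variance decomposition of the intercept-only
structure yields the intraclass correlations

    ICC_animal  = s2_a / (s2_a + s2_s + s2_e)
    ICC_within  = (s2_a + s2_s) / (s2_a + s2_s + s2_e)

i.e. the share of total TAV variance (at fixed MAP) attributable to animal
identity, and to animal plus sequence.  Under random slopes the ICC is not
constant in MAP, so ICCs are always computed from a companion
intercepts-only fit even when a random-slopes model is requested; the slope
variances are reported alongside.  Confidence intervals use a parametric
bootstrap because the estimator's sampling distribution with a handful of
animals is far from normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .errors import ConfigError, ConvergenceError, DataError

__all__ = ["LMMFit", "ICCResult", "fit_lmm", "compute_icc", "icc_ci",
           "predict_per_animal"]

REQUIRED_COLUMNS = ("animal", "sequence", "map_mmHg", "tav_cm_s")


@dataclass
class LMMFit:
    """Fitted mixed model: fixed polynomial and variance components.

    ``beta`` is on the raw MAP scale (intercept, mmHg^-1, mmHg^-2 terms);
    variances are cm^2/s^2.
    """

    beta: tuple[float, float, float]
    sigma2_animal: float
    sigma2_sequence: float
    sigma2_residual: float
    slope_variances: dict = field(default_factory=dict)
    loglik: float = np.nan
    converged: bool = False
    reml: bool = True
    degree: int = 2
    map_center: float = 0.0
    map_scale: float = 1.0
    random_effects: dict = field(default_factory=dict)
    map_ranges: dict = field(default_factory=dict)


@dataclass
class ICCResult:
    """Point estimates (and optional bootstrap CIs) for the two ICCs."""

    icc_animal: float
    icc_within: float
    ci_animal: tuple[float, float] | None = None
    ci_within: tuple[float, float] | None = None
    method: str = "variance-components"
    n_boot: int = 0
    boot_failures: int = 0
    warning: str | None = None


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"study table missing columns {missing}")
    if not np.isfinite(table[["map_mmHg", "tav_cm_s"]].to_numpy()).all():
        raise DataError("MAP/TAV must be finite")
    # strict nesting: a sequence label may not span animals
    span = table.groupby("sequence")["animal"].nunique()
    if (span > 1).any():
        raise DataError("sequence labels must be nested within a single animal")
    return table


def fit_lmm(table: pd.DataFrame, degree: int = 2, random_slopes: bool = False,
            reml: bool = True) -> LMMFit:
    """Fit TAV ~ poly(MAP, degree) with nested random intercepts.

    MAP is centered and scaled internally for conditioning and the fixed
    coefficients are returned on the raw mmHg scale.  Requires at least three
    animals with two sequences each.  ``random_slopes=True`` additionally
    gives each animal random MAP and (for degree 2) MAP^2 slopes.
    """
    table = _validate_table(table)
    if degree not in (1, 2):
        raise ConfigError("degree must be 1 or 2")
    n_animals = table["animal"].nunique()
    seq_counts = table.groupby("animal")["sequence"].nunique()
    if n_animals < 3 or (seq_counts < 2).any():
        raise ConfigError("need >= 3 animals with >= 2 sequences each")

    center = float(table["map_mmHg"].mean())
    scale = float(table["map_mmHg"].std()) or 1.0
    df = table.copy()
    df["m"] = (df["map_mmHg"] - center) / scale
    df["m2"] = df["m"] ** 2
    fixed = "tav_cm_s ~ m" + (" + m2" if degree == 2 else "")
    re_formula = "1"
    if random_slopes:
        re_formula = "1 + m" + (" + m2" if degree == 2 else "")
    model = smf.mixedlm(fixed, df, groups=df["animal"], re_formula=re_formula,
                        vc_formula={"sequence": "0 + C(sequence)"})
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = model.fit(reml=reml, method=["lbfgs", "cg", "powell"])
    if not res.converged:
        grad = float(np.linalg.norm(getattr(res, "score_obs", lambda: np.nan)()
                                    if callable(getattr(res, "score_obs", None))
                                    else np.nan))
        raise ConvergenceError(f"mixed model failed to converge (|grad|={grad})")

    # back-transform the polynomial to the raw MAP scale
    fe = res.fe_params
    b0c = float(fe["Intercept"])
    b1c = float(fe["m"])
    b2c = float(fe.get("m2", 0.0))
    b2 = b2c / scale ** 2
    b1 = b1c / scale - 2.0 * b2c * center / scale ** 2
    b0 = b0c - b1c * center / scale + b2c * (center / scale) ** 2

    s2_a = float(np.asarray(res.cov_re)[0, 0])
    s2_s = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    s2_e = float(res.scale)
    slope_vars = {}
    if random_slopes:
        cov = np.asarray(res.cov_re)
        names = list(res.cov_re.index) if hasattr(res.cov_re, "index") else []
        for i, name in enumerate(names[1:], start=1):
            # back to raw MAP units
            factor = scale ** 2 if name == "m" else scale ** 4
            slope_vars[f"sigma2_slope_{name}"] = float(cov[i, i]) / factor

    re_by_group = {g: float(np.asarray(v)[0]) for g, v in res.random_effects.items()}
    ranges = {g: (float(sub["map_mmHg"].min()), float(sub["map_mmHg"].max()))
              for g, sub in table.groupby("animal")}
    return LMMFit(beta=(b0, b1, b2), sigma2_animal=s2_a, sigma2_sequence=s2_s,
                  sigma2_residual=s2_e, slope_variances=slope_vars,
                  loglik=float(res.llf), converged=bool(res.converged),
                  reml=reml, degree=degree, map_center=center, map_scale=scale,
                  random_effects=re_by_group, map_ranges=ranges)


def compute_icc(fit: LMMFit) -> ICCResult:
    """Intraclass correlations from the intercept variance decomposition.

    Scale-invariant: multiplying all variance components by a constant leaves
    both ICCs unchanged.  Returns NaN sentinels when all components are zero.
    """
    s2_a, s2_s, s2_e = fit.sigma2_animal, fit.sigma2_sequence, fit.sigma2_residual
    total = s2_a + s2_s + s2_e
    if total <= 0:
        return ICCResult(icc_animal=np.nan, icc_within=np.nan,
                         warning="all variance components are zero")
    return ICCResult(icc_animal=s2_a / total, icc_within=(s2_a + s2_s) / total)


def _simulate_from_fit(fit: LMMFit, design: pd.DataFrame,
                       rng: np.random.Generator) -> pd.DataFrame:
    b0, b1, b2 = fit.beta
    df = design.copy()
    animals = df["animal"].unique()
    a = dict(zip(animals, rng.normal(0.0, np.sqrt(max(fit.sigma2_animal, 0.0)),
                                     size=len(animals))))
    seqs = df["sequence"].unique()
    b = dict(zip(seqs, rng.normal(0.0, np.sqrt(max(fit.sigma2_sequence, 0.0)),
                                  size=len(seqs))))
    m = df["map_mmHg"].to_numpy()
    mu = b0 + b1 * m + b2 * m ** 2
    mu = mu + df["animal"].map(a).to_numpy() + df["sequence"].map(b).to_numpy()
    df["tav_cm_s"] = mu + rng.normal(0.0, np.sqrt(max(fit.sigma2_residual, 0.0)),
                                     size=len(df))
    return df


def icc_ci(table: pd.DataFrame, fit: LMMFit, n_boot: int = 200,
           rng: np.random.Generator | int | None = None,
           level: float = 0.95) -> ICCResult:
    """Parametric-bootstrap percentile CIs for both ICCs.

    Datasets are simulated from the fitted fixed effects and variance
    components on the observed (animal, sequence, MAP) design and refit with
    the intercepts-only model.  ``n_boot=0`` returns point estimates only.
    A warning flag is set if more than 20% of refits fail.
    """
    if not fit.converged:
        raise ConvergenceError("cannot bootstrap a non-converged fit")
    point = compute_icc(fit)
    if n_boot == 0:
        return point
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    design = _validate_table(table)[["animal", "sequence", "map_mmHg"]]
    icc_a, icc_w, failures = [], [], 0
    for _ in range(n_boot):
        sim = _simulate_from_fit(fit, design, rng)
        try:
            refit = fit_lmm(sim, degree=fit.degree, random_slopes=False,
                            reml=fit.reml)
            icc = compute_icc(refit)
            icc_a.append(icc.icc_animal)
            icc_w.append(icc.icc_within)
        except (ConvergenceError, ConfigError):
            failures += 1
    if not icc_a:
        raise ConvergenceError("all bootstrap refits failed")
    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    warning = None
    if failures > 0.2 * n_boot:
        warning = f"{failures}/{n_boot} bootstrap refits failed"
    return ICCResult(
        icc_animal=point.icc_animal, icc_within=point.icc_within,
        ci_animal=(float(np.percentile(icc_a, lo)), float(np.percentile(icc_a, hi))),
        ci_within=(float(np.percentile(icc_w, lo)), float(np.percentile(icc_w, hi))),
        method="parametric-bootstrap", n_boot=n_boot, boot_failures=failures,
        warning=warning)


def predict_per_animal(fit: LMMFit, table: pd.DataFrame,
                       map_grid: Sequence[float] | None = None,
                       n_points: int = 50) -> pd.DataFrame:
    """Per-animal fitted TAV-vs-MAP curves (fixed polynomial plus the
    animal's random intercept), evaluated over each animal's observed MAP
    range.

    A user-supplied ``map_grid`` may not extend more than 10% of the observed
    span beyond the data (no silent extrapolation).
    """
    if not fit.converged:
        raise ConvergenceError("fit did not converge")
    table = _validate_table(table)
    b0, b1, b2 = fit.beta
    frames = []
    for animal, (lo, hi) in fit.map_ranges.items():
        span = hi - lo
        if map_grid is None:
            grid = np.linspace(lo, hi, n_points)
        else:
            grid = np.asarray(map_grid, dtype=float)
            if grid.min() < lo - 0.1 * span or grid.max() > hi + 0.1 * span:
                raise ConfigError(
                    f"MAP grid extrapolates beyond 10% of animal {animal}'s range")
        a = fit.random_effects.get(animal, 0.0)
        tav = b0 + a + b1 * grid + b2 * grid ** 2
        frames.append(pd.DataFrame({"animal": animal, "map_mmHg": grid,
                                    "tav_hat_cm_s": tav}))
    return pd.concat(frames, ignore_index=True)
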