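"""Design matrix, factor coding, and estimated marginal means.

The exposure model regresses minute-level calibrated PM2.5 on
microenvironment (8-level land-use factor, reference ``other``), an indoor
indicator interacting with the IDW home background concentration, season,
local hour, and participant demographics, with a per-participant random
intercept. Factors are treatment-coded against fixed reference levels, and
column names like ``landuse[residential]`` or ``indoor:idw`` are the shared
vocabulary between the fitter, the profiler, and the EMM table.

EMMs average model predictions over the levels of every other factor with
equal weights, hold the continuous background at its observed mean, and set
random effects to zero; with a single indoor-by-background interaction this
reduces to closed-form sums over coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical factor level orders; the first level is the reference.
CANONICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "landuse": (
        "other",
        "commercial",
        "industrial",
        "office",
        "park_open_space",
        "public_facilities",
        "residential",
        "vehicle",
    ),
    "season": ("spring", "summer", "autumn", "winter"),
    "hour": tuple(str(h) for h in range(24)),
    "age_group": ("0-29", "30-39", "40-49", "50-59", "60+"),
    "sex": ("female", "male"),
    "marital": ("unmarried", "married"),
    "race": ("non-white", "white"),
    "edu": ("lt_ba", "ba", "gt_ba"),
    "income": ("low", "high"),
}
DEMOGRAPHIC_FACTORS = ("age_group", "sex", "marital", "race", "edu", "income")
SPATIOTEMPORAL_FACTORS = ("landuse", "season", "hour")


class DesignError(ValueError):
    pass


@dataclass
class Design:
    X: np.ndarray
    names: list[str]
    y: np.ndarray
    groups: np.ndarray
    factor_levels: dict[str, tuple[str, ...]]  # observed levels, ref first
    idw_mean: float


def _observed_levels(df: pd.DataFrame, factor: str) -> tuple[str, ...]:
    observed = set(df[factor].astype(str))
    if factor == "hour" and observed - set(CANONICAL_LEVELS["hour"]):
        # binned hours (e.g. "16-19"): order by the bin's starting hour
        levels = tuple(sorted(observed, key=lambda s: int(s.split("-")[0])))
    elif factor in CANONICAL_LEVELS:
        levels = tuple(l for l in CANONICAL_LEVELS[factor] if l in observed)
        stray = observed - set(CANONICAL_LEVELS[factor])
        if stray:
            raise DesignError(f"unknown {factor} level(s): {sorted(stray)}")
    else:
        levels = tuple(sorted(observed))
    if len(levels) < 2:
        raise DesignError(f"factor {factor} has fewer than 2 observed levels")
    return levels


def build_design(
    df: pd.DataFrame,
    response: str = "y",
    demographics: str = "full",
    hour_col: str = "hour",
    check_rank: bool = True,
) -> Design:
    """Treatment-coded fixed-effects design for the exposure model.

    ``demographics`` is one of ``full`` (all six covariates), ``age_sex``
    (partially adjusted), ``none`` (unadjusted), or an explicit tuple of
    demographic factor names.
    """
    if isinstance(demographics, (tuple, list)):
        demo = tuple(demographics)
        unknown = set(demo) - set(DEMOGRAPHIC_FACTORS)
        if unknown:
            raise DesignError(f"unknown demographic factor(s): {sorted(unknown)}")
    elif demographics in {"full", "age_sex", "none"}:
        demo = {
            "full": DEMOGRAPHIC_FACTORS,
            "age_sex": ("age_group", "sex"),
            "none": (),
        }[demographics]
    else:
        raise DesignError("demographics must be 'full', 'age_sex', 'none', or a tuple")

    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    factor_levels: dict[str, tuple[str, ...]] = {}

    indoor = df["indoor"].astype(float).to_numpy()
    idw = df["idw"].astype(float).to_numpy()
    factor_levels["indoor"] = ("outdoor", "indoor")

    def add_factor(factor: str, col: str) -> None:
        levels = _observed_levels(df, col)
        factor_levels[factor] = levels
        vals = df[col].astype(str).to_numpy()
        for lev in levels[1:]:
            cols.append((vals == lev).astype(float))
            names.append(f"{factor}[{lev}]")

    add_factor("landuse", "landuse")
    cols.append(indoor)
    names.append("indoor")
    cols.append(idw)
    names.append("idw")
    cols.append(indoor * idw)
    names.append("indoor:idw")
    add_factor("season", "season")
    add_factor("hour", hour_col)
    for f in demo:
        add_factor(f, f)

    X = np.column_stack(cols)
    if check_rank:
        _check_full_rank(X, names)
    return Design(
        X=X,
        names=names,
        y=df[response].astype(float).to_numpy() if response in df.columns else np.zeros(n),
        groups=df["studyid"].astype(str).to_numpy(),
        factor_levels=factor_levels,
        idw_mean=float(np.mean(idw)),
    )


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[piv[k]] for k in range(rank, X.shape[1])]
        raise DesignError(f"rank-deficient design; aliased column(s): {aliased}")


# ---------------------------------------------------------------------------
# Estimated marginal means


def _level_term(coefs: dict[str, float], factor: str, level: str, ref: str,
                idw_mean: float) -> float:
    """Fixed-effect contribution of setting ``factor`` to ``level``."""
    if factor == "indoor":
        if level == "indoor":
            return coefs.get("indoor", 0.0) + coefs.get("indoor:idw", 0.0) * idw_mean
        return 0.0
    if level == ref:
        return 0.0
    return coefs.get(f"{factor}[{level}]", 0.0)


def emm_table(
    coefs: dict[str, float],
    factor_levels: dict[str, tuple[str, ...]],
    idw_mean: float,
) -> pd.DataFrame:
    """EMM for each level of each factor (equal weights, background at mean).

    Valid for models whose only interaction is indoor x background, which
    the ``indoor`` handling folds in explicitly.
    """
    base = coefs.get("intercept", 0.0) + coefs.get("idw", 0.0) * idw_mean
    factor_means = {
        f: np.mean([_level_term(coefs, f, l, levels[0], idw_mean) for l in levels])
        for f, levels in factor_levels.items()
    }
    rows = []
    for f, levels in factor_levels.items():
        others = sum(m for g, m in factor_means.items() if g != f)
        for lev in levels:
            rows.append(
                {
                    "factor": f,
                    "level": lev,
                    "emm": base + others + _level_term(coefs, f, lev, levels[0], idw_mean),
                }
            )
    return pd.DataFrame(rows)


def emm_contrast(emms: pd.DataFrame, factor: str, level_a: str, level_b: str) -> float:
    """EMM(level_a) - EMM(level_b) within one factor."""
    sub = emms[emms["factor"] == factor].set_index("level")["emm"]
    return float(sub[level_a] - sub[level_b])
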