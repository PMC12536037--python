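"""Published fully adjusted exposure-model coefficients, as a worked example.

The packaged table holds the fixed-effect coefficients and estimated
marginal means reported by a two-week personal PM2.5 monitoring cohort
(163 adults, Washington State) for the exposure model this package fits.
It is used to demonstrate — and regression-test — the coefficient algebra
(indoor-stratum slope, EMM contrasts) on real published numbers without
access to the underlying monitoring data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from pmexposure.design import emm_table


def load_reported_table() -> pd.DataFrame:
    with resources.files("pmexposure.data").joinpath("reported_cohort_model.csv").open() as fh:
        return pd.read_csv(fh, dtype={"level": str})


def reported_coefs() -> dict[str, float]:
    """Coefficients keyed by the design-matrix naming convention."""
    tab = load_reported_table()
    out: dict[str, float] = {}
    for _, r in tab.iterrows():
        if pd.isna(r["coefficient"]):
            continue  # reference level
        if r["factor"] == "model":
            out["intercept" if r["level"] == "intercept" else r["level"]] = float(
                r["coefficient"]
            )
        elif r["factor"] == "indoor":
            out["indoor"] = float(r["coefficient"])
        else:
            out[f"{r['factor']}[{r['level']}]"] = float(r["coefficient"])
    return out


def reported_factor_levels() -> dict[str, tuple[str, ...]]:
    tab = load_reported_table()
    return {
        f: tuple(sub["level"]) for f, sub in tab[tab["factor"] != "model"].groupby(
            "factor", sort=False
        )
    }


def reported_emm_table(idw_mean: float = 0.0) -> pd.DataFrame:
    """EMMs recomputed from the published coefficients.

    Within-factor EMM contrasts are invariant to ``idw_mean`` and to the
    other factors, so the default of 0 is sufficient for contrasts.
    """
    return emm_table(reported_coefs(), reported_factor_levels(), idw_mean)
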