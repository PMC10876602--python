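"""Group-level statistics on per-trial suborthogonality records.

Fits the study's linear mixed-effects model

    delta_theta ~ Group * (EyesClosed + Unstable) + H1 + H2
                  + (1 | Participant)

with the young-adult group (YA) as the baseline level, by REML through
statsmodels' MixedLM. Wald p-values use the normal approximation (the
approximation is named in the result). The stage is validated by
parameter recovery on simulated cohorts, not by re-deriving externally
reported coefficients, which requires the original datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .errors import OfscaError

__all__ = ["LmeResult", "MODEL_DESCRIPTION", "fit_group_model",
           "summarize_groups", "prepare_records"]

#: the fitted model in the field's (lme4-style) notation
MODEL_DESCRIPTION = (
    "delta_theta ~ Group*(EyesClosed+Unstable) + H1 + H2 + (1|Participant)"
)

#: two-tailed significance level reported alongside fits (never used to
#: filter rows)
ALPHA_LEVEL = 0.05


class ModelError(OfscaError, RuntimeError):
    """Mixed-model fitting failure (singular fit, rank deficiency...)."""


@dataclass
class LmeResult:
    """Coefficient table and bookkeeping of one mixed-model fit."""

    coefficients: pd.DataFrame  # term, estimate, se, t, p
    variance_components: dict
    n_obs: int
    n_participants: int
    n_excluded: int
    formula: str
    model_description: str = MODEL_DESCRIPTION
    p_value_method: str = "Wald test, normal approximation"
    converged: bool = True

    def coef(self, term: str) -> float:
        row = self.coefficients.loc[self.coefficients["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r}; have {self.coefficients['term'].tolist()}")
        return float(row["estimate"].iloc[0])

    def se(self, term: str) -> float:
        row = self.coefficients.loc[self.coefficients["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["se"].iloc[0])


_REQUIRED = ("participant_id", "group", "eyes_closed", "unstable",
             "delta_theta", "h1", "h2")


def prepare_records(records: pd.DataFrame, baseline: str = "YA"):
    """Split a record table into modelable rows and an exclusion count.

    Rows with missing response/covariates or degenerate qc flags are
    excluded (and counted); group becomes an ordered categorical with the
    baseline level first so treatment coding matches the study's contrasts.
    """
    missing = [c for c in _REQUIRED if c not in records.columns]
    if missing:
        raise ModelError(f"record table lacks columns {missing}")
    df = records.copy()
    ok = df[["delta_theta", "h1", "h2"]].notna().all(axis=1)
    if "qc_flags" in df.columns:
        flags = df["qc_flags"].fillna("").astype(str)
        ok &= ~flags.str.contains("degenerate|ofsca_error|short_data")
    excluded = int((~ok).sum())
    df = df.loc[ok].copy()
    levels = [baseline] + [g for g in df["group"].unique() if g != baseline]
    df["group"] = pd.Categorical(df["group"], categories=levels)
    return df, excluded


def _pretty_term(term: str) -> str:
    """Map patsy's term names onto lme4-style coefficient names."""
    out = (term.replace("C(group)", "Group")
               .replace("Group[T.", "Group").replace("]", "")
               .replace("eyes_closed", "EyesClosed")
               .replace("unstable", "Unstable")
               .replace("h1", "H1").replace("h2", "H2")
               .replace("Intercept", "(Intercept)"))
    return out


def fit_group_model(records: pd.DataFrame, baseline: str = "YA",
                    include_h: bool = True) -> LmeResult:
    """REML fit of the group x condition mixed model to trial records.

    Parameters
    ----------
    records : DataFrame
        Tidy per-trial table (one row per trial) with the columns produced
        by the posture pipeline.
    baseline : str
        Reference group level (YA in the study).
    include_h : bool
        Include the H1/H2 scaling-exponent covariates (study default).
    """
    df, excluded = prepare_records(records, baseline)
    counts = df.groupby("group", observed=True)["participant_id"].nunique()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ModelError(f"need >= 2 participants per group; too few in {small}")

    fixed = "C(group) * (eyes_closed + unstable)"
    if include_h:
        dropped = [c for c in ("h1", "h2") if df[c].nunique() <= 1]
        if dropped:
            raise ModelError(
                f"covariate(s) {dropped} are constant across rows and would "
                "alias the intercept; drop them explicitly (include_h=False) "
                "or provide varying values"
            )
        fixed += " + h1 + h2"
    formula = f"delta_theta ~ {fixed}"

    model = smf.mixedlm(formula, df, groups=df["participant_id"])
    with np.errstate(all="ignore"):
        fit = model.fit(reml=True)
    fe = fit.fe_params
    se = fit.bse_fe
    coef = pd.DataFrame({
        "term": [_pretty_term(t) for t in fe.index],
        "estimate": fe.to_numpy(),
        "se": se.to_numpy(),
    })
    coef["t"] = coef["estimate"] / coef["se"]
    coef["p"] = fit.pvalues[fe.index].to_numpy()
    vc = {
        "participant_intercept_var": float(fit.cov_re.iloc[0, 0]),
        "residual_var": float(fit.scale),
    }
    if vc["participant_intercept_var"] <= 0:
        raise ModelError(
            f"singular fit: participant intercept variance collapsed to "
            f"{vc['participant_intercept_var']:.3g} (residual var "
            f"{vc['residual_var']:.3g})"
        )
    return LmeResult(
        coefficients=coef,
        variance_components=vc,
        n_obs=len(df),
        n_participants=int(df["participant_id"].nunique()),
        n_excluded=excluded,
        formula=formula,
        converged=bool(getattr(fit, "converged", True)),
    )


def summarize_groups(records: pd.DataFrame) -> pd.DataFrame:
    """Per group x condition summary of delta_theta, H1 and H2.

    Returns a tidy table of mean, median, SD and n for each measure;
    degenerate-flagged rows are excluded and counted in ``n_excluded``.
    Empty groups yield an n=0 row rather than disappearing silently.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    df, excluded = prepare_records(records)
    rows = []
    all_groups = records["group"].unique()
    for group in all_groups:
        sub_g = df[df["group"] == group]
        for (ec, un), sub in sub_g.groupby(["eyes_closed", "unstable"]):
            row = {"group": group, "eyes_closed": ec, "unstable": un,
                   "n": len(sub), "n_excluded": excluded}
            for col in ("delta_theta", "h1", "h2"):
                row[f"{col}_mean"] = sub[col].mean()
                row[f"{col}_median"] = sub[col].median()
                row[f"{col}_sd"] = sub[col].std()
            rows.append(row)
        if sub_g.empty:
            rows.append({"group": group, "eyes_closed": np.nan,
                         "unstable": np.nan, "n": 0, "n_excluded": excluded})
    return pd.DataFrame(rows)
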