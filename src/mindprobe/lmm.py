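"""Linear mixed-effects control analyses.

The cluster permutation test treats session-level matrices as
independent; these models verify that an upper-vs-lower end effect on
mean cluster power survives participant-level variance. The primary
model has a fixed end effect with random intercepts for participant and
for session nested within participant; the covariate model adds the
session x end mean ratings of the three dimensions most correlated
with the target (plus optional demographics) and keeps a participant
random intercept only.

Fits use statsmodels MixedLM. Reported estimates and Wald intervals
come from a REML fit; the p-value for the end effect is a
likelihood-ratio test between ML fits with and without the term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass
class LMMResult:
    """Fixed effects, variance components, and the end-effect LR test."""

    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    variance_components: dict[str, float]
    lr_stat: float
    p_value: float
    singular: bool
    converged: bool
    collinear: bool = False
    model_description: str = ""

    @property
    def end_effect(self) -> float:
        return float(self.params["end_upper"])

    @property
    def end_ci(self) -> tuple[float, float]:
        lo, hi = self.conf_int.loc["end_upper"]
        return float(lo), float(hi)

    def summary(self) -> str:
        lines = [self.model_description,
                 f"{'term':<24}{'estimate':>10}{'SE':>10}{'95% CI':>24}"]
        for name in self.params.index:
            lo, hi = self.conf_int.loc[name]
            lines.append(f"{name:<24}{self.params[name]:>10.4f}"
                         f"{self.bse[name]:>10.4f}"
                         f"{f'[{lo:.4f}, {hi:.4f}]':>24}")
        vc = ", ".join(f"{k} = {v:.4f}" for k, v in self.variance_components.items())
        lines.append(f"variance components: {vc}")
        lines.append(f"end effect LR chi2(1) = {self.lr_stat:.3f}, p = {self.p_value:.4g}")
        if self.singular:
            lines.append("note: singular fit (a variance component is ~0)")
        if self.collinear:
            lines.append("note: collinear fixed-effect design")
        return "\n".join(lines)


def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    required = {"response", "end", "participant", "session"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    if not set(df["end"].unique()) <= {"upper", "lower"}:
        raise ValueError("end column must contain 'upper'/'lower'")
    df["end_upper"] = (df["end"] == "upper").astype(float)
    return df


def _fit(formula: str, df: pd.DataFrame, vc_formula, re_formula):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, df, groups=df["participant"],
                            re_formula=re_formula, vc_formula=vc_formula)
        reml = model.fit(reml=True)
        ml = model.fit(reml=False)
        null_formula = formula.replace("end_upper + ", "").replace(
            " ~ end_upper", " ~ 1")
        null_model = smf.mixedlm(null_formula, df, groups=df["participant"],
                                 re_formula=re_formula, vc_formula=vc_formula)
        ml0 = null_model.fit(reml=False)
    return reml, ml, ml0


def _collect(reml, ml, ml0, description: str, collinear: bool = False) -> LMMResult:
    lr = max(0.0, 2.0 * (ml.llf - ml0.llf))
    p = float(stats.chi2.sf(lr, 1))
    fe = reml.fe_params.index
    vc = {"participant": float(np.squeeze(reml.cov_re.values))
          if reml.cov_re.size else 0.0}
    if reml.vcomp.size:
        for name, v in zip(reml.model.exog_vc.names, reml.vcomp):
            vc[name] = float(v)
    vc["residual"] = float(reml.scale)
    converged = bool(reml.converged and ml.converged and ml0.converged)
    singular = (not converged
                or reml.model.n_groups < 2
                or any(v < 1e-8 * vc["residual"] for k, v in vc.items()
                       if k != "residual"))
    return LMMResult(
        params=reml.params[fe],
        bse=reml.bse[fe],
        conf_int=reml.conf_int().loc[fe],
        variance_components=vc,
        lr_stat=lr,
        p_value=p,
        singular=singular,
        converged=converged,
        collinear=collinear,
        model_description=description,
    )


def fit_lmm_end(response_table: pd.DataFrame) -> LMMResult:
    """Gaussian LMM: response ~ end + (1 | participant) +
    (1 | participant:session).

    ``response_table`` has one row per session x end: columns
    ``response`` (mean periodic power inside the significant cluster),
    ``end`` ('upper'/'lower'), ``participant``, ``session``. Singular
    fits are flagged, not raised.
    """
    df = _prepare(response_table)
    vc = {"session": "0 + C(session)"}
    reml, ml, ml0 = _fit("response ~ end_upper", df, vc, "1")
    return _collect(reml, ml, ml0,
                    "LMM: response ~ end + (1|participant) + (1|participant:session)")


def fit_lmm_covariates(response_table: pd.DataFrame,
                       covariates: list[str]) -> LMMResult:
    """End-effect LMM with fixed rating covariates and a participant
    random intercept.

    ``covariates`` names additional numeric columns of the table (the
    session x end mean ratings of the top-correlated dimensions, and
    optionally demographics such as age or sex). A rank-deficient fixed
    design is flagged and the fit proceeds.
    """
    df = _prepare(response_table)
    for cov in covariates:
        if cov not in df.columns:
            raise ValueError(f"covariate column {cov!r} missing from table")
    # greedy rank screen: drop covariates that add no new direction to the
    # fixed design, so the fit can proceed on a full-rank model
    base = [np.ones(len(df)), df["end_upper"].to_numpy(dtype=float)]
    kept, collinear = [], False
    for cov in covariates:
        cand = np.column_stack(base + [pd.to_numeric(df[cov]).to_numpy(float)])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            base.append(cand[:, -1])
            kept.append(cov)
        else:
            collinear = True
    if collinear:
        dropped = sorted(set(covariates) - set(kept))
        warnings.warn(f"collinear fixed-effect design; dropped {dropped}")
    terms = " + ".join(["end_upper"] + kept) if kept else "end_upper"
    reml, ml, ml0 = _fit(f"response ~ {terms}", df, None, "1")
    return _collect(reml, ml, ml0,
                    f"LMM: response ~ end + {' + '.join(kept) or '(none)'} "
                    "+ (1|participant)",
                    collinear=collinear)


def cluster_response_table(session_pairs, cluster_mask: np.ndarray) -> pd.DataFrame:
    """Session x end mean periodic power inside a cluster mask.

    session_pairs is an iterable of (upper, lower) SessionCondition
    pairs; returns the long-format table consumed by the LMM fits.
    """
    rows = []
    for up, lo in session_pairs:
        for sc in (up, lo):
            rows.append({
                "participant": sc.participant_id,
                "session": sc.session_id,
                "end": sc.end,
                "response": float(sc.matrix.periodic[cluster_mask].mean()),
            })
    return pd.DataFrame(rows)
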