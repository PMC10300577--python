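"""Whole-brain association models: three-level linear mixed models.

Yearly repeated measures of atrophy (PBVC or PVVC) are regressed on the
concurrent total lesion volume change (TLVC) with age and sex as fixed
covariates, using random intercepts for study site and for patient nested
within site (observations < patients < sites).  Interaction models add a
TLVC x group term (group = treatment arm, interval-specific CDMS status, or
untreated/treated period) and report per-group simple slopes.

Estimation is REML (statsmodels MixedLM with a variance component for
patient-within-site); interaction tests use an ML refit; p-values are Wald z
on the fixed effects.  The study-question row subsets (q1..q3) implement the
trial's inclusion rules for the untreated period, first treatment year and
stable-treatment period of the two arms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

OUTCOMES = ("pbvc", "pvvc")
QUESTIONS = ("q1", "q2", "q2a", "q2b", "q2c", "q3")


@dataclass
class ModelFit:
    """Fixed effects with SE and Wald p, variance components, diagnostics."""

    params: pd.DataFrame  # columns: term, B, SE, p
    variance_components: dict  # site, patient, residual
    formula: str
    converged: bool
    flags: list = field(default_factory=list)
    simple_slopes: pd.DataFrame | None = None
    interaction_term: str | None = None

    def coef(self, term: str) -> tuple[float, float, float]:
        row = self.params[self.params["term"] == term]
        if row.empty:
            raise KeyError(f"no fixed effect {term!r}; have {list(self.params['term'])}")
        r = row.iloc[0]
        return float(r["B"]), float(r["SE"]), float(r["p"])


def _validate_long_table(table: pd.DataFrame):
    required = {"subject", "site", "pbvc", "tlvc", "age", "sex"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"long table is missing columns {sorted(missing)}")
    if "interval" in table.columns:
        dup = table.duplicated(subset=["subject", "interval"])
        if dup.any():
            raise ValueError("duplicate (subject, interval) rows")
    nsite = table.groupby("subject")["site"].nunique()
    if (nsite > 1).any():
        raise ValueError("each subject must belong to exactly one site")


def _fit_mixedlm(formula: str, df: pd.DataFrame, reml: bool, drop_site: bool = False):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if drop_site:
            md = smf.mixedlm(formula, df, groups="subject", re_formula="1")
        else:
            md = smf.mixedlm(
                formula, df, groups="site", re_formula="1",
                vc_formula={"patient": "0 + C(subject)"},
            )
        fit = md.fit(reml=reml, method=["lbfgs", "powell"])
    return fit


def _collect(fit, formula, drop_site, flags) -> ModelFit:
    fe = [n for n in fit.fe_params.index]
    params = pd.DataFrame(
        {
            "term": fe,
            "B": [float(fit.fe_params[n]) for n in fe],
            "SE": [float(fit.bse[n]) for n in fe],
            "p": [float(fit.pvalues[n]) for n in fe],
        }
    )
    if drop_site:
        vc = {
            "site": 0.0,
            "patient": float(fit.cov_re.iloc[0, 0]),
            "residual": float(fit.scale),
        }
    else:
        vc = {
            "site": float(fit.cov_re.iloc[0, 0]),
            "patient": float(fit.vcomp[0]) if len(fit.vcomp) else 0.0,
            "residual": float(fit.scale),
        }
    return ModelFit(
        params=params, variance_components=vc, formula=formula,
        converged=bool(fit.converged), flags=list(flags),
    )


def fit_three_level_lmm(
    table: pd.DataFrame,
    outcome: str = "pbvc",
    terms: tuple = ("tlvc",),
    reml: bool = True,
) -> ModelFit:
    """Random intercepts for site and patient-within-site; fixed age + sex.

    ``terms`` are appended to the always-present age and sex covariates
    (e.g. ``("tlvc", "C(treatment)", "cdms")``).  Non-convergence raises; a
    singular site variance triggers a two-level refit without the site
    intercept, flagged in ``ModelFit.flags``.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be in {OUTCOMES}")
    _validate_long_table(table)
    df = table.reset_index(drop=True).copy()
    if df.groupby("site")["subject"].nunique().min() < 2:
        raise ValueError("need >= 2 subjects per site")
    formula = f"{outcome} ~ age + sex + " + " + ".join(terms)
    flags: list = []
    fit = _fit_mixedlm(formula, df, reml)
    if not fit.converged:
        raise RuntimeError(
            f"mixed model did not converge for {formula!r}; "
            f"gradient norm may be reported by statsmodels"
        )
    site_var = float(fit.cov_re.iloc[0, 0])
    if site_var < 1e-8 * max(float(fit.scale), 1e-12):
        flags.append("singular site variance: refit without site intercept")
        log.info("singular site variance; refitting two-level model")
        try:
            refit = _fit_mixedlm(formula, df, reml, drop_site=True)
            if refit.converged:
                return _collect(refit, formula, True, flags)
        except np.linalg.LinAlgError:
            pass
        flags.append("two-level refit failed; keeping three-level fit")
        log.warning("two-level refit failed; keeping three-level fit")
    return _collect(fit, formula, False, flags)


def interaction_fit(
    table: pd.DataFrame,
    outcome: str,
    interaction: str,
) -> ModelFit:
    """TLVC x group interaction with per-group simple slopes.

    ``interaction`` names a two-level column (``treatment``, ``cdms`` or
    ``period``).  The interaction p comes from a Wald z test on an ML refit;
    simple slopes and their SEs come from the group-specific-slope (cell
    means) REML parameterisation.
    """
    _validate_long_table(table)
    df = table.reset_index(drop=True).copy()
    levels = sorted(df[interaction].astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"interaction column {interaction!r} has a single level")
    if len(levels) > 2:
        raise ValueError(f"interaction column {interaction!r} must be two-level")
    df["_grp"] = df[interaction].astype(str)
    # ML fit with the difference coding for the interaction test
    formula_int = f"{outcome} ~ age + sex + C(_grp) + tlvc + tlvc:C(_grp)"
    fit_ml = _fit_mixedlm(formula_int, df, reml=False)
    if not fit_ml.converged:
        raise RuntimeError(f"interaction model did not converge for {formula_int!r}")
    int_term = [n for n in fit_ml.fe_params.index if n.startswith("tlvc:C(_grp)")]
    assert len(int_term) == 1
    int_term = int_term[0]
    # REML fit with per-group slopes for the simple-slope estimates
    formula_ss = f"{outcome} ~ age + sex + C(_grp) + C(_grp):tlvc"
    fit_ss = _fit_mixedlm(formula_ss, df, reml=True)
    slopes = []
    for lev in levels:
        name = f"C(_grp)[{lev}]:tlvc"
        slopes.append(
            dict(
                group=lev,
                slope=float(fit_ss.fe_params[name]),
                SE=float(fit_ss.bse[name]),
                p=float(fit_ss.pvalues[name]),
            )
        )
    out = _collect(fit_ml, formula_int, False, [])
    out.simple_slopes = pd.DataFrame(slopes)
    out.interaction_term = int_term
    return out


# ---------------------------------------------------------------------------
# study-question subsets


def build_analysis_subsets(table: pd.DataFrame, question: str) -> pd.DataFrame:
    """Row subsets implementing the trial's analysis questions.

    * ``q1``/``q2``/``q3``: all available data points (q2 adds a TLVC x
      treatment interaction, q3 a TLVC x CDMS interaction, in the model).
    * ``q2a``: delayed-treatment (DT) patients only — their untreated years 1
      and 2 excluding interval-specific CDMS converters, plus their treated
      years 4 and 5; a ``period`` column marks untreated/treated.
    * ``q2b``: first year of treatment — ET year 1 and DT year 3, dropping DT
      patients who converted to CDMS during years 1-2 (they started
      treatment at conversion, before year 3).
    * ``q2c``: stable treatment (at least one year on drug) — ET years
      2, 3, 4, 5 and DT years 4, 5.
    """
    if question not in QUESTIONS:
        raise ValueError(f"unknown question {question!r}; expected one of {QUESTIONS}")
    df = table.reset_index(drop=True)
    for col in ("treatment", "cdms", "interval"):
        if col not in df.columns:
            raise ValueError(f"subset rules need column {col!r}")
    if question in ("q1", "q2", "q3"):
        return df.copy()
    et = df["treatment"] == "ET"
    dt = df["treatment"] == "DT"
    if question == "q2a":
        untreated = dt & df["interval"].isin([1, 2]) & (df["cdms"] == 0)
        treated = dt & df["interval"].isin([4, 5])
        out = df[untreated | treated].copy()
        out["period"] = np.where(out["interval"].isin([1, 2]), "untreated", "treated")
        return out
    if question == "q2b":
        pretreatment_converters = set(
            df.loc[dt & df["interval"].isin([1, 2]) & (df["cdms"] == 1), "subject"]
        )
        keep = (et & (df["interval"] == 1)) | (
            dt & (df["interval"] == 3) & ~df["subject"].isin(pretreatment_converters)
        )
        return df[keep].copy()
    if question == "q2c":
        keep = (et & df["interval"].isin([2, 3, 4, 5])) | (
            dt & df["interval"].isin([4, 5])
        )
        return df[keep].copy()
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# simulation used by the recovery/power checks


def simulate_long_table(
    n_sites: int = 10,
    n_patients_per_site: int = 20,
    n_obs: int = 4,
    tlvc_slope: float = 0.05,
    group_slopes: dict | None = None,
    group_col: str = "treatment",
    sd_site: float = 0.2,
    sd_patient: float = 0.3,
    sd_resid: float = 0.5,
    outcome: str = "pbvc",
    seed: int = 0,
) -> pd.DataFrame:
    """Nested longitudinal data with a known TLVC slope.

    With ``group_slopes`` (e.g. ``{"ET": 0.08, "DT": -0.14}``) the TLVC
    effect differs by group, for interaction power checks.  Age and sex enter
    with zero true effect.
    """
    rng = np.random.default_rng(seed)
    rows = []
    groups = list(group_slopes) if group_slopes else ["ET", "DT"]
    for s in range(n_sites):
        u_s = rng.normal(0.0, sd_site)
        for p in range(n_patients_per_site):
            u_p = rng.normal(0.0, sd_patient)
            subj = f"s{s:02d}p{p:02d}"
            grp = groups[int(rng.uniform() < 0.5)]
            slope = group_slopes[grp] if group_slopes else tlvc_slope
            age = float(rng.normal(31.5, 8.35))
            sex = int(rng.uniform() < 0.617)
            for t in range(1, n_obs + 1):
                tlvc = float(rng.normal(0.0, 1.0))
                y = slope * tlvc + u_s + u_p + rng.normal(0.0, sd_resid)
                rows.append(
                    dict(
                        subject=subj, site=f"site{s:02d}", interval=t,
                        age=age, sex=sex, treatment=grp,
                        cdms=int(rng.uniform() < 0.1), tlvc=tlvc,
                        **{outcome: y},
                        **({"pvvc": 0.0} if outcome == "pbvc" else {"pbvc": 0.0}),
                    )
                )
    return pd.DataFrame(rows)
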