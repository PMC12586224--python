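"""Mixed-effects models of field size and voxel density, FDR, group swap.

Models are ``outcome ~ fixed terms + (1 | subject)`` fitted by maximum
likelihood.  Fixed terms are drawn from {sex, age, sex:age}; males are the
reference sex level and age enters linearly in months.  P-values use a
residual-degrees-of-freedom t approximation (recorded on every result).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LMEResult",
    "FDRReport",
    "VoxelwiseResult",
    "GroupSwapResult",
    "fit_lme",
    "bh_fdr",
    "voxelwise_lme",
    "group_swap_refit",
    "simulate_longitudinal",
    "simulate_density_field",
]

logger = logging.getLogger(__name__)

VALID_TERMS = ("sex", "age", "sex:age")

# model term -> dataframe column / patsy term
_TERM_TO_PATSY = {
    "sex": "sex",
    "age": "scan_age_months",
    "sex:age": "sex:scan_age_months",
}
_PARAM_TO_TERM = {
    "Intercept": "intercept",
    "sex[T.female]": "sex",
    "scan_age_months": "age",
    "sex[T.female]:scan_age_months": "sex:age",
}


@dataclass
class LMEResult:
    """Per-term fixed-effect statistics from one mixed-model fit."""

    terms: pd.DataFrame          # columns: term, estimate, se, t, p
    converged: bool
    method: str                  # "ml" (MixedLM) or "ols" (zero random variance)
    df_method: str
    df_resid: float
    n_obs: int
    n_subjects: int
    formula: str

    def term(self, name: str) -> pd.Series:
        rows = self.terms[self.terms["term"] == name]
        if rows.empty:
            raise KeyError(f"term {name!r} not in fitted model")
        return rows.iloc[0]


def _build_formula(fixed: tuple[str, ...], outcome: str) -> str:
    parts = []
    if "sex" in fixed:
        parts.append(_TERM_TO_PATSY["sex"])
    if "age" in fixed:
        parts.append(_TERM_TO_PATSY["age"])
    if "sex:age" in fixed:
        parts.append(_TERM_TO_PATSY["sex:age"])
    return f"{outcome} ~ " + " + ".join(parts) if parts else f"{outcome} ~ 1"


def _failed_result(formula: str, fixed_names: list[str], n_obs: int,
                   n_subjects: int) -> LMEResult:
    terms = pd.DataFrame({"term": fixed_names,
                          "estimate": np.nan, "se": np.nan,
                          "t": np.nan, "p": np.nan})
    return LMEResult(terms=terms, converged=False, method="ml",
                     df_method="residual", df_resid=np.nan, n_obs=n_obs,
                     n_subjects=n_subjects, formula=formula)


def fit_lme(table: pd.DataFrame, fixed: tuple[str, ...] = ("sex", "age"),
            outcome: str = "size_voxels",
            force_zero_re: bool = False) -> LMEResult:
    """Fit ``outcome ~ fixed + (1 | subject_id)`` by maximum likelihood.

    ``force_zero_re=True`` fixes the random-intercept variance at zero, in
    which case the fit reduces exactly to ordinary least squares (used for
    the single-observation-per-subject limit).  Non-convergent or singular
    fits come back flagged (``converged=False``) rather than raising.
    """
    fixed = tuple(fixed)
    for t in fixed:
        if t not in VALID_TERMS:
            raise ValueError(f"unknown fixed term {t!r}; valid terms: {VALID_TERMS}")
    if "sex:age" in fixed and not {"sex", "age"} <= set(fixed):
        raise ValueError("the sex:age interaction requires both main effects")
    if outcome not in table.columns:
        raise ValueError(f"outcome column {outcome!r} missing from table")
    df = table.copy()
    n_subjects = df["subject_id"].nunique()
    if n_subjects < 2:
        raise ValueError("at least 2 subjects are required")
    if "sex" in fixed:
        present = set(df["sex"].unique())
        if not {"male", "female"} <= present:
            raise ValueError(
                f"sex term requires both sexes in the table, found {sorted(present)}")
        df["sex"] = pd.Categorical(df["sex"], categories=["male", "female"])
    formula = _build_formula(fixed, outcome)
    fixed_names = [t for t in ("sex", "age", "sex:age") if t in fixed]

    if force_zero_re:
        res = smf.ols(formula, data=df).fit()
        params, bse = res.params, res.bse
        df_resid = float(res.df_resid)
        converged = True
        method = "ols"
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data=df, groups=df["subject_id"])
                res = model.fit(reml=False)
        except (np.linalg.LinAlgError, ValueError):
            return _failed_result(formula, fixed_names, len(df), n_subjects)
        params = res.fe_params
        bse = res.bse_fe
        k = len(params)
        df_resid = float(len(df) - k)
        converged = bool(res.converged)
        method = "ml"

    rows = []
    for name in params.index:
        term = _PARAM_TO_TERM.get(name, name)
        est = float(params[name])
        se = float(bse[name])
        if se > 0 and np.isfinite(se):
            tval = est / se
            pval = float(2 * sps.t.sf(abs(tval), df_resid))
        else:
            tval, pval = np.nan, np.nan
            converged = False
        rows.append({"term": term, "estimate": est, "se": se,
                     "t": tval, "p": pval})
    return LMEResult(terms=pd.DataFrame(rows), converged=converged,
                     method=method, df_method="residual", df_resid=df_resid,
                     n_obs=len(df), n_subjects=n_subjects, formula=formula)


@dataclass
class FDRReport:
    """Benjamini-Hochberg step-up decisions for one family of tests."""

    family: str
    ids: list
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"unit": self.ids, "p": self.p, "q": self.q,
                             "significant": self.significant})


def bh_fdr(pvals, alpha: float = 0.05, family: str = "",
           ids: list | None = None) -> FDRReport:
    """Benjamini-Hochberg step-up adjustment with monotonized q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return FDRReport(family=family, ids=[], p=p, q=p.copy(),
                         significant=np.zeros(0, dtype=bool), alpha=alpha)
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    if ids is None:
        ids = list(range(p.size))
    return FDRReport(family=family, ids=list(ids), p=p, q=q,
                     significant=reject, alpha=alpha)


@dataclass
class VoxelwiseResult:
    """Per-voxel model table plus one FDR family per fixed term."""

    table: pd.DataFrame          # voxel_x, voxel_y, term, estimate, se, t, p, q, significant
    reports: dict                # term -> FDRReport
    n_failed: int
    family: str

    def significant_voxels(self, term: str, sign: int = 0) -> pd.DataFrame:
        sub = self.table[(self.table["term"] == term) & self.table["significant"]]
        if sign > 0:
            sub = sub[sub["t"] > 0]
        elif sign < 0:
            sub = sub[sub["t"] < 0]
        return sub


def voxelwise_lme(table: pd.DataFrame, fixed: tuple[str, ...] = ("sex", "age"),
                  outcome: str = "density", alpha: float = 0.05,
                  family: str = "") -> VoxelwiseResult:
    """One mixed model per voxel, BH-corrected across the voxel family.

    Voxels whose fit fails to converge are excluded from the FDR family and
    counted (logged), never imputed.  The FDR family is all converged voxels
    of the field, applied separately per fixed term.
    """
    rows = []
    n_failed = 0
    if table.empty:
        empty = pd.DataFrame(columns=["voxel_x", "voxel_y", "term", "estimate",
                                      "se", "t", "p", "q", "significant"])
        return VoxelwiseResult(empty, {}, 0, family)
    for (vx, vy), sub in table.groupby(["voxel_x", "voxel_y"], sort=True):
        res = fit_lme(sub, fixed=fixed, outcome=outcome)
        ok = res.converged and not res.terms["p"].isna().any()
        if not ok:
            n_failed += 1
            continue
        for _, r in res.terms.iterrows():
            if r["term"] == "intercept":
                continue
            rows.append({"voxel_x": vx, "voxel_y": vy, "term": r["term"],
                         "estimate": r["estimate"], "se": r["se"],
                         "t": r["t"], "p": r["p"]})
    if n_failed:
        logger.warning("%d voxel fits failed to converge and were excluded "
                       "from the FDR family", n_failed)
    out = pd.DataFrame(rows)
    reports: dict[str, FDRReport] = {}
    if out.empty:
        out = pd.DataFrame(columns=["voxel_x", "voxel_y", "term", "estimate",
                                    "se", "t", "p", "q", "significant"])
        return VoxelwiseResult(out, reports, n_failed, family)
    out["q"] = np.nan
    out["significant"] = False
    for term in out["term"].unique():
        idx = out.index[out["term"] == term]
        ids = [(int(out.loc[i, "voxel_x"]), int(out.loc[i, "voxel_y"])) for i in idx]
        rep = bh_fdr(out.loc[idx, "p"].to_numpy(), alpha=alpha,
                     family=f"{family}:{term}" if family else term, ids=ids)
        out.loc[idx, "q"] = rep.q
        out.loc[idx, "significant"] = rep.significant
        reports[term] = rep
    return VoxelwiseResult(out, reports, n_failed, family)


@dataclass
class GroupSwapResult:
    """Side-by-side voxelwise sex-effect summaries before/after relabeling."""

    n_significant_before: int
    n_significant_after: int
    mean_t_before: float
    mean_t_after: float
    before: VoxelwiseResult
    after: VoxelwiseResult
    swapped_subjects: tuple[str, ...]


def group_swap_refit(table: pd.DataFrame, swap_subjects,
                     fixed: tuple[str, ...] = ("sex",),
                     outcome: str = "density",
                     alpha: float = 0.05) -> GroupSwapResult:
    """Relabel a male subject subset as female and re-run the voxelwise LME.

    A confound check: if the original sex effect is genuine, diluting the
    female group with effect-free males should not increase the number of
    significant voxels.
    """
    swap = tuple(swap_subjects)
    if len(swap) == 0:
        raise ValueError("swap subset must be nonempty")
    if "sex" not in fixed:
        raise ValueError("group swap requires a sex term in the model")
    sex_by_subject = table.drop_duplicates("subject_id").set_index("subject_id")["sex"]
    for sid in swap:
        if sid not in sex_by_subject.index:
            raise ValueError(f"swap subject {sid!r} not in table")
        if sex_by_subject[sid] != "male":
            raise ValueError(f"swap subject {sid!r} is not male")
    before = voxelwise_lme(table, fixed=fixed, outcome=outcome, alpha=alpha,
                           family="original")
    relabeled = table.copy()
    relabeled.loc[relabeled["subject_id"].isin(swap), "sex"] = "female"
    after = voxelwise_lme(relabeled, fixed=fixed, outcome=outcome, alpha=alpha,
                          family="swapped")

    def _summary(res: VoxelwiseResult) -> tuple[int, float]:
        sig = res.table[(res.table["term"] == "sex") & res.table["significant"]]
        n = len(sig)
        return n, (float(sig["t"].mean()) if n else float("nan"))

    n_b, t_b = _summary(before)
    n_a, t_a = _summary(after)
    return GroupSwapResult(n_b, n_a, t_b, t_a, before, after, swap)


# --------------------------------------------------------------------------- #
# Lightweight generators used for model calibration and operating
# characteristics.  These draw Gaussian outcomes directly from the model the
# fitter assumes, so recovery targets are exact.


def simulate_longitudinal(n_subjects: int, scan_ages=(6.0, 12.0, 18.0),
                          n_female: int | None = None, intercept: float = 100.0,
                          sex_effect: float = 0.0, age_slope: float = 0.0,
                          subject_sd: float = 5.0, resid_sd: float = 3.0,
                          rng: np.random.Generator | None = None,
                          outcome: str = "size_voxels") -> pd.DataFrame:
    """Balanced Gaussian longitudinal table from the random-intercept model."""
    if rng is None:
        rng = np.random.default_rng()
    if n_female is None:
        n_female = n_subjects // 2
    rows = []
    for i in range(n_subjects):
        sid = f"sub{i:03d}"
        sex = "female" if i < n_female else "male"
        u = rng.normal(0, subject_sd)
        for age in scan_ages:
            mu = (intercept + age_slope * age
                  + (sex_effect if sex == "female" else 0.0) + u)
            rows.append({"subject_id": sid, "sex": sex, "cohort": "sim",
                         "scan_age_months": float(age),
                         outcome: mu + rng.normal(0, resid_sd)})
    return pd.DataFrame(rows)


def simulate_density_field(n_voxels: int, effect_voxels, n_subjects: int = 30,
                           scan_ages=(6.0, 12.0, 18.0),
                           n_female: int | None = None,
                           sex_effect: float = 0.0, age_slope: float = 0.0,
                           intercept: float = 0.3, subject_sd: float = 0.03,
                           resid_sd: float = 0.03,
                           rng: np.random.Generator | None = None,
                           ) -> pd.DataFrame:
    """Voxelwise density table with the effect planted on selected voxels.

    ``effect_voxels`` is an iterable of voxel indices (ints); those voxels
    carry the sex/age effects, the rest are null.  Voxel coordinates are
    laid out on a 1 x n strip.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_female is None:
        n_female = n_subjects // 2
    effect_set = set(int(v) for v in effect_voxels)
    subjects = []
    for i in range(n_subjects):
        sid = f"sub{i:03d}"
        sex = "female" if i < n_female else "male"
        subjects.append((sid, sex, rng.normal(0, subject_sd)))
    rows = []
    for v in range(n_voxels):
        carries = v in effect_set
        for sid, sex, u in subjects:
            for age in scan_ages:
                mu = intercept + u
                if carries:
                    mu += (sex_effect if sex == "female" else 0.0) + age_slope * age
                rows.append({"subject_id": sid, "sex": sex, "cohort": "sim",
                             "scan_age_months": float(age),
                             "voxel_x": v, "voxel_y": 0,
                             "density": mu + rng.normal(0, resid_sd)})
    return pd.DataFrame(rows)
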