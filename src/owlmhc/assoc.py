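"""Mixed-model association between parental MHC and breeding success.

Two inference procedures over Poisson (clutch size) and binomial
(fledglings out of clutch) GLMMs with random intercepts for parental
identities and year:

* divergence models — the parents' MHC functional divergences (linear,
  quadratic, mother x father interaction) plus always-included covariates
  (parental ages, laying date and its quadratic), Gelman-standardized,
  run through marginality-constrained sub-model enumeration, AICc ranking,
  and full averaging of the delta-AICc <= 2 set;

* supertype models — one GLMM per common supertype on the parents'
  presence/absence indicators and their interaction, Wald tests corrected
  by Benjamini-Hochberg within the locus x response x dataset family, and
  Tukey-style estimated-marginal-mean contrasts for significant
  interactions.

On the cross-fostered subset (full swaps only) the same models carry the
genetic and the social parents' MHC variables side by side, separating
inherited from rearing effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glmm import MixedGLM, MixedGLMResults
from .modelavg import AveragedModel, enumerate_submodels, model_average

__all__ = [
    "standardize_predictors",
    "vif_check",
    "run_divergence_analysis",
    "run_supertype_analysis",
    "emm_contrasts",
    "SupertypeTest",
]

log = logging.getLogger(__name__)

COVARIATES = ["mother_age", "father_age", "laying_date", "laying_date^2"]


def standardize_predictors(
    df: pd.DataFrame, columns: list[str], scheme: str = "gelman"
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Center continuous predictors and divide by 2 SD (Gelman), putting
    them on a scale comparable with 0/1 indicators.  Returns the frame
    plus scaling metadata {column: (mean, scale)} for back-transforming.
    """
    if scheme not in ("gelman", "unit"):
        raise ValueError(f"unknown scheme {scheme!r}")
    out = df.copy()
    meta: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = out[col].astype(float)
        sd = float(x.std())
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"constant predictor: {col!r}")
        scale = 2 * sd if scheme == "gelman" else sd
        out[col] = (x - x.mean()) / scale
        meta[col] = (float(x.mean()), scale)
    return out, meta


def back_transform(values: pd.Series, meta: dict[str, tuple[float, float]]) -> pd.Series:
    out = values.copy()
    for col, (mean, scale) in meta.items():
        if col in out.index:
            out[col] = out[col] * scale + mean
    return out


def vif_check(design: pd.DataFrame, threshold: float = 10.0) -> pd.Series:
    """Variance inflation factors, VIF_j = 1/(1 - R^2_j) from regressing
    predictor j on the others (with intercept).  Aliased predictors are
    reported as infinite."""
    cols = [c for c in design.columns if design[c].nunique() > 1]
    x = design[cols].to_numpy(float)
    n = x.shape[0]
    vifs = {}
    for j, col in enumerate(cols):
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        y = x[:, j]
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 1.0
        vifs[col] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    s = pd.Series(vifs, name="vif")
    worst = s.max()
    if worst > threshold:
        raise ValueError(f"collinear design: max VIF {worst:.1f} > {threshold}")
    return s


# ---------------------------------------------------------------------------
# design construction


def _merge_parent_divergence(
    nests: pd.DataFrame, divergence: pd.DataFrame, locus: str, roles: list[str]
) -> pd.DataFrame:
    div = divergence[divergence["locus"] == locus].set_index("sample_id")[
        "functional_divergence"
    ]
    out = nests.copy()
    for role in roles:
        out[f"{role}_div"] = out[role].map(div)
    return out.dropna(subset=[f"{r}_div" for r in roles]).reset_index(drop=True)


def _random_groups(data: pd.DataFrame, structure: str) -> dict[str, np.ndarray]:
    if structure == "parents":
        return {
            "mother": data["genetic_mother"].to_numpy(),
            "father": data["genetic_father"].to_numpy(),
            "year": data["year"].to_numpy(),
        }
    if structure == "couple":
        couple = (
            data["genetic_mother"].astype(str) + "x" + data["genetic_father"].astype(str)
        )
        return {"couple": couple.to_numpy(), "year": data["year"].to_numpy()}
    raise ValueError(f"unknown random structure {structure!r}")


def _prepare_covariates(data: pd.DataFrame) -> pd.DataFrame:
    if "laying_date" not in data.columns and "laying_date_julian" in data.columns:
        data = data.rename(columns={"laying_date_julian": "laying_date"})
    return data


def _response(data: pd.DataFrame, response: str):
    if response == "clutch":
        return data["clutch"].to_numpy(float), None, "poisson"
    if response == "fledging":
        return data["fledged"].to_numpy(float), data["clutch"].to_numpy(float), "binomial"
    raise ValueError(f"unknown response {response!r}")


def _fit_candidates(
    data: pd.DataFrame,
    term_sets: list[frozenset[str]],
    all_terms: list[str],
    response: str,
    random_structure: str,
):
    """Fit every candidate sub-model, warm-starting the variance search at
    the full model's estimates; non-converged candidates are dropped."""
    endog, trials, family = _response(data, response)
    groups = _random_groups(data, random_structure)
    base_cols = ["const"] + COVARIATES

    def design(terms):
        cols = base_cols + [t for t in all_terms if t in terms]
        return data[cols]

    full_terms = max(term_sets, key=len)
    full = MixedGLM(endog, design(full_terms), groups=groups,
                    family=family, trials=trials).fit()
    warm = full.sigmas if full.converged else None
    fits = []
    for terms in term_sets:
        if terms == full_terms and full.converged:
            res = full
        else:
            res = MixedGLM(endog, design(terms), groups=groups,
                           family=family, trials=trials).fit(start_sigmas=warm)
        if not res.converged or not np.isfinite(res.llf):
            log.warning("dropping non-converged sub-model %s", sorted(terms))
            continue
        fits.append((terms, res.params, res.bse, res.llf, res.k_params, res.nobs))
    return fits, full


def run_divergence_analysis(
    nests: pd.DataFrame,
    divergence: pd.DataFrame,
    locus: str,
    response: str = "fledging",
    dataset_mode: str = "full",
    random_structure: str = "parents",
    min_records: int = 30,
) -> AveragedModel:
    """Multimodel-averaged divergence analysis for one locus x response.

    ``dataset_mode="full"`` uses every nest with the genetic parents'
    divergences; ``"crossfostered"`` restricts to fully cross-fostered
    clutches and carries the genetic and social parents' divergences in
    the same models.
    """
    if dataset_mode == "full":
        data = nests.copy()
        roles = ["genetic_mother", "genetic_father"]
        rename = {"genetic_father_div": "f_div", "genetic_mother_div": "m_div"}
    elif dataset_mode == "crossfostered":
        data = nests[nests["crossfoster"] == "full"].copy()
        roles = ["genetic_mother", "genetic_father", "social_mother", "social_father"]
        rename = {
            "genetic_father_div": "gf_div",
            "genetic_mother_div": "gm_div",
            "social_father_div": "sf_div",
            "social_mother_div": "sm_div",
        }
    else:
        raise ValueError(f"unknown dataset_mode {dataset_mode!r}")
    data = _merge_parent_divergence(data, divergence, locus, roles)
    data = _prepare_covariates(data.rename(columns={k: v for k, v in rename.items()}))
    div_cols = sorted(rename.values())
    if dataset_mode == "crossfostered":
        # aliasing guard: without real swaps the social columns duplicate
        # the genetic ones and cannot be separated
        if np.allclose(data["gf_div"], data["sf_div"]) and np.allclose(
            data["gm_div"], data["sm_div"]
        ):
            log.warning(
                "social divergences identical to genetic ones; social terms dropped"
            )
            div_cols = ["gf_div", "gm_div"]
    if len(data) < min_records:
        raise ValueError(
            f"only {len(data)} usable records (< {min_records}): analysis underpowered"
        )
    data, _ = standardize_predictors(data, div_cols + COVARIATES[:3])
    data["laying_date^2"] = data["laying_date"] ** 2
    data["const"] = 1.0

    optional: list[str] = []
    pairs = (
        [("f_div", "m_div")]
        if dataset_mode == "full" or div_cols == ["gf_div", "gm_div"]
        else [("gf_div", "gm_div"), ("sf_div", "sm_div")]
    )
    if dataset_mode == "crossfostered" and div_cols == ["gf_div", "gm_div"]:
        pairs = [("gf_div", "gm_div")]
    for f, m in pairs:
        optional += [f, m, f + "^2", m + "^2", f + ":" + m]
        data[f + "^2"] = data[f] ** 2
        data[m + "^2"] = data[m] ** 2
        data[f + ":" + m] = data[f] * data[m]

    vif_check(data[[c for c in div_cols] + COVARIATES])
    term_sets = enumerate_submodels(optional)
    fits, _full = _fit_candidates(data, term_sets, optional, response, random_structure)
    return model_average(fits, focal_terms=optional)


# ---------------------------------------------------------------------------
# supertype tests


@dataclass
class SupertypeTest:
    """Per-supertype GLMM of parental presence/absence."""

    supertype: str
    terms: pd.DataFrame  # term, beta, se, p_raw, p_adj, significant
    result: MixedGLMResults
    emm: pd.DataFrame | None = None
    contrasts: pd.DataFrame | None = None

    @property
    def significant_terms(self) -> list[str]:
        return list(self.terms.index[self.terms["significant"]])

    def summary(self) -> str:
        out = [f"Supertype {self.supertype}:",
               self.terms.to_string(float_format=lambda v: f"{v: .4f}")]
        if self.contrasts is not None:
            out += ["Tukey EMM contrasts:", self.contrasts.to_string(index=False)]
        return "\n".join(out)


def run_supertype_analysis(
    nests: pd.DataFrame,
    presence: pd.DataFrame,
    supertype_list: list[str],
    response: str = "fledging",
    dataset_mode: str = "full",
    random_structure: str = "parents",
    alpha: float = 0.05,
    min_records: int = 30,
) -> list[SupertypeTest]:
    """One presence/absence GLMM per supertype with BH correction across
    the supertype x focal-term family; significant interactions get
    Tukey-adjusted EMM contrasts."""
    if dataset_mode == "crossfostered":
        data_all = nests[nests["crossfoster"] == "full"].copy()
        roles = {
            "gf": "genetic_father", "gm": "genetic_mother",
            "sf": "social_father", "sm": "social_mother",
        }
        inter_pairs = [("gf", "gm"), ("sf", "sm")]
    else:
        data_all = nests.copy()
        roles = {"f": "genetic_father", "m": "genetic_mother"}
        inter_pairs = [("f", "m")]
    if len(data_all) < min_records:
        raise ValueError(f"only {len(data_all)} usable records (< {min_records})")

    tests: list[SupertypeTest] = []
    raw_p: list[float] = []
    index: list[tuple[int, str]] = []
    for st in supertype_list:
        data = data_all.copy()
        focal = []
        for short, role in roles.items():
            data[f"{short}_st"] = data[role].map(presence[st]).astype(float)
            focal.append(f"{short}_st")
        for a, b in inter_pairs:
            data[f"{a}_st:{b}_st"] = data[f"{a}_st"] * data[f"{b}_st"]
            focal.append(f"{a}_st:{b}_st")
        data = _prepare_covariates(data.dropna(subset=focal).reset_index(drop=True))
        data, _ = standardize_predictors(data, COVARIATES[:3])
        data["laying_date^2"] = data["laying_date"] ** 2
        data["const"] = 1.0
        # drop aliased / constant indicator terms
        usable = [c for c in focal if data[c].nunique() > 1]
        endog, trials, family = _response(data, response)
        design = data[["const"] + COVARIATES + usable]
        res = MixedGLM(endog, design, groups=_random_groups(data, random_structure),
                       family=family, trials=trials).fit()
        rows = []
        for term in focal:
            if term in usable and res.converged:
                rows.append({
                    "term": term,
                    "beta": float(res.params[term]),
                    "se": float(res.bse[term]),
                    "p_raw": float(res.pvalues[term]),
                })
            else:
                rows.append({"term": term, "beta": np.nan, "se": np.nan, "p_raw": np.nan})
        terms = pd.DataFrame(rows).set_index("term")
        tests.append(SupertypeTest(st, terms, res))
        for term in terms.index:
            p = terms.loc[term, "p_raw"]
            if np.isfinite(p):
                raw_p.append(float(p))
                index.append((len(tests) - 1, term))

    if raw_p:
        _, p_adj, _, _ = multipletests(raw_p, alpha=alpha, method="fdr_bh")
        for (ti, term), pa in zip(index, p_adj):
            tests[ti].terms.loc[term, "p_adj"] = pa
    for t in tests:
        if "p_adj" not in t.terms.columns:
            t.terms["p_adj"] = np.nan
        t.terms["significant"] = t.terms["p_adj"] < alpha
        sig_inter = [
            term for term in t.significant_terms if ":" in term
        ]
        for term in sig_inter:
            a, b = term.split(":")
            emm, contr = emm_contrasts(t.result, (a, b))
            t.emm, t.contrasts = emm, contr
    return tests


# ---------------------------------------------------------------------------
# estimated marginal means


def emm_contrasts(
    result: MixedGLMResults, factors: tuple[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """EMMs on the link scale for the 2x2 factor grid (covariates at their
    design means) and all pairwise contrasts with a Tukey-style
    multivariate-normal max-|z| adjustment; odds ratios for logit models.
    """
    model = result.model
    names = model.exog_names
    fa, fb = factors
    inter = f"{fa}:{fb}" if f"{fa}:{fb}" in names else f"{fb}:{fa}"
    if fa not in names or fb not in names or inter not in names:
        raise ValueError("factors and their interaction must be in the design")
    xbar = model.exog.mean(axis=0)
    grid = [(0, 0), (0, 1), (1, 0), (1, 1)]
    rows = []
    for va, vb in grid:
        x = xbar.copy()
        x[names.index(fa)] = va
        x[names.index(fb)] = vb
        x[names.index(inter)] = va * vb
        rows.append(x)
    x_grid = np.array(rows)
    beta = result.params.to_numpy()
    cov = result.cov_params_arr
    emm_vals = x_grid @ beta
    emm_se = np.sqrt(np.einsum("ij,jk,ik->i", x_grid, cov, x_grid))
    labels = [f"{fa}={a},{fb}={b}" for a, b in grid]
    emm = pd.DataFrame(
        {"emm": emm_vals, "se": emm_se,
         "ci_low": emm_vals - 1.96 * emm_se, "ci_high": emm_vals + 1.96 * emm_se},
        index=labels,
    )
    # pairwise contrasts
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    c_mat = np.array([x_grid[i] - x_grid[j] for i, j in pairs])
    est = c_mat @ beta
    vcv = c_mat @ cov @ c_mat.T
    se = np.sqrt(np.maximum(np.diag(vcv), 1e-300))
    z = est / se
    corr = vcv / np.outer(se, se)
    p_adj = np.array([_max_abs_z_p(abs(zi), corr) for zi in z])
    contr = pd.DataFrame({
        "contrast": [f"({labels[i]}) - ({labels[j]})" for i, j in pairs],
        "estimate": est,
        "se": se,
        "z": z,
        "p_tukey": p_adj,
    })
    if model.family == "binomial":
        contr["odds_ratio"] = np.exp(est)
        contr["or_se"] = np.exp(est) * se  # delta method
    return emm, contr


def _max_abs_z_p(z_abs: float, corr: np.ndarray) -> float:
    """P(max_j |Z_j| >= z) for Z ~ N(0, corr) — single-step adjustment."""
    if z_abs == 0:
        return 1.0
    m = corr.shape[0]
    corr = corr + np.eye(m) * 1e-10
    mvn = stats.multivariate_normal(mean=np.zeros(m), cov=corr, allow_singular=True)
    inside = mvn.cdf(np.full(m, z_abs), lower_limit=np.full(m, -z_abs))
    return float(np.clip(1.0 - inside, 0.0, 1.0))
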