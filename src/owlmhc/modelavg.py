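"""AICc-based multimodel inference with full model averaging.

The workflow mirrors the information-theoretic approach common in
behavioural ecology: enumerate all sub-models of a full model that
respect marginality (an interaction only with both main effects, a
quadratic only with its linear term), rank by AICc, keep the set with
delta-AICc <= 2, and fully average the coefficients over that set (a
term absent from a model contributes 0), with unconditional standard
errors in the Burnham-Anderson square-root form and z-based 95% CIs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "aicc",
    "akaike_weights",
    "enumerate_submodels",
    "model_average",
    "AveragedModel",
]

Z95 = 1.959963984540054


def aicc(llf: float, k_params: int, nobs: int) -> float:
    """AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if nobs <= k_params + 1:
        raise ValueError(
            f"AICc undefined: nobs={nobs} must exceed k_params+1={k_params + 1}"
        )
    return -2.0 * llf + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (
        nobs - k_params - 1
    )


def akaike_weights(aicc_values) -> np.ndarray:
    a = np.asarray(aicc_values, float)
    rel = np.exp(-0.5 * (a - a.min()))
    return rel / rel.sum()


def enumerate_submodels(
    optional_terms: list[str], requires: dict[str, set[str]] | None = None
) -> list[frozenset[str]]:
    """All subsets of the optional terms respecting marginality.

    ``requires`` maps a term to the terms it depends on; by default the
    dependencies are inferred from naming: ``a:b`` needs ``a`` and ``b``,
    ``a^2`` needs ``a``.
    """
    if requires is None:
        requires = {}
        for t in optional_terms:
            if ":" in t:
                requires[t] = set(t.split(":"))
            elif t.endswith("^2"):
                requires[t] = {t[:-2]}
    valid = []
    for r in range(len(optional_terms) + 1):
        for combo in itertools.combinations(optional_terms, r):
            s = frozenset(combo)
            if all(requires.get(t, set()) <= s for t in s):
                valid.append(s)
    return valid


@dataclass
class AveragedModel:
    """Model-selection table plus fully averaged coefficients."""

    selection_table: pd.DataFrame  # one row per candidate model
    coef: pd.DataFrame  # term, beta, se_unconditional, ci_low, ci_high, significant
    retained: pd.DataFrame  # the delta-AICc <= 2 subset with weights

    @property
    def significant_terms(self) -> list[str]:
        return list(self.coef.index[self.coef["significant"]])

    def summary(self) -> str:
        lines = [
            f"Model set: {len(self.selection_table)} candidates, "
            f"{len(self.retained)} retained (delta-AICc <= 2)",
            self.retained[["terms", "k", "llf", "aicc", "delta", "weight"]]
            .to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            "Full-averaged coefficients (95% CI):",
            self.coef.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)


def model_average(
    fits: list[tuple[frozenset[str], pd.Series, pd.Series, float, int, int]],
    focal_terms: list[str],
    delta_max: float = 2.0,
) -> AveragedModel:
    """Average a fitted candidate set.

    Each entry of ``fits`` is (terms, params, bse, llf, k_params, nobs).
    ``focal_terms`` are the optional (MHC) terms to report; a term absent
    from a model contributes beta = 0 to the full average.
    """
    if not fits:
        raise ValueError("no converged candidate models to average")
    rows = []
    for terms, params, bse, llf, k, n in fits:
        rows.append(
            {
                "terms": "+".join(sorted(terms)) if terms else "(null)",
                "term_set": terms,
                "k": k,
                "llf": llf,
                "aicc": aicc(llf, k, n),
                "params": params,
                "bse": bse,
            }
        )
    table = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    table["delta"] = table["aicc"] - table["aicc"].iloc[0]
    retained = table[table["delta"] <= delta_max].copy()
    retained["weight"] = akaike_weights(retained["aicc"])

    coef_rows = []
    for term in focal_terms:
        betas = np.array(
            [
                row["params"].get(term, 0.0)
                for _, row in retained.iterrows()
            ]
        )
        ses = np.array(
            [row["bse"].get(term, 0.0) for _, row in retained.iterrows()]
        )
        w = retained["weight"].to_numpy()
        beta_bar = float(np.sum(w * betas))
        se_unc = float(np.sum(w * np.sqrt(ses**2 + (betas - beta_bar) ** 2)))
        lo, hi = beta_bar - Z95 * se_unc, beta_bar + Z95 * se_unc
        in_models = sum(term in row["term_set"] for _, row in retained.iterrows())
        coef_rows.append(
            {
                "term": term,
                "beta": beta_bar,
                "se_unconditional": se_unc,
                "ci_low": lo,
                "ci_high": hi,
                "significant": bool(lo > 0 or hi < 0),
                "n_models": in_models,
            }
        )
    coef_cols = ["term", "beta", "se_unconditional", "ci_low", "ci_high",
                 "significant", "n_models"]
    coef = pd.DataFrame(coef_rows, columns=coef_cols).set_index("term")
    sel = table.drop(columns=["params", "bse", "term_set"])
    keep = retained.drop(columns=["params", "bse", "term_set"])
    return AveragedModel(selection_table=sel, coef=coef, retained=keep)
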