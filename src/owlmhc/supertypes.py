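"""Supertype clustering of MHC alleles from physicochemical descriptors.

Alleles are described by the five z-scale descriptors of the residues at
positively selected codon positions (rows = alleles, columns = site x
descriptor, standardized), k-means clustered with the number of clusters
chosen by BIC (the n*ln(WSS/n) + k*ln(n) convention) or mean silhouette,
and finally re-assigned in a reduced discriminant space (PCA retaining
>= 90% variance followed by nearest linear-discriminant centroid), the
usual DAPC-style workflow.  Supertype population frequencies count the
individuals carrying at least one allele of the supertype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import silhouette_score

from .datatables import Z_SCALES

__all__ = [
    "screen_selected_sites",
    "build_descriptor_matrix",
    "select_k",
    "assign_supertypes",
    "SupertypeAssignment",
    "supertype_frequencies",
    "filter_common_supertypes",
]

log = logging.getLogger(__name__)


def shannon_entropy(column: list[str]) -> float:
    _, counts = np.unique(column, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def screen_selected_sites(
    alignment: dict[str, str],
    method: str = "external_list",
    sites: list[int] | None = None,
    n_sites: int | None = None,
) -> list[int]:
    """Positively selected codon positions (1-based) used for clustering.

    ``external_list`` passes through a user-supplied list — the supported
    path for real data, where sites come from codon-model selection
    inference.  ``heuristic`` ranks alignment columns by amino-acid
    Shannon entropy and returns the ``n_sites`` most variable ones; it is
    a self-contained stand-in for synthetic data only and is not
    equivalent to codon-model inference.
    """
    if method == "external_list":
        if not sites:
            raise ValueError("external_list requires a non-empty site list")
        return list(sites)
    if method != "heuristic":
        raise ValueError(f"unknown method {method!r}")
    seqs = list(alignment.values())
    if not seqs:
        raise ValueError("empty alignment")
    length = len(seqs[0])
    ent = [shannon_entropy([s[i] for s in seqs]) for i in range(length)]
    variable = [i for i in range(length) if ent[i] > 0]
    if not variable:
        raise ValueError("monomorphic alignment: no variable sites to screen")
    m = n_sites or min(10, len(variable))
    ranked = sorted(variable, key=lambda i: (-ent[i], i))[:m]
    return sorted(i + 1 for i in ranked)


def build_descriptor_matrix(
    alignment: dict[str, str], sites: list[int]
) -> pd.DataFrame:
    """Alleles x (selected sites x 5 z-scales), column-standardized.

    Constant columns (a site monomorphic across alleles) standardize to 0.
    """
    if not sites:
        raise ValueError("empty site list: clustering undefined")
    labels = sorted(alignment)
    cols, data = [], []
    for lab in labels:
        seq = alignment[lab]
        row = []
        for s in sites:
            res = seq[s - 1]
            if res not in Z_SCALES:
                raise ValueError(f"no descriptor values for residue {res!r}")
            row.extend(Z_SCALES[res])
        data.append(row)
    for s in sites:
        cols.extend(f"site{s}_z{k}" for k in range(1, 6))
    mat = pd.DataFrame(data, index=labels, columns=cols)
    sd = mat.std(ddof=0)
    mat = (mat - mat.mean()) / sd.replace(0, np.nan)
    return mat.fillna(0.0)


def _kmeans(x: np.ndarray, k: int, seed: int, n_restarts: int) -> KMeans:
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    km.fit(x)
    return km


def kmeans_bic(x: np.ndarray, labels: np.ndarray, centers: np.ndarray, k: int) -> float:
    """BIC for a k-means partition: n*ln(WSS/n) + k*ln(n)."""
    n = x.shape[0]
    wss = float(((x - centers[labels]) ** 2).sum())
    wss = max(wss, 1e-12)
    return n * np.log(wss / n) + k * np.log(n)


def select_k(
    matrix: pd.DataFrame,
    k_range: range | list[int] = range(2, 21),
    method: str = "BIC",
    seed: int = 0,
    n_restarts: int = 100,
    silhouette_floor: float = 0.25,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of supertypes by BIC (minimised) or mean
    silhouette (maximised) over best-of-restarts k-means fits.

    Returns (k, criterion table).  A winning silhouette below
    ``silhouette_floor`` logs a weak-structure warning.
    """
    x = matrix.to_numpy(float)
    n = x.shape[0]
    n_distinct = len(np.unique(x, axis=0))
    k_cap = min(n - 1, n_distinct)
    ks = [k for k in k_range if 2 <= k <= k_cap]
    if not ks:
        raise ValueError("k_range contains no feasible k")
    if max(k_range) > k_cap:
        log.warning("k_range truncated to %d (distinct alleles / n-1)", k_cap)
    rows = []
    for k in ks:
        km = _kmeans(x, k, seed, n_restarts)
        bic = kmeans_bic(x, km.labels_, km.cluster_centers_, k)
        if len(np.unique(km.labels_)) > 1:
            sil = float(silhouette_score(x, km.labels_))
        else:
            sil = np.nan
        rows.append({"k": k, "bic": bic, "silhouette": sil})
    table = pd.DataFrame(rows).set_index("k")
    if method.upper() == "BIC":
        k_opt = int(table["bic"].idxmin())
    elif method == "silhouette":
        k_opt = int(table["silhouette"].idxmax())
        if table.loc[k_opt, "silhouette"] < silhouette_floor:
            log.warning(
                "weak cluster structure: best silhouette %.3f below floor %.2f",
                table.loc[k_opt, "silhouette"],
                silhouette_floor,
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    return k_opt, table


@dataclass
class SupertypeAssignment:
    locus: str
    mapping: dict[str, str]  # allele label -> supertype id ("ST1"...)
    k: int
    k_selection_method: str
    seed: int
    frequencies: pd.Series | None = None

    def alleles_of(self, supertype: str) -> list[str]:
        return sorted(a for a, s in self.mapping.items() if s == supertype)


def assign_supertypes(
    matrix: pd.DataFrame,
    k: int,
    seed: int = 0,
    locus: str = "",
    n_restarts: int = 100,
    k_selection_method: str = "BIC",
) -> SupertypeAssignment:
    """k-means partition refined by PCA (>= 90% variance) + nearest
    linear-discriminant centroid, with deterministic supertype numbering
    (clusters ordered by their lexicographically smallest allele)."""
    labels_idx = list(matrix.index)
    x = matrix.to_numpy(float)
    if k == 1:
        mapping = {a: "ST1" for a in labels_idx}
        return SupertypeAssignment(locus, mapping, 1, k_selection_method, seed)
    km = _kmeans(x, k, seed, n_restarts)
    part = km.labels_.copy()
    # discriminant refinement in PC space
    n_pc = min(x.shape[0] - 1, x.shape[1])
    if n_pc >= 1:
        pca = PCA(n_components=n_pc, random_state=seed)
        scores = pca.fit_transform(x)
        var = np.cumsum(pca.explained_variance_ratio_)
        keep = int(np.searchsorted(var, 0.90) + 1)
        scores = scores[:, :keep]
        if len(np.unique(part)) > 1:
            try:
                lda = LinearDiscriminantAnalysis()
                lda.fit(scores, part)
                part = lda.predict(scores)
            except np.linalg.LinAlgError:  # degenerate within-class scatter
                pass
    # deterministic relabeling
    order = sorted(
        np.unique(part), key=lambda c: min(labels_idx[i] for i in np.flatnonzero(part == c))
    )
    rename = {c: f"ST{r + 1}" for r, c in enumerate(order)}
    mapping = {a: rename[c] for a, c in zip(labels_idx, part)}
    return SupertypeAssignment(locus, mapping, len(order), k_selection_method, seed)


def supertype_frequencies(
    assignment: SupertypeAssignment, genotypes: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Population frequency of each supertype (carriers / genotyped) and
    the per-individual presence/absence matrix."""
    sts = sorted(set(assignment.mapping.values()), key=lambda s: int(s[2:]))
    samples = sorted(genotypes["sample_id"].unique())
    presence = pd.DataFrame(0, index=samples, columns=sts, dtype=int)
    for rec in genotypes.itertuples(index=False):
        for allele in str(rec.alleles).split(";"):
            st = assignment.mapping.get(allele)
            if st is not None:
                presence.loc[rec.sample_id, st] = 1
    freqs = presence.mean(axis=0)
    freqs.name = "frequency"
    assignment.frequencies = freqs
    return freqs, presence


def filter_common_supertypes(frequencies: pd.Series, floor: float = 0.10) -> list[str]:
    """Supertypes tested downstream: population frequency strictly above
    the floor."""
    common = [st for st, f in frequencies.items() if f > floor]
    if not common:
        log.warning("no supertype above frequency %.2f: supertype tests skipped", floor)
    return common
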