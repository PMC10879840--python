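"""Pairwise allele distances and per-individual MHC divergence.

Two distances over equal-length amino-acid sequences are provided: the
amino-acid p-distance (proportion of differing sites) and the Grantham
functional distance (mean, or summed, per-site Grantham distance).  An
individual's MHC divergence is the mean distance over all unordered pairs
of its distinct alleles; homozygotes score 0.  For the co-amplified
MHC-Ialpha amplicon (up to four alleles per bird) all pairs among the
distinct alleles enter the mean.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pandas as pd

from .datatables import (
    AMINO_ACIDS,
    GRANTHAM_ALPHA,
    GRANTHAM_BETA,
    GRANTHAM_GAMMA,
    GRANTHAM_PROPERTIES,
)

__all__ = [
    "grantham_rho",
    "grantham_distance",
    "grantham_matrix",
    "sequence_distance",
    "individual_divergence",
    "divergence_table",
    "metric_correlation",
]


def _raw_grantham(res_a: str, res_b: str) -> float:
    ca, pa, va = GRANTHAM_PROPERTIES[res_a]
    cb, pb, vb = GRANTHAM_PROPERTIES[res_b]
    return float(
        np.sqrt(
            GRANTHAM_ALPHA * (ca - cb) ** 2
            + GRANTHAM_BETA * (pa - pb) ** 2
            + GRANTHAM_GAMMA * (va - vb) ** 2
        )
    )


@lru_cache(maxsize=1)
def grantham_rho() -> float:
    """Scaling constant making the mean distance over the 190 pairs 100."""
    dists = [_raw_grantham(a, b) for a, b in itertools.combinations(AMINO_ACIDS, 2)]
    return 100.0 / float(np.mean(dists))


def grantham_distance(res_a: str, res_b: str) -> float:
    """Grantham distance between two residues (0 iff identical)."""
    for r in (res_a, res_b):
        if r not in GRANTHAM_PROPERTIES:
            raise ValueError(f"unknown residue code: {r!r}")
    if res_a == res_b:
        return 0.0
    return grantham_rho() * _raw_grantham(res_a, res_b)


@lru_cache(maxsize=1)
def grantham_matrix() -> pd.DataFrame:
    """Full 20x20 Grantham distance matrix as a DataFrame."""
    aas = list(AMINO_ACIDS)
    m = np.zeros((20, 20))
    for i, a in enumerate(aas):
        for j, b in enumerate(aas):
            if i < j:
                m[i, j] = m[j, i] = grantham_distance(a, b)
    return pd.DataFrame(m, index=aas, columns=aas)


def _check_pair(seq1: str, seq2: str) -> None:
    if len(seq1) != len(seq2):
        raise ValueError(
            f"sequences must be aligned to equal length ({len(seq1)} != {len(seq2)})"
        )
    if len(seq1) == 0:
        raise ValueError("empty sequences")


def sequence_distance(
    seq1: str, seq2: str, metric: str = "grantham", mode: str = "per_site"
) -> float:
    """Distance between two aligned amino-acid sequences.

    Parameters
    ----------
    metric : "p_distance" or "grantham"
    mode : for the Grantham metric, "per_site" (mean per-site distance,
        the default scale) or "raw" (sum over sites).
    """
    _check_pair(seq1, seq2)
    if metric == "p_distance":
        diffs = sum(a != b for a, b in zip(seq1, seq2))
        return diffs / len(seq1)
    if metric == "grantham":
        total = sum(grantham_distance(a, b) for a, b in zip(seq1, seq2) if a != b)
        if mode == "raw":
            return total
        if mode == "per_site":
            return total / len(seq1)
        raise ValueError(f"unknown mode {mode!r}")
    raise ValueError(f"unknown metric {metric!r}")


def individual_divergence(
    alleles: set[str] | list[str],
    alignment: dict[str, str],
    metric: str = "grantham",
    mode: str = "per_site",
) -> float:
    """Mean pairwise distance over an individual's distinct alleles.

    ``alleles`` are allele labels, looked up in ``alignment`` (label ->
    amino-acid sequence).  Homozygous (single-allele) individuals score 0.
    """
    labels = sorted(set(alleles))
    for lab in labels:
        if lab not in alignment:
            raise KeyError(f"allele {lab!r} absent from alignment")
    if len(labels) < 2:
        return 0.0
    dists = [
        sequence_distance(alignment[a], alignment[b], metric=metric, mode=mode)
        for a, b in itertools.combinations(labels, 2)
    ]
    return float(np.mean(dists))


def divergence_table(
    genotypes: pd.DataFrame,
    alignments: dict[str, dict[str, str]],
    mode: str = "per_site",
) -> pd.DataFrame:
    """Per-individual divergence for every sample x locus genotype row.

    ``genotypes`` needs columns sample_id, locus, alleles (semicolon-joined
    labels).  Returns sample_id, locus, p_distance, functional_divergence.
    """
    rows = []
    for rec in genotypes.itertuples(index=False):
        alleles = [a for a in str(rec.alleles).split(";") if a]
        aln = alignments[rec.locus]
        rows.append(
            {
                "sample_id": rec.sample_id,
                "locus": rec.locus,
                "n_alleles": len(set(alleles)),
                "p_distance": individual_divergence(alleles, aln, "p_distance"),
                "functional_divergence": individual_divergence(
                    alleles, aln, "grantham", mode=mode
                ),
            }
        )
    return pd.DataFrame(rows)


def metric_correlation(div: pd.DataFrame) -> pd.Series:
    """Pearson r between per-individual p-distance and functional divergence,
    per locus (QC output; in realistic data the two track closely)."""
    out = {}
    for locus, sub in div.groupby("locus"):
        x = sub["p_distance"].to_numpy(float)
        y = sub["functional_divergence"].to_numpy(float)
        if len(sub) < 3 or x.std() == 0 or y.std() == 0:
            out[locus] = np.nan
        else:
            out[locus] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out, name="pearson_r")
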