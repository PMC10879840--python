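"""Amplicon MHC allele calling from variant-depth spectra.

Two complementary callers separate true alleles from PCR/sequencing
artifacts in a per-amplicon table of unique sequences and read depths:

* Degree-of-Change (DoC): sorts variants by depth and locates the
  inflection in cumulative depth.  With cumulative depths C_i of the
  top-i variants, DOC_i = (C_i - C_{i-1}) / (C_{i+1} - C_i), i.e. the
  ratio of successive depth increments d_i / d_{i+1}; the called allele
  number is the i <= max_alleles maximising DOC_i.  When every remaining
  variant would be called (i equals the number of variants) the
  denominator is zero and DOC is treated as +inf.

* Threshold: variants whose within-amplicon frequency reaches an
  artifact threshold T_art are called, capped at max_alleles by depth.

Calls are screened for chimeric variants (single-breakpoint crossovers
of two deeper variants) and non-functional sequences (off-frame length
or internal stop codon), then the two methods are reconciled; replicate
amplifications give a reproducibility estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "VariantTable",
    "GenotypeCall",
    "GenotyperParams",
    "filter_variants",
    "doc_genotype",
    "threshold_genotype",
    "detect_chimeras",
    "screen_functionality",
    "consensus_genotype",
    "call_genotype",
    "call_all",
    "replicate_concordance",
]

MAX_ALLELES = {"MHC-Ia": 4, "DAB1": 2, "DAB2": 2}


@dataclass
class VariantTable:
    """Unique-sequence depth spectrum for one sample x locus amplicon."""

    sample_id: str
    locus: str
    replicate: int
    sequences: list[str]
    depths: list[int]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.depths):
            raise ValueError("sequences and depths differ in length")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("duplicate sequences in variant table")
        if any(d < 0 for d in self.depths):
            raise ValueError("negative depth")
        # canonical order: depth desc, then sequence (deterministic tie-break)
        order = sorted(
            range(len(self.sequences)),
            key=lambda i: (-self.depths[i], self.sequences[i]),
        )
        self.sequences = [self.sequences[i] for i in order]
        self.depths = [int(self.depths[i]) for i in order]

    @property
    def total_depth(self) -> int:
        return int(sum(self.depths))

    def frequencies(self) -> np.ndarray:
        tot = self.total_depth
        if tot == 0:
            return np.zeros(len(self.depths))
        return np.asarray(self.depths, float) / tot


@dataclass
class GenotypeCall:
    sample_id: str
    locus: str
    replicate: int = 0
    alleles: frozenset[str] = frozenset()
    method_agreement: bool = True
    qc_flags: set[str] = field(default_factory=set)

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def callable(self) -> bool:
        return "uncallable" not in self.qc_flags and self.n_alleles > 0


@dataclass(frozen=True)
class GenotyperParams:
    min_total_depth: int = 50
    expected_length_nt: int | None = None
    min_variant_freq: float = 0.01
    artifact_threshold: float = 0.05  # Threshold-method T_art
    max_alleles: int | None = None  # default: per-locus lookup

    def __post_init__(self) -> None:
        if not (0 < self.artifact_threshold < 1):
            raise ValueError("artifact_threshold must lie in (0, 1)")
        if not (0 <= self.min_variant_freq < 1):
            raise ValueError("min_variant_freq must lie in [0, 1)")
        if self.min_total_depth < 1:
            raise ValueError("min_total_depth must be >= 1")

    def max_alleles_for(self, locus: str) -> int:
        if self.max_alleles is not None:
            return self.max_alleles
        return MAX_ALLELES.get(locus, 2)


def filter_variants(
    table: VariantTable, params: GenotyperParams
) -> tuple[VariantTable, set[str]]:
    """Pre-filter: drop off-length variants, sub-frequency variants and
    depth-1 singletons; flag amplicons below the total-depth floor."""
    flags: set[str] = set()
    if not table.sequences:
        return table, {"uncallable", "low_depth"}
    keep_seqs, keep_depths = [], []
    tot = table.total_depth
    for seq, depth in zip(table.sequences, table.depths):
        if params.expected_length_nt is not None and len(seq) != params.expected_length_nt:
            continue
        if depth <= 1:
            continue
        if tot > 0 and depth / tot < params.min_variant_freq:
            continue
        keep_seqs.append(seq)
        keep_depths.append(depth)
    filtered = replace(table, sequences=keep_seqs, depths=keep_depths)
    if filtered.total_depth < params.min_total_depth:
        flags |= {"uncallable", "low_depth"}
    if not keep_seqs:
        flags.add("uncallable")
    return filtered, flags


def doc_genotype(
    table: VariantTable, max_alleles: int
) -> tuple[int, frozenset[str], list[float], set[str]]:
    """Degree-of-Change call: returns (n_alleles, alleles, doc_profile, flags)."""
    flags: set[str] = set()
    depths = np.asarray(table.depths, float)
    m = len(depths)
    if m == 0:
        return 0, frozenset(), [], {"uncallable"}
    if m == 1:
        return 1, frozenset(table.sequences), [np.inf], flags
    profile: list[float] = []
    upper = min(max_alleles, m)
    for i in range(1, upper + 1):
        d_i = depths[i - 1]
        d_next = depths[i] if i < m else 0.0
        profile.append(float(d_i / d_next) if d_next > 0 else np.inf)
    n = int(np.argmax(profile)) + 1
    # depth ties spanning the cut: include tied variants if the cap allows,
    # else keep the lexicographically smallest (canonical sort order) + flag
    if n < m and table.depths[n - 1] == table.depths[n]:
        tied_depth = table.depths[n - 1]
        hi = n
        while hi < m and table.depths[hi] == tied_depth:
            hi += 1
        if hi <= max_alleles:
            n = hi
        flags.add("depth_tie")
    alleles = frozenset(table.sequences[:n])
    return n, alleles, profile, flags


def threshold_genotype(
    table: VariantTable, t_art: float, max_alleles: int
) -> tuple[int, frozenset[str], set[str]]:
    """Threshold-method call: variants at frequency >= T_art, depth-capped."""
    flags: set[str] = set()
    freqs = table.frequencies()
    idx = [i for i, f in enumerate(freqs) if f >= t_art]
    if not idx:
        return 0, frozenset(), {"uncallable"}
    if len(idx) > max_alleles:
        idx = idx[:max_alleles]  # canonical order is depth-descending
        flags.add("max_alleles_capped")
    return len(idx), frozenset(table.sequences[i] for i in idx), flags


def detect_chimeras(alleles: frozenset[str], table: VariantTable) -> set[str]:
    """Called variants explainable as a single-breakpoint crossover of two
    strictly deeper variants from the full table."""
    depth_of = dict(zip(table.sequences, table.depths))
    chimeric: set[str] = set()
    for seq in alleles:
        d = depth_of.get(seq, 0)
        parents = [
            s
            for s in table.sequences
            if depth_of[s] > d and len(s) == len(seq) and s != seq
        ]
        if len(parents) < 2:
            continue
        found = False
        for k in range(1, len(seq)):
            for a in parents:
                if a[:k] != seq[:k]:
                    continue
                for b in parents:
                    if b is not a and b[k:] == seq[k:]:
                        found = True
                        break
                if found:
                    break
            if found:
                break
        if found:
            chimeric.add(seq)
    return chimeric


def translate(seq: str) -> str:
    return str(Seq(seq).translate())


def screen_functionality(alleles: frozenset[str]) -> tuple[frozenset[str], set[str]]:
    """Drop putative non-functional alleles: off-frame length (frameshift
    proxy) or an internal stop codon in the annotated reading frame."""
    kept, flags = set(), set()
    for seq in alleles:
        if len(seq) % 3 != 0 or "*" in translate(seq):
            flags.add("nonfunctional_removed")
        else:
            kept.add(seq)
    return frozenset(kept), flags


def consensus_genotype(
    doc_alleles: frozenset[str], thr_alleles: frozenset[str]
) -> tuple[frozenset[str], bool, set[str]]:
    """Reconcile the two callers: agreement, else non-empty intersection
    (flag discordant), else uncallable."""
    if doc_alleles == thr_alleles:
        return doc_alleles, True, set()
    inter = doc_alleles & thr_alleles
    if inter:
        return inter, False, {"discordant"}
    return frozenset(), False, {"discordant", "uncallable"}


def call_genotype(table: VariantTable, params: GenotyperParams) -> GenotypeCall:
    """Full single-amplicon pipeline: filter -> DoC + Threshold -> chimera
    and functionality screens -> consensus."""
    max_alleles = params.max_alleles_for(table.locus)
    filtered, flags = filter_variants(table, params)
    call = GenotypeCall(table.sample_id, table.locus, table.replicate, qc_flags=flags)
    if "uncallable" in flags:
        return call
    _, doc_alleles, _, doc_flags = doc_genotype(filtered, max_alleles)
    _, thr_alleles, thr_flags = threshold_genotype(
        filtered, params.artifact_threshold, max_alleles
    )
    call.qc_flags |= doc_flags | thr_flags

    def screen(alleles: frozenset[str]) -> frozenset[str]:
        chim = detect_chimeras(alleles, filtered)
        if chim:
            call.qc_flags.add("chimera_removed")
            alleles = frozenset(alleles - chim)
        alleles, func_flags = screen_functionality(alleles)
        call.qc_flags |= func_flags
        return alleles

    doc_alleles, thr_alleles = screen(doc_alleles), screen(thr_alleles)
    final, agree, cons_flags = consensus_genotype(doc_alleles, thr_alleles)
    call.alleles = final
    call.method_agreement = agree
    call.qc_flags |= cons_flags
    if not final:
        call.qc_flags.add("uncallable")
    return call


def call_all(tables: list[VariantTable], params: GenotyperParams) -> list[GenotypeCall]:
    return [call_genotype(t, params) for t in tables]


def replicate_concordance(calls: list[GenotypeCall]) -> float:
    """Fraction of replicated sample x locus pairs with identical final
    allele sets (only callable replicate pairs enter)."""
    by_key: dict[tuple[str, str], list[GenotypeCall]] = {}
    for c in calls:
        by_key.setdefault((c.sample_id, c.locus), []).append(c)
    n_pairs = n_same = 0
    for reps in by_key.values():
        if len(reps) < 2:
            continue
        reps = sorted(reps, key=lambda c: c.replicate)
        for a, b in zip(reps[:-1], reps[1:]):
            n_pairs += 1
            if a.alleles == b.alleles:
                n_same += 1
    if n_pairs == 0:
        return float("nan")
    return n_same / n_pairs


def calls_to_frame(calls: list[GenotypeCall]) -> pd.DataFrame:
    """Genotype calls as a tidy frame (one row per sample x locus, first
    replicate only), with alleles semicolon-joined in sorted order."""
    rows = []
    for c in calls:
        if c.replicate != 0:
            continue
        rows.append(
            {
                "sample_id": c.sample_id,
                "locus": c.locus,
                "alleles": ";".join(sorted(c.alleles)),
                "n_alleles": c.n_alleles,
                "method_agreement": c.method_agreement,
                "qc_flags": ";".join(sorted(c.qc_flags)),
            }
        )
    return pd.DataFrame(rows)
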