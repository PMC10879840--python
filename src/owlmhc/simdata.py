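"""Synthetic data generator for the full pipeline.

Emulates, with known ground truth, the four data layers the pipeline
consumes: (1) per-locus allele pools with designated positively selected
codon positions and motif (supertype) structure; (2) diploid genotypes
under Hardy-Weinberg sampling, with the class-I amplicon carrying two
co-amplified genes (up to four alleles per bird); (3) noisy amplicon
variant-depth spectra with PCR point-error derivatives, single-breakpoint
chimeras, allelic amplification imbalance and replicate amplifications;
(4) breeding records (clutch size, fledglings) for couples subjected to a
cross-fostering plan, with configurable MHC effects injected on the
fledging logit plus year and parent random intercepts.

Loci default to the dimensions typical of a simple avian MHC: class-I
exon 3 with 8 selected sites, two class-IIB genes (DAB1/DAB2) with 15 and
10 selected sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotyper import VariantTable, translate

log = logging.getLogger(__name__)

__all__ = [
    "LocusSpec",
    "NoiseConfig",
    "EffectConfig",
    "DEFAULT_LOCI",
    "generate_allele_pool",
    "simulate_population",
    "simulate_amplicon_reads",
    "simulate_breeding",
]

# sense codons only (no TAA/TAG/TGA)
_BASES = "ACGT"
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
]
# codons by encoded amino acid
_CODONS_BY_AA: dict[str, list[str]] = {}
for cod in _SENSE_CODONS:
    _CODONS_BY_AA.setdefault(translate(cod), []).append(cod)


@dataclass(frozen=True)
class LocusSpec:
    """Shape of one MHC amplicon pool."""

    name: str
    exon_length_nt: int
    n_alleles: int
    selected_sites: tuple[int, ...]  # 1-based codon positions
    coamplified: bool = False  # two genes in one amplicon (class I)
    n_motifs: int = 8  # supertype motifs built into the pool
    background_sub_rate: float = 0.02  # per-codon off-site AA substitution rate

    def __post_init__(self) -> None:
        if self.exon_length_nt % 3 != 0:
            raise ValueError("exon_length_nt must be a multiple of 3")
        n_codons = self.exon_length_nt // 3
        if any(not (1 <= s <= n_codons) for s in self.selected_sites):
            raise ValueError("selected_sites outside 1..n_codons")
        if self.n_alleles < 1:
            raise ValueError("need at least one allele")
        if self.n_alleles > 4 ** self.exon_length_nt:
            raise ValueError("more alleles than sequence space")

    @property
    def max_alleles_per_individual(self) -> int:
        return 4 if self.coamplified else 2


DEFAULT_LOCI: dict[str, LocusSpec] = {
    "MHC-Ia": LocusSpec("MHC-Ia", 270, 40, (5, 9, 24, 45, 63, 66, 70, 80),
                        coamplified=True, n_motifs=9),
    "DAB1": LocusSpec("DAB1", 270, 31,
                      (3, 9, 11, 13, 26, 28, 30, 32, 37, 38, 47, 56, 60, 70, 74),
                      n_motifs=14),
    "DAB2": LocusSpec("DAB2", 270, 22, (9, 11, 13, 26, 28, 37, 47, 56, 61, 71),
                      n_motifs=10),
}


@dataclass(frozen=True)
class NoiseConfig:
    """Read-level noise model for amplicon simulation."""

    mean_depth: float = 1000.0
    depth_dispersion: float = 5.0  # negative-binomial size parameter
    substitution_rate: float = 1e-4  # per base, per read
    chimera_rate: float = 0.05  # probability of one chimeric variant
    allelic_imbalance: float = 25.0  # Dirichlet concentration per gene copy
    replicate_fraction: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.chimera_rate, self.replicate_fraction):
            if not (0 <= r <= 1):
                raise ValueError("rates must lie in [0, 1]")
        if self.mean_depth < 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")

    @classmethod
    def noiseless(cls, **kw) -> "NoiseConfig":
        return cls(substitution_rate=0.0, chimera_rate=0.0, **kw)


@dataclass
class EffectConfig:
    """True effects injected into the breeding records (logit/log scale)."""

    beta_div_genetic_father: float = 0.0
    beta_div_genetic_mother: float = 0.0
    beta_div_social_father: float = 0.0
    beta_div_social_mother: float = 0.0
    # supertype id -> (father effect, mother effect, interaction effect)
    supertype_effects: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )
    fledging_intercept: float = 0.405  # logit of ~0.6 fledging success
    clutch_log_mean: float = float(np.log(6.23))
    sigma_year: float = 0.3
    sigma_individual: float = 0.3
    # slopes on standardized covariates in the fledging predictor
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {
            "mother_age": 0.05,
            "father_age": 0.05,
            "laying_date": -0.10,
            "laying_date^2": -0.05,
        }
    )

    def __post_init__(self) -> None:
        if self.sigma_year < 0 or self.sigma_individual < 0:
            raise ValueError("random-intercept SDs must be >= 0")


# ---------------------------------------------------------------------------
# allele pools


def _random_coding_seq(n_codons: int, rng: np.random.Generator) -> list[str]:
    return [
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons)
    ]


def generate_allele_pool(spec: LocusSpec, seed: int) -> dict[str, str]:
    """Labelled nucleotide allele pool with motif structure.

    Variation is concentrated at the selected sites: alleles belonging to
    the same motif share the selected-site residues exactly, while other
    codons accumulate sparse background substitutions.  All sequences are
    in frame, stop-free, pairwise distinct with distinct translations
    (when the pool size allows).
    """
    rng = np.random.default_rng(seed)
    n_codons = spec.exon_length_nt // 3
    base = _random_coding_seq(n_codons, rng)
    sel_idx = [s - 1 for s in spec.selected_sites]
    n_motifs = min(spec.n_motifs, spec.n_alleles)
    aas = sorted(_CODONS_BY_AA)
    # per-motif residue choice at each selected site, drawn to be diverse
    motif_residues = []
    for _ in range(n_motifs):
        motif_residues.append([aas[i] for i in rng.integers(0, 20, len(sel_idx))])
    # ensure motifs are pairwise distinct at selected sites
    for i in range(1, n_motifs):
        while any(motif_residues[i] == motif_residues[j] for j in range(i)):
            motif_residues[i] = [aas[k] for k in rng.integers(0, 20, len(sel_idx))]

    pool: dict[str, str] = {}
    seen_nt: set[str] = set()
    seen_aa: set[str] = set()
    width = len(str(spec.n_alleles))
    for a in range(spec.n_alleles):
        motif = a % n_motifs
        for _attempt in range(200):
            codons = list(base)
            for pos, aa in zip(sel_idx, motif_residues[motif]):
                options = _CODONS_BY_AA[aa]
                codons[pos] = options[rng.integers(0, len(options))]
            # sparse background variation away from selected sites
            for pos in range(n_codons):
                if pos in sel_idx:
                    continue
                if rng.random() < spec.background_sub_rate:
                    codons[pos] = _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS))]
            nt = "".join(codons)
            aa_seq = translate(nt)
            if nt in seen_nt:
                continue
            # prefer distinct translations while the AA space allows it
            if aa_seq in seen_aa and _attempt < 150:
                continue
            break
        else:
            raise RuntimeError("could not generate a distinct allele")
        label = f"{spec.name}*{a + 1:0{width}d}"
        pool[label] = nt
        seen_nt.add(nt)
        seen_aa.add(aa_seq)
    return pool


# ---------------------------------------------------------------------------
# genotypes


def simulate_population(
    pools: dict[str, dict[str, str]],
    n_individuals: int,
    seed: int,
    allele_freqs: dict[str, np.ndarray] | None = None,
    loci: dict[str, LocusSpec] | None = None,
) -> pd.DataFrame:
    """Hardy-Weinberg genotypes for every individual x locus.

    DAB loci draw two gene copies with replacement; a co-amplified
    class-I locus draws four (two genes jointly genotyped, so up to four
    distinct alleles).  Returns columns sample_id, locus, copies
    (semicolon-joined labels with repeats), alleles (distinct, sorted).
    """
    loci = loci or DEFAULT_LOCI
    rng = np.random.default_rng(seed)
    rows = []
    for locus, pool in pools.items():
        labels = sorted(pool)
        if allele_freqs is not None and locus in allele_freqs:
            freqs = np.asarray(allele_freqs[locus], float)
            if len(freqs) != len(labels):
                raise ValueError(f"{locus}: frequency vector length mismatch")
            if abs(freqs.sum() - 1.0) > 1e-8:
                raise ValueError(f"{locus}: allele frequencies must sum to 1")
        else:
            freqs = np.full(len(labels), 1.0 / len(labels))
        spec = loci.get(locus)
        n_copies = 4 if (spec is not None and spec.coamplified) else 2
        draws = rng.choice(len(labels), size=(n_individuals, n_copies), p=freqs)
        for i in range(n_individuals):
            copies = sorted(labels[j] for j in draws[i])
            rows.append(
                {
                    "sample_id": f"ind{i + 1:04d}",
                    "locus": locus,
                    "copies": ";".join(copies),
                    "alleles": ";".join(sorted(set(copies))),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# amplicon reads


def _mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    s = list(seq)
    for p in pos:
        s[p] = rng.choice([b for b in _BASES if b != s[p]])
    return "".join(s)


def simulate_amplicon_reads(
    genotypes: pd.DataFrame,
    pools: dict[str, dict[str, str]],
    noise: NoiseConfig,
    seed: int,
) -> list[VariantTable]:
    """Per-amplicon variant-depth spectra for every genotype row.

    True alleles share the total depth through a Dirichlet draw weighted
    by gene-copy number; point-error derivatives (1-2 substitutions) and
    single-breakpoint chimeras are added at low depth.  A fraction of
    individuals is amplified twice with independent noise.
    """
    rng = np.random.default_rng(seed)
    if noise.mean_depth == 0:
        warnings.warn("zero requested depth: variant tables will be empty")
    tables: list[VariantTable] = []
    samples = sorted(genotypes["sample_id"].unique())
    replicated = {
        s for s in samples if rng.random() < noise.replicate_fraction
    }
    for rec in genotypes.itertuples(index=False):
        pool = pools[rec.locus]
        copies = [c for c in str(rec.copies).split(";") if c]
        counts = pd.Series(copies).value_counts().sort_index()
        n_reps = 2 if rec.sample_id in replicated else 1
        for rep in range(n_reps):
            tables.append(
                _one_amplicon(
                    rec.sample_id, rec.locus, rep, counts, pool, noise, rng
                )
            )
    return tables


def _one_amplicon(sample_id, locus, rep, copy_counts, pool, noise, rng):
    if noise.mean_depth == 0:
        return VariantTable(sample_id, locus, rep, [], [])
    # negative-binomial total depth
    size = noise.depth_dispersion
    p = size / (size + noise.mean_depth)
    total = int(rng.negative_binomial(size, p)) + 1
    labels = list(copy_counts.index)
    alpha = noise.allelic_imbalance * copy_counts.to_numpy(float)
    shares = rng.dirichlet(alpha) if len(labels) > 1 else np.array([1.0])
    depths = rng.multinomial(total, shares)
    variant_depth: dict[str, int] = {}
    for lab, d in zip(labels, depths):
        if d > 0:
            variant_depth[pool[lab]] = variant_depth.get(pool[lab], 0) + int(d)
    true_seqs = [pool[lab] for lab in labels]
    length = len(true_seqs[0])
    # PCR/sequencing point-error derivatives
    if noise.substitution_rate > 0:
        per_read = min(1.0, noise.substitution_rate * length)
        for seq in list(variant_depth):
            if seq not in true_seqs:
                continue
            n_err = rng.binomial(variant_depth[seq], per_read)
            if n_err == 0:
                continue
            variant_depth[seq] -= n_err
            for chunk in _split_int(n_err, rng.integers(1, 3), rng):
                if chunk == 0:
                    continue
                deriv = _mutate(seq, int(rng.integers(1, 3)), rng)
                variant_depth[deriv] = variant_depth.get(deriv, 0) + chunk
    # single-breakpoint chimera of two true alleles
    distinct_true = sorted(set(true_seqs))
    if noise.chimera_rate > 0 and len(distinct_true) >= 2:
        if rng.random() < noise.chimera_rate:
            a, b = rng.choice(len(distinct_true), size=2, replace=False)
            k = int(rng.integers(1, length))
            chim = distinct_true[a][:k] + distinct_true[b][k:]
            if chim not in variant_depth:
                parent_min = min(
                    variant_depth.get(distinct_true[a], 0),
                    variant_depth.get(distinct_true[b], 0),
                )
                d = max(2, int(0.02 * total * rng.random()))
                if d < parent_min:
                    variant_depth[chim] = d
    seqs = [s for s, d in variant_depth.items() if d > 0]
    return VariantTable(sample_id, locus, rep, seqs, [variant_depth[s] for s in seqs])


def _split_int(n: int, parts: int, rng) -> list[int]:
    if parts <= 1 or n <= 1:
        return [n]
    cut = int(rng.integers(0, n + 1))
    return [cut, n - cut]


# ---------------------------------------------------------------------------
# breeding records


def simulate_breeding(
    divergence: pd.Series,
    effects: EffectConfig,
    n_nests: int,
    seed: int,
    crossfoster_plan: dict[str, float] | str = "study",
    supertype_presence: pd.DataFrame | None = None,
    n_years: int = 10,
) -> pd.DataFrame:
    """Breeding records for ``n_nests`` couples with injected MHC effects.

    ``divergence`` maps individual id -> focal-locus functional
    divergence (used for the divergence effects after 2-SD
    standardization, matching the analysis scale).  ``crossfoster_plan``
    is "none", "full", "study" (the none/partial/full mix of a long-term
    cross-fostering protocol, 0.34/0.35/0.31) or an explicit fraction
    mapping.  Full swaps exchange whole clutches between nests matched on
    laying date, so genetic and social parents differ.
    """
    rng = np.random.default_rng(seed)
    plans = {
        "none": {"none": 1.0, "partial": 0.0, "full": 0.0},
        "full": {"none": 0.0, "partial": 0.0, "full": 1.0},
        "study": {"none": 0.34, "partial": 0.35, "full": 0.31},
    }
    if isinstance(crossfoster_plan, str):
        plan = plans[crossfoster_plan]
    else:
        plan = dict(crossfoster_plan)
    if abs(sum(plan.values()) - 1.0) > 1e-8:
        raise ValueError("cross-fostering fractions must sum to 1")

    ids = list(divergence.index)
    if len(ids) < 4:
        raise ValueError("need at least four genotyped individuals (two couples)")
    perm = rng.permutation(len(ids))
    half = len(ids) // 2
    females = [ids[i] for i in perm[:half]]
    males = [ids[i] for i in perm[half : 2 * half]]
    # socially monogamous couples; re-used across nests when there are more
    # nests than couples (repeated breeding attempts across years)
    n_couples = min(half, n_nests)
    couple_of_nest = rng.integers(0, n_couples, n_nests) if n_couples < n_nests else np.arange(n_nests)
    mothers = [females[couple_of_nest[i]] for i in range(n_nests)]
    fathers = [males[couple_of_nest[i]] for i in range(n_nests)]

    div = divergence.astype(float)
    sd = float(div.std())
    zdiv = (div - div.mean()) / (2 * sd) if sd > 0 else div * 0.0

    years = rng.integers(1, n_years + 1, n_nests)
    laydate = np.clip(rng.normal(120, 25, n_nests), 40, 240).round().astype(int)
    mother_age = rng.poisson(1.5, n_nests) + 1
    father_age = rng.poisson(1.5, n_nests) + 1

    u_year = rng.normal(0, effects.sigma_year, n_years + 1)
    u_ind = {
        i: rng.normal(0, effects.sigma_individual)
        for i in sorted(set(mothers) | set(fathers))
    }
    u_year_clutch = rng.normal(0, effects.sigma_year, n_years + 1)

    # cross-fostering assignment: full-swap nests paired by laying date
    statuses = rng.choice(
        ["none", "partial", "full"],
        size=n_nests,
        p=[plan["none"], plan["partial"], plan["full"]],
    )
    full_idx = sorted(np.flatnonzero(statuses == "full"), key=lambda i: laydate[i])
    social_of = {i: i for i in range(n_nests)}
    if len(full_idx) % 2 == 1:
        log.info("odd number of full-swap nests: nest %d left unswapped",
                 full_idx[-1])
        statuses[full_idx[-1]] = "none"
        full_idx = full_idx[:-1]
    for a, b in zip(full_idx[::2], full_idx[1::2]):
        social_of[a], social_of[b] = b, a

    zdate = (laydate - laydate.mean()) / (2 * laydate.std() + 1e-12)
    zma = (mother_age - mother_age.mean()) / (2 * mother_age.std() + 1e-12)
    zfa = (father_age - father_age.mean()) / (2 * father_age.std() + 1e-12)
    cov = effects.covariate_effects
    cov_eta = (
        cov.get("mother_age", 0.0) * zma
        + cov.get("father_age", 0.0) * zfa
        + cov.get("laying_date", 0.0) * zdate
        + cov.get("laying_date^2", 0.0) * zdate**2
    )

    rows = []
    for i in range(n_nests):
        j = social_of[i]
        gm, gf = mothers[i], fathers[i]
        sm, sf = mothers[j], fathers[j]
        eta_clutch = effects.clutch_log_mean + u_year_clutch[years[i]]
        clutch = max(1, int(rng.poisson(np.exp(eta_clutch))))
        eta = (
            effects.fledging_intercept
            + effects.beta_div_genetic_father * zdiv[gf]
            + effects.beta_div_genetic_mother * zdiv[gm]
            + effects.beta_div_social_father * zdiv[sf]
            + effects.beta_div_social_mother * zdiv[sm]
            + cov_eta[i]
            + u_year[years[i]]
            + u_ind[gm]
            + u_ind[gf]
        )
        if supertype_presence is not None:
            for st, (fe, me, ie) in effects.supertype_effects.items():
                f_has = float(supertype_presence.loc[gf, st])
                m_has = float(supertype_presence.loc[gm, st])
                eta += fe * f_has + me * m_has + ie * f_has * m_has
        p_fledge = 1.0 / (1.0 + np.exp(-eta))
        fledged = int(rng.binomial(clutch, p_fledge))
        rows.append(
            {
                "nest_id": f"nest{i + 1:04d}",
                "year": int(years[i]),
                "laying_date_julian": int(laydate[i]),
                "clutch": clutch,
                "fledged": fledged,
                "genetic_mother": gm,
                "genetic_father": gf,
                "social_mother": sm,
                "social_father": sf,
                "mother_age": int(mother_age[i]),
                "father_age": int(father_age[i]),
                "crossfoster": statuses[i],
            }
        )
    return pd.DataFrame(rows)
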