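"""End-to-end pipeline: simulate -> genotype -> diversify -> supertype ->
associate, with schema validation between stages and a JSON run report."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, divergence, simdata, supertypes
from .genotyper import GenotyperParams, call_all, calls_to_frame, replicate_concordance, translate
from .io import RunConfig, read_fasta, read_table, read_variants, write_fasta, write_table, write_variants

log = logging.getLogger(__name__)


def stage_simulate(cfg: RunConfig) -> dict:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = cfg.seed
    loci = {name: simdata.DEFAULT_LOCI[name] for name in cfg.loci}
    pools = {
        name: simdata.generate_allele_pool(spec, seed=rng_seed + i)
        for i, (name, spec) in enumerate(loci.items())
    }
    for name, pool in pools.items():
        write_fasta(out / f"alleles_true_{name}.fasta", pool)
        (out / f"sites_{name}.txt").write_text(
            "\n".join(str(s) for s in loci[name].selected_sites) + "\n"
        )
    genotypes = simdata.simulate_population(pools, cfg.n_individuals, seed=rng_seed + 100, loci=loci)
    write_table(out / "genotypes_true.csv", genotypes, header=cfg.header())
    noise = simdata.NoiseConfig(**cfg.noise)
    tables = simdata.simulate_amplicon_reads(genotypes, pools, noise, seed=rng_seed + 200)
    write_variants(out / "variants.tsv", tables, header=cfg.header())

    # truth layer for the breeding simulation: divergence + supertypes of
    # the focal locus from the true genotypes
    alignments = {n: {lab: translate(s) for lab, s in p.items()} for n, p in pools.items()}
    div = divergence.divergence_table(genotypes, alignments)
    focal = cfg.focal_locus
    div_focal = div[div["locus"] == focal].set_index("sample_id")["functional_divergence"]
    effects = simdata.EffectConfig(**cfg.effects)
    st_presence = None
    if effects.supertype_effects:
        spec = loci[focal]
        mat = supertypes.build_descriptor_matrix(alignments[focal], list(spec.selected_sites))
        assign = supertypes.assign_supertypes(mat, k=spec.n_motifs, seed=rng_seed, locus=focal)
        _, st_presence = supertypes.supertype_frequencies(
            assign, genotypes[genotypes["locus"] == focal]
        )
    nests = simdata.simulate_breeding(
        div_focal, effects, cfg.n_nests, seed=rng_seed + 300,
        crossfoster_plan=cfg.crossfoster_plan, supertype_presence=st_presence,
    )
    write_table(out / "nests.csv", nests, header=cfg.header())
    truth = {
        "seed": cfg.seed,
        "focal_locus": focal,
        "effects": {
            k: v for k, v in effects.__dict__.items() if not isinstance(v, dict)
        },
        "supertype_effects": effects.supertype_effects,
        "covariate_effects": effects.covariate_effects,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, default=float))
    return {"n_individuals": cfg.n_individuals, "n_nests": int(len(nests)),
            "n_amplicons": len(tables)}


def stage_genotype(cfg: RunConfig) -> dict:
    out = Path(cfg.outdir)
    tables = read_variants(out / "variants.tsv")
    params = GenotyperParams(**cfg.genotyper)
    calls = call_all(tables, params)
    concordance = replicate_concordance(calls)
    # label called sequences against the reference pools; unseen sequences
    # get fresh per-locus labels
    seq_to_label: dict[tuple[str, str], str] = {}
    for locus in cfg.loci:
        ref = read_fasta(out / f"alleles_true_{locus}.fasta")
        for lab, seq in ref.items():
            seq_to_label[(locus, seq)] = lab
    novel_count: dict[str, int] = {}
    for c in calls:
        labels = []
        for seq in sorted(c.alleles):
            key = (c.locus, seq)
            if key not in seq_to_label:
                novel_count[c.locus] = novel_count.get(c.locus, 0) + 1
                seq_to_label[key] = f"{c.locus}*new{novel_count[c.locus]:02d}"
            labels.append(seq_to_label[key])
        c.alleles = frozenset(labels)
    frame = calls_to_frame(calls)
    frame = frame[frame["alleles"] != ""]
    write_table(out / "genotypes.csv", frame, header=cfg.header())
    called = {
        (locus, seq): lab for (locus, seq), lab in seq_to_label.items()
    }
    for locus in cfg.loci:
        used = set()
        for alleles in frame.loc[frame["locus"] == locus, "alleles"]:
            used.update(alleles.split(";"))
        write_fasta(
            out / f"alleles_{locus}.fasta",
            {lab: seq for (loc, seq), lab in sorted(called.items(), key=lambda kv: kv[1])
             if loc == locus and lab in used},
        )
    return {
        "replicate_concordance": None if np.isnan(concordance) else float(concordance),
        "n_called": int(len(frame)),
        "novel_alleles": novel_count,
    }


def stage_diversify(cfg: RunConfig) -> dict:
    out = Path(cfg.outdir)
    genotypes = read_table(out / "genotypes.csv")
    alignments = {}
    for locus in cfg.loci:
        nts = read_fasta(out / f"alleles_{locus}.fasta", aligned=True)
        alignments[locus] = {lab: translate(s) for lab, s in nts.items()}
    div = divergence.divergence_table(genotypes, alignments)
    write_table(out / "divergence.csv", div, header=cfg.header())
    corr = divergence.metric_correlation(div)
    return {"metric_correlation": {k: None if pd.isna(v) else float(v)
                                   for k, v in corr.items()}}


def stage_supertype(cfg: RunConfig) -> dict:
    out = Path(cfg.outdir)
    genotypes = read_table(out / "genotypes.csv")
    report = {}
    for locus in cfg.loci:
        sites_path = out / f"sites_{locus}.txt"
        if not sites_path.exists():
            raise FileNotFoundError(
                f"missing site list {sites_path}; supply positively selected "
                f"codon positions (method=external_list) for locus {locus}"
            )
        sites = [int(x) for x in sites_path.read_text().split()]
        nts = read_fasta(out / f"alleles_{locus}.fasta", aligned=True)
        aln = {lab: translate(s) for lab, s in nts.items()}
        sites = supertypes.screen_selected_sites(aln, "external_list", sites=sites)
        mat = supertypes.build_descriptor_matrix(aln, sites)
        method = cfg.k_method.get(locus, "BIC")
        k_max = min(20, len(mat) - 1)
        k, _tab = supertypes.select_k(mat, range(2, k_max + 1), method=method, seed=cfg.seed)
        assign = supertypes.assign_supertypes(mat, k, seed=cfg.seed, locus=locus,
                                              k_selection_method=method)
        freqs, presence = supertypes.supertype_frequencies(
            assign, genotypes[genotypes["locus"] == locus]
        )
        pd.DataFrame(
            {"allele": list(assign.mapping), "supertype": list(assign.mapping.values())}
        ).to_csv(out / f"supertypes_{locus}.csv", index=False)
        presence.rename_axis("sample_id").reset_index().to_csv(
            out / f"presence_{locus}.csv", index=False
        )
        report[locus] = {
            "k": k,
            "frequencies": {s: float(f) for s, f in freqs.items()},
            "common": supertypes.filter_common_supertypes(freqs),
        }
    return report


def stage_associate(cfg: RunConfig) -> dict:
    out = Path(cfg.outdir)
    nests = read_table(out / "nests.csv")
    div = read_table(out / "divergence.csv")
    report = {}
    locus = cfg.focal_locus
    avg = assoc.run_divergence_analysis(
        nests, div, locus, response=cfg.response, dataset_mode=cfg.dataset_mode,
        random_structure=cfg.random_structure,
    )
    write_table(out / "model_selection.csv", avg.selection_table, header=cfg.header())
    write_table(out / "averaged_coefficients.csv",
                avg.coef.reset_index(), header=cfg.header())
    presence = read_table(out / f"presence_{locus}.csv").set_index("sample_id")
    common = supertypes.filter_common_supertypes(presence.mean(axis=0))
    st_rows, emm_rows = [], []
    if common:
        tests = assoc.run_supertype_analysis(
            nests, presence, common, response=cfg.response,
            dataset_mode=cfg.dataset_mode, random_structure=cfg.random_structure,
        )
        for t in tests:
            tab = t.terms.reset_index()
            tab.insert(0, "supertype", t.supertype)
            st_rows.append(tab)
            if t.contrasts is not None:
                c = t.contrasts.copy()
                c.insert(0, "supertype", t.supertype)
                emm_rows.append(c)
        report["supertype_significant"] = [
            f"{t.supertype}:{term}" for t in tests for term in t.significant_terms
        ]
    if st_rows:
        write_table(out / "supertype_tests.csv", pd.concat(st_rows), header=cfg.header())
    if emm_rows:
        write_table(out / "emm_contrasts.csv", pd.concat(emm_rows), header=cfg.header())
    report["averaged_significant"] = avg.significant_terms
    report["n_candidate_models"] = int(len(avg.selection_table))
    report["n_retained"] = int(len(avg.retained))
    return report


STAGES = {
    "simulate": stage_simulate,
    "genotype": stage_genotype,
    "diversify": stage_diversify,
    "supertype": stage_supertype,
    "associate": stage_associate,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order and write a JSON run report."""
    report = {"config_hash": cfg.config_hash, "seed": cfg.seed}
    for name, fn in STAGES.items():
        log.info("stage %s", name)
        report[name] = fn(cfg)
    out = Path(cfg.outdir)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
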