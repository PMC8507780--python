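"""End-to-end orchestration of the SILAC quantification stages for one
isogenic cell-line pair: quantify -> peptidome -> binder calling ->
interactome -> integration, with a structured summary written to disk.

Normalization factors are derived from the whole-cell proteome table
(whose bulk is unchanged between the lines) and applied to every table
of the run; this removes technical channel imbalance while preserving a
genuine global shift confined to the HLA-presented peptidome.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
import yaml

from . import integrate, interactome, io as hio, motif, peptidome, quantify

log = logging.getLogger("hlaquant")


@dataclass
class PipelineConfig:
    """Input paths and every analysis threshold, with standard defaults."""

    peptide_table: str
    proteome_table: str
    outdir: str
    interactome_table: str | None = None
    fasta: str | None = None
    contaminants: str | None = None
    known_interactors: str | None = None
    gene_sets: str | None = None
    directions: str | None = None
    epitopes: dict = field(default_factory=dict)  # allele -> peptide list path
    pep_up: float = 2.0
    pep_down: float = 0.5
    int_up: float = 1.5
    int_down: float = 0.67
    strong_rank: float = 2.0
    altered_log2: float = 0.6
    fdr_max: float = 0.01
    min_unique: int = 2
    alpha: float = 0.05
    n_background: int = 2000
    seed: int = 0

    def validate(self) -> None:
        for name in ("pep_up", "pep_down", "int_up", "int_down",
                     "strong_rank", "altered_log2", "fdr_max", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cutoff {name} must be positive")
        for name in ("peptide_table", "proteome_table"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name}: {path} does not exist")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        stray = set(data) - known
        if stray:
            raise ValueError(f"unknown config keys: {sorted(stray)}")
        return cls(**data)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the stage TSVs plus summary.json.

    The interactome and integration stages are skipped (marked absent in
    the summary) when their inputs are missing or empty; the peptidome
    outputs are produced regardless.
    """
    cfg = config
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    summary: dict = {}

    # ---- quantify: proteome first, its factors anchor the run ----------
    prot_table = hio.read_protein_table(cfg.proteome_table)
    # median-ratio centering on the proteome bulk: robust to the
    # heavy-tailed differential species that bias channel sums
    factors = quantify.normalization_factors(prot_table, method="median")
    log.info("normalization factors from proteome: %s",
             {k: round(v, 4) for k, v in factors.items()})
    prot_rep = quantify.compute_ratios(
        quantify.normalize_channels(prot_table, factors), "protein")
    prot_quant = quantify.aggregate_replicates(prot_rep, "protein")
    gene_map = (prot_table.drop_duplicates("protein")
                .set_index("protein")["gene"])
    prot_quant["gene"] = prot_quant["protein"].map(gene_map)
    _write_quant(prot_quant, "protein", os.path.join(cfg.outdir, "proteome_quant.tsv"))
    summary["proteome"] = {"n_quantified": len(prot_quant)}

    # ---- peptidome ------------------------------------------------------
    pep_table = hio.read_peptide_table(cfg.peptide_table)
    pep_norm = quantify.normalize_channels(pep_table, factors)
    pep_rep = quantify.compute_ratios(pep_norm, "peptide")
    pep_quant = quantify.aggregate_replicates(pep_rep, "peptide")
    prot_of_pep = (pep_table.drop_duplicates("peptide")
                   .set_index("peptide")["proteins"])
    pep_quant["proteins"] = pep_quant["peptide"].map(prot_of_pep)
    _write_quant(pep_quant, "peptide", os.path.join(cfg.outdir, "peptide_quant.tsv"))

    identified = pep_table["peptide"].unique()
    cascade = peptidome.discovery_pipeline(identified, pep_quant)
    log.info("discovery cascade: %d identified -> %d K/R -> %d quantified "
             "-> %d 8-14mer", cascade.n_identified, cascade.n_labelable,
             cascade.n_quantified, cascade.n_8_14)
    cascade.as_frame().to_csv(os.path.join(cfg.outdir, "cascade.tsv"),
                              sep="\t", index=False)

    counts, mode = peptidome.length_distribution(cascade.quantified)
    nine_mers = [p for p in cascade.quantified if len(p) == 9]
    label_profile = (peptidome.label_position_profile(nine_mers)
                     if nine_mers else None)
    if label_profile is not None:
        label_profile.to_csv(os.path.join(cfg.outdir, "label_positions.tsv"),
                             sep="\t", index=False)

    final_quant = pep_quant[pep_quant["peptide"].isin(cascade.in_8_14)]
    calls, diff_summary = peptidome.call_differential_presentation(
        final_quant, up=cfg.pep_up, down=cfg.pep_down)
    calls.drop(columns=["replicate_log2"], errors="ignore").to_csv(
        os.path.join(cfg.outdir, "peptide_calls.tsv"), sep="\t",
        index=False, na_rep="")
    shift = peptidome.global_shift(final_quant) if len(final_quant) else None
    try:
        corr = quantify.replicate_correlation(pep_rep, "peptide")
        corr_min = float(np.nanmin(corr.values[~np.eye(len(corr), dtype=bool)]))
    except ValueError:
        corr_min = None
    summary["peptidome"] = {
        "cascade": {
            "n_identified": cascade.n_identified,
            "n_labelable": cascade.n_labelable,
            "n_quantified": cascade.n_quantified,
            "n_8_14": cascade.n_8_14,
        },
        "length_mode": mode,
        "length_counts": {str(k): v for k, v in counts.items()},
        "differential": diff_summary,
        "global_shift": shift,
        "min_replicate_correlation": corr_min,
    }

    # ---- binder calling -------------------------------------------------
    if cfg.fasta and cfg.epitopes:
        proteins = hio.read_fasta(cfg.fasta)
        pwms, backgrounds = [], {}
        all_epitopes: list[str] = []
        for allele, path in sorted(cfg.epitopes.items()):
            eps = hio.read_peptide_list(path)
            pwm = motif.build_pwm(eps, allele=allele,
                                  background=None, pseudocount=1.0)
            pwms.append(pwm)
            backgrounds[allele] = motif.background_scores(
                pwm, proteins, n=cfg.n_background, seed=cfg.seed)
            all_epitopes.extend(eps)
        callable_peps = [p for p in cascade.in_8_14]
        binder_calls, strong_counts = motif.call_binders(
            callable_peps, pwms, backgrounds, strong=cfg.strong_rank)
        binder_calls.to_csv(os.path.join(cfg.outdir, "binder_calls.tsv"),
                            sep="\t", index=False, na_rep="")
        covered = binder_calls[binder_calls["covered"]]
        n_strong = int((covered["class"] == "strong").sum())
        summary["binders"] = {
            "n_scored": len(covered),
            "n_strong": n_strong,
            "strong_fraction": (n_strong / len(covered)) if len(covered) else None,
            "strong_by_length": dict(zip(strong_counts["length"].astype(str),
                                         strong_counts["n_strong"])),
        }
        ref_9 = [e for e in all_epitopes if len(e) == 9]
        if nine_mers and ref_9:
            z = motif.motif_difference(nine_mers, ref_9)
            hio.write_pwm(z, os.path.join(cfg.outdir, "motif_difference_z.tsv"))
            summary["binders"]["motif_max_abs_z"] = float(np.abs(z.values).max())
    else:
        summary["binders"] = None

    # ---- interactome ----------------------------------------------------
    int_table = None
    if cfg.interactome_table and os.path.exists(cfg.interactome_table):
        int_table = hio.read_protein_table(cfg.interactome_table)
    if int_table is not None and len(int_table):
        contaminants = (hio.read_accession_list(cfg.contaminants)
                        if cfg.contaminants else [])
        hci = interactome.filter_hci(int_table, contaminants,
                                     fdr_max=cfg.fdr_max,
                                     min_unique=cfg.min_unique)
        hci.to_csv(os.path.join(cfg.outdir, "hci.tsv"), sep="\t", index=False)
        log.info("HCI filter: %d proteins in -> %d HCIs",
                 int_table["protein"].nunique(), len(hci))
        hci_set = set(hci["protein"])
        int_sub = int_table[int_table["protein"].isin(hci_set)]
        int_rep = quantify.compute_ratios(
            quantify.normalize_channels(int_sub, factors), "protein")
        int_quant = quantify.aggregate_replicates(int_rep, "protein")
        int_calls, int_summary = interactome.call_differential_interaction(
            int_quant, up=cfg.int_up, down=cfg.int_down, alpha=cfg.alpha)
        int_calls.drop(columns=["replicate_log2"], errors="ignore").to_csv(
            os.path.join(cfg.outdir, "interaction_calls.tsv"), sep="\t",
            index=False, na_rep="")
        summary["interactome"] = {
            "n_input_proteins": int(int_table["protein"].nunique()),
            "n_hci": len(hci),
            "differential": int_summary,
        }
        if cfg.known_interactors:
            known = hio.read_accession_list(cfg.known_interactors)
            summary["interactome"]["known_recovery"] = \
                interactome.known_recovery(hci_set, known)
    else:
        int_quant = None
        summary["interactome"] = None

    # ---- integration ----------------------------------------------------
    integration: dict = {}
    try:
        pp = integrate.peptide_protein_correlation(pep_quant, prot_quant)
        integration["peptide_protein"] = {k: pp[k] for k in
                                          ("slope", "r", "p", "n")}
    except ValueError as exc:
        integration["peptide_protein"] = None
        log.info("peptide-protein correlation skipped: %s", exc)
    altered = integrate.select_altered(prot_quant, log2_cutoff=cfg.altered_log2)
    integration["n_altered_proteins"] = len(altered)
    if cfg.gene_sets:
        gene_sets = hio.read_gmt(cfg.gene_sets)
        universe = set(prot_quant["gene"].dropna())
        query = set(altered) & universe
        enr = integrate.enrich_gene_sets(query, gene_sets, universe)
        if cfg.directions:
            directions = hio.read_directions(cfg.directions)
            log2_by_gene = dict(zip(prot_quant["gene"], prot_quant["log2_ratio"]))
            enr = integrate.add_activation_zscores(
                enr, gene_sets, log2_by_gene, directions,
                log2_cutoff=cfg.altered_log2)
        enr.to_csv(os.path.join(cfg.outdir, "enrichment.tsv"), sep="\t",
                   index=False, na_rep="")
        sig = enr[enr["p_adj"] < 0.05]
        integration["n_enriched_sets"] = len(sig)
    if int_quant is not None:
        try:
            pi = integrate.proteome_interactome_correlation(prot_quant, int_quant)
            integration["proteome_interactome"] = pi
        except ValueError as exc:
            integration["proteome_interactome"] = None
            log.info("proteome-interactome correlation skipped: %s", exc)
    else:
        integration["proteome_interactome"] = None
    summary["integration"] = integration

    with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    return summary


def _write_quant(quant: pd.DataFrame, key: str, path: str) -> None:
    cols = [key, "ratio_hl", "log2_ratio", "capped", "p_value", "n_reps"]
    quant[cols].to_csv(path, sep="\t", index=False, na_rep="")
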