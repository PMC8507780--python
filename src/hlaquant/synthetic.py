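"""Synthetic SILAC experiment generator with planted ground truth.

Emulates one isogenic cell-line pair (parental = light, resistant =
heavy) measured in replicate: an HLA class I immunopeptidome table with
a 9-mer-dominant length distribution, anchor-constrained binding motifs
and a planted global downshift of the heavy channel; a whole-cell
proteome table; and an AP-MS class I interactome table containing
contaminants, sub-threshold identifications and planted differential
interactors.  Every planted quantity is recorded in a truth object so
each downstream stage can be tested against known answers.

Peptides are sampled from per-allele position-weight matrices whose
anchor positions (2 and C-terminal) prefer hydrophobic residues and
deplete Lys/Arg, then spliced into the synthetic reference proteome so
the peptide -> source-protein mapping is verifiable by string search.
Intensities are log-normal: heavy = light x planted ratio x a shared
per-replicate technical channel-imbalance factor x multiplicative noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from . import io as hio
from .motif import AMINO_ACIDS, AllelePWM
from .peptidome import has_kr
from .quantify import CAP_HEAVY_ONLY, CAP_LIGHT_ONLY

#: approximate human-proteome residue frequencies (normalized below)
_HUMAN_AA_FREQ = {
    "A": 8.3, "R": 5.5, "N": 4.0, "D": 5.4, "C": 1.4, "Q": 4.8, "E": 7.2,
    "G": 7.1, "H": 2.2, "I": 4.3, "L": 10.0, "K": 5.7, "M": 2.1, "F": 3.6,
    "P": 6.3, "S": 8.3, "T": 5.3, "W": 1.1, "Y": 2.7, "V": 6.0,
}

DEFAULT_LENGTH_WEIGHTS = {
    8: 0.09, 9: 0.43, 10: 0.17, 11: 0.10, 12: 0.07,
    13: 0.04, 14: 0.03, 15: 0.04, 16: 0.03,
}

#: anchor preferences of the two synthetic alleles (position 2, C-term)
_ALLELE_ANCHORS = {
    "HLA-A*SYN01": ({"L": 0.55, "M": 0.20, "I": 0.10, "V": 0.05},
                    {"V": 0.40, "L": 0.30, "I": 0.15, "F": 0.05}),
    "HLA-B*SYN02": ({"P": 0.60, "A": 0.15, "S": 0.10},
                    {"L": 0.40, "F": 0.25, "Y": 0.15, "M": 0.05}),
}
#: mild per-position preferences cycled over non-anchor positions
_PREF_CYCLE = {
    "HLA-A*SYN01": "AEGSTDNQ",
    "HLA-B*SYN02": "GQETANDS",
}


def human_background() -> pd.Series:
    s = pd.Series(_HUMAN_AA_FREQ, dtype=float).reindex(list(AMINO_ACIDS))
    return s / s.sum()


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic isogenic cell-line pair."""

    n_peptides: int = 1200
    n_proteins: int = 5000
    n_replicates: int = 3
    length_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS))
    frac_kr: float = 0.65
    global_log2_shift: float = -0.5
    frac_reduced: float = 0.54
    frac_increased: float = 0.05
    frac_heavy_only: float = 0.02
    frac_light_only: float = 0.02
    frac_unquantified: float = 0.33
    noise_sd: float = 0.2
    channel_imbalance_sd: float = 0.10
    contaminant_rate: float = 0.10
    n_interactors: int = 500
    frac_interactor_highfdr: float = 0.10
    frac_interactor_single_peptide: float = 0.10
    frac_interaction_increased: float = 0.10
    frac_interaction_decreased: float = 0.10
    interactome_coupling: float = 0.6
    proteome_frac_up: float = 0.10
    proteome_frac_down: float = 0.10
    n_known: int = 150
    known_recovery_frac: float = 0.40
    n_gene_sets: int = 20
    n_epitopes_per_allele: int = 200
    seed: int = 0

    def validate(self) -> None:
        fracs = [
            "frac_kr", "frac_reduced", "frac_increased", "frac_heavy_only",
            "frac_light_only", "frac_unquantified", "contaminant_rate",
            "frac_interactor_highfdr", "frac_interactor_single_peptide",
            "frac_interaction_increased", "frac_interaction_decreased",
            "proteome_frac_up", "proteome_frac_down", "known_recovery_frac",
        ]
        for name in fracs:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"configuration error: {name}={v} not in [0,1]")
        if self.n_peptides < 0:
            raise ValueError("configuration error: n_peptides < 0")
        if self.n_proteins < 1:
            raise ValueError("configuration error: n_proteins must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("configuration error: n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("configuration error: noise_sd < 0")
        total = sum(self.length_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"configuration error: length_weights sum to {total}, not 1")
        if any((not isinstance(k, int)) or k < 8 for k in self.length_weights):
            raise ValueError("configuration error: peptide lengths must be >= 8")
        if self.frac_reduced + self.frac_increased > 1.0:
            raise ValueError(
                "configuration error: frac_reduced + frac_increased > 1")
        if self.frac_heavy_only > self.frac_increased:
            raise ValueError(
                "configuration error: frac_heavy_only exceeds frac_increased")
        if self.frac_light_only > self.frac_reduced:
            raise ValueError(
                "configuration error: frac_light_only exceeds frac_reduced")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = {f.name for f in dc_fields(cls)}
        stray = set(d) - known
        if stray:
            raise ValueError(f"unknown generator options: {sorted(stray)}")
        if "length_weights" in d:
            d = dict(d)
            d["length_weights"] = {int(k): float(v)
                                   for k, v in d["length_weights"].items()}
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-peptide and per-interactor labels."""

    peptides: pd.DataFrame
    interactors: pd.DataFrame
    proteome: pd.DataFrame


@dataclass
class SyntheticExperiment:
    """All tables and side files for one synthetic cell-line pair."""

    config: GeneratorConfig
    peptide_table: pd.DataFrame
    proteome_table: pd.DataFrame
    interactome_table: pd.DataFrame
    truth: SyntheticTruth
    proteins: dict
    genes: dict
    contaminants: list
    known_interactors: list
    gene_sets: dict
    directions: pd.DataFrame
    pwms: dict
    epitopes: dict
    imbalance: dict


def make_allele_pwm(allele: str, length: int,
                    background: pd.Series | None = None) -> AllelePWM:
    """Anchor-constrained PWM for a synthetic allele at a given length.

    Anchor positions 2 and C-terminal put most of their mass on the
    allele's preferred hydrophobic residues and deplete K/R; non-anchor
    positions mix the background with a mild per-position preference so
    true binders separate from random proteome windows.
    """
    if allele not in _ALLELE_ANCHORS:
        raise ValueError(f"unknown synthetic allele {allele!r}")
    if background is None:
        background = human_background()
    anchor2, anchor_c = _ALLELE_ANCHORS[allele]
    cols = []
    cycle = _PREF_CYCLE[allele]
    for pos in range(length):
        if pos == 1 or pos == length - 1:
            prefs = anchor2 if pos == 1 else anchor_c
            col = pd.Series(0.0, index=list(AMINO_ACIDS))
            for res, p in prefs.items():
                col[res] = p
            # residual mass follows the background over non-preferred,
            # non-K/R residues; K/R near-absent at anchors
            col["K"] = col["R"] = 0.003
            rest = [a for a in AMINO_ACIDS if a not in prefs and a not in "KR"]
            residual = 1.0 - col.sum()
            bg_rest = background[rest] / background[rest].sum()
            col[rest] = residual * bg_rest
        else:
            pref = cycle[pos % len(cycle)]
            col = 0.60 * background.copy()
            col[pref] += 0.40
        cols.append(col / col.sum())
    freq = pd.concat(cols, axis=1)
    freq.columns = range(1, length + 1)
    return AllelePWM(allele=allele, length=length, freq=freq,
                     background=background)


def sample_binder_peptides(pwm: AllelePWM, n: int, seed=0) -> list[str]:
    """Draw n peptides residue-by-residue from the PWM frequency columns."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    columns = []
    for pos in range(1, pwm.length + 1):
        p = pwm.freq[pos].to_numpy()
        columns.append(rng.choice(aas, size=n, p=p / p.sum()))
    mat = np.stack(columns, axis=1)
    return ["".join(row) for row in mat]


def _enforce_kr(peptide: str, want_kr: bool, pwm: AllelePWM,
                rng: np.random.Generator) -> str:
    """Force or remove K/R content without touching motif anchors when
    adding (K/R is added at a non-anchor position only)."""
    length = len(peptide)
    if want_kr and not has_kr(peptide):
        non_anchor = [i for i in range(length) if i not in (1, length - 1)]
        pos = int(rng.choice(non_anchor))
        res = "K" if rng.random() < 0.5 else "R"
        return peptide[:pos] + res + peptide[pos + 1:]
    if not want_kr and has_kr(peptide):
        out = list(peptide)
        for i, res in enumerate(out):
            if res in "KR":
                col = pwm.freq[i + 1].drop(["K", "R"])
                p = col.to_numpy()
                out[i] = str(rng.choice(col.index.to_numpy(), p=p / p.sum()))
        return "".join(out)
    return peptide


def _sample_peptides(cfg: GeneratorConfig, pwms_by_len: dict,
                     rng: np.random.Generator) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Unique peptides with lengths, alleles and enforced K/R fractions."""
    allele_names = sorted(pwms_by_len[min(pwms_by_len)].keys())
    lengths = rng.choice(sorted(cfg.length_weights),
                         p=[cfg.length_weights[k]
                            for k in sorted(cfg.length_weights)],
                         size=cfg.n_peptides)
    alleles = rng.integers(0, len(allele_names), size=cfg.n_peptides)
    want_kr = rng.random(cfg.n_peptides) < cfg.frac_kr
    peptides: list[str] = [""] * cfg.n_peptides
    seen: set[str] = set()
    for i in range(cfg.n_peptides):
        pwm = pwms_by_len[int(lengths[i])][allele_names[alleles[i]]]
        for _attempt in range(100):
            pep = sample_binder_peptides(pwm, 1, rng)[0]
            pep = _enforce_kr(pep, bool(want_kr[i]), pwm, rng)
            if pep not in seen:
                break
        seen.add(pep)
        peptides[i] = pep
    allele_labels = np.array([allele_names[a] for a in alleles])
    return peptides, lengths.astype(int), allele_labels


def _splice_peptides(protein_seqs: list[str], peptide_protein: np.ndarray,
                     peptides: list[str], rng: np.random.Generator) -> list[str]:
    """Embed each peptide into its source protein at a non-overlapping
    random offset so the mapping is verifiable by substring search."""
    by_protein: dict[int, list[int]] = {}
    for pep_idx, prot_idx in enumerate(peptide_protein):
        by_protein.setdefault(int(prot_idx), []).append(pep_idx)
    seqs = list(protein_seqs)
    for prot_idx, pep_indices in by_protein.items():
        seq = seqs[prot_idx]
        taken: list[tuple[int, int]] = []
        for pep_idx in pep_indices:
            pep = peptides[pep_idx]
            span = len(pep)
            placed = False
            for _try in range(200):
                start = int(rng.integers(0, len(seq) - span + 1))
                if all(start + span <= s or start >= e for s, e in taken):
                    taken.append((start, start + span))
                    seq = seq[:start] + pep + seq[start + span:]
                    placed = True
                    break
            if not placed:  # pathological overcrowding: extend the protein
                taken.append((len(seq), len(seq) + span))
                seq = seq + pep
        seqs[prot_idx] = seq
    return seqs


def _assign_groups(n_q: int, cfg: GeneratorConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Differential group and detection channel for quantifiable peptides.

    One-channel peptides are carved out of the increased/reduced groups
    first (their capped ratios 256/0.01 count toward those calls), so
    the pipeline's observed fractions match the configured fractions.
    """
    n_inc = round(cfg.frac_increased * n_q)
    n_red = round(cfg.frac_reduced * n_q)
    n_ho = min(round(cfg.frac_heavy_only * n_q), n_inc)
    n_lo = min(round(cfg.frac_light_only * n_q), n_red)
    group = np.array(["unchanged"] * n_q, dtype=object)
    channel = np.array(["both"] * n_q, dtype=object)
    order = rng.permutation(n_q)
    inc_idx = order[:n_inc]
    red_idx = order[n_inc:n_inc + n_red]
    group[inc_idx] = "increased"
    group[red_idx] = "reduced"
    channel[inc_idx[:n_ho]] = "heavy_only"
    channel[red_idx[:n_lo]] = "light_only"
    return group, channel


def _true_log2(group: np.ndarray, channel: np.ndarray, cfg: GeneratorConfig,
               rng: np.random.Generator) -> np.ndarray:
    """Planted true log2 H/L per quantifiable peptide.

    Differential groups sit beyond the 2.0/0.5 cutoffs with a safety
    margin (|log2| >= 1.3) and the unchanged bulk is centered on the
    global shift and clipped well inside the cutoffs, so planted labels
    stay identifiable under replicate noise.
    """
    n = len(group)
    out = np.empty(n)
    inc = group == "increased"
    red = group == "reduced"
    unchanged = ~(inc | red)
    out[inc] = 1.3 + rng.exponential(0.8, size=int(inc.sum()))
    out[red] = -1.3 - rng.exponential(0.8, size=int(red.sum()))
    out[unchanged] = np.clip(
        rng.normal(cfg.global_log2_shift, 0.2, size=int(unchanged.sum())),
        -0.75, 0.75)
    out[channel == "heavy_only"] = np.log2(CAP_HEAVY_ONLY)
    out[channel == "light_only"] = np.log2(CAP_LIGHT_ONLY)
    return out


def generate_experiment(config: GeneratorConfig) -> SyntheticExperiment:
    """Generate one complete synthetic SILAC experiment with planted truth.

    Deterministic given the config (including its seed): identical
    configs yield byte-identical tables.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    background = human_background()
    reps = [f"R{r}" for r in range(1, cfg.n_replicates + 1)]
    imbalance = {rep: float(2.0 ** rng.normal(0.0, cfg.channel_imbalance_sd))
                 for rep in reps}

    # ---- reference proteome --------------------------------------------
    accs = [f"SYNP{i:05d}" for i in range(cfg.n_proteins)]
    gene_names = [f"GSYN{i:05d}" for i in range(cfg.n_proteins)]
    genes = dict(zip(accs, gene_names))
    prot_lengths = rng.integers(150, 301, size=cfg.n_proteins)
    aas = np.array(list(AMINO_ACIDS))
    flat = rng.choice(aas, size=int(prot_lengths.sum()),
                      p=background.to_numpy())
    protein_seqs = []
    offset = 0
    for ln in prot_lengths:
        protein_seqs.append("".join(flat[offset:offset + ln]))
        offset += ln

    # ---- proteome truth -------------------------------------------------
    n_up = round(cfg.proteome_frac_up * cfg.n_proteins)
    n_down = round(cfg.proteome_frac_down * cfg.n_proteins)
    order = rng.permutation(cfg.n_proteins)
    prot_label = np.array(["unchanged"] * cfg.n_proteins, dtype=object)
    prot_label[order[:n_up]] = "up"
    prot_label[order[n_up:n_up + n_down]] = "down"
    prot_log2 = np.clip(rng.normal(0.0, 0.22, size=cfg.n_proteins), -0.55, 0.55)
    prot_log2[prot_label == "up"] = rng.uniform(0.7, 2.0, size=n_up)
    prot_log2[prot_label == "down"] = -rng.uniform(0.7, 2.0, size=n_down)

    # ---- allele PWMs and training epitopes ------------------------------
    lengths_needed = sorted(set(cfg.length_weights) | {9})
    pwms_by_len: dict[int, dict[str, AllelePWM]] = {
        ln: {name: make_allele_pwm(name, ln, background)
             for name in sorted(_ALLELE_ANCHORS)}
        for ln in lengths_needed
    }
    epitopes = {name: sample_binder_peptides(pwms_by_len[9][name],
                                             cfg.n_epitopes_per_allele, rng)
                for name in sorted(_ALLELE_ANCHORS)}

    # ---- peptides -------------------------------------------------------
    if cfg.n_peptides > 0:
        peptides, pep_lengths, pep_alleles = _sample_peptides(
            cfg, pwms_by_len, rng)
        pep_protein_idx = rng.integers(0, cfg.n_proteins, size=cfg.n_peptides)
        protein_seqs = _splice_peptides(protein_seqs, pep_protein_idx,
                                        peptides, rng)
        labelable = np.array([has_kr(p) for p in peptides])
        unquantified = labelable & (rng.random(cfg.n_peptides)
                                    < cfg.frac_unquantified)
        quantifiable = labelable & ~unquantified
        q_idx = np.flatnonzero(quantifiable)
        group_q, channel_q = _assign_groups(len(q_idx), cfg, rng)
        log2_q = _true_log2(group_q, channel_q, cfg, rng)
        group = np.array(["none"] * cfg.n_peptides, dtype=object)
        channel = np.array(["none"] * cfg.n_peptides, dtype=object)
        true_log2 = np.full(cfg.n_peptides, np.nan)
        group[q_idx] = group_q
        channel[q_idx] = channel_q
        true_log2[q_idx] = log2_q
        # non-labelable peptides carry no heavy label: light channel only
        channel[~labelable] = "light_no_label"
    else:
        peptides, pep_lengths, pep_alleles = [], np.zeros(0, int), np.zeros(0)
        pep_protein_idx = np.zeros(0, int)
        labelable = np.zeros(0, bool)
        unquantified = np.zeros(0, bool)
        quantifiable = np.zeros(0, bool)
        group = np.zeros(0, object)
        channel = np.zeros(0, object)
        true_log2 = np.zeros(0)

    # ---- peptide intensity table ---------------------------------------
    base_l = rng.normal(21.0, 1.5, size=cfg.n_peptides)
    pep_rows = []
    for i, pep in enumerate(peptides):
        acc = accs[pep_protein_idx[i]]
        n_kr = sum(pep.count(r) for r in "KR")
        fdr = float(rng.uniform(0.0005, 0.009))
        for rep in reps:
            light = np.nan
            heavy = np.nan
            if labelable[i] and unquantified[i]:
                light = heavy = np.nan  # identified, never MS1-quantified
            elif not labelable[i]:
                light = float(2.0 ** (base_l[i] + rng.normal(0, 0.3)))
            else:
                lvl = base_l[i] + rng.normal(0, 0.3)
                if channel[i] == "heavy_only":
                    heavy = float(2.0 ** (lvl + rng.normal(0, cfg.noise_sd))
                                  * imbalance[rep])
                elif channel[i] == "light_only":
                    light = float(2.0 ** lvl)
                else:
                    light = float(2.0 ** lvl)
                    heavy = float(light * 2.0 ** (true_log2[i]
                                                  + rng.normal(0, cfg.noise_sd))
                                  * imbalance[rep])
            pep_rows.append({
                "peptide": pep, "proteins": acc, "n_kr": n_kr,
                "replicate": rep, "intensity_L": light, "intensity_H": heavy,
                "id_fdr": fdr,
            })
    peptide_table = pd.DataFrame(pep_rows, columns=hio.PEPTIDE_COLUMNS)

    truth_peptides = pd.DataFrame({
        "peptide": peptides,
        "protein": [accs[j] for j in pep_protein_idx],
        "allele": pep_alleles,
        "length": pep_lengths,
        "labelable": labelable,
        "quantifiable": quantifiable,
        "label": group,
        "channel": channel,
        "true_log2": true_log2,
        "true_ratio": 2.0 ** true_log2,
    })

    # ---- whole-proteome table ------------------------------------------
    prot_base = rng.normal(20.0, 1.2, size=cfg.n_proteins)
    prot_unique = 2 + rng.poisson(6, size=cfg.n_proteins)
    prot_fdr = rng.uniform(0.0005, 0.009, size=cfg.n_proteins)
    prot_rows = []
    for i, acc in enumerate(accs):
        for rep in reps:
            light = float(2.0 ** (prot_base[i] + rng.normal(0, 0.3)))
            heavy = float(light * 2.0 ** (prot_log2[i]
                                          + rng.normal(0, cfg.noise_sd))
                          * imbalance[rep])
            prot_rows.append({
                "protein": acc, "gene": gene_names[i], "replicate": rep,
                "intensity_L": light, "intensity_H": heavy,
                "unique_peptides": int(prot_unique[i]),
                "id_fdr": float(prot_fdr[i]),
            })
    proteome_table = pd.DataFrame(prot_rows, columns=hio.PROTEIN_COLUMNS)
    truth_proteome = pd.DataFrame({
        "protein": accs, "gene": gene_names,
        "label": prot_label, "true_log2": prot_log2,
    })

    # ---- interactome ----------------------------------------------------
    n_cont = round(cfg.contaminant_rate * cfg.n_interactors)
    n_real = min(cfg.n_interactors - n_cont, cfg.n_proteins)
    cont_pool = [f"CRAP{i:04d}" for i in range(max(30, n_cont))]
    cont_genes = {acc: f"CRAPG{i:04d}" for i, acc in enumerate(cont_pool)}
    cont_rows_accs = list(rng.choice(cont_pool, size=n_cont, replace=False)) \
        if n_cont else []
    real_idx = rng.choice(cfg.n_proteins, size=n_real, replace=False)

    n_highfdr = round(cfg.frac_interactor_highfdr * n_real)
    n_single = round(cfg.frac_interactor_single_peptide * n_real)
    real_order = rng.permutation(n_real)
    int_flag = np.array(["hci"] * n_real, dtype=object)
    int_flag[real_order[:n_highfdr]] = "high_fdr"
    int_flag[real_order[n_highfdr:n_highfdr + n_single]] = "single_peptide"
    hci_mask = int_flag == "hci"
    hci_pos = np.flatnonzero(hci_mask)
    n_hci = len(hci_pos)

    # differential interactions align with differential protein expression
    # (the planted shared proteome/interactome signal)
    n_i_inc = round(cfg.frac_interaction_increased * n_hci)
    n_i_dec = round(cfg.frac_interaction_decreased * n_hci)
    shuffled = list(rng.permutation(hci_pos))
    up_pool = [p for p in shuffled if prot_label[real_idx[p]] == "up"]
    down_pool = [p for p in shuffled if prot_label[real_idx[p]] == "down"]
    inc_set = up_pool[:n_i_inc]
    dec_set = down_pool[:n_i_dec]
    spare = [p for p in shuffled
             if p not in set(inc_set) and p not in set(dec_set)]
    if len(inc_set) < n_i_inc:
        take = n_i_inc - len(inc_set)
        inc_set, spare = inc_set + spare[:take], spare[take:]
    if len(dec_set) < n_i_dec:
        take = n_i_dec - len(dec_set)
        dec_set, spare = dec_set + spare[:take], spare[take:]
    int_group = np.array(["unchanged"] * n_real, dtype=object)
    int_group[list(inc_set)] = "increased"
    int_group[list(dec_set)] = "decreased"
    int_group[~hci_mask] = "none"

    int_log2 = np.clip(
        cfg.interactome_coupling * prot_log2[real_idx]
        + rng.normal(0, 0.25, size=n_real), -0.3, 0.3)
    inc_mask = int_group == "increased"
    dec_mask = int_group == "decreased"
    int_log2[inc_mask] = rng.uniform(0.9, 2.2, size=int(inc_mask.sum()))
    int_log2[dec_mask] = -rng.uniform(0.9, 2.2, size=int(dec_mask.sum()))

    int_rows = []
    truth_int_rows = []
    int_base = rng.normal(19.0, 1.2, size=n_real)
    for j in range(n_real):
        acc = accs[real_idx[j]]
        gene = gene_names[real_idx[j]]
        if int_flag[j] == "high_fdr":
            fdr = float(rng.uniform(0.011, 0.08))
        else:
            fdr = float(rng.uniform(0.0005, 0.009))
        unique = 1 if int_flag[j] == "single_peptide" \
            else int(2 + rng.poisson(5))
        for rep in reps:
            light = float(2.0 ** (int_base[j] + rng.normal(0, 0.3)))
            heavy = float(light * 2.0 ** (int_log2[j]
                                          + rng.normal(0, cfg.noise_sd))
                          * imbalance[rep])
            int_rows.append({
                "protein": acc, "gene": gene, "replicate": rep,
                "intensity_L": light, "intensity_H": heavy,
                "unique_peptides": unique, "id_fdr": fdr,
            })
        truth_int_rows.append({
            "protein": acc, "gene": gene, "flag": int_flag[j],
            "contaminant": False, "hci": bool(int_flag[j] == "hci"),
            "label": int_group[j], "true_log2": float(int_log2[j]),
        })
    for acc in cont_rows_accs:
        fdr = float(rng.uniform(0.0005, 0.009))
        unique = int(2 + rng.poisson(8))
        base = float(rng.normal(20.0, 1.0))
        for rep in reps:
            light = float(2.0 ** (base + rng.normal(0, 0.3)))
            heavy = float(light * 2.0 ** rng.normal(0, cfg.noise_sd)
                          * imbalance[rep])
            int_rows.append({
                "protein": acc, "gene": cont_genes[acc], "replicate": rep,
                "intensity_L": light, "intensity_H": heavy,
                "unique_peptides": unique, "id_fdr": fdr,
            })
        truth_int_rows.append({
            "protein": acc, "gene": cont_genes[acc], "flag": "contaminant",
            "contaminant": True, "hci": False, "label": "none",
            "true_log2": np.nan,
        })
    interactome_table = pd.DataFrame(int_rows, columns=hio.PROTEIN_COLUMNS)
    truth_interactors = pd.DataFrame(
        truth_int_rows, columns=["protein", "gene", "flag", "contaminant",
                                 "hci", "label", "true_log2"])

    # ---- known interactors ---------------------------------------------
    hci_accs = sorted(truth_interactors.loc[truth_interactors["hci"],
                                            "protein"])
    n_rec = min(round(cfg.known_recovery_frac * cfg.n_known), len(hci_accs))
    recovered = list(rng.choice(hci_accs, size=n_rec, replace=False)) \
        if n_rec else []
    unrecovered = [f"KNWN{i:04d}" for i in range(cfg.n_known - n_rec)]
    known_interactors = sorted(recovered) + unrecovered

    # ---- gene sets and direction annotations ---------------------------
    gene_sets: dict[str, dict] = {}
    dir_rows = []
    up_genes = [gene_names[i] for i in np.flatnonzero(prot_label == "up")]
    down_genes = [gene_names[i] for i in np.flatnonzero(prot_label == "down")]
    all_genes = list(gene_names)
    n_planted = min(3, cfg.n_gene_sets // 2)
    for s in range(cfg.n_gene_sets):
        if s < n_planted and len(up_genes) >= 10:
            core = list(rng.choice(up_genes, size=10, replace=False))
            name, desc = f"SET_ACT_{s + 1}", "planted activated pathway"
        elif s < 2 * n_planted and len(down_genes) >= 10:
            core = list(rng.choice(down_genes, size=10, replace=False))
            name, desc = f"SET_INH_{s + 1 - n_planted}", "planted inhibited pathway"
        else:
            core = []
            name, desc = f"SET_RND_{s + 1}", "random background set"
        n_fill = int(rng.integers(12, 25))
        fill = list(rng.choice(all_genes, size=n_fill, replace=False))
        members = sorted(set(core + fill))
        gene_sets[name] = {"description": desc, "genes": members}
        for g in members:
            if name.startswith("SET_RND"):
                direction = int(rng.choice([-1, 1]))
            else:
                direction = 1
            dir_rows.append({"set": name, "gene": g, "direction": direction})
    directions = pd.DataFrame(dir_rows, columns=["set", "gene", "direction"])

    proteins = dict(zip(accs, protein_seqs))
    return SyntheticExperiment(
        config=cfg,
        peptide_table=peptide_table,
        proteome_table=proteome_table,
        interactome_table=interactome_table,
        truth=SyntheticTruth(peptides=truth_peptides,
                             interactors=truth_interactors,
                             proteome=truth_proteome),
        proteins=proteins,
        genes=genes,
        contaminants=sorted(cont_pool),
        known_interactors=known_interactors,
        gene_sets=gene_sets,
        directions=directions,
        pwms=pwms_by_len,
        epitopes=epitopes,
        imbalance=imbalance,
    )


def write_fixtures(experiment: SyntheticExperiment, directory) -> dict:
    """Write all experiment files to a directory; returns name -> path.

    Re-reading the TSV/FASTA/list files reproduces the in-memory tables.
    """
    import os

    os.makedirs(directory, exist_ok=True)
    paths = {
        "peptides": os.path.join(directory, "peptides.tsv"),
        "proteome": os.path.join(directory, "proteome.tsv"),
        "interactome": os.path.join(directory, "interactome.tsv"),
        "fasta": os.path.join(directory, "reference.fasta"),
        "contaminants": os.path.join(directory, "contaminants.txt"),
        "known_interactors": os.path.join(directory, "known_interactors.txt"),
        "gene_sets": os.path.join(directory, "gene_sets.gmt"),
        "directions": os.path.join(directory, "directions.tsv"),
        "truth_peptides": os.path.join(directory, "truth_peptides.tsv"),
        "truth_interactors": os.path.join(directory, "truth_interactors.tsv"),
        "truth_proteome": os.path.join(directory, "truth_proteome.tsv"),
    }
    hio.write_peptide_table(experiment.peptide_table, paths["peptides"])
    hio.write_protein_table(experiment.proteome_table, paths["proteome"])
    hio.write_protein_table(experiment.interactome_table, paths["interactome"])
    hio.write_fasta(experiment.proteins, paths["fasta"])
    hio.write_accession_list(experiment.contaminants, paths["contaminants"])
    hio.write_accession_list(experiment.known_interactors,
                             paths["known_interactors"])
    hio.write_gmt(experiment.gene_sets, paths["gene_sets"])
    hio.write_directions(experiment.directions, paths["directions"])
    experiment.truth.peptides.to_csv(paths["truth_peptides"], sep="\t",
                                     index=False, na_rep="")
    experiment.truth.interactors.to_csv(paths["truth_interactors"], sep="\t",
                                        index=False, na_rep="")
    experiment.truth.proteome.to_csv(paths["truth_proteome"], sep="\t",
                                     index=False, na_rep="")
    for allele, eps in experiment.epitopes.items():
        key = f"epitopes_{allele}"
        safe = allele.replace("*", "").replace(":", "").replace("-", "_")
        paths[key] = os.path.join(directory, f"epitopes_{safe}.txt")
        hio.write_accession_list(eps, paths[key])
    return paths
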