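"""AP-MS class I interactome analysis: high-confidence interaction (HCI)
filtering, overlap and known-interactor recovery statistics, and
differential-interaction calls.

An HCI is a protein passing three filters: identification FDR < 0.01,
at least two unique peptides, and absence from a CRAPome-style
contaminant list (nonspecific IgG/bead binders).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peptidome import summary_percentages

REQUIRED_COLUMNS = {"protein", "unique_peptides", "id_fdr"}


@dataclass
class OverlapStats:
    """Venn-style overlap between two HCI accession sets."""

    n_a: int
    n_b: int
    n_shared: int
    union: int
    percent_b_in_a: int


def collapse_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """One row per protein from a long (per-replicate) interactor table.

    A protein's evidence is its best across replicates: maximum unique
    peptides, minimum identification FDR.
    """
    missing = REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"interactor table missing columns: {sorted(missing)}")
    agg: dict = {"unique_peptides": "max", "id_fdr": "min"}
    if "gene" in table.columns:
        agg["gene"] = "first"
    return (table.groupby("protein", sort=True).agg(agg).reset_index())


def filter_hci(table: pd.DataFrame, contaminants,
               fdr_max: float = 0.01, min_unique: int = 2,
               contaminant_genes=None) -> pd.DataFrame:
    """Apply the HCI filters and return passing proteins.

    Pass iff id_fdr < fdr_max (strict) AND unique_peptides >= min_unique
    (inclusive: "no less than two") AND the accession is not a
    contaminant.  Contaminant matching is by accession, with an optional
    gene-symbol fallback for gene-keyed contaminant lists.
    """
    per_protein = collapse_replicates(table)
    contaminants = set(contaminants)
    bad = per_protein["protein"].isin(contaminants)
    if contaminant_genes is not None and "gene" in per_protein.columns:
        bad |= per_protein["gene"].isin(set(contaminant_genes))
    keep = ((per_protein["id_fdr"] < fdr_max)
            & (per_protein["unique_peptides"] >= min_unique)
            & ~bad)
    out = per_protein[keep].reset_index(drop=True)
    out["hci"] = True
    return out


def overlap_stats(set_a, set_b) -> OverlapStats:
    """Overlap between two accession sets; percent of B found in A."""
    a, b = set(set_a), set(set_b)
    shared = len(a & b)
    n_b = len(b)
    pct = summary_percentages(shared, n_b) if n_b else 0
    return OverlapStats(n_a=len(a), n_b=n_b, n_shared=shared,
                        union=len(a) + n_b - shared, percent_b_in_a=pct)


def known_recovery(hci_set, known) -> dict:
    """Recovery of a known-interactor list and the novel-interactor count."""
    known = set(known)
    if not known:
        raise ValueError("known-interactor list is empty")
    hci_set = set(hci_set)
    recovered = len(known & hci_set)
    return {
        "n_known": len(known),
        "n_recovered": recovered,
        "percent_recovered": summary_percentages(recovered, len(known)),
        "n_novel": len(hci_set) - recovered,
    }


def call_differential_interaction(quant: pd.DataFrame, up: float = 1.5,
                                  down: float = 0.67,
                                  alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Differential class I-interaction calls at the 1.5 / 0.67 cutoffs.

    A measured interaction is increased iff ratio >= up with p < alpha,
    decreased iff ratio <= down with p < alpha (a statistically
    significant altered ratio); capped-ratio interactions (one-channel
    detections, which admit no t-test) are called on the ratio alone.
    """
    if up <= 0 or down <= 0:
        raise ValueError("fold-change cutoffs must be positive")
    calls = quant.copy()
    ratio = calls["ratio_hl"].to_numpy(dtype=float)
    capped = calls["capped"].to_numpy() if "capped" in calls.columns else np.array(
        ["none"] * len(calls))
    p = calls["p_value"].to_numpy(dtype=float) if "p_value" in calls.columns \
        else np.full(len(calls), np.nan)
    significant = np.where(capped != "none", True, p < alpha)
    status = np.where((ratio >= up) & significant, "increased",
                      np.where((ratio <= down) & significant, "decreased",
                               "unchanged"))
    calls["status"] = status
    n = len(calls)
    summary = {
        "n_quantified": n,
        "n_increased": int((status == "increased").sum()),
        "n_decreased": int((status == "decreased").sum()),
    }
    summary["n_unchanged"] = n - summary["n_increased"] - summary["n_decreased"]
    if n:
        summary["frac_increased"] = summary["n_increased"] / n
        summary["frac_decreased"] = summary["n_decreased"] / n
        summary["frac_altered"] = (summary["n_increased"]
                                   + summary["n_decreased"]) / n
    return calls, summary
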