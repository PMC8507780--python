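"""Cross-layer integration: peptide-vs-protein and proteome-vs-interactome
correlations, altered-protein selection, hypergeometric gene-set
enrichment with Benjamini-Hochberg adjustment, and a sign-concordance
activation z-score per pathway.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _uncapped(quant: pd.DataFrame) -> pd.DataFrame:
    if "capped" in quant.columns:
        return quant[quant["capped"] == "none"]
    return quant


def peptide_protein_correlation(peptide_quant: pd.DataFrame,
                                protein_quant: pd.DataFrame) -> dict:
    """Correlate presented-peptide abundance changes with source-protein
    expression changes.

    Peptides are exploded over their (semicolon-joined) source proteins;
    when several peptides derive from one protein their median log2
    ratio is used.  Capped ratios are conventions rather than
    measurements and are excluded from both layers.  Returns the
    least-squares slope, Pearson r and its two-sided p, and the paired
    per-protein table.
    """
    peps = _uncapped(peptide_quant).copy()
    prots = _uncapped(protein_quant)
    peps["protein"] = peps["proteins"].str.split(";")
    exploded = peps.explode("protein")
    per_protein = (exploded.groupby("protein")["log2_ratio"]
                   .median().rename("peptide_log2"))
    paired = (prots.set_index("protein")["log2_ratio"].rename("protein_log2")
              .to_frame().join(per_protein, how="inner").dropna())
    if len(paired) < 3:
        raise ValueError(
            f"need >=3 shared proteins for correlation, got {len(paired)}")
    fit = stats.linregress(paired["protein_log2"], paired["peptide_log2"])
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r": float(fit.rvalue),
        "p": float(fit.pvalue),
        "n": len(paired),
        "paired": paired.reset_index(),
    }


def select_altered(protein_quant: pd.DataFrame,
                   log2_cutoff: float = 0.6,
                   gene_col: str = "gene") -> list[str]:
    """Genes of significantly altered proteins: |log2 ratio H/L| > cutoff."""
    mask = protein_quant["log2_ratio"].abs() > log2_cutoff
    genes = protein_quant.loc[mask, gene_col].dropna()
    return sorted(set(genes))


def enrich_gene_sets(query, gene_sets: dict, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in a query list.

    p = P(X >= k) for k = |query ∩ set|, with the set intersected with
    the universe; Benjamini-Hochberg adjustment across sets; results
    sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query)
    stray = query - universe
    if stray:
        raise ValueError(
            f"query genes outside the universe: {sorted(stray)[:5]}")
    n, big_n = len(query), len(universe)
    rows = []
    for name, entry in gene_sets.items():
        members = set(entry["genes"] if isinstance(entry, dict) else entry) \
            & universe
        k = len(query & members)
        big_k = len(members)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"set": name, "k": k, "K": big_k, "n": n, "N": big_n,
                     "p": p})
    result = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    if len(result):
        result["p_adj"] = multipletests(result["p"], method="fdr_bh")[1]
        result = result.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        result["p_adj"] = []
    return result


def activation_zscore(set_genes, log2_by_gene: dict,
                      directions: dict, log2_cutoff: float = 0.6) -> float | None:
    """Sign-concordance activation z-score for one gene set.

    Over the m altered genes (|log2| > cutoff) with an annotated expected
    direction, z = sum(sign(log2) * direction) / sqrt(m).  Positive z
    means the pathway's observed changes run with their activating
    directions (net activation), negative means net inhibition.  None
    when no gene contributes.
    """
    total = 0.0
    m = 0
    for gene in set_genes:
        if gene not in log2_by_gene or gene not in directions:
            continue
        lfc = log2_by_gene[gene]
        if abs(lfc) <= log2_cutoff or lfc == 0:
            continue
        total += np.sign(lfc) * directions[gene]
        m += 1
    if m == 0:
        return None
    return float(total / np.sqrt(m))


def add_activation_zscores(enrichment: pd.DataFrame, gene_sets: dict,
                           log2_by_gene: dict, directions: pd.DataFrame,
                           log2_cutoff: float = 0.6) -> pd.DataFrame:
    """Attach a z column to an enrichment table from direction annotations.

    ``directions`` has columns set, gene, direction (+1/-1).
    """
    out = enrichment.copy()
    zs = []
    for name in out["set"]:
        entry = gene_sets.get(name, {})
        genes = entry["genes"] if isinstance(entry, dict) else entry
        dirs = directions[directions["set"] == name]
        dir_map = dict(zip(dirs["gene"], dirs["direction"]))
        zs.append(activation_zscore(genes, log2_by_gene, dir_map,
                                    log2_cutoff=log2_cutoff))
    out["z"] = [np.nan if z is None else z for z in zs]
    return out


def proteome_interactome_correlation(protein_quant: pd.DataFrame,
                                     interaction_quant: pd.DataFrame) -> dict:
    """Pearson correlation of protein-expression vs class I-interaction
    log2 ratios over shared accessions (capped excluded)."""
    prots = _uncapped(protein_quant).set_index("protein")["log2_ratio"]
    ints = _uncapped(interaction_quant).set_index("protein")["log2_ratio"]
    paired = pd.concat([prots.rename("proteome"), ints.rename("interactome")],
                       axis=1, join="inner").dropna()
    if len(paired) < 3:
        raise ValueError(
            f"need >=3 shared proteins for correlation, got {len(paired)}")
    res = stats.pearsonr(paired["proteome"], paired["interactome"])
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": len(paired)}
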