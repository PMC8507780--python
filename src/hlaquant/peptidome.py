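"""Immunopeptidome profiling: the discovery cascade, length and
label-position distributions, differential presentation calls and the
global-shift summary.

The discovery cascade mirrors how a SILAC immunopeptidomics experiment
loses peptides stage by stage: every identified peptide -> peptides
carrying at least one Lys/Arg (the only ones that receive a heavy label)
-> peptides with a valid (possibly capped) SILAC ratio -> peptides of
canonical HLA class I length (8-14 residues).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CANONICAL_LENGTHS = range(8, 15)


def has_kr(sequence: str) -> bool:
    return ("K" in sequence) or ("R" in sequence)


@dataclass
class FilterCascadeResult:
    """Peptide counts and per-stage lists after each filtering step."""

    n_identified: int
    n_labelable: int
    n_quantified: int
    n_8_14: int
    identified: list[str] = field(default_factory=list, repr=False)
    labelable: list[str] = field(default_factory=list, repr=False)
    quantified: list[str] = field(default_factory=list, repr=False)
    in_8_14: list[str] = field(default_factory=list, repr=False)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stage": ["identified", "labelable_kr", "quantified", "len_8_14"],
            "n_peptides": [self.n_identified, self.n_labelable,
                           self.n_quantified, self.n_8_14],
        })


def discovery_pipeline(identified_peptides,
                       quant: pd.DataFrame) -> FilterCascadeResult:
    """Apply the discovery cascade and count survivors at each stage.

    ``identified_peptides`` is any iterable of peptide sequences (the
    identification universe); ``quant`` is the aggregated quantification
    table whose ``peptide`` column marks peptides with a valid SILAC ratio.
    """
    identified = sorted(set(identified_peptides))
    quantified_set = set(quant["peptide"]) if len(quant) else set()
    labelable = [p for p in identified if has_kr(p)]
    quantified = [p for p in labelable if p in quantified_set]
    in_8_14 = [p for p in quantified if 8 <= len(p) <= 14]
    return FilterCascadeResult(
        n_identified=len(identified),
        n_labelable=len(labelable),
        n_quantified=len(quantified),
        n_8_14=len(in_8_14),
        identified=identified,
        labelable=labelable,
        quantified=quantified,
        in_8_14=in_8_14,
    )


def length_distribution(peptides) -> tuple[dict, int | None]:
    """Counts per length 8..14 (plus 'other') and the modal length.

    The mode is taken over the actual peptide lengths; None for empty input.
    """
    lengths = [len(p) for p in peptides]
    counts: dict = {length: 0 for length in CANONICAL_LENGTHS}
    counts["other"] = 0
    for ln in lengths:
        if 8 <= ln <= 14:
            counts[ln] += 1
        else:
            counts["other"] += 1
    if not lengths:
        return counts, None
    values, freqs = np.unique(lengths, return_counts=True)
    mode = int(values[np.argmax(freqs)])
    return counts, mode


def label_position_profile(peptides) -> pd.DataFrame:
    """Per-position Lys/Arg counts and frequencies over a set of 9-mers.

    In HLA class I 9-mers the anchor positions are 2 and 9; a depleted
    K/R frequency there is the expected signature of anchor-constrained
    binding motifs.
    """
    peptides = list(peptides)
    for p in peptides:
        if len(p) != 9:
            raise ValueError(f"label_position_profile expects 9-mers, got {p!r}")
    counts = np.zeros(9, dtype=int)
    for p in peptides:
        for i, res in enumerate(p):
            if res in ("K", "R"):
                counts[i] += 1
    n = len(peptides)
    freq = counts / n if n else np.zeros(9)
    return pd.DataFrame({
        "position": np.arange(1, 10),
        "n_kr": counts,
        "freq_kr": freq,
    })


def summary_percentages(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half away from zero."""
    if denominator == 0:
        raise ValueError("summary_percentages: zero denominator")
    x = 100.0 * numerator / denominator
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def call_differential_presentation(quant: pd.DataFrame, up: float = 2.0,
                                   down: float = 0.5) -> tuple[pd.DataFrame, dict]:
    """Three-way partition of quantified peptides at the fold-change cutoffs.

    Cutoffs are inclusive (ratio >= up -> increased, ratio <= down ->
    reduced); peptides quantified only via capped ratios participate —
    a heavy-only peptide (ratio 256) is an increased call.
    """
    if up <= 0 or down <= 0:
        raise ValueError("fold-change cutoffs must be positive")
    calls = quant.copy()
    ratio = calls["ratio_hl"]
    calls["status"] = np.where(ratio >= up, "increased",
                               np.where(ratio <= down, "reduced", "unchanged"))
    n = len(calls)
    counts = calls["status"].value_counts().to_dict()
    summary = {
        "n_quantified": n,
        "n_increased": counts.get("increased", 0),
        "n_reduced": counts.get("reduced", 0),
        "n_unchanged": counts.get("unchanged", 0),
    }
    if n > 0:
        summary["pct_increased"] = summary_percentages(summary["n_increased"], n)
        summary["pct_reduced"] = summary_percentages(summary["n_reduced"], n)
    return calls, summary


def global_shift(quant: pd.DataFrame) -> dict:
    """Five-number summary of the log2 H/L ratios, capped peptides included.

    A median below zero indicates globally reduced presentation in the
    heavy-labeled (resistant) line.
    """
    if len(quant) == 0:
        raise ValueError("global_shift requires at least one quantified peptide")
    x = quant["log2_ratio"].to_numpy(dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "min": float(np.min(x)),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(np.max(x)),
    }
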