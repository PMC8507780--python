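"""SILAC ratio quantification: channel normalization, capped H/L ratios,
replicate aggregation and replicate correlation.

The heavy channel is the resistant line, so ratio H/L < 1 means reduced
abundance upon resistance.  Species detected in only one channel receive
the conventional capped ratios 256 (heavy-only) and 0.01 (light-only).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: capped ratio for species detected only in the heavy (resistant) channel
CAP_HEAVY_ONLY = 256.0
#: capped ratio for species detected only in the light (parental) channel
CAP_LIGHT_ONLY = 0.01


@dataclass
class PeptideQuant:
    """Replicate-aggregated SILAC quantification for one peptide or protein."""

    key: str
    ratio_hl: float
    log2_ratio: float
    capped: str  # none | heavy_only | light_only
    replicate_log2: list[float] = field(default_factory=list)
    p_value: float = float("nan")
    n_quantified_reps: int = 0


def _check_intensity_table(df: pd.DataFrame) -> None:
    for col in ("replicate", "intensity_L", "intensity_H"):
        if col not in df.columns:
            raise ValueError(f"intensity table missing column {col!r}")


def normalization_factors(df: pd.DataFrame, method: str = "sum") -> dict:
    """Per-replicate rescaling factor for the heavy channel.

    method="sum": factor ΣL/ΣH over rows where both channels were
    measured (total-peptide "auto" normalization).  method="median":
    factor 1/median(H/L) over the same rows (median ratio centering,
    robust to heavy-tailed differential species whose linear-scale means
    would bias the channel sums).  Capped one-channel rows are excluded
    in both cases because their single-channel values would distort the
    statistic.
    """
    _check_intensity_table(df)
    if method not in ("sum", "median"):
        raise ValueError(f"unknown normalization method {method!r}")
    factors: dict = {}
    for rep, sub in df.groupby("replicate"):
        has_l = sub["intensity_L"].notna()
        has_h = sub["intensity_H"].notna()
        if not has_l.any():
            raise ValueError(f"replicate {rep!r}: light channel entirely absent")
        if not has_h.any():
            raise ValueError(f"replicate {rep!r}: heavy channel entirely absent")
        both = has_l & has_h
        if not both.any():
            raise ValueError(
                f"replicate {rep!r}: no row with both channels measured")
        light = sub.loc[both, "intensity_L"]
        heavy = sub.loc[both, "intensity_H"]
        if method == "sum":
            if heavy.sum() <= 0 or light.sum() <= 0:
                raise ValueError(f"replicate {rep!r}: non-positive channel sum")
            factors[rep] = light.sum() / heavy.sum()
        else:
            factors[rep] = 1.0 / float(np.median(heavy / light))
    return factors


def normalize_channels(df: pd.DataFrame, factors: dict | None = None) -> pd.DataFrame:
    """Rescale heavy intensities so the channel totals match per replicate.

    When ``factors`` is None they are computed from ``df`` itself; passing
    factors derived from another table of the same run (e.g., the whole-cell
    proteome, whose bulk is unchanged) removes technical channel imbalance
    without flattening a genuine global shift confined to this table.

    Rows with an absent channel keep the present channel rescaled
    consistently (heavy-only rows are multiplied by the same factor).
    """
    _check_intensity_table(df)
    if factors is None:
        factors = normalization_factors(df)
    out = df.copy()
    scale = out["replicate"].map(factors)
    if scale.isna().any():
        missing = sorted(out.loc[scale.isna(), "replicate"].unique())
        raise ValueError(f"no normalization factor for replicate(s) {missing}")
    out["intensity_H"] = out["intensity_H"] * scale
    return out


def compute_ratios(df: pd.DataFrame, key: str) -> pd.DataFrame:
    """Per-row (key × replicate) H/L ratios from a normalized table.

    Both channels present -> H/L; heavy only -> 256 (capped heavy_only);
    light only -> 0.01 (capped light_only); both absent -> row dropped
    (identification without quantification, excluded downstream).  The
    capped values are the extremes of the representable ratio scale, so
    a measured ratio is clipped into [0.01, 256] as well; the ``capped``
    flag records one-channel detection only.
    """
    _check_intensity_table(df)
    has_l = df["intensity_L"].notna() & (df["intensity_L"] > 0)
    has_h = df["intensity_H"].notna() & (df["intensity_H"] > 0)
    out = df.loc[has_l | has_h, [key, "replicate"]].copy()
    both = (has_l & has_h)[out.index]
    measured = np.clip(
        df.loc[out.index, "intensity_H"] / df.loc[out.index, "intensity_L"],
        CAP_LIGHT_ONLY, CAP_HEAVY_ONLY)
    ratio = np.where(
        both, measured,
        np.where(has_h[out.index], CAP_HEAVY_ONLY, CAP_LIGHT_ONLY),
    )
    capped = np.where(both, "none",
                      np.where(has_h[out.index], "heavy_only", "light_only"))
    out["ratio_hl"] = ratio
    out["log2_ratio"] = np.log2(ratio)
    out["capped"] = capped
    return out.reset_index(drop=True)


def _aggregate_one(sub: pd.DataFrame) -> dict | None:
    uncapped = sub[sub["capped"] == "none"]
    n_reps = len(sub)
    if len(uncapped) >= 1:
        log2s = uncapped["log2_ratio"].to_numpy()
        med = float(np.median(log2s))
        p = float("nan")
        if len(log2s) >= 2 and np.std(log2s) > 0:
            p = float(stats.ttest_1samp(log2s, 0.0).pvalue)
        return {
            "ratio_hl": float(2.0 ** med),
            "log2_ratio": med,
            "capped": "none",
            "p_value": p,
            "n_reps": n_reps,
            "replicate_log2": list(log2s),
        }
    # only capped replicates: all on one side -> capped summary; a mixed
    # heavy-only/light-only peptide with no measured replicate is
    # uninterpretable -> majority side, ties dropped
    n_heavy = int((sub["capped"] == "heavy_only").sum())
    n_light = int((sub["capped"] == "light_only").sum())
    if n_heavy == n_light:
        return None
    if n_heavy > n_light:
        ratio, flag = CAP_HEAVY_ONLY, "heavy_only"
    else:
        ratio, flag = CAP_LIGHT_ONLY, "light_only"
    return {
        "ratio_hl": ratio,
        "log2_ratio": float(np.log2(ratio)),
        "capped": flag,
        "p_value": float("nan"),
        "n_reps": n_reps,
        "replicate_log2": [],
    }


def aggregate_replicates(rep_ratios: pd.DataFrame, key: str) -> pd.DataFrame:
    """Collapse replicate-level ratios to one quantification per key.

    The summary log2 ratio is the median over uncapped replicate log2
    ratios (robust to a single outlier replicate); capped replicates are
    excluded from the median and from the one-sample t-test, which is run
    against 0 when ≥2 uncapped replicates with nonzero variance exist.
    """
    rows = []
    for k, sub in rep_ratios.groupby(key, sort=True):
        agg = _aggregate_one(sub)
        if agg is not None:
            rows.append({key: k, **agg})
    columns = [key, "ratio_hl", "log2_ratio", "capped",
               "p_value", "n_reps", "replicate_log2"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows, columns=columns)


def quantify_table(df: pd.DataFrame, key: str,
                   factors: dict | None = None) -> pd.DataFrame:
    """normalize -> per-replicate ratios -> replicate aggregation."""
    normed = normalize_channels(df, factors=factors)
    return aggregate_replicates(compute_ratios(normed, key), key)


def replicate_correlation(rep_ratios: pd.DataFrame, key: str,
                          min_shared: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlation of uncapped log2 ratios across replicates.

    Each pair is computed on the rows quantified (uncapped) in both
    members; pairs with fewer than ``min_shared`` shared rows get NaN.
    """
    uncapped = rep_ratios[rep_ratios["capped"] == "none"]
    wide = uncapped.pivot_table(index=key, columns="replicate",
                                values="log2_ratio", aggfunc="first")
    reps = sorted(wide.columns)
    if len(reps) < 2:
        raise ValueError("replicate correlation requires >=2 replicates")
    mat = pd.DataFrame(np.nan, index=reps, columns=reps, dtype=float)
    np.fill_diagonal(mat.values, 1.0)
    for a, b in itertools.combinations(reps, 2):
        pair = wide[[a, b]].dropna()
        if len(pair) < min_shared:
            continue
        r = float(stats.pearsonr(pair[a], pair[b]).statistic)
        mat.loc[a, b] = mat.loc[b, a] = r
    return mat
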