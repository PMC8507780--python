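"""Position-weight-matrix binder calling and motif comparison.

A PWM trained on known allele-specific epitopes scores peptides by
summed log-odds against a background residue distribution; the score is
converted to a percentile rank (%rank) among random reference-proteome
peptides of the same length, with lower rank meaning stronger predicted
binding.  Peptides at %rank <= 2.0 are called strong binders.  Motif
differences between two peptide sets are expressed as per-position,
per-residue z-scores of the residue-frequency difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: NetMHCpan-style strong/weak binder percentile-rank cutoffs
STRONG_RANK = 2.0
WEAK_RANK = 10.0


def uniform_background() -> pd.Series:
    return pd.Series(1.0 / 20.0, index=list(AMINO_ACIDS))


@dataclass
class AllelePWM:
    """Length-specific log-odds matrix for one HLA allele.

    freq: 20 x length residue-frequency matrix (columns 1..length, each
    summing to 1); background: 20-vector of reference residue frequencies.
    """

    allele: str
    length: int
    freq: pd.DataFrame
    background: pd.Series
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        col_sums = self.freq.sum(axis=0).to_numpy()
        if not np.allclose(col_sums, 1.0, atol=1e-9):
            raise ValueError(f"PWM columns must sum to 1 (got {col_sums})")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")


def _residue_counts(peptides: list[str], length: int) -> np.ndarray:
    counts = np.zeros((20, length), dtype=float)
    for pep in peptides:
        for pos, res in enumerate(pep):
            try:
                counts[_AA_INDEX[res], pos] += 1
            except KeyError:
                raise ValueError(f"non-canonical residue {res!r} in {pep!r}")
    return counts


def build_pwm(epitopes, allele: str = "allele",
              background: pd.Series | None = None,
              pseudocount: float = 1.0) -> AllelePWM:
    """Train a PWM from equal-length epitopes.

    freq[a][p] = (count(a at p) + pseudocount * background[a]) / (n + pseudocount)
    """
    epitopes = list(epitopes)
    if not epitopes:
        raise ValueError("cannot build a PWM from an empty epitope list")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    length = len(epitopes[0])
    if any(len(e) != length for e in epitopes):
        raise ValueError("epitopes must all have the same length")
    if background is None:
        background = uniform_background()
    background = background.reindex(list(AMINO_ACIDS)).astype(float)
    counts = _residue_counts(epitopes, length)
    n = len(epitopes)
    freq = (counts + pseudocount * background.to_numpy()[:, None]) / (n + pseudocount)
    freq_df = pd.DataFrame(freq, index=list(AMINO_ACIDS),
                           columns=range(1, length + 1))
    return AllelePWM(allele=allele, length=length, freq=freq_df,
                     background=background, pseudocount=pseudocount)


def score_peptide(pwm: AllelePWM, peptide: str) -> float:
    """Summed log2 odds of the peptide under the PWM vs the background."""
    if len(peptide) != pwm.length:
        raise ValueError(
            f"peptide length {len(peptide)} != PWM length {pwm.length}")
    score = 0.0
    freq = pwm.freq.to_numpy()
    bg = pwm.background.to_numpy()
    for pos, res in enumerate(peptide):
        idx = _AA_INDEX.get(res)
        if idx is None:
            raise ValueError(f"non-canonical residue {res!r} in {peptide!r}")
        score += np.log2(freq[idx, pos] / bg[idx])
    return float(score)


def score_peptides(pwm: AllelePWM, peptides) -> np.ndarray:
    """Vectorized scoring of many equal-length peptides."""
    peptides = list(peptides)
    if not peptides:
        return np.zeros(0)
    arr = np.array([[_AA_INDEX[res] for res in pep] for pep in peptides])
    if arr.shape[1] != pwm.length:
        raise ValueError("peptide length does not match PWM length")
    logodds = np.log2(pwm.freq.to_numpy() /
                      pwm.background.to_numpy()[:, None])
    pos = np.arange(pwm.length)
    return logodds[arr, pos].sum(axis=1)


def percent_rank(score: float, background_scores: np.ndarray) -> float:
    """100 x fraction of background peptides scoring strictly above the query."""
    background_scores = np.asarray(background_scores, dtype=float)
    if background_scores.size == 0:
        raise ValueError("empty %rank background")
    return float(100.0 * np.mean(background_scores > score))


def proteome_windows(proteins, length: int) -> list[str]:
    """Deduplicated sliding windows of the given length over a proteome."""
    seen: set[str] = set()
    for seq in (proteins.values() if hasattr(proteins, "values") else proteins):
        for i in range(len(seq) - length + 1):
            window = seq[i:i + length]
            if all(res in _AA_INDEX for res in window):
                seen.add(window)
    return sorted(seen)


def background_scores(pwm: AllelePWM, proteins, n: int = 2000,
                      seed: int = 0) -> np.ndarray:
    """Score a random sample of reference-proteome windows for %rank.

    Sampled once per allele/length with a recorded seed so the
    build -> score -> %rank chain is deterministic.
    """
    windows = proteome_windows(proteins, pwm.length)
    if len(windows) == 0:
        raise ValueError("reference proteome yields no windows of this length")
    rng = np.random.default_rng(seed)
    if len(windows) > n:
        idx = rng.choice(len(windows), size=n, replace=False)
        windows = [windows[i] for i in idx]
    return score_peptides(pwm, windows)


def call_binders(peptides, pwms: list[AllelePWM], backgrounds: dict,
                 strong: float = STRONG_RANK,
                 weak: float = WEAK_RANK) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Best-allele %rank per peptide and per-length strong-binder counts.

    ``backgrounds`` maps allele name -> background score array (same
    length as the allele's PWM).  Each peptide takes the lowest %rank
    across alleles covering its length; class is strong (<= strong),
    weak (<= weak) or non.  Peptides whose length no allele covers are
    flagged uncovered and classed non.
    """
    by_length: dict[int, list[AllelePWM]] = {}
    for pwm in pwms:
        by_length.setdefault(pwm.length, []).append(pwm)
    rows = []
    for pep in peptides:
        candidates = by_length.get(len(pep), [])
        best = None
        for pwm in candidates:
            sc = score_peptide(pwm, pep)
            pr = percent_rank(sc, backgrounds[pwm.allele])
            if best is None or pr < best[2]:
                best = (pwm.allele, sc, pr)
        if best is None:
            rows.append({"peptide": pep, "best_allele": None,
                         "score": np.nan, "percent_rank": np.nan,
                         "class": "non", "covered": False})
        else:
            allele, sc, pr = best
            cls = "strong" if pr <= strong else ("weak" if pr <= weak else "non")
            rows.append({"peptide": pep, "best_allele": allele, "score": sc,
                         "percent_rank": pr, "class": cls, "covered": True})
    calls = pd.DataFrame(rows, columns=["peptide", "best_allele", "score",
                                        "percent_rank", "class", "covered"])
    if len(calls):
        strong_counts = (calls[calls["class"] == "strong"]
                         .assign(length=lambda d: d["peptide"].str.len())
                         .groupby("length").size().rename("n_strong")
                         .reset_index())
    else:
        strong_counts = pd.DataFrame(columns=["length", "n_strong"])
    return calls, strong_counts


def motif_difference(sample, reference) -> pd.DataFrame:
    """Per-position, per-residue z-scores of residue-frequency differences.

    z[a][p] = (f_sample - f_ref) / sqrt(f_ref (1 - f_ref) / n_sample),
    with f_ref floored at 1/(n_ref + 20) in the denominator so unseen
    reference residues do not produce a division by zero.
    """
    sample = list(sample)
    reference = list(reference)
    if not sample or not reference:
        raise ValueError("both peptide sets must be nonempty")
    length = len(sample[0])
    if any(len(p) != length for p in sample + reference):
        raise ValueError("peptide sets must share a single length")
    n_s, n_r = len(sample), len(reference)
    f_s = _residue_counts(sample, length) / n_s
    f_r = _residue_counts(reference, length) / n_r
    floor = 1.0 / (n_r + 20)
    f_r_den = np.clip(f_r, floor, 1.0 - floor)
    z = (f_s - f_r) / np.sqrt(f_r_den * (1.0 - f_r_den) / n_s)
    return pd.DataFrame(z, index=list(AMINO_ACIDS), columns=range(1, length + 1))
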