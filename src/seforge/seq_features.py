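"""Sequence-derived features of constituent enhancers.

Features: region size, GC fraction, softmask repeat fraction, mean
phastCons-style conservation, TRAP biophysical motif affinity, thresholded
motif hit counts, and canonical k-mer spectra.

TRAP models expected TF occupancy: for each sequence window i the mismatch
energy relative to the PWM consensus is

    E_i = (1/lambda) * sum_j ln(p_max,j / p_base(i+j),j)

and the window contributes p_i = R0 e^{-E_i} / (1 + R0 e^{-E_i}) with
R0 = exp(slope * L + intercept).  The defaults (lambda = 0.7,
slope = 0.584, intercept = -5.66) are the TRAP method's published
parameterization.  Windows containing N contribute 0 and are skipped in
k-mer and motif counting rather than probabilistically imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from math import exp, log

import numpy as np
import pandas as pd

from seforge.genomics_io import (
    CoverageTrack,
    FeatureMatrix,
    GenomeSequence,
    GenomicInterval,
    PWM,
)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TrapParams:
    lam: float = 0.7
    ln_r0_slope: float = 0.584
    ln_r0_intercept: float = -5.66
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")

    def r0(self, motif_length: int) -> float:
        return exp(self.ln_r0_slope * motif_length + self.ln_r0_intercept)


def gc_fraction(seq: str) -> float:
    """(G + C) / (non-N bases); case-insensitive; errors on all-N input."""
    if not seq:
        raise ValueError("empty sequence")
    upper = seq.upper()
    denom = len(upper) - upper.count("N")
    if denom == 0:
        raise ValueError("sequence contains only N bases")
    return (upper.count("G") + upper.count("C")) / denom


def repeat_fraction(seq: str) -> float:
    """Fraction of softmasked (lowercase) bases."""
    if not seq:
        raise ValueError("empty sequence")
    return sum(1 for b in seq if b.islower()) / len(seq)


def mean_conservation(track: CoverageTrack, region: GenomicInterval) -> float:
    return track.mean_over(region)


def _window_energies(seq: str, pwm: PWM, params: TrapParams) -> np.ndarray:
    """Mismatch energies for every valid window; NaN where a window holds N."""
    L = len(pwm)
    n_windows = len(seq) - L + 1
    upper = seq.upper()
    # per-position log(p_max / p_base), indexed [position in motif, base]
    log_ratio = np.log(pwm.matrix.max(axis=1, keepdims=True) / pwm.matrix)
    energies = np.full(n_windows, np.nan)
    codes = np.array([_BASE_INDEX.get(b, -1) for b in upper], dtype=np.int64)
    for i in range(n_windows):
        window = codes[i : i + L]
        if np.any(window < 0):
            continue
        energies[i] = log_ratio[np.arange(L), window].sum() / params.lam
    return energies


def trap_affinity(seq: str, pwm: PWM, params: TrapParams | None = None) -> float:
    """Expected occupancy summed over all windows (both strands by default)."""
    params = params if params is not None else TrapParams()
    L = len(pwm)
    if len(seq) < L:
        raise ValueError(f"sequence shorter than motif ({len(seq)} < {L})")
    r0 = params.r0(L)
    total = 0.0
    strands = [seq, reverse_complement(seq)] if params.both_strands else [seq]
    for strand_seq in strands:
        energies = _window_energies(strand_seq, pwm, params)
        valid = energies[~np.isnan(energies)]
        if valid.size:
            occ = r0 * np.exp(-valid)
            total += float(np.sum(occ / (1.0 + occ)))
    return total


def motif_hit_count(
    seq: str, pwm: PWM, score_fraction: float = 0.8
) -> int:
    """Count windows (both strands) scoring >= score_fraction of max log-odds.

    Log-odds are against a uniform background (0.25 per base); windows with
    N are skipped.
    """
    if not 0 < score_fraction <= 1:
        raise ValueError("score_fraction must be in (0, 1]")
    L = len(pwm)
    if len(seq) < L:
        raise ValueError(f"sequence shorter than motif ({len(seq)} < {L})")
    log_odds = np.log2(pwm.matrix / 0.25)
    max_score = float(log_odds.max(axis=1).sum())
    threshold = score_fraction * max_score
    count = 0
    for strand_seq in (seq, reverse_complement(seq)):
        upper = strand_seq.upper()
        codes = np.array([_BASE_INDEX.get(b, -1) for b in upper], dtype=np.int64)
        for i in range(len(upper) - L + 1):
            window = codes[i : i + L]
            if np.any(window < 0):
                continue
            score = float(log_odds[np.arange(L), window].sum())
            if score >= threshold:
                count += 1
    return count


def canonical_kmers(k: int) -> list[str]:
    """All canonical k-mers (lexicographic min of k-mer and its revcomp)."""
    out = []
    seen: set[str] = set()
    for combo in product("ACGT", repeat=k):
        kmer = "".join(combo)
        canon = min(kmer, reverse_complement(kmer))
        if canon not in seen:
            seen.add(canon)
            out.append(canon)
    return out


def kmer_spectrum(
    seq: str, k: int = 5, canonical: bool = True, normalize: bool = False
) -> dict[str, float]:
    """Counts of each window's canonical k-mer; N-containing windows skipped."""
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k ({len(seq)} < {k})")
    upper = seq.upper()
    counts: dict[str, float] = {}
    n_windows = 0
    for i in range(len(upper) - k + 1):
        kmer = upper[i : i + k]
        if "N" in kmer:
            continue
        if canonical:
            kmer = min(kmer, reverse_complement(kmer))
        counts[kmer] = counts.get(kmer, 0.0) + 1.0
        n_windows += 1
    if normalize and n_windows:
        counts = {kmer: c / n_windows for kmer, c in counts.items()}
    return counts


def sequence_feature_matrix(
    regions: list[GenomicInterval],
    genome: GenomeSequence,
    conservation: CoverageTrack | None = None,
    pwms: list[PWM] | None = None,
    trap_params: TrapParams | None = None,
    kmer_k: int | None = None,
) -> FeatureMatrix:
    """Per-region table: size_bp, gc, repeat_fraction, phastcons_mean,
    one TRAP column per PWM, and an optional canonical k-mer block."""
    pwms = pwms or []
    trap_params = trap_params if trap_params is not None else TrapParams()
    names = [r.name if r.name else f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    rows: list[dict[str, float]] = []
    kmer_names = canonical_kmers(kmer_k) if kmer_k else []
    for region in regions:
        seq = genome.fetch(region)  # raises naming the region if out of bounds
        row: dict[str, float] = {
            "size_bp": float(region.length()),
            "gc": gc_fraction(seq),
            "repeat_fraction": repeat_fraction(seq),
            "phastcons_mean": (
                mean_conservation(conservation, region) if conservation else 0.0
            ),
        }
        for pwm in pwms:
            row[f"trap_{pwm.motif_id}"] = trap_affinity(seq, pwm, trap_params)
        if kmer_k:
            spectrum = kmer_spectrum(seq, k=kmer_k, canonical=True, normalize=True)
            for kmer in kmer_names:
                row[f"kmer_{kmer}"] = spectrum.get(kmer, 0.0)
        rows.append(row)
    return FeatureMatrix(pd.DataFrame(rows, index=names))
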