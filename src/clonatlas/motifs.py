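"""PWM scanning and motif enrichment over peak sequences.

A motif is a position weight matrix of per-position base probabilities scored
by log-odds (base 2) against a background base composition; a window is a hit
when its score reaches the motif's threshold (default 80% of the maximum
achievable score). Both strands are scanned. Cluster-level enrichment is a
one-sided hypergeometric test of hit-bearing peaks in a target set against
target + background peaks; cross-collection motif sharing is plain set
intersection counting; density profiles histogram hit starts around peak
centers (window 2000 bp, bin 20 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_CODE["N"] = 4
NEG_LOG10_DISPLAY = 100.0  # dot-plot display gate on -log10(p)


@dataclass
class MotifPWM:
    name: str
    matrix: np.ndarray                      # L x 4 probabilities, columns A,C,G,T
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float | None = None          # log-odds bits; None -> 0.8 * max score

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 5 log2(p/bg); the 5th column (N) contributes 0."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.matrix / self.background)
        return np.column_stack([lo, np.zeros(len(self))])

    @property
    def max_score(self) -> float:
        return float(np.max(self.log_odds[:, :4], axis=1).sum())

    @property
    def effective_threshold(self) -> float:
        return self.threshold if self.threshold is not None else 0.8 * self.max_score

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=1))

    def reverse_complement(self) -> "MotifPWM":
        return MotifPWM(
            name=self.name,
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            threshold=self.threshold,
        )


def _encode(sequence: str) -> np.ndarray:
    return np.fromiter((_CODE.get(b, 4) for b in sequence.upper()), dtype=np.int8,
                       count=len(sequence))


def _strand_scores(code: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score of every window start on one strand; empty when motif > sequence."""
    L = lo.shape[0]
    n = len(code) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(L):
        scores += lo[j, code[j : j + n]]
    return scores


def scan(sequence: str, pwm: MotifPWM) -> pd.DataFrame:
    """All hits of the PWM in the sequence, both strands.

    Returns a frame with ``position`` (0-based start of the occupied window on
    the forward sequence), ``strand`` and ``score``. A motif longer than the
    sequence yields zero hits.
    """
    code = _encode(sequence)
    thr = pwm.effective_threshold
    rows = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = _strand_scores(code, mat.log_odds)
        for pos in np.flatnonzero(scores >= thr):
            rows.append((int(pos), strand, float(scores[pos])))
    return pd.DataFrame(rows, columns=["position", "strand", "score"]).sort_values(
        ["position", "strand"], ignore_index=True
    )


def has_hit(sequence: str, pwm: MotifPWM) -> bool:
    code = _encode(sequence)
    thr = pwm.effective_threshold
    for mat in (pwm, pwm.reverse_complement()):
        scores = _strand_scores(code, mat.log_odds)
        if len(scores) and scores.max() >= thr:
            return True
    return False


def _peak_sequence(row, sequence: dict[str, str]) -> str:
    return sequence[row.chrom][row.start : row.end]


def enrich(
    target_peaks: pd.DataFrame,
    background_peaks: pd.DataFrame,
    sequence: dict[str, str],
    library: list[MotifPWM],
) -> pd.DataFrame:
    """Per-motif hypergeometric enrichment of hit-bearing peaks.

    Target and background must be disjoint peak sets (the usual background is
    all other atlas peaks). For each motif: population = target + background,
    successes = peaks with >=1 hit anywhere in the population, draw = target;
    the p-value is the one-sided upper tail for the observed target hits.
    """
    if len(target_peaks) == 0:
        raise ValueError("empty target peak set")
    t_hits = {
        m.name: sum(has_hit(_peak_sequence(r, sequence), m)
                    for r in target_peaks.itertuples(index=False))
        for m in library
    }
    b_hits = {
        m.name: sum(has_hit(_peak_sequence(r, sequence), m)
                    for r in background_peaks.itertuples(index=False))
        for m in library
    }
    nT, nB = len(target_peaks), len(background_peaks)
    rows = []
    for m in library:
        k, kb = t_hits[m.name], b_hits[m.name]
        N, K = nT + nB, k + kb
        p = float(hypergeom.sf(k - 1, N, K, nT))
        rows.append(
            {
                "motif": m.name,
                "target_hits": k,
                "target_size": nT,
                "background_hits": kb,
                "background_size": nB,
                "percent_target": 100.0 * k / nT,
                "p_value": p,
                "neg_log10_p": -np.log10(p) if p > 0 else np.inf,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["enriched"] = table["neg_log10_p"] > NEG_LOG10_DISPLAY
    return table.sort_values("p_value", ignore_index=True)


def share_matrix(
    collection_a: dict[str, set[str]],
    collection_b: dict[str, set[str]],
) -> pd.DataFrame:
    """Counts of shared motif names between two collections of named sets."""
    return pd.DataFrame(
        {b: {a: len(sa & sb) for a, sa in collection_a.items()}
         for b, sb in collection_b.items()}
    ).rename_axis(index="collection_a", columns="collection_b")


def density_profile(
    peaks: pd.DataFrame,
    pwm: MotifPWM,
    sequence: dict[str, str],
    window: int = 2000,
    bin_size: int = 20,
) -> pd.Series:
    """Motif hit density by offset from peak center.

    Hit starts are binned over [-window/2, +window/2) relative to peak
    centers; the density is hits per peak per bin, where each bin's
    denominator counts only peaks whose window was not truncated at a
    chromosome edge over that bin.
    """
    if window % bin_size != 0 or window % 2 != 0:
        raise ValueError("window must be even and a multiple of bin_size")
    half = window // 2
    n_bins = window // bin_size
    edges = np.arange(-half, half + 1, bin_size)
    hits = np.zeros(n_bins)
    coverage = np.zeros(n_bins)
    for row in peaks.itertuples(index=False):
        chrom_seq = sequence[row.chrom]
        center = (row.start + row.end) // 2
        lo = max(0, center - half)
        hi = min(len(chrom_seq), center + half)
        covered = np.flatnonzero(
            (edges[:-1] >= lo - center) & (edges[1:] <= hi - center)
        )
        coverage[covered] += 1
        sub = chrom_seq[lo:hi]
        for h in scan(sub, pwm).itertuples(index=False):
            offset = lo + h.position - center
            b = (offset + half) // bin_size
            if 0 <= b < n_bins:
                hits[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.where(coverage > 0, hits / np.maximum(coverage, 1), 0.0)
    return pd.Series(dens, index=edges[:-1], name=pwm.name).rename_axis("offset")


def read_pwms(path: str, fmt: str = "jaspar", pseudocount: float = 0.0) -> list[MotifPWM]:
    """Load a PWM library from JASPAR or MEME-minimal text via Bio.motifs."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar" if fmt == "jaspar" else "minimal")
    out = []
    for m in parsed:
        counts = np.column_stack([np.asarray(m.counts[b], dtype=float) for b in BASES])
        counts += pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        out.append(MotifPWM(name=m.name or m.base_id, matrix=probs))
    return out


def write_pwms_jaspar(pwms: list[MotifPWM], path: str, scale: int = 100) -> None:
    """Write PWMs as JASPAR-format count matrices (probabilities x scale)."""
    with open(path, "w") as fh:
        for m in pwms:
            fh.write(f">{m.name}\t{m.name}\n")
            for bi, base in enumerate(BASES):
                vals = " ".join(f"{v * scale:.2f}" for v in m.matrix[:, bi])
                fh.write(f"{base}  [ {vals} ]\n")
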