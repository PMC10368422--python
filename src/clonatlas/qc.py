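"""Sample quality control: mapped-fragment count and FRiP gates.

A library passes QC iff it has at least ``min_fragments`` mapped fragments AND
a fraction of fragments in peaks (FRiP) of at least ``min_frip``; both
comparisons are inclusive. Defaults suit adult-brain clonal-unit ATAC-seq:
2 million fragments and FRiP 0.2. FRiP is computed
against each sample's OWN peak calls, before any atlas is built.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._intervals import overlaps_any

MIN_FRAGMENTS_DEFAULT = 2_000_000
MIN_FRIP_DEFAULT = 0.2


@dataclass
class SampleQC:
    sample_id: str
    total_fragments: int
    fragments_in_peaks: int
    frip: float | None  # None when total_fragments == 0 (undefined)
    passed: bool = False
    fail_reason: str | None = None

    def __post_init__(self) -> None:
        if self.frip is not None and not 0.0 <= self.frip <= 1.0:
            raise ValueError(f"frip out of [0,1]: {self.frip}")


def compute_frip(sample_id: str, fragments: pd.DataFrame, peaks: pd.DataFrame) -> SampleQC:
    """FRiP for one sample: fraction of fragments overlapping >=1 bp of any peak.

    Each fragment is counted once however many peaks it touches. Zero fragments
    leaves FRiP undefined (reported as a failing record, never a division by
    zero).
    """
    total = int(len(fragments))
    if total == 0:
        return SampleQC(sample_id, 0, 0, None, passed=False,
                        fail_reason="no fragments; FRiP undefined")
    in_peaks = int(overlaps_any(fragments, peaks).sum()) if len(peaks) else 0
    return SampleQC(sample_id, total, in_peaks, in_peaks / total)


def qc_filter(
    samples: list[SampleQC],
    min_fragments: int = MIN_FRAGMENTS_DEFAULT,
    min_frip: float = MIN_FRIP_DEFAULT,
) -> tuple[list[SampleQC], list[SampleQC]]:
    """Partition samples into (passing, failing); annotates each record in place."""
    passed: list[SampleQC] = []
    failed: list[SampleQC] = []
    for s in samples:
        reasons = []
        if s.total_fragments < min_fragments:
            reasons.append(f"total_fragments {s.total_fragments} < {min_fragments}")
        if s.frip is None:
            reasons.append("FRiP undefined (no fragments)")
        elif s.frip < min_frip:
            reasons.append(f"FRiP {s.frip:.4f} < {min_frip}")
        s.passed = not reasons
        s.fail_reason = "; ".join(reasons) or None
        (passed if s.passed else failed).append(s)
    return passed, failed


def qc_table(samples: list[SampleQC]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "total_fragments": [s.total_fragments for s in samples],
            "fragments_in_peaks": [s.fragments_in_peaks for s in samples],
            "frip": [s.frip if s.frip is not None else float("nan") for s in samples],
            "pass": [s.passed for s in samples],
            "fail_reason": [s.fail_reason or "" for s in samples],
        }
    )
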