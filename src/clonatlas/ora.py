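"""Over-representation analysis of gene sets against term annotations.

For each term, membership of the study set is tested against the universe by
a one-sided hypergeometric upper tail; fold enrichment is (k/n)/(K/N). FDR is
Benjamini-Hochberg across tested terms. Terms annotating fewer than
``min_term_size`` universe genes (default 3) are skipped as noise. Display
convention in dot plots: show a term only when FDR < 0.01.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

FDR_DISPLAY = 0.01
MIN_TERM_SIZE = 3


def ora(
    study: set[str],
    universe: set[str],
    terms: dict[str, list[str]],
    min_term_size: int = MIN_TERM_SIZE,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``study`` within ``universe``.

    The study set must be contained in the universe; term memberships are
    intersected with the universe before testing. Rows are sorted by p-value.
    """
    offenders = study - universe
    if offenders:
        raise ValueError(
            f"study genes outside the universe: {sorted(offenders)[:10]}"
            + ("..." if len(offenders) > 10 else "")
        )
    N, n = len(universe), len(study)
    rows = []
    for term, members in terms.items():
        in_universe = set(members) & universe
        K = len(in_universe)
        if K < min_term_size:
            continue
        k = len(in_universe & study)
        fold = (k / n) / (K / N) if n else 0.0
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term,
                "study_hits": k,
                "study_size": n,
                "term_size": K,
                "universe_size": N,
                "fold_enrichment": fold,
                "p_value": p,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["term_id", "study_hits", "study_size", "term_size",
                 "universe_size", "fold_enrichment", "p_value"],
    )
    if len(table):
        table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["displayed"] = table["fdr"] < FDR_DISPLAY
        table = table.sort_values("p_value", ignore_index=True)
    else:
        table["fdr"] = np.nan
        table["displayed"] = False
    return table
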