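"""Amino-acid composition comparison between the two sides of a pair set.

Produces the classic HP-vs-MP composition table: per amino acid, the mean
and standard deviation of its fraction on each side, with unpaired and
paired two-sample t-test p-values for the difference.  The paired test uses
the ortholog pairing and is typically far more sensitive than the unpaired
one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .features import DEFAULT_CONFIG, ResidueClassConfig, extract_features
from .seqio import LabeledPair
from .tables import STANDARD_AA


def composition_stats(
    pairs: list[LabeledPair], cfg: ResidueClassConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Per-amino-acid composition comparison across a labeled pair set.

    Returns a DataFrame indexed by amino acid with columns
    ``mean_stable``, ``sd_stable``, ``mean_other``, ``sd_other``,
    ``p_unpaired``, ``p_paired``.
    """
    if not pairs:
        raise ValueError("composition comparison requires at least one pair")
    names = [f"x_{aa}" for aa in STANDARD_AA]
    S = np.array([[extract_features(p.stable, cfg)[n] for n in names] for p in pairs])
    O = np.array([[extract_features(p.other, cfg)[n] for n in names] for p in pairs])
    rows = {}
    for j, aa in enumerate(STANDARD_AA):
        s, o = S[:, j], O[:, j]
        if len(pairs) >= 2 and (s.std() > 0 or o.std() > 0):
            p_unpaired = float(stats.ttest_ind(s, o).pvalue)
            p_paired = float(stats.ttest_rel(s, o).pvalue) if np.any(s != o) else 1.0
        else:
            p_unpaired = p_paired = float("nan")
        rows[aa] = {
            "mean_stable": float(s.mean()),
            "sd_stable": float(s.std(ddof=1)) if len(pairs) > 1 else 0.0,
            "mean_other": float(o.mean()),
            "sd_other": float(o.std(ddof=1)) if len(pairs) > 1 else 0.0,
            "p_unpaired": p_unpaired,
            "p_paired": p_paired,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "amino_acid"
    return df
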