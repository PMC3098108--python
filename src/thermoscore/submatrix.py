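"""Directional amino-acid substitution preference matrix.

Given pre-aligned mesophilic/hyperthermophilic (MP/HP) ortholog pairs with
the MP sequence as the top row, every aligned column holding two distinct
standard residues increments the directional count N(mp -> hp).  The
aggregate over a pair collection is a 20x20 table with 380 informative
off-diagonal cells.  For each unordered residue pair the forward/reverse
count ratio and a two-sided symmetry p-value (exact binomial at p = 0.5 by
default; a Fisher variant against the direction totals is available)
quantify substitution bias between the two thermal classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import inf, isnan, nan

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import GAP, AlignedPair
from .tables import STANDARD_AA


def count_pair_substitutions(ap: AlignedPair) -> Counter:
    """Directional substitution counts from one aligned pair.

    Top row is MP, bottom row is HP (caller's contract).  Columns with a
    gap, an ambiguity code, or identical residues are ignored; for every
    other column the count for (mp_residue, hp_residue) is incremented.
    """
    counts: Counter = Counter()
    std = set(STANDARD_AA)
    for mp_res, hp_res in zip(ap.top, ap.bottom):
        if mp_res == GAP or hp_res == GAP:
            continue
        if mp_res not in std or hp_res not in std:
            continue
        if mp_res != hp_res:
            counts[(mp_res, hp_res)] += 1
    return counts


def symmetry_pvalue(n_forward: int, n_reverse: int, method: str = "binomial") -> float:
    """Two-sided p-value for asymmetry of forward vs reverse counts.

    ``binomial`` (default): exact two-sided binomial test of k = n_forward
    successes in n = n_forward + n_reverse trials at p = 0.5, minlike
    convention (sum of all outcome probabilities not exceeding that of the
    observed count).  ``fisher`` is only meaningful through
    :meth:`SubstitutionMatrix.pvalue`, where the direction totals provide
    the second row of the 2x2 table.  n = 0 gives p = 1 by convention.
    """
    if n_forward < 0 or n_reverse < 0:
        raise ValueError("substitution counts must be non-negative")
    if method != "binomial":
        raise ValueError("only 'binomial' is defined from two counts alone; "
                         "use SubstitutionMatrix.pvalue for the Fisher variant")
    n = n_forward + n_reverse
    if n == 0:
        return 1.0
    return float(stats.binomtest(n_forward, n, p=0.5, alternative="two-sided").pvalue)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """20x20 directional count table with asymmetry statistics.

    ``counts[a][b]`` is N(a -> b), the number of aligned columns where MP
    has residue a and HP has residue b; the diagonal is unused and zero.
    """

    counts: pd.DataFrame  # index = MP residue, columns = HP residue
    skipped_columns: int = 0  # ambiguity-code columns ignored during counting

    @classmethod
    def from_tables(cls, tables_: list[Counter], skipped: int = 0) -> "SubstitutionMatrix":
        """Aggregate per-pair sparse count tables element-wise."""
        aas = list(STANDARD_AA)
        M = pd.DataFrame(0, index=aas, columns=aas, dtype=int)
        for t in tables_:
            for (a, b), n in t.items():
                M.loc[a, b] += n
        return cls(counts=M, skipped_columns=skipped)

    @classmethod
    def from_aligned_pairs(cls, pairs: list[AlignedPair]) -> "SubstitutionMatrix":
        std = set(STANDARD_AA)
        skipped = 0
        for ap in pairs:
            for a, b in zip(ap.top, ap.bottom):
                if a != GAP and b != GAP and (a not in std or b not in std):
                    skipped += 1
        return cls.from_tables([count_pair_substitutions(ap) for ap in pairs], skipped)

    @property
    def total(self) -> int:
        """Total mismatched aligned standard-residue columns."""
        return int(self.counts.to_numpy().sum())

    def count(self, a: str, b: str) -> int:
        return int(self.counts.loc[a, b])

    def ratio(self, a: str, b: str) -> float:
        """Forward/reverse ratio N(a->b)/N(b->a); inf if reverse is 0 and
        forward > 0, NaN if both are 0."""
        fwd, rev = self.count(a, b), self.count(b, a)
        if rev == 0:
            return inf if fwd > 0 else nan
        return fwd / rev

    def pvalue(self, a: str, b: str, method: str = "binomial") -> float:
        """Two-sided symmetry p-value for the unordered pair {a, b}.

        Symmetric in its arguments.  ``method='fisher'`` tests the 2x2 table
        [[N(a->b), N(b->a)], [T - N(a->b), T - N(b->a)]] where T is the
        total substitution count, i.e. whether the a->b exchange is biased
        relative to the overall directional flow.
        """
        fwd, rev = self.count(a, b), self.count(b, a)
        if method == "binomial":
            return symmetry_pvalue(fwd, rev)
        if method == "fisher":
            if fwd + rev == 0:
                return 1.0
            T = self.total
            table = [[fwd, rev], [T - fwd, T - rev]]
            return float(stats.fisher_exact(table, alternative="two-sided")[1])
        raise ValueError(f"unknown method {method!r}")

    def to_long_table(
        self, method: str = "binomial", significance: float = 1e-10
    ) -> pd.DataFrame:
        """Long-format table over all 380 ordered off-diagonal cells.

        Columns: mp, hp, count, reverse_count, ratio, pvalue, significant.
        The default significance threshold of 1e-10 flags strongly biased
        substitutions.
        """
        rows = []
        for a in STANDARD_AA:
            for b in STANDARD_AA:
                if a == b:
                    continue
                rows.append({
                    "mp": a,
                    "hp": b,
                    "count": self.count(a, b),
                    "reverse_count": self.count(b, a),
                    "ratio": self.ratio(a, b),
                    "pvalue": self.pvalue(a, b, method),
                })
        df = pd.DataFrame(rows)
        df["significant"] = df["pvalue"] < significance
        return df


def aggregate_matrix(tables_: list[Counter]) -> SubstitutionMatrix:
    """Element-wise sum of per-pair count tables into one matrix."""
    return SubstitutionMatrix.from_tables(tables_)
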