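"""Short-motif statistics around the cleavage site.

Beyond single-subsite preferences, a protease may recognise short sequence
patterns spanning the residues just upstream of the scissile bond.  This
module covers:

* P2–P1 ordered pair counts and their enrichment Z-scores against an
  ordered-dipeptide background (the same binomial-proportion form used for
  single residues, for internal consistency);
* the P1 distribution conditioned on a chosen residue occupying P2 (e.g.
  proline), versus all other cases — a direct test of whether the P2
  context restricts the P1 repertoire;
* ranked P3–P2–P1 triplet patterns, both concrete triples and generalized
  templates with wildcards ('X') and residue classes ('[LMP]').
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._aa import AMINO_ACIDS, AA_INDEX
from .extraction import CleavageWindow
from .profile import BackgroundComposition, _window_strings

__all__ = [
    "PairMatrix",
    "TripletPattern",
    "PairMotifProfiler",
    "pair_counts",
    "pair_zscores",
    "conditional_p1_distribution",
    "triplet_patterns",
]


def _subsite_column(windows: Sequence, label: str) -> list[str]:
    """Residue at a named subsite for each window (plain strings assume the
    default P6..P5' layout)."""
    out = []
    for w in windows:
        if isinstance(w, CleavageWindow):
            out.append(w.subsite(label))
        else:
            from ._aa import subsite_labels

            out.append(str(w)[subsite_labels(6, len(str(w)) - 6).index(label)])
    return out


@dataclass
class PairMatrix:
    """20 × 20 ordered (P2 residue, P1 residue) matrix; rows are P2,
    columns P1, both alphabetical."""

    counts: np.ndarray
    n_pairs: int
    layer: str = "count"
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(AMINO_ACIDS), len(AMINO_ACIDS)):
            raise ValueError(f"pair counts must be 20 x 20, got {self.counts.shape}")
        if int(self.counts.sum()) != self.n_pairs:
            raise ValueError("counts must sum to n_pairs")

    def layer_values(self) -> np.ndarray:
        return self.counts.astype(float) if self.layer == "count" else self.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.layer_values(), index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS)
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="P2", float_format="%.10g")

    def top_pairs(self, k: int = 10) -> list[tuple[str, str, float]]:
        """The k largest entries as (P2, P1, value), descending; ties break
        alphabetically by (P2, P1)."""
        vals = self.layer_values()
        entries = [
            (AMINO_ACIDS[i], AMINO_ACIDS[j], float(vals[i, j]))
            for i in range(len(AMINO_ACIDS))
            for j in range(len(AMINO_ACIDS))
        ]
        entries.sort(key=lambda t: (-t[2], t[0], t[1]))
        return entries[:k]


@dataclass(frozen=True)
class TripletPattern:
    """A P3–P2–P1 pattern: each symbol is a residue, 'X' (any residue), or
    a bracketed residue class like '[LMP]'; e.g. ``G-X-[LMP]``."""

    pattern: str
    count: int = 0

    def matchers(self) -> list[frozenset[str]]:
        symbols = re.split(r"[-–]", self.pattern)
        if len(symbols) != 3:
            raise ValueError(f"triplet pattern needs 3 symbols: {self.pattern!r}")
        out = []
        for sym in symbols:
            sym = sym.strip()
            if sym == "X":
                out.append(frozenset(AMINO_ACIDS))
            elif sym.startswith("[") and sym.endswith("]"):
                out.append(frozenset(sym[1:-1].replace("/", "")))
            elif len(sym) == 1 and sym in AA_INDEX:
                out.append(frozenset(sym))
            else:
                raise ValueError(f"bad pattern symbol {sym!r} in {self.pattern!r}")
        return out

    def matches(self, triple: str) -> bool:
        return len(triple) == 3 and all(
            res in allowed for res, allowed in zip(triple, self.matchers())
        )


def pair_counts(windows: Sequence) -> PairMatrix:
    """Count ordered (P2, P1) residue pairs over windows with both subsites
    defined and canonical."""
    p2s = _subsite_column(windows, "P2")
    p1s = _subsite_column(windows, "P1")
    counts = np.zeros((len(AMINO_ACIDS), len(AMINO_ACIDS)), dtype=int)
    for a, b in zip(p2s, p1s):
        i, j = AA_INDEX.get(a), AA_INDEX.get(b)
        if i is not None and j is not None:
            counts[i, j] += 1
    return PairMatrix(counts, int(counts.sum()))


def pair_zscores(
    pairs: PairMatrix, background: BackgroundComposition
) -> PairMatrix:
    """Binomial-proportion Z of each observed pair frequency against the
    background ordered-dipeptide frequency:

        Z[a][b] = (p_ab - q_ab) / sqrt(q_ab (1 - q_ab) / n_pairs)

    An observed pair with zero background frequency is fatal (the
    background does not cover the observation).
    """
    q = background.dipeptide_matrix()
    if pairs.n_pairs < 1:
        raise ValueError("no pairs counted")
    p_hat = pairs.counts / pairs.n_pairs
    bad = (pairs.counts > 0) & (q == 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"pair {AMINO_ACIDS[i]}-{AMINO_ACIDS[j]} observed but has zero "
            "background dipeptide frequency"
        )
    se = np.sqrt(q * (1.0 - q) / pairs.n_pairs)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (p_hat - q) / se
    degenerate = se == 0
    if degenerate.any():
        with np.errstate(invalid="ignore"):
            z = np.where(degenerate & (p_hat == q), 0.0, z)
            z = np.where(degenerate & (p_hat != q), np.sign(p_hat - q) * np.inf, z)
    return PairMatrix(pairs.counts, pairs.n_pairs, layer="zscore", values=z)


def conditional_p1_distribution(
    windows: Sequence, condition_residue: str = "P"
) -> dict:
    """P1 residue frequencies in two partitions of the defined-P2 windows:
    those with ``condition_residue`` at P2 and all others.

    Returns a dict with frequency vectors (length 20, alphabetical), the
    partition event counts, and flags marking empty partitions.
    """
    p2s = _subsite_column(windows, "P2")
    p1s = _subsite_column(windows, "P1")
    with_counts = np.zeros(len(AMINO_ACIDS))
    without_counts = np.zeros(len(AMINO_ACIDS))
    n_with = n_without = 0
    for a, b in zip(p2s, p1s):
        if a not in AA_INDEX or b not in AA_INDEX:
            continue
        if a == condition_residue:
            with_counts[AA_INDEX[b]] += 1
            n_with += 1
        else:
            without_counts[AA_INDEX[b]] += 1
            n_without += 1
    return {
        "condition_residue": condition_residue,
        "freq_with": with_counts / n_with if n_with else with_counts,
        "freq_without": without_counts / n_without if n_without else without_counts,
        "n_with": n_with,
        "n_without": n_without,
        "insufficient_with": n_with == 0,
        "insufficient_without": n_without == 0,
    }


def triplet_patterns(
    windows: Sequence, patterns: Sequence[str] = ()
) -> list[TripletPattern]:
    """Rank P3–P2–P1 triples by occurrence.

    Counts every concrete triple with all three subsites defined, plus any
    user-declared generalized patterns (wildcards / residue classes).
    Ranked by count descending, ties alphabetical by pattern string.
    """
    p3s = _subsite_column(windows, "P3")
    p2s = _subsite_column(windows, "P2")
    p1s = _subsite_column(windows, "P1")
    triples = [
        a + b + c
        for a, b, c in zip(p3s, p2s, p1s)
        if a in AA_INDEX and b in AA_INDEX and c in AA_INDEX
    ]
    concrete: dict[str, int] = {}
    for t in triples:
        key = f"{t[0]}-{t[1]}-{t[2]}"
        concrete[key] = concrete.get(key, 0) + 1
    ranked = [TripletPattern(p, c) for p, c in concrete.items()]
    for pat in patterns:
        template = TripletPattern(pat)
        count = sum(template.matches(t) for t in triples)
        ranked.append(TripletPattern(pat, count))
    ranked.sort(key=lambda tp: (-tp.count, tp.pattern))
    return ranked


class PairMotifProfiler(BaseEstimator):
    """Estimator for P2–P1 pair statistics and conditional P1 analysis.

    Attributes after fit: ``pair_counts_`` (PairMatrix), ``pair_zscores_``
    (PairMatrix, if the background carries dipeptide frequencies),
    ``top_pairs_`` (ranked (P2, P1, Z)), and ``conditional_``
    (the P2-conditioned P1 distributions).
    """

    def __init__(
        self,
        background: BackgroundComposition | None = None,
        condition_residue: str = "P",
        top_k: int = 10,
    ):
        self.background = background
        self.condition_residue = condition_residue
        self.top_k = top_k

    def fit(self, X: Sequence, y=None):
        self.pair_counts_ = pair_counts(X)
        if self.background is not None and self.background.dipeptide_freq is not None:
            self.pair_zscores_ = pair_zscores(self.pair_counts_, self.background)
            self.top_pairs_ = self.pair_zscores_.top_pairs(self.top_k)
        else:
            self.top_pairs_ = self.pair_counts_.top_pairs(self.top_k)
        self.conditional_ = conditional_p1_distribution(X, self.condition_residue)
        return self
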