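"""Unique-peptide length distributions and missed-cleavage accounting.

The length of the fragments a protease produces is itself a specificity
signature: an enzyme that cleaves densely and processively yields short
peptides, a selective one yields long fragments with many skipped
(missed) sites.  All statistics here run on unique peptide sequences —
a peptide identified by many spectra is one observation of the enzyme's
behaviour, not many.

A missed cleavage is an internal peptide residue matching the enzyme's
cleavage-residue set that was left uncut.  The final residue of a peptide
is never a missed cleavage (it is the realized cut, or the protein's
natural terminus); the first residue is eligible, since the cut that
produced the peptide's N-terminus happened one bond earlier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median as _median
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._aa import round_half_up

logger = logging.getLogger(__name__)

__all__ = [
    "LengthSummary",
    "MissedCleavageReport",
    "LengthProfiler",
    "length_summary",
    "count_missed_cleavages",
    "missed_cleavage_report",
    "LENGTH_BINS",
]

#: Named length ranges used for binned reporting.  The open-ended last bin
#: keeps the conventional ">21" label while covering every length the
#: "17-20" bin does not, so the five bins partition lengths >= 5.
LENGTH_BINS: tuple[tuple[str, int, int], ...] = (
    ("5-8", 5, 8),
    ("9-12", 9, 12),
    ("13-16", 13, 16),
    ("17-20", 17, 20),
    (">21", 21, 10**9),
)


@dataclass
class LengthSummary:
    """Moments, order statistics and percentage histogram of unique-peptide
    lengths.  ``histogram`` covers every observed length; ``bins`` covers
    the five named ranges (lengths below 5 fall outside them and their
    count is reported separately)."""

    n_unique: int
    mean: float
    sd: float
    median: float
    mode: int
    histogram: dict[int, float]
    bins: dict[str, float]
    n_below_bins: int = 0

    def to_dict(self) -> dict:
        return {
            "n_unique": self.n_unique,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "mode": self.mode,
            "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
            "bins": dict(self.bins),
            "n_below_bins": self.n_below_bins,
        }


@dataclass
class MissedCleavageReport:
    """Fraction of unique peptides containing at least one missed cleavage
    for a given cleavage-residue set, with per-peptide counts."""

    rule_residues: frozenset[str]
    n_peptides: int
    n_with_missed: int
    fraction: float  # percentage of peptides with >= 1 missed cleavage
    per_peptide: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "rule_residues": "".join(sorted(self.rule_residues)),
            "n_peptides": self.n_peptides,
            "n_with_missed": self.n_with_missed,
            "fraction_pct": self.fraction,
            "mean_missed_per_peptide": (
                sum(self.per_peptide.values()) / self.n_peptides
                if self.n_peptides else 0.0
            ),
        }


def length_summary(peptides: Iterable[str]) -> LengthSummary:
    """Summarise the length distribution of a unique peptide set.

    Duplicate sequences are collapsed before counting.  The mode is the
    most frequent length, ties broken toward the smaller length; the
    standard deviation is the sample (n-1) estimator, 0 for a single
    peptide.  Histogram and bin values are percentages of all unique
    peptides, so the histogram sums to 100 and each named bin equals the
    sum of its member lengths' histogram mass.
    """
    unique = sorted(set(peptides))
    if not unique:
        raise ValueError("empty peptide set")
    lengths = np.array([len(p) for p in unique])
    n = len(lengths)
    values, counts = np.unique(lengths, return_counts=True)
    mode = int(values[np.argmax(counts)])  # np.unique sorts → smallest tie wins
    histogram = {int(v): 100.0 * c / n for v, c in zip(values, counts)}
    bins = {
        label: float(100.0 * np.sum(counts[(values >= lo) & (values <= hi)]) / n)
        for label, lo, hi in LENGTH_BINS
    }
    n_below = int(np.sum(counts[values < LENGTH_BINS[0][1]]))
    if n_below:
        logger.info("%d unique peptides shorter than %d fall outside the named bins",
                    n_below, LENGTH_BINS[0][1])
    return LengthSummary(
        n_unique=n,
        mean=float(lengths.mean()),
        sd=float(lengths.std(ddof=1)) if n > 1 else 0.0,
        median=float(_median(lengths.tolist())),
        mode=mode,
        histogram=histogram,
        bins=bins,
        n_below_bins=n_below,
    )


def count_missed_cleavages(peptide: str, rule_residues: Iterable[str]) -> int:
    """Number of internal residues of ``peptide`` (all but the final one)
    belonging to ``rule_residues``."""
    if len(peptide) < 1:
        raise ValueError("empty peptide")
    residues = frozenset(rule_residues)
    return sum(1 for r in peptide[:-1] if r in residues)


def missed_cleavage_report(
    peptides: Iterable[str], rule_residues: Iterable[str]
) -> MissedCleavageReport:
    """Missed-cleavage statistics over a unique peptide set: per-peptide
    counts and the percentage of peptides with at least one miss."""
    unique = sorted(set(peptides))
    residues = frozenset(rule_residues)
    per_peptide = {p: count_missed_cleavages(p, residues) for p in unique}
    n = len(unique)
    n_with = sum(1 for c in per_peptide.values() if c > 0)
    return MissedCleavageReport(
        rule_residues=residues,
        n_peptides=n,
        n_with_missed=n_with,
        fraction=100.0 * n_with / n if n else 0.0,
        per_peptide=per_peptide,
    )


class LengthProfiler(BaseEstimator):
    """Estimator wrapping length and missed-cleavage summaries.

    ``rule_residues`` is the cleavage-residue set used for missed-cleavage
    accounting (e.g. "G" or "GK"); leave empty to skip it.
    Fitted attributes: ``summary_`` (LengthSummary), ``missed_``
    (MissedCleavageReport or None), plus convenience scalars ``mean_``,
    ``sd_``, ``median_``, ``mode_``, ``missed_fraction_``.
    """

    def __init__(self, rule_residues: str = ""):
        self.rule_residues = rule_residues

    def fit(self, X: Sequence[str], y=None):
        self.summary_ = length_summary(X)
        self.mean_ = self.summary_.mean
        self.sd_ = self.summary_.sd
        self.median_ = self.summary_.median
        self.mode_ = self.summary_.mode
        if self.rule_residues:
            self.missed_ = missed_cleavage_report(X, self.rule_residues)
            self.missed_fraction_ = self.missed_.fraction
        else:
            self.missed_ = None
            self.missed_fraction_ = None
        return self

    def report_percent(self, ndigits: int = 1) -> dict:
        """Headline numbers rounded the way summary tables print them."""
        out = {
            "n_unique": self.summary_.n_unique,
            "mean": round_half_up(self.mean_, 2),
            "sd": round_half_up(self.sd_, 2),
            "median": self.median_,
            "mode": self.mode_,
        }
        if self.missed_fraction_ is not None:
            out["missed_fraction_pct"] = round_half_up(self.missed_fraction_, ndigits)
        return out
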