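"""Position-specific specificity matrices and background normalization.

The central object is a residue × subsite matrix built from cleavage
windows.  Four layers are derived from the same counts:

``raw_count``
    counts[r][s] = number of windows with residue r at subsite s.  Padded
    (out-of-protein) and non-canonical slots are not observations and do
    not contribute anywhere.
``frequency``
    counts divided by the per-subsite number of defined observations, so
    each subsite column is a probability vector over the 20 residues.
``normalized_ratio``
    observed frequency divided by the residue's background frequency —
    the enrichment of a residue at a subsite over its natural abundance.
``zscore``
    the deviation of the observed frequency from the background
    expectation in standard-deviation units, under a one-sample
    binomial-proportion model per cell:

        Z[r][s] = (f_obs[r][s] - q[r]) / sqrt(q[r] (1 - q[r]) / n[s])

    with q the background frequency and n the subsite's defined count.

Backgrounds come either from an external composition table (e.g. a
database-wide snapshot) or from the pooled residues of the identified
proteins themselves, each protein counted once.

:class:`SpecificityProfiler` wraps the whole chain as a scikit-learn-style
estimator so it can sit in standard tooling; the module-level functions
are the thin functional surface over the same computations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._aa import AMINO_ACIDS, AA_INDEX, round_half_up, subsite_labels
from .extraction import CleavageWindow

__all__ = [
    "SpecificityMatrix",
    "BackgroundComposition",
    "SpecificityProfiler",
    "build_matrix",
    "background_from_proteins",
    "normalize",
    "zscore",
    "compare_compositions",
]

LAYERS = ("raw_count", "frequency", "normalized_ratio", "zscore")


def _window_strings(windows: Sequence) -> list[str]:
    return [w.residues if isinstance(w, CleavageWindow) else str(w) for w in windows]


@dataclass
class SpecificityMatrix:
    """Residue × subsite matrix in one of the four layers.

    ``counts`` (20 × n_subsites) and ``n_defined`` (per-subsite defined
    observations) are always present; ``values`` carries the layer's reals
    for non-count layers.  Rows follow :data:`AMINO_ACIDS` (alphabetical),
    columns follow ``subsites`` (N- to C-terminal).
    """

    counts: np.ndarray
    n_defined: np.ndarray
    subsites: list[str] = field(default_factory=subsite_labels)
    layer: str = "raw_count"
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.n_defined = np.asarray(self.n_defined, dtype=int)
        if self.counts.shape != (len(AMINO_ACIDS), len(self.subsites)):
            raise ValueError(
                f"counts must be {len(AMINO_ACIDS)} x {len(self.subsites)}, "
                f"got {self.counts.shape}"
            )
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if (self.counts.sum(axis=0) != self.n_defined).any():
            raise ValueError("counts column sums must equal n_defined")

    @property
    def frequencies(self) -> np.ndarray:
        """Per-subsite residue frequencies (columns sum to 1 where any
        observation is defined)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = self.counts / self.n_defined
        return np.where(self.n_defined > 0, freq, 0.0)

    def layer_values(self) -> np.ndarray:
        if self.layer == "raw_count":
            return self.counts.astype(float)
        if self.layer == "frequency":
            return self.frequencies
        assert self.values is not None
        return self.values

    def percent(self, residue: str, subsite: str, ndigits: int = 1) -> float:
        """Observed frequency of ``residue`` at ``subsite`` as a percentage,
        rounded half-up (the convention of printed tables)."""
        f = self.frequencies[AA_INDEX[residue], self.subsites.index(subsite)]
        return round_half_up(100.0 * f, ndigits)

    def with_layer(self, layer: str, values: np.ndarray) -> "SpecificityMatrix":
        return SpecificityMatrix(
            self.counts, self.n_defined, list(self.subsites), layer, np.asarray(values, float)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.layer_values(), index=list(AMINO_ACIDS), columns=self.subsites
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="residue", float_format="%.10g")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "layer": self.layer,
            "subsites": self.subsites,
            "residues": list(AMINO_ACIDS),
            "n_defined": self.n_defined.tolist(),
            "values": self.layer_values().tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class BackgroundComposition:
    """Per-residue (and optionally per-ordered-dipeptide) frequencies of a
    reference set, used as the null expectation for enrichment."""

    source: str  # "identified_proteins" or "external_table"
    residue_freq: dict[str, float]
    dipeptide_freq: dict[str, float] | None = None
    n_residues: int = 0

    def __post_init__(self) -> None:
        total = sum(self.residue_freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"residue frequencies sum to {total}, expected 1")
        if self.dipeptide_freq is not None:
            total = sum(self.dipeptide_freq.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"dipeptide frequencies sum to {total}, expected 1")

    def residue_vector(self) -> np.ndarray:
        vec = np.zeros(len(AMINO_ACIDS))
        for res, f in self.residue_freq.items():
            if res in AA_INDEX:
                vec[AA_INDEX[res]] = f
        return vec

    def dipeptide_matrix(self) -> np.ndarray:
        """Ordered-pair frequencies as a 20 × 20 matrix indexed
        (first residue, second residue)."""
        if self.dipeptide_freq is None:
            raise ValueError("background has no dipeptide frequencies")
        mat = np.zeros((len(AMINO_ACIDS), len(AMINO_ACIDS)))
        for pair, f in self.dipeptide_freq.items():
            a, b = pair[0], pair[1]
            if a in AA_INDEX and b in AA_INDEX:
                mat[AA_INDEX[a], AA_INDEX[b]] = f
        return mat

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BackgroundComposition":
        """Read a two-column (residue, frequency) table, e.g. a database
        composition snapshot."""
        table = pd.read_csv(path, sep="\t", comment="#", header=None,
                            names=["residue", "frequency"])
        freq = {str(r).strip().upper(): float(f)
                for r, f in zip(table["residue"], table["frequency"])}
        total = sum(freq.values())
        if total <= 0:
            raise ValueError(f"{path}: background frequencies sum to {total}")
        freq = {r: f / total for r, f in freq.items()}  # tolerate percent tables
        return cls(source="external_table", residue_freq=freq)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            for res in AMINO_ACIDS:
                handle.write(f"{res}\t{self.residue_freq.get(res, 0.0):.10g}\n")


def build_matrix(windows: Sequence) -> SpecificityMatrix:
    """Tally residues per subsite over a window collection (raw counts).

    Padded and non-canonical slots are excluded both from the counts and
    from the per-subsite denominators.  Raises on empty input: a matrix of
    no cleavage sites is meaningless.
    """
    strings = _window_strings(windows)
    if not strings:
        raise ValueError("no cleavage sites: cannot build a specificity matrix")
    width = len(strings[0])
    if any(len(s) != width for s in strings):
        raise ValueError("all windows must have the same subsite width")
    counts = np.zeros((len(AMINO_ACIDS), width), dtype=int)
    for s in strings:
        for j, res in enumerate(s):
            i = AA_INDEX.get(res)
            if i is not None:
                counts[i, j] += 1
    first = windows[0]
    if isinstance(first, CleavageWindow):
        labels = subsite_labels(first.upstream, first.downstream)
    else:
        labels = subsite_labels(6, width - 6) if width >= 7 else [f"s{j}" for j in range(width)]
    return SpecificityMatrix(counts, counts.sum(axis=0), labels)


def background_from_proteins(
    proteins: Iterable[tuple[str, str]] | dict[str, str],
) -> BackgroundComposition:
    """Residue and ordered-dipeptide frequencies pooled over a unique
    protein set (each protein counted once, regardless of how many peptides
    identified it).  Dipeptides are adjacent ordered pairs within each
    sequence; pairs never span protein boundaries.  Non-canonical residues
    are skipped, as are pairs touching one.
    """
    if isinstance(proteins, dict):
        items = sorted(proteins.items())
    else:
        items = sorted(set(proteins))
    if not items:
        raise ValueError("empty protein set")
    counts = np.zeros(len(AMINO_ACIDS), dtype=np.int64)
    pair_counts = np.zeros((len(AMINO_ACIDS), len(AMINO_ACIDS)), dtype=np.int64)
    for _, seq in items:
        prev = None
        for res in seq:
            i = AA_INDEX.get(res)
            if i is not None:
                counts[i] += 1
                if prev is not None:
                    pair_counts[prev, i] += 1
            prev = i
    n = int(counts.sum())
    if n == 0:
        raise ValueError("protein set contains no canonical residues")
    residue_freq = {aa: counts[i] / n for i, aa in enumerate(AMINO_ACIDS)}
    n_pairs = int(pair_counts.sum())
    dipeptide_freq = None
    if n_pairs:
        dipeptide_freq = {
            a + b: pair_counts[i, j] / n_pairs
            for i, a in enumerate(AMINO_ACIDS)
            for j, b in enumerate(AMINO_ACIDS)
        }
    return BackgroundComposition(
        source="identified_proteins",
        residue_freq=residue_freq,
        dipeptide_freq=dipeptide_freq,
        n_residues=n,
    )


def normalize(
    matrix: SpecificityMatrix, background: BackgroundComposition
) -> SpecificityMatrix:
    """Divide observed subsite frequencies by background residue
    frequencies (enrichment-ratio layer).

    A residue observed at any subsite must have non-zero background
    frequency; a zero-background residue that is never observed gets
    ratio 0.
    """
    q = background.residue_vector()
    freq = matrix.frequencies
    observed = matrix.counts.sum(axis=1) > 0
    bad = observed & (q == 0)
    if bad.any():
        residues = ", ".join(np.array(list(AMINO_ACIDS))[bad])
        raise ValueError(
            f"residue(s) {residues} observed in windows but have zero "
            "background frequency"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(q[:, None] > 0, freq / np.where(q[:, None] > 0, q[:, None], 1.0), 0.0)
    return matrix.with_layer("normalized_ratio", ratio)


def zscore(
    matrix: SpecificityMatrix, background: BackgroundComposition
) -> SpecificityMatrix:
    """Binomial-proportion Z-scores of observed subsite frequencies against
    the background.

    Degenerate background frequencies (0 or 1) have zero sampling variance:
    the Z is 0 when the observation matches the expectation exactly and
    signed infinity otherwise.
    """
    if (matrix.n_defined < 1).any():
        raise ValueError("every subsite needs at least one defined observation")
    q = background.residue_vector()[:, None]
    n = matrix.n_defined.astype(float)[None, :]
    f = matrix.frequencies
    se = np.sqrt(q * (1.0 - q) / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (f - q) / se
    degenerate = se == 0
    if degenerate.any():
        with np.errstate(invalid="ignore"):
            z = np.where(degenerate & (f == q), 0.0, z)
            z = np.where(degenerate & (f != q), np.sign(f - q) * np.inf, z)
    return matrix.with_layer("zscore", z)


def compare_compositions(
    a: BackgroundComposition, b: BackgroundComposition
) -> tuple[float, float]:
    """Pearson r and Spearman rho between two residue compositions, over
    the 20 paired frequencies.  Zero variance in either vector makes the
    coefficients undefined; NaN is returned."""
    x = a.residue_vector()
    y = b.residue_vector()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    pearson = stats.pearsonr(x, y).statistic
    spearman = stats.spearmanr(x, y).statistic
    return (float(pearson), float(spearman))


class SpecificityProfiler(BaseEstimator):
    """Estimator building all specificity-matrix layers from cleavage
    windows.

    Parameters
    ----------
    background : BackgroundComposition, "identified" or None
        Null model for normalization.  ``"identified"`` derives it from the
        protein set passed to :meth:`fit` (the composition actually exposed
        to the protease); ``None`` computes only counts and frequencies.

    Attributes (after fit)
    ----------------------
    matrix_ : SpecificityMatrix          raw counts
    frequencies_ : ndarray (20, S)       per-subsite residue frequencies
    n_defined_ : ndarray (S,)            defined observations per subsite
    background_ : BackgroundComposition  the background actually used
    ratios_, zscores_ : ndarray          normalized layers (if background)
    top_p1_ : list[str]                  residues by descending P1 Z-score
    """

    def __init__(self, background: BackgroundComposition | str | None = "identified"):
        self.background = background

    def fit(self, X: Sequence, y=None, proteins=None):
        """Fit on windows ``X`` (CleavageWindow objects or plain strings);
        ``proteins`` supplies (accession, sequence) pairs when the
        background is derived from the identified proteins."""
        self.matrix_ = build_matrix(X)
        self.frequencies_ = self.matrix_.frequencies
        self.n_defined_ = self.matrix_.n_defined
        background = self.background
        if background == "identified":
            if proteins is None:
                raise ValueError(
                    "background='identified' requires proteins= at fit time"
                )
            background = background_from_proteins(proteins)
        self.background_ = background
        if background is not None:
            self.ratios_ = normalize(self.matrix_, background).values
            zmat = zscore(self.matrix_, background)
            self.zscores_ = zmat.values
            p1 = self.matrix_.subsites.index("P1")
            order = np.argsort(-self.zscores_[:, p1], kind="stable")
            self.top_p1_ = [AMINO_ACIDS[i] for i in order]
        return self

    def layer(self, name: str) -> SpecificityMatrix:
        """The fitted matrix in a named layer."""
        if name == "raw_count":
            return self.matrix_
        if name == "frequency":
            return self.matrix_.with_layer("frequency", self.frequencies_)
        if name == "normalized_ratio":
            return self.matrix_.with_layer("normalized_ratio", self.ratios_)
        if name == "zscore":
            return self.matrix_.with_layer("zscore", self.zscores_)
        raise ValueError(f"unknown layer {name!r}")
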