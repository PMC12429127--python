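"""In-silico proteolysis simulator.

Generates synthetic proteomes, digests them with a probabilistic,
P1-conditioned protease rule (optionally modulated by the residue at P2),
and emits post-search-style identification tables with known ground-truth
cleavage sites.  The simulator is the generative inverse of the profiling
pipeline: feeding its output through cleavage-site extraction and
specificity profiling should recover the rule's preferred P1 residues.

The generative model is deliberately simple: each peptide bond is an
independent Bernoulli trial whose success probability is the cleavage
probability of the P1 residue times an optional multiplicative factor for
the residue occupying P2, clamped to [0, 1].  An N-terminal (initiator)
methionine is never itself a cut P1, mirroring co-translational Met removal
so that the downstream initiator-Met exclusion rule has a clean ground
truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._aa import AMINO_ACIDS, AA_INDEX, validate_composition
from .io import PeptideIdentification

logger = logging.getLogger(__name__)

__all__ = [
    "LengthLaw",
    "ProteomeSpec",
    "ProteaseRule",
    "ScoreLaw",
    "IdentificationSimConfig",
    "generate_proteome",
    "digest_protein",
    "simulate_identifications",
]

_LOGNORMAL_BOUNDS = (50, 2000)


@dataclass(frozen=True)
class LengthLaw:
    """Protein-length distribution.

    Supported laws:

    ``fixed``
        params = (length,)
    ``uniform``
        params = (min, max), inclusive integer bounds
    ``lognormal``
        params = (mu, sigma) of the underlying normal; samples are rounded
        and truncated by resampling to [50, 2000], the realistic span of
        single-domain to large multi-domain proteins.
    """

    name: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.name not in {"fixed", "uniform", "lognormal"}:
            raise ValueError(f"unknown length law: {self.name!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.name == "fixed":
            lengths = np.full(size, int(self.params[0]))
        elif self.name == "uniform":
            lo, hi = (int(p) for p in self.params)
            lengths = rng.integers(lo, hi + 1, size=size)
        else:  # lognormal, truncated by resampling
            mu, sigma = self.params
            lo, hi = _LOGNORMAL_BOUNDS
            lengths = np.rint(rng.lognormal(mu, sigma, size=size)).astype(int)
            bad = (lengths < lo) | (lengths > hi)
            while bad.any():
                lengths[bad] = np.rint(
                    rng.lognormal(mu, sigma, size=int(bad.sum()))
                ).astype(int)
                bad = (lengths < lo) | (lengths > hi)
        if (lengths < 2).any():
            raise ValueError("length law produced a protein shorter than 2 residues")
        return lengths


@dataclass(frozen=True)
class ProteomeSpec:
    """Parameters of a synthetic substrate pool.

    The defaults emulate a diverse natural substrate mixture (e.g. pooled
    tissue lysate and serum proteins): several hundred proteins with
    lognormal lengths and a near-uniform residue composition.
    """

    n_proteins: int
    length_law: LengthLaw = LengthLaw("lognormal", (6.0, 0.5))
    composition: dict[str, float] | None = None  # None → uniform over the 20
    initiator_met: bool = False
    seed: int = 0

    def composition_vector(self) -> np.ndarray:
        if self.composition is None:
            return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        return validate_composition(self.composition)


@dataclass(frozen=True)
class ProteaseRule:
    """Probabilistic cleavage specificity of a protease.

    ``p1_prob`` maps a P1 residue to its per-bond cleavage probability;
    unlisted residues are never cut.  ``p2_modifier`` multiplies that
    probability when the given residue occupies P2 (one position upstream);
    the product is clamped to [0, 1].
    """

    name: str
    p1_prob: dict[str, float] = field(default_factory=dict)
    p2_modifier: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for res, p in self.p1_prob.items():
            if res not in AA_INDEX:
                raise ValueError(f"unknown P1 residue in rule: {res!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p1_prob[{res}] = {p} outside [0, 1]")
        for res, m in self.p2_modifier.items():
            if res not in AA_INDEX:
                raise ValueError(f"unknown P2 residue in rule: {res!r}")
            if m < 0:
                raise ValueError(f"p2_modifier[{res}] = {m} is negative")

    @property
    def residues(self) -> frozenset[str]:
        """Residues with non-zero cleavage probability at P1."""
        return frozenset(r for r, p in self.p1_prob.items() if p > 0)

    def p1_vector(self) -> np.ndarray:
        vec = np.zeros(len(AMINO_ACIDS))
        for res, p in self.p1_prob.items():
            vec[AA_INDEX[res]] = p
        return vec

    def p2_vector(self) -> np.ndarray:
        vec = np.ones(len(AMINO_ACIDS))
        for res, m in self.p2_modifier.items():
            vec[AA_INDEX[res]] = m
        return vec


@dataclass(frozen=True)
class ScoreLaw:
    """A one-dimensional score distribution (``uniform`` (lo, hi) or
    ``normal`` (mu, sigma))."""

    name: str
    params: tuple[float, float]

    def __post_init__(self) -> None:
        if self.name not in {"uniform", "normal"}:
            raise ValueError(f"unknown score law: {self.name!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        a, b = self.params
        if self.name == "uniform":
            return rng.uniform(a, b, size=size)
        return rng.normal(a, b, size=size)


@dataclass(frozen=True)
class IdentificationSimConfig:
    """Detectability window, score model and decoy contamination of the
    emitted identification table.

    Defaults reflect typical LC–MS/MS identification behaviour: peptides of
    5–40 residues are detectable, confident matches score well above the
    usual ion-score confidence cut-off of 20 while spurious matches score
    below it.
    """

    detect_len: tuple[int, int] = (5, 40)
    true_score_law: ScoreLaw = ScoreLaw("uniform", (30.0, 80.0))
    decoy_score_law: ScoreLaw = ScoreLaw("uniform", (0.0, 15.0))
    decoy_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.detect_len[0] < 1 or self.detect_len[1] < self.detect_len[0]:
            raise ValueError(f"invalid detect_len window {self.detect_len}")
        if not 0.0 <= self.decoy_fraction < 1.0:
            raise ValueError("decoy_fraction must lie in [0, 1)")


def generate_proteome(spec: ProteomeSpec) -> list[tuple[str, str]]:
    """Generate ``spec.n_proteins`` random protein sequences.

    Returns ``(accession, sequence)`` pairs with unique accessions, in a
    deterministic order for a given seed.
    """
    comp = spec.composition_vector()
    rng = np.random.default_rng(spec.seed)
    lengths = spec.length_law.sample(rng, spec.n_proteins)
    residues = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    proteome: list[tuple[str, str]] = []
    width = max(4, len(str(spec.n_proteins)))
    for i, n in enumerate(lengths):
        draw = rng.choice(residues, size=int(n), p=comp)
        seq = draw.tobytes().decode()
        if spec.initiator_met:
            seq = "M" + seq[1:]
        proteome.append((f"SYN{i + 1:0{width}d}", seq))
    return proteome


def _digest_with_rng(
    sequence: str, rule: ProteaseRule, rng: np.random.Generator
) -> tuple[list[str], list[int]]:
    """Core digestion: independent Bernoulli draw per bond, left to right."""
    n = len(sequence)
    if n < 2:
        return [sequence], []
    idx = np.fromiter((AA_INDEX.get(r, -1) for r in sequence), dtype=int, count=n)
    p1 = rule.p1_vector()
    p2 = rule.p2_vector()
    # probability of cutting after position i (1-based), i = 1..n-1
    probs = np.where(idx[:-1] >= 0, p1[np.maximum(idx[:-1], 0)], 0.0)
    probs[1:] *= np.where(idx[:-2] >= 0, p2[np.maximum(idx[:-2], 0)], 1.0)
    np.clip(probs, 0.0, 1.0, out=probs)
    if sequence[0] == "M":
        probs[0] = 0.0  # initiator Met is never a cut P1
    cut_mask = rng.random(n - 1) < probs
    cuts = [int(i) + 1 for i in np.nonzero(cut_mask)[0]]
    peptides = []
    prev = 0
    for c in cuts:
        peptides.append(sequence[prev:c])
        prev = c
    peptides.append(sequence[prev:])
    return peptides, cuts


def digest_protein(
    sequence: str, rule: ProteaseRule, seed: int = 0
) -> tuple[list[str], list[int]]:
    """Digest one protein.

    Returns the ordered peptide fragments and the realized cut positions
    (1-based index of the P1 residue of each cleaved bond).  Concatenating
    the fragments always reconstructs the input sequence.
    """
    if len(sequence) < 1:
        raise ValueError("sequence must contain at least one residue")
    return _digest_with_rng(sequence, rule, np.random.default_rng(seed))


def simulate_identifications(
    proteome: list[tuple[str, str]],
    rule: ProteaseRule,
    cfg: IdentificationSimConfig,
) -> tuple[list[PeptideIdentification], list[tuple[str, int]]]:
    """Digest a proteome and emit a post-search-style identification table.

    Fragments within the detectability window become true-hit records with
    scores from the true-hit law.  A ``decoy_fraction`` of the emitted rows
    are spurious records: random substrings of real proteins (so their
    coordinates are internally consistent) scored from the decoy law.  The
    returned ground truth lists every realized cut as
    ``(accession, p1_position)``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.detect_len
    records: list[PeptideIdentification] = []
    truth: list[tuple[str, int]] = []
    for accession, sequence in proteome:
        peptides, cuts = _digest_with_rng(sequence, rule, rng)
        truth.extend((accession, c) for c in cuts)
        start = 1
        for pep in peptides:
            end = start + len(pep) - 1
            if lo <= len(pep) <= hi:
                records.append(
                    PeptideIdentification(
                        accession=accession,
                        protein_sequence=sequence,
                        peptide_sequence=pep,
                        start=start,
                        end=end,
                        score=float(cfg.true_score_law.sample(rng, 1)[0]),
                    )
                )
            start = end + 1
    n_true = len(records)
    decoy_pool = [(a, s) for a, s in proteome if len(s) >= lo]
    if cfg.decoy_fraction > 0 and n_true > 0 and decoy_pool:
        n_decoy = int(round(cfg.decoy_fraction * n_true / (1.0 - cfg.decoy_fraction)))
        for _ in range(n_decoy):
            accession, sequence = decoy_pool[rng.integers(len(decoy_pool))]
            max_len = min(hi, len(sequence))
            length = int(rng.integers(lo, max_len + 1))
            start = int(rng.integers(1, len(sequence) - length + 2))
            end = start + length - 1
            records.append(
                PeptideIdentification(
                    accession=accession,
                    protein_sequence=sequence,
                    peptide_sequence=sequence[start - 1 : end],
                    start=start,
                    end=end,
                    score=float(cfg.decoy_score_law.sample(rng, 1)[0]),
                )
            )
    logger.info(
        "simulated %d identification rows (%d true) from %d proteins",
        len(records), n_true, len(proteome),
    )
    return records, truth
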