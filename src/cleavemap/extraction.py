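"""Cleavage-site inference and subsite-window extraction.

Each identified peptide witnesses up to two protease cuts: one at its
N-terminal boundary (the residue immediately before the peptide is the P1
of that cut) and one at its C-terminal boundary (the peptide's final
residue is the P1).  Two boundary situations are not cleavage evidence and
are excluded:

* a peptide starting at protein position 1 has no N-boundary cut, and one
  starting at position 2 of a protein whose first residue is methionine is
  attributed to co-translational initiator-Met removal, not proteolysis;
* a peptide ending at the protein's last residue ends at the natural
  C-terminus, so its final residue is not a cut P1.

Sites are deduplicated by (accession, position) — a bond cleaved once is a
single specificity observation no matter how many peptides witness it.
Around every unique site a fixed window of subsites (default P6..P1 on the
N-terminal side and P1'..P5' on the C-terminal side) is read from the
parent protein, padded with ``-`` where a subsite falls outside the
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from ._aa import PAD, subsite_labels
from .io import PeptideIdentification

__all__ = [
    "CleavageSite",
    "CleavageWindow",
    "extract_sites",
    "extract_windows",
    "write_windows_tsv",
    "read_windows_tsv",
]


@dataclass(frozen=True)
class CleavageSite:
    """A unique cut position: ``position`` is the 1-based index of the P1
    residue; the bond cleaved lies between ``position`` and ``position+1``."""

    accession: str
    position: int
    p1_residue: str
    origin: str  # "n_boundary" or "c_boundary" of the witnessing peptide

    def key(self) -> tuple[str, int]:
        return (self.accession, self.position)


@dataclass(frozen=True)
class CleavageWindow:
    """A cleavage site with its fixed-length subsite context.

    ``residues`` holds one character per subsite, N- to C-terminal
    (P6..P1, P1'..P5' by default); ``-`` marks subsites outside the
    protein.
    """

    site: CleavageSite
    residues: str
    upstream: int = 6
    downstream: int = 5

    @property
    def subsites(self) -> list[str]:
        return subsite_labels(self.upstream, self.downstream)

    def subsite(self, label: str) -> str:
        """Residue at a named subsite (e.g. ``"P1"``, ``"P2'"``)."""
        return self.residues[self.subsites.index(label)]


def extract_sites(records: Iterable[PeptideIdentification]) -> list[CleavageSite]:
    """Infer unique cleavage sites from peptide boundaries.

    Returns sites sorted by (accession, position).  When the same position
    is witnessed by both an N-boundary and a C-boundary, the site counts
    once (the first witness's origin is kept).
    """
    sites: dict[tuple[str, int], CleavageSite] = {}
    for rec in records:
        protein = rec.protein_sequence
        # N-boundary: the residue before the peptide is a cut P1, unless the
        # peptide starts the protein or directly follows an initiator Met.
        if rec.start > 1 and not (rec.start == 2 and protein[0] == "M"):
            pos = rec.start - 1
            sites.setdefault(
                (rec.accession, pos),
                CleavageSite(rec.accession, pos, protein[pos - 1], "n_boundary"),
            )
        # C-boundary: the peptide's last residue is a cut P1, unless the
        # peptide ends at the protein's C-terminus.
        if rec.end < len(protein):
            sites.setdefault(
                (rec.accession, rec.end),
                CleavageSite(rec.accession, rec.end, protein[rec.end - 1], "c_boundary"),
            )
    return [sites[k] for k in sorted(sites)]


def extract_windows(
    sites: Iterable[CleavageSite],
    proteins: dict[str, str] | list[tuple[str, str]],
    upstream: int = 6,
    downstream: int = 5,
) -> list[CleavageWindow]:
    """Read the fixed subsite window around each site from its parent
    protein.

    ``proteins`` maps accession to sequence.  Subsites before the first or
    after the last residue are padded with ``-``.  Windows are returned
    sorted by (accession, position); an unresolvable accession is fatal.
    """
    if not isinstance(proteins, dict):
        proteins = dict(proteins)
    windows = []
    for site in sorted(sites, key=CleavageSite.key):
        try:
            seq = proteins[site.accession]
        except KeyError:
            raise KeyError(
                f"no protein sequence for accession {site.accession!r}"
            ) from None
        if seq[site.position - 1] != site.p1_residue:
            raise ValueError(
                f"site {site.accession}:{site.position} claims P1 "
                f"{site.p1_residue!r} but protein has {seq[site.position - 1]!r}"
            )
        chars = []
        for offset in range(-upstream + 1, downstream + 1):  # P_up..P1, P1'..P_down
            pos = site.position + offset  # 1-based
            chars.append(seq[pos - 1] if 1 <= pos <= len(seq) else PAD)
        windows.append(
            CleavageWindow(site, "".join(chars), upstream=upstream, downstream=downstream)
        )
    return windows


def write_windows_tsv(windows: Iterable[CleavageWindow], path) -> None:
    """Write sites and their windows as TSV (accession, position, p1,
    origin, window)."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "position", "p1", "origin", "window"])
        for w in windows:
            writer.writerow(
                [w.site.accession, w.site.position, w.site.p1_residue,
                 w.site.origin, w.residues]
            )


def read_windows_tsv(path, upstream: int = 6) -> list[CleavageWindow]:
    """Read windows written by :func:`write_windows_tsv`.  ``upstream``
    declares how many non-prime subsites the window column holds."""
    import csv

    windows = []
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            residues = row["window"]
            site = CleavageSite(
                row["accession"], int(row["position"]), row["p1"],
                row.get("origin", "n_boundary"),
            )
            windows.append(
                CleavageWindow(site, residues, upstream=upstream,
                               downstream=len(residues) - upstream)
            )
    return windows
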