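"""Reading and writing peptide identification results.

Supported inputs are Mascot XML exports (with protein sequences included in
the hit output) and a plain tab-separated dialect with the columns
``accession, protein_sequence, peptide_sequence, start, end, score``.
Coordinates are 1-based and inclusive on both ends, following Mascot
conventions.  Every record is checked for coordinate consistency — the
stated peptide must equal the protein substring at (start, end) — and
inconsistent records are dropped with a logged reason rather than silently
propagated.

The confidence filter retains records whose ion score is at or above a
threshold (default 20) and, optionally, collapses duplicate peptide
sequences to the single highest-scoring occurrence.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path

from lxml import etree

from ._aa import is_canonical

logger = logging.getLogger(__name__)

__all__ = [
    "PeptideIdentification",
    "FilterConfig",
    "read_mascot_xml",
    "write_mascot_xml",
    "read_identification_tsv",
    "write_identification_tsv",
    "read_fasta",
    "write_fasta",
    "apply_filters",
]

TSV_COLUMNS = ("accession", "protein_sequence", "peptide_sequence", "start", "end", "score")

# Mascot writes variable modifications inline in some export dialects,
# e.g. "M(Oxidation)" or "M[+15.99]"; specificity counting needs plain residues.
_MOD_ANNOTATION = re.compile(r"\(.*?\)|\[.*?\]")


@dataclass(frozen=True)
class PeptideIdentification:
    """One identified peptide with its parent-protein context.

    ``start`` and ``end`` are 1-based inclusive coordinates of the peptide
    in ``protein_sequence``; ``score`` carries Mascot ion-score semantics.
    """

    accession: str
    protein_sequence: str
    peptide_sequence: str
    start: int
    end: int
    score: float

    def is_consistent(self) -> bool:
        """Coordinate consistency: the peptide is the stated substring."""
        return (
            1 <= self.start <= self.end <= len(self.protein_sequence)
            and self.protein_sequence[self.start - 1 : self.end] == self.peptide_sequence
            and len(self.peptide_sequence) >= 1
        )


@dataclass(frozen=True)
class FilterConfig:
    """Confidence filter: minimum ion score (inclusive) and sequence-level
    deduplication (the highest-scoring occurrence of each distinct peptide
    sequence is retained)."""

    min_ion_score: float = 20.0
    dedupe_peptides: bool = True

    def __post_init__(self) -> None:
        if self.min_ion_score < 0:
            raise ValueError("min_ion_score must be non-negative")


def _clean_peptide(sequence: str) -> str:
    return _MOD_ANNOTATION.sub("", sequence).strip().upper()


def _validate_records(
    records: list[PeptideIdentification], source: str
) -> list[PeptideIdentification]:
    kept = []
    for rec in records:
        if not rec.is_consistent():
            logger.warning(
                "%s: dropping inconsistent record %s:%d-%d (%s): "
                "peptide does not match the protein substring",
                source, rec.accession, rec.start, rec.end, rec.peptide_sequence,
            )
            continue
        kept.append(rec)
    return kept


def _localname(element: etree._Element) -> str:
    return etree.QName(element).localname


def read_mascot_xml(path: str | Path) -> list[PeptideIdentification]:
    """Parse a Mascot XML search-result export.

    The export must include protein sequences in the hit output.  One
    record is produced per peptide hit per protein; hits under a protein
    lacking a sequence are skipped with a warning, and records failing
    coordinate consistency are dropped with a logged reason.  Unknown
    elements are ignored, so minor schema-version differences are
    tolerated.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed Mascot XML in {path}: {exc}") from exc
    records: list[PeptideIdentification] = []
    for protein in tree.iter():
        if _localname(protein) != "protein":
            continue
        accession = protein.get("accession", "")
        prot_seq = None
        peptides = []
        for child in protein.iter():
            name = _localname(child)
            if name == "prot_seq":
                prot_seq = (child.text or "").strip().upper()
            elif name == "peptide":
                peptides.append(child)
        if not prot_seq:
            logger.warning(
                "%s: protein %s has no prot_seq element; skipping its hits",
                path.name, accession,
            )
            continue
        for pep in peptides:
            fields: dict[str, str] = {}
            for child in pep.iter():
                fields[_localname(child)] = (child.text or "").strip()
            try:
                records.append(
                    PeptideIdentification(
                        accession=accession,
                        protein_sequence=prot_seq,
                        peptide_sequence=_clean_peptide(fields["pep_seq"]),
                        start=int(fields["pep_start"]),
                        end=int(fields["pep_end"]),
                        score=float(fields["pep_score"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                logger.warning(
                    "%s: skipping malformed peptide hit under %s: %s",
                    path.name, accession, exc,
                )
    return _validate_records(records, path.name)


def write_mascot_xml(records: list[PeptideIdentification], path: str | Path) -> None:
    """Write records in the minimal Mascot-export element layout read by
    :func:`read_mascot_xml` (synthetic fixture/interchange writer; not a
    full Mascot schema)."""
    root = etree.Element("mascot_search_results")
    hits = etree.SubElement(root, "hits")
    by_protein: dict[str, list[PeptideIdentification]] = {}
    for rec in records:
        by_protein.setdefault(rec.accession, []).append(rec)
    for number, (accession, recs) in enumerate(by_protein.items(), start=1):
        hit = etree.SubElement(hits, "hit", number=str(number))
        protein = etree.SubElement(hit, "protein", accession=accession)
        etree.SubElement(protein, "prot_seq").text = recs[0].protein_sequence
        for query, rec in enumerate(recs, start=1):
            pep = etree.SubElement(protein, "peptide", query=str(query), rank="1")
            etree.SubElement(pep, "pep_seq").text = rec.peptide_sequence
            etree.SubElement(pep, "pep_start").text = str(rec.start)
            etree.SubElement(pep, "pep_end").text = str(rec.end)
            etree.SubElement(pep, "pep_score").text = repr(rec.score)
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def read_identification_tsv(path: str | Path) -> list[PeptideIdentification]:
    """Read the tab-separated identification dialect.

    A missing required column is fatal; rows with non-numeric coordinates
    or scores are skipped with a warning; coordinate-inconsistent rows are
    dropped with a logged reason.
    """
    path = Path(path)
    records: list[PeptideIdentification] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        for column in TSV_COLUMNS:
            if column not in header:
                raise ValueError(f"{path}: missing required column {column!r}")
        for i, row in enumerate(reader, start=2):
            try:
                records.append(
                    PeptideIdentification(
                        accession=row["accession"],
                        protein_sequence=row["protein_sequence"].strip().upper(),
                        peptide_sequence=_clean_peptide(row["peptide_sequence"]),
                        start=int(row["start"]),
                        end=int(row["end"]),
                        score=float(row["score"]),
                    )
                )
            except (TypeError, ValueError) as exc:
                logger.warning("%s line %d: skipping malformed row: %s", path.name, i, exc)
    return _validate_records(records, path.name)


def write_identification_tsv(
    records: list[PeptideIdentification], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.accession, rec.protein_sequence, rec.peptide_sequence,
                 rec.start, rec.end, repr(rec.score)]
            )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA sequence collection as (accession, sequence) pairs."""
    from Bio import SeqIO

    return [
        (record.id, str(record.seq).upper())
        for record in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(proteome: list[tuple[str, str]], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    SeqIO.write(
        [SeqRecord(Seq(seq), id=acc, description="") for acc, seq in proteome],
        str(path),
        "fasta",
    )


def apply_filters(
    records: list[PeptideIdentification], cfg: FilterConfig = FilterConfig()
) -> list[PeptideIdentification]:
    """Apply the confidence filter.

    Retains records with ``score >= cfg.min_ion_score`` (inclusive, so a
    score exactly at the threshold passes).  Records whose peptide contains
    a residue outside the 20-letter canonical alphabet (B, Z, X, U, O, …)
    are excluded with a warning, since they cannot be counted in
    specificity matrices.  With ``dedupe_peptides`` each distinct peptide
    sequence is kept once, as its highest-scoring occurrence (first
    occurrence wins ties).  The operation is idempotent.
    """
    kept: list[PeptideIdentification] = []
    for rec in records:
        if rec.score < cfg.min_ion_score:
            continue
        if not is_canonical(rec.peptide_sequence):
            logger.warning(
                "excluding peptide %s (%s): non-canonical residue",
                rec.peptide_sequence, rec.accession,
            )
            continue
        kept.append(rec)
    if cfg.dedupe_peptides:
        best: dict[str, PeptideIdentification] = {}
        for rec in kept:
            current = best.get(rec.peptide_sequence)
            if current is None or rec.score > current.score:
                best[rec.peptide_sequence] = rec
        kept = [best[seq] for seq in best]  # insertion order = first occurrence
    return kept
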