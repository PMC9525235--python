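"""Annotation of neuropeptide precursors.

A prohormone precursor is a signal peptide followed by one or more mature
peptide copies, each flanked by short cleavage sites — classically dibasic
(K/R) motifs, but in the basal metazoans acidic (D/E) sites are equally
prominent. An amidated peptide is additionally followed in the precursor by
the glycine whose backbone nitrogen becomes the C-terminal amide.

This module locates mature peptides inside their precursors, classifies the
two-residue cleavage sites on either flank as basic / acidic / mixed /
other, checks the glycine amide donor and N-terminal pyroglutamate, and
accumulates position-specific residue counts around cleavage junctions into
logo-ready context matrices (site of 2 residues plus a 6-residue flank on
the precursor side of the junction, both configurable).

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masschem import AMINO_ACIDS, Peptidoform

__all__ = [
    "CleavageSite",
    "PrecursorAnnotation",
    "ContextMatrix",
    "map_peptides",
    "classify_sites",
    "detect_amide_donor",
    "detect_pyroglu",
    "cleavage_context",
    "annotate_precursor",
    "read_fasta",
    "write_fasta",
]

BASIC = set("KR")
ACIDIC = set("DE")
GAP = "-"


def classify_residue_pair(pair: str) -> str:
    """basic / acidic / mixed / other for a 2-residue cleavage site."""
    if len(pair) != 2:
        return "other"
    a, b = pair
    in_basic = (a in BASIC) + (b in BASIC)
    in_acidic = (a in ACIDIC) + (b in ACIDIC)
    if in_basic == 2:
        return "basic"
    if in_acidic == 2:
        return "acidic"
    if in_basic == 1 and in_acidic == 1:
        return "mixed"
    return "other"


@dataclass(frozen=True)
class CleavageSite:
    position: int              # index of the site's first residue in the precursor
    side: str                  # "n_terminal" | "c_terminal" relative to the peptide
    site_residues: str
    cls: str

    def __post_init__(self):
        if self.side not in ("n_terminal", "c_terminal"):
            raise ValueError(f"bad side {self.side!r}")


@dataclass
class PrecursorAnnotation:
    precursor_id: str
    sequence: str
    signal_peptide: tuple[int, int] | None = None
    peptide_spans: list[tuple[Peptidoform, tuple[int, int]]] = field(default_factory=list)
    cleavage_sites: list[CleavageSite] = field(default_factory=list)

    def __post_init__(self):
        for pep, (s, e) in self.peptide_spans:
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"span ({s},{e}) outside precursor bounds")
            if self.sequence[s:e] != pep.sequence:
                raise ValueError(
                    f"span ({s},{e}) subsequence != peptide {pep.sequence}"
                )


def map_peptides(
    sequence: str, peptides: list[Peptidoform]
) -> tuple[list[tuple[Peptidoform, tuple[int, int]]], list[Peptidoform]]:
    """All exact occurrences of each peptide; absent peptides go to a miss list."""
    if not peptides:
        raise ValueError("peptides must be non-empty")
    spans = []
    misses = []
    for pep in peptides:
        found = False
        start = 0
        while True:
            i = sequence.find(pep.sequence, start)
            if i < 0:
                break
            spans.append((pep, (i, i + len(pep.sequence))))
            found = True
            start = i + 1  # overlapping occurrences allowed
        if not found:
            misses.append(pep)
    spans.sort(key=lambda x: x[1])
    return spans, misses


def _c_site_start(annotation: PrecursorAnnotation, pep: Peptidoform, end: int) -> int:
    """Start of the C-terminal cleavage site, skipping one amide-donor G."""
    seq = annotation.sequence
    if pep.c_amidated and end < len(seq) and seq[end] == "G":
        return end + 1
    return end


def classify_sites(annotation: PrecursorAnnotation, site_len: int = 2) -> PrecursorAnnotation:
    """Fill ``cleavage_sites`` with classified N- and C-flank sites per span.

    Sites truncated by the precursor boundary are omitted rather than
    fabricated from partial windows.
    """
    seq = annotation.sequence
    sites = []
    for pep, (s, e) in annotation.peptide_spans:
        if s - site_len >= 0:
            res = seq[s - site_len:s]
            sites.append(
                CleavageSite(position=s - site_len, side="n_terminal",
                             site_residues=res, cls=classify_residue_pair(res))
            )
        c0 = _c_site_start(annotation, pep, e)
        if c0 + site_len <= len(seq):
            res = seq[c0:c0 + site_len]
            sites.append(
                CleavageSite(position=c0, side="c_terminal",
                             site_residues=res, cls=classify_residue_pair(res))
            )
    annotation.cleavage_sites = sites
    return annotation


def detect_amide_donor(
    annotation: PrecursorAnnotation,
) -> tuple[list[bool], list[tuple[Peptidoform, tuple[int, int]]]]:
    """Per-peptide flag: is the residue just past the span a glycine?

    Returns (flags, inconsistencies); an inconsistency is an amidated
    peptide not followed by G (peptides abutting the precursor C-terminus
    included — there is no donor to be had there).
    """
    seq = annotation.sequence
    flags = []
    inconsistent = []
    for pep, (s, e) in annotation.peptide_spans:
        donor = e < len(seq) and seq[e] == "G"
        flags.append(donor)
        if pep.c_amidated and not donor:
            inconsistent.append((pep, (s, e)))
    return flags, inconsistent


def detect_pyroglu(peptides: list[Peptidoform]) -> list[bool]:
    """True iff the identification carries pyroGlu on an N-terminal Q/E."""
    return [p.n_pyroglu and p.sequence[0] in "QE" for p in peptides]


@dataclass
class ContextMatrix:
    """Position-specific residue counts around cleavage junctions.

    ``counts`` and ``frequencies`` are position × amino-acid DataFrames;
    positions outside the precursor were padded with a gap symbol that is
    excluded from the frequency normalization, so each frequency row sums
    to 1 over the 20 residues (or to 0 where only gaps were seen).
    """

    positions: list[int]
    counts: pd.DataFrame
    frequencies: pd.DataFrame

    @property
    def n_junctions(self) -> int:
        if self.counts.empty:
            return 0
        return int(self.counts.sum(axis=1).max())


def _window_counts(windows: list[str], positions: list[int]) -> ContextMatrix:
    aas = list(AMINO_ACIDS)
    counts = pd.DataFrame(0, index=positions, columns=aas, dtype=int)
    for w in windows:
        for pos, aa in zip(positions, w):
            if aa != GAP:
                counts.loc[pos, aa] += 1
    totals = counts.sum(axis=1)
    freqs = counts.div(totals.where(totals > 0, other=1), axis=0).astype(float)
    return ContextMatrix(positions=list(positions), counts=counts, frequencies=freqs)


def cleavage_context(
    annotations: list[PrecursorAnnotation],
    site_len: int = 2,
    flank_len: int = 6,
) -> tuple[ContextMatrix, ContextMatrix]:
    """Context matrices for N-terminal and C-terminal cleavage junctions.

    For an N-terminal junction the window is the ``flank_len + site_len``
    residues immediately preceding the peptide (positions −(f+s)..−1,
    right-aligned at the junction); for a C-terminal junction it is the
    residues following the peptide (after the amide-donor G, positions
    +1..+(s+f), left-aligned). Out-of-bounds positions are gap-padded.
    """
    if site_len < 0 or flank_len < 0:
        raise ValueError("site_len and flank_len must be >= 0")
    w = site_len + flank_len
    n_pos = list(range(-w, 0))
    c_pos = list(range(1, w + 1))
    n_windows, c_windows = [], []
    for ann in annotations:
        seq = ann.sequence
        for pep, (s, e) in ann.peptide_spans:
            left = seq[max(0, s - w):s]
            n_windows.append(GAP * (w - len(left)) + left)
            c0 = _c_site_start(ann, pep, e)
            right = seq[c0:c0 + w]
            c_windows.append(right + GAP * (w - len(right)))
    if w == 0 or not n_windows:
        empty = pd.DataFrame(columns=list(AMINO_ACIDS), dtype=float)
        return (
            ContextMatrix([], empty.astype(int), empty),
            ContextMatrix([], empty.astype(int), empty),
        )
    return _window_counts(n_windows, n_pos), _window_counts(c_windows, c_pos)


def annotate_precursor(
    precursor_id: str,
    sequence: str,
    peptides: list[Peptidoform],
    signal_peptide: tuple[int, int] | None = None,
) -> tuple[PrecursorAnnotation, list[Peptidoform]]:
    """Map peptides into a precursor and classify its cleavage sites."""
    spans, misses = map_peptides(sequence, peptides)
    ann = PrecursorAnnotation(
        precursor_id=precursor_id,
        sequence=sequence,
        signal_peptide=signal_peptide,
        peptide_spans=spans,
    )
    classify_sites(ann)
    return ann, misses


# ---------------------------------------------------------------------------
# FASTA IO (thin wrappers over Biopython)
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n{sequences[name]}\n")
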