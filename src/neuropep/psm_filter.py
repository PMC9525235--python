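"""Post-search curation of peptide-spectrum-match exports.

Search engines emit every spectrum-to-peptide assignment they can make; a
neuropeptidomics experiment wants the subset that plausibly derives from
secreted peptide precursors. The curation applied here mirrors standard
practice for endogenous-peptide work:

1. drop peptides whose precursor protein carries any known protein-family
   motif other than a neuropeptide-related one (at a stringent e-value,
   default 1e-10) — those are digestion/contamination products of ordinary
   proteins, not prohormone cleavage products;
2. keep only C-terminally amidated identifications, amidation being the
   defining mark of secreted neuropeptides in these lineages;
3. collapse to a single top-scoring representative per precursor (the form
   chosen for synthesis and validation).

The stages are exposed individually and as a composed, idempotent pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .masschem import Peptidoform

__all__ = [
    "PSMRecord",
    "DomainHit",
    "FilterConfig",
    "exclude_by_domains",
    "retain_amidated",
    "select_top_per_precursor",
    "run_filter",
    "read_psm_table",
    "write_psm_table",
    "read_domain_table",
]


@dataclass(frozen=True)
class PSMRecord:
    """One search-engine identification."""

    peptide: Peptidoform
    precursor_id: str
    score: float
    engine: str = "unknown"

    def __post_init__(self):
        if not self.precursor_id:
            raise ValueError("precursor_id must be non-empty")
        if not self.score == self.score or self.score in (float("inf"), -float("inf")):
            raise ValueError("score must be finite")


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    motif_accession: str
    evalue: float

    def __post_init__(self):
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")


@dataclass
class FilterConfig:
    """Knobs of the curation pipeline.

    ``allowed_motifs`` are motif accessions considered neuropeptide-related;
    a precursor hit by any *other* motif below ``exclusion_evalue`` is
    treated as an ordinary protein and its PSMs removed.
    """

    allowed_motifs: set[str] = field(default_factory=set)
    exclusion_evalue: float = 1e-10
    require_amidation: bool = True

    def __post_init__(self):
        if self.exclusion_evalue <= 0:
            raise ValueError("exclusion_evalue must be positive")


def exclude_by_domains(
    records: list[PSMRecord],
    hits: list[DomainHit],
    cfg: FilterConfig,
) -> list[PSMRecord]:
    """Remove PSMs whose precursor has a disallowed motif below the cutoff."""
    contaminated = {
        h.protein_id
        for h in hits
        if h.motif_accession not in cfg.allowed_motifs
        and h.evalue <= cfg.exclusion_evalue
    }
    return [r for r in records if r.precursor_id not in contaminated]


def retain_amidated(records: list[PSMRecord]) -> list[PSMRecord]:
    """Keep only C-terminally amidated identifications."""
    return [r for r in records if r.peptide.c_amidated]


def _rank_key(r: PSMRecord):
    # highest score first; ties: longer peptide, then lexicographic sequence
    return (-r.score, -len(r.peptide.sequence), r.peptide.sequence)


def select_top_per_precursor(records: list[PSMRecord]) -> list[PSMRecord]:
    """One representative (best-scoring) record per precursor."""
    best: dict[str, PSMRecord] = {}
    for r in records:
        cur = best.get(r.precursor_id)
        if cur is None or _rank_key(r) < _rank_key(cur):
            best[r.precursor_id] = r
    return [best[k] for k in sorted(best)]


def run_filter(
    records: list[PSMRecord],
    hits: list[DomainHit],
    cfg: FilterConfig | None = None,
) -> list[PSMRecord]:
    """Full curation: domain exclusion, amidation filter, top-per-precursor."""
    cfg = cfg or FilterConfig()
    out = exclude_by_domains(records, hits, cfg)
    if cfg.require_amidation:
        out = retain_amidated(out)
    return select_top_per_precursor(out)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _mods_to_str(p: Peptidoform) -> str:
    parts = []
    if p.c_amidated:
        parts.append("amide")
    if p.n_pyroglu:
        parts.append("pyroglu")
    for i in sorted(p.oxidized_positions):
        parts.append(f"ox{i}")
    return ";".join(parts)


def _mods_from_str(s: str) -> dict:
    amid = pyro = False
    ox = set()
    for token in filter(None, (s or "").split(";")):
        if token == "amide":
            amid = True
        elif token == "pyroglu":
            pyro = True
        elif token.startswith("ox"):
            ox.add(int(token[2:]))
        else:
            raise ValueError(f"unknown modification token {token!r}")
    return {"c_amidated": amid, "n_pyroglu": pyro, "oxidized_positions": frozenset(ox)}


def write_psm_table(records: list[PSMRecord], path) -> None:
    rows = [
        {
            "peptide": r.peptide.sequence,
            "modifications": _mods_to_str(r.peptide),
            "precursor_id": r.precursor_id,
            "score": r.score,
            "engine": r.engine,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["peptide", "modifications", "precursor_id", "score", "engine"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_psm_table(path) -> list[PSMRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "modifications": str}, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        pep = Peptidoform(
            sequence=row.peptide,
            precursor_id=row.precursor_id,
            **_mods_from_str(row.modifications),
        )
        records.append(
            PSMRecord(peptide=pep, precursor_id=row.precursor_id,
                      score=float(row.score), engine=str(row.engine))
        )
    return records


def read_domain_table(path) -> list[DomainHit]:
    """Read motif hits from a simple TSV or HMMER-style tabular output.

    A TSV with header (protein_id, motif_accession, evalue) is read as such;
    otherwise lines are treated as whitespace-delimited HMMER ``--tblout``
    rows (target name, target accession, query name, query accession,
    full-sequence e-value, ...), with ``#`` comments skipped.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.rstrip("\n").split("\t")[:3] == ["protein_id", "motif_accession", "evalue"]:
        df = pd.read_csv(path, sep="\t")
        return [
            DomainHit(str(r.protein_id), str(r.motif_accession), float(r.evalue))
            for r in df.itertuples(index=False)
        ]
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            hits.append(DomainHit(protein_id=f[0], motif_accession=f[3], evalue=float(f[4])))
    return hits
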