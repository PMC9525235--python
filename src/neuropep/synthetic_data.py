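"""Synthetic inputs with ground-truth manifests.

Every upstream data product the pipeline consumes can be emulated here at
desk scale, with the planted truth recorded so downstream stages can be
scored by parameter recovery:

* prohormone-like precursors — signal peptide, repeated mature-peptide
  copies separated by two-residue basic (K/R) or acidic (D/E) cleavage
  sites, a glycine amide donor after each amidated copy;
* peptide-spectrum-match tables mixing true amidated peptides with
  non-amidated forms and contaminant-protein records that carry disallowed
  domain hits;
* compound-protein interaction tables whose labels follow a planted
  bilinear rule in descriptor space (so the outer-product SVM can, by
  construction, learn them), together with 7-TM receptor models and
  5/6-segment distractors;
* clustered negative-binomial UMI matrices with marker genes (including
  the planted receptor genes) elevated in a home cluster.

All randomness flows from one master seed through labelled sub-streams, so
stages are reproducible independently and whole runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gpcr_pred
from .gpcr_pred import CPIRecord, ReceptorModel
from .masschem import Peptidoform
from .psm_filter import DomainHit, PSMRecord

__all__ = [
    "GenConfig",
    "CPIConfig",
    "UMIConfig",
    "TruthManifest",
    "gen_precursors",
    "gen_precursor_families",
    "gen_psm_table",
    "gen_cpi",
    "gen_umi",
    "ALLOWED_MOTIF",
    "CONTAMINANT_MOTIF",
]

# stream labels -> fixed sub-seed components
_STREAMS = {
    "precursors": 11,
    "families": 13,
    "psm": 17,
    "cpi": 19,
    "umi": 23,
}

# residues used inside mature peptides: no K/R/D/E (would fake cleavage
# sites) and no G (would fake amide donors)
_PEPTIDE_ALPHABET = "ACFHILMNPQSTVWY"
_AROMATIC = "WYF"
_HYDROPHOBIC = "AILVFM"
_LOOP_ALPHABET = "GSTNQDEKRH"

BASIC_SITES = ["KR", "KK", "RR", "RK"]
ACIDIC_SITES = ["DE", "DD", "EE", "ED"]

ALLOWED_MOTIF = "NP_MOTIF"       # treated as neuropeptide-related
CONTAMINANT_MOTIF = "PF_HOUSE"   # an ordinary-protein family motif


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


@dataclass
class CPIConfig:
    n_peptides: int = 150
    n_receptors: int = 300
    n_positives: int = 600
    n_distractors: int = 6          # receptors with 5 or 6 TM segments
    n_planted_pairs: int = 12       # cognate ligand-receptor pairs built into W
    planted_rule_strength: float = 0.5   # cognate coupling strength in W
    interaction_prevalence: float = 0.015  # fraction of grid pairs that interact
    label_noise: float = 0.0


@dataclass
class UMIConfig:
    n_genes: int = 2000
    n_cells: int = 5000
    n_clusters: int = 8
    marker_fold: float = 8.0
    dispersion: float = 2.0
    n_low_genes: int = 20           # genes planted below the total-count filter


@dataclass
class GenConfig:
    seed: int = 0
    n_precursors: int = 50
    copies_per_precursor: tuple[int, int] = (1, 4)   # inclusive range
    peptide_length: tuple[int, int] = (6, 16)
    basic_site_fraction: float = 0.7
    amidated_fraction: float = 0.8
    psm_decoy_fraction: float = 0.4
    n_psm_records: int | None = None
    cpi: CPIConfig = field(default_factory=CPIConfig)
    umi: UMIConfig = field(default_factory=UMIConfig)

    def __post_init__(self):
        for f in (self.basic_site_fraction, self.amidated_fraction,
                  self.psm_decoy_fraction, self.cpi.label_noise):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class TruthManifest:
    """What was planted, keyed the way downstream checks need it."""

    precursors: dict = field(default_factory=dict)
    psm_survivors: list = field(default_factory=list)
    cpi: dict = field(default_factory=dict)
    umi: dict = field(default_factory=dict)
    families: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# precursors
# ---------------------------------------------------------------------------

def _draw_peptide(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(list(_PEPTIDE_ALPHABET), size=length - 1))
    # cosmetic C-terminal aromatic bias, echoing amidated termini like -NPWa
    tail = rng.choice(list(_AROMATIC)) if rng.random() < 0.6 else rng.choice(
        list(_PEPTIDE_ALPHABET)
    )
    return body + str(tail)


def _draw_site(rng: np.random.Generator, basic_fraction: float) -> str:
    pool = BASIC_SITES if rng.random() < basic_fraction else ACIDIC_SITES
    return str(rng.choice(pool))


def gen_precursors(cfg: GenConfig) -> tuple[dict[str, str], TruthManifest]:
    """Precursor sequences with planted peptide copies, sites and donors."""
    rng = _rng(cfg.seed, "precursors")
    sequences: dict[str, str] = {}
    manifest = TruthManifest()
    lo_c, hi_c = cfg.copies_per_precursor
    lo_l, hi_l = cfg.peptide_length
    for i in range(cfg.n_precursors):
        pid = f"PREC{i:04d}"
        while True:
            copies = int(rng.integers(lo_c, hi_c + 1))
            pep_seq = _draw_peptide(rng, int(rng.integers(lo_l, hi_l + 1)))
            amidated = bool(rng.random() < cfg.amidated_fraction)
            pyroglu = pep_seq[0] == "Q"
            signal = "M" + "".join(rng.choice(list(_HYDROPHOBIC),
                                              size=int(rng.integers(17, 24))))
            parts = [signal]
            records = []
            pos = len(signal)
            for _ in range(copies):
                site = _draw_site(rng, cfg.basic_site_fraction)
                parts.append(site)
                pos += 2
                n_site = site
                span = (pos, pos + len(pep_seq))
                parts.append(pep_seq)
                pos += len(pep_seq)
                if amidated:
                    parts.append("G")
                    pos += 1
                records.append({"span": span, "n_site": n_site})
            final_site = _draw_site(rng, cfg.basic_site_fraction)
            parts.append(final_site)
            tail = "".join(rng.choice(list(_HYDROPHOBIC), size=5))
            parts.append(tail)
            seq = "".join(parts)
            if seq.count(pep_seq) != copies:
                continue  # accidental extra occurrence: redraw
            # fill in C-terminal sites (the site after the donor G / span)
            for r in records:
                _, e = r["span"]
                c0 = e + (1 if amidated else 0)
                r["c_site"] = seq[c0:c0 + 2]
            break
        sequences[pid] = seq
        manifest.precursors[pid] = {
            "sequence": seq,
            "signal_peptide": [0, len(signal)],
            "peptide": pep_seq,
            "amidated": amidated,
            "pyroglu": pyroglu,
            "copies": copies,
            "spans": [list(r["span"]) for r in records],
            "n_sites": [r["n_site"] for r in records],
            "c_sites": [r["c_site"] for r in records],
            "donor": amidated,
        }
    _verify_precursor_manifest(sequences, manifest)
    return sequences, manifest


def _verify_precursor_manifest(sequences: dict[str, str], manifest: TruthManifest) -> None:
    for pid, info in manifest.precursors.items():
        seq = sequences[pid]
        assert seq == info["sequence"]
        assert seq.count(info["peptide"]) == info["copies"]
        for (s, e) in info["spans"]:
            assert seq[s:e] == info["peptide"]
            if info["amidated"]:
                assert seq[e] == "G"


def gen_precursor_families(
    n_families: int = 3,
    per_family: int = 20,
    length: int = 200,
    intra_identity: float = 0.8,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, int]]:
    """Unrelated sequence families for similarity-cluster recovery tests.

    Each family descends from an independent random ancestor; members carry
    iid substitutions at rate ``1 - intra_identity``.
    """
    rng = _rng(seed, "families")
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    sequences: dict[str, str] = {}
    family_of: dict[str, int] = {}
    for f in range(n_families):
        ancestor = rng.choice(alphabet, size=length)
        for m in range(per_family):
            member = ancestor.copy()
            mutate = rng.random(length) > intra_identity
            member[mutate] = rng.choice(alphabet, size=int(mutate.sum()))
            name = f"FAM{f}_M{m:02d}"
            sequences[name] = "".join(member)
            family_of[name] = f
    return sequences, family_of


# ---------------------------------------------------------------------------
# PSM + domain tables
# ---------------------------------------------------------------------------

def gen_psm_table(
    cfg: GenConfig, manifest: TruthManifest
) -> tuple[list[PSMRecord], list[DomainHit], TruthManifest]:
    """Search-engine-style PSM and domain-hit tables for planted precursors.

    True amidated peptides get the top score of their precursor; decoys are
    non-amidated forms, truncation variants and contaminant-protein records
    whose precursors carry a disallowed motif hit below the exclusion
    cutoff. ``manifest.psm_survivors`` lists the (precursor, peptide,
    score) rows the curation pipeline must recover exactly.
    """
    rng = _rng(cfg.seed, "psm")
    records: list[PSMRecord] = []
    hits: list[DomainHit] = []
    survivors = []

    for pid in sorted(manifest.precursors):
        info = manifest.precursors[pid]
        pep_seq = info["peptide"]
        top_score = float(70 + rng.uniform(0, 25))
        pep = Peptidoform(
            sequence=pep_seq,
            c_amidated=info["amidated"],
            n_pyroglu=info["pyroglu"],
            precursor_id=pid,
        )
        records.append(PSMRecord(peptide=pep, precursor_id=pid,
                                 score=top_score, engine="peaks"))
        if info["amidated"]:
            survivors.append([pid, pep_seq, top_score])
        # lower-scoring truncation variants (amidated iff parent peptide is)
        for _ in range(int(rng.integers(0, 3))):
            if len(pep_seq) <= 4:
                break
            cut = int(rng.integers(1, len(pep_seq) - 3))
            records.append(
                PSMRecord(
                    peptide=Peptidoform(sequence=pep_seq[cut:],
                                        c_amidated=info["amidated"],
                                        precursor_id=pid),
                    precursor_id=pid,
                    score=float(rng.uniform(20, 65)),
                    engine="peaks",
                )
            )
        # free-acid (non-amidated) sibling identification
        if rng.random() < 0.5:
            records.append(
                PSMRecord(
                    peptide=Peptidoform(sequence=pep_seq, precursor_id=pid),
                    precursor_id=pid,
                    score=float(rng.uniform(20, 65)),
                    engine="mascot",
                )
            )
        # benign domain annotations: allowed motif, or disallowed above cutoff
        if rng.random() < 0.3:
            hits.append(DomainHit(pid, ALLOWED_MOTIF, float(10 ** rng.uniform(-20, -12))))
        if rng.random() < 0.2:
            hits.append(DomainHit(pid, CONTAMINANT_MOTIF, float(10 ** rng.uniform(-6, -2))))

    # contaminant precursors: excluded by the domain filter even when amidated
    n_base = len(records)
    n_target = cfg.n_psm_records
    if n_target is None:
        n_target = int(round(n_base / max(1e-9, 1 - cfg.psm_decoy_fraction)))
    if n_target < n_base:
        raise ValueError(
            f"n_psm_records={n_target} below the {n_base} true-precursor records"
        )
    i = 0
    while len(records) < n_target:
        cid = f"CONTAM{i:04d}"
        i += 1
        hits.append(DomainHit(cid, CONTAMINANT_MOTIF, float(10 ** rng.uniform(-16, -11))))
        for _ in range(int(rng.integers(1, 4))):
            if len(records) >= n_target:
                break
            seq = _draw_peptide(rng, int(rng.integers(6, 14)))
            records.append(
                PSMRecord(
                    peptide=Peptidoform(sequence=seq,
                                        c_amidated=bool(rng.random() < 0.5),
                                        precursor_id=cid),
                    precursor_id=cid,
                    score=float(rng.uniform(20, 95)),
                    engine="peaks",
                )
            )
    manifest.psm_survivors = sorted(survivors)
    return records, hits, manifest


# ---------------------------------------------------------------------------
# CPI tables
# ---------------------------------------------------------------------------

def _draw_receptor(rng: np.random.Generator, rid: str, n_segments: int) -> ReceptorModel:
    parts = []
    segments = []
    pos = 0
    for s in range(n_segments):
        loop = "".join(rng.choice(list(_LOOP_ALPHABET), size=int(rng.integers(8, 15))))
        parts.append(loop)
        pos += len(loop)
        tm = "".join(rng.choice(list(_HYDROPHOBIC + "WCTSG"),
                                size=int(rng.integers(19, 24))))
        segments.append((pos, pos + len(tm)))
        parts.append(tm)
        pos += len(tm)
    tail = "".join(rng.choice(list(_LOOP_ALPHABET), size=10))
    parts.append(tail)
    return ReceptorModel(receptor_id=rid, sequence="".join(parts),
                         tm_segments=tuple(segments))


def gen_cpi(cfg: GenConfig) -> tuple[list[CPIRecord], list[ReceptorModel], TruthManifest]:
    """CPI training table with a planted, descriptor-space-learnable rule.

    The interaction truth is a bilinear form b(p, r) = z(p)^T W z(r) on
    z-scored peptide/receptor descriptors. W is a random coupling matrix
    plus, for each of ``n_planted_pairs`` cognate ligand-receptor pairs, a
    rank-one term aligned with that pair's descriptor directions and scaled
    by ``planted_rule_strength`` — cognate pairs therefore sit far above
    the interaction threshold, the way co-evolved ligand-receptor pairs
    have an affinity gap over background, while the truth stays exactly a
    bilinear threshold rule.

    Interacting pairs are the top ``interaction_prevalence`` fraction of b
    over the grid (sparse, like real ligand-receptor matrices); positives
    for training are the cognate pairs plus a sample of the rest of that
    tail, shuffle negatives a sample of the equally-sized bottom tail, and
    labels are flipped with probability ``label_noise``. The cognate pairs
    are the planted ligand-receptor pairs reported for assignment-recovery
    benchmarks.
    """
    c = cfg.cpi
    rng = _rng(cfg.seed, "cpi")
    peptides = []
    seen = set()
    while len(peptides) < c.n_peptides:
        seq = _draw_peptide(rng, int(rng.integers(6, 18)))
        if seq in seen:
            continue
        seen.add(seq)
        peptides.append(
            Peptidoform(sequence=seq, c_amidated=bool(rng.random() < 0.7),
                        precursor_id=f"PEP{len(peptides):03d}")
        )
    receptors = [_draw_receptor(rng, f"GPCR{i:03d}", 7) for i in range(c.n_receptors)]
    distractors = [
        _draw_receptor(rng, f"GPCR_PART{i:02d}", int(rng.choice([5, 6])))
        for i in range(c.n_distractors)
    ]

    P = np.array([gpcr_pred.peptide_descriptor(p) for p in peptides])
    R = np.array([gpcr_pred.receptor_descriptor(r) for r in receptors])
    Pz = (P - P.mean(axis=0)) / np.where(P.std(axis=0) > 0, P.std(axis=0), 1.0)
    Rz = (R - R.mean(axis=0)) / np.where(R.std(axis=0) > 0, R.std(axis=0), 1.0)

    if c.n_planted_pairs > min(c.n_peptides, c.n_receptors):
        raise ValueError("n_planted_pairs exceeds the grid's matching capacity")
    cog_peps = rng.choice(c.n_peptides, size=c.n_planted_pairs, replace=False)
    cog_recs = rng.choice(c.n_receptors, size=c.n_planted_pairs, replace=False)
    W = rng.standard_normal((Pz.shape[1], Rz.shape[1])) / np.sqrt(
        Pz.shape[1] * Rz.shape[1]
    )
    for pi, ri in zip(cog_peps, cog_recs):
        u = Pz[pi] / np.linalg.norm(Pz[pi])
        v = Rz[ri] / np.linalg.norm(Rz[ri])
        W += c.planted_rule_strength * np.outer(u, v)
    bilinear = Pz @ W @ Rz.T          # peptides x receptors

    order = np.argsort(bilinear, axis=None)
    n_pairs = bilinear.size
    n_tail = int(round(c.interaction_prevalence * n_pairs))
    low_idx = order[:n_tail]
    high_idx = order[-n_tail:]
    if c.n_positives > n_tail:
        raise ValueError(
            f"n_positives={c.n_positives} exceeds the {n_tail} interacting "
            "pairs; grow the grid or raise interaction_prevalence"
        )
    high_set = set(int(x) for x in high_idx)
    cognate_flat = [int(pi * c.n_receptors + ri) for pi, ri in zip(cog_peps, cog_recs)]
    outside = [f for f in cognate_flat if f not in high_set]
    if outside:  # cognate coupling too weak to clear the threshold
        raise ValueError(
            f"{len(outside)} cognate pairs fell outside the interacting tail; "
            "raise planted_rule_strength"
        )
    rest = np.array(sorted(high_set - set(cognate_flat)))
    pos_flat = np.concatenate(
        [cognate_flat,
         rng.choice(rest, size=c.n_positives - len(cognate_flat), replace=False)]
    )
    neg_flat = rng.choice(low_idx, size=c.n_positives, replace=False)

    def to_records(flat_idx, label):
        out = []
        for fi in sorted(int(x) for x in flat_idx):
            pi, ri = divmod(fi, c.n_receptors)
            lab = label
            if c.label_noise > 0 and rng.random() < c.label_noise:
                lab = "non_interact" if label == "interact" else "interact"
            out.append(
                CPIRecord(peptide=peptides[pi], receptor=receptors[ri], label=lab,
                          provenance="planted" if label == "interact" else "shuffle")
            )
        return out

    cpis = to_records(pos_flat, "interact") + to_records(neg_flat, "non_interact")

    planted_pairs = [
        [peptides[pi].precursor_id, receptors[ri].receptor_id]
        for pi, ri in zip(cog_peps, cog_recs)
    ]

    manifest = TruthManifest()
    manifest.cpi = {
        "peptides": [p.precursor_id for p in peptides],
        "receptors": [r.receptor_id for r in receptors],
        "distractors": [r.receptor_id for r in distractors],
        "planted_pairs": sorted(planted_pairs),
        "label_noise": c.label_noise,
    }
    return cpis, receptors + distractors, manifest


# ---------------------------------------------------------------------------
# UMI matrices
# ---------------------------------------------------------------------------

def gen_umi(
    cfg: GenConfig,
    marker_genes: dict[str, str] | None = None,
) -> tuple["pd.DataFrame", pd.Series, TruthManifest]:
    """Clustered negative-binomial UMI counts with planted markers.

    ``marker_genes`` maps gene name -> home cluster for externally supplied
    markers (e.g. the planted receptor genes); additional per-cluster
    markers are planted automatically. Returns (counts genes x cells,
    cluster labels, manifest).
    """
    u = cfg.umi
    rng = _rng(cfg.seed, "umi")
    clusters = [f"C{k:02d}" for k in range(u.n_clusters)]
    cell_cluster = pd.Series(
        [clusters[int(k)] for k in rng.integers(0, u.n_clusters, size=u.n_cells)],
        index=[f"cell{i:05d}" for i in range(u.n_cells)],
    )

    marker_genes = dict(marker_genes or {})
    auto_markers = {}
    for k, cl in enumerate(clusters):
        for j in range(2):
            auto_markers[f"MARK_{cl}_{j}"] = cl
    marker_home = {**marker_genes, **auto_markers}

    n_filler = u.n_genes - len(marker_home) - u.n_low_genes
    if n_filler < 0:
        raise ValueError("n_genes too small for the requested markers")
    genes = (
        sorted(marker_home)
        + [f"GENE{i:05d}" for i in range(n_filler)]
        + [f"LOW{i:03d}" for i in range(u.n_low_genes)]
    )

    base_mu = np.empty(len(genes))
    for gi, g in enumerate(genes):
        if g in marker_home:
            base_mu[gi] = 1.0
        elif g.startswith("LOW"):
            base_mu[gi] = 10.0 / (u.n_cells * 4.0)
        else:
            base_mu[gi] = float(rng.lognormal(mean=np.log(0.1), sigma=1.2))

    counts = np.zeros((len(genes), u.n_cells), dtype=np.int64)
    theta = u.dispersion
    for cl in clusters:
        cols = np.flatnonzero((cell_cluster == cl).values)
        mu = base_mu.copy()
        for gi, g in enumerate(genes):
            if marker_home.get(g) == cl:
                mu[gi] *= u.marker_fold
        p = theta / (theta + mu)
        counts[:, cols] = rng.negative_binomial(
            theta, p[:, None], size=(len(genes), len(cols))
        )

    counts_df = pd.DataFrame(counts, index=genes, columns=cell_cluster.index)
    manifest = TruthManifest()
    manifest.umi = {
        "marker_home": marker_home,
        "clusters": clusters,
        "marker_fold": u.marker_fold,
    }
    return counts_df, cell_cluster, manifest
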