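"""Peptide-GPCR pair prediction.

Candidate ligand-receptor relationships are scored by a two-class support
vector machine trained on known compound-protein interactions (CPIs) and
shuffle-generated non-interactions. A pair is featurized as the linearized
outer product of a peptide descriptor and a receptor descriptor, so the
classifier sees every pairwise product of a ligand property with a receptor
property — the natural feature space for a bilinear compatibility rule.

Descriptors are built from the five z-scale physicochemical components per
amino acid (Sandberg et al. 1998, J Med Chem 41:2481):

* peptide (37-dim): 5 whole-sequence z-scale means, the position-specific
  z-scales of the 3 N-terminal and 3 C-terminal residues (zero-padded if
  shorter than the window), sequence length, and a C-terminal-amidation
  indicator. This is a documented, swappable stand-in for the peptide
  descriptor of the original CPI model, with the same outer-product
  architecture.
* receptor (35-dim): 5 z-scale means for each of the seven transmembrane
  segments, in segment order. Receptors lacking exactly seven annotated TM
  segments are excluded from prediction.

After scoring the full peptide x receptor grid, a receptor is assigned to
the peptide on which it attains its maximum score, and each peptide keeps
at most its five best assigned receptors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .masschem import Peptidoform

__all__ = [
    "Z_SCALES",
    "ReceptorModel",
    "CPIRecord",
    "PairScore",
    "peptide_descriptor",
    "receptor_descriptor",
    "linearized_outer_product",
    "generate_negatives",
    "train",
    "InteractionModel",
    "predict_pairs",
    "filter_seven_tm",
    "choose_representative",
    "assign_receptors",
    "read_cpi_table",
    "write_cpi_table",
    "read_tm_table",
    "write_tm_table",
]

# five z-scale components per residue (Sandberg et al. 1998)
Z_SCALES = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
}

PEPTIDE_DESCRIPTOR_DIM = 37
RECEPTOR_DESCRIPTOR_DIM = 35
_END_WINDOW = 3


@dataclass(frozen=True)
class ReceptorModel:
    receptor_id: str
    sequence: str
    tm_segments: tuple[tuple[int, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "tm_segments", tuple(tuple(s) for s in self.tm_segments))
        prev_end = -1
        for s, e in self.tm_segments:
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"TM segment ({s},{e}) outside sequence bounds")
            if s <= prev_end:
                raise ValueError("TM segments must be non-overlapping and ascending")
            prev_end = e - 1

    @property
    def full_length(self) -> bool:
        return len(self.tm_segments) == 7


@dataclass(frozen=True)
class CPIRecord:
    peptide: Peptidoform
    receptor: ReceptorModel
    label: str  # "interact" | "non_interact"
    provenance: str = "curated"

    def __post_init__(self):
        if self.label not in ("interact", "non_interact"):
            raise ValueError(f"bad label {self.label!r}")


@dataclass(frozen=True)
class PairScore:
    peptide_id: str
    receptor_id: str
    score: float

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0, 1]")


def _zs(seq: str) -> np.ndarray:
    try:
        return np.array([Z_SCALES[a] for a in seq], dtype=float)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r} in sequence") from None


def peptide_descriptor(p: Peptidoform) -> np.ndarray:
    """37-dim peptide descriptor (z-scale means, termini, length, amide flag)."""
    if len(p.sequence) < 3:
        raise ValueError("peptide descriptor requires length >= 3")
    z = _zs(p.sequence)
    mean = z.mean(axis=0)
    nterm = np.zeros((_END_WINDOW, 5))
    cterm = np.zeros((_END_WINDOW, 5))
    k = min(_END_WINDOW, len(p.sequence))
    nterm[:k] = z[:k]
    cterm[:k] = z[-k:]
    return np.concatenate(
        [mean, nterm.ravel(), cterm.ravel(),
         [float(len(p.sequence)), float(p.c_amidated)]]
    )


def receptor_descriptor(r: ReceptorModel) -> np.ndarray:
    """35-dim receptor descriptor: z-scale means of the 7 TM segments in order."""
    if not r.full_length:
        raise ValueError(
            f"receptor {r.receptor_id} has {len(r.tm_segments)} TM segments; "
            "7 required (filter with filter_seven_tm first)"
        )
    parts = [_zs(r.sequence[s:e]).mean(axis=0) for s, e in r.tm_segments]
    return np.concatenate(parts)


def linearized_outer_product(pep_vec: np.ndarray, rec_vec: np.ndarray) -> np.ndarray:
    """Row-major flattening of the outer product pep_vec x rec_vec."""
    pep_vec = np.asarray(pep_vec, dtype=float)
    rec_vec = np.asarray(rec_vec, dtype=float)
    if pep_vec.size == 0 or rec_vec.size == 0:
        raise ValueError("descriptor vectors must be non-empty")
    return np.outer(pep_vec, rec_vec).ravel()


def filter_seven_tm(receptors: list[ReceptorModel]) -> list[ReceptorModel]:
    """Keep receptors with all seven TM segments annotated."""
    return [r for r in receptors if r.full_length]


def generate_negatives(
    cpis: list[CPIRecord], ratio: float = 1.0, seed: int = 0
) -> list[CPIRecord]:
    """Shuffle-generated non-interaction pairs.

    Random peptide x receptor recombinations drawn (without repetition)
    from the peptides and receptors of the positive set, excluding every
    pair present among the positives.
    """
    peptides = {}
    receptors = {}
    positive_keys = set()
    for r in cpis:
        peptides[r.peptide.sequence + ("a" if r.peptide.c_amidated else "")] = r.peptide
        receptors[r.receptor.receptor_id] = r.receptor
        positive_keys.add(
            (r.peptide.sequence, r.peptide.c_amidated, r.receptor.receptor_id)
        )
    if len(peptides) < 2 or len(receptors) < 2:
        raise ValueError("need >= 2 distinct peptides and receptors to shuffle")
    pep_list = [peptides[k] for k in sorted(peptides)]
    rec_list = [receptors[k] for k in sorted(receptors)]
    candidates = [
        (i, j)
        for i, p in enumerate(pep_list)
        for j, r in enumerate(rec_list)
        if (p.sequence, p.c_amidated, r.receptor_id) not in positive_keys
    ]
    n_wanted = int(round(ratio * len(cpis)))
    if n_wanted > len(candidates):
        raise ValueError(
            f"requested {n_wanted} negatives but only {len(candidates)} "
            "non-positive pairs exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_wanted, replace=False)
    return [
        CPIRecord(
            peptide=pep_list[candidates[c][0]],
            receptor=rec_list[candidates[c][1]],
            label="non_interact",
            provenance="shuffle",
        )
        for c in sorted(chosen)
    ]


class InteractionModel:
    """Calibrated SVM over linearized outer-product features."""

    def __init__(self, pipeline: Pipeline):
        self._pipeline = pipeline

    def score(self, features: np.ndarray) -> np.ndarray:
        """Interaction scores in [0, 1] for rows of ``features``."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        proba = self._pipeline.predict_proba(features)
        idx = list(self._pipeline.classes_).index(1)
        return proba[:, idx]

    def margin(self, features: np.ndarray) -> np.ndarray:
        """Uncalibrated decision-function values (monotone with score).

        The calibrated probability saturates at 1.0 for strong pairs, so
        rankings among them are numerically meaningless; the raw margin
        orders them stably.
        """
        features = np.atleast_2d(np.asarray(features, dtype=float))
        d = self._pipeline.decision_function(features)
        return d if self._pipeline.classes_[-1] == 1 else -d

    def score_pair(self, p: Peptidoform, r: ReceptorModel) -> float:
        feat = linearized_outer_product(peptide_descriptor(p), receptor_descriptor(r))
        return float(self.score(feat[None, :])[0])


def cpi_features(cpis: list[CPIRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and 0/1 label vector for a CPI list."""
    X = np.array(
        [
            linearized_outer_product(
                peptide_descriptor(r.peptide), receptor_descriptor(r.receptor)
            )
            for r in cpis
        ]
    )
    y = np.array([1 if r.label == "interact" else 0 for r in cpis])
    return X, y


def train(
    features: np.ndarray,
    labels: np.ndarray,
    hyperparams: dict | str | None = None,
    seed: int = 0,
) -> InteractionModel:
    """Train the two-class RBF SVM with probability calibration.

    ``hyperparams`` may be a dict of SVC keyword arguments, the string
    ``"grid"`` for a small fixed-seed cross-validated grid search, or None
    for the defaults (C=10, gamma="scale").
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires both interaction classes")

    def make(**svc_kw) -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(kernel="rbf", probability=True, random_state=seed, **svc_kw)),
            ]
        )

    if hyperparams == "grid":
        grid = GridSearchCV(
            make(),
            {"svc__C": [1.0, 10.0], "svc__gamma": ["scale", 0.01]},
            cv=StratifiedKFold(3, shuffle=True, random_state=seed),
            scoring="roc_auc",
            n_jobs=1,
        )
        grid.fit(features, labels)
        return InteractionModel(grid.best_estimator_)
    pipe = make(**(hyperparams or {"C": 10.0}))
    pipe.fit(features, labels)
    return InteractionModel(pipe)


def predict_pairs(
    model: InteractionModel,
    peptides: list[Peptidoform],
    receptors: list[ReceptorModel],
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every peptide x receptor pair.

    Returns (all scores, predicted subset with score >= threshold), each a
    DataFrame with columns peptide_id, receptor_id, score.
    """
    not_full = [r.receptor_id for r in receptors if not r.full_length]
    if not_full:
        raise ValueError(f"receptors lacking 7 TM segments: {not_full}")
    pep_ids = [p.precursor_id or p.sequence for p in peptides]
    pvecs = [peptide_descriptor(p) for p in peptides]
    rvecs = [receptor_descriptor(r) for r in receptors]
    rows = []
    for pid, pv in zip(pep_ids, pvecs):
        feats = np.array([linearized_outer_product(pv, rv) for rv in rvecs])
        scores = model.score(feats)
        margins = model.margin(feats)
        for r, s, m in zip(receptors, scores, margins):
            rows.append({"peptide_id": pid, "receptor_id": r.receptor_id,
                         "score": float(s), "margin": float(m)})
    scores_df = pd.DataFrame(rows).sort_values(
        ["peptide_id", "receptor_id"], ignore_index=True
    )
    predicted = scores_df[scores_df["score"] >= threshold].reset_index(drop=True)
    return scores_df, predicted


def _edit_distance(a: str, b: str) -> int:
    # Levenshtein distance, O(len(a)*len(b)) DP
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def choose_representative(family: list[Peptidoform]) -> list[Peptidoform]:
    """Representative peptide(s) of a family of detected forms.

    Families that are pure length-variant ladders (every member a
    C-terminal-aligned substring of the longest) are represented by the
    longest form, shorter forms being likely preparation artefacts.
    Structurally varied families are represented by the edit-distance
    medoid (ties: longer, then lexicographic), with a second representative
    added on an exact medoid tie. At most two are returned.
    """
    if not family:
        raise ValueError("family must be non-empty")
    seqs = [p.sequence for p in family]
    longest = max(family, key=lambda p: (len(p.sequence), p.sequence))
    if all(longest.sequence.endswith(s) for s in seqs):
        return [longest]
    ranked = sorted(
        family,
        key=lambda p: (
            sum(_edit_distance(p.sequence, q) for q in seqs),
            -len(p.sequence),
            p.sequence,
        ),
    )
    def total(p):
        return sum(_edit_distance(p.sequence, q) for q in seqs)
    reps = [ranked[0]]
    if len(ranked) > 1 and total(ranked[1]) == total(ranked[0]):
        reps.append(ranked[1])
    return reps


def assign_receptors(scores: pd.DataFrame, max_per_peptide: int = 5) -> pd.DataFrame:
    """Receptor-to-peptide assignment from a full score grid.

    Each receptor goes to the peptide on which it scores highest (ties by
    peptide identifier order); each peptide then keeps its
    ``max_per_peptide`` best assigned receptors ranked by score. The result
    is a partial matching: no receptor appears under two peptides. When a
    ``margin`` column is present it is used as the ranking key (the
    calibrated probability saturates; the margin is monotone with it and
    keeps full precision).
    """
    key = "margin" if "margin" in scores.columns else "score"
    assigned = []
    for rid, grp in scores.groupby("receptor_id", sort=True):
        grp = grp.sort_values([key, "peptide_id"], ascending=[False, True])
        top = grp.iloc[0]
        row = {"peptide_id": top["peptide_id"], "receptor_id": rid,
               "score": float(top["score"])}
        if key == "margin":
            row["margin"] = float(top["margin"])
        assigned.append(row)
    if not assigned:
        return pd.DataFrame(columns=["peptide_id", "receptor_id", "score", "rank"])
    df = pd.DataFrame(assigned)
    out = []
    for pid, grp in df.groupby("peptide_id", sort=True):
        grp = grp.sort_values([key, "receptor_id"], ascending=[False, True]).head(
            max_per_peptide
        )
        grp = grp.assign(rank=range(1, len(grp) + 1))
        out.append(grp)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_cpi_table(cpis: list[CPIRecord], path) -> None:
    rows = [
        {
            "peptide": r.peptide.sequence,
            "amidated": int(r.peptide.c_amidated),
            "receptor_id": r.receptor.receptor_id,
            "label": r.label,
            "provenance": r.provenance,
        }
        for r in cpis
    ]
    pd.DataFrame(rows, columns=["peptide", "amidated", "receptor_id", "label", "provenance"]).to_csv(
        path, sep="\t", index=False
    )


def read_cpi_table(path, receptors: dict[str, ReceptorModel]) -> list[CPIRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CPIRecord(
                peptide=Peptidoform(sequence=row.peptide, c_amidated=bool(row.amidated)),
                receptor=receptors[row.receptor_id],
                label=row.label,
                provenance=getattr(row, "provenance", "curated"),
            )
        )
    return out


def write_tm_table(receptors: list[ReceptorModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("receptor_id\tseg_index\tstart\tend\n")
        for r in sorted(receptors, key=lambda r: r.receptor_id):
            for i, (s, e) in enumerate(r.tm_segments):
                fh.write(f"{r.receptor_id}\t{i}\t{s}\t{e}\n")


def read_tm_table(path, sequences: dict[str, str]) -> list[ReceptorModel]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for rid, grp in df.groupby("receptor_id", sort=True):
        grp = grp.sort_values("seg_index")
        out.append(
            ReceptorModel(
                receptor_id=str(rid),
                sequence=sequences[str(rid)],
                tm_segments=tuple((int(s), int(e)) for s, e in zip(grp["start"], grp["end"])),
            )
        )
    return out
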