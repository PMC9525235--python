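"""Monoisotopic mass and fragment-ion chemistry for mature peptides.

Mature neuropeptides carry a small, recurring set of post-translational
modifications: C-terminal amidation (the hallmark of secreted neuropeptides,
installed by PAM on a glycine-extended intermediate), N-terminal
pyroglutamate (cyclization of Gln or Glu), and methionine oxidation (mostly
a sample-handling artefact, but routinely searched). All masses here are
monoisotopic and derived from atomic composition, so the modification deltas
are exact consequences of the chemistry rather than copied constants:

* amidation replaces the C-terminal -OH with -NH2  (delta = N + H - O)
* pyroGlu from E loses water                       (delta = -H2O)
* pyroGlu from Q loses ammonia                     (delta = -NH3)
* Met oxidation gains one oxygen                   (delta = +O)

The module also builds theoretical b/y fragment spectra and scores observed
against theoretical spectra with a greedy-matched cosine similarity, which
is how endogenous identifications are validated against spectra of the
corresponding synthetic peptides.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "Peptidoform",
    "MassTable",
    "FragmentSpectrum",
    "DEFAULT_MASS_TABLE",
    "modification_delta",
    "monoisotopic_mass",
    "by_fragments",
    "spectral_similarity",
    "read_peptidoform_table",
    "write_peptidoform_table",
    "read_peak_list",
    "write_peak_list",
]

# ---------------------------------------------------------------------------
# atomic masses (monoisotopic, IUPAC/CODATA)
# ---------------------------------------------------------------------------

MASS_H = 1.00782503207
MASS_C = 12.0
MASS_N = 14.0030740048
MASS_O = 15.9949146196
MASS_S = 31.97207100
MASS_PROTON = 1.00727646688

MASS_WATER = 2 * MASS_H + MASS_O
MASS_AMMONIA = MASS_N + 3 * MASS_H

# residue elemental compositions (C, H, N, O, S), i.e. amino acid - H2O
_RESIDUE_FORMULAS = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _formula_mass(c: int, h: int, n: int, o: int, s: int) -> float:
    return c * MASS_C + h * MASS_H + n * MASS_N + o * MASS_O + s * MASS_S


MOD_DELTAS = {
    # replace C-terminal OH by NH2
    "c_amidation": MASS_N + MASS_H - MASS_O,
    # cyclization of N-terminal Glu, loss of H2O
    "pyroglu_from_E": -MASS_WATER,
    # cyclization of N-terminal Gln, loss of NH3
    "pyroglu_from_Q": -MASS_AMMONIA,
    # sulfoxide
    "met_oxidation": MASS_O,
}


class UnsupportedModificationError(KeyError):
    """Raised for a modification name outside the supported set."""


def modification_delta(mod_name: str) -> float:
    """Signed monoisotopic mass delta (Da) of a named modification."""
    try:
        return MOD_DELTAS[mod_name]
    except KeyError:
        raise UnsupportedModificationError(
            f"unsupported modification {mod_name!r}; "
            f"supported: {sorted(MOD_DELTAS)}"
        ) from None


@dataclass(frozen=True)
class MassTable:
    """Monoisotopic residue masses plus the constants mass arithmetic needs."""

    residue_masses: dict[str, float]
    water: float = MASS_WATER
    proton: float = MASS_PROTON
    mod_deltas: dict[str, float] = field(default_factory=lambda: dict(MOD_DELTAS))

    def residue(self, aa: str) -> float:
        try:
            return self.residue_masses[aa]
        except KeyError:
            raise KeyError(f"residue {aa!r} not in mass table") from None


DEFAULT_MASS_TABLE = MassTable(
    residue_masses={aa: _formula_mass(*f) for aa, f in _RESIDUE_FORMULAS.items()}
)


@dataclass(frozen=True)
class Peptidoform:
    """A mature peptide: sequence plus its modification state.

    ``span`` is a 0-based half-open interval in precursor coordinates when
    the peptide has been located in its precursor.
    """

    sequence: str
    c_amidated: bool = False
    n_pyroglu: bool = False
    oxidized_positions: frozenset[int] = frozenset()
    precursor_id: str | None = None
    span: tuple[int, int] | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-canonical residues in sequence: {sorted(bad)}")
        object.__setattr__(self, "oxidized_positions", frozenset(self.oxidized_positions))
        for i in self.oxidized_positions:
            if not 0 <= i < len(self.sequence) or self.sequence[i] != "M":
                raise ValueError(f"oxidized position {i} does not hold M")
        if self.n_pyroglu and self.sequence[0] not in "QE":
            raise ValueError("n_pyroglu requires an N-terminal Q or E")
        if self.span is not None:
            s, e = self.span
            if e - s != len(self.sequence):
                raise ValueError("span length does not match sequence length")

    @property
    def pyroglu_mod(self) -> str | None:
        if not self.n_pyroglu:
            return None
        return "pyroglu_from_Q" if self.sequence[0] == "Q" else "pyroglu_from_E"


@dataclass
class FragmentSpectrum:
    """A peak list (m/z, intensity), sorted by m/z."""

    peaks: list[tuple[float, float]]
    precursor_charge: int = 1

    def __post_init__(self):
        if self.precursor_charge < 1:
            raise ValueError("precursor_charge must be >= 1")
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("intensities must be non-negative")
        self.peaks = sorted(self.peaks)

    @property
    def mz(self) -> list[float]:
        return [m for m, _ in self.peaks]


# ---------------------------------------------------------------------------
# mass arithmetic
# ---------------------------------------------------------------------------

def monoisotopic_mass(p: Peptidoform, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Neutral monoisotopic mass of a peptidoform (Da)."""
    mass = sum(table.residue(aa) for aa in p.sequence) + table.water
    if p.c_amidated:
        mass += table.mod_deltas["c_amidation"]
    if p.n_pyroglu:
        mass += table.mod_deltas[p.pyroglu_mod]
    mass += len(p.oxidized_positions) * table.mod_deltas["met_oxidation"]
    return mass


def by_fragments(
    p: Peptidoform,
    table: MassTable = DEFAULT_MASS_TABLE,
    charge: int = 1,
) -> FragmentSpectrum:
    """Theoretical b/y ion m/z values for charge states 1..charge.

    The C-terminal amide shifts only y ions; pyroglutamate shifts only
    b ions; oxidized methionines shift whichever fragment contains them.
    Intensities are unit (the comparison is positional, not quantitative).
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    n = len(p.sequence)
    ox_delta = table.mod_deltas["met_oxidation"]

    prefix = [0.0] * (n + 1)
    for i, aa in enumerate(p.sequence):
        prefix[i + 1] = prefix[i] + table.residue(aa) + (
            ox_delta if i in p.oxidized_positions else 0.0
        )

    peaks = []
    for i in range(1, n):  # cleavage between i-1 and i
        b_neutral = prefix[i]
        if p.n_pyroglu:
            b_neutral += table.mod_deltas[p.pyroglu_mod]
        y_neutral = prefix[n] - prefix[i] + table.water
        if p.c_amidated:
            y_neutral += table.mod_deltas["c_amidation"]
        for z in range(1, charge + 1):
            peaks.append(((b_neutral + z * table.proton) / z, 1.0))
            peaks.append(((y_neutral + z * table.proton) / z, 1.0))
    return FragmentSpectrum(peaks=peaks, precursor_charge=charge)


# ---------------------------------------------------------------------------
# spectral comparison
# ---------------------------------------------------------------------------

def spectral_similarity(
    observed: FragmentSpectrum,
    theoretical: FragmentSpectrum,
    tol: float = 0.3,
) -> float:
    """Cosine similarity between two spectra after greedy peak matching.

    Peak pairs within ``tol`` (Da) are matched greedily by ascending m/z
    difference, ties toward lower m/z; unmatched peaks contribute zero to
    the dot product but their intensity still counts in the norms, so the
    score lives in [0, 1]. Empty input yields 0 with a warning.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not observed.peaks or not theoretical.peaks:
        warnings.warn("empty spectrum in similarity computation; returning 0")
        return 0.0

    candidates = []
    for i, (mo, _) in enumerate(observed.peaks):
        for j, (mt, _) in enumerate(theoretical.peaks):
            d = abs(mo - mt)
            if d <= tol:
                candidates.append((d, min(mo, mt), i, j))
    candidates.sort()

    used_o: set[int] = set()
    used_t: set[int] = set()
    dot = 0.0
    for _, _, i, j in candidates:
        if i in used_o or j in used_t:
            continue
        used_o.add(i)
        used_t.add(j)
        dot += observed.peaks[i][1] * theoretical.peaks[j][1]

    norm_o = sum(x * x for _, x in observed.peaks) ** 0.5
    norm_t = sum(x * x for _, x in theoretical.peaks) ** 0.5
    if norm_o == 0 or norm_t == 0:
        warnings.warn("zero-intensity spectrum; returning 0")
        return 0.0
    return dot / (norm_o * norm_t)


# ---------------------------------------------------------------------------
# tabular / peak-list IO
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "sequence", "c_amidated", "n_pyroglu", "oxidized_positions",
    "precursor_id", "span_start", "span_end",
]


def write_peptidoform_table(peptides: list[Peptidoform], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for p in peptides:
            ox = ",".join(str(i) for i in sorted(p.oxidized_positions))
            s, e = p.span if p.span is not None else ("", "")
            fh.write(
                f"{p.sequence}\t{int(p.c_amidated)}\t{int(p.n_pyroglu)}\t{ox}\t"
                f"{p.precursor_id or ''}\t{s}\t{e}\n"
            )


def read_peptidoform_table(path) -> list[Peptidoform]:
    peptides = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TABLE_COLUMNS:
            raise ValueError(f"unexpected peptide table header: {header}")
        for line in fh:
            seq, amid, pyro, ox, prec, s, e = line.rstrip("\n").split("\t")
            peptides.append(
                Peptidoform(
                    sequence=seq,
                    c_amidated=bool(int(amid)),
                    n_pyroglu=bool(int(pyro)),
                    oxidized_positions=frozenset(
                        int(x) for x in ox.split(",") if x
                    ),
                    precursor_id=prec or None,
                    span=(int(s), int(e)) if s else None,
                )
            )
    return peptides


def write_peak_list(spectrum: FragmentSpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# charge={spectrum.precursor_charge}\n")
        for mz, inten in spectrum.peaks:
            fh.write(f"{mz:.6f}\t{inten:.6g}\n")


def read_peak_list(path) -> FragmentSpectrum:
    peaks = []
    charge = 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"charge=(\d+)", line)
                if m:
                    charge = int(m.group(1))
                continue
            mz, inten = line.split()
            peaks.append((float(mz), float(inten)))
    return FragmentSpectrum(peaks=peaks, precursor_charge=charge)
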