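"""Limited-proteolysis fragment-mass assignment.

Average masses of contiguous protein fragments and exhaustive matching of
observed intact masses (ESI-MS of ~16 kDa species reports average, not
monoisotopic, mass).  The matching logic recovers which cleavage fragments
of a repeat protein are compatible with a set of deconvoluted masses, e.g.
discriminating a C-terminal fragment one Ala shorter (71.08 Da) from an
alternative double-cut fragment of nearly identical mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "ProteinSequence",
    "FragmentMatch",
    "fragment_average_mass",
    "match_fragments",
    "read_fasta",
    "D1_SCAFFOLD_SYNTHETIC",
    "TM3_SYNTHETIC",
]

# Average (isotope-weighted) residue masses, Da, standard 20-residue table.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.05, "A": 71.08, "S": 87.08, "P": 97.12, "V": 99.13,
    "T": 101.10, "C": 103.14, "L": 113.16, "I": 113.16, "N": 114.10,
    "D": 115.09, "Q": 128.13, "K": 128.17, "E": 129.12, "M": 131.19,
    "H": 137.14, "F": 147.18, "R": 156.19, "Y": 163.18, "W": 186.21,
}

WATER_MASS = 18.02  # one water per fragment (free N/C termini)

# Synthetic stand-in sequences for the D1 DARPin scaffold and its TM-3
# triple mutant (H118R, I152T, N158S).  These are NOT deposited sequences:
# they are reconstructions built from the canonical N3C DARPin consensus
# framework (MRGSHHHHHHGS his-tag, N-cap, three internal repeats, C-cap),
# constrained so that every framework position referenced by the study's
# numbering (His118, Ile122, Glu127, Val131, Ala149, Phe150, Ile152,
# Asp155, Asn158, Glu159) falls on the consensus residue, and with the
# randomized library positions fixed once so the 1-149 fragment has an
# average mass near 15.8 kDa.  Suitable as a fixture for the fragment
# assignment logic; not for sequence-level conclusions.
D1_SCAFFOLD_SYNTHETIC = (
    "MRGSHHHHHHGS"                        # 1-12   his-tag
    "DLGKKLLEAARAGQDDEVRILMANGADVNA"      # 13-42  N-cap
    "KDNSGFTPLHLAAHNGHLEIVEVLLKNGADVNA"   # 43-75  internal repeat 1
    "IDILGHTPLHLAASDGHLEIVEVLLKYGADVNA"   # 76-108 internal repeat 2
    "KDFAGITPLHLAAISGHLEIVEVLLKNGADVNA"   # 109-141 internal repeat 3
    "QDKFGKTAFDISIDNGNEDLAEILQKLN"        # 142-169 C-cap (two helices)
)

_tm3 = list(D1_SCAFFOLD_SYNTHETIC)
_tm3[117], _tm3[151], _tm3[157] = "R", "T", "S"  # H118R, I152T, N158S
TM3_SYNTHETIC = "".join(_tm3)
del _tm3


class SequenceError(ValueError):
    """Raised for invalid residues or fragment index ranges."""


@dataclass(frozen=True)
class ProteinSequence:
    """A one-letter-coded protein sequence with a label."""

    residues: str
    label: str = ""

    def __post_init__(self) -> None:
        bad = set(self.residues) - set(AVERAGE_RESIDUE_MASS)
        if bad:
            raise SequenceError(
                f"non-canonical residues {sorted(bad)} in sequence {self.label!r}"
            )
        if not self.residues:
            raise SequenceError("empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FragmentMatch:
    """A contiguous fragment whose computed mass matches an observed mass."""

    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    computed_mass: float
    observed_mass: float

    @property
    def delta(self) -> float:
        return self.computed_mass - self.observed_mass


def fragment_average_mass(seq: ProteinSequence, start: int, end: int) -> float:
    """Average mass (Da) of the fragment ``start..end`` (1-based, inclusive).

    Sum of average residue masses plus one water.  Additive across splits:
    ``mass(1, n) == mass(1, k) + mass(k+1, n) - WATER_MASS``.
    """
    if not (1 <= start <= end <= len(seq)):
        raise SequenceError(
            f"invalid fragment range ({start}, {end}) for length {len(seq)}"
        )
    return (
        sum(AVERAGE_RESIDUE_MASS[a] for a in seq.residues[start - 1 : end])
        + WATER_MASS
    )


def match_fragments(
    seq: ProteinSequence,
    observed_masses: list[float],
    tolerance: float = 2.0,
) -> list[list[FragmentMatch]]:
    """All contiguous fragments within ``tolerance`` Da of each observed mass.

    Exhaustively scans every ``(start, end)`` pair (prefix-sum based, so
    O(n^2) with a vectorized inner step).  For each observed mass the
    matches are returned sorted by ``|delta|``.  The default 2 Da tolerance
    discriminates at the single-residue level for ~16 kDa species while
    absorbing mass-table rounding.
    """
    if tolerance <= 0:
        raise SequenceError(f"tolerance must be > 0, got {tolerance!r}")
    res = np.array([AVERAGE_RESIDUE_MASS[a] for a in seq.residues])
    prefix = np.concatenate([[0.0], np.cumsum(res)])
    n = len(seq)
    results: list[list[FragmentMatch]] = []
    for obs in observed_masses:
        matches: list[FragmentMatch] = []
        for start in range(1, n + 1):
            # masses of fragments start..start, ..., start..n
            frag = prefix[start:] - prefix[start - 1] + WATER_MASS
            hits = np.nonzero(np.abs(frag - obs) <= tolerance)[0]
            for idx in hits:
                matches.append(
                    FragmentMatch(
                        start=start,
                        end=start + int(idx),
                        computed_mass=float(frag[idx]),
                        observed_mass=float(obs),
                    )
                )
        matches.sort(key=lambda m: abs(m.delta))
        results.append(matches)
    return results


def read_fasta(text: str) -> list[ProteinSequence]:
    """Parse FASTA text into labeled protein sequences."""
    sequences: list[ProteinSequence] = []
    label: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if label is not None:
                sequences.append(ProteinSequence("".join(chunks), label))
            label = line[1:].strip()
            chunks = []
        else:
            if label is None:
                raise SequenceError("FASTA data before first header line")
            chunks.append(line.upper())
    if label is not None:
        sequences.append(ProteinSequence("".join(chunks), label))
    return sequences
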