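"""Frequent-triplet (FT) scanning and assignment.

A Frequent Triplet is an amino-acid k-mer (k = 3 by default) that occurs at
least ``n`` times (default 5) in a single protein, counted at every start
position so that overlapping occurrences all contribute.  A protein carrying
at least one FT is called compositionally ordered (CO); proteins without any
FT are NO proteins.  The "restrictive" variant additionally requires the
``n`` qualifying occurrences to fall within a window of ``M`` consecutive
residues, which suppresses spurious assignments on very long sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "CANONICAL_AA",
    "TOLERATED_AA",
    "ProteinRecord",
    "FTParams",
    "FTProfile",
    "scan_kmers",
    "detect_fts",
    "is_co",
]

#: The 20 canonical amino-acid letters; only windows made entirely of these
#: are eligible FT occurrences (the null model puts p = 1/20^k on them).
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Letters tolerated in input sequences but never part of an FT occurrence.
TOLERATED_AA = "XBZUO*"

_CANONICAL_SET = frozenset(CANONICAL_AA)
_ALLOWED_SET = frozenset(CANONICAL_AA + TOLERATED_AA)


@dataclass(frozen=True)
class ProteinRecord:
    """One named amino-acid sequence, the unit of FT scanning.

    The sequence is uppercased on construction.  Characters outside the 20
    canonical letters plus the tolerated set (X, B, Z, U, O, *) are rejected.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) == 0:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.seq) - _ALLOWED_SET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: unexpected characters {sorted(bad)}"
            )

    @property
    def L(self) -> int:
        """Sequence length in residues."""
        return len(self.seq)


@dataclass(frozen=True)
class FTParams:
    """Parameters of FT assignment.

    n : minimum occurrence count for FT status (default 5).
    M : optional window length for the restrictive definition; ``None``
        selects the regular definition.  The restrictive default used in
        the literature for long proteins is M = 2000.
    k : word length (default 3; configurable for sensitivity scans).
    """

    n: int = 5
    M: int | None = None
    k: int = 3

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.M is not None and self.M < self.k:
            raise ValueError("M must be >= k when given")

    @property
    def restrictive(self) -> bool:
        return self.M is not None


@dataclass
class FTProfile:
    """Per-protein map FT -> ordered start positions of all occurrences.

    Positions are 0-based start indices of overlapping matches; consecutive
    entries may differ by 1.  ``ft_positions`` only lists k-mers that passed
    the FT criterion, but each kept k-mer retains *all* of its occurrences.
    """

    protein_id: str
    ft_positions: dict[str, list[int]]
    params: FTParams
    L: int

    @property
    def dft_count(self) -> int:
        """Number of Different Frequent Triplets (FT types)."""
        return len(self.ft_positions)

    @property
    def total_occurrences(self) -> int:
        return sum(len(p) for p in self.ft_positions.values())

    def fts(self) -> list[str]:
        return sorted(self.ft_positions)

    def to_rows(self) -> list[tuple[str, str, int, str]]:
        """TSV export rows: (protein_id, FT, count, comma-joined positions)."""
        return [
            (self.protein_id, ft, len(pos), ",".join(map(str, pos)))
            for ft, pos in sorted(self.ft_positions.items())
        ]


def scan_kmers(protein: ProteinRecord, k: int = 3) -> dict[str, list[int]]:
    """All distinct canonical k-mers with their overlapping start positions.

    A window is counted only when all of its k letters are canonical.
    Returns an empty map when k exceeds the sequence length.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = protein.seq
    positions: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if _CANONICAL_SET.issuperset(w):
            positions.setdefault(w, []).append(i)
    return positions


def _within_window(pos: list[int], n: int, k: int, M: int) -> bool:
    # Sliding criterion: some run of n occurrences spans <= M residues,
    # measured from the first start to the end of the n-th occurrence.
    return any(pos[i + n - 1] + k - pos[i] <= M for i in range(len(pos) - n + 1))


def detect_fts(protein: ProteinRecord, params: FTParams = FTParams()) -> FTProfile:
    """Assign FTs to a protein under the regular or restrictive definition.

    Regular mode keeps k-mers with total occurrence count >= n; restrictive
    mode additionally requires n occurrences within a window of M residues.
    Kept k-mers retain their full occurrence lists.
    """
    kmers = scan_kmers(protein, params.k)
    if params.restrictive:
        kept = {
            w: pos
            for w, pos in kmers.items()
            if len(pos) >= params.n
            and _within_window(pos, params.n, params.k, params.M)
        }
    else:
        kept = {w: pos for w, pos in kmers.items() if len(pos) >= params.n}
    return FTProfile(
        protein_id=protein.id,
        ft_positions=dict(sorted(kept.items())),
        params=params,
        L=protein.L,
    )


def is_co(profile: FTProfile) -> bool:
    """True iff the protein carries at least one FT (is compositionally ordered)."""
    return profile.dft_count >= 1


def profiles_to_tsv(profiles: Iterable[FTProfile]) -> str:
    """Serialize FT profiles as TSV (protein_id, FT, count, positions)."""
    lines = ["protein_id\tft\tcount\tpositions"]
    for prof in profiles:
        for row in prof.to_rows():
            lines.append("\t".join(map(str, row)))
    return "\n".join(lines) + "\n"
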