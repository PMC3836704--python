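"""Per-protein measures of compositional order.

Three complementary aspects of order are quantified from the FT profile of a
protein:

* **regularity** — the relative coverage RC, the fraction of residues lying
  under at least one FT occurrence; anti-correlated with k-mer entropy;
* **periodicity** — the most frequent interval MFI between consecutive
  occurrences of the same FT (pooled over all FTs), and the relative
  periodicity RP, the fraction of the FT occurrence structure concentrated
  at the MFI;
* **vocabulary** — the number of Different Frequent Triplets (DFT).

RP convention (frozen): the numerator of RP is the number of pooled
consecutive-occurrence intervals equal to the MFI, and the denominator is
the total number of FT occurrences.  This is the convention that reproduces
the published worked examples exactly (the alternative — counting
occurrences that participate in at least one MFI-sized gap — does not).

Purity of a repeated motif is read off the relation between DFT and MFI:
DFT == MFI indicates a pure motif of unit length MFI, DFT < MFI a
mutationally degraded motif, DFT > MFI regularity exceeding periodicity.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .ft_core import (
    CANONICAL_AA,
    FTParams,
    FTProfile,
    ProteinRecord,
    detect_fts,
    is_co,
)

__all__ = [
    "IntervalDistribution",
    "EntropyResult",
    "COProfile",
    "round_half_up",
    "relative_coverage",
    "interval_distribution",
    "most_frequent_interval",
    "relative_periodicity",
    "sequence_entropy",
    "classify_protein",
    "profiles_to_dataframe",
]

#: Default minimum number of interval recurrences at MFI for a protein to be
#: called periodic (about half of CO proteins qualify at this setting).
DEFAULT_PERIODICITY_THRESHOLD = 4

#: Float slack on the upper bound of normalized entropies.
NS_TOLERANCE = 1e-9


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up, the convention for printed-table comparison."""
    import decimal

    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


@dataclass
class IntervalDistribution:
    """Gaps between consecutive occurrences of the same FT.

    ``per_ft_intervals`` maps each FT to its own gap list (m - 1 entries for
    m occurrences); ``pooled_intervals`` aggregates all FTs of one protein.
    """

    per_ft_intervals: dict[str, list[int]]
    pooled_intervals: list[int]

    def histogram(self) -> Counter:
        return Counter(self.pooled_intervals)


@dataclass(frozen=True)
class EntropyResult:
    """Shannon entropy of overlapping k-mer composition, in bits."""

    k: int
    s_k: float
    ns_k: float
    normalization_base: float


@dataclass
class COProfile:
    """All per-protein order measures in one record."""

    protein_id: str
    L: int
    is_co: bool
    dft_count: int
    dfts: list[str]
    total_occurrences: int
    rc: float
    mfi: int | None
    mfi_support: int
    rp: float
    periodic: bool
    purity_class: str | None
    entropies: dict[int, EntropyResult] = field(default_factory=dict)

    def ns(self, k: int) -> float | None:
        e = self.entropies.get(k)
        return None if e is None else e.ns_k


def relative_coverage(profile: FTProfile, L: int | None = None) -> float:
    """Fraction of residues covered by at least one FT occurrence.

    RC = |union over FT occurrences of [pos, pos + k - 1]| / L.
    """
    if L is None:
        L = profile.L
    if L <= 0:
        raise ValueError("L must be positive")
    k = profile.params.k
    covered: set[int] = set()
    for positions in profile.ft_positions.values():
        for p in positions:
            covered.update(range(p, p + k))
    return len(covered) / L


def interval_distribution(profile: FTProfile) -> IntervalDistribution:
    """Consecutive-occurrence gaps per FT and pooled over all FTs."""
    per_ft: dict[str, list[int]] = {}
    pooled: list[int] = []
    for ft, pos in profile.ft_positions.items():
        gaps = [b - a for a, b in zip(pos, pos[1:])]
        per_ft[ft] = gaps
        pooled.extend(gaps)
    return IntervalDistribution(per_ft_intervals=per_ft, pooled_intervals=pooled)


def most_frequent_interval(dist: IntervalDistribution) -> int | None:
    """Modal pooled interval; ties broken toward the smallest interval.

    Returns None when the pooled multiset is empty (no FT recurs), in which
    case RP is 0 by convention.
    """
    hist = dist.histogram()
    if not hist:
        return None
    top = max(hist.values())
    return min(i for i, c in hist.items() if c == top)


def relative_periodicity(
    profile: FTProfile, dist: IntervalDistribution, mfi: int | None
) -> float:
    """RP: pooled intervals equal to MFI over total FT occurrences.

    Approaches zero as the MFI loses support; equals 0 when MFI is
    undefined.  Raises on an empty profile (zero denominator), which cannot
    occur for CO proteins.
    """
    total = profile.total_occurrences
    if total == 0:
        raise ValueError("relative periodicity undefined for empty profile")
    if mfi is None:
        return 0.0
    return sum(1 for g in dist.pooled_intervals if g == mfi) / total


def sequence_entropy(protein: ProteinRecord, k: int = 3) -> EntropyResult:
    """Generalized Shannon entropy over overlapping k-mer counts.

    S_k = -sum_i (n_i / W) log2(n_i / W) over the W = L - k + 1 windows.
    The normalization base is log2(20^k) when 20^k <= L (composition-limited
    regime) and log2(L) otherwise, where the number of windows, not the
    alphabet, caps the attainable entropy.
    """
    L = protein.L
    if L < k:
        raise ValueError(f"sequence shorter than k ({L} < {k})")
    windows = Counter(protein.seq[i : i + k] for i in range(L - k + 1))
    W = L - k + 1
    s = -sum((c / W) * math.log2(c / W) for c in windows.values())
    n_possible = len(CANONICAL_AA) ** k
    base = math.log2(n_possible) if n_possible <= L else math.log2(L)
    ns = s / base if base > 0 else 0.0
    if not -NS_TOLERANCE <= ns <= 1.0 + NS_TOLERANCE:
        raise AssertionError(f"normalized entropy out of bounds: {ns}")
    return EntropyResult(k=k, s_k=s, ns_k=ns, normalization_base=base)


def _purity_class(dft_count: int, mfi: int | None) -> str | None:
    if mfi is None:
        return None
    if dft_count == mfi:
        return "pure"
    if dft_count < mfi:
        return "degraded"
    return "complex"


def classify_protein(
    protein: ProteinRecord,
    params: FTParams = FTParams(),
    periodicity_threshold: int = DEFAULT_PERIODICITY_THRESHOLD,
    entropy_ks: Sequence[int] = (1, 3),
) -> COProfile:
    """Assemble the full set of order measures for one protein.

    A protein is *periodic* when its MFI recurs at least
    ``periodicity_threshold`` times (default 4).  Entropies are computed for
    each requested k not exceeding the sequence length.
    """
    profile = detect_fts(protein, params)
    entropies = {
        k: sequence_entropy(protein, k) for k in entropy_ks if protein.L >= k
    }
    if not is_co(profile):
        return COProfile(
            protein_id=protein.id,
            L=protein.L,
            is_co=False,
            dft_count=0,
            dfts=[],
            total_occurrences=0,
            rc=0.0,
            mfi=None,
            mfi_support=0,
            rp=0.0,
            periodic=False,
            purity_class=None,
            entropies=entropies,
        )
    dist = interval_distribution(profile)
    mfi = most_frequent_interval(dist)
    support = dist.histogram().get(mfi, 0) if mfi is not None else 0
    rp = relative_periodicity(profile, dist, mfi)
    return COProfile(
        protein_id=protein.id,
        L=protein.L,
        is_co=True,
        dft_count=profile.dft_count,
        dfts=profile.fts(),
        total_occurrences=profile.total_occurrences,
        rc=relative_coverage(profile),
        mfi=mfi,
        mfi_support=support,
        rp=rp,
        periodic=support >= periodicity_threshold,
        purity_class=_purity_class(profile.dft_count, mfi),
        entropies=entropies,
    )


def profiles_to_dataframe(profiles: Iterable[COProfile]) -> pd.DataFrame:
    """Tabulate COProfiles, one row per protein (the tool's text output)."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "protein_id": p.protein_id,
                "L": p.L,
                "is_co": p.is_co,
                "dft_count": p.dft_count,
                "leading_fts": ";".join(p.dfts[:5]),
                "total_occurrences": p.total_occurrences,
                "mfi": p.mfi,
                "mfi_support": p.mfi_support,
                "rc": round(p.rc, 4),
                "rp": round(p.rp, 4),
                "ns1": None if p.ns(1) is None else round(p.ns(1), 4),
                "ns3": None if p.ns(3) is None else round(p.ns(3), 4),
                "periodic": p.periodic,
                "purity_class": p.purity_class,
            }
        )
    return pd.DataFrame(rows)
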