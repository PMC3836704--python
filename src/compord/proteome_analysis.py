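"""Proteome-level FT vocabulary and universality analyses.

The FT vocabulary of a proteome is the set of Different Frequent Triplets
(DFT) observed in at least one of its proteins — a count of FT *types*, not
occurrences, and therefore insensitive to protein redundancy.  Vocabularies
of two proteomes (or proteins) are compared with the Jaccard index
C_IJ = |DFT_I ∩ DFT_J| / |DFT_I ∪ DFT_J|.  DFT abundance across proteins
follows an approximate power law (few triplets are carried by many
proteins, most by few), and per-protein RP and DFT show power-law
dependence on protein length with exponents of opposite sign; both are
quantified here with log-log least-squares fits.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import linregress, pearsonr

from .ft_core import FTParams, FTProfile, ProteinRecord, detect_fts, is_co
from .order_measures import COProfile

__all__ = [
    "ProteomeVocabulary",
    "RegressionFit",
    "build_vocabulary",
    "jaccard",
    "correlation_matrix",
    "rank_predominant_fts",
    "dft_abundance_distribution",
    "fit_loglog",
    "binned_measure_length_regression",
]


@dataclass
class ProteomeVocabulary:
    """DFT set of one proteome plus per-FT carrier-protein counts."""

    source_id: str
    dft_set: frozenset[str]
    carrier_counts: Counter
    per_protein_dft: list[int]
    n_proteins: int
    n_co: int

    @property
    def dft_count(self) -> int:
        return len(self.dft_set)


@dataclass(frozen=True)
class RegressionFit:
    """Least-squares line on log-log axes; slope is the power-law exponent."""

    slope: float
    intercept: float
    r: float
    pvalue: float
    fit_range: tuple[float, float]
    n_points: int
    rho_unbinned: float | None = None


def build_vocabulary(
    proteome: Sequence[ProteinRecord],
    params: FTParams = FTParams(),
    source_id: str = "proteome",
) -> ProteomeVocabulary:
    """Union of per-protein FT sets with carrier counts.

    Each FT's carrier count is the number of CO proteins containing it, so
    duplicated proteins inflate counts but never the DFT set itself.
    """
    if len(proteome) == 0:
        raise ValueError("empty proteome")
    carrier: Counter = Counter()
    per_protein_dft: list[int] = []
    n_co = 0
    for rec in proteome:
        profile = detect_fts(rec, params)
        if is_co(profile):
            n_co += 1
            carrier.update(profile.ft_positions.keys())
            per_protein_dft.append(profile.dft_count)
    return ProteomeVocabulary(
        source_id=source_id,
        dft_set=frozenset(carrier),
        carrier_counts=carrier,
        per_protein_dft=per_protein_dft,
        n_proteins=len(proteome),
        n_co=n_co,
    )


def jaccard(a: ProteomeVocabulary, b: ProteomeVocabulary) -> float:
    """Jaccard index of two DFT sets; 0 (with a warning) when both are empty."""
    union = a.dft_set | b.dft_set
    if not union:
        warnings.warn("Jaccard of two empty vocabularies; returning 0")
        return 0.0
    return len(a.dft_set & b.dft_set) / len(union)


def correlation_matrix(
    vocabularies: Sequence[ProteomeVocabulary],
    tree: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, str]:
    """Symmetric C_IJ matrix of vocabularies; optional clustering tree.

    When ``tree`` is true, a Newick string from average-linkage hierarchical
    clustering on Euclidean distance between matrix rows is returned
    alongside the matrix.
    """
    if len(vocabularies) < 2:
        raise ValueError("need at least 2 vocabularies")
    ids = [v.source_id for v in vocabularies]
    m = len(vocabularies)
    mat = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            mat[i, j] = mat[j, i] = jaccard(vocabularies[i], vocabularies[j])
    frame = pd.DataFrame(mat, index=ids, columns=ids)
    if not tree:
        return frame
    Z = linkage(pdist(mat, metric="euclidean"), method="average")
    from skbio.tree import TreeNode

    tree_node = TreeNode.from_linkage_matrix(Z, ids)
    return frame, str(tree_node)


def rank_predominant_fts(
    vocab: ProteomeVocabulary, top_n: int | None = None
) -> pd.DataFrame:
    """FTs ranked by carrier-protein count (ties lexicographic).

    The ``homo_run`` flag marks FTs made of a single amino acid — the
    signature of amino-acid runs on protein sequences.
    """
    items = sorted(vocab.carrier_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None:
        items = items[:top_n]
    return pd.DataFrame(
        {
            "ft": [ft for ft, _ in items],
            "carrier_count": [c for _, c in items],
            "homo_run": [len(set(ft)) == 1 for ft, _ in items],
        }
    )


def dft_abundance_distribution(
    vocab: ProteomeVocabulary,
) -> tuple[pd.Series, pd.Series]:
    """Normalized histograms of FT abundance and per-protein DFT counts.

    Returns (carrier-count distribution over FTs, DFT-count distribution
    over CO proteins); both sum to 1.
    """
    carrier = pd.Series(Counter(vocab.carrier_counts.values())).sort_index()
    carrier = carrier / carrier.sum()
    per_protein = pd.Series(Counter(vocab.per_protein_dft)).sort_index()
    per_protein = per_protein / per_protein.sum()
    return carrier, per_protein


def fit_loglog(
    x: Sequence[float],
    p: Sequence[float],
    fit_range: tuple[float, float] | None = None,
) -> RegressionFit:
    """Least-squares line on (log10 x, log10 p).

    ``fit_range`` restricts the fit to log10(x) within the given interval
    (the convention used for plotted power-law ranges).  Points with
    non-positive x or p are excluded.  Requires >= 3 points in range.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    ok = (x > 0) & (p > 0)
    lx, lp = np.log10(x[ok]), np.log10(p[ok])
    if fit_range is None:
        lo, hi = (-np.inf, np.inf) if lx.size == 0 else (lx.min(), lx.max())
    else:
        lo, hi = fit_range
    sel = (lx >= lo) & (lx <= hi)
    if sel.sum() < 3:
        raise ValueError("need at least 3 positive points inside fit_range")
    res = linregress(lx[sel], lp[sel])
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        pvalue=float(res.pvalue),
        fit_range=(float(lx[sel].min()), float(lx[sel].max())),
        n_points=int(sel.sum()),
    )


_MEASURES = {"rp": "rp", "rc": "rc", "dft_count": "dft_count"}


def binned_measure_length_regression(
    profiles: Iterable[COProfile],
    measure: str = "rp",
    n_bins: int = 50,
) -> RegressionFit:
    """Power-law fit of an order measure against protein length.

    CO proteins with a strictly positive measure are binned into ``n_bins``
    equally spaced intervals along the measure axis; within each non-empty
    bin the mean length is taken, and a least-squares line is fitted to
    (log10 mean L, log10 bin center).  Empty bins are dropped.  The unbinned
    Pearson correlation between log measure and log L is reported as
    ``rho_unbinned``.
    """
    if measure not in _MEASURES:
        raise ValueError(f"measure must be one of {sorted(_MEASURES)}")
    vals, lengths = [], []
    for p in profiles:
        v = getattr(p, measure)
        if p.is_co and v is not None and v > 0:
            vals.append(float(v))
            lengths.append(float(p.L))
    vals = np.asarray(vals)
    lengths = np.asarray(lengths)
    if vals.size < n_bins:
        raise ValueError(
            f"need at least n_bins={n_bins} CO proteins with positive "
            f"{measure} (got {vals.size})"
        )
    edges = np.linspace(vals.min(), vals.max(), n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(vals, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            xs.append(lengths[mask].mean())
            ys.append(centers[b])
    if len(xs) < 3:
        raise ValueError("too few non-empty bins for a regression")
    res = linregress(np.log10(xs), np.log10(ys))
    rho = pearsonr(np.log10(lengths), np.log10(vals)).statistic
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        pvalue=float(res.pvalue),
        fit_range=(float(np.log10(min(xs))), float(np.log10(max(xs)))),
        n_points=len(xs),
        rho_unbinned=float(rho),
    )
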