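"""Threshold-sweep functional enrichment over order measures.

For a free-text annotation term, the sweep tracks the fraction of
term-matching proteins among those whose order measure exceeds a rising
threshold.  Matching is a case-insensitive literal substring search in the
supplied annotation text (no ontology-graph semantics).  Significance at
the ratio-maximizing threshold is assessed with a one-sided hypergeometric
test against the composition at the minimal threshold; thresholds with
fewer than 16 matching proteins, or fewer than 10% of the matches seen at
the minimal threshold, are not considered (small-number guard).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .ft_core import FTProfile
from .order_measures import COProfile, interval_distribution

__all__ = [
    "AnnotationTable",
    "EnrichmentCurve",
    "enrichment_sweep",
    "run_length_measure",
    "read_annotations",
]

MIN_N_FUN = 15  # admissible thresholds need n_fun > this
MIN_N_FUN_FRACTION = 0.1  # ... and n_fun >= this fraction of n_fun at t_min


@dataclass
class AnnotationTable:
    """protein_id -> free-text annotation; lookups are case-insensitive."""

    annotations: dict[str, str]

    def matches(self, protein_id: str, term: str) -> bool:
        text = self.annotations.get(protein_id)
        return text is not None and term.lower() in text.lower()


def read_annotations(path: str) -> AnnotationTable:
    """Two-column TSV (protein_id, annotation text); extra tabs join."""
    ann: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t", 1)
            if len(parts) != 2:
                raise ValueError(f"malformed annotation line: {line!r}")
            ann[parts[0]] = parts[1]
    return AnnotationTable(ann)


@dataclass
class EnrichmentCurve:
    """One term's enrichment pattern over a threshold grid."""

    term: str
    measure: str
    curve: pd.DataFrame  # columns: threshold, n_tot, n_fun, ratio
    pvalue: float | None
    best_threshold: float | None
    reason: str | None = None  # set when the P-value is undefined

    def summary_row(self) -> dict:
        if self.best_threshold is None:
            best = {"n_fun": None, "n_tot": None, "ratio": None}
        else:
            row = self.curve.loc[self.curve.threshold == self.best_threshold].iloc[0]
            best = {
                "n_fun": int(row.n_fun),
                "n_tot": int(row.n_tot),
                "ratio": float(row.ratio),
            }
        return {
            "term": self.term,
            "measure": self.measure,
            "best_threshold": self.best_threshold,
            **best,
            "pvalue": self.pvalue,
            "reason": self.reason,
        }


def _measure_values(
    profiles: Sequence[COProfile],
    measure: str,
    run_lengths: Mapping[str, int] | None,
) -> pd.DataFrame:
    if measure in ("rc", "rp"):
        vals = [(p.protein_id, getattr(p, measure)) for p in profiles if p.is_co]
    elif measure == "mfi_run_length":
        if run_lengths is None:
            raise ValueError("mfi_run_length sweep needs run_lengths mapping")
        vals = [
            (p.protein_id, run_lengths.get(p.protein_id, 0))
            for p in profiles
            if p.is_co
        ]
    else:
        raise ValueError("measure must be rc, rp or mfi_run_length")
    return pd.DataFrame(vals, columns=["protein_id", "value"])


def enrichment_sweep(
    profiles: Sequence[COProfile],
    annotations: AnnotationTable,
    term: str,
    measure: str = "rc",
    thresholds: Sequence[float] | None = None,
    run_lengths: Mapping[str, int] | None = None,
) -> EnrichmentCurve:
    """Enrichment curve of ``term`` against a rising measure threshold.

    At each threshold t, n_tot counts CO proteins with measure > t and
    n_fun those among them whose annotation matches the term.  The default
    threshold grid is the deciles of the measure's empirical distribution,
    preceded by a minimal threshold just below the smallest value so that
    the first point covers the whole CO set.  The P-value is a one-sided
    upper hypergeometric tail at the admissible threshold maximizing
    n_fun/n_tot: population and successes are taken at the minimal
    threshold, sample and observed at the chosen one.
    """
    if not term:
        raise ValueError("term must be non-empty")
    table = _measure_values(profiles, measure, run_lengths)
    if table.empty:
        raise ValueError("no CO proteins with the requested measure")
    values = table.value.to_numpy(dtype=float)
    matched = np.array(
        [annotations.matches(pid, term) for pid in table.protein_id]
    )
    if thresholds is None:
        eps = 1e-12 + 1e-9 * max(abs(values.min()), 1.0)
        deciles = np.unique(np.quantile(values, np.linspace(0.1, 0.9, 9)))
        thresholds = np.concatenate([[values.min() - eps], deciles])
    thresholds = np.asarray(sorted(thresholds), dtype=float)

    rows = []
    for t in thresholds:
        above = values > t
        n_tot = int(above.sum())
        n_fun = int((above & matched).sum())
        rows.append(
            {
                "threshold": t,
                "n_tot": n_tot,
                "n_fun": n_fun,
                "ratio": n_fun / n_tot if n_tot else np.nan,
            }
        )
    curve = pd.DataFrame(rows)

    base = curve.iloc[0]
    N, K = int(base.n_tot), int(base.n_fun)
    admissible = curve[
        (curve.n_fun > MIN_N_FUN)
        & (curve.n_fun >= MIN_N_FUN_FRACTION * K)
        & (curve.n_tot > 0)
    ]
    if N == 0 or K == 0 or admissible.empty:
        reason = "term unmatched" if K == 0 else "no admissible threshold"
        return EnrichmentCurve(term, measure, curve, None, None, reason)
    best = admissible.loc[admissible.ratio.idxmax()]
    pval = float(
        hypergeom.sf(int(best.n_fun) - 1, N, K, int(best.n_tot))
    )
    return EnrichmentCurve(
        term, measure, curve, pval, float(best.threshold), None
    )


def run_length_measure(profile: FTProfile) -> int:
    """Total FT recurrences at interval 1 (effective coverage of runs).

    This is the sweep variable for run-length enrichment: the number of
    pooled consecutive-occurrence intervals equal to 1.
    """
    dist = interval_distribution(profile)
    return sum(1 for g in dist.pooled_intervals if g == 1)
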