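"""Bundled worked-example sequences and synthetic proteome generators.

The module makes the whole toolkit testable without any download: six
published example proteins spanning the main order phenomena (runs,
keratin-like high coverage, repeated motifs of unit length 5-28) are
bundled as FASTA, and seedable generators produce planted-motif proteins
and whole synthetic proteomes with known ground truth.

Transcription note: the bundled A4 record is 769 residues whereas its
source table states 770 — one residue was lost in transcription of the
printed sequence.  All of its published order measures (DFT 3, MFI 1,
RC 0.04, RP 0.4) reproduce exactly on the 769-residue sequence, so it is
kept verbatim.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .ft_core import CANONICAL_AA, ProteinRecord

__all__ = [
    "PlantedMotifSpec",
    "SyntheticProteomeSpec",
    "table1_fixtures",
    "plant_motif",
    "generate_proteome",
]

#: Expected residue counts of the bundled example proteins (A4 per the
#: transcription note above).
FIXTURE_LENGTHS = {
    "A4": 769,
    "LORI": 312,
    "CAMKV": 501,
    "COLQ": 455,
    "ASPX": 265,
    "PRDM9": 894,
}

#: Content digest of the bundled FASTA, guarding against fixture corruption.
_FIXTURE_SHA256 = "b6f3aa41977cbe11b4f6604ac041b2c826d471ecd2e31e6cd3e8bd218774b393"


def table1_fixtures() -> list[ProteinRecord]:
    """The six bundled example proteins (A4, LORI, CAMKV, COLQ, ASPX, PRDM9).

    Verifies the stored content digest and per-record lengths; a mismatch
    means fixture corruption and raises immediately.
    """
    text = (
        resources.files("compord").joinpath("data/table1.fasta").read_text()
    )
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise RuntimeError("bundled fixture FASTA is corrupted (digest mismatch)")
    records: list[ProteinRecord] = []
    current_id, chunks = None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if current_id is not None:
                records.append(ProteinRecord(current_id, "".join(chunks)))
            current_id = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.strip())
    if current_id is not None:
        records.append(ProteinRecord(current_id, "".join(chunks)))
    for rec in records:
        expected = FIXTURE_LENGTHS[rec.id]
        if rec.L != expected:
            raise RuntimeError(
                f"fixture {rec.id}: length {rec.L} != expected {expected}"
            )
    return records


@dataclass(frozen=True)
class PlantedMotifSpec:
    """A tandem array of a motif with optional substitutions and flanks.

    motif : amino-acid string of length m (the repeat unit).
    repeats : number of copies laid head-to-tail.
    impurity_rate : per-position probability of substituting a repeat
        residue with a random different canonical letter.
    flank_lengths : random-residue padding (before, after).
    """

    motif: str
    repeats: int
    impurity_rate: float = 0.0
    flank_lengths: tuple[int, int] = (0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not 0 <= self.impurity_rate < 1:
            raise ValueError("impurity_rate must be in [0, 1)")
        if not self.motif or not set(self.motif) <= set(CANONICAL_AA):
            raise ValueError("motif must be non-empty canonical letters")


def _random_letters(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(CANONICAL_AA), size=n)) if n else ""


def plant_motif(
    spec: PlantedMotifSpec, protein_id: str = "planted"
) -> tuple[ProteinRecord, dict]:
    """A planted-motif protein plus its ground truth.

    Returns (record, truth) where truth records the motif, its unit length
    m, repeat count r, and the (start, end) coordinates of the repeat array
    within the final sequence.
    """
    rng = np.random.default_rng(spec.seed)
    m = len(spec.motif)
    letters = list(spec.motif * spec.repeats)
    n_sub = 0
    if spec.impurity_rate > 0:
        for i in range(len(letters)):
            if rng.random() < spec.impurity_rate:
                choices = [c for c in CANONICAL_AA if c != letters[i]]
                letters[i] = rng.choice(choices)
                n_sub += 1
    left = _random_letters(rng, spec.flank_lengths[0])
    right = _random_letters(rng, spec.flank_lengths[1])
    body = "".join(letters)
    seq = left + body + right
    truth = {
        "motif": spec.motif,
        "m": m,
        "r": spec.repeats,
        "start": len(left),
        "end": len(left) + len(body),
        "n_substitutions": n_sub,
        "seed": spec.seed,
    }
    return ProteinRecord(protein_id, seq), truth


@dataclass(frozen=True)
class SyntheticProteomeSpec:
    """A proteome with controllable order structure and annotations.

    Lengths are log-normal (defaults chosen to resemble eukaryotic protein
    length distributions: median ~375 residues, sigma 0.65 on the natural
    log scale).  A fraction of proteins receives a planted tandem motif
    drawn from ``motif_pool``; the rest are i.i.d. random.  When
    ``enrichment_term`` is set, each protein receives the term with
    probability sigmoid(logit(baseline_term_prob) + enrichment_log_odds *
    c), where c is the fraction of the sequence occupied by the planted
    repeat array (0 for unplanted proteins) — so the term is enriched
    among high-coverage ordered proteins with a known effect size.
    """

    n_proteins: int = 500
    length_mu: float = math.log(375.0)
    length_sigma: float = 0.65
    planted_fraction: float = 0.3
    motif_pool: tuple[str, ...] = ("A", "SGE", "TPATDGSA", "PGP")
    repeats_range: tuple[int, int] = (8, 20)
    impurity_rate: float = 0.0
    enrichment_term: str | None = None
    enrichment_log_odds: float = 3.0
    baseline_term_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")
        if not 0 < self.baseline_term_prob < 1:
            raise ValueError("baseline_term_prob must be in (0, 1)")


def generate_proteome(
    spec: SyntheticProteomeSpec,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Reproducible synthetic proteome plus a ground-truth ledger.

    The ledger has one row per protein: id, length, whether a motif was
    planted (and which, with coordinates), and the annotation text when
    enrichment planting is on.  It is sufficient for parameter-recovery
    tests; no hidden state is needed.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    rows = []
    for i in range(spec.n_proteins):
        pid = f"syn{i:05d}"
        L = max(30, int(round(rng.lognormal(spec.length_mu, spec.length_sigma))))
        planted = rng.random() < spec.planted_fraction
        motif, start, end, r = None, None, None, None
        if planted:
            motif = str(rng.choice(spec.motif_pool))
            r = int(rng.integers(spec.repeats_range[0], spec.repeats_range[1] + 1))
            body_len = len(motif) * r
            flank_total = max(L - body_len, 0)
            left = int(rng.integers(0, flank_total + 1))
            mspec = PlantedMotifSpec(
                motif=motif,
                repeats=r,
                impurity_rate=spec.impurity_rate,
                flank_lengths=(left, flank_total - left),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec, truth = plant_motif(mspec, pid)
            start, end = truth["start"], truth["end"]
        else:
            rec = ProteinRecord(pid, _random_letters(rng, L))
        annotation = None
        if spec.enrichment_term is not None:
            base_logit = math.log(
                spec.baseline_term_prob / (1 - spec.baseline_term_prob)
            )
            coverage = (end - start) / rec.L if planted else 0.0
            logit = base_logit + spec.enrichment_log_odds * coverage
            p_term = 1 / (1 + math.exp(-logit))
            annotation = (
                spec.enrichment_term if rng.random() < p_term else "unrelated"
            )
        records.append(rec)
        rows.append(
            {
                "protein_id": pid,
                "L": rec.L,
                "planted": planted,
                "motif": motif,
                "repeats": r,
                "start": start,
                "end": end,
                "annotation": annotation,
            }
        )
    return records, pd.DataFrame(rows)
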