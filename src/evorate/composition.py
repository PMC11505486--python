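"""Per-species amino-acid occurrence of a protein and its correlation with
life-history traits.

Occurrence is the percentage of each of the 20 standard amino acids among
counted residues (gaps and ambiguity codes excluded from the denominator).
For each amino acid, Pearson's r across species between occurrence and the
trait measures preference (positive r: the trait rises with occurrence) or
avoidance (negative r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats

from .errors import CodonError, InsufficientDataError
from .io import TraitTable

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
_IGNORED = frozenset("-X*")


@dataclass(frozen=True)
class CompositionProfile:
    """Occurrence (%) of the 20 standard amino acids in one species' protein."""

    species_id: str
    occurrence: Mapping[str, float]

    def __post_init__(self):
        if set(self.occurrence) != set(AMINO_ACIDS):
            raise ValueError("occurrence must cover exactly the 20 standard amino acids")
        total = sum(self.occurrence.values())
        if not math.isclose(total, 100.0, rel_tol=1e-9):
            raise ValueError(f"occurrence sums to {total}, expected 100")


def composition(protein: str, species_id: str = "") -> CompositionProfile:
    """Occurrence profile of one protein sequence.

    Gaps, ``X`` and ``*`` are excluded from both numerator and denominator.
    Raises on an empty or all-gap sequence or on non-standard residues.
    """
    counts = {aa: 0 for aa in AMINO_ACIDS}
    total = 0
    for ch in protein.upper():
        if ch in _IGNORED:
            continue
        if ch not in counts:
            raise CodonError(f"{species_id}: non-standard residue {ch!r}")
        counts[ch] += 1
        total += 1
    if total == 0:
        raise InsufficientDataError(f"{species_id}: empty or all-gap sequence")
    return CompositionProfile(
        species_id=species_id,
        occurrence={aa: 100.0 * c / total for aa, c in counts.items()},
    )


@dataclass(frozen=True)
class CompositionCorrelation:
    amino_acid: str
    mean_occurrence: float
    r: float | None
    p: float | None


def correlate_composition(
    profiles: Iterable[CompositionProfile],
    traits: TraitTable,
    trait: str,
) -> dict[str, CompositionCorrelation]:
    """Per-amino-acid Pearson correlation of occurrence with a trait.

    ``trait`` is ``"mrls"`` (years) or ``"lg_weight"`` (log10 grams).
    Species lacking the trait are dropped.  An amino acid whose occurrence
    has zero variance gets ``r = p = None``; all others are unaffected.
    """
    rows: list[tuple[str, dict[str, float], float]] = []
    for prof in profiles:
        rec = traits.get(prof.species_id)
        if rec is None:
            continue
        if trait == "mrls":
            y = rec.mrls
        elif trait == "lg_weight":
            y = None if rec.weight is None else math.log10(rec.weight)
        else:
            raise ValueError(f"unknown trait {trait!r}")
        if y is None:
            continue
        rows.append((prof.species_id, dict(prof.occurrence), y))
    if len(rows) < 3:
        raise InsufficientDataError(
            f"{len(rows)} species with both profile and {trait}, need >= 3"
        )
    ys = [y for _, _, y in rows]
    out: dict[str, CompositionCorrelation] = {}
    for aa in AMINO_ACIDS:
        xs = [occ[aa] for _, occ, _ in rows]
        mean_occ = sum(xs) / len(xs)
        if len(set(xs)) == 1 or len(set(ys)) == 1:
            out[aa] = CompositionCorrelation(aa, mean_occ, None, None)
            continue
        r, p = stats.pearsonr(xs, ys)
        out[aa] = CompositionCorrelation(aa, mean_occ, float(r), float(p))
    return out
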