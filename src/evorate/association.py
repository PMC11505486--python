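"""Least-squares association of the median-omega characteristic with
life-history traits.

The trait is regressed on the characteristic: y = a·x + b with x the
median omega and y either the maximal reported lifespan (years) or the
common logarithm of adult body weight (grams) — the latter is the linear
form of an exponential weight–rate relationship.  Significance is the
two-sided test of Pearson's r under the null of no linear relationship
(t distribution with n − 2 degrees of freedom), exactly what
``scipy.stats.linregress`` reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

from scipy import stats

from .errors import InsufficientDataError, ZeroVarianceError
from .io import TraitTable
from .median import GeneSpeciesCharacteristic

TraitName = Literal["mrls", "lg_weight"]
TRAIT_NAMES = ("mrls", "lg_weight")


@dataclass(frozen=True)
class AssociationResult:
    """One summary-table row: sample size, correlation, fit and interval."""

    gene_id: str
    trait: str
    n: int
    r: float
    p: float
    slope: float
    intercept: float
    interval: tuple[float, float]


def _trait_value(traits: TraitTable, species_id: str, trait: str) -> float | None:
    rec = traits.get(species_id)
    if rec is None:
        return None
    if trait == "mrls":
        return rec.mrls
    if trait == "lg_weight":
        return None if rec.weight is None else math.log10(rec.weight)
    raise ValueError(f"unknown trait {trait!r}; expected one of {TRAIT_NAMES}")


def fit_association(
    chars: Iterable[GeneSpeciesCharacteristic],
    traits: TraitTable,
    trait: TraitName,
) -> AssociationResult:
    """Regress a trait on the median-omega characteristic across species.

    Species lacking either a defined median or the trait are dropped
    per-trait (not listwise); ``n`` reflects the drop.  Requires at least
    three usable points and non-zero variance in both coordinates.
    """
    xs: list[float] = []
    ys: list[float] = []
    gene_id = ""
    for ch in chars:
        gene_id = ch.gene_id
        if ch.median_omega is None:
            continue
        y = _trait_value(traits, ch.species_id, trait)
        if y is None:
            continue
        xs.append(ch.median_omega)
        ys.append(y)
    if len(xs) < 3:
        raise InsufficientDataError(
            f"{gene_id}/{trait}: {len(xs)} usable points, need >= 3"
        )
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise ZeroVarianceError(f"{gene_id}/{trait}: zero variance")
    fit = stats.linregress(xs, ys)
    return AssociationResult(
        gene_id=gene_id,
        trait=trait,
        n=len(xs),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        interval=(min(xs), max(xs)),
    )


def classify_selection_signal(
    result: AssociationResult, alpha: float = 1e-3
) -> str:
    """``"associated"`` iff p <= alpha (boundary inclusive), else
    ``"not_associated"``.

    The default alpha of 10^-3 is the most lenient level treated as a real
    signal in this analysis family; larger p-values are read as absence of
    correlation.
    """
    return "associated" if result.p <= alpha else "not_associated"
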