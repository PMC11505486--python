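"""The genomic characteristic: median pairwise dN/dS of a gene in a focal
species against all other functional orthologs of a taxon.

The characteristic is computed star-wise around the focal species (one
value per species, as in a per-species scatter plot), not over all pairs
within the taxon.  Pairs with undefined omega (dS = 0) or a saturated
correction are excluded from the median and counted.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

from .codon import GeneticCode, estimate_pair
from .errors import InsufficientDataError, SaturationError, StopCodonError
from .io import CodonAlignment, OrthologMap


@dataclass(frozen=True)
class GeneSpeciesCharacteristic:
    """Median pairwise omega of one gene in one focal species vs a taxon."""

    gene_id: str
    species_id: str
    taxon: str
    median_omega: float | None
    n_pairs_used: int
    n_pairs_excluded: int
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.median_omega is not None


def median_omega(
    gene_id: str,
    focal: str,
    aln: CodonAlignment,
    omap: OrthologMap,
    taxon_species: Iterable[str],
    taxon_name: str = "",
    code: GeneticCode | None = None,
) -> GeneSpeciesCharacteristic:
    """Median of pairwise omega between *focal* and every other functional
    taxon member, on a filtered (gap-free) alignment.

    The focal species must itself be functional; otherwise the
    characteristic is undefined with reason ``"pseudogene/lost"``.  Pairs
    whose omega is undefined (dS = 0), saturated, or whose partner sequence
    carries an internal stop are excluded and counted in
    ``n_pairs_excluded``.  With no usable pair the characteristic is
    undefined with reason ``"no_pairs"``.
    """
    taxon_list = [sp for sp in taxon_species if sp != focal]
    if omap.status(gene_id, focal) != "functional":
        return GeneSpeciesCharacteristic(
            gene_id, focal, taxon_name, None, 0, 0, reason="pseudogene/lost"
        )
    focal_seq = aln.sequence(focal)
    omegas: list[float] = []
    excluded = 0
    for other in taxon_list:
        if omap.status(gene_id, other) != "functional":
            continue
        if other not in aln.species:
            continue
        try:
            counts = estimate_pair(focal_seq, aln.sequence(other), code)
        except (SaturationError, StopCodonError):
            excluded += 1
            continue
        if counts.omega is None:
            excluded += 1
            continue
        omegas.append(counts.omega)
    if not omegas:
        return GeneSpeciesCharacteristic(
            gene_id, focal, taxon_name, None, 0, excluded, reason="no_pairs"
        )
    return GeneSpeciesCharacteristic(
        gene_id,
        focal,
        taxon_name,
        statistics.median(omegas),
        len(omegas),
        excluded,
    )


def taxon_characteristics(
    gene_id: str,
    aln: CodonAlignment,
    omap: OrthologMap,
    taxon_species: Sequence[str],
    taxon_name: str = "",
    code: GeneticCode | None = None,
) -> list[GeneSpeciesCharacteristic]:
    """The characteristic for every taxon species in turn (one per species)."""
    return [
        median_omega(gene_id, sp, aln, omap, taxon_species, taxon_name, code)
        for sp in taxon_species
    ]


def median_interval(
    records: Iterable[GeneSpeciesCharacteristic],
) -> tuple[float, float]:
    """(min, max) of the defined medians — the median variation interval."""
    values = [r.median_omega for r in records if r.median_omega is not None]
    if not values:
        raise InsufficientDataError("no defined median in any record")
    return min(values), max(values)
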