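"""Domain consensus, per-taxon deviation counting and radical-substitution
analysis, plus longevity-quotient comparisons at a residue position.

A *radical* substitution replaces an amino acid by one from a different
physicochemical group under a six-group partition of the 20 standard amino
acids: {C}, {S,T,A,G,P}, {D,E,N,Q}, {H,R,K}, {M,I,L,V}, {W,Y,F}.
Substitutions within a group are conservative.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .errors import AlignmentError, EvorateError, InsufficientDataError
from .io import ProteinAlignment, TraitTable

_GAPLIKE = frozenset("-X*")


@dataclass(frozen=True)
class GroupScheme:
    """A partition of the 20 standard amino acids into six disjoint groups."""

    groups: tuple[frozenset[str], ...]

    def __post_init__(self):
        if len(self.groups) != 6:
            raise ValueError(f"expected 6 groups, got {len(self.groups)}")
        union = set().union(*self.groups)
        if union != set("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError("groups must cover exactly the 20 standard amino acids")
        if sum(len(g) for g in self.groups) != 20:
            raise ValueError("groups must be disjoint")
        object.__setattr__(
            self,
            "_index",
            {aa: i for i, g in enumerate(self.groups) for aa in g},
        )

    def group_of(self, aa: str) -> int:
        try:
            return self._index[aa]
        except KeyError:
            raise EvorateError(f"non-standard residue {aa!r}") from None


#: cysteine | small (S,T,A,G,P) | acid/amide (D,E,N,Q) | basic (H,R,K)
#: | aliphatic (M,I,L,V) | aromatic (W,Y,F)
SIX_GROUPS = GroupScheme(
    groups=(
        frozenset("C"),
        frozenset("STAGP"),
        frozenset("DENQ"),
        frozenset("HRK"),
        frozenset("MILV"),
        frozenset("WYF"),
    )
)


def is_radical(aa1: str, aa2: str, scheme: GroupScheme = SIX_GROUPS) -> bool:
    """True iff the two residues belong to different groups.

    Symmetric; false for identical residues.  Raises on non-standard
    residues (gaps included).
    """
    return scheme.group_of(aa1.upper()) != scheme.group_of(aa2.upper())


def build_consensus(msa: ProteinAlignment) -> tuple[str, tuple[bool, ...]]:
    """Per-column plurality consensus of a protein alignment.

    Gaps and ambiguity codes are ignored per column.  Ties are broken by
    alphabetical order of the tied residues and flagged in the returned
    boolean vector.  A column consisting entirely of gaps raises.
    """
    if len(msa.entries) < 2:
        raise AlignmentError("consensus requires at least 2 rows")
    consensus = []
    ties = []
    for pos in range(msa.length):
        counts: dict[str, int] = {}
        for _, seq in msa.entries:
            ch = seq[pos]
            if ch in _GAPLIKE:
                continue
            counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            raise AlignmentError(f"column {pos + 1} is entirely gaps")
        best = max(counts.values())
        winners = sorted(aa for aa, c in counts.items() if c == best)
        consensus.append(winners[0])
        ties.append(len(winners) > 1)
    return "".join(consensus), tuple(ties)


DeviationMode = Literal["all", "radical"]


@dataclass(frozen=True)
class DeviationTable:
    """Per-taxon, per-position counts of deviations from a consensus.

    ``counts[taxon][pos]`` is the number of taxon species whose residue at
    0-based position ``pos`` differs from the consensus (mode ``"all"``) or
    differs radically (mode ``"radical"``).  Gaps are never deviations.
    ``conservative_positions[taxon]`` counts positions with zero counted
    deviations in that taxon; key ``"overall"`` counts positions with zero
    deviations in every taxon.
    """

    consensus: str
    mode: str
    taxa: tuple[str, ...]
    counts: Mapping[str, tuple[int, ...]]
    conservative_positions: Mapping[str, int]


def deviation_counts(
    msa: ProteinAlignment,
    consensus: str,
    taxon_map: Mapping[str, str],
    mode: DeviationMode = "all",
    scheme: GroupScheme = SIX_GROUPS,
) -> DeviationTable:
    """Count per-taxon deviations from the consensus at every position.

    Every alignment row must be assigned to a taxon by *taxon_map*.  In
    mode ``"radical"`` only between-group substitutions are counted; at
    every position and taxon the radical count is bounded by the all-mode
    count.
    """
    if len(consensus) != msa.length:
        raise AlignmentError(
            f"consensus length {len(consensus)} != alignment length {msa.length}"
        )
    if mode not in ("all", "radical"):
        raise ValueError(f"unknown mode {mode!r}")
    for sp in msa.species:
        if sp not in taxon_map:
            raise EvorateError(f"row {sp!r} has no taxon assignment")
    taxa = tuple(dict.fromkeys(taxon_map[sp] for sp in msa.species))
    counts = {t: [0] * msa.length for t in taxa}
    for sp, seq in msa.entries:
        taxon = taxon_map[sp]
        for pos in range(msa.length):
            ch = seq[pos]
            if ch in _GAPLIKE:
                continue
            cons = consensus[pos]
            if ch == cons:
                continue
            if mode == "all" or is_radical(ch, cons, scheme):
                counts[taxon][pos] += 1
    conservative = {
        t: sum(1 for c in counts[t] if c == 0) for t in taxa
    }
    conservative["overall"] = sum(
        1 for pos in range(msa.length) if all(counts[t][pos] == 0 for t in taxa)
    )
    return DeviationTable(
        consensus=consensus,
        mode=mode,
        taxa=taxa,
        counts={t: tuple(c) for t, c in counts.items()},
        conservative_positions=conservative,
    )


@dataclass(frozen=True)
class LqComparison:
    """Median LQ of species matching a positional criterion vs the rest."""

    position: int
    criterion: str
    n_in: int
    n_out: int
    median_lq_in: float
    median_lq_out: float
    percent_difference: float


def residue_group_lq_compare(
    msa: ProteinAlignment,
    position: int,
    traits: TraitTable,
    residue: str | None = None,
    mode: Literal["exact_residue", "radical_vs_consensus"] = "exact_residue",
    consensus: str | None = None,
    scheme: GroupScheme = SIX_GROUPS,
) -> LqComparison:
    """Compare median longevity quotient between two species groups split by
    a 1-based domain position.

    mode ``"exact_residue"``: the in-group carries *residue* at the
    position; everyone else (including gap carriers) is out-group.
    mode ``"radical_vs_consensus"``: the in-group carries a residue that
    differs radically from the consensus residue at the position (the
    consensus is computed from *msa* when not supplied); gaps are never
    radical.

    ``percent_difference = 100 × (median_in − median_out) / median_out``.
    Species without an LQ value are dropped before the split.
    """
    if not 1 <= position <= msa.length:
        raise EvorateError(
            f"position {position} outside domain 1..{msa.length}"
        )
    if mode == "exact_residue":
        if not residue:
            raise ValueError("mode 'exact_residue' requires a residue")
        criterion = f"residue {residue.upper()} at position {position}"
    elif mode == "radical_vs_consensus":
        if consensus is None:
            consensus, _ = build_consensus(msa)
        criterion = (
            f"radical substitution vs consensus "
            f"{consensus[position - 1]} at position {position}"
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    idx = position - 1
    lq_in: list[float] = []
    lq_out: list[float] = []
    for sp, seq in msa.entries:
        rec = traits.get(sp)
        if rec is None or rec.lq is None:
            continue
        ch = seq[idx]
        if mode == "exact_residue":
            member = ch == residue.upper()
        else:
            member = ch not in _GAPLIKE and is_radical(
                ch, consensus[idx], scheme
            )
        (lq_in if member else lq_out).append(rec.lq)
    if not lq_in or not lq_out:
        raise InsufficientDataError(
            f"empty group at position {position}: "
            f"{len(lq_in)} in, {len(lq_out)} out"
        )
    m_in = statistics.median(lq_in)
    m_out = statistics.median(lq_out)
    return LqComparison(
        position=position,
        criterion=criterion,
        n_in=len(lq_in),
        n_out=len(lq_out),
        median_lq_in=m_in,
        median_lq_out=m_out,
        percent_difference=100.0 * (m_in - m_out) / m_out,
    )
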