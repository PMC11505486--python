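"""Pairwise dN/dS estimation by codon site counting, and a codon
substitution simulator.

The estimator is the Nei–Gojobori (1986) counting method: synonymous and
nonsynonymous *sites* are counted fractionally per codon (each of the nine
single-nucleotide neighbours contributes 1/3 of a site), *differences*
between two codons are averaged over all mutational pathways (orderings of
the single-step changes), and the observed proportions are corrected for
multiple hits with the Jukes–Cantor formula.  dN/dS (omega) below one
indicates purifying selection, near one neutrality, above one positive
selection.

The simulator evolves a sequence by repeated single-nucleotide proposals,
transition-biased by kappa, accepting synonymous changes always,
nonsynonymous changes with probability omega, and stop-creating changes
never — so the counting estimator can be validated by parameter recovery.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from Bio.Data import CodonTable

from .errors import CodonError, SaturationError, StopCodonError

NUCLEOTIDES = "ACGT"
#: purine<->purine and pyrimidine<->pyrimidine single-nucleotide changes
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class GeneticCode:
    """A codon -> amino-acid table with precomputed site counts.

    Only the standard nuclear code ships with the package; the class exists
    so the counting functions are explicit about which code they use and so
    per-codon site counts and pairwise difference counts are computed once.
    """

    def __init__(self, table: dict[str, str], name: str = "custom"):
        if len(table) != 64:
            raise CodonError(f"genetic code must map 64 codons, got {len(table)}")
        stops = [c for c, aa in table.items() if aa == "*"]
        if len(stops) != 3:
            raise CodonError(f"expected 3 stop codons, got {len(stops)}")
        self.name = name
        self.table = dict(table)
        self.stop_codons = frozenset(stops)
        self.sense_codons = tuple(sorted(c for c in table if table[c] != "*"))
        self._sites = {c: _count_sites_impl(c, self) for c in self.sense_codons}
        self._diffs: dict[tuple[str, str], "DifferenceCounts"] = {}

    def translate(self, codon: str) -> str:
        try:
            return self.table[codon]
        except KeyError:
            raise CodonError(f"not an unambiguous codon: {codon!r}") from None

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def is_synonymous(self, c1: str, c2: str) -> bool:
        return self.translate(c1) == self.translate(c2)

    @classmethod
    def standard(cls) -> "GeneticCode":
        bio = CodonTable.unambiguous_dna_by_id[1]
        table = dict(bio.forward_table)
        for stop in bio.stop_codons:
            table[stop] = "*"
        return cls(table, name="standard")


def _neighbours(codon: str) -> Iterator[str]:
    """The nine codons one nucleotide change away."""
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                yield codon[:pos] + nt + codon[pos + 1:]


def _count_sites_impl(codon: str, code: GeneticCode) -> tuple[float, float]:
    s = 0.0
    for nb in _neighbours(codon):
        # a change creating a stop codon is a nonsynonymous opportunity
        if not code.is_stop(nb) and code.translate(nb) == code.translate(codon):
            s += 1.0 / 3.0
    return s, 3.0 - s


def count_sites(codon: str, code: GeneticCode | None = None) -> tuple[float, float]:
    """Fractional synonymous and nonsynonymous site counts of one codon.

    Each of the nine single-nucleotide neighbours contributes one third of a
    site: synonymous if it encodes the same amino acid, nonsynonymous
    otherwise.  Mutations to stop codons count as nonsynonymous.  S + N = 3
    exactly for every sense codon.

    Raises
    ------
    CodonError
        If *codon* is a stop codon or contains ambiguity characters.
    """
    code = code or STANDARD_CODE
    codon = codon.upper()
    if code.is_stop(codon):
        raise CodonError(f"stop codon has no site counts: {codon}")
    if codon in code._sites:
        return code._sites[codon]
    return _count_sites_impl(codon, code)  # pragma: no cover - custom codes


@dataclass(frozen=True)
class DifferenceCounts:
    """Pathway-averaged synonymous/nonsynonymous differences for one codon pair."""

    sd: float
    nd: float
    #: True when every mutational pathway passed through a stop codon and the
    #: counts fall back to classifying stop-passing steps as nonsynonymous.
    used_stop_paths: bool = False


def count_differences(
    c1: str, c2: str, code: GeneticCode | None = None
) -> DifferenceCounts:
    """Synonymous/nonsynonymous differences between two sense codons.

    If the codons differ at ``k`` positions, every one of the ``k!``
    orderings of single-nucleotide steps is enumerated; each step is
    classified synonymous or nonsynonymous and the counts are averaged over
    orderings.  Orderings whose intermediate codons are stops are excluded
    and the average renormalised over the remainder.  Should every ordering
    be blocked by a stop (does not occur between sense codons under the
    standard code), all orderings are used with stop-passing steps counted
    as nonsynonymous and the result flagged.

    ``sd + nd`` equals the number of differing positions.
    """
    code = code or STANDARD_CODE
    c1, c2 = c1.upper(), c2.upper()
    key = (c1, c2) if c1 <= c2 else (c2, c1)
    cached = code._diffs.get(key)
    if cached is not None:
        return cached
    for c in (c1, c2):
        if code.is_stop(c):
            raise StopCodonError(f"stop codon in difference counting: {c}")
        code.translate(c)  # raises on ambiguity
    result = _count_differences_impl(c1, c2, code)
    code._diffs[key] = result
    return result


def _path_steps(c1: str, c2: str, order: tuple[int, ...]) -> list[tuple[str, str]]:
    steps = []
    cur = c1
    for pos in order:
        nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
        steps.append((cur, nxt))
        cur = nxt
    return steps


def _count_differences_impl(c1: str, c2: str, code: GeneticCode) -> DifferenceCounts:
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return DifferenceCounts(0.0, 0.0)
    valid: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        steps = _path_steps(c1, c2, order)
        sd = nd = 0.0
        through_stop = any(code.is_stop(b) for _, b in steps[:-1])
        for a, b in steps:
            if code.is_stop(a) or code.is_stop(b):
                nd += 1.0  # only reachable in the all-blocked fallback
            elif code.is_synonymous(a, b):
                sd += 1.0
            else:
                nd += 1.0
        (blocked if through_stop else valid).append((sd, nd))
    if valid:
        sd = sum(v[0] for v in valid) / len(valid)
        nd = sum(v[1] for v in valid) / len(valid)
        return DifferenceCounts(sd, nd)
    paths = blocked
    sd = sum(v[0] for v in paths) / len(paths)
    nd = sum(v[1] for v in paths) / len(paths)
    return DifferenceCounts(sd, nd, used_stop_paths=True)


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Raises :class:`SaturationError` for p >= 3/4, where the correction is
    undefined (the pair is saturated and must be excluded).
    """
    if p < 0:
        raise ValueError(f"proportion must be non-negative, got {p}")
    if p >= 0.75:
        raise SaturationError(f"difference proportion {p:.4f} >= 3/4: saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class CodonPairCounts:
    """Site, difference, proportion and distance summary for one sequence pair.

    ``omega`` is ``None`` when dS = 0 (no synonymous divergence observed),
    in which case the ratio is undefined and the pair is excluded from
    downstream medians.
    """

    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ds: float
    dn: float
    omega: float | None
    n_codons: int


def _codons(seq: str) -> list[str]:
    return [seq[i: i + 3] for i in range(0, len(seq), 3)]


def estimate_pair(
    seq_a: str, seq_b: str, code: GeneticCode | None = None
) -> CodonPairCounts:
    """Nei–Gojobori pairwise dN/dS for two aligned, gap-free coding sequences.

    Site counts are summed per codon and averaged between the two sequences;
    difference counts are summed over codon pairs; proportions are corrected
    with :func:`jukes_cantor`.

    Raises
    ------
    StopCodonError
        On an internal stop codon in either sequence (pseudogene signal).
    SaturationError
        When pS or pN reaches the correction's domain boundary.
    CodonError
        On length mismatch, broken frame, gaps or ambiguity characters.
    """
    code = code or STANDARD_CODE
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise CodonError(
            f"sequence length mismatch: {len(seq_a)} vs {len(seq_b)}"
        )
    if len(seq_a) % 3 != 0:
        raise CodonError(f"length {len(seq_a)} not a multiple of 3")
    if len(seq_a) == 0:
        raise CodonError("zero retained codons")
    s_a = n_a = s_b = n_b = sd = nd = 0.0
    n_codons = 0
    for ca, cb in zip(_codons(seq_a), _codons(seq_b)):
        for c in (ca, cb):
            if any(ch not in NUCLEOTIDES for ch in c):
                raise CodonError(f"gap or ambiguous base in codon {c!r}; filter first")
            if code.is_stop(c):
                raise StopCodonError(f"internal stop codon {c}")
        sa, na = count_sites(ca, code)
        sb, nb = count_sites(cb, code)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        d = count_differences(ca, cb, code)
        sd += d.sd
        nd += d.nd
        n_codons += 1
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    dn = jukes_cantor(pn)
    if ps >= 0.75:
        # synonymous saturation: with zero nonsynonymous divergence the
        # ratio is still a clean 0; otherwise the pair is unusable
        if nd == 0.0:
            ds, omega = math.inf, 0.0
        else:
            raise SaturationError(
                f"synonymous proportion {ps:.4f} >= 3/4: saturated"
            )
    else:
        ds = jukes_cantor(ps)
        omega = dn / ds if ds > 0 else None
    return CodonPairCounts(
        s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd,
        ps=ps, pn=pn, ds=ds, dn=dn, omega=omega, n_codons=n_codons,
    )


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the codon substitution simulator.

    omega_true
        Target dN/dS: acceptance probability of nonsynonymous proposals.
    kappa
        Transition/transversion proposal rate ratio.
    t
        Expected number of substitution proposals per codon.
    n_codons
        Sequence length in codons.
    seed
        Fixes the full output.
    """

    omega_true: float
    kappa: float = 2.0
    t: float = 0.3
    n_codons: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.omega_true < 0 or self.kappa < 0 or self.t < 0:
            raise ValueError("omega_true, kappa and t must be non-negative")
        if self.n_codons < 1:
            raise ValueError("n_codons must be positive")


def random_coding_sequence(
    n_codons: int, rng: np.random.Generator, code: GeneticCode | None = None
) -> str:
    """A sequence of *n_codons* sense codons drawn uniformly."""
    code = code or STANDARD_CODE
    idx = rng.integers(0, len(code.sense_codons), size=n_codons)
    return "".join(code.sense_codons[i] for i in idx)


def evolve_sequence(
    seq: str,
    omega: float,
    kappa: float,
    t: float,
    rng: np.random.Generator,
    code: GeneticCode | None = None,
) -> str:
    """Evolve a coding sequence by Poisson(t × n_codons) proposal events.

    Each event picks a codon and one of its three positions uniformly,
    proposes an alternative nucleotide with relative rate *kappa* for the
    transition and 1 for each transversion, then accepts with probability 1
    (synonymous), *omega* (nonsynonymous) or 0 (stop-creating).
    """
    code = code or STANDARD_CODE
    codons = _codons(seq.upper())
    n = len(codons)
    n_events = int(rng.poisson(t * n))
    for _ in range(n_events):
        ci = int(rng.integers(n))
        pos = int(rng.integers(3))
        cur = codons[ci]
        base = cur[pos]
        ts = _TRANSITION[base]
        tv = [b for b in NUCLEOTIDES if b != base and b != ts]
        total = kappa + 2.0
        u = rng.random() * total
        new_base = ts if u < kappa else tv[0] if u < kappa + 1.0 else tv[1]
        new = cur[:pos] + new_base + cur[pos + 1:]
        if code.is_stop(new):
            continue
        if code.is_synonymous(cur, new):
            codons[ci] = new
        elif rng.random() < omega:
            codons[ci] = new
    return "".join(codons)


def simulate_pair(
    params: SimulationParams, code: GeneticCode | None = None
) -> tuple[str, str]:
    """Draw an ancestral sequence and a derived sequence under *params*.

    The ancestral sequence is uniform over sense codons; the derived one is
    produced by :func:`evolve_sequence`.  Deterministic given ``params.seed``.
    """
    code = code or STANDARD_CODE
    rng = np.random.default_rng(params.seed)
    anc = random_coding_sequence(params.n_codons, rng, code)
    der = evolve_sequence(anc, params.omega_true, params.kappa, params.t, rng, code)
    return anc, der


STANDARD_CODE = GeneticCode.standard()
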