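"""End-to-end orchestration: simulate or ingest a study, then run every
analysis stage and write plain-text reports plus a run manifest.

Stage outputs are pure functions of the declared inputs and the seed; the
manifest records the package version, the seed and SHA-256 digests of all
inputs and reports so a run can be audited and reproduced byte for byte.
Excluded pairs and species are counted in the reports, keeping the sample
size bookkeeping auditable.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Seq import Seq

from . import __version__
from .association import AssociationResult, classify_selection_signal, fit_association
from .codon import GeneticCode, STANDARD_CODE, estimate_pair
from .composition import composition, correlate_composition
from .domains import (
    SIX_GROUPS,
    build_consensus,
    deviation_counts,
    residue_group_lq_compare,
)
from .errors import EvorateError, SaturationError, StopCodonError, ZeroVarianceError, InsufficientDataError
from .io import (
    CodonAlignment,
    OrthologMap,
    ProteinAlignment,
    TraitTable,
    filter_alignment,
    read_codon_alignment,
    read_ortholog_map,
    read_protein_alignment,
    read_trait_table,
    write_association_report,
    write_codon_alignment,
    write_ortholog_map,
    write_protein_alignment,
    write_trait_table,
)
from .median import GeneSpeciesCharacteristic, median_interval, taxon_characteristics
from .synth import (
    PlannedDeviation,
    StudyConfig,
    _deviant_residue,
    generate_domain_alignment,
    generate_ortholog_set,
    generate_traits,
    species_panel,
)


@dataclass(frozen=True)
class PipelineParams:
    """Analysis knobs shared by simulate and ingest runs."""

    min_len: int | None = None  # codon threshold for the short-sequence filter
    alpha: float = 1e-3
    position: int = 19  # 1-based domain position of interest
    residue: str = ""  # residue of interest; simulate mode fills it in
    taxon_name: str = "panel"


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs of one pipeline run.

    Simulate mode draws the whole study from ``study``; ingest mode reads
    the referenced files.  File existence is checked before any computation.
    """

    mode: str = "simulate"
    study: StudyConfig = field(default_factory=StudyConfig)
    alignment_paths: Mapping[str, str] = field(default_factory=dict)
    ortholog_map_path: str = ""
    traits_path: str = ""
    domain_alignment_path: str = ""
    taxa: Mapping[str, Sequence[str]] = field(default_factory=dict)
    params: PipelineParams = field(default_factory=PipelineParams)


def _fmt(x: float | None) -> str:
    return "NA" if x is None else f"{x:.10g}"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_pair_table(
    aln: CodonAlignment, path: str | Path, code: GeneticCode | None = None
) -> None:
    """One row per unordered species pair: site counts, differences,
    corrected distances and omega (``NA`` when undefined or saturated)."""
    lines = ["speciesA\tspeciesB\tS\tN\tSd\tNd\tdN\tdS\tomega"]
    for (sp_a, seq_a), (sp_b, seq_b) in itertools.combinations(aln.entries, 2):
        try:
            c = estimate_pair(seq_a, seq_b, code)
        except (SaturationError, StopCodonError):
            lines.append(f"{sp_a}\t{sp_b}\tNA\tNA\tNA\tNA\tNA\tNA\tNA")
            continue
        lines.append(
            f"{sp_a}\t{sp_b}\t{_fmt(c.s_sites)}\t{_fmt(c.n_sites)}"
            f"\t{_fmt(c.sd)}\t{_fmt(c.nd)}\t{_fmt(c.dn)}\t{_fmt(c.ds)}"
            f"\t{_fmt(c.omega)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_characteristics(
    chars: Sequence[GeneSpeciesCharacteristic], path: str | Path
) -> None:
    lines = ["gene\tspecies\tmedian_omega\tn_used\tn_excluded\treason"]
    for ch in chars:
        lines.append(
            f"{ch.gene_id}\t{ch.species_id}\t{_fmt(ch.median_omega)}"
            f"\t{ch.n_pairs_used}\t{ch.n_pairs_excluded}\t{ch.reason or ''}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _write_deviation_table(table, path: Path) -> None:
    n = len(table.consensus)
    header = "taxon\t" + "\t".join(f"pos{i}" for i in range(1, n + 1)) + "\tconservative"
    lines = [header, "consensus\t" + "\t".join(table.consensus) + "\t"]
    for taxon in table.taxa:
        cells = "\t".join(str(c) for c in table.counts[taxon])
        lines.append(f"{taxon}\t{cells}\t{table.conservative_positions[taxon]}")
    lines.append(
        "overall\t" + "\t".join("" for _ in range(n))
        + f"\t{table.conservative_positions['overall']}"
    )
    path.write_text("\n".join(lines) + "\n")


def translate_alignment(aln: CodonAlignment) -> list[tuple[str, str]]:
    """Translate a filtered (gap-free) codon alignment to proteins."""
    return [
        (sp, str(Seq(seq).translate())) for sp, seq in aln.entries
    ]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the report bundle into *out_dir*.

    Returns a summary dict (also serialised as ``manifest.json``).  Any
    stage failure raises with a stage-attributed message; in ingest mode
    missing input files abort before any computation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.params
    if config.mode == "ingest":
        _preflight(config)
        alignments = {
            gene: read_codon_alignment(path, gene)
            for gene, path in config.alignment_paths.items()
        }
        omap = read_ortholog_map(config.ortholog_map_path)
        traits = read_trait_table(config.traits_path)
        domain_aln = (
            read_protein_alignment(config.domain_alignment_path)
            if config.domain_alignment_path
            else None
        )
        taxa = {k: tuple(v) for k, v in config.taxa.items()}
        domain_taxon_map = {
            sp: name for name, members in taxa.items() for sp in members
        }
        residue = params.residue
        input_files = [
            Path(p)
            for p in (
                *config.alignment_paths.values(),
                config.ortholog_map_path,
                config.traits_path,
                config.domain_alignment_path,
            )
            if p
        ]
    elif config.mode == "simulate":
        study = config.study
        alignments, omap = generate_ortholog_set(study)
        # the domain alignment reuses the species panel: half and half taxa
        n = study.n_species
        sizes = {"taxonA": (n + 1) // 2, "taxonB": n // 2}
        plan = (
            PlannedDeviation(params.position, "taxonA", max(sizes["taxonA"] // 3, 1)),
            PlannedDeviation(params.position, "taxonB", max(sizes["taxonB"] // 4, 1)),
        )
        domain_aln, domain_taxon_map, consensus = generate_domain_alignment(
            sizes, plan, seed=study.seed + 1
        )
        panel = species_panel(study.n_species)
        rename = dict(zip(domain_aln.species, panel))
        domain_taxon_map = {rename[sp]: t for sp, t in domain_taxon_map.items()}
        domain_aln = ProteinAlignment(
            name=domain_aln.name,
            entries=tuple((rename[sp], seq) for sp, seq in domain_aln.entries),
        )
        residue = params.residue or _deviant_residue(
            consensus[params.position - 1], True, SIX_GROUPS
        )
        carriers = {
            sp
            for sp, seq in domain_aln.entries
            if seq[params.position - 1] == residue
        }
        # traits are planted on the first trait-coupled gene's medians
        planted_gene = next(
            (g.gene_id for g in study.genes if g.omega_mode == "trait_coupled"),
            study.genes[0].gene_id,
        )
        filtered0 = filter_alignment(alignments[planted_gene], params.min_len)
        chars0 = taxon_characteristics(
            planted_gene,
            filtered0,
            omap,
            omap.functional_species(planted_gene),
            params.taxon_name,
        )
        medians = {
            ch.species_id: ch.median_omega for ch in chars0 if ch.defined
        }
        traits = generate_traits(
            medians,
            study.trait_model,
            seed=study.seed + 2,
            lq_model=study.lq_model,
            lq_carriers=carriers,
        )
        taxa = {}
        # persist the simulated inputs so the run is self-documenting
        input_files = []
        for gene, aln in alignments.items():
            p = out / f"input_{gene}.fasta"
            write_codon_alignment(aln, p)
            input_files.append(p)
        write_ortholog_map(omap, out / "input_orthologs.tsv")
        write_trait_table(traits, out / "input_traits.tsv")
        write_protein_alignment(domain_aln, out / "input_domain.fasta")
        input_files += [
            out / "input_orthologs.tsv",
            out / "input_traits.tsv",
            out / "input_domain.fasta",
        ]
    else:
        raise EvorateError(f"unknown pipeline mode {config.mode!r}")

    # --- median characteristics and associations, per gene ----------------
    all_chars: list[GeneSpeciesCharacteristic] = []
    assoc_rows: dict[str, list[AssociationResult]] = {"mrls": [], "lg_weight": []}
    calls: list[tuple[str, str, float, str]] = []
    for gene, aln in sorted(alignments.items()):
        try:
            filtered = filter_alignment(aln, params.min_len)
        except EvorateError as e:
            raise EvorateError(f"stage filter[{gene}]: {e}") from e
        functional = omap.functional_species(gene)
        chars = taxon_characteristics(
            gene, filtered, omap, functional, params.taxon_name
        )
        all_chars.extend(chars)
        for trait in ("mrls", "lg_weight"):
            try:
                res = fit_association(chars, traits, trait)
            except (ZeroVarianceError, InsufficientDataError):
                continue
            assoc_rows[trait].append(res)
            calls.append((gene, trait, res.p, classify_selection_signal(res, params.alpha)))
    write_characteristics(all_chars, out / "medians.tsv")
    write_association_report(assoc_rows["mrls"], out / "association_mrls.tsv")
    write_association_report(assoc_rows["lg_weight"], out / "association_lg_weight.tsv")
    (out / "classification.tsv").write_text(
        "gene\ttrait\tp\tcall\n"
        + "".join(f"{g}\t{t}\t{p:.10g}\t{c}\n" for g, t, p, c in calls)
    )

    # --- composition stage (first gene's protein) --------------------------
    first_gene = sorted(alignments)[0]
    filtered = filter_alignment(alignments[first_gene], params.min_len)
    profiles = []
    for sp, prot in translate_alignment(filtered):
        if omap.status(first_gene, sp) != "functional":
            continue
        profiles.append(composition(prot.replace("*", ""), sp))
    comp_lines = ["amino_acid\tmean_occurrence_pct\tr\tp"]
    try:
        comp = correlate_composition(profiles, traits, "mrls")
        for aa in sorted(comp):
            c = comp[aa]
            comp_lines.append(
                f"{aa}\t{_fmt(c.mean_occurrence)}\t{_fmt(c.r)}\t{_fmt(c.p)}"
            )
    except InsufficientDataError:
        pass
    (out / "composition_mrls.tsv").write_text("\n".join(comp_lines) + "\n")

    # --- domain stage -------------------------------------------------------
    summary_domain = {}
    if domain_aln is not None and domain_taxon_map:
        consensus_str, _tie = build_consensus(domain_aln)
        for mode in ("all", "radical"):
            table = deviation_counts(domain_aln, consensus_str, domain_taxon_map, mode)
            _write_deviation_table(table, out / f"deviations_{mode}.tsv")
        lq_lines = ["position\tcriterion\tn_in\tn_out\tmedian_lq_in\tmedian_lq_out\tpercent_difference"]
        try:
            cmp_res = residue_group_lq_compare(
                domain_aln,
                params.position,
                traits,
                residue=residue or None,
                mode="exact_residue" if residue else "radical_vs_consensus",
                consensus=consensus_str,
            )
            lq_lines.append(
                f"{cmp_res.position}\t{cmp_res.criterion}\t{cmp_res.n_in}"
                f"\t{cmp_res.n_out}\t{_fmt(cmp_res.median_lq_in)}"
                f"\t{_fmt(cmp_res.median_lq_out)}\t{_fmt(cmp_res.percent_difference)}"
            )
            summary_domain = {
                "lq_percent_difference": cmp_res.percent_difference,
                "n_carriers": cmp_res.n_in,
            }
        except (InsufficientDataError, EvorateError):
            pass
        (out / "lq_comparison.tsv").write_text("\n".join(lq_lines) + "\n")

    # --- manifest -----------------------------------------------------------
    report_files = sorted(
        p for p in out.iterdir() if p.name != "manifest.json" and p.is_file()
    )
    manifest = {
        "version": __version__,
        "mode": config.mode,
        "seed": config.study.seed if config.mode == "simulate" else None,
        "alpha": params.alpha,
        "inputs": {p.name: _sha256(Path(p)) for p in input_files},
        "reports": {p.name: _sha256(p) for p in report_files},
        "classification": [
            {"gene": g, "trait": t, "p": p, "call": c} for g, t, p, c in calls
        ],
        "domain": summary_domain,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _preflight(config: PipelineConfig) -> None:
    missing = [
        p
        for p in (
            *config.alignment_paths.values(),
            config.ortholog_map_path,
            config.traits_path,
            config.domain_alignment_path,
        )
        if p and not Path(p).exists()
    ]
    if missing:
        raise EvorateError(f"missing input files: {missing}")
    if not config.alignment_paths:
        raise EvorateError("ingest mode requires at least one alignment path")
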