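"""End-to-end pipeline over an emitted fixture (or equivalently laid-out data).

Stages: parse domain hits -> E-value/coverage filter -> overlap
resolution -> architectures -> protein classification -> module census ->
gene labeling -> susCD pair detection -> PUL calling -> cellulosome
reports -> novelty scoring -> spectral-count integration.  All outputs
are stable-ordered text (TSV/JSON) so repeated runs on the same fixture
are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import architecture as arch_mod
from . import domain_io, loci, novelty, summarize
from .model import Gene, gene_labels_from_architecture
from .synthetic_data import load_fixture_set


def _json_dump(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def label_genes(genes, architectures) -> list:
    """Attach functional labels derived from domain architectures."""
    out = []
    for g in genes:
        arch = architectures.get(g.protein_id)
        labels = (
            gene_labels_from_architecture(arch)
            if arch is not None and len(arch) > 0
            else frozenset({"OTHER"})
        )
        out.append(
            Gene(
                genome_id=g.genome_id, contig_id=g.contig_id,
                protein_id=g.protein_id, start=g.start, end=g.end,
                strand=g.strand, rank=g.rank, functional_labels=labels,
            )
        )
    return out


def run_fixture(
    fixture_dir,
    out_dir,
    window: int = loci.DEFAULT_WINDOW,
    evalue_max: float = domain_io.DEFAULT_EVALUE_MAX,
    coverage_min: float = domain_io.DEFAULT_COVERAGE_MIN,
    novelty_threshold: float = novelty.DEFAULT_THRESHOLD,
    run_novelty: bool = True,
) -> dict:
    """Run the full discovery pipeline on a fixture directory.

    Returns a results dict with the in-memory objects; writes the report
    files under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bins, raw_hits, sequences, manifest, spectra = load_fixture_set(fixture_dir)

    filtered = domain_io.filter_hits(raw_hits, evalue_max, coverage_min)
    all_pids = sorted(sequences.proteins)
    architectures = domain_io.build_architectures(filtered, all_protein_ids=all_pids)
    domain_io.write_hits_tsv(filtered, out / "filtered_hits.tsv")
    domain_io.write_architectures_tsv(architectures, out / "architectures.tsv")

    classifications = {
        pid: arch_mod.classify_protein(arch) for pid, arch in architectures.items()
    }
    genome_of = {
        g.protein_id: b.genome_id for b in bins for g in b.genes
    }
    arch_mod.write_classifications_tsv(
        classifications, architectures, out / "classifications.tsv", genome_of
    )
    cen = arch_mod.census(classifications, architectures)
    _json_dump(cen.to_dict(), out / "census.json")
    duf_records = arch_mod.duf_screen(classifications, architectures)
    _json_dump(
        [
            {"protein_id": pid, "dufs": list(d), "accessory": list(a)}
            for pid, d, a in duf_records
        ],
        out / "duf_screen.json",
    )

    # locus calling on re-ranked, re-labeled genes
    genes = label_genes(
        loci.assign_ranks([g for b in bins for g in b.genes]), architectures
    )
    pairs = loci.detect_sus_pairs(genes)
    calls = loci.call_puls(genes, pairs, window=window)
    fmap = summarize.FunctionMap()
    pul_summaries = [loci.summarize_pul(c, function_map=fmap) for c in calls]
    loci.write_pul_table(calls, out / "puls.tsv")
    _json_dump(pul_summaries, out / "pul_summary.json")

    cell_reports = {}
    for b in bins:
        pids = [g.protein_id for g in b.genes]
        cell_reports[b.genome_id] = loci.detect_cellulosomes(
            b.genome_id, {p: classifications[p] for p in pids}
        )
    _json_dump(
        {g: r.to_dict() for g, r in sorted(cell_reports.items())},
        out / "cellulosomes.json",
    )

    novelty_records = []
    novelty_sum = None
    if run_novelty and sequences.references:
        queries = {
            pid: sequences.proteins[pid]
            for pid, c in classifications.items()
            if c.is_cazyme
        }
        classes = {
            pid: (classifications[pid].catalytic_families[:1] or [""])[0]
            for pid in queries
        }
        novelty_records = novelty.score_queries(queries, sequences.references, classes)
        novelty_sum = novelty.novelty_summary(novelty_records, threshold=novelty_threshold)
        novelty.write_novelty_tsv(novelty_records, out / "novelty.tsv")
        _json_dump(novelty_sum, out / "novelty_summary.json")

    integration = summarize.integrate_metaproteome(
        spectra, classifications, architectures, fmap
    )
    _json_dump(integration, out / "integration.json")
    matrix = summarize.genome_matrix(architectures, genome_of)
    matrix.to_csv(out / "genome_matrix.tsv", sep="\t")
    frac = summarize.binned_fraction(classifications, genome_of)
    _json_dump(
        {
            "binned_cazyme_fraction": frac,
            "n_puls": len(calls),
            "n_puls_with_cazyme": sum(1 for c in calls if not c.no_cazyme),
            "cellulosome_capable_genomes": sorted(
                g for g, r in cell_reports.items() if r.is_cellulosome_capable
            ),
        },
        out / "overview.json",
    )

    return {
        "bins": bins,
        "manifest": manifest,
        "filtered_hits": filtered,
        "architectures": architectures,
        "classifications": classifications,
        "census": cen,
        "duf_records": duf_records,
        "genes": genes,
        "sus_pairs": pairs,
        "pul_calls": calls,
        "pul_summaries": pul_summaries,
        "cellulosome_reports": cell_reports,
        "novelty_records": novelty_records,
        "novelty_summary": novelty_sum,
        "integration": integration,
        "genome_matrix": matrix,
        "binned_fraction": frac,
        "genome_of": genome_of,
    }
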