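"""End-to-end orchestration: simulate -> catalog -> diversity -> codon usage
-> selection, with a deterministic run manifest.

Every stage writes plain-text outputs under the run directory and appends
itself to ``manifest.json``; re-running with the same seed and configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .catalog import (
    FamilySummary,
    catalog_genome,
    summaries_to_tsv,
    summarize_family,
)
from .codon import (
    CodingSequence,
    effective_number_of_codons,
    fop,
    gc3s,
    mask_repetitive_regions,
    noncoding_gc,
)
from .divergence import cohort_builder, intra_element_ltr_identity, nucleotide_diversity
from .errors import ConfigError, UndefinedStatisticError
from .seqio import FeatureRecord, write_gff3
from .selection import FamilyStatsRow, domain_accuracy_test, selection_report
from .simulate import (
    SYNTHETIC_OPTIMAL_CODONS,
    TEFamily,
    simulate_genome,
    write_simulation,
)

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "simulate": {
        "background_len": 120_000,
        "background_gc": 0.50,
        "age_range": [0.001, 0.02],
        "indel_rate": 0.0,
        "expression_dispersion": 0.5,
    },
    "catalog": {"min_identity": 0.8, "seed_k": 12},
    "diversity": {"deletion_mode": "complete"},
    "codon": {"optimal_codons": sorted(SYNTHETIC_OPTIMAL_CODONS)},
    "selection": {"expression_transform": "log10"},
}


def _merged_config(config: Mapping | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if key in cfg and isinstance(value, Mapping):
            cfg[key].update(value)
        else:
            cfg[key] = value
    if "seed" not in cfg:
        raise ConfigError("config is missing required field 'seed'")
    if not cfg["codon"].get("optimal_codons"):
        raise ConfigError("config field codon.optimal_codons is missing or empty")
    return cfg


def family_coding_sequence(family: TEFamily, mask_repeats: bool = True) -> CodingSequence:
    """The family's ORF as a labelled CodingSequence.

    Exons are concatenated; each codon is labelled domain / non_domain
    according to the family's functional-domain annotation, codons
    straddling a region boundary or overlapping a repetitive-region mask
    are labelled masked and excluded from downstream statistics.
    """
    coding = "".join(family.consensus[s:e] for s, e, _ in family.orf_intervals)
    # consensus coordinate of every coding nucleotide
    coords = [i for s, e, _ in family.orf_intervals for i in range(s, e)]
    labels = []
    for idx in range(len(coding) // 3):
        span = coords[idx * 3 : idx * 3 + 3]
        flags = {
            any(s <= p < e for s, e in family.domain_intervals) for p in span
        }
        if len(flags) > 1:
            labels.append("masked")  # codon straddles a domain boundary
        else:
            labels.append("domain" if flags.pop() else "non_domain")
    if mask_repeats:
        _, masked_codons = mask_repetitive_regions(coding)
        for idx in masked_codons:
            if idx < len(labels):
                labels[idx] = "masked"
    return CodingSequence.from_nucleotides(
        id=family.name, seq=coding, family=family.name, region_labels=labels
    )


def family_noncoding_intervals(family: TEFamily) -> list[tuple[int, int]]:
    """Non-coding compartments on the consensus: terminal repeats, UTRs and
    introns (everything outside exons)."""
    coding = sorted((s, e) for s, e, _ in family.orf_intervals)
    out = []
    prev = 0
    for s, e in coding:
        if s > prev:
            out.append((prev, s))
        prev = e
    if prev < len(family.consensus):
        out.append((prev, len(family.consensus)))
    return out


def family_codon_stats(
    family: TEFamily, optimal_set: Sequence[str]
) -> dict[str, float | None]:
    cds = family_coding_sequence(family)
    kept = CodingSequence(
        id=cds.id,
        codons=[c for c, lab in zip(cds.codons, cds.region_labels) if lab != "masked"],
        family=cds.family,
    )
    return {
        "nc": effective_number_of_codons(kept),
        "fop": fop(kept, optimal_set),
        "gc3s": gc3s(kept),
        "noncoding_gc": noncoding_gc(
            family.consensus, family_noncoding_intervals(family)
        ),
    }


def make_table_rows(
    summaries: Mapping[str, FamilySummary],
    diversity: Mapping[str, Mapping[str, float]],
    codon_stats: Mapping[str, Mapping[str, float | None]],
    expression: Mapping[str, int],
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Join per-family outputs into one statistics table.

    A family present in only some inputs yields a row with explicit
    missing cells and a warning, never a silent drop.
    """
    all_families = sorted(
        set(summaries) | set(diversity) | set(codon_stats) | set(expression)
    )
    rows = []
    for fam in all_families:
        missing = [
            name
            for name, source in (
                ("catalog", summaries),
                ("codon", codon_stats),
                ("expression", expression),
            )
            if fam not in source
        ]
        if missing:
            log.warning("family %s missing from: %s", fam, ", ".join(missing))
        s = summaries.get(fam)
        cs = codon_stats.get(fam, {})
        div = diversity.get(fam, {})
        rows.append(
            {
                "family": fam,
                "group": (groups or {}).get(fam, "unknown"),
                "nc": cs.get("nc"),
                "fop": cs.get("fop"),
                "gc3s": cs.get("gc3s"),
                "noncoding_gc": cs.get("noncoding_gc"),
                "copy_number": s.copy_number_total if s else None,
                "n_fle": s.n_fle if s else None,
                "n_solo": s.n_solo if s else None,
                "n_truncated": s.n_truncated if s else None,
                "expression_reads": expression.get(fam),
                "pi_all": div.get("All"),
                "pi_fle": div.get("FLE"),
                "pi_solo": div.get("Solo"),
            }
        )
    return pd.DataFrame(rows)


_GROUP_BY_CLASS = {
    "LTR_copia": "copia",
    "LTR_chromovirus": "chromovirus",
    "LTR_gypsy_nonchromo": "gypsy_nonchromo",
    "DNA_transposon": "transposon",
    "helitron": "transposon",
}


def run_pipeline(config: Mapping | None, out_dir: str | Path) -> dict:
    """Run every stage on a synthetic genome; returns the manifest."""
    cfg = _merged_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "tool_version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16],
        "stages": [],
    }

    # -- simulate ----------------------------------------------------------
    sim_cfg = dict(cfg["simulate"])
    sim_cfg["age_range"] = tuple(sim_cfg.get("age_range", (0.001, 0.02)))
    contigs, families, truth, counts = simulate_genome(seed=seed, **sim_cfg)
    write_simulation(out / "sim", contigs, families, truth, counts)
    manifest["stages"].append(
        {"stage": "simulate", "n_insertions": len(truth.insertions),
         "outputs": ["sim.genome.fasta", "sim.truth.gff3", "sim.truth.json",
                     "sim.expression.tsv", "sim.consensus.fasta"]}
    )

    # -- catalog -----------------------------------------------------------
    records, partials = catalog_genome(contigs, families, **cfg["catalog"])
    feats = []
    kinds = {"FLE": "te_full_length", "solo_LTR": "te_solo_ltr", "truncated": "te_truncated"}
    for rec in records:
        attrs = {"Family": rec.family, "Kind": rec.kind}
        if rec.tsd_seq:
            attrs["TSD"] = rec.tsd_seq
        for i, (s, e) in enumerate(rec.ltr_intervals[:2]):
            attrs[f"LTR{'53'[i]}"] = f"{s + 1}-{e}"
        feats.append(
            FeatureRecord(contig=rec.contig, start=rec.start + 1, end=rec.end,
                          strand=rec.strand, type=kinds[rec.kind], attributes=attrs)
        )
    write_gff3(feats, out / "catalog.gff3", {k: len(v) for k, v in contigs.items()})

    summaries = {}
    identities: dict[str, list[float]] = {}
    for name, fam in families.items():
        fam_records = [r for r in records if r.family == name]
        idents = []
        for rec in fam_records:
            if rec.kind == "FLE" and fam.is_ltr:
                idents.append(intra_element_ltr_identity(rec, contigs))
        identities[name] = idents
        seqs = [contigs[r.contig][r.start : r.end] for r in fam_records]
        summaries[name] = summarize_family(
            name, fam_records, counts.get(name), idents, seqs
        )
    summaries_to_tsv(summaries.values(), out / "summary.tsv")
    manifest["stages"].append(
        {"stage": "catalog", "n_records": len(records), "n_partial": len(partials),
         "outputs": ["catalog.gff3", "summary.tsv"]}
    )

    # -- diversity ---------------------------------------------------------
    deletion_mode = cfg["diversity"]["deletion_mode"]
    diversity: dict[str, dict[str, float]] = {}
    with open(out / "pi.tsv", "w") as fh:
        fh.write("family\tcohort\tpi\tn_sequences\tn_sites\n")
        for name, fam in families.items():
            if not fam.is_ltr:
                continue
            blocks = cohort_builder(records, contigs, family=name)
            diversity[name] = {}
            for cohort, block in blocks.items():
                try:
                    res = nucleotide_diversity(block, deletion_mode)
                except UndefinedStatisticError:
                    continue
                diversity[name][cohort] = res.pi
                fh.write(
                    f"{name}\t{cohort}\t{res.pi:.6f}\t{res.n_sequences}\t"
                    f"{res.n_sites_analysed}\n"
                )
    manifest["stages"].append(
        {"stage": "diversity",
         "n_rows": sum(len(v) for v in diversity.values()),
         "outputs": ["pi.tsv"]}
    )

    # -- codon usage -------------------------------------------------------
    optimal = cfg["codon"]["optimal_codons"]
    codon_stats = {name: family_codon_stats(fam, optimal) for name, fam in families.items()}
    with open(out / "table3.tsv", "w") as fh:
        fh.write("family\tnc\tfop\tgc3s\tnoncoding_gc\n")
        for name, st in codon_stats.items():
            ngc = f"{st['noncoding_gc']:.3f}" if st["noncoding_gc"] is not None else "-"
            fh.write(f"{name}\t{st['nc']:.2f}\t{st['fop']:.3f}\t{st['gc3s']:.3f}\t{ngc}\n")
    manifest["stages"].append(
        {"stage": "codonuse", "n_rows": len(codon_stats), "outputs": ["table3.tsv"]}
    )

    # -- selection ---------------------------------------------------------
    groups = {name: _GROUP_BY_CLASS[fam.te_class] for name, fam in families.items()}
    table = make_table_rows(summaries, diversity, codon_stats, counts, groups)
    table.to_csv(out / "family_stats.tsv", sep="\t", index=False)
    report = selection_report(table, cfg["selection"]["expression_transform"])
    report["domain_accuracy"] = {}
    for name, fam in families.items():
        try:
            res = domain_accuracy_test(family_coding_sequence(fam), optimal)
        except UndefinedStatisticError as exc:
            report["domain_accuracy"][name] = {"note": str(exc)}
            continue
        report["domain_accuracy"][name] = {
            "fop_domain": res.fop_domain,
            "fop_nondomain": res.fop_nondomain,
            "p_value": res.p_value,
            "direction": res.direction,
            "accuracy_consistent": res.accuracy_consistent,
        }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    manifest["stages"].append(
        {"stage": "selection",
         "n_regressions": report["n_regressions_run"],
         "outputs": ["family_stats.tsv", "report.json"]}
    )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
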