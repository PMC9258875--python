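"""End-to-end orchestration: files in, ranked candidates and summaries out.

Ties the stages together for one or more families: read the multi-sample
VCF and pedigrees, restrict to the intersection of the capture-kit targets,
apply frequency/impact filters with low-coverage rescue, evaluate the
configured inheritance models, rank candidates by gene evidence, detect
co-segregating distinct-gene pairs, and summarize.

A family's outcome is classified from its ranked candidates: ``causative``
if a strong-evidence candidate survives, ``candidate_only`` if any
candidate survives, ``none`` otherwise.  (In the source study "causative"
additionally required functional validation or an established
gene-phenotype link; the class here is the pipeline's mechanical proxy.)
"""

from __future__ import annotations

import hashlib
import io
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .annotation import VariantAnnotation, load_annotation_table
from .evaluation import (
    CandidateReport,
    GeneEvidence,
    cosegregating_pairs,
    diagnostic_yield,
    load_gene_evidence,
    rank_candidates,
    write_candidates,
)
from .filters import FilterConfig, run_filters
from .intervals import IntervalSet, intersect_sets, read_bed
from .pedigree import Pedigree, parse_pedigrees
from .segregation import (
    AUTOSOMAL_DOMINANT,
    MODELS,
    confirmation_manifest,
    family_candidates,
)
from .variants import read_callset

__all__ = ["RunConfig", "ConfigError", "load_run_config", "run_pipeline", "FamilyResult"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    vcf: str | None = None
    ped: str | None = None
    beds: list[str] = field(default_factory=list)
    annotation: str | None = None
    knowledge: str | None = None
    out_dir: str = "results"
    seed: int = 0
    filters: FilterConfig = field(default_factory=FilterConfig)
    # family id -> list of models; "*" is the default entry
    models: dict[str, list[str]] = field(default_factory=lambda: {"*": [AUTOSOMAL_DOMINANT]})
    allow_unaffected_carriers: bool = False
    pad: int = 0

    def models_for(self, family_id: str) -> list[str]:
        return self.models.get(family_id, self.models.get("*", [AUTOSOMAL_DOMINANT]))


def load_run_config(path_or_text: str) -> RunConfig:
    """Load a YAML run configuration (see README for the schema)."""
    if os.path.exists(path_or_text):
        with open(path_or_text) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(io.StringIO(path_or_text))
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("run config must be a YAML mapping")
    filt = doc.pop("filters", {}) or {}
    try:
        fc = FilterConfig(
            maf_max=float(filt.get("maf_max", 0.01)),
            cadd_min=float(filt.get("cadd_min", 20.0)),
            rescue_depth_max=int(filt.get("rescue_depth_max", 10)),
            genes_of_interest=frozenset(filt.get("genes_of_interest", []) or []),
            unscored_policy=filt.get("unscored_policy", "retain_flagged"),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad filters block: {exc}") from exc
    models = doc.pop("models", None) or {"*": [AUTOSOMAL_DOMINANT]}
    if isinstance(models, list):
        models = {"*": models}
    for fam, mlist in models.items():
        unknown = set(mlist) - set(MODELS)
        if unknown:
            raise ConfigError(f"unknown models for family {fam!r}: {sorted(unknown)}")
    known = {"vcf", "ped", "beds", "annotation", "knowledge", "out_dir", "seed",
             "allow_unaffected_carriers", "pad"}
    bad = set(doc) - known
    if bad:
        raise ConfigError(f"unknown config keys: {sorted(bad)}")
    return RunConfig(
        vcf=doc.get("vcf"),
        ped=doc.get("ped"),
        beds=list(doc.get("beds", []) or []),
        annotation=doc.get("annotation"),
        knowledge=doc.get("knowledge"),
        out_dir=doc.get("out_dir", "results"),
        seed=int(doc.get("seed", 0)),
        filters=fc,
        models=models,
        allow_unaffected_carriers=bool(doc.get("allow_unaffected_carriers", False)),
        pad=int(doc.get("pad", 0)),
    )


@dataclass
class FamilyResult:
    family_id: str
    candidates: list[CandidateReport]
    pairs: list
    funnel_tsv: str
    manifest: list[tuple[str, str]]
    outcome: str


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {
            "maf_max": config.filters.maf_max,
            "cadd_min": config.filters.cadd_min,
            "rescue_depth_max": config.filters.rescue_depth_max,
            "genes_of_interest": sorted(config.filters.genes_of_interest),
            "unscored_policy": config.filters.unscored_policy,
            "models": {k: sorted(v) for k, v in config.models.items()},
            "allow_unaffected_carriers": config.allow_unaffected_carriers,
            "pad": config.pad,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(
    config: RunConfig,
    pedigrees: Mapping[str, Pedigree] | None = None,
    records: Sequence | None = None,
    annotations: Mapping[tuple, VariantAnnotation] | None = None,
    knowledge: Mapping[str, GeneEvidence] | None = None,
    targets: IntervalSet | None = None,
    write: bool = True,
) -> dict:
    """Run the full analysis; in-memory inputs override configured paths.

    Returns the summary report dict (also written as JSON alongside the
    per-family TSVs when ``write`` is set).
    """
    if pedigrees is None:
        if not config.ped:
            raise ConfigError("no pedigree input")
        with open(config.ped) as fh:
            pedigrees = parse_pedigrees(fh)
    if records is None:
        if not config.vcf:
            raise ConfigError("no VCF input")
        records = read_callset(config.vcf)
    if annotations is None:
        if not config.annotation:
            raise ConfigError("no annotation input")
        annotations = load_annotation_table(config.annotation)
    if knowledge is None:
        knowledge = load_gene_evidence(config.knowledge) if config.knowledge else {}
    if targets is None and config.beds:
        sets = []
        for bed in config.beds:
            with open(bed) as fh:
                sets.append(read_bed(fh))
        targets = intersect_sets(sets)
        if config.pad:
            targets = targets.pad(config.pad)

    fc = config.filters
    if targets is not None:
        fc = FilterConfig(
            maf_max=fc.maf_max,
            cadd_min=fc.cadd_min,
            target_regions=targets,
            rescue_depth_max=fc.rescue_depth_max,
            genes_of_interest=fc.genes_of_interest,
            unscored_policy=fc.unscored_policy,
        )

    triples = []
    for site, calls in records:
        ann = annotations.get(site.key)
        if ann is None:
            continue
        triples.append((site, calls, ann))

    chash = _config_hash(config)
    families: dict[str, FamilyResult] = {}
    outcomes: dict[str, str] = {}
    for fam_id in sorted(pedigrees):
        ped = pedigrees[fam_id]
        sample_ids = set(ped.members)
        fam_triples = [
            (s, {k: v for k, v in c.items() if k in sample_ids}, a)
            for s, c, a in triples
        ]
        fam_triples = [t for t in fam_triples if t[1]]
        survivors, funnel = run_filters(fam_triples, fc, pedigree=ped)
        results = family_candidates(
            survivors,
            ped,
            models=config.models_for(fam_id),
            allow_unaffected_carriers=config.allow_unaffected_carriers,
        )
        cands = rank_candidates(results, knowledge, annotations, family_id=fam_id)
        pairs = cosegregating_pairs(cands)
        manifest = confirmation_manifest(results, ped)
        if any(c.evidence_class == "strong" for c in cands):
            outcome = "causative"
        elif cands:
            outcome = "candidate_only"
        else:
            outcome = "none"
        outcomes[fam_id] = outcome
        families[fam_id] = FamilyResult(
            family_id=fam_id,
            candidates=cands,
            pairs=pairs,
            funnel_tsv=funnel.to_tsv(),
            manifest=manifest,
            outcome=outcome,
        )

    num, den, pct = diagnostic_yield(outcomes) if outcomes else (0, 0, 0)
    report = {
        "config_hash": chash,
        "n_families": len(families),
        "diagnostic_yield": {"causative": num, "families": den, "percent": pct},
        "families": {
            fid: {
                "outcome": fr.outcome,
                "n_candidates": len(fr.candidates),
                "candidates": [
                    {
                        "rank": c.rank,
                        "variant": c.variant_label,
                        "gene": c.gene,
                        "max_maf": c.max_maf,
                        "cadd_phred": c.cadd_phred,
                        "tier": c.tier,
                        "evidence_class": c.evidence_class,
                        "models_passed": list(c.models_passed),
                        "demotion_flags": list(c.demotion_flags),
                    }
                    for c in fr.candidates
                ],
                "pairs": [
                    {
                        "genes": [a.gene, b.gene],
                        "variants": [a.variant_label, b.variant_label],
                        "cooccurrence_probability": p,
                    }
                    for (a, b), p in fr.pairs
                ],
            }
            for fid, fr in families.items()
        },
    }
    if write:
        os.makedirs(config.out_dir, exist_ok=True)
        for fid, fr in families.items():
            base = os.path.join(config.out_dir, f"family_{fid}")
            with open(base + "_candidates.tsv", "w") as fh:
                fh.write(f"# config={chash}\n")
                write_candidates(fr.candidates, fh)
            with open(base + "_funnel.tsv", "w") as fh:
                fh.write(f"# config={chash}\n")
                fh.write(fr.funnel_tsv)
            with open(base + "_confirmation.tsv", "w") as fh:
                fh.write(f"# config={chash}\nindividual_id\tvariant\n")
                for iid, var in fr.manifest:
                    fh.write(f"{iid}\t{var}\n")
        with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
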