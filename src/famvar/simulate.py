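"""Pedigree gene-dropping simulator for family exome callsets.

Generates Mendelian-consistent multi-sample callsets over a pedigree, with
a background of rare variants (log-uniform allele frequencies, a CADD
mixture with configurable mass in each impact tier) plus injected causal
variants under dominant (with reduced penetrance), recessive, compound-
heterozygous and digenic models.  Founder genotypes are drawn under
Hardy-Weinberg at each site's allele frequency; each non-founder receives
one allele from each recorded parent uniformly at random per site (sites
are in linkage equilibrium).  Parents absent from the pedigree contribute
founder-like draws.

Per-call total depth is drawn from a negative binomial; allele depths
split binomially (0.5 for heterozygotes).  Designated genes can be forced
to low coverage (depth <= 10) to exercise the rescue path.

Two affection modes:

* ``template`` (default) — affection statuses come from the input pedigree
  (the ascertained-family design); causal genotypes are constrained to
  co-segregate with the declared model in the affected members.
* ``genotype`` — a founder carrier is seeded, alleles drop naturally, and
  affection is assigned as risk-genotype x penetrance.

Identical seeds produce byte-identical output files.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .annotation import PopulationFrequencies, VariantAnnotation
from .intervals import GenomicInterval, IntervalSet, canonicalize, write_bed
from .pedigree import Individual, Pedigree, parse_pedigrees, write_pedigrees
from .segregation import (
    AUTOSOMAL_DOMINANT,
    AUTOSOMAL_RECESSIVE_HOM,
    COMPOUND_HETEROZYGOUS,
)
from .variants import GenotypeCall, VariantSite, read_callset, write_vcf

__all__ = [
    "CausalSpec",
    "SimulationConfig",
    "TruthRecord",
    "SimulatedCohort",
    "SimulationError",
    "simulate_cohort",
    "inject_digenic",
    "mendelian_check",
    "two_generation_pedigree",
    "sib_pair_pedigree",
]

DIGENIC_PAIR = "digenic_pair"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CausalSpec:
    """One injected causal signal (one site, or two for pair models)."""

    model: str  # autosomal_dominant | autosomal_recessive_hom | compound_heterozygous | digenic_pair
    gene_symbol: str
    maf: float = 0.001
    cadd: float = 35.0
    penetrance: float = 1.0
    gene_symbol_b: str | None = None  # second gene, digenic_pair only

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise SimulationError("penetrance must lie in [0,1]")
        if not 0.0 <= self.maf <= 1.0:
            raise SimulationError("maf must lie in [0,1]")
        if self.model == DIGENIC_PAIR and not self.gene_symbol_b:
            raise SimulationError("digenic_pair requires gene_symbol_b")

    @property
    def n_sites(self) -> int:
        return 2 if self.model in (COMPOUND_HETEROZYGOUS, DIGENIC_PAIR) else 1


@dataclass
class SimulationConfig:
    pedigree: Pedigree
    n_background_variants: int = 1000
    background_maf_range: tuple[float, float] = (1e-5, 0.05)  # log-uniform
    # probability mass on CADD < 20 / [20,30) / >= 30
    cadd_tier_mass: tuple[float, float, float] = (0.85, 0.10, 0.05)
    causal_specs: list[CausalSpec] = field(default_factory=list)
    missing_genotype_rate: float = 0.0
    depth_mean: float = 70.0
    depth_dispersion: float = 8.0  # negative-binomial size parameter
    low_coverage_genes: frozenset[str] = frozenset()
    affection_mode: str = "template"  # or "genotype"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_variants < 0:
            raise SimulationError("n_background_variants must be >= 0")
        if not 0.0 <= self.missing_genotype_rate <= 1.0:
            raise SimulationError("missing_genotype_rate must lie in [0,1]")
        if abs(sum(self.cadd_tier_mass) - 1.0) > 1e-9:
            raise SimulationError("cadd_tier_mass must sum to 1")
        if self.affection_mode not in ("template", "genotype"):
            raise SimulationError(f"unknown affection_mode {self.affection_mode!r}")
        self.low_coverage_genes = frozenset(self.low_coverage_genes)


@dataclass
class TruthRecord:
    """Ground truth for parameter-recovery tests."""

    causal_sites: list[dict] = field(default_factory=list)  # {key, gene, model, pair_id}
    expected_pass_per_model: dict[str, list[str]] = field(default_factory=dict)
    expected_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "causal_sites": self.causal_sites,
                "expected_pass_per_model": self.expected_pass_per_model,
                "expected_pairs": self.expected_pairs,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class SimulatedCohort:
    pedigree: Pedigree
    records: list[tuple[VariantSite, dict[str, GenotypeCall]]]
    annotations: dict[tuple[str, int, str, str], VariantAnnotation]
    targets: IntervalSet
    truth: TruthRecord
    config: SimulationConfig

    @property
    def samples(self) -> list[str]:
        return [m.individual_id for m in self.pedigree if m.sequenced]

    def vcf_text(self) -> str:
        buf = io.StringIO()
        write_vcf(self.records, self.samples, buf)
        return buf.getvalue()

    def annotation_tsv(self) -> str:
        lines = [
            "chrom\tpos\tref\talt\tgene\ttranscript\thgvs_c\thgvs_p\tconsequence"
            "\taf_exomes_all\tnhomalt\tcadd_phred"
        ]
        for (chrom, pos, ref, alt), ann in self.annotations.items():
            af = ""
            for coh in ann.frequencies:
                for _, f in coh.frequencies:
                    af = repr(f)
            cadd = "" if ann.cadd_phred is None else repr(ann.cadd_phred)
            lines.append(
                f"{chrom}\t{pos}\t{ref}\t{alt}\t{ann.gene_symbol}\t{ann.transcript}"
                f"\t{ann.hgvs_c or ''}\t{ann.hgvs_p or ''}\t{ann.consequence}"
                f"\t{af}\t\t{cadd}"
            )
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        """Emit VCF / PED / BED / annotation TSV / truth JSON; returns paths."""
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "vcf": os.path.join(outdir, "cohort.vcf"),
            "ped": os.path.join(outdir, "cohort.ped"),
            "bed": os.path.join(outdir, "targets.bed"),
            "annotation": os.path.join(outdir, "annotation.tsv"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        with open(paths["vcf"], "w") as fh:
            fh.write(self.vcf_text())
        with open(paths["ped"], "w") as fh:
            fh.write(write_pedigrees([self.pedigree]))
        with open(paths["bed"], "w") as fh:
            write_bed(self.targets, fh)
        with open(paths["annotation"], "w") as fh:
            fh.write(self.annotation_tsv())
        with open(paths["truth"], "w") as fh:
            fh.write(self.truth.to_json())
        return paths


# ---------------------------------------------------------------------------
# built-in pedigree shapes (2-6 members, mirroring the study's family forms)

def two_generation_pedigree(
    n_affected_children: int = 2,
    n_unaffected_children: int = 0,
    parents_affected: tuple[bool, bool] = (True, False),
    parents_sequenced: bool = True,
    family_id: str = "SIM",
) -> Pedigree:
    """Couple plus children; used for dominant/recessive/compound-het tests."""
    ped = Pedigree(family_id=family_id)
    pa, ma = parents_affected
    ped.add(Individual("F1", family_id, sex="male",
                       affection="affected" if pa else "unaffected",
                       sequenced=parents_sequenced))
    ped.add(Individual("M1", family_id, sex="female",
                       affection="affected" if ma else "unaffected",
                       sequenced=parents_sequenced))
    k = 0
    for _ in range(n_affected_children):
        k += 1
        ped.add(Individual(f"C{k}", family_id, father_id="F1", mother_id="M1",
                           affection="affected"))
    for _ in range(n_unaffected_children):
        k += 1
        ped.add(Individual(f"C{k}", family_id, father_id="F1", mother_id="M1",
                           affection="unaffected"))
    ped.validate()
    return ped


def sib_pair_pedigree(n_affected: int = 2, family_id: str = "SIM") -> Pedigree:
    """Affected siblings with unrecorded parents (the study's smallest shape)."""
    ped = Pedigree(family_id=family_id)
    for i in range(1, n_affected + 1):
        ped.add(Individual(f"S{i}", family_id, affection="affected"))
    ped.validate()
    return ped


# ---------------------------------------------------------------------------

_CHROMS = [str(c) for c in range(1, 23)]


def _topological_members(ped: Pedigree) -> list[Individual]:
    order: list[Individual] = []
    placed: set[str] = set()
    pending = sorted(ped.members.values(), key=lambda m: m.individual_id)
    while pending:
        progressed = False
        rest = []
        for m in pending:
            deps = [p for p in (m.father_id, m.mother_id) if p and p in ped.members]
            if all(d in placed for d in deps):
                order.append(m)
                placed.add(m.individual_id)
                progressed = True
            else:
                rest.append(m)
        if not progressed:
            raise SimulationError("pedigree is not acyclic")
        pending = rest
    return order


def _drop_alleles(
    ped: Pedigree, mafs: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Gene dropping: per member a (2, n_sites) haplotype array (0/1).

    Row 0 is the paternally transmitted haplotype, row 1 maternal; an
    unrecorded parent contributes a Hardy-Weinberg founder draw.
    """
    n = len(mafs)
    haps: dict[str, np.ndarray] = {}
    for m in _topological_members(ped):
        h = np.empty((2, n), dtype=np.uint8)
        for row, pid in ((0, m.father_id), (1, m.mother_id)):
            if pid and pid in ped.members:
                parent = haps[pid]
                pick = rng.integers(0, 2, size=n)
                h[row] = parent[pick, np.arange(n)]
            else:
                h[row] = rng.random(n) < mafs
        haps[m.individual_id] = h
    return haps


def _carrier_closure(ped: Pedigree) -> dict[str, str | None]:
    """Affected members plus the parents needed to connect them.

    Returns carrier -> transmitting recorded parent id (or None for a
    founder-origin copy).
    """
    carriers: dict[str, str | None] = {}
    for m in _topological_members(ped):
        if m.affection == "affected":
            carriers[m.individual_id] = None
    changed = True
    while changed:
        changed = False
        for iid in list(carriers):
            m = ped.members[iid]
            recorded = [p for p in (m.father_id, m.mother_id) if p and p in ped.members]
            if not recorded:
                continue
            in_set = [p for p in recorded if p in carriers]
            if in_set:
                if carriers[iid] is None:
                    carriers[iid] = in_set[0]
                continue
            # pull in a parent: prefer affected, then unknown, then unaffected
            recorded.sort(
                key=lambda p: {"affected": 0, "unknown": 1, "unaffected": 2}[
                    ped.members[p].affection
                ]
            )
            carriers[recorded[0]] = None
            carriers[iid] = recorded[0]
            changed = True
    return carriers


def _force_dominant(
    ped: Pedigree, haps: Mapping[str, np.ndarray], col: int, lineage: str | None = None
) -> None:
    """Overwrite column ``col`` so the alt co-segregates dominantly.

    ``lineage`` ('father'|'mother') pins which parental slot carries the alt
    in members with no recorded carrier parent (used for trans phasing).
    """
    carriers = _carrier_closure(ped)
    for m in _topological_members(ped):
        h = haps[m.individual_id]
        h[:, col] = 0
        if m.individual_id in carriers:
            origin = carriers[m.individual_id]
            if origin is None:
                row = 1 if lineage == "mother" else 0
            else:
                row = 0 if origin == m.father_id else 1
            h[row, col] = 1


def _force_recessive(ped: Pedigree, haps: Mapping[str, np.ndarray], col: int) -> None:
    affected_ids = {m.individual_id for m in ped if m.affection == "affected"}
    for m in _topological_members(ped):
        h = haps[m.individual_id]
        if m.individual_id in affected_ids:
            h[:, col] = 1
        else:
            h[:, col] = 0
    # recorded parents of affected members must be carriers
    for m in ped:
        if m.individual_id not in affected_ids:
            continue
        for row, pid in ((0, m.father_id), (1, m.mother_id)):
            if pid and pid in ped.members and pid not in affected_ids:
                ph = haps[pid]
                if ph[:, col].sum() == 0:
                    ph[row, col] = 1
    # ensure non-affected children of carrier couples are not hom-alt (they are 0 or het)


def _seed_founder_carrier(
    ped: Pedigree, haps: Mapping[str, np.ndarray], col: int, hom: bool
) -> None:
    founder = sorted(ped.founders(), key=lambda m: m.individual_id)[0]
    h = haps[founder.individual_id]
    h[:, col] = 1 if hom else 0
    if not hom:
        h[0, col] = 1


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run the generator; see the module docstring for the model."""
    rng = np.random.default_rng(config.seed)
    ped = Pedigree(
        family_id=config.pedigree.family_id,
        members=dict(config.pedigree.members),
    )

    # --- site table ------------------------------------------------------
    n_bg = config.n_background_variants
    lo, hi = config.background_maf_range
    bg_mafs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_bg)) if n_bg else np.empty(0)
    m0, m1, m2 = config.cadd_tier_mass
    tier_draw = rng.choice(3, size=n_bg, p=[m0, m1, m2]) if n_bg else np.empty(0, int)
    bg_cadd = np.where(
        tier_draw == 0,
        rng.uniform(0.0, 20.0, size=n_bg),
        np.where(
            tier_draw == 1,
            rng.uniform(20.0, 30.0, size=n_bg),
            rng.uniform(30.0, 50.0, size=n_bg),
        ),
    ) if n_bg else np.empty(0)

    sites: list[VariantSite] = []
    genes: list[str] = []
    mafs: list[float] = []
    cadds: list[float | None] = []
    pos_counter: dict[str, int] = {c: 1000 for c in _CHROMS}
    for i in range(n_bg):
        chrom = _CHROMS[i % len(_CHROMS)]
        pos_counter[chrom] += 150
        sites.append(VariantSite(chrom=chrom, pos=pos_counter[chrom], ref="A", alt="G"))
        genes.append(f"BG{i:05d}")
        mafs.append(float(bg_mafs[i]))
        cadds.append(float(bg_cadd[i]))

    truth = TruthRecord()
    causal_cols: list[tuple[CausalSpec, list[int]]] = []
    for k, spec in enumerate(config.causal_specs):
        cols = []
        for j in range(spec.n_sites):
            # comp-het sites share the gene, hence the chromosome
            off = j if spec.model == DIGENIC_PAIR else 0
            chrom = _CHROMS[(n_bg + k * 2 + off) % len(_CHROMS)]
            pos_counter[chrom] += 150
            gene = spec.gene_symbol if (j == 0 or spec.model == COMPOUND_HETEROZYGOUS) else spec.gene_symbol_b
            sites.append(VariantSite(chrom=chrom, pos=pos_counter[chrom], ref="C", alt="T"))
            genes.append(gene)
            mafs.append(spec.maf)
            cadds.append(spec.cadd)
            cols.append(len(sites) - 1)
        causal_cols.append((spec, cols))

    maf_arr = np.asarray(mafs, dtype=float)
    n_sites = len(sites)

    # --- gene dropping ---------------------------------------------------
    haps = _drop_alleles(ped, maf_arr, rng)

    for spec, cols in causal_cols:
        if config.affection_mode == "genotype":
            hom = spec.model == AUTOSOMAL_RECESSIVE_HOM
            for col in cols:
                _seed_founder_carrier(ped, haps, col, hom=hom)
            # redrop below the seeded founder would be ideal; transmission is
            # re-simulated by dropping again conditioned on founder haplotypes
            haps = _redrop_from_founders(ped, haps, rng, n_sites)
        else:
            if spec.model == AUTOSOMAL_DOMINANT:
                _force_dominant(ped, haps, cols[0])
            elif spec.model == AUTOSOMAL_RECESSIVE_HOM:
                _force_recessive(ped, haps, cols[0])
            elif spec.model == COMPOUND_HETEROZYGOUS:
                if not _has_couple_or_sibs(ped):
                    raise SimulationError(
                        "compound het unsatisfiable: pedigree has no couple/sib structure"
                    )
                _force_pair(ped, haps, cols[0], cols[1])
            elif spec.model == DIGENIC_PAIR:
                _force_pair(ped, haps, cols[0], cols[1])
            else:
                raise SimulationError(f"unknown causal model {spec.model!r}")

        site_keys = [list(sites[c].key) for c in cols]
        truth.causal_sites += [
            {"key": key, "gene": genes[c], "model": spec.model, "pair_id": k}
            for k, (key, c) in enumerate(zip(site_keys, cols))
        ]
        labels = [f"{s[0]}:{s[1]}:{s[2]}>{s[3]}" for s in site_keys]
        model_key = AUTOSOMAL_DOMINANT if spec.model == DIGENIC_PAIR else spec.model
        truth.expected_pass_per_model.setdefault(model_key, []).extend(labels)
        if spec.n_sites == 2:
            truth.expected_pairs.append((labels[0], labels[1]))

    # --- affection assignment (genotype mode) ----------------------------
    if config.affection_mode == "genotype":
        for spec, cols in causal_cols:
            for m in list(ped.members.values()):
                g = haps[m.individual_id]
                if spec.model == AUTOSOMAL_RECESSIVE_HOM:
                    at_risk = g[:, cols[0]].sum() == 2
                elif spec.n_sites == 2:
                    at_risk = g[:, cols[0]].sum() >= 1 and g[:, cols[1]].sum() >= 1
                else:
                    at_risk = g[:, cols[0]].sum() >= 1
                if at_risk and rng.random() < spec.penetrance:
                    ped.members[m.individual_id] = replace(m, affection="affected")
                else:
                    ped.members[m.individual_id] = replace(m, affection="unaffected")

    # --- depths, missingness, call objects --------------------------------
    samples = [m.individual_id for m in ped if m.sequenced]
    p_nb = config.depth_dispersion / (config.depth_dispersion + config.depth_mean)
    records: list[tuple[VariantSite, dict[str, GenotypeCall]]] = []
    low_cov = np.array([g in config.low_coverage_genes for g in genes])
    depth = rng.negative_binomial(config.depth_dispersion, p_nb, size=(len(samples), n_sites))
    if low_cov.any():
        forced = rng.integers(3, 11, size=(len(samples), int(low_cov.sum())))
        depth[:, low_cov] = forced
    miss = rng.random((len(samples), n_sites)) < config.missing_genotype_rate
    u_alt = rng.random((len(samples), n_sites))
    het_reads = rng.binomial(depth, 0.5)

    dosage = np.stack([haps[s].sum(axis=0) for s in samples])  # (n_samples, n_sites)
    for j, site in enumerate(sites):
        calls: dict[str, GenotypeCall] = {}
        for i, s in enumerate(samples):
            dp = int(depth[i, j])
            d = int(dosage[i, j])
            if d == 0:
                alt_reads = 0
            elif d == 2:
                alt_reads = dp
            else:
                alt_reads = int(het_reads[i, j])
            if miss[i, j]:
                alleles = ("missing", "missing")
            elif d == 0:
                alleles = ("ref", "ref")
            elif d == 1:
                alleles = ("ref", "alt") if u_alt[i, j] < 0.5 else ("alt", "ref")
            else:
                alleles = ("alt", "alt")
            calls[s] = GenotypeCall(
                sample_id=s,
                alleles=alleles,
                total_depth=dp,
                allele_depths=(dp - alt_reads, alt_reads),
            )
        records.append((site, calls))

    # --- annotations & targets -------------------------------------------
    annotations: dict[tuple[str, int, str, str], VariantAnnotation] = {}
    for j, site in enumerate(sites):
        annotations[site.key] = VariantAnnotation(
            chrom=site.chrom,
            pos=site.pos,
            ref=site.ref,
            alt=site.alt,
            gene_symbol=genes[j],
            transcript=f"NM_{j:06d}.1",
            consequence="missense_variant",
            frequencies=(
                PopulationFrequencies("exomes", (("all", float(maf_arr[j])),)),
            ),
            cadd_phred=cadds[j],
        )
    max_pos: dict[str, int] = {}
    for site in sites:
        max_pos[site.chrom] = max(max_pos.get(site.chrom, 0), site.pos)
    targets = canonicalize(
        GenomicInterval(c, 0, p + 1000) for c, p in sorted(max_pos.items())
    )

    records.sort(key=lambda r: (_CHROMS.index(r[0].chrom), r[0].pos))
    return SimulatedCohort(
        pedigree=ped,
        records=records,
        annotations=annotations,
        targets=targets,
        truth=truth,
        config=config,
    )


def _redrop_from_founders(
    ped: Pedigree, haps: dict[str, np.ndarray], rng: np.random.Generator, n_sites: int
) -> dict[str, np.ndarray]:
    """Re-transmit all sites from (possibly edited) founder haplotypes."""
    out: dict[str, np.ndarray] = {}
    for m in _topological_members(ped):
        h = np.empty((2, n_sites), dtype=np.uint8)
        for row, pid in ((0, m.father_id), (1, m.mother_id)):
            if pid and pid in ped.members:
                parent = out[pid]
                pick = rng.integers(0, 2, size=n_sites)
                h[row] = parent[pick, np.arange(n_sites)]
            else:
                h[row] = haps[m.individual_id][row]
        out[m.individual_id] = h
    return out


def _has_couple_or_sibs(ped: Pedigree) -> bool:
    affected = [m for m in ped if m.affection == "affected"]
    if len(affected) >= 2:
        return True
    return any(
        (m.father_id and m.father_id in ped.members)
        or (m.mother_id and m.mother_id in ped.members)
        for m in affected
    )


def _force_pair(
    ped: Pedigree, haps: Mapping[str, np.ndarray], col_a: int, col_b: int
) -> None:
    """Force two sites in trans in every affected member.

    Site A rides the paternally transmitted haplotype, site B the maternal
    one; recorded non-affected parents of affected members become single-
    variant carriers (father of A, mother of B), everyone else is
    non-carrier.  Affected recorded parents carry the pair like any other
    affected member.
    """
    affected_ids = {m.individual_id for m in ped if m.affection == "affected"}
    for m in _topological_members(ped):
        h = haps[m.individual_id]
        h[:, [col_a, col_b]] = 0
        if m.individual_id in affected_ids:
            h[0, col_a] = 1
            h[1, col_b] = 1
    for m in ped:
        if m.individual_id not in affected_ids:
            continue
        for row, pid, col in ((0, m.father_id, col_a), (1, m.mother_id, col_b)):
            if pid and pid in ped.members and pid not in affected_ids:
                haps[pid][row, col] = 1


def inject_digenic(
    config: SimulationConfig,
    gene_a: str,
    gene_b: str,
    maf_a: float = 0.014,
    maf_b: float = 0.012,
    cadd_a: float = 33.0,
    cadd_b: float = 26.1,
    penetrance: float = 1.0,
) -> SimulatedCohort:
    """Simulate a cohort with a digenic pair co-segregating in all affected.

    Defaults mirror a two-affected-sibling family carrying one paternally
    and one maternally inherited candidate.
    """
    if len([m for m in config.pedigree if m.affection == "affected"]) < 2:
        raise SimulationError("digenic injection requires >= 2 affected members")
    spec = CausalSpec(
        model=DIGENIC_PAIR,
        gene_symbol=gene_a,
        gene_symbol_b=gene_b,
        maf=maf_a,
        cadd=cadd_a,
        penetrance=penetrance,
    )
    cfg = replace(config, causal_specs=list(config.causal_specs) + [spec])
    cohort = simulate_cohort(cfg)
    # the B-site frequency/CADD differ from the A-site: patch annotation
    b_keys = [
        tuple(c["key"]) for c in cohort.truth.causal_sites
        if c["model"] == DIGENIC_PAIR and c["gene"] == gene_b
    ]
    for key in b_keys:
        ann = cohort.annotations[key]
        cohort.annotations[key] = replace(
            ann,
            frequencies=(PopulationFrequencies("exomes", (("all", maf_b),)),),
            cadd_phred=cadd_b,
        )
    return cohort


def mendelian_check(
    vcf: str | os.PathLike | IO[str] | Sequence,
    ped: str | IO[str] | Pedigree | Mapping[str, Pedigree],
) -> list[tuple[VariantSite, str]]:
    """Transmission violations: (site, child id) pairs.

    ``vcf`` may be a VCF path/handle or an in-memory record list from
    :func:`famvar.variants.read_callset`; ``ped`` a PED path/stream/text or
    parsed pedigree(s).  Calls with a missing genotype in the trio are
    skipped.
    """
    if isinstance(vcf, (str, os.PathLike)) or hasattr(vcf, "read"):
        records = read_callset(vcf)  # type: ignore[arg-type]
    else:
        records = list(vcf)
    if isinstance(ped, Pedigree):
        pedigrees: Iterable[Pedigree] = [ped]
    elif isinstance(ped, Mapping):
        pedigrees = ped.values()
    else:
        text = ped.read() if hasattr(ped, "read") else open(ped).read() if os.path.exists(str(ped)) else str(ped)
        pedigrees = parse_pedigrees(text).values()

    def contrib(n_alt: int) -> set[int]:
        return {0: {0}, 1: {0, 1}, 2: {1}}[n_alt]

    violations: list[tuple[VariantSite, str]] = []
    for site, calls in records:
        for pedigree in pedigrees:
            for m in pedigree:
                child = calls.get(m.individual_id)
                if child is None or child.n_alt is None:
                    continue
                par_dosages = []
                for pid in (m.father_id, m.mother_id):
                    if pid and pid in pedigree.members:
                        pc = calls.get(pid)
                        if pc is None or pc.n_alt is None:
                            par_dosages.append(None)
                        else:
                            par_dosages.append(pc.n_alt)
                    else:
                        par_dosages.append(None)
                f, mo = par_dosages
                cf = contrib(f) if f is not None else {0, 1}
                cm = contrib(mo) if mo is not None else {0, 1}
                if f is None and mo is None:
                    continue
                if not any(a + b == child.n_alt for a in cf for b in cm):
                    violations.append((site, m.individual_id))
    return violations
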