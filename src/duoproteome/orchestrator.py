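"""Config-driven end-to-end runs, reporting and provenance.

Pipeline: simulate (or load) -> all-vs-all alignment -> similarity graph
-> MCL ortholog groups -> identity threshold from 1:1 orthologs ->
protein-vs-genome rescue of presumptive specifics -> evidence lines
(AED/KS, outgroup support, functional matches) -> GO enrichment ->
validated report (JSON + markdown).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from ._core import ConfigError, InputError, logger, read_fasta
from . import evidence as ev
from . import ortholog_groups as og_mod
from . import specificity as sp_mod
from .pairwise_align import ScoringScheme, all_vs_all, \
    protein_vs_genome, read_hits, write_hits
from .synthetic_data import (SPECIES_A, SPECIES_B, SPECIES_OUT,
                             SimulationConfig, SimulationResult, TruthLedger,
                             simulate)

VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``mode`` is ``simulate+analyze`` (generate inputs from ``sim``) or
    ``analyze-only`` (read the files under ``indir``, as written by a
    previous simulate stage or prepared externally).
    """

    outdir: str = "duoproteome_run"
    mode: str = "simulate+analyze"
    indir: str | None = None           # analyze-only input directory
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # alignment stage
    hit_evalue_max: float = 1.0e-3
    prefilter: bool = True
    # clustering stage
    percent_match_cutoff: float = 50.0
    evalue_exponent_cutoff: float = -5.0
    inflation: float = 1.5
    # significant-match criteria
    percentile: float = 5.0
    identity_min: float | None = None  # overrides the derived percentile
    identity_mode: str = "mean"
    rescue_evalue_max: float = 1.0e-5
    alignment_length_min: int = 30
    query_coverage_min: float = 0.5
    genome_min_aa: int = 30
    # functional support + enrichment
    functional_evalue_max: float = 1.0e-5
    alpha: float = 0.01

    def validate(self) -> None:
        if self.mode not in ("simulate+analyze", "analyze-only"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "analyze-only" and not self.indir:
            raise ConfigError("analyze-only mode requires indir")
        self.sim.validate()
        if self.inflation <= 1.0:
            raise ConfigError("inflation must be > 1")
        if not 0.0 < self.percentile < 100.0:
            raise ConfigError("percentile outside (0, 100)")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha outside (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["sim"]["aed_conserved_params"] = list(d["sim"]["aed_conserved_params"])
        d["sim"]["aed_specific_params"] = list(d["sim"]["aed_specific_params"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown run config keys: {sorted(unknown)}")
        cfg = cls(sim=SimulationConfig.from_dict(sim), **d)
        cfg.validate()
        return cfg


@dataclass
class RunReport:
    """Validated summary of one pipeline run."""

    version: str
    seed: int
    parameters: dict
    og_summary: dict
    threshold: dict
    specificity: dict          # per species: presumptive / rescued / final
    evidence: dict             # aed comparisons, outgroup, functional counts
    enrichment: dict           # per species: significant terms
    truth_eval: dict | None    # planted-truth comparison when available

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))

    def validate(self) -> None:
        """Conservation identities every report must satisfy."""
        for sp in ("A", "B"):
            shared = self.og_summary[f"shared_genes_{sp.lower()}"]
            presumptive = self.og_summary[f"presumptive_specific_{sp.lower()}"]
            size = self.og_summary[f"proteome_size_{sp.lower()}"]
            if shared + presumptive != size:
                raise InputError(
                    f"species {sp}: shared ({shared}) + presumptive "
                    f"({presumptive}) != proteome size ({size})")
            s = self.specificity[sp]
            if s["rescued"] + s["final_specific"] != s["presumptive"]:
                raise InputError(
                    f"species {sp}: rescued + final != presumptive")
            if s["presumptive"] != presumptive:
                raise InputError(
                    f"species {sp}: specificity pool disagrees with OG summary")


# ---------------------------------------------------------------------------
# input loading for analyze-only mode


def _load_inputs(indir: str | Path) -> dict[str, Any]:
    indir = Path(indir)
    data: dict[str, Any] = {}
    data["proteomes"] = {
        SPECIES_A: read_fasta(indir / "proteome_A.faa", SPECIES_A),
        SPECIES_B: read_fasta(indir / "proteome_B.faa", SPECIES_B),
    }
    out_path = indir / "proteome_out.faa"
    if out_path.exists():
        data["proteomes"][SPECIES_OUT] = read_fasta(out_path, SPECIES_OUT)
    genomes = {}
    for sp, name in ((SPECIES_A, "genome_A.fna"), (SPECIES_B, "genome_B.fna")):
        recs = read_fasta(indir / name, sp)
        genomes[sp] = (recs[0].gene_id, recs[0].seq)
    data["genomes"] = genomes
    data["aed"] = pd.read_csv(indir / "aed.tsv", sep="\t")
    data["go"] = pd.read_csv(indir / "go.tsv", sep="\t", dtype=str)
    truth_path = indir / "truth.tsv"
    data["truth"] = TruthLedger.read(truth_path) if truth_path.exists() else None
    return data


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and write all intermediates to outdir."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_echo.yaml")

    # ---- stage: inputs -----------------------------------------------------
    if config.mode == "simulate+analyze":
        logger.info("stage simulate: seed=%d", config.sim.seed)
        sim: SimulationResult = simulate(config.sim)
        sim.write(outdir)
        proteomes = sim.proteomes
        genomes = sim.genomes
        aed_table, go_table, truth = sim.aed, sim.go, sim.truth
    else:
        logger.info("stage load: %s", config.indir)
        data = _load_inputs(config.indir)
        proteomes = data["proteomes"]
        genomes = data["genomes"]
        aed_table, go_table, truth = data["aed"], data["go"], data["truth"]
    has_outgroup = SPECIES_OUT in proteomes and bool(proteomes[SPECIES_OUT])

    species_of: dict[str, str] = {}
    seq_lengths: dict[str, int] = {}
    for sp, recs in proteomes.items():
        for r in recs:
            if r.gene_id in species_of:
                raise InputError(f"duplicate gene id {r.gene_id!r} across proteomes")
            species_of[r.gene_id] = sp
            seq_lengths[r.gene_id] = len(r)

    # ---- stage: all-vs-all alignment --------------------------------------
    scheme = ScoringScheme.blosum62()
    logger.info("stage align: A-B")
    hits_ab = all_vs_all(proteomes[SPECIES_A], proteomes[SPECIES_B], scheme,
                         prefilter=config.prefilter,
                         evalue_max=config.hit_evalue_max)
    write_hits(hits_ab, outdir / "hits_AB.tsv")
    all_hits = list(hits_ab)
    for sp, name in ((SPECIES_A, "hits_AA.tsv"), (SPECIES_B, "hits_BB.tsv")):
        logger.info("stage align: %s-%s", sp, sp)
        intra = all_vs_all(proteomes[sp], proteomes[sp], scheme,
                           prefilter=config.prefilter,
                           evalue_max=config.hit_evalue_max)
        write_hits(intra, outdir / name)
        all_hits.extend(intra)
    if has_outgroup:
        for sp, name in ((SPECIES_A, "hits_AOUT.tsv"), (SPECIES_B, "hits_BOUT.tsv")):
            logger.info("stage align: %s-OUT", sp)
            h = all_vs_all(proteomes[sp], proteomes[SPECIES_OUT], scheme,
                           prefilter=config.prefilter,
                           evalue_max=config.hit_evalue_max)
            write_hits(h, outdir / name)
            all_hits.extend(h)

    # ---- stage: cluster ----------------------------------------------------
    logger.info("stage cluster: building graph from %d hits", len(all_hits))
    graph = og_mod.build_graph(all_hits, species_of, seq_lengths,
                               config.percent_match_cutoff,
                               config.evalue_exponent_cutoff)
    clusters, mcl_info = og_mod.mcl_cluster(graph, inflation=config.inflation)
    ogs, og_summary = og_mod.classify_ogs(clusters, species_of,
                                          SPECIES_A, SPECIES_B, SPECIES_OUT)
    og_mod.write_ogs(ogs, species_of, outdir / "ogs.tsv")
    with open(outdir / "og_summary.json", "w") as fh:
        json.dump(og_summary, fh, sort_keys=True, indent=2)

    # ---- stage: identity threshold -----------------------------------------
    identities = sp_mod.one_to_one_identities(ogs, hits_ab, species_of,
                                              SPECIES_A, SPECIES_B,
                                              mode=config.identity_mode)
    if config.identity_min is not None:
        identity_min = float(config.identity_min)
        threshold_info = {"identity_min": identity_min, "source": "manual",
                          "n_one_to_one": len(identities)}
    else:
        identity_min = sp_mod.derive_threshold(identities, config.percentile)
        threshold_info = {"identity_min": identity_min,
                          "source": f"percentile_{config.percentile:g}",
                          "n_one_to_one": len(identities)}
    logger.info("stage threshold: identity_min=%.2f from %d 1:1 orthologs",
                identity_min, len(identities))
    criteria = sp_mod.MatchCriteria(
        identity_min=identity_min, evalue_max=config.rescue_evalue_max,
        alignment_length_min=config.alignment_length_min,
        query_coverage_min=config.query_coverage_min,
        percentile=config.percentile)

    # ---- stage: genome rescue ----------------------------------------------
    specificity_summary: dict[str, dict] = {}
    calls_by_species: dict[str, list] = {}
    pools: dict[str, set[str]] = {}
    for sp, partner in ((SPECIES_A, SPECIES_B), (SPECIES_B, SPECIES_A)):
        pool = og_mod.presumptive_pool(ogs, species_of, sp)
        pools[sp] = pool
        pool_records = [r for r in proteomes[sp] if r.gene_id in pool]
        logger.info("stage genomesearch: %d presumptive %s genes vs genome %s",
                    len(pool), sp, partner)
        if pool_records:
            ghits = protein_vs_genome(pool_records, genomes[partner], scheme,
                                      min_aa=config.genome_min_aa,
                                      evalue_max=config.hit_evalue_max,
                                      prefilter=config.prefilter)
        else:
            ghits = []
        write_hits(ghits, outdir / f"ghits_{sp}.tsv")
        counts = sp_mod.apply_criteria(ghits, criteria)
        calls, summary = sp_mod.partition_specific(pool, counts, sp)
        sp_mod.write_calls(calls, outdir / f"specificity_{sp}.tsv")
        specificity_summary[sp] = summary
        calls_by_species[sp] = calls

    # ---- stage: evidence ----------------------------------------------------
    logger.info("stage evidence")
    aed_of = dict(zip(aed_table["gene_id"], aed_table["aed"]))
    conserved_genes: dict[str, set[str]] = {SPECIES_A: set(), SPECIES_B: set()}
    for og in ogs:
        if og.conserved:
            for g in og.members:
                if species_of[g] in conserved_genes:
                    conserved_genes[species_of[g]].add(g)
    evidence_summary: dict[str, Any] = {"aed": {}}
    final_specific: dict[str, set[str]] = {}
    for sp in (SPECIES_A, SPECIES_B):
        final_specific[sp] = {c.gene_id for c in calls_by_species[sp]
                              if c.final_specific}
        cons = [aed_of[g] for g in sorted(conserved_genes[sp]) if g in aed_of]
        spec = [aed_of[g] for g in sorted(final_specific[sp]) if g in aed_of]
        if cons and spec:
            comp = ev.compare_aed_groups(cons, spec)
            evidence_summary["aed"][sp] = dataclasses.asdict(comp)
        else:
            evidence_summary["aed"][sp] = None
    if has_outgroup:
        support = ev.outgroup_support(ogs)
        evidence_summary["outgroup"] = dataclasses.asdict(support)
        functional = {}
        for sp, name in ((SPECIES_A, "hits_AOUT.tsv"), (SPECIES_B, "hits_BOUT.tsv")):
            ext_hits = read_hits(outdir / name)
            count, genes = ev.functional_support(
                final_specific[sp], ext_hits,
                evalue_max=config.functional_evalue_max)
            functional[sp] = count
        evidence_summary["functional_matches"] = functional
    else:
        evidence_summary["outgroup"] = None
        evidence_summary["functional_matches"] = None

    # ---- stage: GO enrichment ----------------------------------------------
    logger.info("stage enrich")
    enrichment_summary: dict[str, Any] = {}
    for sp in (SPECIES_A, SPECIES_B):
        universe = {r.gene_id for r in proteomes[sp]}
        sub_table = go_table[go_table["gene_id"].isin(universe)]
        results = ev.go_enrichment(final_specific[sp], universe, sub_table,
                                   alpha=config.alpha)
        ev.write_enrichment(results, outdir / f"enrichment_{sp}.tsv")
        sig = [r.go_term for r in results if r.significant]
        enrichment_summary[sp] = {
            "n_terms_tested": len(results),
            "n_significant": len(sig),
            "significant_terms": sig,
        }

    # ---- stage: truth comparison -------------------------------------------
    truth_eval = None
    if truth is not None:
        truth_eval = {}
        for sp in (SPECIES_A, SPECIES_B):
            expected = truth.expected_specific(sp)
            found = final_specific[sp]
            tp = len(found & expected)
            precision = tp / len(found) if found else float("nan")
            recall = tp / len(expected) if expected else float("nan")
            hidden = truth.hidden_sources(sp)
            rescued = {c.gene_id for c in calls_by_species[sp] if c.rescued}
            hidden_rescued = len(hidden & rescued) / len(hidden) if hidden \
                else float("nan")
            truth_eval[sp] = {
                "n_expected_specific": len(expected),
                "n_final_specific": len(found),
                "precision": precision,
                "recall": recall,
                "n_hidden": len(hidden),
                "hidden_rescue_rate": hidden_rescued,
            }

    parameters = {
        "mode": config.mode,
        "hit_evalue_max": config.hit_evalue_max,
        "percent_match_cutoff": config.percent_match_cutoff,
        "evalue_exponent_cutoff": config.evalue_exponent_cutoff,
        "inflation": config.inflation,
        "percentile": config.percentile,
        "identity_mode": config.identity_mode,
        "rescue_evalue_max": config.rescue_evalue_max,
        "alignment_length_min": config.alignment_length_min,
        "query_coverage_min": config.query_coverage_min,
        "functional_evalue_max": config.functional_evalue_max,
        "alpha": config.alpha,
        "mcl_converged": mcl_info["converged"],
        "sim": {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config.sim).items()},
    }
    report = RunReport(
        version=VERSION, seed=config.sim.seed, parameters=parameters,
        og_summary=og_summary, threshold=threshold_info,
        specificity=specificity_summary, evidence=evidence_summary,
        enrichment=enrichment_summary, truth_eval=truth_eval)
    report.validate()
    (outdir / "report.json").write_text(report.to_json())
    (outdir / "report.md").write_text(render_report(report))
    logger.info("pipeline complete: %s", outdir)
    return report


# ---------------------------------------------------------------------------
# rendering


def _md_table(d: dict, key_header: str = "quantity",
              value_header: str = "value") -> list[str]:
    lines = [f"| {key_header} | {value_header} |", "| --- | --- |"]
    for k in sorted(d):
        v = d[k]
        if isinstance(v, float):
            v = f"{v:.6g}"
        lines.append(f"| {k} | {v} |")
    return lines


def render_report(report: RunReport) -> str:
    """Deterministic human-readable markdown mirroring the JSON report."""
    out: list[str] = [f"# duoproteome run report (v{report.version}, "
                      f"seed {report.seed})", ""]
    out.append("## Ortholog groups")
    out += _md_table(report.og_summary) + [""]
    out.append("## Identity threshold")
    out += _md_table(report.threshold) + [""]
    out.append("## Species-specific genes")
    for sp in sorted(report.specificity):
        out.append(f"### Species {sp}")
        out += _md_table(report.specificity[sp]) + [""]
    out.append("## Evidence")
    for sp in sorted(report.evidence.get("aed", {})):
        comp = report.evidence["aed"][sp]
        out.append(f"### AED, species {sp}")
        if comp is None:
            out.append("no AED comparison (empty group)")
            out.append("")
        else:
            out += _md_table(comp) + [""]
    if report.evidence.get("outgroup"):
        out.append("### Outgroup support")
        out += _md_table(report.evidence["outgroup"]) + [""]
    if report.evidence.get("functional_matches"):
        out.append("### Functional matches")
        out += _md_table(report.evidence["functional_matches"]) + [""]
    out.append("## GO enrichment")
    for sp in sorted(report.enrichment):
        e = report.enrichment[sp]
        out.append(f"### Species {sp}")
        if e["n_significant"] == 0:
            out.append(f"no terms significant at alpha "
                       f"({e['n_terms_tested']} tested)")
            out.append("")
        else:
            out += _md_table({
                "n_terms_tested": e["n_terms_tested"],
                "n_significant": e["n_significant"],
                "significant_terms": ", ".join(e["significant_terms"]),
            }) + [""]
    if report.truth_eval is not None:
        out.append("## Planted-truth comparison")
        for sp in sorted(report.truth_eval):
            out.append(f"### Species {sp}")
            out += _md_table(report.truth_eval[sp]) + [""]
    return "\n".join(out) + "\n"
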