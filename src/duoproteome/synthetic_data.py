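"""Paired-proteome simulator with planted ground truth.

Emulates two annotated proteomes descended from a common ancestral gene
set (plus an outgroup), with tunable ortholog divergence, lineage-specific
losses and recent duplications, genuinely species-specific genes, genes
present in the partner genome but missing from its annotation, annotation
quality (AED) scores drawn from distinct distributions for conserved
vs. specific genes, and GO assignments with an optionally enriched term.

The ground truth of every planted event is kept in a :class:`TruthLedger`
so downstream classification can be scored against it.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Data import CodonTable

from ._core import ConfigError, ProteinRecord, write_fasta

# ---------------------------------------------------------------------------
# Amino-acid background (Robinson & Robinson frequencies, as used by BLAST)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_RR = np.array([
    0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199,
    0.05142, 0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264,
    0.05129, 0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
])
AA_FREQS = _RR / _RR.sum()

# species tags used throughout the synthetic pipeline
SPECIES_A = "A"
SPECIES_B = "B"
SPECIES_OUT = "OUT"

CATEGORIES = (
    "shared_ortholog",
    "inparalog",
    "lost_in_other",
    "specific",
    "hidden_in_other_genome",
)
#: categories that make a gene operationally species-specific (present in
#: one annotated proteome and genuinely absent from the other genome)
SPECIFIC_CATEGORIES = frozenset({"specific", "lost_in_other"})

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
# aa -> sorted list of synonymous codons (standard code, stops excluded)
_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_STANDARD.forward_table.items()):
    _CODONS.setdefault(aa, []).append(codon)
_STOP_CODONS = sorted(_STANDARD.stop_codons)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimulationConfig:
    """All knobs of the paired-proteome simulation.

    ``identity_mean``/``identity_sd`` describe the target percent identity
    of ortholog *pairs* (truncated normal on (0, 100]); the per-lineage
    divergence applied by :func:`evolve_proteome` is derived from them
    (see :func:`lineage_params_for`).
    """

    n_ancestral: int = 600
    mean_len: float = 250.0          # mean protein length, amino acids
    sd_len: float = 100.0            # sd of protein length (lognormal)
    identity_mean: float = 80.0      # ortholog-pair percent identity target
    identity_sd: float = 8.0
    p_loss_A: float = 0.05
    p_loss_B: float = 0.05
    p_dup_A: float = 0.05
    p_dup_B: float = 0.05
    n_specific_A: int = 40
    n_specific_B: int = 40
    n_hidden_A: int = 30             # B-annotated genes hidden in genome A
    n_hidden_B: int = 30             # A-annotated genes hidden in genome B
    outgroup_identity_mean: float = 60.0
    p_loss_out: float = 0.05
    dup_identity: float = 96.0       # identity between recent in-paralog copies
    hidden_identity: float = 95.0    # identity of hidden genome copy to its protein
    aed_conserved_params: tuple[float, float] = (3.5, 6.5)   # beta, mean 0.35
    aed_specific_params: tuple[float, float] = (7.3, 2.7)    # beta, mean 0.73
    go_vocab_size: int = 200
    go_terms_per_gene: float = 3.0
    enriched_term: str = "GO:0000001"
    enrichment_odds: float = 8.0
    base_term_prob: float = 0.2      # enriched-term frequency outside the planted set
    intergenic_len: int = 200        # spacer length between genes, bp
    indels: bool = False
    indel_rate: float = 0.002        # indel events per residue when enabled
    seed: int = 42

    def validate(self) -> None:
        for name in ("p_loss_A", "p_loss_B", "p_dup_A", "p_dup_B", "p_loss_out"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in ("identity_mean", "outgroup_identity_mean",
                     "dup_identity", "hidden_identity"):
            v = getattr(self, name)
            if not 0.0 < v <= 100.0:
                raise ConfigError(f"{name}={v} outside (0, 100]")
        if self.n_ancestral < 1:
            raise ConfigError("n_ancestral must be >= 1")
        if self.mean_len <= 0 or self.sd_len < 0:
            raise ConfigError("invalid protein length parameters")
        if self.identity_sd < 0:
            raise ConfigError("identity_sd must be >= 0")
        for name in ("n_specific_A", "n_specific_B", "n_hidden_A", "n_hidden_B"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("aed_conserved_params", "aed_specific_params"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ConfigError(f"{name} must be positive beta shapes")
        if self.go_vocab_size < 1:
            raise ConfigError("go_vocab_size must be >= 1")
        if self.enrichment_odds <= 0:
            raise ConfigError("enrichment_odds must be > 0")
        if not 0.0 < self.base_term_prob < 1.0:
            raise ConfigError("base_term_prob must be in (0, 1)")
        if self.intergenic_len < 0:
            raise ConfigError("intergenic_len must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["aed_conserved_params"] = list(d["aed_conserved_params"])
        d["aed_specific_params"] = list(d["aed_specific_params"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("aed_conserved_params", "aed_specific_params"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class LineageParams:
    """Per-lineage divergence parameters for :func:`evolve_proteome`.

    ``identity_mean``/``identity_sd`` here target the identity of each
    descendant to its *ancestor* (truncated normal on (0, 100]).
    """

    species: str
    identity_mean: float
    identity_sd: float
    p_loss: float
    p_dup: float
    dup_identity: float = 96.0
    indels: bool = False
    indel_rate: float = 0.002


def lineage_params_for(config: SimulationConfig, species: str) -> LineageParams:
    """Derive per-lineage ancestor-identity targets from the pair target.

    With both lineages mutating independent sites, pair identity is
    approximately the product of the two ancestor identities, so the
    lineage mean is 100*sqrt(pair_mean/100) and the lineage sd is chosen
    so the pair sd matches the configured value
    (sd_l = m_l * (pair_sd/pair_mean) / sqrt(2)).
    """
    if config.identity_mean <= 0:
        raise ConfigError("identity_mean must be > 0")
    m_l = 100.0 * math.sqrt(config.identity_mean / 100.0)
    sd_l = m_l * (config.identity_sd / config.identity_mean) / math.sqrt(2.0)
    if species == SPECIES_A:
        return LineageParams(SPECIES_A, m_l, sd_l, config.p_loss_A,
                             config.p_dup_A, config.dup_identity,
                             config.indels, config.indel_rate)
    if species == SPECIES_B:
        return LineageParams(SPECIES_B, m_l, sd_l, config.p_loss_B,
                             config.p_dup_B, config.dup_identity,
                             config.indels, config.indel_rate)
    if species == SPECIES_OUT:
        # outgroup pair identity ~ outgroup_identity_mean against either ingroup
        m_out = 100.0 * config.outgroup_identity_mean / m_l
        if not 0.0 < m_out <= 100.0:
            raise ConfigError("outgroup_identity_mean incompatible with identity_mean")
        return LineageParams(SPECIES_OUT, m_out, sd_l, config.p_loss_out, 0.0)
    raise ConfigError(f"unknown species {species!r}")


# ---------------------------------------------------------------------------
# Truth ledger


class TruthLedger:
    """Per-gene ground truth for the two annotated proteomes.

    One row per emitted A/B gene: species, category (one of
    :data:`CATEGORIES`), ancestral_id (empty for planted genes) and the
    true orthologous-group id.
    """

    COLUMNS = ("gene_id", "species", "category", "ancestral_id", "true_og_id")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ConfigError(f"truth ledger missing columns {sorted(missing)}")
        if frame["gene_id"].duplicated().any():
            raise ConfigError("truth ledger has duplicate gene ids")
        bad = set(frame["category"]) - set(CATEGORIES)
        if bad:
            raise ConfigError(f"unknown truth categories {sorted(bad)}")
        self.frame = frame.reset_index(drop=True)

    def genes(self, species: str, categories: Sequence[str] | None = None) -> set[str]:
        sub = self.frame[self.frame["species"] == species]
        if categories is not None:
            sub = sub[sub["category"].isin(list(categories))]
        return set(sub["gene_id"])

    def expected_specific(self, species: str) -> set[str]:
        """Genes of ``species`` that are genuinely species-specific."""
        return self.genes(species, SPECIFIC_CATEGORIES)

    def hidden_sources(self, species: str) -> set[str]:
        """Genes of ``species`` whose homolog is hidden in the partner genome."""
        return self.genes(species, ["hidden_in_other_genome"])

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "TruthLedger":
        frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        return cls(frame)


# ---------------------------------------------------------------------------
# Sequence-level primitives


def _sample_lengths(n: int, mean_len: float, sd_len: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Lognormal protein lengths with the given arithmetic mean/sd, clamped >= 30."""
    if mean_len <= 0 or sd_len < 0:
        raise ConfigError("invalid length parameters")
    if sd_len == 0:
        lengths = np.full(n, mean_len)
    else:
        sigma2 = math.log(1.0 + (sd_len / mean_len) ** 2)
        mu = math.log(mean_len) - sigma2 / 2.0
        lengths = rng.lognormal(mu, math.sqrt(sigma2), size=n)
    return np.maximum(30, np.rint(lengths).astype(int))


def random_protein(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(len(AA_ALPHABET), size=length, p=AA_FREQS)
    return "".join(AA_ALPHABET[i] for i in idx)


def _truncnorm(mean: float, sd: float, rng: np.random.Generator,
               low: float = 0.0, high: float = 100.0) -> float:
    """Rejection-sampled normal truncated to (low, high]."""
    if sd == 0:
        if not low < mean <= high:
            raise ConfigError(f"target {mean} outside ({low}, {high}]")
        return mean
    for _ in range(10000):
        v = rng.normal(mean, sd)
        if low < v <= high:
            return v
    raise ConfigError(f"truncated normal ({mean}, {sd}) never hit ({low}, {high}]")


def mutate_to_identity(seq: str, identity_pct: float,
                       rng: np.random.Generator) -> str:
    """Substitute an exact count of sites so identity to ``seq`` is the
    closest achievable value to ``identity_pct``.

    Replacement residues are drawn from the background frequencies and are
    always different from the original residue.
    """
    n = len(seq)
    k = int(round(n * (1.0 - identity_pct / 100.0)))
    k = max(0, min(n, k))
    if k == 0:
        return seq
    positions = rng.choice(n, size=k, replace=False)
    out = list(seq)
    for pos in positions:
        while True:
            new = AA_ALPHABET[rng.choice(len(AA_ALPHABET), p=AA_FREQS)]
            if new != out[pos]:
                break
        out[pos] = new
    return "".join(out)


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Geometric-length (mean 3) insertions/deletions at Poisson-spaced sites."""
    n_events = rng.poisson(rate * len(seq))
    out = seq
    for _ in range(n_events):
        if len(out) <= 31:
            break
        pos = int(rng.integers(0, len(out)))
        length = int(rng.geometric(1.0 / 3.0))
        if rng.random() < 0.5:
            out = out[:pos] + random_protein(length, rng) + out[pos:]
        else:
            out = out[:pos] + out[pos + length:]
    return out


def _identity_between(a: str, b: str) -> float:
    """Ungapped percent identity of two equal-length sequences."""
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * matches / max(len(a), len(b))


# ---------------------------------------------------------------------------
# Simulation stages


def simulate_ancestral_proteome(config: SimulationConfig,
                                rng: np.random.Generator | None = None
                                ) -> list[ProteinRecord]:
    """Random ancestral gene set over the 20-letter alphabet."""
    if config.n_ancestral < 1:
        raise ConfigError("n_ancestral must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lengths = _sample_lengths(config.n_ancestral, config.mean_len,
                              config.sd_len, rng)
    return [
        ProteinRecord(f"ANC{i + 1:05d}", "ANC", random_protein(int(L), rng))
        for i, L in enumerate(lengths)
    ]


def evolve_proteome(ancestral: Sequence[ProteinRecord], params: LineageParams,
                    seed: int | np.random.Generator
                    ) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Evolve one lineage from the ancestral gene set.

    Per ancestral gene: loss with ``p_loss``; otherwise one descendant
    mutated to a drawn ancestor-identity target, plus (with ``p_dup``) a
    second, recently duplicated copy mutated from the first at
    ``dup_identity``. Returns the descendant records and an event table
    (species, ancestral_id, gene_id, event, target_identity,
    realized_identity) where loss rows have an empty gene_id.
    """
    if not ancestral:
        raise ConfigError("ancestral proteome is empty")
    if params.identity_mean <= 0:
        raise ConfigError("identity target must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    rows = []
    for anc in ancestral:
        num = anc.gene_id.replace("ANC", "")
        if rng.random() < params.p_loss:
            rows.append((params.species, anc.gene_id, "", "loss", np.nan, np.nan))
            continue
        target = _truncnorm(params.identity_mean, params.identity_sd, rng)
        child = mutate_to_identity(anc.seq, target, rng)
        if params.indels:
            child = _apply_indels(child, params.indel_rate, rng)
        gene_id = f"{params.species}_{num}"
        records.append(ProteinRecord(gene_id, params.species, child))
        rows.append((params.species, anc.gene_id, gene_id, "descend",
                     target, _identity_between(anc.seq, child)))
        if rng.random() < params.p_dup:
            copy = mutate_to_identity(child, params.dup_identity, rng)
            copy_id = f"{params.species}_{num}d"
            records.append(ProteinRecord(copy_id, params.species, copy))
            rows.append((params.species, anc.gene_id, copy_id, "duplicate",
                         params.dup_identity, _identity_between(anc.seq, copy)))
    events = pd.DataFrame(rows, columns=[
        "species", "ancestral_id", "gene_id", "event",
        "target_identity", "realized_identity"])
    return records, events


def plant_specific_and_hidden(proteomes: dict[str, list[ProteinRecord]],
                              config: SimulationConfig,
                              rng: np.random.Generator
                              ) -> tuple[dict[str, list[ProteinRecord]],
                                         dict[str, list[tuple[str, str]]],
                                         pd.DataFrame]:
    """Add genuinely specific and hidden-in-partner-genome genes.

    Specific genes are fresh random sequences with no homolog anywhere.
    Hidden genes are fresh sequences annotated in one proteome, whose
    diverged copy (``hidden_identity``) is planted only in the *partner
    genome* sequence. Returns updated proteomes, the per-genome hidden
    plan {genome_species: [(source_gene_id, protein_to_embed), ...]},
    and the truth rows for the planted genes.
    """
    proteomes = {sp: list(recs) for sp, recs in proteomes.items()}
    hidden_plan: dict[str, list[tuple[str, str]]] = {SPECIES_A: [], SPECIES_B: []}
    rows = []
    specs = [(SPECIES_A, config.n_specific_A), (SPECIES_B, config.n_specific_B)]
    for sp, count in specs:
        lengths = _sample_lengths(count, config.mean_len, config.sd_len, rng) \
            if count else []
        for i in range(count):
            gid = f"{sp}_sp{i + 1:04d}"
            proteomes[sp].append(
                ProteinRecord(gid, sp, random_protein(int(lengths[i]), rng)))
            rows.append((gid, sp, "specific", "", f"TOG_{gid}"))
    # n_hidden_B = genes annotated in A, hidden in genome B (and mirrored)
    hidden = [(SPECIES_A, SPECIES_B, config.n_hidden_B),
              (SPECIES_B, SPECIES_A, config.n_hidden_A)]
    for src_sp, genome_sp, count in hidden:
        lengths = _sample_lengths(count, config.mean_len, config.sd_len, rng) \
            if count else []
        for i in range(count):
            gid = f"{src_sp}_hid{i + 1:04d}"
            protein = random_protein(int(lengths[i]), rng)
            proteomes[src_sp].append(ProteinRecord(gid, src_sp, protein))
            embedded = mutate_to_identity(protein, config.hidden_identity, rng)
            hidden_plan[genome_sp].append((gid, embedded))
            rows.append((gid, src_sp, "hidden_in_other_genome", "", f"TOG_{gid}"))
    planted = pd.DataFrame(rows, columns=list(TruthLedger.COLUMNS))
    return proteomes, hidden_plan, planted


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with uniformly random synonymous codons plus a stop."""
    codons = []
    for aa in protein:
        options = _CODONS[aa]
        codons.append(options[int(rng.integers(0, len(options)))])
    codons.append(_STOP_CODONS[int(rng.integers(0, len(_STOP_CODONS)))])
    return "".join(codons)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def emit_genomes(proteomes: dict[str, list[ProteinRecord]],
                 hidden_plan: dict[str, list[tuple[str, str]]],
                 config: SimulationConfig,
                 rng: np.random.Generator
                 ) -> tuple[dict[str, tuple[str, str]], pd.DataFrame]:
    """Emit one intron-free chromosome per annotated species.

    Every annotated protein and every hidden gene is back-translated and
    embedded on a random strand between fixed-length random spacers.
    Returns {species: (chrom_id, sequence)} and a table of planted coding
    intervals (1-based inclusive, strand, hidden flag).
    """
    genomes: dict[str, tuple[str, str]] = {}
    interval_rows = []
    for sp in (SPECIES_A, SPECIES_B):
        items = [(rec.gene_id, rec.seq, False) for rec in proteomes[sp]]
        items += [(gid, prot, True) for gid, prot in hidden_plan.get(sp, [])]
        order = rng.permutation(len(items))
        chrom = f"chr{sp}"
        parts: list[str] = []
        pos = 0  # 0-based running coordinate
        spacer_len = config.intergenic_len

        def _spacer() -> str:
            if spacer_len == 0:
                return ""
            idx = rng.integers(0, 4, size=spacer_len)
            return "".join("ACGT"[i] for i in idx)

        parts.append(_spacer())
        pos += spacer_len
        for j in order:
            gid, prot, is_hidden = items[j]
            cds = back_translate(prot, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            parts.append(cds if strand == "+" else _revcomp(cds))
            interval_rows.append((sp, chrom, gid, pos + 1, pos + len(cds),
                                  strand, is_hidden))
            pos += len(cds)
            parts.append(_spacer())
            pos += spacer_len
        genomes[sp] = (chrom, "".join(parts))
    intervals = pd.DataFrame(interval_rows, columns=[
        "genome_species", "chrom", "gene_id", "start", "end", "strand", "hidden"])
    return genomes, intervals


def assign_aed_and_go(truth: TruthLedger, config: SimulationConfig,
                      rng: np.random.Generator
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-gene AED scores and GO assignments from the planted truth.

    Operationally specific genes (categories ``specific`` and
    ``lost_in_other``) draw AED from the specific beta; all others from
    the conserved beta. The enriched GO term is assigned with elevated
    odds to planted ``specific`` genes; remaining terms are background.
    """
    frame = truth.frame
    aed_rows = []
    go_rows = []
    vocab = [f"GO:{i + 1:07d}" for i in range(config.go_vocab_size)]
    background = [t for t in vocab if t != config.enriched_term]
    p0 = config.base_term_prob
    odds1 = config.enrichment_odds * p0 / (1.0 - p0)
    p1 = odds1 / (1.0 + odds1)
    a_c, b_c = config.aed_conserved_params
    a_s, b_s = config.aed_specific_params
    for row in frame.itertuples(index=False):
        if row.category in SPECIFIC_CATEGORIES:
            aed = float(rng.beta(a_s, b_s))
        else:
            aed = float(rng.beta(a_c, b_c))
        aed_rows.append((row.gene_id, row.species, aed))
        p_term = p1 if row.category == "specific" else p0
        if rng.random() < p_term:
            go_rows.append((row.gene_id, config.enriched_term))
        k = int(rng.poisson(config.go_terms_per_gene))
        if k > 0 and background:
            k = min(k, len(background))
            for t_idx in sorted(rng.choice(len(background), size=k, replace=False)):
                go_rows.append((row.gene_id, background[t_idx]))
    aed = pd.DataFrame(aed_rows, columns=["gene_id", "species", "aed"])
    go = pd.DataFrame(go_rows, columns=["gene_id", "go_term"])
    return aed, go


# ---------------------------------------------------------------------------
# Whole-simulation driver


@dataclass
class SimulationResult:
    """Everything one simulated study produces, plus its ground truth."""

    config: SimulationConfig
    proteomes: dict[str, list[ProteinRecord]]
    genomes: dict[str, tuple[str, str]]
    gene_intervals: pd.DataFrame
    truth: TruthLedger
    aed: pd.DataFrame
    go: pd.DataFrame
    events: pd.DataFrame = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteomes[SPECIES_A], outdir / "proteome_A.faa")
        write_fasta(self.proteomes[SPECIES_B], outdir / "proteome_B.faa")
        write_fasta(self.proteomes[SPECIES_OUT], outdir / "proteome_out.faa")
        write_fasta([self.genomes[SPECIES_A]], outdir / "genome_A.fna")
        write_fasta([self.genomes[SPECIES_B]], outdir / "genome_B.fna")
        self.aed.to_csv(outdir / "aed.tsv", sep="\t", index=False)
        self.go.to_csv(outdir / "go.tsv", sep="\t", index=False)
        self.truth.write(outdir / "truth.tsv")
        self.gene_intervals.to_csv(outdir / "intervals.tsv", sep="\t", index=False)
        self.config.to_yaml(outdir / "config.yaml")


def _build_truth(events_a: pd.DataFrame, events_b: pd.DataFrame,
                 planted: pd.DataFrame) -> TruthLedger:
    rows = []
    by_anc: dict[str, dict[str, list[str]]] = {}
    for ev in (events_a, events_b):
        for r in ev.itertuples(index=False):
            if r.event == "loss":
                continue
            by_anc.setdefault(r.ancestral_id, {}).setdefault(r.species, []).append(
                (r.gene_id, r.event))
    for anc_id in sorted(by_anc):
        per_sp = by_anc[anc_id]
        both = SPECIES_A in per_sp and SPECIES_B in per_sp
        for sp, copies in sorted(per_sp.items()):
            for i, (gid, event) in enumerate(copies):
                if both:
                    cat = "shared_ortholog" if event == "descend" else "inparalog"
                else:
                    cat = "lost_in_other"
                rows.append((gid, sp, cat, anc_id, f"TOG_{anc_id}"))
    frame = pd.DataFrame(rows, columns=list(TruthLedger.COLUMNS))
    frame = pd.concat([frame, planted], ignore_index=True)
    return TruthLedger(frame)


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full generator: ancestral set, three lineages, planted
    specific/hidden genes, genomes, AED and GO tables, truth ledger."""
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    rng_anc, rng_a, rng_b, rng_out, rng_plant, rng_rest = \
        (np.random.default_rng(s) for s in seeds)
    ancestral = simulate_ancestral_proteome(config, rng_anc)
    prot_a, events_a = evolve_proteome(
        ancestral, lineage_params_for(config, SPECIES_A), rng_a)
    prot_b, events_b = evolve_proteome(
        ancestral, lineage_params_for(config, SPECIES_B), rng_b)
    prot_out, events_out = evolve_proteome(
        ancestral, lineage_params_for(config, SPECIES_OUT), rng_out)
    proteomes = {SPECIES_A: prot_a, SPECIES_B: prot_b, SPECIES_OUT: prot_out}
    proteomes, hidden_plan, planted = plant_specific_and_hidden(
        proteomes, config, rng_plant)
    genomes, intervals = emit_genomes(proteomes, hidden_plan, config, rng_rest)
    truth = _build_truth(events_a, events_b, planted)
    # conservation: every annotated gene appears exactly once in the ledger
    for sp in (SPECIES_A, SPECIES_B):
        ledgered = truth.genes(sp)
        annotated = {r.gene_id for r in proteomes[sp]}
        if ledgered != annotated:
            raise ConfigError("truth ledger does not partition the proteome")
    aed, go = assign_aed_and_go(truth, config, rng_rest)
    events = pd.concat([events_a, events_b, events_out], ignore_index=True)
    return SimulationResult(config, proteomes, genomes, intervals,
                            truth, aed, go, events)
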