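"""Synthetic multi-omic bundles with a planted gene regulatory network.

Generates, from one seed, everything the linked-SOM analysis consumes: a
small random genome with non-overlapping gene models; a planted TF ->
target network whose edges carry cis-regulatory modules (CRMs) with exact
IUPAC motif realizations written into the sequence; decoy CRMs carrying
knockout-substituted motif variants (hard negatives); per-experiment
chromatin peak sets and read placements whose expected RPKM follows each
region's chromatin-state signature; and a TPM expression matrix with
temporal wild-type series, morpholino (MO) knockdown/control replicate
pairs, and spatial dissection profiles, under multiplicative log-normal
noise.

The generator's defaults are the study conditions for every downstream
test: 3 TFs x 20 targets, six expression modules, log2-scale noise SD
0.25, a 10x co-activator signal separation between active enhancers and
heterochromatin, and a 4x MO knockdown of true targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from somgrn.linking import GeneModel
from somgrn.motifs import IUPAC, expand_iupac, reverse_complement
from somgrn.partition import GenomicInterval, Read

# Fox-family and Sox-family consensus patterns plus generated fill-ins
DEFAULT_CONSENSI = ["AATMHACA", "ACAAWRG", "TGAYGTCA", "CATTGTYW", "GGAWTGYC"]

# published knockout substitutions for the two named motifs; generated
# motifs get two informative positions flipped to an excluded base
KNOCKOUT_SUBSTITUTIONS = {
    "AATMHACA": "AAGMHAAA",
    "ACAAWRG": "ATAGWRG",
}


def knockout_variant(consensus: str) -> str:
    """The motif-ablating substitution pattern for a consensus."""
    if consensus in KNOCKOUT_SUBSTITUTIONS:
        return KNOCKOUT_SUBSTITUTIONS[consensus]
    out = list(consensus)
    flipped = 0
    for i in range(2, len(out)):
        allowed = set(IUPAC[out[i]])
        excluded = [b for b in "ACGT" if b not in allowed]
        if excluded:
            out[i] = excluded[0]
            flipped += 1
        if flipped == 2:
            break
    return "".join(out)


@dataclass
class ChromatinState:
    """Named signature: expected RPKM per chromatin experiment (0 = silent)."""

    name: str
    signature: dict[str, float]


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 8_400_000
    n_genes: int = 150
    n_tfs: int = 3
    targets_per_tf: int = 20
    n_expression_modules: int = 6
    stages: list[str] = field(
        default_factory=lambda: ["8", "9", "10", "10.5", "11", "12"]
    )
    tissues: list[str] = field(default_factory=lambda: ["animal", "dorsal", "vegetal"])
    perturbations: list[tuple[str, str]] | None = None  # (tf id, stage); default: all TFs at stage 9
    noise_sd: float = 0.25
    chromatin_states: list[ChromatinState] | None = None
    # CRM geometry: within the 1 Mb linking window, close enough to the
    # target TSS that the target is its nearest gene at default spacing
    crm_min_dist: int = 1_000
    crm_max_dist: int = 50_000
    crm_length: int = 300
    motif_instances_per_crm: int = 4  # homotypic site cluster per CRM
    gene_length: int = 2_000
    knockdown_factor: float = 0.25
    n_replicates: int = 3
    negative_fraction: float = 0.5  # decoy CRMs per planted CRM
    n_distractor_regions: int = 240  # inactive regions dominate, as in a genome
    total_mapped: int = 20_000_000
    peak_jitter: int = 30

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs must be <= n_genes")


@dataclass
class PlantedEdge:
    tf: str
    target: str
    crm: GenomicInterval
    consensus: str


@dataclass
class PlantedGRN:
    edges: list[PlantedEdge]
    tf_consensus: dict[str, str]
    target_module: dict[str, int]
    crm_state: dict[int, str]  # crm index -> chromatin state name

    @property
    def tf_ids(self) -> list[str]:
        return sorted(self.tf_consensus)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.tf, e.target) for e in self.edges}

    def to_json(self) -> str:
        return json.dumps(
            {
                "tf_consensus": self.tf_consensus,
                "target_module": self.target_module,
                "edges": [
                    {
                        "tf": e.tf,
                        "target": e.target,
                        "crm": [e.crm.chrom, e.crm.start, e.crm.end],
                        "consensus": e.consensus,
                    }
                    for e in self.edges
                ],
            },
            indent=2,
        )


@dataclass
class RegionTruth:
    """One simulated regulatory region (planted CRM, decoy, or distractor)."""

    interval: GenomicInterval
    state: str
    kind: str  # "crm" | "decoy" | "distractor"
    tf: str | None = None
    gene: str | None = None
    scale: float = 1.0  # region-level intensity multiplier on the signature


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    grn: PlantedGRN
    regions: list[RegionTruth]
    planted_sites: pd.DataFrame  # tf, chrom, start, strand, word, kind
    peak_sets: dict[str, list[GenomicInterval]]
    reads: dict[str, list[Read]]
    total_mapped: dict[str, int]
    expression: pd.DataFrame
    experiment_meta: pd.DataFrame
    states: list[ChromatinState]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def region_sequence(self, iv: GenomicInterval) -> str:
        return self.genome[iv.chrom][iv.start : iv.end]

    def gastrulation_list(self) -> set[str]:
        """Curated-regulator stand-in derived from the planted truth: all
        planted targets and TFs plus every decoy/distractor-adjacent gene."""
        out = {e.target for e in self.grn.edges} | set(self.grn.tf_ids)
        out |= {r.gene for r in self.regions if r.gene is not None}
        return out

    def tf_growthfactor_list(self) -> set[str]:
        return self.gastrulation_list()


def _default_states(tf_ids: list[str]) -> list[ChromatinState]:
    states = []
    for tf in tf_ids:
        sig = {
            f"chip_{tf}": 50.0,
            "H3K4me1": 40.0,
            "H3K27ac": 40.0,
            "Ep300_stage9": 50.0,
            "ATAC": 40.0,
        }
        states.append(ChromatinState(name=f"active_enhancer_{tf}", signature=sig))
    states.append(ChromatinState(name="poised_enhancer", signature={"H3K4me1": 30.0, "H3K27me3": 30.0}))
    states.append(ChromatinState(name="primed_enhancer", signature={"H3K4me1": 20.0, "ATAC": 10.0}))
    states.append(ChromatinState(name="polycomb", signature={"H3K27me3": 35.0}))
    # 10x lower co-activator signal than active enhancers
    states.append(ChromatinState(name="heterochromatin", signature={"H3K9me3": 20.0, "Ep300_stage9": 5.0}))
    return states

DISTRACTOR_STATES = ["poised_enhancer", "primed_enhancer", "polycomb", "heterochromatin"]


def chromatin_experiments(states: list[ChromatinState]) -> list[str]:
    exps: set[str] = set()
    for st in states:
        exps |= set(st.signature)
    return sorted(exps)


# ------------------------------------------------------------------ genome


def generate_genome(config: SyntheticConfig, rng: np.random.Generator | None = None
                    ) -> tuple[dict[str, str], list[GeneModel]]:
    """Random uniform genome plus non-overlapping, evenly spread gene models."""
    if config.chromosome_length < 10_000:
        raise ValueError("chromosome_length must be >= 10,000")
    if config.n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    rng = rng or np.random.default_rng(config.seed)
    genome = {}
    for i in range(config.n_chromosomes):
        bases = rng.integers(0, 4, size=config.chromosome_length)
        genome[f"chr{i + 1}"] = np.frombuffer(b"ACGT", dtype="S1")[bases].tobytes().decode()

    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    genes: list[GeneModel] = []
    gid = 0
    for i, n in enumerate(per_chrom):
        chrom = f"chr{i + 1}"
        slot = config.chromosome_length / max(n, 1)
        if slot < config.gene_length + 2:
            raise ValueError(
                "genes cannot be placed without overlap: "
                f"{n} genes of {config.gene_length} bp need more than "
                f"{config.chromosome_length} bp on {chrom}"
            )
        for j in range(n):
            # jitter bounded to a third of the slot keeps neighbours apart
            jitter = rng.integers(0, max(int(slot // 3) - config.gene_length, 1))
            start = int(j * slot) + int(jitter)
            start = min(start, config.chromosome_length - config.gene_length)
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else start + config.gene_length
            tss = min(tss, config.chromosome_length - 1)
            gid += 1
            genes.append(GeneModel(f"g{gid:04d}", chrom, int(tss), strand))
    return genome, genes


# --------------------------------------------------------------------- GRN


def generate_planted_grn(
    config: SyntheticConfig,
    genes: list[GeneModel],
    rng: np.random.Generator | None = None,
) -> PlantedGRN:
    """Assign TF consensi, pick disjoint target sets, place one CRM per edge."""
    if config.n_tfs < 1 or config.targets_per_tf < 1:
        raise ValueError("need n_tfs >= 1 and targets_per_tf >= 1")
    needed = config.n_tfs * (1 + config.targets_per_tf)
    if needed > len(genes):
        raise ValueError(
            f"{config.n_tfs} TFs x {config.targets_per_tf} targets need "
            f"{needed} genes but only {len(genes)} are available"
        )
    rng = rng or np.random.default_rng(config.seed + 1)
    consensi = list(DEFAULT_CONSENSI)
    while len(consensi) < config.n_tfs:
        consensi.append("".join(rng.choice(list("ACGT"), size=8)))
    order = rng.permutation(len(genes))
    tf_idx = order[: config.n_tfs]
    target_pool = order[config.n_tfs :]
    tf_ids = [genes[i].gene_id for i in tf_idx]
    tf_consensus = {tf: consensi[k] for k, tf in enumerate(tf_ids)}
    chrom_len = {g.chrom: config.chromosome_length for g in genes}
    from somgrn.linking import GeneIndex

    gene_index = GeneIndex(genes)

    edges: list[PlantedEdge] = []
    target_module: dict[str, int] = {}
    crm_state: dict[int, str] = {}
    pos = 0
    for k, tf in enumerate(tf_ids):
        module = k  # modules 0..n_tfs-1 are reserved for TF target sets
        for _ in range(config.targets_per_tf):
            gene = genes[target_pool[pos]]
            pos += 1
            crm = _place_crm(gene, config, chrom_len, rng, gene_index)
            edges.append(PlantedEdge(tf=tf, target=gene.gene_id, crm=crm,
                                     consensus=tf_consensus[tf]))
            target_module[gene.gene_id] = module
            crm_state[len(edges) - 1] = f"active_enhancer_{tf}"
    for tf in tf_ids:
        target_module[tf] = config.n_tfs % config.n_expression_modules
    return PlantedGRN(edges=edges, tf_consensus=tf_consensus,
                      target_module=target_module, crm_state=crm_state)


def _place_crm(
    gene: GeneModel,
    config: SyntheticConfig,
    chrom_len: dict[str, int],
    rng: np.random.Generator,
    gene_index=None,
) -> GenomicInterval:
    """Place one CRM 1-50 kb from the gene's TSS.

    When a gene index is supplied, placements whose midpoint is nearer some
    other gene's TSS are rejected, so the region-to-gene linking step can in
    principle recover the edge (regulatory ambiguity between neighbouring
    genes is not part of what the planted network tests).
    """
    L = chrom_len[gene.chrom]
    fallback = None
    for _ in range(200):
        d = int(rng.integers(config.crm_min_dist, config.crm_max_dist + 1))
        side = -1 if rng.random() < 0.5 else 1
        mid = gene.tss + side * d
        start = mid - config.crm_length // 2
        end = start + config.crm_length
        if not (0 <= start and end <= L):
            continue
        iv = GenomicInterval(gene.chrom, start, end)
        if fallback is None:
            fallback = iv
        if gene_index is not None:
            near, _dist = gene_index.nearest(gene.chrom, iv.midpoint)
            if near is not None and near.gene_id != gene.gene_id:
                continue
        return iv
    if fallback is not None:
        return fallback
    start = max(0, min(gene.tss + config.crm_min_dist, L - config.crm_length))
    return GenomicInterval(gene.chrom, start, start + config.crm_length)


# ------------------------------------------------------------ motif plant


def _realize(pattern: str, rng: np.random.Generator) -> str:
    return "".join(IUPAC[c][rng.integers(0, len(IUPAC[c]))] for c in pattern)


def _scrub_pattern(seq_list: list[str], lo: int, hi: int, pattern: str,
                   protect: set[int], rng: np.random.Generator) -> None:
    """Destroy accidental matches of ``pattern`` (either strand) in [lo, hi)."""
    words = set(expand_iupac(pattern)) | {reverse_complement(w) for w in expand_iupac(pattern)}
    w = len(pattern)
    window = "".join(seq_list[lo:hi])
    for off in range(len(window) - w + 1):
        if window[off : off + w] in words:
            gpos = lo + off
            if any(gpos <= p < gpos + w for p in protect):
                continue
            j = gpos + w // 2
            cur = seq_list[j]
            seq_list[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[cur]
            window = "".join(seq_list[lo:hi])


def _plant_in_interval(
    seq_list: list[str],
    iv: GenomicInterval,
    pattern: str,
    n_instances: int,
    rng: np.random.Generator,
) -> list[tuple[int, str, str]]:
    """Write ``n_instances`` realizations of ``pattern`` into non-overlapping
    slots of the interval; returns (genome start, strand, word) per site."""
    w = len(pattern)
    if iv.length < w:
        raise ValueError(f"interval {iv} shorter than pattern {pattern}")
    n = min(n_instances, iv.length // max(w, 1))
    slot = iv.length / n
    sites = []
    for k in range(n):
        lo = int(k * slot)
        hi = min(int((k + 1) * slot), iv.length) - w
        off = int(rng.integers(lo, hi + 1)) if hi >= lo else lo
        strand = "+" if rng.random() < 0.5 else "-"
        word = _realize(pattern, rng)
        written = word if strand == "+" else reverse_complement(word)
        gpos = iv.start + off
        seq_list[gpos : gpos + w] = list(written)
        sites.append((gpos, strand, word))
    return sites


def plant_motif_instances(
    genome: dict[str, str],
    grn: PlantedGRN,
    decoys: list[RegionTruth],
    rng: np.random.Generator,
    n_instances: int = 4,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write motif realizations into CRMs and knockout variants into decoys.

    Every planted CRM receives a homotypic cluster of ``n_instances`` exact
    realizations of its TF's consensus (random strands and offsets); every
    decoy receives the same number of knockout-substituted variant
    realizations, and any accidental match of the original pattern inside a
    decoy is scrubbed.  Returns the modified genome and a truth table of
    planted sites (tf, chrom, start, strand, word, kind).
    """
    seqs = {c: list(s) for c, s in genome.items()}
    rows = []
    for edge in grn.edges:
        for gpos, strand, word in _plant_in_interval(
            seqs[edge.crm.chrom], edge.crm, edge.consensus, n_instances, rng
        ):
            rows.append((edge.tf, edge.crm.chrom, gpos, strand, word, "crm"))
    for dec in decoys:
        pattern = grn.tf_consensus[dec.tf]
        variant = knockout_variant(pattern)
        for gpos, strand, word in _plant_in_interval(
            seqs[dec.interval.chrom], dec.interval, variant, n_instances, rng
        ):
            rows.append((dec.tf, dec.interval.chrom, gpos, strand, word, "decoy"))
        _scrub_pattern(seqs[dec.interval.chrom], dec.interval.start,
                       dec.interval.end, pattern, set(), rng)
    out_genome = {c: "".join(s) for c, s in seqs.items()}
    truth = pd.DataFrame(rows, columns=["tf", "chrom", "start", "strand", "word", "kind"])
    return out_genome, truth


# ------------------------------------------------------------- expression


def _module_profiles(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_modules, n_stages) smooth temporal mean TPM profiles.

    TF-target modules (the first n_tfs) peak inside the early-stage window
    so they pass the expression filter; every module peaks at a distinct
    time with amplitude 20-60 TPM over a baseline of 1.
    """
    n_stages = len(config.stages)
    prof = np.zeros((config.n_expression_modules, n_stages))
    for m in range(config.n_expression_modules):
        if m < config.n_tfs:
            center = rng.uniform(0.5, min(3.0, n_stages - 1))
        else:
            center = rng.uniform(0, n_stages - 1)
        width = rng.uniform(0.9, 1.6)
        amp = rng.uniform(20, 60)
        t = np.arange(n_stages)
        prof[m] = 1.0 + amp * np.exp(-((t - center) ** 2) / (2 * width**2))
    return prof


def generate_expression_matrix(
    config: SyntheticConfig,
    grn: PlantedGRN,
    genes: list[GeneModel],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TPM matrix (genes x experiments) plus per-column metadata.

    Columns: one wild-type column per stage; one column per dissected
    tissue plus a whole-embryo reference; per perturbation, MO and control
    replicate columns at the perturbed stage.  Observed TPM =
    mean * 2^Normal(0, noise_sd).
    """
    if len(config.stages) < 2:
        raise ValueError("need >=2 stages")
    rng = rng or np.random.default_rng(config.seed + 2)
    perturbations = config.perturbations
    if perturbations is None:
        perturbations = [(tf, "9" if "9" in config.stages else config.stages[1])
                         for tf in grn.tf_ids]
    for tf, _stage in perturbations:
        if tf not in grn.tf_consensus:
            raise ValueError(f"perturbation names unknown TF {tf!r}")

    profiles = _module_profiles(config, rng)
    n_stages = len(config.stages)
    gene_ids = [g.gene_id for g in genes]
    module_of = {
        gid: grn.target_module.get(gid, int(rng.integers(config.n_tfs, config.n_expression_modules)))
        for gid in gene_ids
    }
    # per-module x tissue multiplicative spatial offsets (log2 in +-2)
    tissue_factor = 2.0 ** rng.uniform(-2, 2, size=(config.n_expression_modules, len(config.tissues)))

    targets_of = {tf: set() for tf in grn.tf_ids}
    for e in grn.edges:
        targets_of[e.tf].add(e.target)

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    mods = np.array([module_of[g] for g in gene_ids])
    wt = profiles[mods]  # (n_genes, n_stages)
    for si, stage in enumerate(config.stages):
        cols[f"wt_{stage}"] = wt[:, si]
        meta_rows.append((f"wt_{stage}", "wildtype", stage, "", "", ""))
    # spatial columns at the mid time point; whole embryo = plain mean
    mid = min(3, n_stages - 1)
    cols["tissue_whole"] = wt[:, mid]
    meta_rows.append(("tissue_whole", "spatial", config.stages[mid], "whole", "", ""))
    for ti, tissue in enumerate(config.tissues):
        cols[f"tissue_{tissue}"] = wt[:, mid] * tissue_factor[mods, ti]
        meta_rows.append((f"tissue_{tissue}", "spatial", config.stages[mid], tissue, "", ""))
    for tf, stage in perturbations:
        si = config.stages.index(stage) if stage in config.stages else mid
        kd = np.where(np.isin(gene_ids, list(targets_of[tf])), config.knockdown_factor, 1.0)
        for rep in range(1, config.n_replicates + 1):
            mo_name = f"{tf}_MO_rep{rep}"
            ct_name = f"{tf}_ctrl_rep{rep}"
            cols[mo_name] = wt[:, si] * kd
            cols[ct_name] = wt[:, si]
            meta_rows.append((mo_name, "knockdown", stage, "", tf, ct_name))
            meta_rows.append((ct_name, "control", stage, "", tf, ""))

    mat = pd.DataFrame(cols, index=gene_ids)
    if config.noise_sd > 0:
        noise = 2.0 ** rng.normal(0.0, config.noise_sd, size=mat.shape)
        mat = mat * noise
    meta = pd.DataFrame(
        meta_rows,
        columns=["experiment", "condition", "stage", "tissue", "perturbed_tf", "control_pair"],
    ).set_index("experiment")
    return mat, meta


# --------------------------------------------------------------- chromatin


def make_regions(
    config: SyntheticConfig,
    grn: PlantedGRN,
    genes: list[GeneModel],
    rng: np.random.Generator,
) -> list[RegionTruth]:
    """Planted CRMs + decoy CRMs (near non-target genes) + distractors."""
    regions = [
        RegionTruth(interval=e.crm, state=grn.crm_state[i], kind="crm",
                    tf=e.tf, gene=e.target)
        for i, e in enumerate(grn.edges)
    ]
    target_ids = {e.target for e in grn.edges} | set(grn.tf_ids)
    free_genes = [g for g in genes if g.gene_id not in target_ids]
    rng.shuffle(free_genes)
    n_decoys = int(round(config.negative_fraction * len(grn.edges)))
    chrom_len = {g.chrom: config.chromosome_length for g in genes}
    tf_cycle = grn.tf_ids
    for i in range(min(n_decoys, len(free_genes))):
        gene = free_genes[i]
        tf = tf_cycle[i % len(tf_cycle)]
        iv = _place_crm(gene, config, chrom_len, rng)
        regions.append(RegionTruth(interval=iv, state=f"active_enhancer_{tf}",
                                   kind="decoy", tf=tf, gene=gene.gene_id))
    # distractors: random positions, inactive chromatin states with a
    # continuous per-region intensity (chromatin signal is a spectrum, not
    # a few discrete levels)
    for i in range(config.n_distractor_regions):
        chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
        start = int(rng.integers(0, config.chromosome_length - config.crm_length))
        state = DISTRACTOR_STATES[i % len(DISTRACTOR_STATES)]
        regions.append(RegionTruth(
            interval=GenomicInterval(chrom, start, start + config.crm_length),
            state=state, kind="distractor",
            scale=float(2.0 ** rng.uniform(-2, 2))))
    return regions


def generate_chromatin_data(
    config: SyntheticConfig,
    regions: list[RegionTruth],
    states: list[ChromatinState],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[GenomicInterval]], dict[str, list[Read]], dict[str, int]]:
    """Per-experiment peak sets and read placements from state signatures.

    A region emits a peak (edge-jittered per experiment) in every experiment
    its state marks; 50 bp reads are placed uniformly with a Poisson count
    whose expectation makes the region's expected RPKM equal the signature
    level.  All-zero signatures emit nothing.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    state_by_name = {s.name: s for s in states}
    experiments = chromatin_experiments(states)
    for r in regions:
        if r.state not in state_by_name:
            raise ValueError(f"region references unknown chromatin state {r.state!r}")
    peaks: dict[str, list[GenomicInterval]] = {e: [] for e in experiments}
    reads: dict[str, list[Read]] = {e: [] for e in experiments}
    total_mapped = {e: config.total_mapped for e in experiments}
    for r in regions:
        sig = state_by_name[r.state].signature
        iv = r.interval
        for exp in experiments:
            level = sig.get(exp, 0.0)
            if level <= 0:
                continue
            j1 = int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
            j2 = int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
            start = max(0, iv.start + j1)
            end = min(config.chromosome_length, iv.end + j2)
            if end - start < 50:
                start, end = iv.start, iv.end
            peaks[exp].append(GenomicInterval(iv.chrom, start, end))
            # expected RPKM = signature level x region intensity, with
            # log-normal experiment-level wobble
            level_obs = level * r.scale
            if config.noise_sd:
                level_obs *= 2.0 ** rng.normal(0.0, config.noise_sd)
            lam = level_obs * iv.length * total_mapped[exp] / 1e9
            n_reads = int(rng.poisson(lam))
            if n_reads:
                starts = rng.integers(iv.start, max(iv.end - 50, iv.start + 1), size=n_reads)
                for s in starts:
                    reads[exp].append(Read(iv.chrom, int(s), int(s) + 50, "+"))
    return peaks, reads, total_mapped


# ------------------------------------------------------------------ bundle


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the full synthetic study from one seed (deterministic)."""
    root = np.random.default_rng(config.seed)
    # independent child streams so stage order never perturbs another stage
    r_genome, r_grn, r_regions, r_plant, r_expr, r_chrom = (
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(6)
    )
    del root
    genome, genes = generate_genome(config, r_genome)
    grn = generate_planted_grn(config, genes, r_grn)
    regions = make_regions(config, grn, genes, r_regions)
    decoys = [r for r in regions if r.kind == "decoy"]
    genome, planted_sites = plant_motif_instances(
        genome, grn, decoys, r_plant, n_instances=config.motif_instances_per_crm
    )
    expression, experiment_meta = generate_expression_matrix(config, grn, genes, r_expr)
    states = config.chromatin_states or _default_states(grn.tf_ids)
    peak_sets, reads, total_mapped = generate_chromatin_data(config, regions, states, r_chrom)
    return SyntheticBundle(
        config=config,
        genome=genome,
        genes=genes,
        grn=grn,
        regions=regions,
        planted_sites=planted_sites,
        peak_sets=peak_sets,
        reads=reads,
        total_mapped=total_mapped,
        expression=expression,
        experiment_meta=experiment_meta,
        states=states,
    )


# ------------------------------------------------------------------- I/O


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write the bundle as FASTA / BED / TSV / JSON files."""
    from pathlib import Path

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(s), id=c, description="") for c, s in bundle.genome.items()]
    SeqIO.write(records, out / "genome.fa", "fasta")
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand) for g in bundle.genes],
        columns=["gene_id", "chrom", "tss", "strand"],
    ).to_csv(out / "genes.tsv", sep="\t", index=False)
    for exp, peaks in bundle.peak_sets.items():
        with open(out / f"peaks_{exp}.bed", "w") as fh:
            for iv in peaks:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    for exp, rds in bundle.reads.items():
        with open(out / f"reads_{exp}.bed", "w") as fh:
            for rd in rds:
                fh.write(f"{rd.chrom}\t{rd.start}\t{rd.end}\t.\t0\t{rd.strand}\n")
    bundle.expression.to_csv(out / "expression.tsv", sep="\t")
    bundle.experiment_meta.to_csv(out / "experiments.tsv", sep="\t")
    (out / "grn_truth.json").write_text(bundle.grn.to_json())
    bundle.planted_sites.to_csv(out / "planted_sites.tsv", sep="\t", index=False)
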