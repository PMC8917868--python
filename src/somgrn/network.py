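"""Filter cascade, network assembly, FPR/FDR estimation and CRM scoring.

Enriched motif instances are passed through the multi-stage cascade: keep
instances whose region's DNA metacluster has TF ChIP signal in the top
percentile of metacluster means AND enriched co-activator (Ep300) signal,
and whose linked gene's RNA metacluster is expressed (>min_tpm) in the
stages of interest; then restrict linked genes to a curated regulator list
and finally to TFs/growth factors.  Surviving (TF, target) pairs become
network edges carrying their supporting CRMs.

The false-positive rate is estimated against a true-negative gene set
built by intersecting, across knockdown experiments, genes called
significantly UNchanging by an equivalence (TOST) test on log2 fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from somgrn.motifs import bh_qvalues
from somgrn.partition import GenomicInterval

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- filters


def _metacluster_means(
    region_metaclusters: pd.Series, signal: pd.DataFrame, experiment: str
) -> pd.Series:
    if experiment not in signal.columns:
        raise KeyError(f"experiment {experiment!r} not in signal matrix")
    col = signal[experiment]
    means = {}
    for lab in sorted(region_metaclusters.unique()):
        regions = region_metaclusters.index[region_metaclusters == lab]
        regions = regions.intersection(signal.index)
        if len(regions) == 0:
            logger.warning("DNA metacluster %s has no regions in matrix; excluded", lab)
            continue
        means[lab] = float(col.loc[regions].mean())
    return pd.Series(means)


def chip_percentile_filter(
    region_metaclusters: pd.Series,
    signal: pd.DataFrame,
    experiment: str,
    percentile: float = 75.0,
) -> set[int]:
    """DNA metaclusters whose mean RPKM for ``experiment`` reaches the given
    percentile (linear interpolation) of per-metacluster means."""
    means = _metacluster_means(region_metaclusters, signal, experiment)
    if means.empty:
        return set()
    cutoff = float(np.percentile(means.to_numpy(), percentile))
    return set(means.index[means >= cutoff].astype(int))


def ep300_filter(
    region_metaclusters: pd.Series,
    signal: pd.DataFrame,
    ep300_experiment: str,
    percentile: float = 75.0,
) -> set[int]:
    """'Enriched' co-activator signal: same percentile rule on the Ep300 column."""
    return chip_percentile_filter(region_metaclusters, signal, ep300_experiment, percentile)


def expression_filter(
    profiles: pd.DataFrame,
    stages: list[str],
    min_tpm: float = 1.0,
) -> set[int]:
    """RNA metaclusters whose eigen-profile exceeds ``min_tpm`` in >=1 stage.

    ``profiles`` are mean member TPM per metacluster (rows) x experiment
    columns; ``stages`` names the columns to examine.
    """
    missing = [s for s in stages if s not in profiles.columns]
    if missing:
        raise KeyError(f"stage columns missing from profiles: {missing}")
    sub = profiles[stages]
    keep = (sub > min_tpm).any(axis=1)
    return set(sub.index[keep].astype(int))


# ------------------------------------------------------------- the network


@dataclass
class RegulatoryEdge:
    tf: str
    target: str
    crms: list[int]
    motif_hits: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    effect_scores: dict = field(default_factory=dict)


@dataclass
class RegulatoryNetwork:
    edges: list[RegulatoryEdge]
    cascade: pd.DataFrame  # stage name -> n_motifs, n_genes

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for e in self.edges:
            g.add_edge(e.tf, e.target, n_crms=len(e.crms))
        return g

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.tf, e.target) for e in self.edges}

    def targets_of(self, tf: str) -> set[str]:
        return {e.target for e in self.edges if e.tf == tf}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "tf": e.tf,
                    "target": e.target,
                    "n_crms": len(e.crms),
                    **{f"score_{k}": v for k, v in e.effect_scores.items()},
                }
                for e in self.edges
            ]
        )


def assemble_network(
    enriched_hits: pd.DataFrame,
    lm_map,
    region_metaclusters: pd.Series,
    gene_metaclusters: pd.Series,
    retained_dna_chip: dict[str, set[int]],
    retained_dna_ep300: set[int],
    retained_rna: set[int],
    gastrulation_genes: set[str] | None = None,
    tf_growthfactor_genes: set[str] | None = None,
) -> RegulatoryNetwork:
    """Apply the filter cascade to enriched motif instances and emit edges.

    ``enriched_hits`` must carry columns motif (the TF), region; each TF has
    its own ChIP-percentile-retained DNA metacluster set in
    ``retained_dna_chip``.  The cascade stages are recorded with motif and
    unique-gene counts so monotonicity can be audited.
    """
    # region -> linked gene lookup from the LM map
    region_gene: dict[int, str] = {}
    for (_r, _d), pairs in lm_map.bins.items():
        for region, gene, _dist in pairs:
            region_gene[region] = gene

    df = enriched_hits.copy()
    stages = []

    def record(stage: str, frame: pd.DataFrame) -> None:
        genes = frame["region"].map(region_gene).dropna()
        stages.append((stage, len(frame), genes.nunique()))

    record("enriched_motif_instances", df)

    dna_mc = region_metaclusters.to_dict()
    gene_mc = gene_metaclusters.to_dict()

    def _region_dna_ok(row) -> bool:
        mc = dna_mc.get(row["region"])
        chip_keep = retained_dna_chip.get(row["motif"], set())
        return mc is not None and mc in chip_keep

    if len(df):
        df = df[df.apply(_region_dna_ok, axis=1)]
    record("tf_chip_percentile", df)

    if len(df):
        df = df[df["region"].map(lambda r: dna_mc.get(r) in retained_dna_ep300)]
    record("ep300_enriched", df)

    def _gene_rna_ok(region) -> bool:
        g = region_gene.get(region)
        return g is not None and gene_mc.get(g) in retained_rna
    if len(df):
        df = df[df["region"].map(_gene_rna_ok)]
    record("rna_expression", df)

    if gastrulation_genes is not None and len(df):
        df = df[df["region"].map(lambda r: region_gene.get(r) in gastrulation_genes)]
    record("gastrulation_list", df)

    if tf_growthfactor_genes is not None and len(df):
        df = df[df["region"].map(lambda r: region_gene.get(r) in tf_growthfactor_genes)]
    record("tf_growthfactor_list", df)

    edges: list[RegulatoryEdge] = []
    if len(df):
        df = df.assign(target=df["region"].map(region_gene))
        for (tf, target), grp in df.groupby(["motif", "target"], sort=True):
            edges.append(
                RegulatoryEdge(
                    tf=str(tf),
                    target=str(target),
                    crms=sorted(grp["region"].unique().tolist()),
                    motif_hits=grp.reset_index(drop=True),
                    provenance={
                        "tf_chip_percentile": True,
                        "ep300_enriched": True,
                        "rna_expression": True,
                        "gastrulation_list": gastrulation_genes is not None,
                        "tf_growthfactor_list": tf_growthfactor_genes is not None,
                    },
                )
            )
    cascade = pd.DataFrame(stages, columns=["stage", "n_motifs", "n_genes"])
    return RegulatoryNetwork(edges=edges, cascade=cascade)


# ------------------------------------------------- unchanging genes & FPR


def unchanging_test(
    mo: pd.DataFrame,
    control: pd.DataFrame,
    lfc_threshold: float = 0.5,
    pseudocount: float = 1.0,
    stabilizer: float = 0.05,
) -> pd.DataFrame:
    """Equivalence (TOST) test that |log2 FC| < ``lfc_threshold`` per gene.

    ``mo`` and ``control`` are genes x replicates (TPM).  Per gene the
    log2(x + pseudocount) replicate means are compared; per-gene replicate
    variances are moderated toward the across-gene mean variance (few
    replicates make raw per-gene variances unusably noisy), and a small
    additive stabilizer guards all-zero genes.  p = max of the two
    one-sided p-values; BH across genes; a gene is called unchanging at
    q < 0.05.
    """
    if mo.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("need >=2 replicates per arm")
    lm = np.log2(mo.to_numpy(dtype=float) + pseudocount)
    lc = np.log2(control.to_numpy(dtype=float) + pseudocount)
    n1, n2 = lm.shape[1], lc.shape[1]
    lfc = lm.mean(axis=1) - lc.mean(axis=1)
    # pooled within-gene variance, shrunk toward its genome-wide mean
    # (empirical-Bayes moderation with a fixed prior weight)
    v_gene = (lm.var(axis=1, ddof=1) * (n1 - 1) + lc.var(axis=1, ddof=1) * (n2 - 1)) / (
        n1 + n2 - 2
    )
    d_resid = n1 + n2 - 2
    d_prior = 10.0
    v_prior = float(np.mean(v_gene))
    v_mod = (d_prior * v_prior + d_resid * v_gene) / (d_prior + d_resid)
    var = v_mod * (1.0 / n1 + 1.0 / n2)
    se = np.sqrt(var + stabilizer**2)
    z_lo = (lfc + lfc_threshold) / se   # H0: lfc <= -thr vs H1: lfc > -thr
    z_hi = (lfc - lfc_threshold) / se   # H0: lfc >= +thr vs H1: lfc < +thr
    p_lo = stats.norm.sf(z_lo)
    p_hi = stats.norm.cdf(z_hi)
    p = np.maximum(p_lo, p_hi)
    q = bh_qvalues(p)
    degenerate = (mo.var(axis=1).to_numpy() == 0) & (lfc == 0)
    return pd.DataFrame(
        {"log2fc": lfc, "se": se, "p": p, "q": q,
         "unchanging": q < 0.05, "degenerate": degenerate},
        index=mo.index,
    )


def true_negative_set(unchanging_calls: list[set[str]]) -> set[str]:
    """Genes called unchanging in EVERY condition (set intersection)."""
    if not unchanging_calls:
        raise ValueError("need >=1 condition")
    out = set(unchanging_calls[0])
    for calls in unchanging_calls[1:]:
        out &= set(calls)
    return out


def fpr_fdr(predicted: set[str], true_negatives: set[str]) -> tuple[float, float]:
    """FPR = 100 * |TN ∩ P| / |TN|; FDR = 100 * |TN ∩ P| / |P| (percent)."""
    if not true_negatives:
        raise ValueError("true-negative set is empty; FPR undefined")
    overlap = len(set(predicted) & set(true_negatives))
    fpr = 100.0 * overlap / len(true_negatives)
    fdr = 100.0 * overlap / len(predicted) if predicted else 0.0
    return fpr, fdr


def fpr_fdr_from_counts(n_overlap: int, n_true_negative: int, n_predicted: int) -> tuple[float, float]:
    """FPR/FDR in percent directly from set sizes."""
    if n_true_negative <= 0:
        raise ValueError("true-negative count must be > 0")
    fpr = 100.0 * n_overlap / n_true_negative
    fdr = 100.0 * n_overlap / n_predicted if n_predicted else 0.0
    return fpr, fdr


# ----------------------------------------------------------- CRM scoring


SCORE_COMPONENTS = ("h3k4me1", "h3k27ac", "ep300", "tf_signal_density", "chromatin_accessibility")


def crm_effect_scores(
    crm_partitions: dict[int, list[int]],
    signal: pd.DataFrame,
    experiment_groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Six per-CRM scores: five signal-group means plus their combined mean.

    ``experiment_groups`` maps each of the five component names (h3k4me1,
    h3k27ac, ep300, tf_signal_density, chromatin_accessibility) to >=1
    signal-matrix column; each component score is the mean RPKM over the
    group's experiments over the CRM's partitions; ``combined`` is the
    arithmetic mean of the five components.
    """
    for comp in SCORE_COMPONENTS:
        if comp not in experiment_groups or not experiment_groups[comp]:
            raise ValueError(f"experiment group {comp!r} is empty or missing")
    rows = {}
    for crm, parts in crm_partitions.items():
        scores = {}
        for comp in SCORE_COMPONENTS:
            cols = experiment_groups[comp]
            scores[comp] = float(signal.loc[parts, cols].to_numpy().mean())
        scores["combined"] = float(np.mean([scores[c] for c in SCORE_COMPONENTS]))
        rows[crm] = scores
    return pd.DataFrame.from_dict(rows, orient="index")


def score_validation_agreement(
    scorecards: pd.DataFrame,
    observed_effects: pd.Series,
) -> pd.DataFrame:
    """Spearman rank correlation of each scoring method with observed effects.

    Rows are CRMs; the observed effect magnitudes are aligned on the CRM
    index.  Methods are ranked by correlation (ties reported); a constant
    score vector yields an undefined correlation and is flagged.
    """
    shared = scorecards.index.intersection(observed_effects.index)
    if len(shared) < 3:
        raise ValueError("need >=3 CRMs with observed effects")
    obs = observed_effects.loc[shared].abs()
    rows = []
    for method in scorecards.columns:
        vals = scorecards.loc[shared, method]
        if vals.nunique() <= 1:
            rows.append((method, np.nan, True))
            continue
        rho = stats.spearmanr(vals, obs).statistic
        rows.append((method, float(rho), False))
    out = pd.DataFrame(rows, columns=["method", "spearman_r", "degenerate"])
    out = out.sort_values("spearman_r", ascending=False, na_position="last")
    out["rank"] = out["spearman_r"].rank(ascending=False, method="min")
    return out.reset_index(drop=True)


def spatial_regulator_classification(
    tf_profile: pd.Series,
    target_mean_profile: pd.Series,
    tf_significant: bool = True,
) -> dict:
    """Pearson correlation of a TF's spatial profile with its targets' mean.

    Positive correlation labels the TF an activator, negative a repressor.
    The label is only reported when the TF's own spatial differential test
    is significant.
    """
    if len(tf_profile) < 3 or len(tf_profile) != len(target_mean_profile):
        raise ValueError("profiles must share >=3 ordered tissue columns")
    a = tf_profile.to_numpy(dtype=float)
    b = target_mean_profile.to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        return {"r": np.nan, "label": "undefined", "reported": False}
    r = float(stats.pearsonr(a, b).statistic)
    label = "activator" if r > 0 else "repressor" if r < 0 else "ambiguous"
    return {"r": r, "label": label, "reported": bool(tf_significant)}


# ------------------------------------------------ overlap permutation test


def region_overlap_permutation(
    predicted: list[GenomicInterval],
    holdout: list[GenomicInterval],
    chrom_lengths: dict[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Circular-shift permutation test of region-set overlap.

    Observed statistic: number of predicted regions overlapping >=1 holdout
    peak.  Null: per permutation, each chromosome's predicted regions are
    circularly shifted by one uniform offset (wrap-around) and the overlap
    recount.  p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    hold_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {h.chrom for h in holdout}:
        ivs = sorted((h.start, h.end) for h in holdout if h.chrom == chrom)
        merged: list[list[int]] = []  # union, so ends stay sorted for bisection
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        hold_by_chrom[chrom] = (
            np.array([s for s, _ in merged]),
            np.array([e for _, e in merged]),
        )

    def _piece_hits(chrom: str, s: int, e: int) -> bool:
        idx = hold_by_chrom.get(chrom)
        if idx is None:
            return False
        starts, ends = idx
        j = np.searchsorted(ends, s, side="right")
        return j < len(starts) and starts[j] < e

    def count_overlaps(regions: list[list[tuple[str, int, int]]]) -> int:
        # each region is a list of pieces (wrap-around splits); counted once
        return sum(any(_piece_hits(*pc) for pc in pieces) for pieces in regions)

    base = [(p.chrom, p.start, p.end) for p in predicted]
    observed = count_overlaps([[r] for r in base])
    chroms = sorted({c for c, _, _ in base})
    null = np.empty(n_perm, dtype=int)
    for it in range(n_perm):
        shifted: list[list[tuple[str, int, int]]] = []
        offsets = {c: int(rng.integers(0, chrom_lengths[c])) for c in chroms}
        for chrom, s, e in base:
            L = chrom_lengths[chrom]
            ns = (s + offsets[chrom]) % L
            ne = ns + (e - s)
            if ne <= L:
                shifted.append([(chrom, ns, ne)])
            else:  # wrap-around: split into the two arcs
                shifted.append([(chrom, ns, L), (chrom, 0, ne - L)])
        null[it] = count_overlaps(shifted)
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return {"observed": observed, "null": null, "p": float(p)}
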