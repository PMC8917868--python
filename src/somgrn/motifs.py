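"""PWM/IUPAC motif scanning with exact p-values and density enrichment.

Motifs are position weight matrices scored as log2 likelihood ratios
against a background nucleotide distribution.  Per-position p-values are
exact: the null distribution of the discretized score under the background
model is built by position-wise convolution (dynamic programming), so
p(hit) = P(score >= observed) at a single position and strand with no
sampling error beyond the score discretization.  Hits are filtered by
Benjamini-Hochberg q-value (family = all scanned positions of one motif
across the region set), and per-linked-metacluster motif density is tested
with a one-tailed z-score against the pooled global proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def expand_iupac(pattern: str) -> list[str]:
    """All exact words matched by an IUPAC pattern."""
    words = [""]
    for code in pattern.upper():
        if code not in IUPAC:
            raise ValueError(f"invalid IUPAC code {code!r}")
        words = [w + b for w in words for b in IUPAC[code]]
    return words


UNIFORM_BG = np.full(4, 0.25)


@dataclass
class PWM:
    """Position weight matrix over {A,C,G,T} with its background model."""

    motif_id: str
    probs: np.ndarray  # (w, 4), rows sum to 1
    background: np.ndarray = None
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.background is None:
            self.background = UNIFORM_BG.copy()
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM probs must be (w, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def score_matrix(self) -> np.ndarray:
        """(w, 4) log2 likelihood-ratio scores; -inf where P_pwm = 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(self.background)[None, :]

    def score_word(self, word: str) -> float:
        sm = self.score_matrix()
        return float(sum(sm[i, _BASE_INDEX[b]] for i, b in enumerate(word.upper())))

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id,
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background,
            pseudocount=self.pseudocount,
        )

    def max_score(self) -> float:
        return float(self.score_matrix().max(axis=1).sum())


def pwm_from_sites(
    sites: list[str],
    motif_id: str = "motif",
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
) -> PWM:
    """Build a PWM from aligned equal-length binding sites.

    P(position j, base b) = (count + pseudocount) / (n + 4 * pseudocount).
    """
    if len(sites) < 2:
        raise ValueError("need >=2 sites")
    w = len(sites[0])
    if any(len(s) != w for s in sites):
        raise ValueError("sites must all have equal length")
    counts = np.zeros((w, 4))
    for s in sites:
        for j, b in enumerate(s.upper()):
            if b not in _BASE_INDEX:
                raise ValueError(f"site base {b!r} outside ACGT")
            counts[j, _BASE_INDEX[b]] += 1
    probs = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    return PWM(motif_id=motif_id, probs=probs, background=background, pseudocount=pseudocount)


def iupac_to_pwm(
    pattern: str,
    motif_id: str | None = None,
    pseudocount: float = 0.0,
    background: np.ndarray | None = None,
) -> PWM:
    """PWM with each position uniform over the IUPAC code's base set."""
    pattern = pattern.upper()
    w = len(pattern)
    probs = np.zeros((w, 4))
    for j, code in enumerate(pattern):
        if code not in IUPAC:
            raise ValueError(f"invalid IUPAC code {code!r} in {pattern!r}")
        allowed = [_BASE_INDEX[b] for b in IUPAC[code]]
        probs[j, allowed] = 1.0 / len(allowed)
    if pseudocount > 0:
        probs = (probs + pseudocount) / (1.0 + 4 * pseudocount)
    return PWM(motif_id=motif_id or pattern, probs=probs, background=background,
               pseudocount=pseudocount)


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (incl. N) -> -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _scores_along(encoded: np.ndarray, sm: np.ndarray) -> np.ndarray:
    """Score every offset of a (w,4) score matrix along an encoded sequence.

    Positions whose window contains a non-ACGT base score -inf (skipped).
    """
    w = sm.shape[0]
    n = len(encoded) - w + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(w):
        window = encoded[j : j + n]
        ok = window >= 0
        valid &= ok
        idx = np.where(ok, window, 0)
        col = sm[j]
        contrib = col[idx]
        scores += np.where(ok, contrib, 0.0)
    scores[~valid] = -np.inf
    return scores


def scan_regions(
    sequences: dict, pwm: PWM, both_strands: bool = True
) -> pd.DataFrame:
    """Score every offset of every region on one or both strands.

    Offsets are 0-based on the forward strand; a '-' strand row means the
    reverse complement of the window matches the motif.  Windows containing
    non-ACGT bases are skipped.
    """
    sm = pwm.score_matrix()
    sm_rc = pwm.reverse_complement().score_matrix()
    rows = []
    for region_id, seq in sequences.items():
        enc = encode_sequence(seq)
        if len(enc) < pwm.width:
            logger.info("region %s shorter than motif width", region_id)
            continue
        fwd = _scores_along(enc, sm)
        strands = [("+", fwd)]
        if both_strands:
            strands.append(("-", _scores_along(enc, sm_rc)))
        for strand, sc in strands:
            for off in np.flatnonzero(np.isfinite(sc)):
                rows.append((region_id, int(off), strand, float(sc[off])))
    return pd.DataFrame(rows, columns=["region", "offset", "strand", "score"])


@dataclass
class ScoreDistribution:
    """Exact discretized null distribution of the PWM score under background."""

    granularity: float
    offset: int  # bin index of array position 0
    pmf: np.ndarray
    sf: np.ndarray  # sf[i] = P(score_bin >= offset + i)

    def discretize(self, score: float) -> int:
        return int(np.rint(score / self.granularity))

    def pvalue(self, score) -> np.ndarray | float:
        """P(score >= observed) at one position/strand, exact up to binning."""
        b = np.rint(np.asarray(score, dtype=float) / self.granularity).astype(int) - self.offset
        b = np.clip(b, 0, len(self.sf))
        sf_ext = np.append(self.sf, 0.0)
        out = sf_ext[b]
        return float(out) if np.isscalar(score) else out


def binned_score_matrix(pwm: PWM, granularity: float) -> np.ndarray:
    """(w, 4) integer score bins at ``granularity`` bits per bin.

    Zero-probability PWM entries (score -inf) are floored well below any
    achievable score so the support stays finite; such words always land
    in the far-left tail.
    """
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    sm = pwm.score_matrix()
    finite = sm[np.isfinite(sm)]
    span = float(finite.max() - finite.min()) if finite.size else 1.0
    floor = (finite.min() if finite.size else 0.0) - (span + 1.0) * pwm.width
    sm = np.where(np.isfinite(sm), sm, floor)
    return np.rint(sm / granularity).astype(np.int64)


def score_pvalues(pwm: PWM, granularity: float = 1e-3) -> ScoreDistribution:
    """Exact null score distribution via position-wise convolution.

    Per-position scores are discretized to ``granularity`` bits and the
    per-position distributions under the background model are convolved,
    giving the exact (up to binning) distribution of the score at one
    position and strand.
    """
    bins = binned_score_matrix(pwm, granularity)
    bg = pwm.background
    pmf = np.zeros(1)
    pmf[0] = 1.0
    cur_lo = 0
    used = 1
    for j in range(pwm.width):
        row = bins[j]
        rlo, rhi = int(row.min()), int(row.max())
        new = np.zeros(used + (rhi - rlo))
        for b in range(4):
            shift = int(row[b]) - rlo
            new[shift : shift + used] += bg[b] * pmf[:used]
        pmf = new
        used = len(new)
        cur_lo += rlo
    sf = np.cumsum(pmf[::-1])[::-1]
    return ScoreDistribution(granularity=granularity, offset=cur_lo, pmf=pmf, sf=sf)


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def scan_with_qvalues(
    sequences: dict,
    pwm: PWM,
    granularity: float = 1e-3,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Scan regions, attach exact p-values and BH q-values, keep q < threshold.

    Scanning uses the same discretized score matrix as the DP null, so every
    observed score coincides exactly with an atom of the null distribution.
    The BH family is every scanned position of this motif across the whole
    region set (both strands).
    """
    dist = score_pvalues(pwm, granularity=granularity)
    bins = binned_score_matrix(pwm, granularity)
    sm = bins.astype(float)  # integer-bin scores; multiply by granularity at the end
    sm_rc = sm[::-1, ::-1].copy()
    regions: list = []
    offsets: list[int] = []
    strands: list[str] = []
    scores: list[float] = []
    for region_id, seq in sequences.items():
        enc = encode_sequence(seq)
        if len(enc) < pwm.width:
            logger.info("region %s shorter than motif width", region_id)
            continue
        for strand, mat in (("+", sm), ("-", sm_rc)):
            sc = _scores_along(enc, mat)
            idx = np.flatnonzero(np.isfinite(sc))
            regions.extend([region_id] * len(idx))
            offsets.extend(idx.tolist())
            strands.extend([strand] * len(idx))
            scores.extend(sc[idx].tolist())
    if not scores:
        return pd.DataFrame(
            columns=["motif", "region", "offset", "strand", "score", "p", "q"]
        )
    score_bins = np.rint(np.asarray(scores)).astype(np.int64)
    sf_ext = np.append(dist.sf, 0.0)
    b = np.clip(score_bins - dist.offset, 0, len(dist.sf))
    p = sf_ext[b]
    q = bh_qvalues(p)
    keep = q < q_threshold
    out = pd.DataFrame(
        {
            "motif": pwm.motif_id,
            "region": np.asarray(regions, dtype=object)[keep],
            "offset": np.asarray(offsets)[keep],
            "strand": np.asarray(strands, dtype=object)[keep],
            "score": score_bins[keep] * granularity,
            "p": p[keep],
            "q": q[keep],
        }
    ).reset_index(drop=True)
    return out


def scan_grouped_qvalues(
    sequences: dict,
    pwm: PWM,
    groups: dict,
    granularity: float = 1e-3,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Scan regions with the BH family defined per region group.

    ``groups`` maps region id -> family key (e.g. the linked metacluster the
    region belongs to); q-values are computed independently within each
    family over every scanned position of that family's regions (both
    strands), mirroring a separate scanner run per group.  Regions missing
    from ``groups`` form their own pooled family under the key ``None``.
    """
    dist = score_pvalues(pwm, granularity=granularity)
    bins = binned_score_matrix(pwm, granularity)
    sm = bins.astype(float)
    sm_rc = sm[::-1, ::-1].copy()
    sf_ext = np.append(dist.sf, 0.0)
    frames = []
    by_group: dict = {}
    for region_id in sequences:
        by_group.setdefault(groups.get(region_id), []).append(region_id)
    for key, region_ids in by_group.items():
        regions, offsets, strands, scores = [], [], [], []
        for region_id in region_ids:
            enc = encode_sequence(sequences[region_id])
            if len(enc) < pwm.width:
                continue
            for strand, mat in (("+", sm), ("-", sm_rc)):
                sc = _scores_along(enc, mat)
                idx = np.flatnonzero(np.isfinite(sc))
                regions.extend([region_id] * len(idx))
                offsets.extend(idx.tolist())
                strands.extend([strand] * len(idx))
                scores.extend(sc[idx].tolist())
        if not scores:
            continue
        score_bins = np.rint(np.asarray(scores)).astype(np.int64)
        b = np.clip(score_bins - dist.offset, 0, len(dist.sf))
        p = sf_ext[b]
        q = bh_qvalues(p)
        keep = q < q_threshold
        if not keep.any():
            continue
        frames.append(pd.DataFrame({
            "motif": pwm.motif_id,
            "region": np.asarray(regions, dtype=object)[keep],
            "offset": np.asarray(offsets)[keep],
            "strand": np.asarray(strands, dtype=object)[keep],
            "score": score_bins[keep] * granularity,
            "p": p[keep],
            "q": q[keep],
        }))
    if not frames:
        return pd.DataFrame(columns=["motif", "region", "offset", "strand", "score", "p", "q"])
    return pd.concat(frames, ignore_index=True)


def lm_density_enrichment(
    hits: pd.DataFrame,
    lm_map,
    alpha: float = 0.05,
    mode: str = "q",
) -> pd.DataFrame:
    """One-tailed z-score test of per-LM motif density against the global rate.

    For each (LM, motif): p_hat_lm = fraction of the LM's regions with >=1
    hit of that motif; p_hat = global fraction over all linked regions;
    z = (p_hat_lm - p_hat) / sqrt(p_hat (1 - p_hat) / n_lm); upper-tail
    normal p; BH across all (LM, motif) pairs; retained where q < alpha
    (or p < alpha with mode="p").  A region counts once per motif however
    many hits it carries.
    """
    from scipy.stats import norm

    all_regions: set[int] = set()
    lm_regions: dict[tuple[int, int], set[int]] = {}
    for key, pairs in lm_map.bins.items():
        regs = {r for r, _, _ in pairs}
        lm_regions[key] = regs
        all_regions |= regs
    n_all = len(all_regions)
    motifs = sorted(hits["motif"].unique()) if len(hits) else []
    rows = []
    for motif in motifs:
        hit_regions = set(hits.loc[hits["motif"] == motif, "region"]) & all_regions
        p_hat = len(hit_regions) / n_all if n_all else 0.0
        for key, regs in sorted(lm_regions.items()):
            n_lm = len(regs)
            if n_lm == 0:
                continue
            n_with = len(regs & hit_regions)
            p_lm = n_with / n_lm
            if 0.0 < p_hat < 1.0:
                z = (p_lm - p_hat) / np.sqrt(p_hat * (1 - p_hat) / n_lm)
                p = float(norm.sf(z))
                flagged = False
            else:
                z, p, flagged = np.nan, 1.0, True
            rows.append((key[0], key[1], motif, n_lm, n_with, p_lm, p_hat, z, p, flagged))
    out = pd.DataFrame(
        rows,
        columns=["rna_mc", "dna_mc", "motif", "n_regions", "n_with_hit",
                 "proportion", "global_proportion", "z", "p", "degenerate"],
    )
    if len(out):
        out["q"] = bh_qvalues(out["p"].to_numpy())
        stat = out["q"] if mode == "q" else out["p"]
        out["retained"] = stat < alpha
    else:
        out["q"] = pd.Series(dtype=float)
        out["retained"] = pd.Series(dtype=bool)
    return out


def write_meme(pwms: list[PWM], path) -> None:
    """Write PWMs in MEME minimal text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else UNIFORM_BG
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PWM]:
    """Read PWMs from MEME minimal text format."""
    pwms: list[PWM] = []
    bg = UNIFORM_BG.copy()
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            bg = np.array([float(parts[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while not lines[i].strip().startswith("letter-probability"):
                i += 1
            w = int(lines[i].split("w=")[1].split()[0])
            rows = [list(map(float, lines[i + 1 + j].split())) for j in range(w)]
            pwms.append(PWM(motif_id=motif_id, probs=np.array(rows), background=bg))
            i += 1 + w
            continue
        i += 1
    return pwms
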