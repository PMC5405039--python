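"""Consensus motif extraction from rank-ordered PBM intensities.

The rank-ordered fluorescence curve of a specific binder shows a steep left
region (motif-bearing probes) and a long shallow right tail (background).
Two independent straight lines y = a*x + b are least-squares fitted to the
two regions; the breakpoint is chosen to minimise the total squared error,
and the rank at which the two lines intersect is the probe-selection cutoff.
Probes above the cutoff are collapsed to canonical 9-mers, greedily clustered
around intensity anchors, and each cluster yields an intensity-weighted PWM,
an IUPAC consensus, and a rank-sum enrichment p-value.

Because every probe carries its 9-mer concatenated four times, a binding
site can sit across the junction between adjacent copies: the probe presents
every *rotation* of its 9-mer.  Cluster alignment is therefore circular —
a member joins the anchor at the rotation/strand maximising positional
identity (>= 6 of 9 by default).  The 9 rotations correspond to ungapped
offsets -4..+4 modulo the k-mer length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .array_design import ArrayDesign, build_probe_sequence
from .iupac import DNA, code_for, expand, revcomp
from .simulate import SignalTable


class NoBreakpointError(ValueError):
    """The signal distribution is degenerate (no two-line structure)."""


@dataclass
class RankFit:
    """Two-line fit of the rank-ordered intensity curve (y = a*x + b)."""

    left_slope: float
    left_intercept: float
    right_slope: float
    right_intercept: float
    break_index: int  # number of points assigned to the left segment
    cutoff_rank: int  # rounded rank where the two lines intersect
    sse: float


@dataclass
class Cluster:
    """A group of k-mers aligned to a common anchor.

    members are (kmer, rotation, strand, intensity): the anchor's position i
    corresponds to position (i + rotation) mod k of the strand-oriented kmer.
    ``absorbed`` lists k-mers claimed by the cluster whose assembled probe
    carries the site only across the repeat/primer junction (a partial site
    in the 9-mer itself); they are masked but excluded from the PWM.
    """

    anchor: str
    members: list[tuple[str, int, int, float]] = field(default_factory=list)
    absorbed: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class MotifModel:
    """PWM + consensus + enrichment statistics for one recovered motif."""

    member_kmers: list[tuple[str, int, int]]  # (kmer, rotation, strand)
    pwm: np.ndarray  # L x 4 base probabilities, columns A,C,G,T
    consensus: str  # IUPAC string, length L
    core: str  # informative central run of the consensus
    mean_intensity: float
    p_value: float
    n_core_probes: int = 0

    def to_dict(self) -> dict:
        return {
            "consensus": self.consensus,
            "core": self.core,
            "mean_intensity": self.mean_intensity,
            "p_value": self.p_value,
            "n_members": len(self.member_kmers),
            "n_core_probes": self.n_core_probes,
            "pwm": self.pwm.tolist(),
            "members": [list(m) for m in self.member_kmers],
        }


def _segment_sse(sx, sy, sxx, sxy, syy, m):
    """SSE of the least-squares line through a segment given its raw sums."""
    sxx_c = sxx - sx * sx / m
    sxy_c = sxy - sx * sy / m
    syy_c = syy - sy * sy / m
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx_c > 0, sxy_c / np.where(sxx_c > 0, sxx_c, 1.0), 0.0)
    sse = syy_c - slope * sxy_c
    return np.maximum(sse, 0.0), slope


def rank_breakpoint(signals: SignalTable) -> RankFit:
    """Optimal two-segment linear fit of the rank-ordered intensity curve.

    Scans every candidate breakpoint (>= 2 points per side) and minimises the
    summed SSE of the two independently fitted lines, in O(n) via prefix sums.
    ``cutoff_rank`` is the rank at which the fitted lines intersect, rounded
    to the nearest integer and clamped to [1, n].
    """
    y = np.sort(signals.intensities.to_numpy(float))[::-1]
    y = y[y > 0]
    n = len(y)
    if n < 10:
        raise ValueError(f"need >= 10 probes with positive intensity, got {n}")
    if np.allclose(y, y[0]):
        raise NoBreakpointError("constant signal: no breakpoint exists")

    x = np.arange(1, n + 1, dtype=float)
    cx, cy = np.cumsum(x), np.cumsum(y)
    cxx, cxy, cyy = np.cumsum(x * x), np.cumsum(x * y), np.cumsum(y * y)

    # candidate breakpoints: left segment = first c points, c in [2, n-2]
    c = np.arange(2, n - 1)
    i = c - 1
    sse_l, slope_l = _segment_sse(cx[i], cy[i], cxx[i], cxy[i], cyy[i], c)
    m_r = n - c
    sse_r, slope_r = _segment_sse(
        cx[-1] - cx[i], cy[-1] - cy[i], cxx[-1] - cxx[i],
        cxy[-1] - cxy[i], cyy[-1] - cyy[i], m_r,
    )
    total = sse_l + sse_r
    best = int(np.argmin(total))
    c_best = int(c[best])

    def line(lo: int, hi: int) -> tuple[float, float]:
        a, b = np.polyfit(x[lo:hi], y[lo:hi], 1)
        return float(a), float(b)

    a_l, b_l = line(0, c_best)
    a_r, b_r = line(c_best, n)
    if np.isclose(a_l, a_r):
        cutoff = c_best
    else:
        cutoff = int(round((b_r - b_l) / (a_l - a_r)))
    cutoff = max(1, min(n, cutoff))
    return RankFit(
        left_slope=a_l,
        left_intercept=b_l,
        right_slope=a_r,
        right_intercept=b_r,
        break_index=c_best,
        cutoff_rank=cutoff,
        sse=float(total[best]),
    )


def line_intersection_rank(left_intercept, left_slope, right_intercept,
                           right_slope) -> int:
    """Rounded rank at which two fitted lines y = a*x + b intersect."""
    if np.isclose(left_slope, right_slope):
        raise ValueError("parallel lines do not intersect")
    return int(round((right_intercept - left_intercept)
                     / (left_slope - right_slope)))


def select_top_probes(
    signals: SignalTable, design: ArrayDesign, cutoff_rank: int
) -> list[tuple[str, float]]:
    """The cutoff_rank brightest k-mer-bearing probes, collapsed to canonical
    k-mers keeping the maximum intensity, sorted by intensity descending."""
    km = design.probes.loc[
        design.probes["category"].isin(["kmer", "replicate"]),
        ["probe_id", "canonical_kmer"],
    ]
    joined = km.merge(
        signals.intensities.rename("intensity"),
        left_on="probe_id", right_index=True, how="inner",
    )
    if cutoff_rank > len(joined):
        raise ValueError(
            f"cutoff_rank {cutoff_rank} exceeds the {len(joined)} k-mer probes"
        )
    if cutoff_rank < 1:
        raise ValueError("cutoff_rank must be >= 1")
    top = joined.sort_values(
        ["intensity", "probe_id"], ascending=[False, True], kind="mergesort"
    ).head(cutoff_rank)
    collapsed = top.groupby("canonical_kmer", sort=False)["intensity"].max()
    out = sorted(collapsed.items(), key=lambda t: (-t[1], t[0]))
    return [(k, float(v)) for k, v in out]


def _align_to_anchor(anchor: str, kmer: str) -> tuple[int, int, int]:
    """Best circular gapless alignment of *kmer* onto *anchor*.

    Returns (matches, rotation, strand); strand is +1/-1, and anchor position
    i pairs with oriented-kmer position (i + rotation) mod k.
    """
    k = len(anchor)
    best = (-1, 0, 1)
    for strand, oriented in ((1, kmer), (-1, revcomp(kmer))):
        doubled = oriented + oriented
        for rot in range(k):
            m = sum(1 for i in range(k) if anchor[i] == doubled[i + rot])
            if m > best[0]:
                best = (m, rot, strand)
    return best


def _cluster_core(cluster: Cluster, single: float = 0.75,
                  degenerate: float = 0.25, min_ic: float = 0.5) -> str:
    """Informative consensus core of a cluster (see build_motif_model)."""
    freqs = _column_frequencies(cluster)
    ic = _information_content(freqs)
    start, length = _longest_circular_run(ic >= min_ic)
    k = freqs.shape[0]
    rotated = freqs[[(start + i) % k for i in range(k)]]
    return _consensus_code(rotated, single, degenerate)[:length]


def _core_members(
    core: str, pool: list[tuple[str, float]], k: int
) -> tuple[list[tuple[str, int, int, float]], list[str]]:
    """Pool k-mers whose quadrupled probe contains *core* on either strand.

    Returns (members, absorbed): members have the core inside the k-mer
    circle and are aligned so position 0 is the core's first base; absorbed
    k-mers owe their match to the repeat/primer junction of the assembled
    probe and carry only a partial site in the circle."""
    words = [(w, 1) for w in expand(core)]
    words += [(revcomp(w), -1) for w in expand(core)]
    exact = {w for w, _ in words}
    members = []
    absorbed = []
    for kmer, inten in pool:
        placed = False
        for w, strand in words:
            oriented = kmer if strand == 1 else revcomp(kmer)
            pos = (oriented + oriented).find(w, 0, len(kmer) + len(w) - 1)
            if pos >= 0:
                members.append((kmer, pos % len(kmer), strand, inten))
                placed = True
                break
        if not placed:
            probe = build_probe_sequence(kmer, k)
            if any(w in probe or w in revcomp(probe) for w in exact):
                absorbed.append(kmer)
    return members, absorbed


def _trim_core(core: str, pool: list[tuple[str, float]], k: int,
               growth_factor: float = 1.5, min_len: int = 4) -> str:
    """Drop spurious flank columns from a candidate core.

    A genuine motif column constrains which probes are bright, so removing
    it barely changes how many top-pool k-mers match; a flank column that
    crept in by chance excludes most of the true motif class, so removing it
    multiplies the match count.  End columns are dropped while the pool
    membership grows by more than *growth_factor*."""
    count = len(_core_members(core, pool, k)[0])
    while len(core) > min_len:
        for candidate in (core[1:], core[:-1]):
            n = len(_core_members(candidate, pool, k)[0])
            if n > growth_factor * count:
                core, count = candidate, n
                break
        else:
            break
    return core


def align_and_cluster(
    top: list[tuple[str, float]],
    max_motifs: int = 3,
    min_cluster: int = 10,
    min_matches: int = 6,
    refine_iterations: int = 3,
) -> list[Cluster]:
    """Greedy anchor-seeded clustering of the selected k-mers.

    The anchor is the highest-intensity unassigned k-mer; every unassigned
    k-mer whose best circular alignment to the anchor reaches *min_matches*
    identities joins at that (rotation, strand).  The seed cluster is then
    refined: its consensus core is computed, membership is redefined as the
    unassigned k-mers whose circle contains the current core word on either
    strand, and the two steps repeat until stable (at most
    *refine_iterations* rounds).  Refinement separates motif classes that
    share a partial site — e.g. TGASTCA and the reverse complement of
    GGATGAC share a GTCA half-site and cross-join at 6/9 identities — and
    removes the anchor-matching selection bias at the free positions.
    Repeats until *max_motifs* clusters are built or the brightest remaining
    neighbourhood falls below *min_cluster* members; refined clusters below
    *min_cluster* are discarded (their k-mers masked) rather than reported.
    """
    if not top:
        raise ValueError("empty top-probe list")
    unassigned = list(top)  # already intensity-sorted
    clusters: list[Cluster] = []
    attempts = 0
    while unassigned and len(clusters) < max_motifs and attempts < 50:
        attempts += 1
        anchor, _anchor_int = unassigned[0]
        seed_members = []
        for kmer, inten in unassigned:
            m, rot, strand = _align_to_anchor(anchor, kmer)
            if m >= min_matches:
                seed_members.append((kmer, rot, strand, inten))
        if len(seed_members) < min_cluster:
            break  # remaining pool is background dust
        k = len(anchor)
        cl = Cluster(anchor=anchor, members=seed_members)
        for _ in range(max(0, refine_iterations)):
            core = _trim_core(_cluster_core(cl), unassigned, k)
            refined, absorbed = _core_members(core, unassigned, k)
            if not refined:
                break
            new_keys = {m[0] for m in refined}
            old_keys = {m[0] for m in cl.members}
            cl = Cluster(anchor=core, members=refined, absorbed=absorbed)
            if new_keys == old_keys:
                break
        claimed = {m[0] for m in cl.members} | set(cl.absorbed)
        unassigned = [(w, v) for w, v in unassigned if w not in claimed]
        if len(cl) >= min_cluster:
            clusters.append(cl)
    return clusters


def _column_frequencies(cluster: Cluster) -> np.ndarray:
    """Intensity-weighted base frequencies, k x 4 (columns A,C,G,T).

    Columns live on the k-long circle of the member k-mers (the anchor label
    may be a shorter consensus core after refinement)."""
    k = len(cluster.members[0][0])
    counts = np.zeros((k, 4))
    base_idx = {b: j for j, b in enumerate(DNA)}
    for kmer, rot, strand, inten in cluster.members:
        oriented = kmer if strand == 1 else revcomp(kmer)
        doubled = oriented + oriented
        for i in range(k):
            counts[i, base_idx[doubled[i + rot]]] += inten
    return counts / counts.sum(axis=1, keepdims=True)


def _consensus_code(freqs: np.ndarray, single: float, degenerate: float) -> str:
    """Per-column IUPAC call: single base if its frequency >= *single*, else
    the degenerate code covering all bases with frequency >= *degenerate*."""
    out = []
    for row in freqs:
        top = int(np.argmax(row))
        if row[top] >= single:
            out.append(DNA[top])
            continue
        covered = {DNA[j] for j in range(4) if row[j] >= degenerate}
        if not covered:
            covered = {DNA[top]}
        out.append(code_for(covered))
    return "".join(out)


def _information_content(freqs: np.ndarray) -> np.ndarray:
    """Per-column information content in bits (2 - Shannon entropy)."""
    p = np.clip(freqs, 1e-12, 1.0)
    return 2.0 + (p * np.log2(p)).sum(axis=1)


def _longest_circular_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest circular run of True values."""
    k = len(mask)
    if mask.all():
        return 0, k
    ext = np.concatenate([mask, mask])
    best_start, best_len, run = 0, 0, 0
    for i in range(2 * k):
        if ext[i]:
            run += 1
            if run > best_len and i - run + 1 < k:
                best_len, best_start = run, i - run + 1
        else:
            run = 0
    return best_start, min(best_len, k)


def rank_sum_pvalue(a, b) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value for samples *a* vs *b*.

    Exact null enumeration when both samples have < 30 observations,
    otherwise the tie-corrected normal approximation."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    method = "exact" if max(len(a), len(b)) < 30 else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def build_motif_model(
    cluster: Cluster,
    signals: SignalTable,
    design: ArrayDesign,
    single_base_threshold: float = 0.75,
    degenerate_threshold: float = 0.25,
    core_min_ic: float = 0.5,
) -> MotifModel:
    """PWM, IUPAC consensus, representative intensity and enrichment p-value.

    The PWM comes from intensity-weighted base frequencies over the circular
    alignment; the consensus *core* is the longest circular run of columns
    with information content >= *core_min_ic* bits, and the model is rotated
    so the core is contiguous and starts the consensus.  mean_intensity is
    the mean over distinct k-mer probes containing the core (both strands,
    degenerate codes expanded); the p-value is a two-sided rank-sum test of
    those probes against all other k-mer probes (exact below 30 observations).
    """
    if len(cluster) < 2:
        raise ValueError("cannot build a motif model from a singleton cluster")
    freqs = _column_frequencies(cluster)
    ic = _information_content(freqs)
    start, length = _longest_circular_run(ic >= core_min_ic)

    k = freqs.shape[0]
    order = [(start + i) % k for i in range(k)]
    pwm = freqs[order]
    consensus = _consensus_code(pwm, single_base_threshold, degenerate_threshold)
    core = consensus[:length]

    members = [
        (kmer, (rot + start) % k, strand) for kmer, rot, strand, _ in cluster.members
    ]

    km = design.kmer_probes()
    inten = signals.intensities.reindex(km["probe_id"]).to_numpy(float)
    words = set(expand(core)) | {revcomp(s) for s in expand(core)}
    has_core = np.fromiter(
        (any(w in s for w in words) for s in km["sequence"]),
        dtype=bool, count=len(km),
    )
    if has_core.any() and (~has_core).any():
        core_int = inten[has_core]
        rest_int = inten[~has_core]
        p = rank_sum_pvalue(core_int, rest_int)
        mean_intensity = float(core_int.mean())
        n_core = int(has_core.sum())
    else:
        # core matches nothing (or everything): fall back to member intensities
        p = 1.0
        mean_intensity = float(np.mean([m[3] for m in cluster.members]))
        n_core = int(has_core.sum())
    return MotifModel(
        member_kmers=members,
        pwm=pwm,
        consensus=consensus,
        core=core,
        mean_intensity=mean_intensity,
        p_value=p,
        n_core_probes=n_core,
    )


def extract_motifs(
    signals: SignalTable,
    design: ArrayDesign,
    max_motifs: int = 3,
    min_cluster: int = 10,
    min_matches: int = 6,
    **model_kwargs,
) -> tuple[RankFit, list[MotifModel]]:
    """Full extraction: breakpoint -> top probes -> clusters -> motif models."""
    fit = rank_breakpoint(signals)
    top = select_top_probes(signals, design, fit.cutoff_rank)
    clusters = align_and_cluster(top, max_motifs=max_motifs,
                                 min_cluster=min_cluster, min_matches=min_matches)
    models = [build_motif_model(cl, signals, design, **model_kwargs)
              for cl in clusters]
    return fit, models


def to_meme(models: list[MotifModel], name_prefix: str = "motif") -> str:
    """MEME minimal-format text for the recovered PWMs."""
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "",
             "strands: + -", "",
             "Background letter frequencies",
             "A 0.25 C 0.25 G 0.25 T 0.25", ""]
    for i, m in enumerate(models, 1):
        lines.append(f"MOTIF {name_prefix}_{i} {m.core}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {m.pwm.shape[0]} "
            f"nsites= {len(m.member_kmers)} E= {m.p_value:.3g}"
        )
        for row in m.pwm:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
    return "\n".join(lines)


def plot_logo(model: MotifModel, ax=None):
    """Minimal sequence-logo rendering (information-scaled letters)."""
    import matplotlib.pyplot as plt
    from matplotlib.textpath import TextPath
    from matplotlib.patches import PathPatch
    from matplotlib.transforms import Affine2D
    from matplotlib.font_manager import FontProperties

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    if ax is None:
        _, ax = plt.subplots(figsize=(0.6 * model.pwm.shape[0], 2.2))
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    ic = _information_content(model.pwm)
    for x, (row, col_ic) in enumerate(zip(model.pwm, ic)):
        y = 0.0
        for j in np.argsort(row):
            h = row[j] * col_ic
            if h <= 0.005:
                continue
            letter = DNA[j]
            tp = TextPath((0, 0), letter, size=1, prop=fp)
            bb = tp.get_extents()
            tr = (Affine2D()
                  .scale(0.9 / bb.width, h / bb.height)
                  .translate(x - bb.x0 * 0.9 / bb.width + 0.05,
                             y - bb.y0 * h / bb.height))
            ax.add_patch(PathPatch(tr.transform_path(tp),
                                   color=colors[letter], lw=0))
            y += h
    ax.set_xlim(-0.2, model.pwm.shape[0] + 0.2)
    ax.set_ylim(0, 2.05)
    ax.set_xticks(np.arange(model.pwm.shape[0]) + 0.5)
    ax.set_xticklabels(np.arange(1, model.pwm.shape[0] + 1))
    ax.set_ylabel("bits")
    return ax
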