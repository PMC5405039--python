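"""Synthetic-data generators for every measurement the pipeline consumes.

The generators emulate, at the level the analysis actually sees:

* PBM fluorescence — per-probe intensities with planted binding motifs of
  distinct mean affinities over multiplicative log-normal background noise
  (fluorescence is positive and right-skewed, hence the log-normal choice);
* saturation binding curves Y = Bmax*X/(Kd+X) with additive Gaussian noise;
* gene x sample expression matrices with a query gene and neighbours of
  specified population Pearson correlation;
* motif-free 1-kb promoter backgrounds with motif instances planted at
  known positions (bp upstream of the translation start).

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_design import ArrayDesign
from .iupac import compile_pattern, expand, revcomp, validate_pattern

#: Substrate concentration series (uM) used for the saturation binding assays.
STANDARD_CONCENTRATIONS = (0.0, 0.1, 0.2, 0.4, 0.8, 1.2, 2.0, 4.0, 6.0)


@dataclass(frozen=True)
class MotifSpec:
    """A binding motif with its mean fluorescence contribution."""

    name: str
    pattern: str  # IUPAC string, e.g. TGASTCA
    mean_intensity: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", validate_pattern(self.pattern))
        if self.mean_intensity <= 0:
            raise ValueError("mean_intensity must be positive")


#: The three OsSMF1 binding motifs with their observed mean PBM intensities
#: (arbitrary fluorescence units): ACGT > GCN4 > ATGA.
DEFAULT_MOTIFS = (
    MotifSpec("ACGT", "CCACGTS", 13_715.0),
    MotifSpec("GCN4", "TGASTCA", 7_639.0),
    MotifSpec("ATGA", "GGATGAC", 6_463.0),
)

DEFAULT_BASELINE = 500.0
DEFAULT_NOISE_SIGMA = 0.2


@dataclass
class SignalTable:
    """Probe -> fluorescence intensity (arbitrary units, all >= 0)."""

    intensities: pd.Series  # index: probe_id, values: float

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            raise ValueError("duplicate probe_ids in signal table")
        if (self.intensities < 0).any():
            raise ValueError("negative intensity in signal table")

    def __len__(self) -> int:
        return len(self.intensities)

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("probe_id\tintensity\n")
            for pid, v in self.intensities.items():
                fh.write(f"{pid}\t{v:.6g}\n")

    @classmethod
    def from_tsv(cls, path) -> "SignalTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(pd.Series(df["intensity"].to_numpy(float),
                             index=df["probe_id"], name="intensity"))


@dataclass
class BindingCurve:
    """Concentration (uM) / band-intensity pairs of a saturation assay."""

    concentrations: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.concentrations.shape != self.intensities.shape:
            raise ValueError("concentrations and intensities differ in length")
        if len(self.concentrations) < 4:
            raise ValueError("a binding curve needs at least 4 points")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(self.concentrations < 0) or np.any(self.intensities < 0):
            raise ValueError("concentrations and intensities must be >= 0")

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"concentration_uM": self.concentrations, "intensity": self.intensities}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BindingCurve":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df["concentration_uM"].to_numpy(), df["intensity"].to_numpy())


@dataclass
class PromoterSet:
    """gene_id -> upstream sequence (fixed length, default 1,000 nt)."""

    records: dict[str, str]
    length: int = 1000

    def __post_init__(self) -> None:
        for g, s in self.records.items():
            if len(s) != self.length:
                raise ValueError(
                    f"promoter of {g} has length {len(s)}, expected {self.length}"
                )


class InvalidAnnotationError(ValueError):
    """Planted motifs overlap with incompatible letters or fall outside."""


def motif_gain(sequence: str, motifs: tuple[MotifSpec, ...] | list[MotifSpec]) -> float:
    """Best mean_intensity over motifs matched anywhere in *sequence*, both strands.

    Multiple hits combine by max (single-occupancy approximation).  Returns 0
    when no motif matches or the sequence is empty.
    """
    if not sequence:
        return 0.0
    best = 0.0
    seq = sequence.upper()
    rc = revcomp(seq)
    for m in motifs:
        if m.mean_intensity <= best:
            continue
        for s in expand(m.pattern):
            if s in seq or s in rc:
                best = m.mean_intensity
                break
    return best


def expected_signals(
    design: ArrayDesign,
    motifs: list[MotifSpec] | tuple[MotifSpec, ...],
    baseline: float,
) -> np.ndarray:
    """Noise-free expected intensity per probe (design order).

    Probes with a sequence (kmer, replicate, random_control) are matched
    against the motifs on both strands; blank and manufacturer spots carry
    baseline signal only.  Exposed separately so that many noise realisations
    of one design can reuse the (deterministic) matching step.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    seqs = design.probes["sequence"].to_numpy()
    out = np.full(len(seqs), float(baseline))
    if not motifs:
        return out

    # expand every motif once; sort motifs by decreasing intensity so the
    # first hit wins under the max-combination rule
    ms = sorted(motifs, key=lambda m: -m.mean_intensity)
    words = [(tuple(set(expand(m.pattern)) | {revcomp(s) for s in expand(m.pattern)}),
              m.mean_intensity) for m in ms]
    for i, seq in enumerate(seqs):
        if not seq:
            continue
        for strings, gain in words:
            if any(s in seq for s in strings):
                out[i] += gain
                break
    return out


def simulate_pbm_signals(
    design: ArrayDesign,
    motifs: list[MotifSpec] | tuple[MotifSpec, ...] = DEFAULT_MOTIFS,
    baseline: float = DEFAULT_BASELINE,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
    expected: np.ndarray | None = None,
) -> SignalTable:
    """Simulate a PBM hybridisation over *design*.

    intensity = (baseline + best matching motif mean) * exp(N(0, sigma^2)).
    Pass a precomputed ``expected`` array (from :func:`expected_signals`) to
    skip the matching step when only the noise seed varies.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if expected is None:
        expected = expected_signals(design, motifs, baseline)
    rng = np.random.default_rng([int(seed), 11])
    if noise_sigma == 0:
        vals = expected.astype(float)
    else:
        vals = expected * np.exp(rng.normal(0.0, noise_sigma, size=len(expected)))
    return SignalTable(
        pd.Series(vals, index=pd.Index(design.probes["probe_id"], name="probe_id"),
                  name="intensity")
    )


def simulate_binding_curve(
    kd: float,
    bmax: float,
    concentrations=STANDARD_CONCENTRATIONS,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> BindingCurve:
    """Hyperbolic saturation curve Y = Bmax*X/(Kd+X) + N(0, sd^2), floored at 0."""
    if kd <= 0 or bmax <= 0:
        raise ValueError("kd and bmax must be positive")
    x = np.asarray(concentrations, float)
    y = bmax * x / (kd + x)
    if noise_sd > 0:
        rng = np.random.default_rng([int(seed), 12])
        y = y + rng.normal(0.0, noise_sd, size=len(x))
    return BindingCurve(x, np.maximum(y, 0.0))


def simulate_expression(
    n_background: int,
    neighbor_r: list[float],
    n_samples: int,
    seed: int = 0,
    query: str = "query",
) -> pd.DataFrame:
    """Gene x sample expression matrix with controlled co-expression structure.

    The designated *query* gene is standard normal across samples; neighbour j
    is r_j * z_query + sqrt(1 - r_j^2) * eps so its population Pearson
    correlation with the query is exactly r_j.  Background genes are
    independent.  Marginals are standard normal (Pearson r is location/scale
    invariant, so the scale is immaterial).
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples for meaningful correlations")
    for r in neighbor_r:
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"neighbor correlation {r} outside [-1, 1]")
    rng = np.random.default_rng([int(seed), 13])
    zq = rng.standard_normal(n_samples)
    rows = {query: zq}
    for j, r in enumerate(neighbor_r):
        eps = rng.standard_normal(n_samples)
        rows[f"nb{j + 1:02d}"] = r * zq + np.sqrt(1.0 - r * r) * eps
    for j in range(n_background):
        rows[f"bg{j + 1:04d}"] = rng.standard_normal(n_samples)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"s{i + 1:03d}" for i in range(n_samples)]
    df.index.name = "gene_id"
    return df


def _scan_intervals(seq: str, patterns: tuple[str, ...]) -> set[tuple[int, int]]:
    """(start, end) forward-strand intervals of any pattern hit, both strands."""
    hits: set[tuple[int, int]] = set()
    rc = revcomp(seq)
    n = len(seq)
    for p in patterns:
        rx = compile_pattern(p)
        probe = re.compile("(?=" + rx.pattern + ")")
        for m in probe.finditer(seq):
            hits.add((m.start(), m.start() + len(p)))
        for m in probe.finditer(rc):
            s = n - (m.start() + len(p))
            hits.add((s, s + len(p)))
    return hits


def simulate_promoters(
    annotations: dict[str, list[tuple[str, int]]],
    seed: int = 0,
    length: int = 1000,
    forbidden_patterns: tuple[str, ...] | None = None,
    max_tries: int = 500,
) -> PromoterSet:
    """Promoters with motifs planted at annotated positions over clean background.

    *annotations* maps gene_id -> list of (motif_sequence, position) where
    position counts bp upstream of the translation start and anchors the
    motif's 5'-most base (position 1 = the base adjacent to ATG).  The
    background is rejection-sampled until, after planting, the only occurrences
    of the forbidden patterns (default: the three OsSMF1 motifs) are exactly
    the planted ones — so a scan recovers the annotation and nothing else.
    """
    if forbidden_patterns is None:
        forbidden_patterns = tuple(m.pattern for m in DEFAULT_MOTIFS)
    rng = np.random.default_rng([int(seed), 14])
    bases = np.array(list("ACGT"))
    records: dict[str, str] = {}
    for gene in annotations:
        planted: dict[int, str] = {}  # index -> base
        intervals: set[tuple[int, int]] = set()
        for motif_seq, pos in annotations[gene]:
            s = motif_seq.upper()
            start = length - int(pos)
            if start < 0 or start + len(s) > length:
                raise InvalidAnnotationError(
                    f"{gene}: motif {motif_seq!r} at position {pos} does not fit "
                    f"inside {length} bp"
                )
            for i, c in enumerate(s):
                idx = start + i
                if idx in planted and planted[idx] != c:
                    raise InvalidAnnotationError(
                        f"{gene}: overlapping motifs disagree at offset {idx}"
                    )
                planted[idx] = c
            intervals.add((start, start + len(s)))
        for _ in range(max_tries):
            arr = bases[rng.integers(0, 4, size=length)]
            for idx, c in planted.items():
                arr[idx] = c
            seq = "".join(arr)
            if _scan_intervals(seq, forbidden_patterns) == intervals:
                records[gene] = seq
                break
        else:
            raise RuntimeError(
                f"could not synthesise a clean promoter for {gene} "
                f"in {max_tries} tries"
            )
    return PromoterSet(records, length=length)
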