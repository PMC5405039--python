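"""Single-nucleotide substitution profiling and dissociation-constant fitting.

The substitution profile asks, for an exact binding core (e.g. CCACGTC), how
the mean probe intensity changes when each position is mutated to each other
base — a specific binder shows the exact core strictly above every variant.
The dissociation constant comes from nonlinear least squares of the
hyperbolic saturation model Y = Bmax * X / (Kd + X), where Bmax is maximal
binding and Kd the substrate concentration at half-maximal binding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .array_design import ArrayDesign
from .iupac import DNA, is_exact_dna, revcomp
from .simulate import BindingCurve, SignalTable


class EmptyReferenceError(ValueError):
    """The exact core occurs in no probe on the array."""


class FitFailureError(ValueError):
    """The binding curve cannot be fitted (e.g. all-zero intensities)."""


@dataclass
class SubstitutionProfile:
    """Mean intensities of the exact core vs every single-base variant."""

    core: str
    reference_mean: float
    reference_count: int
    variant_means: dict[tuple[int, str], float]  # (0-based position, base)
    counts: dict[tuple[int, str], int]

    def to_frame(self):
        import pandas as pd

        rows = []
        for (pos, base), mean in sorted(self.variant_means.items()):
            rows.append(
                {
                    "position": pos + 1,
                    "base": base,
                    "mean_intensity": mean,
                    "n_probes": self.counts[(pos, base)],
                }
            )
        return pd.DataFrame(rows)


@dataclass
class KdFit:
    """Fitted hyperbolic saturation model."""

    kd: float  # uM
    bmax: float  # intensity units
    rss: float
    converged: bool

    def predict(self, x):
        x = np.asarray(x, float)
        return self.bmax * x / (self.kd + x)


def _contains(seq: str, word: str, word_rc: str) -> bool:
    return word in seq or word_rc in seq


def substitution_profile(
    core: str, signals: SignalTable, design: ArrayDesign
) -> SubstitutionProfile:
    """Mean intensity of probes containing *core* vs each single-base variant.

    Both strands of each probe are searched.  Variant averages exclude probes
    that also contain the exact core elsewhere, so the reference signal never
    contaminates the variant estimate.
    """
    w = core.upper()
    if not (4 <= len(w) <= 9) or not is_exact_dna(w):
        raise ValueError(f"core must be 4-9 bases over ACGT, got {core!r}")

    km = design.kmer_probes()
    seqs = km["sequence"].to_numpy()
    inten = signals.intensities.reindex(km["probe_id"]).to_numpy(float)
    if np.isnan(inten).any():
        raise ValueError("signal table does not cover all k-mer probes")

    w_rc = revcomp(w)
    has_core = np.fromiter(
        (_contains(s, w, w_rc) for s in seqs), dtype=bool, count=len(seqs)
    )
    if not has_core.any():
        raise EmptyReferenceError(f"core {core!r} occurs in no probe")

    variant_means: dict[tuple[int, str], float] = {}
    counts: dict[tuple[int, str], int] = {}
    for pos in range(len(w)):
        for base in DNA:
            if base == w[pos]:
                continue
            v = w[:pos] + base + w[pos + 1:]
            v_rc = revcomp(v)
            sel = np.fromiter(
                (_contains(s, v, v_rc) for s in seqs), dtype=bool, count=len(seqs)
            )
            sel &= ~has_core
            counts[(pos, base)] = int(sel.sum())
            variant_means[(pos, base)] = (
                float(inten[sel].mean()) if sel.any() else float("nan")
            )
    return SubstitutionProfile(
        core=w,
        reference_mean=float(inten[has_core].mean()),
        reference_count=int(has_core.sum()),
        variant_means=variant_means,
        counts=counts,
    )


def fit_kd(curve: BindingCurve, max_iterations: int = 500) -> KdFit:
    """Nonlinear least squares of Y = Bmax*X/(Kd+X).

    Initialisation: Bmax0 = max(Y); Kd0 = the first concentration whose
    intensity reaches Bmax0/2.  Unweighted residuals; X = 0 points are kept
    (the model passes through the origin).  Convergence at relative parameter
    change < 1e-8 or *max_iterations* iterations.
    """
    x = curve.concentrations
    y = curve.intensities
    if len(x) < 4 or len(np.unique(x[x > 0])) < 2:
        raise ValueError("need >= 4 points and >= 2 distinct positive concentrations")
    if np.all(y == 0):
        raise FitFailureError("all intensities are zero")

    bmax0 = float(y.max())
    above = np.nonzero((y >= bmax0 / 2) & (x > 0))[0]
    kd0 = float(x[above[0]]) if len(above) else float(np.median(x[x > 0]))

    def residuals(p):
        kd, bmax = p
        return bmax * x / (kd + x) - y

    res = least_squares(
        residuals,
        x0=[kd0, bmax0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=1e-8,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=max_iterations,
    )
    kd, bmax = res.x
    return KdFit(
        kd=float(kd),
        bmax=float(bmax),
        rss=float(np.sum(res.fun**2)),
        converged=bool(res.success),
    )
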