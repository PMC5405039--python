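"""Co-expression neighbourhoods, promoter motif scanning, and candidate-target
integration.

Putative targets of a transcription factor are genes that (a) are positively
co-expressed with it above a correlation threshold in a large microarray
compendium and (b) carry at least one of its binding motifs within the 1-kb
region upstream of the translation start.  Promoter positions count bp
upstream of the ATG: position 1 is the base immediately 5' of the start
codon, and a hit is anchored at its own 5'-most base.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .iupac import compile_pattern, revcomp
from .simulate import MotifSpec, DEFAULT_MOTIFS, PromoterSet


class ZeroVarianceError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


class UnknownGeneError(KeyError):
    """The query gene is absent from the expression matrix."""


@dataclass
class CoexpressionResult:
    """BFS co-expression neighbourhood of a query gene."""

    query: str
    neighbors: list[tuple[str, float, int]]  # (gene_id, r, depth_found)
    min_r: float = 0.55
    depth: int = 1

    def genes(self) -> list[str]:
        return [g for g, _, _ in self.neighbors]

    def r_of(self, gene: str) -> float:
        for g, r, _ in self.neighbors:
            if g == gene:
                return r
        raise KeyError(gene)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in a promoter."""

    gene_id: str
    motif_name: str
    position: int  # bp upstream of translation start, 5'-most matched base
    strand: str  # "+" or "-"
    matched_sequence: str  # motif-oriented (reverse-complemented for "-")


@dataclass
class CandidateRow:
    gene_id: str
    r: float
    description: str
    hits: list[MotifHit]
    go_terms: list[str]


@dataclass
class CandidateTable:
    """Integrated candidate-target table (gene, r, motif hits, annotation)."""

    rows: list[CandidateRow]
    totals: dict[str, int]
    percentages: dict[str, float]
    denominator: int

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            recs.append(
                {
                    "gene_id": row.gene_id,
                    "r": row.r,
                    "description": row.description,
                    "motifs": ";".join(
                        f"{h.motif_name}:{h.position}:{h.strand}:"
                        f"{h.matched_sequence.lower()}"
                        for h in row.hits
                    ),
                    "go_terms": ";".join(row.go_terms),
                }
            )
        return pd.DataFrame(recs)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length samples."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for a constant sample")
    return float(stats.pearsonr(x, y).statistic)


def _correlations_to(values: np.ndarray, idx: int) -> np.ndarray:
    """Pearson r of row *idx* against every row of *values*."""
    z = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((z * z).sum(axis=1))
    norms[norms == 0] = np.nan
    return (z @ z[idx]) / (norms * norms[idx])


def coexpression_neighbors(
    matrix: pd.DataFrame,
    query: str,
    min_r: float = 0.55,
    depth: int = 1,
    absolute: bool = False,
) -> CoexpressionResult:
    """Breadth-first co-expression neighbourhood of *query*.

    Depth 1 returns genes with r(query, g) >= min_r; at each further depth
    every frontier gene is expanded by the same rule.  Only positive
    correlations count unless *absolute* is set.  Neighbours keep the r and
    depth at which they were first found.
    """
    if query not in matrix.index:
        raise UnknownGeneError(query)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    genes = matrix.index.to_list()
    pos = {g: i for i, g in enumerate(genes)}
    values = matrix.to_numpy(float)

    found: dict[str, tuple[float, int]] = {}
    visited = {query}
    frontier = [query]
    for d in range(1, depth + 1):
        next_frontier: list[str] = []
        for g in frontier:
            r_all = _correlations_to(values, pos[g])
            if absolute:
                r_eff = np.abs(r_all)
            else:
                r_eff = r_all
            for j in np.nonzero(r_eff >= min_r)[0]:
                cand = genes[j]
                if cand in visited:
                    continue
                visited.add(cand)
                found[cand] = (float(r_all[j]), d)
                next_frontier.append(cand)
        frontier = next_frontier
        if not frontier:
            break
    neighbors = sorted(
        ((g, r, d) for g, (r, d) in found.items()),
        key=lambda t: (t[2], -t[1], t[0]),
    )
    return CoexpressionResult(query=query, neighbors=neighbors,
                              min_r=min_r, depth=depth)


def scan_promoter(
    sequence: str,
    motifs: tuple[MotifSpec, ...] | list[MotifSpec] = DEFAULT_MOTIFS,
    gene_id: str = "",
    expected_length: int | None = 1000,
) -> list[MotifHit]:
    """All IUPAC matches of each motif on both strands of a promoter.

    Positions are bp upstream of the translation start (base adjacent to the
    ATG = 1), anchored at the hit's own 5'-most base; for a - strand hit that
    base is the rightmost base of the forward-strand interval.  A - strand
    duplicate of a + strand hit over the same interval (which arises for
    reverse-complement-symmetric degenerate patterns such as TGASTCA) is
    reported once, on the + strand.  Hits are sorted by position.
    """
    seq = sequence.upper()
    if expected_length is not None and len(seq) != expected_length:
        raise ValueError(
            f"promoter length {len(seq)} != expected {expected_length}"
        )
    if re.search("[^ACGT]", seq):
        raise ValueError("promoter contains non-ACGT characters")
    n = len(seq)
    hits: list[MotifHit] = []
    seen_fwd: set[tuple[str, int]] = set()
    for m in motifs:
        L = len(m.pattern)
        rx = re.compile("(?=" + compile_pattern(m.pattern).pattern + ")")
        for match in rx.finditer(seq):
            i = match.start()
            hits.append(
                MotifHit(
                    gene_id=gene_id,
                    motif_name=m.name,
                    position=n - i,
                    strand="+",
                    matched_sequence=seq[i:i + L],
                )
            )
            seen_fwd.add((m.name, i))
        rc = revcomp(seq)
        for match in rx.finditer(rc):
            j = match.start()  # start in rc coordinates
            i = n - (j + L)  # forward-strand start of the interval
            if (m.name, i) in seen_fwd:
                continue  # palindromic duplicate of a + strand hit
            hits.append(
                MotifHit(
                    gene_id=gene_id,
                    motif_name=m.name,
                    position=n - (i + L - 1),
                    strand="-",
                    matched_sequence=rc[j:j + L],
                )
            )
    hits.sort(key=lambda h: (h.position, h.motif_name, h.strand))
    return hits


def scan_promoter_set(
    promoters: PromoterSet,
    motifs: tuple[MotifSpec, ...] | list[MotifSpec] = DEFAULT_MOTIFS,
) -> dict[str, list[MotifHit]]:
    """Scan every promoter; returns gene -> hits (possibly empty lists)."""
    return {
        g: scan_promoter(s, motifs, gene_id=g, expected_length=promoters.length)
        for g, s in promoters.records.items()
    }


def _round_half_up(value: float, ndigits: int = 1) -> float:
    return float(Decimal(str(value)).quantize(Decimal("0." + "0" * ndigits),
                                              rounding=ROUND_HALF_UP))


def integrate(
    coexpr: CoexpressionResult,
    hits: dict[str, list[MotifHit]],
    annotations: dict[str, tuple[str, list[str]]],
    denominator: int,
    motif_names: tuple[str, ...] = ("GCN4", "ACGT", "ATGA"),
) -> CandidateTable:
    """Join co-expression, promoter hits and annotations into a candidate table.

    Rows are the co-expressed genes with >= 1 promoter hit, sorted by r
    descending; the query gene itself, when its promoter was scanned (present
    in *hits*), is kept as a reference row with r = 1 regardless of hits, as
    published candidate tables list the query alongside its targets.  Totals
    count genes (not hits) per motif class over rows with >= 1 hit of that
    motif; percentages are 100 * total / denominator, half-up to one decimal.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    rows: list[CandidateRow] = []
    for gene, r, _d in coexpr.neighbors:
        gene_hits = hits.get(gene, [])
        if not gene_hits:
            continue
        desc, go_terms = annotations.get(gene, ("", []))
        rows.append(CandidateRow(gene, r, desc, list(gene_hits), list(go_terms)))
    if coexpr.query in hits:
        desc, go_terms = annotations.get(coexpr.query, ("", []))
        rows.append(
            CandidateRow(coexpr.query, 1.0, desc,
                         list(hits[coexpr.query]), list(go_terms))
        )
    rows.sort(key=lambda row: (-row.r, row.gene_id))
    totals = {
        m: sum(1 for row in rows if any(h.motif_name == m for h in row.hits))
        for m in motif_names
    }
    percentages = {
        m: _round_half_up(100.0 * totals[m] / denominator) for m in motif_names
    }
    return CandidateTable(rows=rows, totals=totals, percentages=percentages,
                          denominator=denominator)


def go_tabulate(
    table: CandidateTable,
    ontology: dict[str, str] | None = None,
) -> dict[str, list[str]]:
    """Group candidate genes by their GO terms (genes may repeat across terms).

    *ontology* optionally restricts/labels the terms; with None, every term
    attached to a candidate row is tabulated.
    """
    out: dict[str, list[str]] = {}
    for row in table.rows:
        for term in row.go_terms:
            if ontology is not None and term not in ontology:
                continue
            out.setdefault(term, []).append(row.gene_id)
    return {t: sorted(genes) for t, genes in sorted(out.items())}
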