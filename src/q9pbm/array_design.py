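"""Quadruple 9-mer probe universe and slide layout.

A Q9 protein-binding microarray carries every 9-mer over {A,C,G,T} exactly
once, up to reverse complement (131,072 canonical 9-mers).  Each 9-mer is
concatenated four times, followed by the reverse complement of the
amplification primer 5'-CGGAGTCACCTAGTGCAG-3' and a 5-nt thymidine linker,
giving a 59-nt probe.  A slide holds 243,504 spots on a 267 x 912 grid:
131,072 distinct k-mer probes, 101,073 replicate spots of a subset of them,
1,474 random-sequence controls, 8,081 blanks, and 1,804 manufacturer spots.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iupac import DNA, is_exact_dna, revcomp

PRIMER = "CGGAGTCACCTAGTGCAG"
#: Primer-complementary segment appended to every probe (written 5'->3').
PRIMER_SITE = revcomp(PRIMER)
LINKER = "TTTTT"

#: Published slide composition for the 9-mer design.
Q9_LAYOUT = dict(
    n_columns=267,
    n_rows=912,
    n_replicates=101_073,
    n_random=1_474,
    n_blank=8_081,
    n_manufacturer=1_804,
)

CATEGORIES = ("kmer", "replicate", "random_control", "blank", "manufacturer")


class InvalidKmerError(ValueError):
    """A k-mer argument is not a valid DNA string of the expected length."""


@dataclass(frozen=True)
class KmerProbe:
    """One spot on the slide."""

    probe_id: str
    canonical_kmer: str  # empty for non-kmer categories
    sequence: str  # assembled probe, empty for blank/manufacturer spots
    category: str
    column: int
    row: int


@dataclass
class ArrayDesign:
    """Full slide layout.

    ``probes`` is a DataFrame with columns probe_id, category, canonical_kmer,
    sequence, column, row (one row per spot, probe_id unique).
    """

    probes: pd.DataFrame
    n_columns: int
    n_rows: int
    k: int = 9
    seed: int | None = None
    _kmer_seqs: pd.DataFrame | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def category_counts(self) -> dict[str, int]:
        counts = self.probes["category"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in CATEGORIES}

    def probe(self, probe_id: str) -> KmerProbe:
        row = self.probes.loc[self.probes["probe_id"] == probe_id]
        if row.empty:
            raise KeyError(probe_id)
        r = row.iloc[0]
        return KmerProbe(
            probe_id=r["probe_id"],
            canonical_kmer=r["canonical_kmer"],
            sequence=r["sequence"],
            category=r["category"],
            column=int(r["column"]),
            row=int(r["row"]),
        )

    def kmer_probes(self) -> pd.DataFrame:
        """The 'kmer' category spots (one per canonical k-mer), cached."""
        if self._kmer_seqs is None:
            self._kmer_seqs = (
                self.probes.loc[self.probes["category"] == "kmer"]
                .reset_index(drop=True)
                .copy()
            )
        return self._kmer_seqs

    def to_tsv(self, path) -> None:
        self.probes.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ArrayDesign":
        df = pd.read_csv(path, sep="\t", dtype={"canonical_kmer": str, "sequence": str})
        df["canonical_kmer"] = df["canonical_kmer"].fillna("")
        df["sequence"] = df["sequence"].fillna("")
        k = int(df.loc[df["category"] == "kmer", "canonical_kmer"].str.len().iloc[0])
        return cls(
            probes=df,
            n_columns=int(df["column"].max()),
            n_rows=int(df["row"].max()),
            k=k,
        )


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    w = kmer.upper()
    rc = revcomp(w)
    return w if w <= rc else rc


def canonical_kmers(k: int) -> list[str]:
    """All canonical k-mers (each double-stranded word once), sorted.

    For odd k there are 4**k / 2 of them (no odd-length reverse-complement
    palindrome exists); for even k palindromes add 4**(k/2) extra.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError(f"k must be a positive integer, got {k!r}")
    out = []
    for tup in itertools.product(DNA, repeat=int(k)):
        w = "".join(tup)
        if w <= revcomp(w):
            out.append(w)
    return out


def build_probe_sequence(kmer: str, k: int = 9) -> str:
    """Assemble the probe for *kmer*: kmer x4 + primer-complement + TTTTT.

    For the 9-mer design the result is 59 nt (4*9 + 18 + 5).
    """
    w = str(kmer).upper()
    if len(w) != k or not is_exact_dna(w):
        raise InvalidKmerError(
            f"expected a {k}-letter string over ACGT, got {kmer!r}"
        )
    return w * 4 + PRIMER_SITE + LINKER


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(DNA))[rng.integers(0, 4, size=length)])


def design_array(
    seed: int,
    k: int = 9,
    *,
    n_columns: int | None = None,
    n_rows: int | None = None,
    n_replicates: int | None = None,
    n_random: int | None = None,
    n_blank: int | None = None,
    n_manufacturer: int | None = None,
) -> ArrayDesign:
    """Construct the full slide design.

    With ``k=9`` and no overrides this reproduces the published composition
    (243,504 spots on 267 x 912).  The replicated k-mer subset and the spot
    placement, which the design leaves unspecified, are drawn reproducibly
    from *seed*; placement never affects downstream computation.
    """
    kmers = canonical_kmers(k)
    n_kmers = len(kmers)

    overrides = dict(
        n_columns=n_columns,
        n_rows=n_rows,
        n_replicates=n_replicates,
        n_random=n_random,
        n_blank=n_blank,
        n_manufacturer=n_manufacturer,
    )
    if k == 9:
        layout = dict(Q9_LAYOUT)
        layout.update({key: v for key, v in overrides.items() if v is not None})
    else:
        # compact layout for reduced universes (tests, demos)
        n_rep = n_kmers // 2 if n_replicates is None else n_replicates
        n_rnd = 16 if n_random is None else n_random
        n_mfg = 8 if n_manufacturer is None else n_manufacturer
        ncol = 64 if n_columns is None else n_columns
        occupied = n_kmers + n_rep + n_rnd + n_mfg
        nrow = -(-occupied // ncol) if n_rows is None else n_rows
        n_blk = ncol * nrow - occupied if n_blank is None else n_blank
        layout = dict(
            n_columns=ncol,
            n_rows=nrow,
            n_replicates=n_rep,
            n_random=n_rnd,
            n_blank=n_blk,
            n_manufacturer=n_mfg,
        )

    total = layout["n_columns"] * layout["n_rows"]
    occupied = (
        n_kmers
        + layout["n_replicates"]
        + layout["n_random"]
        + layout["n_blank"]
        + layout["n_manufacturer"]
    )
    if occupied != total:
        raise ValueError(
            f"layout mismatch: {occupied} probes for {total} grid cells"
        )
    if layout["n_replicates"] > n_kmers:
        raise ValueError("cannot replicate more k-mers than exist")

    rng_rep = np.random.default_rng([int(seed), 1])
    rng_rand = np.random.default_rng([int(seed), 2])
    rng_place = np.random.default_rng([int(seed), 3])

    ids: list[str] = []
    cats: list[str] = []
    cks: list[str] = []
    seqs: list[str] = []

    for w in kmers:
        ids.append(f"k_{w}")
        cats.append("kmer")
        cks.append(w)
        seqs.append(build_probe_sequence(w, k))

    rep_idx = rng_rep.choice(n_kmers, size=layout["n_replicates"], replace=False)
    rep_idx.sort()
    for i, j in enumerate(rep_idx):
        w = kmers[j]
        ids.append(f"r{i:06d}_{w}")
        cats.append("replicate")
        cks.append(w)
        seqs.append(build_probe_sequence(w, k))

    probe_len = 4 * k + len(PRIMER_SITE) + len(LINKER)
    for i in range(layout["n_random"]):
        ids.append(f"rnd{i:05d}")
        cats.append("random_control")
        cks.append("")
        seqs.append(_random_dna(rng_rand, probe_len))

    for i in range(layout["n_blank"]):
        ids.append(f"blank{i:05d}")
        cats.append("blank")
        cks.append("")
        seqs.append("")

    for i in range(layout["n_manufacturer"]):
        ids.append(f"mfg{i:05d}")
        cats.append("manufacturer")
        cks.append("")
        seqs.append("")

    order = rng_place.permutation(total)
    ncol = layout["n_columns"]
    df = pd.DataFrame(
        {
            "probe_id": ids,
            "category": pd.Categorical(cats, categories=CATEGORIES),
            "canonical_kmer": cks,
            "sequence": seqs,
        }
    )
    df["column"] = (order % ncol) + 1
    df["row"] = (order // ncol) + 1
    return ArrayDesign(
        probes=df,
        n_columns=ncol,
        n_rows=layout["n_rows"],
        k=k,
        seed=int(seed),
    )
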