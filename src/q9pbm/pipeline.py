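"""Formats, configuration, packaged fixtures, and the end-to-end driver.

Ties the stages together in the order the analysis runs: array design ->
simulated PBM hybridisation -> motif extraction -> substitution profiling ->
binding-curve fitting -> co-expression -> promoter synthesis and scanning ->
candidate-table integration -> GO tabulation.  Every stage draws its
randomness from a named substream of one config seed, and every output file
embeds the config hash and seed, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import array_design, binding, motif_discovery, simulate, targets
from .iupac import expand, matches_pattern
from .simulate import DEFAULT_MOTIFS, MotifSpec, PromoterSet
from .targets import CoexpressionResult

log = logging.getLogger("q9pbm")

#: The query transcription factor of the packaged candidate catalogue.
QUERY_GENE = "Os07g0182000"
#: Size of the co-expression neighbourhood the candidate catalogue was drawn
#: from (denominator of the published motif percentages).
NEIGHBORHOOD_SIZE = 85

_PATTERN_BY_NAME = {m.name: m.pattern for m in DEFAULT_MOTIFS}
_MOTIF_COLUMNS = (("GCN4", "gcn4_pos", "gcn4_seq"),
                  ("ACGT", "acgt_pos", "acgt_seq"),
                  ("ATGA", "atga_pos", "atga_seq"))


class FastaParseError(ValueError):
    """Malformed FASTA record (message carries the line number)."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; message names the stage and the cause."""


# ---------------------------------------------------------------- configuration

@dataclass
class PipelineConfig:
    """All tunables of the pipeline, serialisable as flat YAML key-value."""

    seed: int = 0
    k: int = 9
    baseline: float = simulate.DEFAULT_BASELINE
    noise_sigma: float = simulate.DEFAULT_NOISE_SIGMA
    min_r: float = 0.55
    depth: int = 1
    promoter_length: int = 1000
    max_motifs: int = 3
    min_cluster: int = 10
    min_matches: int = 6
    single_base_threshold: float = 0.75
    degenerate_threshold: float = 0.25
    core_min_ic: float = 0.5
    motifs: tuple[MotifSpec, ...] = DEFAULT_MOTIFS

    def __post_init__(self) -> None:
        if not 0 < self.single_base_threshold <= 1:
            raise ValueError("single_base_threshold must be in (0, 1]")
        if not 0 < self.degenerate_threshold <= 0.5:
            raise ValueError("degenerate_threshold must be in (0, 0.5]")
        if not -1 <= self.min_r <= 1:
            raise ValueError("min_r must be in [-1, 1]")
        if self.depth < 1 or self.max_motifs < 1 or self.promoter_length < 1:
            raise ValueError("depth, max_motifs and promoter_length must be >= 1")

    def to_flat_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["motifs"] = ";".join(
            f"{m.name}:{m.pattern}:{m.mean_intensity:g}" for m in self.motifs
        )
        return d

    @classmethod
    def from_flat_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("motifs"), str):
            specs = []
            for item in d["motifs"].split(";"):
                name, pattern, mean = item.split(":")
                specs.append(MotifSpec(name, pattern, float(mean)))
            d["motifs"] = tuple(specs)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_flat_dict(yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_flat_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [f"q9pbm config={self.config_hash} seed={self.seed}"]


# ---------------------------------------------------------------------- formats

def read_fasta(path, expected_length: int | None = None) -> PromoterSet:
    """Read promoters from FASTA; sequences are uppercased."""
    records: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records[rec.id] = str(rec.seq).upper()
    except ValueError as exc:
        raise FastaParseError(f"{path}: {exc}") from exc
    if not records:
        # biopython silently yields nothing for garbage input; be strict
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.strip():
                    if not line.startswith(">"):
                        raise FastaParseError(
                            f"{path}:{lineno}: expected '>' header, got {line[:20]!r}"
                        )
                    break
    if expected_length is None:
        lengths = {len(s) for s in records.values()}
        expected_length = lengths.pop() if len(lengths) == 1 else None
    if expected_length is None:
        raise FastaParseError(f"{path}: records have inconsistent lengths")
    return PromoterSet(records, length=expected_length)


def write_fasta(promoters: PromoterSet, path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(seq), id=gene, description="")
        for gene, seq in promoters.records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def write_expression_tsv(matrix: pd.DataFrame, path, header_lines=None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        matrix.to_csv(fh, sep="\t")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


# --------------------------------------------------------------------- fixtures

def load_candidate_fixture() -> pd.DataFrame:
    """The packaged 44-gene candidate catalogue (validated on load)."""
    with resources.files("q9pbm.data").joinpath("candidate_genes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype=str).fillna("")
    if df["gene_id"].nunique() != 44 or len(df) != 44:
        raise ValueError("candidate fixture must list 44 distinct genes")
    for name, pos_col, seq_col in _MOTIF_COLUMNS:
        pattern = _PATTERN_BY_NAME[name]
        for _, row in df.iterrows():
            seq = row[seq_col]
            if seq and not matches_pattern(seq, pattern):
                raise ValueError(
                    f"{row['gene_id']}: {seq!r} does not match {name} "
                    f"pattern {pattern}"
                )
            if row[pos_col] and not seq:
                raise ValueError(f"{row['gene_id']}: position without sequence")
    return df


def load_go_fixture() -> pd.DataFrame:
    """Packaged GO term / gene associations of the candidate genes."""
    with resources.files("q9pbm.data").joinpath("go_annotations.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype=str)


def fixture_promoter_annotations(
    fixture: pd.DataFrame | None = None,
) -> dict[str, list[tuple[str, int]]]:
    """gene -> [(motif_sequence, position)] for every mappable annotation.

    Genes whose motif has no recorded position (the query's own row) get an
    empty list, so their promoters are synthesised motif-free.
    """
    df = load_candidate_fixture() if fixture is None else fixture
    out: dict[str, list[tuple[str, int]]] = {}
    for _, row in df.iterrows():
        plants = []
        for _name, pos_col, seq_col in _MOTIF_COLUMNS:
            if row[pos_col]:
                plants.append((row[seq_col], int(row[pos_col])))
        out[row["gene_id"]] = plants
    return out


def fixture_gene_annotations(
    fixture: pd.DataFrame | None = None,
    go: pd.DataFrame | None = None,
) -> dict[str, tuple[str, list[str]]]:
    """gene -> (description, [go terms]) from the packaged fixtures."""
    df = load_candidate_fixture() if fixture is None else fixture
    go_df = load_go_fixture() if go is None else go
    terms: dict[str, list[str]] = {}
    for _, row in go_df.iterrows():
        terms.setdefault(row["gene_id"], []).append(row["go_id"])
    return {
        row["gene_id"]: (row["description"], terms.get(row["gene_id"], []))
        for _, row in df.iterrows()
    }


def fixture_coexpression(fixture: pd.DataFrame | None = None) -> CoexpressionResult:
    """The candidate catalogue as a depth-1 co-expression result.

    Neighbours are the 43 non-query genes with their recorded r-values.
    """
    df = load_candidate_fixture() if fixture is None else fixture
    neighbors = [
        (row["gene_id"], float(row["r"]), 1)
        for _, row in df.iterrows()
        if row["gene_id"] != QUERY_GENE
    ]
    neighbors.sort(key=lambda t: (-t[1], t[0]))
    return CoexpressionResult(query=QUERY_GENE, neighbors=neighbors)


def go_term_names(go: pd.DataFrame | None = None) -> dict[str, str]:
    go_df = load_go_fixture() if go is None else go
    return dict(zip(go_df["go_id"], go_df["go_name"]))


# ----------------------------------------------------------------------- driver

def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on seeded synthetic data plus the packaged fixtures.

    Writes motif JSON, rank-fit JSON, substitution TSVs, Kd JSON, candidate
    and GO report TSVs under *outdir* and returns the report as a dict.
    Identical config -> byte-identical outputs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = config.header_lines()
    report: dict = {"config": config.to_flat_dict(),
                    "config_hash": config.config_hash}

    log.info("array design: k=%d seed=%d", config.k, config.seed)
    design = _stage("array_design")(array_design.design_array)(
        config.seed, config.k
    )
    report["array"] = {
        "n_spots": len(design),
        "grid": [design.n_columns, design.n_rows],
        "category_counts": design.category_counts,
    }

    log.info("simulating PBM signals: baseline=%g sigma=%g",
             config.baseline, config.noise_sigma)
    signals = _stage("pbm_simulation")(simulate.simulate_pbm_signals)(
        design, list(config.motifs), config.baseline, config.noise_sigma,
        config.seed,
    )
    signals.to_tsv(out / "signals.tsv", header_lines=header)

    log.info("motif extraction: max_motifs=%d min_cluster=%d min_matches=%d",
             config.max_motifs, config.min_cluster, config.min_matches)
    fit, models = _stage("motif_extraction")(motif_discovery.extract_motifs)(
        signals, design,
        max_motifs=config.max_motifs,
        min_cluster=config.min_cluster,
        min_matches=config.min_matches,
        single_base_threshold=config.single_base_threshold,
        degenerate_threshold=config.degenerate_threshold,
        core_min_ic=config.core_min_ic,
    )
    report["rank_fit"] = dataclasses.asdict(fit)
    report["motifs"] = [m.to_dict() for m in models]
    with open(out / "motifs.json", "w") as fh:
        json.dump({"header": header, "rank_fit": report["rank_fit"],
                   "motifs": report["motifs"]}, fh, indent=2)
    (out / "motifs.meme").write_text(motif_discovery.to_meme(models))

    log.info("substitution profiles for %d motif cores", len(models))
    report["substitution"] = {}
    for model in models:
        core = expand(model.core)[0]  # first exact realisation of the core
        if not 4 <= len(core) <= 9:
            log.warning("skipping substitution profile for core %r", model.core)
            continue
        profile = _stage("substitution_profile")(binding.substitution_profile)(
            core, signals, design,
        )
        frame = profile.to_frame()
        with open(out / f"substitution_{profile.core}.tsv", "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            fh.write(f"# core {profile.core} reference_mean "
                     f"{profile.reference_mean:.6g} "
                     f"n={profile.reference_count}\n")
            frame.to_csv(fh, sep="\t", index=False)
        report["substitution"][profile.core] = {
            "reference_mean": profile.reference_mean,
            "min_variant_mean": float(min(profile.variant_means.values())),
            "max_variant_mean": float(max(profile.variant_means.values())),
        }

    log.info("binding-curve fits at the standard concentration series")
    kd_true = {"GCN4": 0.6458, "ACGT": 0.3353, "ATGA": 1.117}
    report["kd"] = {}
    for i, (name, kd) in enumerate(kd_true.items()):
        curve = simulate.simulate_binding_curve(
            kd, bmax=1.0, noise_sd=0.02, seed=config.seed * 101 + i
        )
        curve.to_tsv(out / f"curve_{name}.tsv")
        fitted = _stage("kd_fit")(binding.fit_kd)(curve)
        report["kd"][name] = {
            "true_kd": kd, "kd": fitted.kd, "bmax": fitted.bmax,
            "rss": fitted.rss, "converged": fitted.converged,
        }
    with open(out / "kd.json", "w") as fh:
        json.dump({"header": header, "fits": report["kd"]}, fh, indent=2)

    log.info("co-expression recovery: min_r=%g depth=%d",
             config.min_r, config.depth)
    expr = simulate.simulate_expression(
        n_background=200, neighbor_r=[0.9, 0.8, 0.7, 0.6],
        n_samples=500, seed=config.seed,
    )
    write_expression_tsv(expr, out / "expression.tsv", header_lines=header)
    coexpr_sim = _stage("coexpression")(targets.coexpression_neighbors)(
        expr, "query", min_r=config.min_r, depth=config.depth
    )
    report["coexpression_demo"] = {
        "n_neighbors": len(coexpr_sim.neighbors),
        "neighbors": [[g, round(r, 4), d] for g, r, d in coexpr_sim.neighbors],
    }

    log.info("promoter synthesis and scan over the packaged candidate catalogue")
    fixture = load_candidate_fixture()
    annotations = fixture_promoter_annotations(fixture)
    promoters = _stage("promoter_simulation")(simulate.simulate_promoters)(
        annotations, seed=config.seed, length=config.promoter_length
    )
    write_fasta(promoters, out / "promoters.fasta")
    hits = _stage("promoter_scan")(targets.scan_promoter_set)(
        promoters, config.motifs
    )

    coexpr = fixture_coexpression(fixture)
    table = _stage("integration")(targets.integrate)(
        coexpr, hits, fixture_gene_annotations(fixture),
        denominator=NEIGHBORHOOD_SIZE,
    )
    with open(out / "candidates.tsv", "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        table.to_frame().to_csv(fh, sep="\t", index=False)
    report["candidates"] = {
        "n_rows": len(table),
        "totals": table.totals,
        "percentages": table.percentages,
        "denominator": table.denominator,
    }

    groups = _stage("go_tabulation")(targets.go_tabulate)(
        table, go_term_names()
    )
    with open(out / "go_report.tsv", "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("go_id\tgo_name\tn_genes\tgenes\n")
        names = go_term_names()
        for term, genes in groups.items():
            fh.write(f"{term}\t{names.get(term, '')}\t{len(genes)}\t"
                     f"{';'.join(genes)}\n")
    report["go"] = {t: len(g) for t, g in groups.items()}

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def require_inputs(*paths) -> None:
    """Fail fast with the offending path when an input file is missing."""
    for p in paths:
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"required input not found: {p}")


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
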