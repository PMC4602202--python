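"""Synthetic planted-signal universe for end-to-end testing.

The generator fabricates a self-contained miniature of the data a real
prioritization run consumes: genes, diseases, candidate variants, the
eight genomic sources, phenotype term counts, and causative/neutral
labels.  The causal structure is planted as follows:

* diseases are grouped into phenotype clusters; diseases in a cluster
  draw term counts from a shared signature vocabulary, so they end up
  mutually most-similar under TF-IDF cosine;
* each cluster owns a disjoint pool of genes; a disease's truth-associated
  gene module is sampled from its cluster pool with probability
  ``signal_strength`` (and from the whole genome otherwise), so cluster
  mates share module genes in proportion to the signal;
* module-pool genes co-behave across the sources — correlated expression,
  shared pathway/domain/GO/miRNA memberships, enriched binding-site
  counts, dense within-pool network edges — again mixed towards
  background as the signal weakens;
* causative variants sit in truth-associated genes and draw deleterious-
  mode functional scores, neutral variants draw benign-mode scores, each
  with probability ``signal_strength`` (otherwise a shared null), so at
  zero signal the two classes are statistically identical;
* a configurable fraction of scores is masked missing, exercising the
  zero-imputation path.

Everything is driven by one integer seed; the same seed reproduces the
universe exactly.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError
from .phenotype import phenotype_similarity, tfidf_vectors
from .similarity import SOURCES, GeneSimilarityMatrix, build_similarity_matrix
from .variants import FLIPPED_SCORES, VARIANT_SCORES, VariantRecord

#: Raw scale (lo, hi) of each functional score, loosely modeled on the
#: published ranges of the corresponding tools.
SCORE_SCALES: dict[str, tuple[float, float]] = {
    "SIFT": (0.0, 1.0),
    "PolyPhen2": (0.0, 1.0),
    "LRT": (0.0, 1.0),
    "MutationTaster": (0.0, 1.0),
    "MutationAccessor": (-5.0, 5.0),
    "MSRV": (0.0, 1.0),
    "GERP": (-12.0, 6.0),
    "Phylop": (-14.0, 10.0),
    "SiPhy": (0.0, 30.0),
    "CADD": (0.0, 40.0),
    "SInBaD": (0.0, 1.0),
}

# beta parameters of the deleterious / benign / null score modes
_DELETERIOUS = (6.0, 2.0)
_BENIGN = (2.0, 6.0)
_NULL = (2.0, 2.0)


@dataclass(frozen=True)
class UniverseConfig:
    """Sizes, signal level and seed of a synthetic universe."""

    n_genes: int = 300
    n_diseases: int = 40
    n_tissues: int = 40
    n_terms: int = 150
    n_go_terms: int = 120
    n_pathways: int = 60
    n_domains: int = 60
    n_factors: int = 40
    n_mirnas: int = 50
    n_causative_variants: int = 400
    n_neutral_variants: int = 800
    n_disease_control_variants: int = 200
    n_clusters: int = 8
    module_size: int = 8
    cluster_pool_size: int = 24
    signal_strength: float = 0.8
    missing_rate: float = 0.2
    all_deleterious: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.signal_strength <= 1.0:
            raise InputError("signal_strength must be in [0, 1]")
        if self.n_clusters * self.cluster_pool_size > self.n_genes:
            raise InputError(
                "cluster pools exceed the gene universe: "
                f"{self.n_clusters} x {self.cluster_pool_size} > {self.n_genes}"
            )
        if self.module_size > self.cluster_pool_size:
            raise InputError("module_size cannot exceed cluster_pool_size")
        if min(
            self.n_genes, self.n_diseases, self.n_tissues, self.n_terms,
            self.n_causative_variants, self.n_neutral_variants,
        ) < 1:
            raise InputError("all counts must be positive")
        if self.n_diseases < self.n_clusters:
            raise InputError("need at least one disease per cluster")


@dataclass
class SyntheticUniverse:
    """A generated universe, held in the in-memory structures the
    pipeline modules consume."""

    config: UniverseConfig
    genes: list[str]
    diseases: list[str]
    cluster_of_disease: dict[str, int]
    associations: dict[str, set[str]]
    positives: list[tuple[str, VariantRecord]]
    neutrals: list[VariantRecord]
    disease_control: list[VariantRecord]
    score_table: pd.DataFrame
    expression: pd.DataFrame
    go_annotations: dict[str, set[str]]
    kegg_sets: dict[str, list[str]]
    pfam_sets: dict[str, list[str]]
    mirna_sets: dict[str, list[str]]
    ppi_edges: list[tuple[str, str]]
    seq_edges: list[tuple[str, str]]
    tsfc: pd.DataFrame
    term_counts: pd.DataFrame
    matrices: dict[str, GeneSimilarityMatrix] = field(default_factory=dict)

    def source_data(self, source: str):
        return {
            "Exp": self.expression,
            "GO": self.go_annotations,
            "KEGG": self.kegg_sets,
            "Seq": self.seq_edges,
            "Pfam": self.pfam_sets,
            "PPI": self.ppi_edges,
            "TSFC": self.tsfc,
            "miRNA": self.mirna_sets,
        }[source]

    def build_matrices(self) -> dict[str, GeneSimilarityMatrix]:
        """Build (and cache) the 8 transformed similarity matrices."""
        if not self.matrices:
            self.matrices = {
                s: build_similarity_matrix(s, self.source_data(s), self.genes)
                for s in SOURCES
            }
        return self.matrices

    def to_pipeline_data(self):
        from .model import PipelineData

        matrices = self.build_matrices()
        vectors = tfidf_vectors(self.term_counts)
        phen = phenotype_similarity(vectors)
        return PipelineData(
            score_table=self.score_table,
            matrices=matrices,
            phenotype=phen,
            associations=self.associations,
            positives=self.positives,
            neutrals=self.neutrals,
            disease_control=self.disease_control,
        )


def _draw_scores(
    rng: np.random.Generator, deleterious: bool, signal: float, missing: float
) -> dict[str, float]:
    mode = _DELETERIOUS if deleterious else _BENIGN
    out: dict[str, float] = {}
    for name in VARIANT_SCORES:
        a, b = mode if rng.random() < signal else _NULL
        u = rng.beta(a, b)  # deleteriousness on the unit scale
        unit = 1.0 - u if name in FLIPPED_SCORES else u
        lo, hi = SCORE_SCALES[name]
        out[name] = float("nan") if rng.random() < missing else lo + unit * (hi - lo)
    return out


def _make_variant(
    rng: np.random.Generator,
    gene: str,
    gene_index: Mapping[str, int],
    counters: dict[str, int],
) -> VariantRecord:
    gi = gene_index[gene]
    counters[gene] = counters.get(gene, 0) + 1
    chrom = f"chr{gi % 22 + 1}"
    pos = (gi + 1) * 100_000 + counters[gene]
    ref, alt = rng.choice(np.array(list("ACGT")), size=2, replace=False)
    return VariantRecord(chrom, int(pos), str(ref), str(alt), gene)


def generate_universe(cfg: UniverseConfig) -> SyntheticUniverse:
    """Generate a deterministic universe with the planted causal signal."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    s = cfg.signal_strength

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    diseases = [f"D{i:03d}" for i in range(cfg.n_diseases)]
    gene_index = {g: i for i, g in enumerate(genes)}
    cluster_of = {d: i % cfg.n_clusters for i, d in enumerate(diseases)}

    # disjoint per-cluster gene pools; leftover genes are background
    perm = rng.permutation(cfg.n_genes)
    pools = [
        [genes[j] for j in perm[c * cfg.cluster_pool_size:(c + 1) * cfg.cluster_pool_size]]
        for c in range(cfg.n_clusters)
    ]

    # truth associations: module genes from own pool w.p. signal
    associations: dict[str, set[str]] = {}
    for d in diseases:
        pool = pools[cluster_of[d]]
        module: set[str] = set()
        while len(module) < cfg.module_size:
            if rng.random() < s:
                module.add(pool[rng.integers(len(pool))])
            else:
                module.add(genes[rng.integers(cfg.n_genes)])
        associations[d] = module

    # phenotype term counts: cluster signature vocabulary + background
    terms = [f"T{i:04d}" for i in range(cfg.n_terms)]
    sig_per_cluster = max(4, cfg.n_terms // (2 * cfg.n_clusters))
    term_counts = pd.DataFrame(0, index=diseases, columns=terms, dtype=int)
    for d in diseases:
        c = cluster_of[d]
        sig = terms[c * sig_per_cluster:(c + 1) * sig_per_cluster]
        background = terms[cfg.n_clusters * sig_per_cluster:] or terms
        for _ in range(80):
            if sig and rng.random() < 0.7:
                t = sig[rng.integers(len(sig))]
            else:
                t = background[rng.integers(len(background))]
            term_counts.at[d, t] += 1

    # expression: cluster latent factor + independent noise
    w = 0.85 * s
    factors = rng.standard_normal((cfg.n_clusters, cfg.n_tissues))
    expr = rng.standard_normal((cfg.n_genes, cfg.n_tissues))
    for c, pool in enumerate(pools):
        for g in pool:
            i = gene_index[g]
            expr[i] = w * factors[c] + np.sqrt(max(1.0 - w * w, 0.0)) * expr[i]
    expression = pd.DataFrame(
        expr, index=genes, columns=[f"tissue{j:02d}" for j in range(cfg.n_tissues)]
    )

    # GO annotations: cluster signature terms + random background terms
    go_terms = [f"GO{i:04d}" for i in range(cfg.n_go_terms)]
    go_sig = max(4, cfg.n_go_terms // (2 * cfg.n_clusters))
    go_annotations: dict[str, set[str]] = {g: set() for g in genes}
    for c, pool in enumerate(pools):
        sig = go_terms[c * go_sig:(c + 1) * go_sig]
        for g in pool:
            for t in sig:
                if rng.random() < 0.6 * s:
                    go_annotations[g].add(t)
    background_go = go_terms[cfg.n_clusters * go_sig:] or go_terms
    for g in genes:
        for t in rng.choice(background_go, size=min(3, len(background_go)), replace=False):
            go_annotations[g].add(str(t))

    def _gene_sets(prefix: str, n_sets: int) -> dict[str, list[str]]:
        names = [f"{prefix}{i:03d}" for i in range(n_sets)]
        sets: dict[str, set[str]] = {name: set() for name in names}
        for c, pool in enumerate(pools):
            for k in range(2):  # two signature sets per cluster
                name = names[(2 * c + k) % n_sets]
                for g in pool:
                    if rng.random() < 0.7 * s:
                        sets[name].add(g)
        for name in names:
            for g in genes:
                if rng.random() < 0.05:
                    sets[name].add(g)
        return {name: sorted(m) for name, m in sets.items() if m}

    kegg_sets = _gene_sets("KEGG", cfg.n_pathways)
    pfam_sets = _gene_sets("PF", cfg.n_domains)
    mirna_sets = _gene_sets("MIR", cfg.n_mirnas)

    # TSFC binding-site counts: Poisson background + cluster signature lift
    tf_names = [f"TF{i:03d}" for i in range(cfg.n_factors)]
    tsfc_counts = rng.poisson(0.3, size=(cfg.n_genes, cfg.n_factors)).astype(float)
    tf_sig = max(3, cfg.n_factors // (2 * cfg.n_clusters))
    for c, pool in enumerate(pools):
        cols = [(c * tf_sig + j) % cfg.n_factors for j in range(tf_sig)]
        for g in pool:
            tsfc_counts[gene_index[g], cols] += rng.poisson(3.0 * s, size=len(cols))
    tsfc = pd.DataFrame(tsfc_counts, index=genes, columns=tf_names)

    # networks: dense within-pool edges over a sparse background
    def _network(p_in: float, p_bg: float) -> list[tuple[str, str]]:
        edges: set[tuple[str, str]] = set()
        for pool in pools:
            for i in range(len(pool)):
                for j in range(i + 1, len(pool)):
                    if rng.random() < p_in:
                        edges.add(tuple(sorted((pool[i], pool[j]))))
        n_pairs = cfg.n_genes * (cfg.n_genes - 1) // 2
        n_bg = rng.binomial(n_pairs, p_bg)
        while n_bg > 0:
            i, j = rng.integers(cfg.n_genes, size=2)
            if i != j:
                edges.add(tuple(sorted((genes[i], genes[j]))))
                n_bg -= 1
        return sorted(edges)

    ppi_edges = _network(0.08 + 0.4 * s, 1.5 / cfg.n_genes)
    seq_edges = _network(0.06 + 0.35 * s, 1.0 / cfg.n_genes)

    # variants and their functional scores
    counters: dict[str, int] = {}
    positives: list[tuple[str, VariantRecord]] = []
    rows: list[dict] = []

    def _add_variant(gene: str, deleterious: bool) -> VariantRecord:
        v = _make_variant(rng, gene, gene_index, counters)
        row = {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt, "gene": gene}
        row.update(_draw_scores(rng, deleterious, s, cfg.missing_rate))
        rows.append(row)
        return v

    for i in range(cfg.n_causative_variants):
        d = diseases[i % cfg.n_diseases]
        gene = sorted(associations[d])[rng.integers(len(associations[d]))]
        positives.append((d, _add_variant(gene, deleterious=True)))

    neutrals = [
        _add_variant(genes[rng.integers(cfg.n_genes)], cfg.all_deleterious)
        for _ in range(cfg.n_neutral_variants)
    ]

    # disease-control variants emulate an external database of variants
    # causative for diseases *outside* the query set: hidden modules are
    # sampled per cluster the same way as query-disease modules
    hidden_modules: list[list[str]] = []
    for c in range(cfg.n_clusters):
        pool = pools[c]
        module: set[str] = set()
        while len(module) < cfg.module_size:
            if rng.random() < s:
                module.add(pool[rng.integers(len(pool))])
            else:
                module.add(genes[rng.integers(cfg.n_genes)])
        hidden_modules.append(sorted(module))
    disease_control = []
    for i in range(cfg.n_disease_control_variants):
        module = hidden_modules[rng.integers(len(hidden_modules))]
        gene = module[rng.integers(len(module))]
        disease_control.append(_add_variant(gene, deleterious=True))

    score_table = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene", *VARIANT_SCORES])

    return SyntheticUniverse(
        config=cfg,
        genes=genes,
        diseases=diseases,
        cluster_of_disease=cluster_of,
        associations=associations,
        positives=positives,
        neutrals=neutrals,
        disease_control=disease_control,
        score_table=score_table,
        expression=expression,
        go_annotations=go_annotations,
        kegg_sets=kegg_sets,
        pfam_sets=pfam_sets,
        mirna_sets=mirna_sets,
        ppi_edges=ppi_edges,
        seq_edges=seq_edges,
        tsfc=tsfc,
        term_counts=term_counts,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_universe(universe: SyntheticUniverse, directory: str | Path) -> None:
    """Write the universe as the file formats the readers consume."""
    from . import io as sfio

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    all_variants = (
        [v for _, v in universe.positives]
        + universe.neutrals
        + universe.disease_control
    )
    sfio.write_vcf(all_variants, d / "candidates.vcf")
    sfio.write_score_table(universe.score_table, d / "scores.tsv")
    sfio.write_matrix_tsv(universe.expression, d / "expression.tsv")
    sfio.write_matrix_tsv(universe.tsfc, d / "tsfc.tsv")
    sfio.write_matrix_tsv(universe.term_counts, d / "term_counts.tsv")
    sfio.write_gmt(universe.kegg_sets, d / "kegg.gmt")
    sfio.write_gmt(universe.pfam_sets, d / "pfam.gmt")
    sfio.write_gmt(universe.mirna_sets, d / "mirna.gmt")
    sfio.write_edge_list(universe.ppi_edges, d / "ppi_edges.tsv")
    sfio.write_edge_list(universe.seq_edges, d / "seq_edges.tsv")
    sfio.write_two_column(
        sorted(
            (g, t) for g, ts in universe.go_annotations.items() for t in sorted(ts)
        ),
        d / "go_annotations.tsv",
    )
    sfio.write_two_column(
        sorted((dd, g) for dd, gs in universe.associations.items() for g in sorted(gs)),
        d / "associations.tsv",
    )
    sfio.write_two_column(
        [(dd, f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}") for dd, v in universe.positives],
        d / "positive_pairs.tsv",
    )
    sfio.write_two_column(
        [("neutral", f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}") for v in universe.neutrals]
        + [
            ("disease_control", f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}")
            for v in universe.disease_control
        ],
        d / "variant_labels.tsv",
    )
    (d / "genes.txt").write_text("\n".join(universe.genes) + "\n")
    config_items = sorted(vars(universe.config).items())
    (d / "config.tsv").write_text(
        "".join(f"{k}\t{v}\n" for k, v in config_items)
    )


def load_universe(directory: str | Path) -> SyntheticUniverse:
    """Read a written universe back into memory (round-trip of
    :func:`write_universe`)."""
    from . import io as sfio

    d = Path(directory)
    cfg_fields = {}
    for k, v in sfio.read_two_column(d / "config.tsv"):
        cfg_fields[k] = v
    cfg = UniverseConfig(
        **{
            k: (
                v == "True"
                if k == "all_deleterious"
                else float(v) if k in ("signal_strength", "missing_rate") else int(v)
            )
            for k, v in cfg_fields.items()
        }
    )
    genes = (d / "genes.txt").read_text().split()
    variants = {
        v.key: v for v in sfio.read_vcf_candidates(d / "candidates.vcf")
    }

    def _lookup(token: str) -> VariantRecord:
        chrom, pos, ref, alt = token.split(":")
        return variants[(chrom, int(pos), ref, alt)]

    positives = [
        (dd, _lookup(tok)) for dd, tok in sfio.read_two_column(d / "positive_pairs.tsv")
    ]
    neutrals, disease_control = [], []
    for label, tok in sfio.read_two_column(d / "variant_labels.tsv"):
        (neutrals if label == "neutral" else disease_control).append(_lookup(tok))
    associations = sfio.read_associations(d / "associations.tsv")
    term_counts = sfio.read_matrix_tsv(d / "term_counts.tsv")
    diseases = list(term_counts.index)
    return SyntheticUniverse(
        config=cfg,
        genes=genes,
        diseases=diseases,
        cluster_of_disease={dd: i % cfg.n_clusters for i, dd in enumerate(diseases)},
        associations=associations,
        positives=positives,
        neutrals=neutrals,
        disease_control=disease_control,
        score_table=sfio.read_score_table(d / "scores.tsv"),
        expression=sfio.read_matrix_tsv(d / "expression.tsv"),
        go_annotations=sfio.read_annotations(d / "go_annotations.tsv"),
        kegg_sets=sfio.read_gmt(d / "kegg.gmt"),
        pfam_sets=sfio.read_gmt(d / "pfam.gmt"),
        mirna_sets=sfio.read_gmt(d / "mirna.gmt"),
        ppi_edges=sfio.read_edge_list(d / "ppi_edges.tsv"),
        seq_edges=sfio.read_edge_list(d / "seq_edges.tsv"),
        tsfc=sfio.read_matrix_tsv(d / "tsfc.tsv"),
        term_counts=term_counts,
    )


def planted_signal_benchmark(cfg: UniverseConfig, cv_config=None) -> dict:
    """Generate a universe, run leakage-controlled CV, return the metrics.

    Returns a dict with ``mrr`` and ``mean_auc`` (both fractions in
    [0, 1]) plus the problem sizes used.
    """
    from .model import CVConfig, run_cross_validation

    universe = generate_universe(cfg)
    data = universe.to_pipeline_data()
    cv = cv_config or CVConfig(seed=cfg.seed)
    result = run_cross_validation(data, cv)
    return {
        "mrr": result.mrr,
        "mean_auc": result.mean_auc,
        "n_diseases": len({d for d, _ in universe.positives}),
        "n_positive_variants": len(universe.positives),
        "n_neutral_variants": len(universe.neutrals),
        "result": result,
    }
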