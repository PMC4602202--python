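"""Disease phenotype similarity and seed-gene selection.

Disease phenotype records arrive as counts of standardized clinical terms
(the product of an upstream text-mining step).  Each disease is embedded
as a TF-IDF vector — term frequency is the within-record relative count,
inverse document frequency the negative log of the fraction of records
containing the term — and phenotype similarity is the cosine between
vectors.  Seed genes for a query disease are the genes known to associate
with the query itself or with its most phenotypically similar diseases;
they anchor the guilt-by-association gene scores.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError
from .variants import VariantRecord


@dataclass(frozen=True)
class SeedGeneSet:
    """Seed genes for one query disease, with provenance.

    ``provenance`` maps every seed gene to the diseases (the query and/or
    similar diseases) whose known associations contributed it.
    """

    query_disease: str
    seed_genes: frozenset[str]
    provenance: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        stray = set(self.provenance) - set(self.seed_genes)
        if stray:
            raise InputError(f"provenance for non-seed genes: {sorted(stray)}")


def tfidf_vectors(
    term_counts: pd.DataFrame, base: float | None = None
) -> pd.DataFrame:
    """TF-IDF embedding of disease term-count records.

    ``term_counts`` is diseases x terms with non-negative integer counts.
    TF(t, d) = count(t, d) / total counts of d; IDF(t) = -log(n_d(t) / N)
    with natural log by default (``base`` only rescales the vectors
    uniformly, leaving cosines unchanged).  All-zero records produce zero
    vectors with a warning.
    """
    if term_counts.shape[0] == 0:
        raise InputError("empty disease term-count corpus")
    counts = term_counts.to_numpy(dtype=float)
    if (counts < 0).any():
        raise InputError("negative term counts")
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} disease record(s) have no terms; "
            "their TF-IDF vectors are zero",
            stacklevel=2,
        )
    tf = np.zeros_like(counts)
    tf[~empty] = counts[~empty] / totals[~empty, None]
    doc_freq = (counts > 0).sum(axis=0)
    n_d = counts.shape[0]
    with np.errstate(divide="ignore"):
        idf = -np.log(doc_freq / n_d)
    idf = np.where(np.isfinite(idf), idf, 0.0)
    if base is not None:
        idf = idf / np.log(base)
    return pd.DataFrame(
        tf * idf[None, :], index=term_counts.index, columns=term_counts.columns
    )


def phenotype_similarity(vectors: pd.DataFrame) -> pd.DataFrame:
    """Symmetric disease x disease cosine-similarity matrix.

    Zero-vector diseases have similarity 0 to everything, themselves
    included.
    """
    x = vectors.to_numpy(dtype=float)
    norms = np.linalg.norm(x, axis=1)
    covered = norms > 0
    unit = np.zeros_like(x)
    unit[covered] = x[covered] / norms[covered, None]
    sim = np.clip(unit @ unit.T, 0.0, 1.0)
    np.fill_diagonal(sim, np.where(covered, 1.0, 0.0))
    return pd.DataFrame(sim, index=vectors.index, columns=vectors.index)


def top_similar_diseases(
    query: str, matrix: pd.DataFrame, k: int = 10
) -> list[str]:
    """The ``k`` diseases most phenotypically similar to ``query``.

    The query itself is always excluded.  Ties are broken by lexicographic
    disease id so the output is deterministic; if fewer than ``k`` other
    diseases exist, all are returned (in descending-similarity order).
    """
    if query not in matrix.index:
        raise InputError(f"unknown query disease {query!r}")
    sims = matrix.loc[query].drop(labels=[query])
    order = sorted(sims.index, key=lambda d: (-sims[d], d))
    return order[:k]


def collect_seed_genes(
    query: str,
    similar: Sequence[str],
    associations: Mapping[str, Iterable[str]],
) -> SeedGeneSet:
    """Union of genes associated with the query or its similar diseases."""
    provenance: dict[str, set[str]] = {}
    for disease in [query, *similar]:
        for gene in associations.get(disease, ()):  # missing disease: no genes
            provenance.setdefault(gene, set()).add(disease)
    return SeedGeneSet(
        query_disease=query,
        seed_genes=frozenset(provenance),
        provenance={g: frozenset(ds) for g, ds in provenance.items()},
    )


def filter_seeds_unbiased(
    seeds: SeedGeneSet,
    test_diseases: Iterable[str],
    test_variants: Iterable[VariantRecord],
    associations: Mapping[str, Iterable[str]],
) -> SeedGeneSet:
    """Remove seed genes that leak test information.

    A seed gene is dropped when it is associated with any test disease or
    hosts any test variant, so seed-derived association scores share no
    gene-level information with the held-out data.
    """
    banned = {v.gene for v in test_variants}
    for disease in test_diseases:
        banned.update(associations.get(disease, ()))
    kept = seeds.seed_genes - banned
    return SeedGeneSet(
        query_disease=seeds.query_disease,
        seed_genes=frozenset(kept),
        provenance={g: seeds.provenance[g] for g in kept if g in seeds.provenance},
    )
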