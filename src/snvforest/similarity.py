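"""Gene functional-similarity matrices from eight genomic data sources.

Each source yields a raw gene-by-gene similarity in [0, 1]:

* ``Exp``   — absolute Pearson correlation of expression profiles across
  tissues;
* ``GO``    — cosine between vectors of information contents of ontology
  terms annotated to each gene;
* ``KEGG``, ``Pfam``, ``miRNA`` — cosine between binary membership vectors
  (pathways, protein domains, microRNA target sets);
* ``TSFC``  — cosine between transcription-factor binding-site count
  vectors over gene promoters;
* ``Seq``, ``PPI`` — a linear transform ``1 - d/D`` of the unweighted
  shortest-path distance ``d`` in a similarity/interaction network, with
  ``D`` the largest finite distance in the network.

Raw similarities are then sharpened with an exponential transform
``S = exp((r - 1) / sigma)`` where ``sigma`` is the standard deviation of
all off-diagonal raw values; the transform maps r = 1 to S = 1, is
strictly increasing in r, and amplifies the difference between strong and
weak similarities so that background similarity is pushed towards zero.

Genes absent from a source are retained in the output matrix with
similarity exactly 0 to every gene (including themselves), so downstream
association scores treat missing coverage as absence of evidence.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InputError

#: Canonical order of the eight genomic sources (also the gene-level
#: feature order).
SOURCES: tuple[str, ...] = ("Exp", "GO", "KEGG", "Seq", "Pfam", "PPI", "TSFC", "miRNA")

_NETWORK_SOURCES = frozenset({"Seq", "PPI"})


@dataclass(frozen=True)
class GeneSimilarityMatrix:
    """Transformed similarity matrix for one genomic source.

    ``matrix`` is a symmetric DataFrame indexed by gene id on both axes.
    Covered pairs hold values in (0, 1]; genes without coverage in the
    source have all-zero rows/columns.  ``sigma`` is the off-diagonal
    standard deviation of the raw similarities used by the exponential
    transform.
    """

    source: str
    matrix: pd.DataFrame
    sigma: float

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    def value(self, g: str, h: str) -> float:
        """Similarity between two genes; 0 for genes not in the matrix."""
        if g not in self.matrix.index or h not in self.matrix.index:
            return 0.0
        return float(self.matrix.at[g, h])


# ---------------------------------------------------------------------------
# scalar raw-similarity measures
# ---------------------------------------------------------------------------

def cosine_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """Cosine of the angle between two profile vectors; 0 if either is null."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise InputError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.clip(np.dot(u, v) / (nu * nv), 0.0, 1.0))


def expression_raw_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """|Pearson r| of two expression profiles; 0 when r is undefined."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise InputError(f"dimension mismatch: {u.shape} vs {v.shape}")
    if u.size < 2:
        raise InputError("expression profiles need at least 2 tissues")
    if np.std(u) == 0.0 or np.std(v) == 0.0:
        return 0.0
    r = np.corrcoef(u, v)[0, 1]
    return float(np.clip(abs(r), 0.0, 1.0))


def information_content_profile(
    annotations: Mapping[str, Iterable[str]],
    terms: Sequence[str] | None = None,
    base: float | None = None,
) -> pd.DataFrame:
    """Per-gene vectors of term information contents.

    The information content of a term is the negative logarithm of its
    relative occurrence frequency among annotated genes,
    ``IC(t) = -log(n_t / N)``; coordinate ``t`` of gene ``g`` is ``IC(t)``
    if ``g`` carries the annotation and 0 otherwise.  The logarithm base
    (default natural) only rescales all coordinates uniformly, so cosine
    similarities are invariant to it.
    """
    ann = {g: frozenset(ts) for g, ts in annotations.items()}
    if not ann or all(len(ts) == 0 for ts in ann.values()):
        raise InputError("empty annotation corpus")
    if terms is None:
        terms = sorted(set().union(*ann.values()))
    genes = sorted(ann)
    n_genes = len(genes)
    counts = pd.Series(0, index=list(terms), dtype=float)
    for ts in ann.values():
        for t in ts:
            if t in counts.index:
                counts[t] += 1
    with np.errstate(divide="ignore"):
        ic = -np.log(counts.to_numpy() / n_genes)
    if base is not None:
        ic = ic / np.log(base)
    ic = np.where(np.isfinite(ic), ic, 0.0)
    mat = np.zeros((n_genes, len(terms)))
    t_index = {t: j for j, t in enumerate(terms)}
    for i, g in enumerate(genes):
        for t in ann[g]:
            j = t_index.get(t)
            if j is not None:
                mat[i, j] = ic[j]
    return pd.DataFrame(mat, index=genes, columns=list(terms))


def shortest_path_raw_similarity(net: nx.Graph) -> pd.DataFrame:
    """Raw similarity ``1 - d/D`` from unweighted shortest-path distances.

    ``D`` is the largest finite pairwise distance across the network; pairs
    in different components get similarity 0, and every node has
    self-similarity 1.  Isolated nodes are allowed (similarity 0 to all
    others).
    """
    if net.number_of_nodes() == 0:
        raise InputError("empty network")
    nodes = sorted(net.nodes())
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for src, lengths in nx.all_pairs_shortest_path_length(net):
        i = index[src]
        for dst, d in lengths.items():
            dist[i, index[dst]] = d
    finite = dist[np.isfinite(dist)]
    diameter = float(finite.max())
    if diameter == 0.0:
        # no edges at all: only self-similarity is defined
        raw = np.eye(n)
    else:
        raw = 1.0 - dist / diameter
        raw[~np.isfinite(dist)] = 0.0
    return pd.DataFrame(raw, index=nodes, columns=nodes)


def exponential_transform(raw: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Apply ``S = exp((r - 1) / sigma)`` elementwise.

    ``sigma`` is the standard deviation of the off-diagonal raw values
    (the structurally-one diagonal is excluded so it cannot shrink sigma).
    Raises :class:`DegenerateInputError` when sigma is zero.
    """
    values = raw.to_numpy(dtype=float)
    n = values.shape[0]
    if n < 2:
        raise DegenerateInputError("need at least two genes for the transform")
    off = values[~np.eye(n, dtype=bool)]
    sigma = float(np.std(off))
    if sigma == 0.0:
        raise DegenerateInputError(
            "all off-diagonal raw similarities are identical (sigma = 0); "
            "the exponential transform is undefined"
        )
    s = np.exp((values - 1.0) / sigma)
    return pd.DataFrame(s, index=raw.index, columns=raw.columns), sigma


# ---------------------------------------------------------------------------
# vectorized matrix builders
# ---------------------------------------------------------------------------

def _cosine_raw_matrix(profiles: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """All-pairs cosine over rows; returns the matrix and a coverage mask."""
    x = profiles.to_numpy(dtype=float)
    norms = np.linalg.norm(x, axis=1)
    covered = norms > 0
    unit = np.zeros_like(x)
    unit[covered] = x[covered] / norms[covered, None]
    raw = np.clip(unit @ unit.T, 0.0, 1.0)
    np.fill_diagonal(raw, 1.0)
    raw[~covered, :] = 0.0
    raw[:, ~covered] = 0.0
    return pd.DataFrame(raw, index=profiles.index, columns=profiles.index), covered


def _abs_pearson_raw_matrix(expr: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    x = expr.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise InputError("expression matrix needs at least 2 tissues")
    covered = np.std(x, axis=1) > 0
    raw = np.zeros((x.shape[0], x.shape[0]))
    if covered.sum() >= 1:
        sub = x[covered]
        c = np.corrcoef(sub) if sub.shape[0] > 1 else np.ones((1, 1))
        raw[np.ix_(covered, covered)] = np.clip(np.abs(c), 0.0, 1.0)
    np.fill_diagonal(raw, 1.0)
    raw[~covered, :] = 0.0
    raw[:, ~covered] = 0.0
    return pd.DataFrame(raw, index=expr.index, columns=expr.index), covered


def _membership_profiles(
    gene_sets: Mapping[str, Iterable[str]], genes: Sequence[str]
) -> pd.DataFrame:
    set_names = sorted(gene_sets)
    mat = np.zeros((len(genes), len(set_names)))
    g_index = {g: i for i, g in enumerate(genes)}
    for j, name in enumerate(set_names):
        for g in gene_sets[name]:
            i = g_index.get(g)
            if i is not None:
                mat[i, j] = 1.0
    return pd.DataFrame(mat, index=list(genes), columns=set_names)


def build_similarity_matrix(
    source: str,
    data,
    gene_ids: Sequence[str] | None = None,
) -> GeneSimilarityMatrix:
    """Build the transformed similarity matrix for one genomic source.

    Parameters
    ----------
    source
        One of :data:`SOURCES`.
    data
        Source-specific raw input: an expression DataFrame (genes x
        tissues) for ``Exp``; a gene->terms mapping for ``GO``; a
        set-name->members mapping (GMT content) for ``KEGG``/``Pfam``/
        ``miRNA``; a count DataFrame (genes x factors) for ``TSFC``; an
        edge list of gene pairs or a :class:`networkx.Graph` for
        ``Seq``/``PPI``.
    gene_ids
        Optional gene universe for the output matrix.  Genes outside the
        source's coverage get all-zero rows/columns.
    """
    if source not in SOURCES:
        raise InputError(f"unknown source {source!r}; expected one of {SOURCES}")

    if source == "Exp":
        raw, covered = _abs_pearson_raw_matrix(data)
    elif source == "GO":
        profiles = information_content_profile(data)
        raw, covered = _cosine_raw_matrix(profiles)
    elif source in ("KEGG", "Pfam", "miRNA"):
        members = set().union(*map(set, data.values())) if data else set()
        profiles = _membership_profiles(data, sorted(members))
        raw, covered = _cosine_raw_matrix(profiles)
    elif source == "TSFC":
        raw, covered = _cosine_raw_matrix(data)
    else:  # Seq / PPI
        net = data if isinstance(data, nx.Graph) else nx.Graph(list(data))
        net.remove_edges_from(nx.selfloop_edges(net))
        raw = shortest_path_raw_similarity(net)
        covered = np.ones(len(raw), dtype=bool)

    transformed, sigma = exponential_transform(raw)
    values = transformed.to_numpy()
    values[~covered, :] = 0.0
    values[:, ~covered] = 0.0
    matrix = pd.DataFrame(values, index=raw.index, columns=raw.columns)

    if gene_ids is not None:
        universe = list(dict.fromkeys(gene_ids))
        extra = [g for g in matrix.index if g not in set(universe)]
        universe = universe + extra
        matrix = matrix.reindex(index=universe, columns=universe, fill_value=0.0)

    return GeneSimilarityMatrix(source=source, matrix=matrix, sigma=sigma)
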