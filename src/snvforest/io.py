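"""Readers and writers for the tabular formats used across the package.

All text formats are tab-separated with ``#`` comment lines; empty cells
mean missing.  Variant candidates are read from VCF (via pysam) with the
host gene taken from a configurable INFO key; multi-allelic records are
split and non-SNV alleles skipped with a logged count.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import joblib
import pandas as pd
import pysam

from .exceptions import InputError, ParseError
from .similarity import GeneSimilarityMatrix
from .variants import VARIANT_SCORES, VariantRecord

logger = logging.getLogger(__name__)

_SNV_BASES = frozenset("ACGT")

SCORE_TABLE_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", *VARIANT_SCORES]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_candidates(path: str | Path, gene_key: str = "GENE") -> list[VariantRecord]:
    """Read biallelic SNV records from a VCF, splitting multi-allelics.

    Non-SNV alleles and records without the gene INFO tag are skipped
    with logged counts.
    """
    records: list[VariantRecord] = []
    skipped_non_snv = 0
    skipped_no_gene = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            gene = rec.info.get(gene_key)
            if isinstance(gene, tuple):
                gene = gene[0]
            for alt in rec.alts or ():
                if (
                    len(rec.ref) != 1
                    or len(alt) != 1
                    or rec.ref not in _SNV_BASES
                    or alt not in _SNV_BASES
                ):
                    skipped_non_snv += 1
                    continue
                if not gene:
                    skipped_no_gene += 1
                    logger.warning(
                        "rejected %s:%d %s>%s: missing %s tag",
                        rec.chrom, rec.pos, rec.ref, alt, gene_key,
                    )
                    continue
                records.append(
                    VariantRecord(rec.chrom, rec.pos, rec.ref, alt, str(gene))
                )
    if skipped_non_snv:
        logger.info("skipped %d non-SNV allele(s)", skipped_non_snv)
    if skipped_no_gene:
        logger.info("rejected %d record(s) without a gene tag", skipped_no_gene)
    return records


def write_vcf(
    variants: Sequence[VariantRecord], path: str | Path, gene_key: str = "GENE"
) -> None:
    """Write variants as sorted VCFv4.2 text with the gene in INFO."""
    chroms = sorted({v.chrom for v in variants})
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            f'##INFO=<ID={gene_key},Number=1,Type=String,'
            'Description="Host gene symbol">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in ordered:
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                f"{gene_key}={v.gene}\n"
            )


# ---------------------------------------------------------------------------
# score tables and generic TSV
# ---------------------------------------------------------------------------

def read_score_table(path: str | Path) -> pd.DataFrame:
    """Variant score table keyed by chrom/pos/ref/alt with a gene column."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in SCORE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    keys = list(zip(df["chrom"], df["pos"], df["ref"], df["alt"]))
    if len(set(keys)) != len(keys):
        dup = pd.Series(keys).duplicated()
        raise ParseError(f"{path}: duplicate variant key at row {int(dup.idxmax()) + 2}")
    return df


def write_score_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Generic labeled numeric matrix (expression, counts, similarities)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate row id {dup!r}")
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.8g")


# ---------------------------------------------------------------------------
# GMT, edge lists, two-column tables
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name, description, tab-separated members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected name, description, members")
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set {name!r}")
            sets[name] = [m for m in parts[2:] if m]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Two-column undirected edge list; self-loops rejected."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not all(parts):
                raise ParseError(f"{path}:{lineno}: expected exactly two columns")
            a, b = parts
            if a == b:
                raise ParseError(f"{path}:{lineno}: self-loop on {a!r}")
            edges.append((a, b))
    return edges


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in edges):
            fh.write(f"{a}\t{b}\n")


def read_two_column(path: str | Path) -> list[tuple[str, str]]:
    """Generic two-column TSV (disease-gene associations, annotations)."""
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not all(parts):
                raise ParseError(f"{path}:{lineno}: expected exactly two columns")
            rows.append((parts[0], parts[1]))
    return rows


def write_two_column(rows: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


def read_associations(path: str | Path) -> dict[str, set[str]]:
    """Disease -> genes mapping from a two-column TSV."""
    assoc: dict[str, set[str]] = {}
    for disease, gene in read_two_column(path):
        assoc.setdefault(disease, set()).add(gene)
    return assoc


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Gene -> ontology terms mapping from a two-column TSV."""
    ann: dict[str, set[str]] = {}
    for gene, term in read_two_column(path):
        ann.setdefault(gene, set()).add(term)
    return ann


# ---------------------------------------------------------------------------
# similarity matrices and models
# ---------------------------------------------------------------------------

def write_similarity_matrix(gsm: GeneSimilarityMatrix, path: str | Path) -> None:
    """Matrix TSV plus a JSON sidecar recording source and sigma."""
    path = Path(path)
    write_matrix_tsv(gsm.matrix, path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({"source": gsm.source, "sigma": gsm.sigma}) + "\n")


def read_similarity_matrix(path: str | Path) -> GeneSimilarityMatrix:
    path = Path(path)
    matrix = read_matrix_tsv(path)
    matrix.columns = matrix.columns.astype(str)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if not sidecar.exists():
        raise InputError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    return GeneSimilarityMatrix(
        source=meta["source"], matrix=matrix, sigma=float(meta["sigma"])
    )


def save_model(model, path: str | Path) -> None:
    """Persist a trained model (joblib) with a JSON metadata sidecar."""
    path = Path(path)
    joblib.dump(model.estimator, path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "feature_order": list(model.feature_order),
                "hyperparams": model.hyperparams,
                "fingerprint": model.fingerprint,
            },
            indent=2,
        )
        + "\n"
    )


def load_model(path: str | Path):
    from .model import TrainedModel

    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text())
    return TrainedModel(
        estimator=joblib.load(path),
        feature_order=tuple(meta["feature_order"]),
        hyperparams=meta["hyperparams"],
        fingerprint=meta["fingerprint"],
    )


def write_ranking(result, path: str | Path) -> None:
    """Ranking TSV: disease, chrom, pos, ref, alt, gene, score, rank, ratio."""
    table = result.table.copy()
    table.insert(0, "disease", result.disease)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
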