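"""Gene annotation of CNV intervals, overrepresentation testing, and
tissue-expression percentile selection.

Overrepresentation follows the classification-system recipe: for each
annotation term, fold enrichment is the query proportion over the reference
proportion, the p-value is a one-sided Fisher exact test in the direction
of the deviation, and Bonferroni correction multiplies by the number of
terms tested.

Expression percentile selection ranks each gene within its tissue across
all genes of the expression table; the percentile of a value is 100 times
the fraction of database genes with a strictly smaller value, so ties never
reach the top band.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import EnrichmentRecord, Gene, GeneSet

__all__ = [
    "annotate_genes",
    "overrepresentation_test",
    "expression_percentile_select",
    "read_glist",
    "write_glist",
    "read_gmt",
    "read_expression_tsv",
    "load_ocular_expression",
]


def annotate_genes(
    intervals: Sequence[tuple[int, int, int]],
    gene_set: GeneSet,
) -> tuple[list[list[str]], float]:
    """Assign genes to intervals by the >=1 bp overlap rule.

    ``intervals`` are (chrom, start, end), 1-based inclusive.  Returns the
    per-interval gene name lists (in gene-set order) and the fraction of
    intervals overlapping at least one gene.
    """
    per_interval: list[list[str]] = []
    for chrom, start, end in intervals:
        hits = [
            g.name
            for g in gene_set.genes
            if g.chrom == chrom and start <= g.end and end >= g.start
        ]
        per_interval.append(hits)
    n = len(per_interval)
    frac = sum(1 for h in per_interval if h) / n if n else 0.0
    return per_interval, frac


def overrepresentation_test(
    query: set[str],
    terms: Mapping[str, set[str]],
    reference: set[str],
) -> list[EnrichmentRecord]:
    """Per-term over/under-representation of ``query`` within ``reference``.

    Fold enrichment is (q/Q) / (t/N) with q query genes in the term, Q
    query genes, t reference genes in the term and N reference genes.  The
    one-sided Fisher p-value is the hypergeometric upper tail when the
    fold exceeds 1 and the lower tail otherwise; Bonferroni multiplies by
    the number of terms.
    """
    if not reference:
        raise ValueError("reference gene set is empty")
    if not query <= reference:
        raise ValueError("query genes must be a subset of the reference")
    n_ref = len(reference)
    n_query = len(query)
    n_terms = len(terms)
    records = []
    for term, members in terms.items():
        in_ref = members & reference
        t = len(in_ref)
        q = len(query & in_ref)
        expected = n_query * t / n_ref
        fold = q / expected if expected > 0 else 0.0
        direction = "+" if fold > 1 else "-"
        if fold > 1:
            p = float(sps.hypergeom.sf(q - 1, n_ref, t, n_query))
        else:
            p = float(sps.hypergeom.cdf(q, n_ref, t, n_query))
        records.append(
            EnrichmentRecord(
                term=term,
                n_query_in_term=q,
                n_query=n_query,
                n_term_in_reference=t,
                n_reference=n_ref,
                fold_enrichment=fold,
                direction=direction,
                p_value=p,
                bonferroni_p=min(1.0, p * n_terms),
            )
        )
    records.sort(key=lambda r: r.p_value)
    return records


def expression_percentile_select(
    table: pd.DataFrame,
    query: Sequence[str],
    tissues: Sequence[str] | None = None,
    hi: float = 90.0,
    lo: float = 10.0,
) -> dict[str, dict[str, list[str]]]:
    """Select query genes with extreme expression per tissue.

    ``table`` is indexed by gene with one column per tissue (NaN = not
    measured).  A gene's percentile within a tissue is its mid-rank over
    the whole table (100 x (#strictly smaller + half of #equal) / n, so
    tied genes share a rank and a constant column selects nothing).  Query
    genes with percentile > ``hi`` enter the ``high`` list and < ``lo``
    the ``low`` list of that tissue.
    """
    if not 0 < lo < hi < 100:
        raise ValueError("need 0 < lo < hi < 100")
    tissues = list(tissues) if tissues is not None else list(table.columns)
    missing = [t for t in tissues if t not in table.columns]
    if missing:
        raise ValueError(f"tissues not in the expression table: {missing}")
    out: dict[str, dict[str, list[str]]] = {}
    for tissue in tissues:
        col = table[tissue].dropna()
        values = col.to_numpy(dtype=float)
        n = len(values)
        high, low = [], []
        for gene in query:
            if gene not in col.index:
                continue
            v = float(col.loc[gene])
            pct = 100.0 * (np.sum(values < v) + 0.5 * np.sum(values == v)) / n
            if pct > hi:
                high.append(gene)
            elif pct < lo:
                low.append(gene)
        out[tissue] = {"high": high, "low": low}
    return out


# ----------------------------------------------------------------- file IO


def read_glist(path: str | Path) -> GeneSet:
    """Read a glist-style gene file: ``chrom  start  end  name`` per line."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields")
            chrom, start, end, name = fields
            genes.append(Gene(name, int(chrom.removeprefix("chr")), int(start), int(end)))
    return GeneSet(genes)


def write_glist(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in gene_set.genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: term, description, then member genes, tab-separated."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, description, genes")
            terms[fields[0]] = set(fields[2:])
    return terms


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a per-gene, per-tissue expression TSV (header ``gene  <tissue>...``)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["-", "NA", ""])
    if df.index.has_duplicates:
        raise ValueError("expression table gene names must be unique")
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValueError("expression values must be non-negative")
    return df


def load_ocular_expression() -> pd.DataFrame:
    """PLIER-normalized expression of glaucoma-associated genes in four
    ocular tissues (bundled fixture table)."""
    with resources.as_file(
        resources.files("cnvrassoc").joinpath("data/ocular_expression_plier.tsv")
    ) as p:
        return read_expression_tsv(p)
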