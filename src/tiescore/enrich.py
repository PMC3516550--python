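"""Gene-set over-representation by the hypergeometric (one-sided) test.

A generic stand-in for GO/DAVID-style enrichment: the user supplies a flat
term -> gene annotation and a gene universe; each term's p-value is the
upper-tail hypergeometric probability P(X >= k) of drawing k annotated genes
in a query of size n from a universe of N containing K annotated genes.
P-values are adjusted across terms by Benjamini-Hochberg (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import ValidationError


@dataclass
class TermAnnotation:
    """One annotation term and its gene set."""

    term_id: str
    term_name: str
    genes: frozenset

    def __post_init__(self) -> None:
        self.genes = frozenset(str(g) for g in self.genes)
        if not self.genes:
            raise ValidationError(f"term {self.term_id!r} has an empty gene set")


def read_terms(path, name_map_path=None) -> list[TermAnnotation]:
    """Read a 2-column (term, gene) TSV, optionally with a term-name map."""
    frame = pd.read_csv(path, sep="\t", comment="#", header=None, names=["term", "gene"])
    names = {}
    if name_map_path is not None:
        nm = pd.read_csv(
            name_map_path, sep="\t", comment="#", header=None, names=["term", "name"]
        )
        names = dict(zip(nm["term"].astype(str), nm["name"].astype(str)))
    terms = []
    for term, sub in frame.groupby("term"):
        tid = str(term)
        terms.append(
            TermAnnotation(
                term_id=tid,
                term_name=names.get(tid, tid),
                genes=frozenset(sub["gene"].astype(str)),
            )
        )
    return terms


def hypergeom_enrich(
    query: Iterable[str],
    terms: Sequence[TermAnnotation],
    universe: Iterable[str],
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-term over-representation of ``query`` within ``universe``.

    Returns a DataFrame with columns term, name, k (query hits), K (term
    size in universe), n (query size in universe), N (universe size),
    p_value and p_adjusted, sorted by p_value.
    """
    universe = {str(g) for g in universe}
    query = {str(g) for g in query} & universe
    if not query:
        raise ValidationError("query is disjoint from the universe")
    big_n = len(universe)
    n = len(query)
    rows = []
    for term in terms:
        term_genes = term.genes & universe
        big_k = len(term_genes)
        k = len(term_genes & query)
        # upper tail P(X >= k)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n)) if big_k else 1.0
        rows.append(
            {
                "term": term.term_id,
                "name": term.term_name,
                "k": k,
                "K": big_k,
                "n": n,
                "N": big_n,
                "p_value": min(p, 1.0),
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["p_adjusted"] = multipletests(frame["p_value"], method=method)[1]
        frame = frame.sort_values("p_value", kind="stable").reset_index(drop=True)
    return frame
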