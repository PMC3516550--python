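"""Domain containers shared by every stage of the pipeline.

The pipeline operates on an F2 intercross panel: genotypes at mapped markers,
per-tissue expression matrices, one clinical trait vector, gene positions and
an undirected protein-protein interaction (PPI) edge list.  Genotypes are
coded 0 (first-strain homozygote, e.g. B6/B6), 1 (heterozygote) and
2 (second-strain homozygote, e.g. BTBR/BTBR); missing values are NaN in
memory and the token ``NA`` in text files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tiescore")

#: single missing-value sentinel used by all text formats
MISSING_TOKEN = "NA"

#: valid genotype codes (0 = homozygote A, 1 = het, 2 = homozygote B)
GENOTYPE_CODES = (0.0, 1.0, 2.0)


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class GeneticMap:
    """Marker coordinates: map (cM) and genomic (bp) position per marker.

    ``table`` has columns ``marker``, ``chromosome``, ``cM``, ``bp`` and is
    kept sorted by (chromosome, cM).  bp positions are 1-based point
    coordinates; cM values are map positions, not recombination fractions.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["marker", "chromosome", "cM", "bp"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"genetic map missing columns: {missing}")
        tab = self.table[required].copy()
        tab["marker"] = tab["marker"].astype(str)
        tab["chromosome"] = tab["chromosome"].astype(str)
        tab["cM"] = tab["cM"].astype(float)
        tab["bp"] = tab["bp"].astype(np.int64)
        if tab["marker"].duplicated().any():
            dupes = tab.loc[tab["marker"].duplicated(), "marker"].tolist()
            raise ValidationError(f"duplicate marker ids in map: {dupes}")
        if (tab["cM"] < 0).any() or (tab["bp"] < 0).any():
            raise ValidationError("negative marker coordinate in map")
        tab = tab.sort_values(["chromosome", "cM"], kind="stable").reset_index(drop=True)
        for chrom, sub in tab.groupby("chromosome", sort=False):
            if not sub["bp"].is_monotonic_increasing:
                raise ValidationError(
                    f"bp order disagrees with cM order on chromosome {chrom}"
                )
        self.table = tab

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return self.table["chromosome"].unique().tolist()

    def marker_row(self, marker_id: str) -> pd.Series:
        rows = self.table[self.table["marker"] == marker_id]
        if rows.empty:
            raise KeyError(f"marker {marker_id!r} not in map")
        return rows.iloc[0]

    def nearest_marker(self, chromosome: str, position_cM: float) -> str:
        """Id of the marker on ``chromosome`` closest to ``position_cM``."""
        sub = self.table[self.table["chromosome"] == str(chromosome)]
        if sub.empty:
            raise KeyError(f"no markers on chromosome {chromosome!r}")
        idx = (sub["cM"] - float(position_cM)).abs().idxmin()
        return sub.loc[idx, "marker"]


@dataclass
class GenotypeMatrix:
    """F2 genotypes, mice x markers, aligned to a :class:`GeneticMap`."""

    mice: list[str]
    gmap: GeneticMap
    codes: np.ndarray  # float array, values in {0, 1, 2, NaN}
    missing_cap: float = 0.2

    def __post_init__(self) -> None:
        self.mice = [str(m) for m in self.mice]
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.mice), self.gmap.n_markers):
            raise ValidationError(
                f"genotype matrix shape {self.codes.shape} does not match "
                f"{len(self.mice)} mice x {self.gmap.n_markers} markers"
            )
        if len(set(self.mice)) != len(self.mice):
            raise ValidationError("duplicate mouse ids in genotype matrix")
        finite = self.codes[np.isfinite(self.codes)]
        bad = ~np.isin(finite, GENOTYPE_CODES)
        if bad.any():
            rows, cols = np.where(
                np.isfinite(self.codes) & ~np.isin(self.codes, GENOTYPE_CODES)
            )
            r, c = rows[0], cols[0]
            raise ValidationError(
                f"invalid genotype code {self.codes[r, c]!r} for mouse "
                f"{self.mice[r]!r} at marker {self.gmap.marker_ids[c]!r}"
            )
        miss_frac = np.isnan(self.codes).mean(axis=0)
        if (miss_frac > self.missing_cap).any():
            worst = int(np.argmax(miss_frac))
            raise ValidationError(
                f"marker {self.gmap.marker_ids[worst]!r} has missingness "
                f"{miss_frac[worst]:.2f} > cap {self.missing_cap}"
            )

    def marker_codes(self, marker_id: str) -> np.ndarray:
        """Per-mouse genotype codes at one marker."""
        j = self.gmap.marker_ids.index(marker_id)
        return self.codes[:, j]


@dataclass
class ExpressionMatrix:
    """Per-tissue transcript abundances (log-ratio scale), genes x mice."""

    genes: list[str]
    mice: list[str]
    values: np.ndarray
    tissue: str = "tissue"

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.mice = [str(m) for m in self.mice]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.mice)):
            raise ValidationError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.mice)} mice"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene ids in expression matrix")
        if np.isinf(self.values).any():
            raise ValidationError("non-finite (inf) expression value")

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.values[self.genes.index(gene_id)]


@dataclass
class GeneAnnotation:
    """Genomic location per gene: columns ``gene``, ``chromosome``, ``bp``."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene", "chromosome", "bp"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"gene annotation missing columns: {missing}")
        tab = self.table[required].copy()
        tab["gene"] = tab["gene"].astype(str)
        tab["chromosome"] = tab["chromosome"].astype(str)
        tab["bp"] = tab["bp"].astype(np.int64)
        if tab["gene"].duplicated().any():
            raise ValidationError("duplicate gene ids in annotation")
        self.table = tab.reset_index(drop=True)

    def position(self, gene_id: str) -> tuple[str, int]:
        rows = self.table[self.table["gene"] == str(gene_id)]
        if rows.empty:
            raise KeyError(f"gene {gene_id!r} not annotated")
        row = rows.iloc[0]
        return row["chromosome"], int(row["bp"])


@dataclass
class TraitVector:
    """One clinical trait value per mouse (e.g. plasma insulin, ng/ml)."""

    mice: list[str]
    values: np.ndarray
    name: str = "trait"

    def __post_init__(self) -> None:
        self.mice = [str(m) for m in self.mice]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mice),):
            raise ValidationError("trait length does not match mouse id list")
        if np.isfinite(self.values).sum() < 3:
            raise ValidationError(
                "trait needs >=3 non-missing values for downstream correlation"
            )

    def reindex(self, mice: Sequence[str]) -> np.ndarray:
        """Trait values in the order of ``mice`` (NaN where absent)."""
        lookup = dict(zip(self.mice, self.values))
        return np.array([lookup.get(str(m), np.nan) for m in mice], dtype=float)


def _norm_edge(a: str, b: str) -> tuple[str, str]:
    a, b = str(a), str(b)
    return (a, b) if a <= b else (b, a)


@dataclass
class PpiNetwork:
    """Undirected PPI edge list; unordered pairs, no self-loops."""

    edges: frozenset = field(default_factory=frozenset)  # of (a, b) sorted tuples
    sources: dict = field(default_factory=dict)  # edge -> source tag

    @classmethod
    def from_edges(
        cls,
        pairs: Iterable[tuple[str, str]],
        sources: Optional[Iterable[Optional[str]]] = None,
    ) -> "PpiNetwork":
        """Build a network, collapsing duplicates and dropping self-loops.

        Duplicate unordered pairs are collapsed (count logged); self-loop
        edges are dropped with a warning.
        """
        seen: dict[tuple[str, str], Optional[str]] = {}
        n_dup = n_self = 0
        src_iter = iter(sources) if sources is not None else None
        for pair in pairs:
            a, b = pair
            tag = next(src_iter) if src_iter is not None else None
            if str(a) == str(b):
                n_self += 1
                logger.warning("dropping self-loop edge (%s, %s)", a, b)
                continue
            key = _norm_edge(a, b)
            if key in seen:
                n_dup += 1
                continue
            seen[key] = tag
        if n_dup:
            logger.info("collapsed %d duplicate edges", n_dup)
        return cls(
            edges=frozenset(seen),
            sources={k: v for k, v in seen.items() if v is not None},
        )

    @property
    def nodes(self) -> set[str]:
        return {g for e in self.edges for g in e}

    def __len__(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return _norm_edge(a, b) in self.edges

    def neighbors(self, gene: str) -> set[str]:
        gene = str(gene)
        return {b if a == gene else a for a, b in self.edges if gene in (a, b)}

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g
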