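"""Readers and writers for the tab-delimited pipeline formats.

All writers emit a header line ``#fileformat=tiescore-v1`` followed by
optional ``#key=value`` metadata lines and a tab-separated table.  Missing
values use the single sentinel ``NA``.  Edge lists are accepted as plain
two-column TSV or as SIF dialect (``A pp B`` / ``A interacts B``).
Every reader/writer pair is an identity on its own output (up to row /
column ordering).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    GENOTYPE_CODES,
    MISSING_TOKEN,
    ExpressionMatrix,
    GeneAnnotation,
    GeneticMap,
    GenotypeMatrix,
    PpiNetwork,
    TraitVector,
    ValidationError,
)

logger = logging.getLogger("tiescore")

FORMAT_LINE = "#fileformat=tiescore-v1"


def _read_lines(path) -> tuple[dict, list[str]]:
    """Split a file into '#key=value' metadata and data lines."""
    meta: dict[str, str] = {}
    data: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
                continue
            data.append(line)
    return meta, data


def _parse_table(data_lines: list[str]) -> pd.DataFrame:
    header = data_lines[0].split("\t")
    rows = [line.split("\t") for line in data_lines[1:]]
    return pd.DataFrame(rows, columns=header)


def _write_table(path, frame: pd.DataFrame, meta: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(FORMAT_LINE + "\n")
        for key, val in (meta or {}).items():
            fh.write(f"#{key}={val}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep=MISSING_TOKEN)


# ---------------------------------------------------------------- genetic map

def read_map(path) -> GeneticMap:
    _, data = _read_lines(path)
    tab = _parse_table(data)
    tab.columns = ["marker", "chromosome", "cM", "bp"]
    return GeneticMap(tab)


def write_map(gmap: GeneticMap, path) -> None:
    _write_table(path, gmap.table)


# ------------------------------------------------------------------ genotypes

def read_genotypes(path, map_path, relabel: Optional[dict] = None) -> GenotypeMatrix:
    """Read a mice x markers genotype table against its genetic map.

    ``relabel`` optionally remaps genotype codes on read (e.g. ``{0: 2, 2: 0}``
    to flip strain orientation).  Unknown codes raise an error naming the
    offending cell; markers absent from the map are a hard error.
    """
    gmap = read_map(map_path)
    _, data = _read_lines(path)
    tab = _parse_table(data)
    marker_cols = list(tab.columns[1:])
    unknown = [m for m in marker_cols if m not in set(gmap.marker_ids)]
    if unknown:
        raise ValidationError(f"marker {unknown[0]!r} not present in genetic map")
    missing_markers = [m for m in gmap.marker_ids if m not in set(marker_cols)]
    if missing_markers:
        raise ValidationError(
            f"genotype file lacks mapped marker {missing_markers[0]!r}"
        )
    mice = tab.iloc[:, 0].astype(str).tolist()
    codes = np.full((len(mice), gmap.n_markers), np.nan)
    col_of = {m: k for k, m in enumerate(gmap.marker_ids)}
    relabel = {float(k): float(v) for k, v in (relabel or {}).items()}
    for col in marker_cols:
        j = col_of[col]
        for i, raw in enumerate(tab[col]):
            token = str(raw).strip()
            if token == MISSING_TOKEN or token == "":
                continue
            try:
                val = float(token)
            except ValueError:
                val = np.nan
            val = relabel.get(val, val)
            if val not in GENOTYPE_CODES:
                raise ValidationError(
                    f"invalid genotype code {token!r} for mouse {mice[i]!r} "
                    f"at marker {col!r}"
                )
            codes[i, j] = val
    return GenotypeMatrix(mice=mice, gmap=gmap, codes=codes)


def write_genotypes(genotypes: GenotypeMatrix, path, map_path=None) -> None:
    frame = pd.DataFrame(genotypes.codes, columns=genotypes.gmap.marker_ids)
    # integer-looking codes in the file, NA for missing
    frame = frame.map(lambda v: "" if np.isnan(v) else str(int(v)))
    frame = frame.replace("", np.nan)
    frame.insert(0, "mouse", genotypes.mice)
    _write_table(path, frame)
    if map_path is not None:
        write_map(genotypes.gmap, map_path)


# ----------------------------------------------------------------- expression

def read_expression(path) -> ExpressionMatrix:
    meta, data = _read_lines(path)
    tab = _parse_table(data)
    genes = tab.iloc[:, 0].astype(str).tolist()
    mice = list(tab.columns[1:])
    values = np.full((len(genes), len(mice)), np.nan)
    for j, col in enumerate(tab.columns[1:]):
        for i, raw in enumerate(tab[col]):
            token = str(raw).strip()
            if token == MISSING_TOKEN or token == "":
                continue
            try:
                values[i, j] = float(token)
            except ValueError:
                raise ValidationError(
                    f"non-numeric expression value {token!r} for gene "
                    f"{genes[i]!r}, mouse {col!r}"
                ) from None
    return ExpressionMatrix(
        genes=genes, mice=mice, values=values, tissue=meta.get("tissue", "tissue")
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    frame = pd.DataFrame(expr.values, columns=expr.mice)
    frame.insert(0, "gene", expr.genes)
    _write_table(path, frame, meta={"tissue": expr.tissue})


# ---------------------------------------------------------------------- trait

def read_trait(path) -> TraitVector:
    meta, data = _read_lines(path)
    tab = _parse_table(data)
    mice = tab.iloc[:, 0].astype(str).tolist()
    raw = tab.iloc[:, 1].astype(str).str.strip()
    values = np.array(
        [np.nan if t == MISSING_TOKEN or t == "" else float(t) for t in raw]
    )
    name = meta.get("trait", tab.columns[1])
    return TraitVector(mice=mice, values=values, name=name)


def write_trait(trait: TraitVector, path) -> None:
    frame = pd.DataFrame({"mouse": trait.mice, "value": trait.values})
    _write_table(path, frame, meta={"trait": trait.name})


# ----------------------------------------------------------------- annotation

def read_annotation(path) -> GeneAnnotation:
    _, data = _read_lines(path)
    tab = _parse_table(data)
    tab.columns = ["gene", "chromosome", "bp"]
    return GeneAnnotation(tab)


def write_annotation(annot: GeneAnnotation, path) -> None:
    _write_table(path, annot.table)


# ------------------------------------------------------------------ edge list

#: SIF relation tokens treated as "interacts"
_SIF_RELATIONS = {"pp", "interacts", "pd", "interaction"}


def read_edges(path) -> PpiNetwork:
    """Read a PPI edge list (two-column TSV or SIF dialect).

    Lines ``A B``, ``A pp B`` and ``A interacts B`` all yield the unordered
    edge (A, B).  Duplicate pairs are collapsed; self-loops dropped with a
    warning.
    """
    _, data = _read_lines(path)
    pairs = []
    for line in data:
        tokens = line.replace("\t", " ").split()
        if not tokens:
            continue
        if len(tokens) == 2:
            a, b = tokens
        elif len(tokens) == 3 and tokens[1].lower() in _SIF_RELATIONS:
            a, _, b = tokens
        else:
            raise ValidationError(f"unparseable edge line: {line!r}")
        if a == "gene1" and b == "gene2":  # header row from our own writer
            continue
        pairs.append((a, b))
    return PpiNetwork.from_edges(pairs)


def write_edges(ppi: PpiNetwork, path) -> None:
    frame = pd.DataFrame(sorted(ppi.edges), columns=["gene1", "gene2"])
    _write_table(path, frame)
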