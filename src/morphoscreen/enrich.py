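"""Gene-set over-representation with an expressed-gene background.

Hypergeometric upper-tail tests of a query gene list against GMT gene
sets, restricted to an expressed-gene background (background
correction), with Benjamini-Hochberg FDR across sets and an
enrichment-strength effect size log10(observed/expected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class GMTParseError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets; identifiers unique, members deduplicated/uppercased."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (set id <tab> description <tab> genes...).

    Gene symbols are uppercased and deduplicated; malformed lines raise
    with their line number.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GMTParseError(
                f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
            )
        name, desc, *genes = fields
        if name in sets:
            raise GMTParseError(f"{path}:{lineno}: duplicate set id {name!r}")
        members = frozenset(g.strip().upper() for g in genes if g.strip())
        if not members:
            raise GMTParseError(f"{path}:{lineno}: set {name!r} has no genes")
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def read_gene_list(path: str | Path) -> set[str]:
    """One symbol per line, uppercased."""
    return {
        line.strip().upper()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def filter_by_expression(genes, expressed) -> set[str]:
    """Case-insensitive intersection with the expressed-gene list.

    For enrichment use the expressed list is the background universe N.
    """
    expressed_up = {g.upper() for g in expressed}
    if not expressed_up:
        raise ValueError("expressed-gene list is empty")
    return {g for g in (x.upper() for x in genes) if g in expressed_up}


def hypergeometric_enrichment(
    query, collection: GeneSetCollection, background
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of the query against every set.

    Per set: N = |background|, K = |set ∩ background|, n = |query|,
    x = |query ∩ set ∩ background|; p = P(X >= x); strength =
    log10(x / E) with E = n*K/N (defined only for x > 0); BH q across
    all tested sets.  Sets with K = 0 are skipped.  Query genes outside
    the background are dropped with a warning.
    """
    bg = {g.upper() for g in background}
    if not bg:
        raise ValueError("empty background")
    q = {g.upper() for g in query}
    outside = q - bg
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside background dropped")
        q &= bg
    if not q:
        raise ValueError("query empty after background intersection")

    N, n = len(bg), len(q)
    rows = []
    for name, members in collection.sets.items():
        K = len(members & bg)
        if K == 0:
            continue
        x = len(q & members & bg)
        expected = n * K / N
        p = float(hypergeom.sf(x - 1, N, K, n))  # P(X >= x); x=0 -> 1
        strength = float(np.log10(x / expected)) if x > 0 else float("nan")
        rows.append((name, N, K, n, x, expected, strength, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["set_id", "N", "K", "n", "x", "expected", "strength", "p"]
    )
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["q"] = []
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def write_enrichment_tsv(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, sep="\t", index=False)
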