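"""Hypergeometric over-representation analysis (ORA).

A selected gene set is tested against a reference list within a gene
universe (all genes measured on the platform; for synthetic runs, all
generated genes). The upper-tail hypergeometric probability of drawing
at least the observed overlap by chance classifies each cell into three
states: ``significant`` (p < 0.05), ``enriched`` (not significant but
overlap above its expectation), ``not_enriched`` otherwise.

The sweep over set sizes (best 40, 60, ..., 200 genes of a ranking)
reports raw per-cell p-values without correction across the grid — a
deliberate, documented caveat of this three-state display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from biomarker_ga.rankers import RankedList

logger = logging.getLogger(__name__)

SIGNIFICANT = "significant"
ENRICHED = "enriched"
NOT_ENRICHED = "not_enriched"


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap of a selected set with one reference list."""

    list_name: str
    selected_size: int
    universe_size: int
    list_size: int
    overlap: int
    p_value: float
    status: str

    @property
    def expected_overlap(self) -> float:
        return self.selected_size * self.list_size / self.universe_size


def hypergeometric_ora(
    selected: set[str] | list[str],
    reference: set[str] | list[str],
    universe: set[str] | list[str],
    list_name: str = "reference",
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of the selected/reference overlap.

    ``reference`` is intersected with the universe first; reference
    genes outside the universe are dropped with a logged count.
    ``selected`` must be a subset of the universe.
    """
    universe = set(universe)
    selected = set(selected)
    if not universe:
        raise ValueError("empty universe")
    if not selected:
        raise ValueError("empty selected set")
    if not selected <= universe:
        raise ValueError("selected genes must lie inside the universe")
    reference_all = set(reference)
    reference = reference_all & universe
    dropped = len(reference_all) - len(reference)
    if dropped:
        logger.info("%s: %d reference genes outside the universe dropped", list_name, dropped)

    m, n_list, n_sel = len(universe), len(reference), len(selected)
    overlap = len(selected & reference)
    # P(X >= overlap), X ~ Hypergeometric(M=m, n=n_list, N=n_sel)
    p = float(hypergeom.sf(overlap - 1, m, n_list, n_sel))
    expected = n_sel * n_list / m
    if p < alpha:
        status = SIGNIFICANT
    elif overlap > expected:
        status = ENRICHED
    else:
        status = NOT_ENRICHED
    return EnrichmentResult(
        list_name=list_name,
        selected_size=n_sel,
        universe_size=m,
        list_size=n_list,
        overlap=overlap,
        p_value=p,
        status=status,
    )


def enrichment_sweep(
    ranking: RankedList,
    reference_lists: dict[str, list[str]],
    universe: set[str] | list[str],
    sizes: tuple[int, ...] = tuple(range(40, 201, 20)),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ORA of incrementally larger top slices of a ranking.

    Returns the full result table and a (list x size) status matrix.
    Sizes exceeding the ranking length are skipped with a warning.
    """
    rows = []
    for size in sizes:
        if size > len(ranking.table):
            logger.warning("ranking shorter than %d genes: size skipped", size)
            continue
        selected = ranking.top(size)
        for name, ref in reference_lists.items():
            r = hypergeometric_ora(selected, ref, universe, list_name=name, alpha=alpha)
            rows.append(
                {
                    "list": name,
                    "size": size,
                    "overlap": r.overlap,
                    "list_size": r.list_size,
                    "p": r.p_value,
                    "status": r.status,
                }
            )
    table = pd.DataFrame(rows)
    matrix = (
        table.pivot(index="list", columns="size", values="status")
        if not table.empty
        else pd.DataFrame()
    )
    return table, matrix


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one symbol per line; blank lines ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT reader: name <tab> description <tab> gene1 <tab> gene2 ..."""
    out: dict[str, list[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {ln[:60]!r}")
        out[parts[0]] = [g for g in parts[2:] if g]
    return out
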