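"""Hypergeometric gene-set over-representation analysis.

Given a marker panel and a GMT gene-set collection, each term is tested for
over-representation of panel genes with the hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

where ``N`` is the background universe size (annotated genes only), ``K``
the term size within the universe, ``n`` the panel size within the universe
and ``k`` the observed overlap.  P-values are adjusted across all tested
terms by Benjamini-Hochberg false-discovery-rate control.  Panel genes
outside the universe are dropped with a logged warning, matching the
annotated-genes-only background convention.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file (term, description, tab-separated gene symbols).

    Symbols are upper-cased; duplicates within a set are collapsed.  A line
    with fewer than three fields is an error naming the line number.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need >= 3 tab-separated "
                    f"fields (name, description, genes...), got {len(fields)}"
                )
            name = fields[0].strip()
            genes = {g.strip().upper() for g in fields[2:] if g.strip()}
            if not genes:
                raise ValueError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets[name] = genes
    return sets


def write_gmt(collection: Mapping[str, Iterable[str]], path: str | Path) -> None:
    """Write a gene-set collection as GMT (description column left blank)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in collection:
            genes = sorted({str(g).upper() for g in collection[name]})
            fh.write("\t".join([name, "", *genes]) + "\n")


def hypergeometric_enrichment(
    panel: Sequence[str],
    collection: Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Test every gene set for over-representation of the panel.

    Parameters
    ----------
    panel : gene symbols of interest (case-insensitive).
    collection : term -> gene set, e.g. from :func:`read_gmt`.
    universe : background gene symbols; defaults to the union of all genes in
        the collection (the annotated-genes-only convention).  Gene sets are
        restricted to the universe before testing; panel genes outside the
        universe are dropped with a warning.

    Returns
    -------
    DataFrame sorted by (q, p, term) with columns ``term``, ``k`` (overlap),
    ``K`` (term size), ``n`` (panel size in universe), ``N`` (universe
    size), ``p`` (hypergeometric upper tail) and ``q``
    (Benjamini-Hochberg adjusted).
    """
    sets = {t: {str(g).upper() for g in gs} for t, gs in collection.items()}
    if universe is None:
        uni = set().union(*sets.values()) if sets else set()
    else:
        uni = {str(g).upper() for g in universe}
    panel_set = {str(g).upper() for g in panel}
    dropped = sorted(panel_set - uni)
    if dropped:
        logger.warning(
            "dropping %d panel gene(s) outside the annotated universe: %s",
            len(dropped), ", ".join(dropped),
        )
    panel_in = panel_set & uni
    if not panel_in:
        raise ValueError("no panel gene is in the background universe")

    N, n = len(uni), len(panel_in)
    rows = []
    for term, genes in sets.items():
        genes_in = genes & uni
        if not genes_in:
            continue
        K = len(genes_in)
        k = len(genes_in & panel_in)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    result = pd.DataFrame(rows)
    if result.empty:
        raise ValueError("no gene set overlaps the background universe")
    result["q"] = multipletests(result["p"], method="fdr_bh")[1]
    return result.sort_values(["q", "p", "term"], ignore_index=True)
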