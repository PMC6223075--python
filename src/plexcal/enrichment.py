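"""Fisher-exact over-representation of gene lists against functional terms.

Tests regulated-gene lists for enrichment in flat gene sets (GO Biological
Process, Reactome-style pathways, or any GMT-supplied collection) against
a background universe — by default all genes quantified at the protein
level, guarding against detection bias. The test is one-sided
over-representation: p = P(X >= k) under the hypergeometric null for the
2x2 table (k, n-k, K-k, N-n-K+k). Terms overlapping fewer than
``min_overlap`` list genes (default 2) are excluded before the
Benjamini-Hochberg correction, which is applied within each ontology tag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .linear_model import adjust_bh

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationSet:
    """One functional term: id, display name, ontology tag and its member
    gene symbols (upper-cased, unique)."""

    term_id: str
    name: str
    ontology: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has no member genes")


def read_gmt(path, ontology: str = "other") -> list[AnnotationSet]:
    """Parse a GMT file (term, description, tab-separated member genes).

    Gene symbols are upper-cased; duplicates within a line are collapsed
    with a warning. Lines with fewer than three fields are a parse error.
    """
    sets: list[AnnotationSet] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
        term, desc, *genes = fields
        genes = [g.strip().upper() for g in genes if g.strip()]
        if len(genes) < 1:
            raise ValueError(f"{path}: line {lineno} ({term}) lists no genes")
        uniq = frozenset(genes)
        if len(uniq) < len(genes):
            logger.warning(
                "%s line %d (%s): %d duplicate gene(s) collapsed",
                path, lineno, term, len(genes) - len(uniq),
            )
        sets.append(AnnotationSet(term, desc or term, ontology, uniq))
    return sets


def fisher_enrichment(
    hits: list[str],
    universe: list[str],
    sets: list[AnnotationSet],
    min_overlap: int = 2,
    bh_within_ontology: bool = True,
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric upper-tail) over-representation.

    Parameters
    ----------
    hits
        The regulated gene list; must be a subset of ``universe``.
    universe
        The background: every gene that could have been called regulated.
    sets
        Functional terms; member sets are intersected with the universe
        before testing.
    min_overlap
        Terms overlapping fewer than this many hit genes are dropped
        before multiple-testing correction (eligibility rule).
    bh_within_ontology
        Apply BH separately within each ontology tag (default), or once
        across all terms.

    Returns
    -------
    DataFrame sorted by ascending p with columns term_id, term_name,
    ontology, k (overlap), n (list size), K (term size in universe),
    N (universe size), odds_ratio, pvalue, adj_pvalue, neg_log10_p,
    overlap_genes.
    """
    uni = {g.upper() for g in universe}
    hit_set = {g.upper() for g in hits}
    stray = sorted(hit_set - uni)
    if stray:
        raise ValueError(f"hit genes absent from the universe: {stray}")
    N, n = len(uni), len(hit_set)
    rows = []
    for term in sets:
        members = term.genes & uni
        if not members:
            continue
        overlap = sorted(members & hit_set)
        k, K = len(overlap), len(members)
        if k < min_overlap:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        a, b, c, d = k, n - k, K - k, N - n - K + k
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.name,
                "ontology": term.ontology,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "odds_ratio": odds,
                "pvalue": min(p, 1.0),
                "overlap_genes": ";".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "term_name", "ontology", "k", "n", "K", "N",
                "odds_ratio", "pvalue", "adj_pvalue", "neg_log10_p", "overlap_genes",
            ]
        )
    out = pd.DataFrame(rows)
    out["adj_pvalue"] = np.nan
    if bh_within_ontology:
        for ont, idx in out.groupby("ontology").groups.items():
            out.loc[idx, "adj_pvalue"] = adjust_bh(out.loc[idx, "pvalue"].to_numpy())
    else:
        out["adj_pvalue"] = adjust_bh(out["pvalue"].to_numpy())
    out["neg_log10_p"] = -np.log10(out["pvalue"].clip(lower=1e-300))
    cols = [
        "term_id", "term_name", "ontology", "k", "n", "K", "N",
        "odds_ratio", "pvalue", "adj_pvalue", "neg_log10_p", "overlap_genes",
    ]
    return out[cols].sort_values(["pvalue", "term_id"], kind="mergesort").reset_index(drop=True)


def collapse_redundant(results: pd.DataFrame, jaccard_threshold: float = 0.5) -> pd.DataFrame:
    """Optional redundancy reduction: within groups of terms whose overlap
    genes have Jaccard similarity >= threshold, keep only the term with
    the smallest p (greedy, in p order). Off by default in the pipeline."""
    if results.empty:
        return results.copy()
    kept_rows = []
    kept_sets: list[set[str]] = []
    for _, row in results.sort_values(["pvalue", "term_id"], kind="mergesort").iterrows():
        genes = set(row["overlap_genes"].split(";")) if row["overlap_genes"] else set()
        redundant = False
        for ks in kept_sets:
            union = genes | ks
            if union and len(genes & ks) / len(union) >= jaccard_threshold:
                redundant = True
                break
        if not redundant:
            kept_rows.append(row)
            kept_sets.append(genes)
    return pd.DataFrame(kept_rows).reset_index(drop=True)


def shared_terms(results_a: pd.DataFrame, results_b: pd.DataFrame) -> pd.DataFrame:
    """Cross-study comparison utility: terms (by name) significant in both
    result tables, with both p-values side by side. A simple set
    intersection — no ortholog mapping."""
    a = results_a.set_index("term_name")["pvalue"]
    b = results_b.set_index("term_name")["pvalue"]
    common = a.index.intersection(b.index)
    return pd.DataFrame(
        {"pvalue_a": a.loc[common], "pvalue_b": b.loc[common]}
    ).sort_values("pvalue_a")
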