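"""Gene-set over-representation analysis against a background transcriptome.

For each gene set the overlap x between the candidate list (size n) and
the set's members restricted to the background (size K, universe N) is
scored with the one-sided hypergeometric upper tail P(X >= x), then
Benjamini-Hochberg adjusted across sets.  The background should be the
post-filter transcriptome of the tissue under study, not the whole
genome.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats as sps

from .postprocess import bh_adjust

log = logging.getLogger("veqtl")

__all__ = ["overrepresentation"]


def overrepresentation(
    candidates,
    background,
    gene_sets: dict,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of candidates in each gene set.

    Parameters
    ----------
    candidates : iterable of gene ids
        Genes of interest; ids not in the background are dropped with a
        warning.
    background : iterable of gene ids
        The universe (e.g. all genes passing the expression filter).
    gene_sets : dict
        ``set_id -> {"description": str, "genes": [ids]}`` as returned by
        :func:`veqtl.io.read_gmt`, or ``set_id -> [ids]``.
    min_overlap : int
        Sets overlapping the candidates in fewer genes are still reported
        (p = 1 at zero overlap) but sets with no member in the background
        are skipped.

    Returns
    -------
    DataFrame with columns set_id, description, set_size (in background),
    overlap, expected, p, p_adjusted, genes — sorted by p.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background gene universe is empty")
    cand = list(dict.fromkeys(candidates))
    if not cand:
        raise ValueError("candidate gene list is empty")
    outside = [g for g in cand if g not in bg]
    if outside:
        log.warning("overrepresentation: %d candidate genes not in background; dropped",
                    len(outside))
        cand = [g for g in cand if g in bg]
        if not cand:
            raise ValueError("no candidate genes remain within the background")
    n_bg, n_cand = len(bg), len(cand)
    cand_set = set(cand)

    rows = []
    for set_id, payload in gene_sets.items():
        if isinstance(payload, dict):
            members, desc = payload.get("genes", []), payload.get("description", "")
        else:
            members, desc = list(payload), ""
        in_bg = sorted(set(members) & bg)
        if not in_bg:
            log.info("overrepresentation: set %s has no members in background; skipped",
                     set_id)
            continue
        k = len(in_bg)
        hits = sorted(cand_set & set(in_bg))
        x = len(hits)
        expected = n_cand * k / n_bg
        # P(X >= x) for X ~ Hypergeom(N=n_bg, K=k, n=n_cand)
        p = float(sps.hypergeom.sf(x - 1, n_bg, k, n_cand)) if x >= min_overlap else 1.0
        rows.append({
            "set_id": set_id,
            "description": desc,
            "set_size": k,
            "overlap": x,
            "expected": expected,
            "p": p,
            "genes": ",".join(hits),
        })
    if not rows:
        raise ValueError("no gene set overlaps the background")
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
    return out[["set_id", "description", "set_size", "overlap", "expected",
                "p", "p_adjusted", "genes"]]
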