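"""Hypergeometric over-representation analysis of functional terms.

Given a foreground transcript set (e.g. worker-biased host transcripts)
and a background (e.g. all host transcripts), each annotation term is
tested with the upper-tail hypergeometric probability

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

where N is the annotated background size, K the background transcripts
carrying the term, n the annotated foreground size and k the foreground
transcripts carrying the term.  P-values are Benjamini-Hochberg adjusted
across tested terms (those with K >= 1); significance is q < 0.05.

Annotations may optionally be propagated up a term parent DAG first
(true-path closure), so that a transcript annotated to a term counts for
all ancestors of that term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .diffabund import bh_adjust

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


@dataclass
class EnrichmentRow:
    term: str
    k: int       # foreground hits
    n: int       # foreground size
    K: int       # background hits
    N: int       # background size
    p: float
    q: float = float("nan")


def load_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column transcript<TAB>term TSV into term -> transcripts."""
    annot: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            transcript, term = line.split("\t")[:2]
            annot.setdefault(term, set()).add(transcript)
    return annot


def _ancestors(dag: dict[str, set[str]]) -> dict[str, set[str]]:
    """Transitive ancestor closure of a child -> parents DAG."""
    memo: dict[str, set[str]] = {}
    in_progress: set[str] = set()

    def visit(term: str) -> set[str]:
        if term in memo:
            return memo[term]
        if term in in_progress:
            raise AnnotationError(f"cycle in term DAG at {term!r}")
        in_progress.add(term)
        anc: set[str] = set()
        for parent in dag.get(term, ()):
            anc.add(parent)
            anc |= visit(parent)
        in_progress.discard(term)
        memo[term] = anc
        return anc

    for term in list(dag):
        visit(term)
    return memo


def propagate_annotations(annot: dict[str, set[str]],
                          dag: dict[str, set[str]]) -> dict[str, set[str]]:
    """True-path propagation: every annotation also applies to ancestors."""
    anc = _ancestors(dag)
    out: dict[str, set[str]] = {t: set(s) for t, s in annot.items()}
    for term, transcripts in annot.items():
        for parent in anc.get(term, ()):
            out.setdefault(parent, set()).update(transcripts)
    return out


def hypergeom_enrich(foreground: set[str], background: set[str],
                     annot: dict[str, set[str]]) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric test of every term with K >= 1.

    The universe is restricted to annotated background transcripts;
    unannotated members of the foreground/background are dropped (with a
    logged count).  Raises if the foreground is not a subset of the
    background.
    """
    if not foreground <= background:
        raise AnnotationError("foreground must be a subset of background")
    annotated = set().union(*annot.values()) if annot else set()
    bg = background & annotated
    fg = foreground & bg
    dropped = len(background) - len(bg)
    if dropped:
        logger.info("dropped %d unannotated background transcripts", dropped)
    N, n = len(bg), len(fg)
    rows = []
    for term in sorted(annot):
        members = annot[term] & bg
        K = len(members)
        if K < 1:
            continue
        k = len(members & fg)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        rows.append(EnrichmentRow(term, k, n, K, N, min(p, 1.0)))
    q = bh_adjust([r.p for r in rows])
    for r, qi in zip(rows, q):
        r.q = float(qi)
    return rows


def enrichment_report(rows: list[EnrichmentRow], alpha: float = 0.05,
                      min_transcripts: int | None = None) -> pd.DataFrame:
    """Significant terms (q < alpha), sorted by q.

    With *min_transcripts* set, terms must additionally have strictly more
    than that many foreground members — the reporting filter used for
    network-wide term summaries.
    """
    keep = [r for r in rows if r.q < alpha]
    if min_transcripts is not None:
        keep = [r for r in keep if r.k > min_transcripts]
    keep.sort(key=lambda r: (r.q, r.p, r.term))
    return pd.DataFrame(
        [{"term": r.term, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
          "p": r.p, "q": r.q} for r in keep],
        columns=["term", "k", "n", "K", "N", "p", "q"])
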