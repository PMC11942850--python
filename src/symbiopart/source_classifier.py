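"""Transcript source partitioning from similarity-search hit tables.

Each assembled transcript from a whole-body lower-termite metatranscriptome
is assigned to one of three sources from its nucleotide similarity hits:

* ``TERMITE`` — best hit inside the host clade (Blattodea, taxid 85823),
  and no substantial off-clade alignment outside the best-hit region;
* ``FLAGELLATE`` — best hit inside the hindgut symbiont clade (Metamonada,
  taxid 2611341), same conflict-freedom condition;
* ``UNCLEAR`` — everything else, including transcripts with no hits.

Flagellate transcripts are further resolved by a top-five consensus: the
five highest-ranking Metamonada hits must all exceed 80% identity and agree
on one order to assign an order, and all exceed 90% identity and agree on
one genus to assign a genus.  Transcripts with fewer than five qualifying
hits stay unresolved under the strict (default) rule; ``min_consensus_hits``
relaxes this.

Hit tables are the standard 12-column tabular alignment format plus a
13th subject-taxid column, no header.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .taxonomy import TaxonomyTable

TERMITE = "termite"
FLAGELLATE = "flagellate"
UNCLEAR = "unclear"

BLATTODEA_TAXID = 85823
METAMONADA_TAXID = 2611341

HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore staxid"
).split()


class HitTableError(ValueError):
    """Raised for malformed hit-table rows."""


@dataclass(frozen=True)
class HitRecord:
    """One alignment between a query transcript and a database subject."""

    qseqid: str
    sseqid: str
    pident: float      # percent identity, 0-100
    length: int        # aligned columns
    mismatch: int
    gapopen: int
    qstart: int        # 1-based inclusive, qstart <= qend
    qend: int
    sstart: int        # may be inverted for minus-strand subjects
    send: int
    evalue: float
    bitscore: float
    staxid: int

    def __post_init__(self):
        if not (0.0 <= self.pident <= 100.0):
            raise HitTableError(f"pident {self.pident} outside [0, 100]")
        if self.qstart > self.qend:
            raise HitTableError(f"qstart {self.qstart} > qend {self.qend}")
        if self.evalue < 0:
            raise HitTableError(f"negative evalue {self.evalue}")


@dataclass(frozen=True)
class ClassifierParams:
    host_clade: int = BLATTODEA_TAXID
    symbiont_clade: int = METAMONADA_TAXID
    evalue_cutoff: float = 1e-5
    tolerance_bp: int = 30       # off-clade bases allowed outside best-hit region
    order_pident: float = 80.0   # strict > comparisons
    genus_pident: float = 90.0
    n_consensus_hits: int = 5
    min_consensus_hits: int = 5  # lower to allow <5-hit consensus


@dataclass
class SourceCall:
    """Per-transcript source verdict with consensus order/genus when resolved."""

    transcript: str
    source: str                       # TERMITE | FLAGELLATE | UNCLEAR
    order: int | None = None          # taxid; FLAGELLATE only
    genus: int | None = None          # taxid; implies order
    best_hit: HitRecord | None = None
    trace: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.source != FLAGELLATE and (self.order or self.genus):
            raise ValueError("order/genus only valid for flagellate calls")


def parse_hits(path: str | Path,
               evalue_cutoff: float = 1e-5) -> dict[str, list[HitRecord]]:
    """Read a 13-column hit table, dropping hits above the E-value cutoff.

    The cutoff is inclusive: hits with ``evalue <= cutoff`` are retained.
    Malformed rows raise :class:`HitTableError` naming the line number.
    """
    hits: dict[str, list[HitRecord]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 13:
                raise HitTableError(
                    f"{path}:{lineno}: expected 13 columns, got {len(fields)}"
                )
            try:
                rec = HitRecord(
                    qseqid=fields[0], sseqid=fields[1],
                    pident=float(fields[2]), length=int(fields[3]),
                    mismatch=int(fields[4]), gapopen=int(fields[5]),
                    qstart=int(fields[6]), qend=int(fields[7]),
                    sstart=int(fields[8]), send=int(fields[9]),
                    evalue=float(fields[10]), bitscore=float(fields[11]),
                    staxid=int(fields[12]),
                )
            except (ValueError, HitTableError) as exc:
                raise HitTableError(f"{path}:{lineno}: {exc}") from None
            if rec.evalue <= evalue_cutoff:
                hits.setdefault(rec.qseqid, []).append(rec)
    return hits


def _hit_rank_key(hit: HitRecord) -> tuple:
    """Composite sort key: best hit first, deterministic under ties."""
    return (-hit.bitscore, hit.evalue, -hit.pident, hit.sseqid)


def best_hit(hits: list[HitRecord]) -> HitRecord:
    """Highest-bitscore hit; ties broken by lower E-value, higher identity,
    then lexicographically smallest subject id."""
    if not hits:
        raise ValueError("empty hit list")
    return min(hits, key=_hit_rank_key)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _bases_outside(iv: tuple[int, int], region: list[tuple[int, int]]) -> int:
    """Bases of the 1-based inclusive interval not covered by *region*."""
    s, e = iv
    covered = 0
    for rs, re in region:
        lo, hi = max(s, rs), min(e, re)
        if lo <= hi:
            covered += hi - lo + 1
    return (e - s + 1) - covered


def conflict_free(hits: list[HitRecord], best: HitRecord,
                  focal_clade: int, tax: TaxonomyTable,
                  tolerance_bp: int = 30) -> bool:
    """Check the off-clade conflict rule for one transcript.

    Let B be the union of query intervals of all alignments to the
    best-scoring subject (multi-HSP subjects count as one match).  The
    transcript fails iff any hit whose subject lies outside *focal_clade*
    aligns more than *tolerance_bp* query bases outside B.
    """
    region = _merge_intervals(
        [(h.qstart, h.qend) for h in hits if h.sseqid == best.sseqid]
    )
    for hit in hits:
        if tax.in_clade(hit.staxid, focal_clade):
            continue
        if _bases_outside((hit.qstart, hit.qend), region) > tolerance_bp:
            return False
    return True


def _consensus(metamonada_hits: list[HitRecord], tax: TaxonomyTable,
               params: ClassifierParams,
               trace: list[str]) -> tuple[int | None, int | None]:
    """Top-five consensus order/genus resolution for a flagellate call."""
    top = sorted(metamonada_hits, key=_hit_rank_key)[: params.n_consensus_hits]
    if len(top) < params.min_consensus_hits:
        trace.append(f"consensus: only {len(top)} symbiont hits, need "
                     f">={params.min_consensus_hits}")
        return None, None

    order = None
    if all(h.pident > params.order_pident for h in top):
        orders = {tax.ancestor_at_rank(h.staxid, "order") for h in top}
        if len(orders) == 1 and None not in orders:
            order = orders.pop()
            trace.append(f"consensus order {tax.name(order)}")
    if order is None:
        trace.append("no order consensus")
        return None, None

    genus = None
    if all(h.pident > params.genus_pident for h in top):
        genera = {tax.ancestor_at_rank(h.staxid, "genus") for h in top}
        if len(genera) == 1 and None not in genera:
            cand = genera.pop()
            # genus must be lineage-consistent with the assigned order
            if tax.in_clade(cand, order):
                genus = cand
                trace.append(f"consensus genus {tax.name(genus)}")
            else:
                trace.append("genus/order lineage conflict; genus dropped")
    return order, genus


def classify_transcript(transcript: str, hits: list[HitRecord],
                        tax: TaxonomyTable,
                        params: ClassifierParams = ClassifierParams()
                        ) -> SourceCall:
    """Assign one transcript to termite / flagellate / unclear.

    UNCLEAR is the fallback for every non-qualifying configuration; this
    function never raises for hit-content reasons.
    """
    trace: list[str] = []
    if not hits:
        return SourceCall(transcript, UNCLEAR, trace=["no hits"])
    best = best_hit(hits)
    trace.append(f"best hit {best.sseqid} bitscore {best.bitscore}")

    for clade, label in ((params.host_clade, TERMITE),
                         (params.symbiont_clade, FLAGELLATE)):
        if tax.in_clade(best.staxid, clade):
            if not conflict_free(hits, best, clade, tax, params.tolerance_bp):
                trace.append("off-clade alignment outside best-hit region")
                return SourceCall(transcript, UNCLEAR, best_hit=best,
                                  trace=trace)
            trace.append(f"best hit within {label} clade, conflict-free")
            if label == TERMITE:
                return SourceCall(transcript, TERMITE, best_hit=best,
                                  trace=trace)
            mm_hits = [h for h in hits
                       if tax.in_clade(h.staxid, params.symbiont_clade)]
            order, genus = _consensus(mm_hits, tax, params, trace)
            return SourceCall(transcript, FLAGELLATE, order=order,
                              genus=genus, best_hit=best, trace=trace)
    trace.append("best hit outside both focal clades")
    return SourceCall(transcript, UNCLEAR, best_hit=best, trace=trace)


def classify_all(hits_by_query: dict[str, list[HitRecord]],
                 tax: TaxonomyTable,
                 params: ClassifierParams = ClassifierParams(),
                 all_transcripts: list[str] | None = None
                 ) -> dict[str, SourceCall]:
    """Classify every transcript; ids in *all_transcripts* without hits
    become UNCLEAR calls."""
    ids = list(all_transcripts) if all_transcripts is not None \
        else sorted(hits_by_query)
    return {
        t: classify_transcript(t, hits_by_query.get(t, []), tax, params)
        for t in ids
    }


UNCLASSIFIED = "unclassified"
OTHER_GENE = "others"


def tabulate_sources(calls: dict[str, SourceCall] | list[SourceCall],
                     gene_labels: dict[str, str],
                     tax: TaxonomyTable | None = None) -> pd.DataFrame:
    """Cross-tabulate flagellate calls by gene class and consensus order.

    Rows are gene classes (18S rRNA, actin, ..., others) plus a ``total``
    row; columns are order names plus ``unclassified`` and a ``total``
    column.  Transcripts missing from *gene_labels* are counted under
    ``others`` with a warning.
    """
    if isinstance(calls, dict):
        calls = list(calls.values())
    rows = []
    n_missing = 0
    for call in calls:
        if call.source != FLAGELLATE:
            continue
        gene = gene_labels.get(call.transcript)
        if gene is None:
            gene = OTHER_GENE
            n_missing += 1
        if call.order is None:
            order_name = UNCLASSIFIED
        elif tax is not None:
            order_name = tax.name(call.order)
        else:
            order_name = str(call.order)
        rows.append((gene, order_name))
    if n_missing:
        warnings.warn(f"{n_missing} flagellate transcripts missing from "
                      f"gene_labels; counted as '{OTHER_GENE}'",
                      stacklevel=2)
    if not rows:
        return pd.DataFrame({"total": pd.Series({"total": 0})})
    df = pd.DataFrame(rows, columns=["gene", "order"])
    table = pd.crosstab(df["gene"], df["order"])
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table


def tabulate_genus_calls(calls: dict[str, SourceCall] | list[SourceCall],
                         gene_labels: dict[str, str],
                         tax: TaxonomyTable | None = None) -> pd.DataFrame:
    """One row per genus-resolved flagellate call (gene, genus, order)."""
    if isinstance(calls, dict):
        calls = list(calls.values())
    rows = []
    for call in calls:
        if call.source != FLAGELLATE or call.genus is None:
            continue
        genus = tax.name(call.genus) if tax else str(call.genus)
        order = tax.name(call.order) if tax else str(call.order)
        rows.append({
            "transcript": call.transcript,
            "gene": gene_labels.get(call.transcript, OTHER_GENE),
            "genus": genus,
            "order": order,
        })
    return pd.DataFrame(rows, columns=["transcript", "gene", "genus", "order"])


def write_calls(calls: dict[str, SourceCall], path: str | Path,
                tax: TaxonomyTable | None = None) -> None:
    """Write the calls table as TSV."""
    rows = []
    for t, c in sorted(calls.items()):
        rows.append({
            "transcript": t,
            "source": c.source,
            "order_name": tax.name(c.order) if (tax and c.order) else "",
            "genus_name": tax.name(c.genus) if (tax and c.genus) else "",
            "best_sseqid": c.best_hit.sseqid if c.best_hit else "",
            "best_pident": c.best_hit.pident if c.best_hit else "",
            "rule_trace": "; ".join(c.trace),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
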